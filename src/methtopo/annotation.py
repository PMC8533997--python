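"""Probe annotation: manifest parsing, TSS-distance regions, island classes.

A 450K-style manifest assigns every probe a genomic position, an optional set
of gene annotations (semicolon-delimited parallel lists, one entry per
transcript), and a relation to the nearest CpG island (Island, N/S shore, N/S
shelf, or open sea).  On top of that this module defines three promoter-side
distance windows from the transcription start site:

* ``R1``: 1–250 bp upstream of the TSS,
* ``R2``: >250 bp to 1 kb,
* ``R3``: >1 kb to 2 kb.

Distances are strand-aware and measured on the promoter side only: a probe
downstream of every annotated TSS receives no region.  Interval bounds are
``(lower, upper]`` so that a probe exactly on a printed boundary (250 bp,
1 kb) falls in the window closer to the TSS, making the three windows a
partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "GeneEntry",
    "ProbeAnnotation",
    "TssRegionAssignment",
    "ISLAND_CLASSES",
    "FEATURE_GROUPS",
    "read_manifest",
    "assign_tss_region",
    "aggregate_island_classes",
    "feature_group_membership",
    "region_membership",
]

ISLAND_CLASSES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
FEATURE_GROUPS = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3")

# manifest spellings -> canonical tokens
_ISLAND_ALIASES = {
    "island": "Island",
    "cpg island": "Island",
    "n_shore": "N_Shore",
    "s_shore": "S_Shore",
    "n_shelf": "N_Shelf",
    "s_shelf": "S_Shelf",
    "opensea": "OpenSea",
    "open sea": "OpenSea",
    "": "OpenSea",
}
_FEATURE_ALIASES = {
    "tss200": "TSS200",
    "tss1500": "TSS1500",
    "5'utr": "UTR5",
    "utr5": "UTR5",
    "1stexon": "FirstExon",
    "firstexon": "FirstExon",
    "body": "Body",
    "3'utr": "UTR3",
    "utr3": "UTR3",
}

# window bounds in bp upstream of the TSS, as (lower-exclusive, upper-inclusive]
REGION_BOUNDS = {"R1": (0, 250), "R2": (250, 1000), "R3": (1000, 2000)}


@dataclass(frozen=True)
class GeneEntry:
    """One transcript-level annotation of a probe."""

    gene: str
    tss_pos: Optional[int]  # 1-based; None in the coordinate-free manifest dialect
    strand: str  # '+' or '-'
    feature_group: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.feature_group not in FEATURE_GROUPS:
            raise ValidationError(f"unknown feature group {self.feature_group!r}")
        if self.tss_pos is not None and self.tss_pos < 1:
            raise ValidationError("tss_pos must be >= 1 (1-based)")


@dataclass
class ProbeAnnotation:
    """One probe's genomic and feature context (the unit of region assignment)."""

    probe_id: str
    chrom: str
    pos: int  # 1-based, manifest MAPINFO convention
    design_type: str  # 'I' or 'II'
    color_channel: str = "none"  # 'red' / 'green' / 'none'
    gene_entries: list[GeneEntry] = field(default_factory=list)
    island_relation: str = "OpenSea"
    is_snp_probe: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id}: pos must be >= 1")
        if self.design_type not in ("I", "II"):
            raise ValidationError(f"probe {self.probe_id}: design_type must be 'I' or 'II'")
        if self.color_channel not in ("red", "green", "none"):
            raise ValidationError(f"probe {self.probe_id}: bad color channel")
        if self.design_type == "II" and self.color_channel != "none":
            raise ValidationError(
                f"probe {self.probe_id}: type II probes carry no color channel"
            )
        if self.island_relation not in ISLAND_CLASSES:
            raise ValidationError(
                f"probe {self.probe_id}: unknown island relation {self.island_relation!r}"
            )


@dataclass(frozen=True)
class TssRegionAssignment:
    probe_id: str
    region: Optional[str]  # 'R1' / 'R2' / 'R3' / None
    tss_distance: Optional[int]  # bp upstream; None if no upstream TSS
    anchor_gene: Optional[str]


def _norm_island(token: str) -> str:
    key = str(token).strip().lower()
    if key in ("nan", "na"):
        key = ""
    try:
        return _ISLAND_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown island relation token {token!r}") from None


def _norm_feature(token: str) -> str:
    try:
        return _FEATURE_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown gene feature group {token!r}") from None


_REQUIRED_COLUMNS = (
    "IlmnID",
    "CHR",
    "MAPINFO",
    "Infinium_Design_Type",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_UCSC_CpG_Island",
)


def _split_list(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell) == "":
        return []
    return str(cell).split(";")


def read_manifest(path) -> list[ProbeAnnotation]:
    """Parse a manifest CSV into :class:`ProbeAnnotation` records.

    Two dialects are accepted and the one used is recorded on the returned
    list as the attribute ``manifest_dialect`` is *not* attached (lists carry
    no attributes); instead the dialect is returned by
    :func:`read_manifest_with_dialect`.  ``read_manifest`` is the plain entry
    point most callers want.
    """
    probes, _ = read_manifest_with_dialect(path)
    return probes


def read_manifest_with_dialect(path) -> tuple[list[ProbeAnnotation], str]:
    """Parse a manifest CSV; also report which dialect was read.

    Dialects:

    * ``"tss-coordinate"`` — has a ``TSS_Coord`` column (semicolon list
      parallel to the gene list) giving each transcript's TSS position.  All
      region assignment functionality is available.
    * ``"illumina"`` — no TSS coordinates (the stock array manifest layout);
      gene entries are parsed with ``tss_pos=None`` and TSS-distance regions
      cannot be assigned from coordinates.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest is missing required column '{col}'")
    has_tss = "TSS_Coord" in df.columns
    dialect = "tss-coordinate" if has_tss else "illumina"

    seen: set[str] = set()
    probes: list[ProbeAnnotation] = []
    for row in df.itertuples(index=False):
        rid = str(getattr(row, "IlmnID"))
        if rid in seen:
            raise ValidationError(f"duplicate probe_id {rid!r} in manifest")
        seen.add(rid)

        genes = _split_list(getattr(row, "UCSC_RefGene_Name"))
        groups = _split_list(getattr(row, "UCSC_RefGene_Group"))
        strands = _split_list(getattr(row, "Strand", "")) if hasattr(row, "Strand") else []
        tss = _split_list(getattr(row, "TSS_Coord")) if has_tss else []
        if genes and len(groups) != len(genes):
            raise FormatError(
                f"probe {rid}: gene list and feature-group list have different "
                f"lengths ({len(genes)} vs {len(groups)})"
            )
        if genes and tss and len(tss) != len(genes):
            raise FormatError(
                f"probe {rid}: gene list and TSS_Coord list have different lengths"
            )
        if genes and strands and len(strands) not in (1, len(genes)):
            raise FormatError(f"probe {rid}: Strand list length mismatch")

        entries = []
        for k, g in enumerate(genes):
            strand = strands[k] if len(strands) == len(genes) else (strands[0] if strands else "+")
            tss_pos = int(tss[k]) if tss else None
            entries.append(GeneEntry(g, tss_pos, strand, _norm_feature(groups[k])))

        channel = str(getattr(row, "Color_Channel", "")).strip().lower() if hasattr(row, "Color_Channel") else ""
        channel = {"red": "red", "grn": "green", "green": "green"}.get(channel, "none")
        design = str(getattr(row, "Infinium_Design_Type")).strip().upper()
        snp_col = str(getattr(row, "Is_SNP")).strip().lower() in ("1", "true", "yes") if hasattr(row, "Is_SNP") else False
        probes.append(
            ProbeAnnotation(
                probe_id=rid,
                chrom=str(getattr(row, "CHR")).strip(),
                pos=int(getattr(row, "MAPINFO")),
                design_type=design,
                color_channel=channel if design == "I" else "none",
                gene_entries=entries,
                island_relation=_norm_island(getattr(row, "Relation_to_UCSC_CpG_Island")),
                is_snp_probe=snp_col or rid.startswith("rs"),
            )
        )
    return probes, dialect


def _upstream_distance(pos: int, entry: GeneEntry) -> Optional[int]:
    """Strand-aware promoter-side distance in bp; None if downstream/at TSS."""
    if entry.tss_pos is None:
        return None
    d = entry.tss_pos - pos if entry.strand == "+" else pos - entry.tss_pos
    return d if d >= 1 else None


def assign_tss_region(probe: ProbeAnnotation) -> TssRegionAssignment:
    """Assign a probe to R1/R2/R3 by its nearest upstream TSS.

    The nearest TSS wins; ties break on lexicographic gene symbol.  Probes
    with no gene entry, no TSS coordinates, or lying downstream of every
    annotated TSS get ``region=None``.  A nearest upstream TSS farther than
    2 kb also yields ``region=None`` but keeps the distance and anchor gene.
    """
    best: tuple[int, str] | None = None
    for entry in probe.gene_entries:
        d = _upstream_distance(probe.pos, entry)
        if d is None:
            continue
        cand = (d, entry.gene)
        if best is None or cand < best:
            best = cand
    if best is None:
        return TssRegionAssignment(probe.probe_id, None, None, None)
    d, gene = best
    region = None
    for name, (lo, hi) in REGION_BOUNDS.items():
        if lo < d <= hi:
            region = name
            break
    return TssRegionAssignment(probe.probe_id, region, d, gene)


def aggregate_island_classes(probes: Iterable[ProbeAnnotation]) -> dict[str, set[str]]:
    """Map each island class to its probe-id set.

    Besides the six elementary classes (which partition all probes) the
    composite classes ``N`` (N_Shore ∪ N_Shelf) and ``S`` (S_Shore ∪ S_Shelf)
    are included.
    """
    classes: dict[str, set[str]] = {c: set() for c in ISLAND_CLASSES}
    for p in probes:
        if p.island_relation not in classes:  # pragma: no cover - blocked upstream
            raise ValidationError(f"unknown island relation {p.island_relation!r}")
        classes[p.island_relation].add(p.probe_id)
    classes["N"] = classes["N_Shore"] | classes["N_Shelf"]
    classes["S"] = classes["S_Shore"] | classes["S_Shelf"]
    return classes


def feature_group_membership(probes: Iterable[ProbeAnnotation]) -> dict[str, set[str]]:
    """Map each gene-feature group to its probe-id set.

    A probe contributes once per group even when several of its transcripts
    share the group.
    """
    groups: dict[str, set[str]] = {g: set() for g in FEATURE_GROUPS}
    for p in probes:
        for entry in p.gene_entries:
            groups[entry.feature_group].add(p.probe_id)
    return groups


def region_membership(probes: Iterable[ProbeAnnotation]) -> dict[str, set[str]]:
    """Full class -> probe-id-set mapping used by the scorer.

    Combines the TSS-distance windows (R1/R2/R3), the island-relative classes
    with N/S composites, and the gene-feature groups.
    """
    probes = list(probes)
    membership: dict[str, set[str]] = {r: set() for r in REGION_BOUNDS}
    for p in probes:
        a = assign_tss_region(p)
        if a.region is not None:
            membership[a.region].add(p.probe_id)
    membership.update(aggregate_island_classes(probes))
    membership.update(feature_group_membership(probes))
    return membership
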