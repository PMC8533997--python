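"""End-to-end orchestration: config -> score tables, contrast reports, CIMP.

``run_pipeline`` reads a manifest, a signal matrix (or a precomputed β
matrix, in which case preprocessing reduces to filtering by annotation) and
a sample sheet, runs the normalization chain, computes the global methylome
scores, and emits plain-TSV reports:

* ``scores.tsv`` — per-sample score table (samples x classes);
* ``tumor_vs_normal.tsv`` — per-class median/IQR/median-difference plus
  Mann–Whitney p, overall and within each histological subtype;
* ``subtype_comparison.tsv`` — Kruskal–Wallis across subtypes plus pairwise
  Mann–Whitney per class (tumor samples);
* ``molecular_contrasts.tsv`` — MSI / KRAS / BRAF / CIMP strata contrasts;
* ``categorical_associations.tsv`` — Freeman–Halton exact tests of the
  sample-sheet categorical variables against subtype;
* ``cimp_calls.tsv`` — per-sample CIMP panel counts and categories;
* ``cimp_gene_vs_score.tsv`` — Mann–Whitney of the 250 bp score by each
  panel gene's methylation call;
* ``run_log.json`` — versions, config hash, per-stage probe counts.

Every number in a report is recomputable from ``scores.tsv`` and the sample
sheet alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import read_manifest_with_dialect, region_membership
from .cimp import OGINO8, CimpClassifier
from .containers import BetaMatrix, ScoreTable, SignalMatrix
from .errors import ValidationError
from .preprocess import (BetaMixtureQuantileCorrector, ColorBiasAdjuster,
                         ProbeFilter, QuantileNormalizer,
                         TypeBackgroundEqualizer, compute_beta, compute_m)
from .scores import score_by_class, score_deltas
from .stats import (bonferroni_report, freeman_halton_exact, kruskal_wallis,
                    mann_whitney_u)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "grouped_score_validation",
           "preprocess_signals"]

# the three TSS-window scores reported in the contrast tables
PRIMARY_CLASSES = ("R1", "R2", "R3")


@dataclass
class RunConfig:
    manifest: str = ""
    signals: str = ""  # either signals or betas must be set
    betas: str = ""
    samples: str = ""
    out_dir: str = "mtopo_out"
    detect_threshold: float = 0.01
    sample_fraction: float = 0.95
    beta_offset: float = 100.0
    m_alpha: float = 100.0
    ogino_high_min: int = 6
    # Bonferroni divisors per report family
    divisor_categorical: int = 15
    divisor_normal_mucosa: int = 5
    divisor_tumor_features: int = 11
    divisor_molecular: int = 5
    score_classes: list = field(default_factory=list)  # empty = all available
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (output path excluded)."""
        params = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preprocess_signals(signals: SignalMatrix, manifest, config: RunConfig):
    """Run the fixed normalization chain; returns (BetaMatrix, stage counts)."""
    filt = ProbeFilter(manifest, config.detect_threshold, config.sample_fraction)
    sig = filt.fit(signals).transform(signals)
    counts = dict(filt.counts_)
    sig = ColorBiasAdjuster(manifest).transform(sig)
    sig = QuantileNormalizer().transform(sig)
    sig = TypeBackgroundEqualizer(manifest).transform(sig)
    betas = compute_beta(sig, config.beta_offset)
    betas = BetaMixtureQuantileCorrector(manifest).transform(betas)
    return betas, counts, sig


def _mwu_contrast_table(scores: ScoreTable, meta: pd.DataFrame, group_col: str,
                        contrast: tuple[str, str], divisor: int,
                        classes) -> pd.DataFrame:
    """Median/IQR layout plus Mann–Whitney p and Bonferroni flag per class."""
    deltas = score_deltas(scores, meta, contrast, group_col)
    sid = pd.Index(scores.sample_ids)
    mask_a = sid.isin(meta.index[meta[group_col] == contrast[0]])
    mask_b = sid.isin(meta.index[meta[group_col] == contrast[1]])
    rows = []
    for cls_name in classes:
        if cls_name not in scores.classes:
            continue
        v = scores[cls_name]
        res = mann_whitney_u(v[mask_a], v[mask_b])
        res = bonferroni_report([res], divisor)[0]
        row = deltas.loc[cls_name].to_dict()
        row.update({"class": cls_name, "group_a": contrast[0], "group_b": contrast[1],
                    "p": res.p_value, "method": res.method,
                    "bonferroni_m": divisor, "significant": res.significant})
        rows.append(row)
    return pd.DataFrame(rows)


def grouped_score_validation(scores: ScoreTable, grouping, classes=None) -> pd.DataFrame:
    """Kruskal–Wallis across >=2 groups per class plus pairwise Mann–Whitney.

    ``grouping`` maps sample id -> group label.  Singleton groups take part
    in the Kruskal–Wallis test but are skipped for pairwise comparisons.
    Output has one Kruskal–Wallis row plus one row per compared pair, per
    class.
    """
    grouping = dict(grouping)
    labels = sorted(set(grouping.values()))
    if len(labels) < 2:
        raise ValidationError("grouped comparison needs at least 2 groups")
    classes = list(classes) if classes else list(scores.classes)
    sid = np.array(scores.sample_ids)
    members = {g: np.array([grouping.get(s) == g for s in sid]) for g in labels}
    rows = []
    for cls_name in classes:
        v = scores[cls_name]
        groups = [v[members[g]] for g in labels]
        kw = kruskal_wallis(groups)
        rows.append({"class": cls_name, "comparison": "all", "test": kw.method,
                     "statistic": kw.statistic, "p": kw.p_value,
                     "n": "/".join(str(int(members[g].sum())) for g in labels)})
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if members[a].sum() < 2 or members[b].sum() < 2:
                    log.warning("pairwise %s vs %s skipped (singleton group)", a, b)
                    continue
                res = mann_whitney_u(v[members[a]], v[members[b]])
                rows.append({"class": cls_name, "comparison": f"{a} vs {b}",
                             "test": res.method, "statistic": res.statistic,
                             "p": res.p_value,
                             "n": f"{int(members[a].sum())}/{int(members[b].sum())}"})
    return pd.DataFrame(rows)


def _categorical_tables(meta: pd.DataFrame, divisor: int) -> pd.DataFrame:
    """Freeman–Halton tests of each categorical variable against subtype."""
    tumors = meta[meta["tissue"] == "tumor"]
    rows = []
    for var in ("sex", "age_group", "location", "BRAF", "KRAS", "MSI",
                "cimp_w", "cimp_ogino"):
        if var not in tumors.columns:
            continue
        sub = tumors[[var, "subtype"]].dropna()
        sub = sub[(sub[var] != "NA") & (sub[var] != "")]
        if sub.empty:
            continue
        table = pd.crosstab(sub["subtype"], sub[var])
        if table.shape[0] < 2 or table.shape[1] < 2:
            log.warning("categorical association for %r skipped (degenerate table)", var)
            continue
        res = freeman_halton_exact(table.to_numpy())
        res = bonferroni_report([res], divisor)[0]
        rows.append({"variable": var, "levels": "x".join(map(str, table.shape)),
                     "n": int(table.to_numpy().sum()), "p": res.p_value,
                     "method": res.method, "bonferroni_m": divisor,
                     "significant": res.significant})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict of frames."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest, dialect = read_manifest_with_dialect(config.manifest)
    meta = pd.read_csv(config.samples, index_col=0)
    counts: dict = {}
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if config.signals:
            signals = SignalMatrix.read_tsv(config.signals)
            betas, counts, _ = preprocess_signals(signals, manifest, config)
        elif config.betas:
            raw = BetaMatrix.read_tsv(config.betas)
            filt = ProbeFilter(manifest, config.detect_threshold, config.sample_fraction)
            keep = [
                p.probe_id for p in manifest
                if not p.is_snp_probe and p.chrom not in {"X", "Y", "chrX", "chrY"}
                and p.probe_id in set(raw.probe_ids)
            ]
            counts = {"retained": len(keep),
                      "removed": len(raw.probe_ids) - len(keep)}
            idx = [raw.probe_ids.index(p) for p in keep]
            betas = BetaMatrix(keep, raw.sample_ids, raw.values[idx])
            del filt
        else:
            raise ValidationError("config must set either 'signals' or 'betas'")

        membership = region_membership(manifest)
        present = set(betas.probe_ids)
        membership = {k: v & present for k, v in membership.items() if v & present}
        scores = score_by_class(betas, membership)
        captured = [str(w.message) for w in wlist]

    # CIMP classification from panel-call columns, if present
    cimp_frame = pd.DataFrame()
    if any(f"cimp_{g}" in meta.columns for g in OGINO8):
        cimp_frame = CimpClassifier(config.ogino_high_min).predict(meta)
        meta = meta.join(cimp_frame)

    classes = config.score_classes or list(scores.classes)
    reports: dict[str, pd.DataFrame] = {}

    # tumor vs normal: overall and within subtype
    tn_rows = []
    if {"tumor", "normal"} <= set(meta["tissue"]):
        t = _mwu_contrast_table(scores, meta, "tissue", ("tumor", "normal"),
                                config.divisor_normal_mucosa, classes)
        t.insert(0, "stratum", "all")
        tn_rows.append(t)
        for subtype in sorted(meta["subtype"].dropna().unique()):
            sub = meta[meta["subtype"] == subtype]
            if sub["tissue"].nunique() < 2:
                log.warning("tumor-vs-normal within %r skipped (empty stratum)", subtype)
                continue
            t = _mwu_contrast_table(scores, sub, "tissue", ("tumor", "normal"),
                                    config.divisor_normal_mucosa, classes)
            t.insert(0, "stratum", subtype)
            tn_rows.append(t)
    if tn_rows:
        reports["tumor_vs_normal"] = pd.concat(tn_rows, ignore_index=True)

    tumors = meta[meta["tissue"] == "tumor"]
    if tumors["subtype"].nunique() >= 2:
        grouping = tumors["subtype"].to_dict()
        sub_scores_mask = [s in grouping for s in scores.sample_ids]
        sub_scores = ScoreTable(
            [s for s in scores.sample_ids if s in grouping],
            list(scores.classes),
            scores.values[np.array(sub_scores_mask)],
            scores.n_probes,
        )
        reports["subtype_comparison"] = grouped_score_validation(
            sub_scores, grouping, classes)

    # molecular strata on tumor samples
    mol_rows = []
    for var, (a, b) in {
        "MSI": ("MSI-H", "MSS"), "KRAS": ("mut", "WT"), "BRAF": ("mut", "WT"),
        "cimp_w": ("high", "low"), "cimp_ogino": ("high", "low"),
    }.items():
        if var not in tumors.columns:
            continue
        if not ((tumors[var] == a).any() and (tumors[var] == b).any()):
            log.warning("molecular contrast %r skipped (empty stratum)", var)
            continue
        t = _mwu_contrast_table(scores, tumors, var, (a, b),
                                config.divisor_molecular, classes)
        t.insert(0, "variable", var)
        mol_rows.append(t)
    if mol_rows:
        reports["molecular_contrasts"] = pd.concat(mol_rows, ignore_index=True)

    reports["categorical_associations"] = _categorical_tables(
        meta, config.divisor_categorical)

    if not cimp_frame.empty:
        reports["cimp_calls"] = cimp_frame
        # per-panel-gene comparison of the 250 bp score (methylated vs not)
        gene_rows = []
        if "R1" in scores.classes:
            v = scores["R1"]
            sid = np.array(scores.sample_ids)
            tumor_ids = set(tumors.index.astype(str))
            tmask = np.array([s in tumor_ids for s in sid])
            for gene in OGINO8:
                col = f"cimp_{gene}"
                if col not in meta.columns:
                    continue
                call = meta.reindex(sid)[col].astype(str).str.upper()
                methylated = call.isin(("M", "P")).to_numpy() & tmask
                unmethylated = (call == "U").to_numpy() & tmask
                if methylated.sum() == 0 or unmethylated.sum() == 0:
                    continue
                res = mann_whitney_u(v[methylated], v[unmethylated])
                gene_rows.append({
                    "gene": gene, "n_methylated": int(methylated.sum()),
                    "n_unmethylated": int(unmethylated.sum()),
                    "median_difference": float(np.median(v[methylated])
                                               - np.median(v[unmethylated])),
                    "p": res.p_value, "method": res.method,
                })
        if gene_rows:
            reports["cimp_gene_vs_score"] = pd.DataFrame(gene_rows)

    # write everything
    scores.write_tsv(out / "scores.tsv")
    for name, frame in reports.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=name == "cimp_calls")
    run_log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "manifest_dialect": dialect,
        "n_samples": int(len(meta)),
        "probe_counts": counts,
        "n_score_classes": len(scores.classes),
        "warnings": captured,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    reports["scores"] = scores.to_frame()
    reports["run_log"] = run_log
    return reports
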