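"""Synthetic 450K-style cohort generation.

The generator emulates the data structure the analysis consumes: a probe
manifest with per-gene TSS geometry (an island overlapping the TSS, shores
within 2 kb of its edges, shelves in the next 2 kb, open sea beyond), a
methylated/unmethylated intensity matrix with detection p-values, and a
sample sheet with tissue, histological subtype, demographics, molecular
calls and CIMP panel calls.

Methylation model
-----------------
Each probe gets a bimodal baseline β (low mode ~0.10, high mode ~0.85, with
an island-class-specific high-mode weight and probe-level logit jitter).
Tumor effects are additive on the logit scale; the logit shift for each
(effect class, subtype) pair is calibrated numerically so that the planted
β-scale class-mean difference equals the configured target, and the achieved
values are written to the truth record.  Each sample carries a trivariate
Gaussian random effect (proximal / mid / distal components, one per probe
stratum) whose correlation structure sets the between-region score
correlations; β values are then drawn from a beta distribution with
configurable precision, converted to intensities through a log-normal total
intensity, and perturbed with the artifacts the preprocessing chain is built
to remove (type-I color bias, type-II β compression, detection failures,
SNP and sex-chromosome probes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ProbeAnnotation, read_manifest
from .containers import SignalMatrix
from .errors import ValidationError

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_manifest",
           "generate_cohort", "write_fixture", "read_fixture"]

SUBTYPES = ("CC", "SAC", "hmMSI-H")
EFFECT_CLASSES = ("R1", "R2", "R3", "Island", "N_Shore", "S_Shore",
                  "N_Shelf", "S_Shelf", "OpenSea")
# probe stratum driving the shared per-sample random effect
_COMPONENT = {"R1": 0, "Island": 0, "R2": 1, "N_Shore": 1, "S_Shore": 1,
              "R3": 2, "N_Shelf": 2, "S_Shelf": 2, "OpenSea": 2}

_CIMP_GENES = ("CACNA1G", "CDKN2A", "CRABP1", "IGF2", "MLH1", "NEUROG1",
               "RUNX3", "SOCS1")


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _default_effects() -> dict:
    # β-scale tumor-vs-normal class-mean targets per subtype: hypermethylation
    # nearest the TSS/island (strongest in hmMSI-H), hypomethylation at 1-2 kb,
    # shelves and open sea (strongest in CC), SAC intermediate.  The
    # study-composition-weighted overall R1/R2/R3 deltas are about
    # +0.0036 / -0.0116 / -0.0384.
    return {
        "CC": {"R1": 0.001, "R2": -0.016, "R3": -0.050, "Island": 0.002,
               "N_Shore": -0.012, "S_Shore": -0.012, "N_Shelf": -0.050,
               "S_Shelf": -0.050, "OpenSea": -0.045},
        "SAC": {"R1": 0.004, "R2": -0.010, "R3": -0.035, "Island": 0.006,
                "N_Shore": -0.008, "S_Shore": -0.008, "N_Shelf": -0.035,
                "S_Shelf": -0.035, "OpenSea": -0.030},
        "hmMSI-H": {"R1": 0.010, "R2": -0.004, "R3": -0.015, "Island": 0.012,
                    "N_Shore": -0.003, "S_Shore": -0.003, "N_Shelf": -0.015,
                    "S_Shelf": -0.015, "OpenSea": -0.012},
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 0
    n_genes: int = 2000
    probes_per_gene: dict = field(
        default_factory=lambda: {"R1": 2, "R2": 2, "R3": 2, "none": 4})
    island_half_width: int = 680
    shore_width: int = 2000
    shelf_width: int = 2000
    # samples per (tissue, subtype) cell; study composition by default
    n_samples: dict = field(default_factory=lambda: {
        ("tumor", "CC"): 32, ("tumor", "SAC"): 40, ("tumor", "hmMSI-H"): 10,
        ("normal", "CC"): 14, ("normal", "SAC"): 15, ("normal", "hmMSI-H"): 6,
    })
    # bimodal baseline
    low_mode: float = 0.10
    high_mode: float = 0.85
    probe_jitter_sd: float = 0.3
    high_weight: dict = field(default_factory=lambda: {
        "Island": 0.22, "N_Shore": 0.717, "S_Shore": 0.717,
        "N_Shelf": 0.78, "S_Shelf": 0.78, "OpenSea": 0.80,
    })
    # planted β-scale effects per subtype and effect class
    effects: dict = field(default_factory=_default_effects)
    beta_precision: float = 200.0
    sample_effect_sd: dict = field(
        default_factory=lambda: {"tumor": 0.04, "normal": 0.02})
    # target Spearman correlations between per-sample proximal/mid/distal effects
    spearman_prox_mid: float = 0.542
    spearman_mid_dist: float = 0.883
    spearman_prox_dist: float = 0.268
    # intensities and planted artifacts
    total_intensity_median: float = 6000.0
    total_intensity_sigma: float = 0.3
    beta_offset_emulated: float = 100.0
    type1_fraction: float = 0.3
    color_bias_factor: float = 1.3
    # mild dynamic-range narrowing of type-II chemistry; keeps the β modes
    # inside their unmethylated/methylated states
    type2_compression: float = 0.9
    detection_p_scale: float = 0.005
    sporadic_failure_rate: float = 0.001
    dead_probe_rate: float = 0.005
    dead_probe_fail_fraction: float = 0.3
    snp_fraction: float = 0.01
    sex_fraction: float = 0.02
    # sample-sheet models (probabilities per subtype)
    p_female: dict = field(default_factory=lambda: {
        "CC": 0.47, "SAC": 0.525, "hmMSI-H": 0.8})
    p_proximal: dict = field(default_factory=lambda: {
        "CC": 0.594, "SAC": 0.70, "hmMSI-H": 1.0})
    p_braf_mut: dict = field(default_factory=lambda: {
        "CC": 0.031, "SAC": 0.30, "hmMSI-H": 0.40})
    p_kras_mut: dict = field(default_factory=lambda: {
        "CC": 0.469, "SAC": 0.375, "hmMSI-H": 0.20})
    p_msi_high: dict = field(default_factory=lambda: {
        "CC": 0.0, "SAC": 0.175, "hmMSI-H": 0.70})
    cimp_gene_p: dict = field(default_factory=lambda: {
        "CC": 0.10, "SAC": 0.45, "hmMSI-H": 0.75})
    cimp_partial_fraction: float = 0.2
    cimp_normal_p: float = 0.02

    def __post_init__(self):
        for w in self.high_weight.values():
            if not 0.0 <= w <= 1.0:
                raise ValidationError("high-mode weights must lie in [0, 1]")
        if self.shore_width <= 0 or self.shelf_width <= 0:
            raise ValidationError("shore/shelf widths must be positive")
        if self.beta_precision <= 0:
            raise ValidationError("beta precision must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "n_samples" in d and not isinstance(next(iter(d["n_samples"])), tuple):
            # YAML form: {"tumor/SAC": 35, ...}
            d["n_samples"] = {tuple(k.split("/")): v for k, v in d["n_samples"].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    manifest: list[ProbeAnnotation]
    manifest_frame: pd.DataFrame  # internal per-probe table (writing + truth)
    signals: SignalMatrix
    samples: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# manifest geometry


def _build_manifest_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ih = config.island_half_width
    rows = []
    pid = 0
    for g in range(config.n_genes):
        chrom = str(1 + g % 22)
        tss = 100_000 + (g // 22) * 60_000
        strand = "+" if g % 2 == 0 else "-"
        sign = -1 if strand == "+" else 1  # upstream direction in coordinates

        def add(offset_upstream: int | None, offset_downstream: int | None,
                region: str | None, feature: str | None):
            nonlocal pid
            if offset_upstream is not None:
                pos = tss + sign * offset_upstream
            else:
                pos = tss - sign * offset_downstream
            # island-relative class from geometry (N = lower-coordinate side)
            d_island = 0
            side = ""
            if pos < tss - ih:
                d_island = (tss - ih) - pos
                side = "N"
            elif pos > tss + ih:
                d_island = pos - (tss + ih)
                side = "S"
            if d_island == 0:
                rel = "Island"
            elif d_island <= config.shore_width:
                rel = f"{side}_Shore"
            elif d_island <= config.shore_width + config.shelf_width:
                rel = f"{side}_Shelf"
            else:
                rel = "OpenSea"
            rows.append({
                "probe_id": f"cg{pid:08d}", "chrom": chrom, "pos": int(pos),
                "strand": strand, "gene": f"GENE{g:05d}",
                "tss": tss if feature is not None else None,
                "feature_group": feature, "island_relation": rel,
                "region": region,
            })
            pid += 1

        for _ in range(config.probes_per_gene.get("R1", 0)):
            d = int(rng.integers(1, 251))
            add(d, None, "R1", "TSS200" if d <= 200 else "TSS1500")
        for _ in range(config.probes_per_gene.get("R2", 0)):
            d = int(rng.integers(251, 1001))
            add(d, None, "R2", "TSS1500")
        for _ in range(config.probes_per_gene.get("R3", 0)):
            d = int(rng.integers(1001, 2001))
            add(d, None, "R3", "TSS1500")
        # non-region probes cycle through the remaining island classes
        recipes = [
            ("shore_down", lambda: int(rng.integers(ih + 1, ih + config.shore_width + 1)), "Body"),
            ("shelf_up", None, None),   # upstream shelf, intergenic
            ("shelf_down", lambda: int(rng.integers(ih + config.shore_width + 1,
                                                    ih + config.shore_width + config.shelf_width + 1)), "UTR3"),
            ("opensea", lambda: int(rng.integers(ih + config.shore_width + config.shelf_width + 1500,
                                                 ih + config.shore_width + config.shelf_width + 6000)), None),
        ]
        for k in range(config.probes_per_gene.get("none", 0)):
            kind, sampler, feature = recipes[k % len(recipes)]
            if kind == "shelf_up":
                d = int(rng.integers(ih + config.shore_width + 1,
                                     ih + config.shore_width + config.shelf_width + 1))
                add(d + 0, None, None, None)  # upstream, >2 kb from TSS: no region
            else:
                add(None, sampler(), None, feature)

    df = pd.DataFrame(rows)
    n = len(df)
    # planted nuisance probes: SNP-measuring and sex-chromosome probes
    nuisance = rng.permutation(n)
    n_snp = int(round(config.snp_fraction * n))
    n_sex = int(round(config.sex_fraction * n))
    snp_idx = nuisance[:n_snp]
    sex_idx = nuisance[n_snp:n_snp + n_sex]
    df["is_snp"] = False
    df.loc[snp_idx, "is_snp"] = True
    df.loc[snp_idx, "probe_id"] = [f"rs{i:08d}" for i in snp_idx]
    df.loc[sex_idx, "chrom"] = "X"
    # design types and channels
    t1 = rng.random(n) < config.type1_fraction
    df["design_type"] = np.where(t1, "I", "II")
    chan = np.where(rng.random(n) < 0.5, "red", "green")
    df["color_channel"] = np.where(t1, chan, "none")
    # dead probes (will fail the detection filter)
    df["dead"] = rng.random(n) < config.dead_probe_rate
    df["effect_class"] = df["region"].where(df["region"].notna(), df["island_relation"])
    df["component"] = df["effect_class"].map(_COMPONENT)
    df["clean"] = ~(df["is_snp"] | (df["chrom"] == "X") | df["dead"])
    return df


def _frame_to_annotations(df: pd.DataFrame) -> list[ProbeAnnotation]:
    from .annotation import GeneEntry

    probes = []
    for row in df.itertuples(index=False):
        entries = []
        if row.feature_group is not None and row.tss is not None:
            entries = [GeneEntry(row.gene, int(row.tss), row.strand, row.feature_group)]
        probes.append(ProbeAnnotation(
            probe_id=row.probe_id, chrom=str(row.chrom), pos=int(row.pos),
            design_type=row.design_type,
            color_channel=row.color_channel if row.design_type == "I" else "none",
            gene_entries=entries, island_relation=row.island_relation,
            is_snp_probe=bool(row.is_snp),
        ))
    return probes


def generate_manifest(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[ProbeAnnotation]:
    """Generate the probe annotations alone (geometry and nuisance planting)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return _frame_to_annotations(_build_manifest_frame(config, rng))


# ---------------------------------------------------------------------------
# cohort generation


def _calibrate_shift(b0: np.ndarray, target: float) -> float:
    """Logit shift moving the class-mean β by `target` (monotone bisection)."""
    if target == 0.0 or len(b0) == 0:
        return 0.0
    base = b0.mean()
    x0 = _logit(b0)

    def achieved(delta):
        return _invlogit(x0 + delta).mean() - base

    lo, hi = -8.0, 8.0
    if not (achieved(lo) <= target <= achieved(hi)):
        raise ValidationError(f"target β delta {target} is unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if achieved(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for (tissue, subtype), count in sorted(config.n_samples.items()):
        for k in range(count):
            sid = f"{'T' if tissue == 'tumor' else 'N'}_{subtype}_{k:03d}"
            age = int(np.clip(round(rng.normal(71, 9)), 40, 95))
            row = {
                "sample_id": sid, "tissue": tissue, "subtype": subtype,
                "age": age, "age_group": "<=71" if age <= 71 else ">=72",
                "sex": "F" if rng.random() < config.p_female[subtype] else "M",
                "location": "proximal" if rng.random() < config.p_proximal[subtype] else "distal",
            }
            if tissue == "tumor":
                row["BRAF"] = "mut" if rng.random() < config.p_braf_mut[subtype] else "WT"
                row["KRAS"] = "mut" if rng.random() < config.p_kras_mut[subtype] else "WT"
                row["MSI"] = "MSI-H" if rng.random() < config.p_msi_high[subtype] else "MSS"
                p_gene = config.cimp_gene_p[subtype]
            else:
                row["BRAF"] = row["KRAS"] = row["MSI"] = "NA"
                p_gene = config.cimp_normal_p
            for gene in _CIMP_GENES:
                if rng.random() < p_gene:
                    call = "P" if rng.random() < config.cimp_partial_fraction else "M"
                else:
                    call = "U"
                row[f"cimp_{gene}"] = call
            rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _latent_corr(config: SimulationConfig) -> np.ndarray:
    # Spearman target -> Pearson correlation of the latent Gaussian
    def conv(rho_s):
        return 2.0 * np.sin(np.pi * rho_s / 6.0)

    a, c, b = conv(config.spearman_prox_mid), conv(config.spearman_mid_dist), conv(config.spearman_prox_dist)
    corr = np.array([[1.0, a, b], [a, 1.0, c], [b, c, 1.0]])
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValidationError("sample-effect correlation targets are not jointly feasible")
    return corr


def generate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; bit-reproducible under the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mf = _build_manifest_frame(config, rng)
    samples = _sample_sheet(config, rng)
    n_probes, n_samples = len(mf), len(samples)

    # baseline β per probe
    is_high = rng.random(n_probes) < mf["island_relation"].map(config.high_weight).to_numpy()
    mode = np.where(is_high, config.high_mode, config.low_mode)
    b0 = _invlogit(_logit(mode) + rng.normal(0.0, config.probe_jitter_sd, n_probes))

    # calibrated logit shifts per (effect class, subtype), on clean probes
    clean = mf["clean"].to_numpy()
    eff_class = mf["effect_class"].to_numpy()
    shifts: dict[str, dict[str, float]] = {}
    achieved: dict[str, dict[str, float]] = {}
    for subtype in {s for (_, s) in config.n_samples}:
        shifts[subtype] = {}
        achieved[subtype] = {}
        for cls_name in EFFECT_CLASSES:
            target = config.effects.get(subtype, {}).get(cls_name, 0.0)
            mask = clean & (eff_class == cls_name)
            delta = _calibrate_shift(b0[mask], target)
            shifts[subtype][cls_name] = delta
            achieved[subtype][cls_name] = (
                float(_invlogit(_logit(b0[mask]) + delta).mean() - b0[mask].mean())
                if mask.any() else 0.0
            )

    # per-sample correlated random effects (proximal / mid / distal strata)
    chol = np.linalg.cholesky(_latent_corr(config))
    eps = rng.standard_normal((n_samples, 3)) @ chol.T
    sd = samples["tissue"].map(config.sample_effect_sd).to_numpy()
    eps *= sd[:, None]

    # expected β per probe x sample
    x0 = _logit(b0)
    subtype_delta = {
        s: pd.Series(eff_class).map(shifts[s]).to_numpy(float) for s in shifts
    }
    delta_mat = np.zeros((n_probes, n_samples))
    tumor = (samples["tissue"] == "tumor").to_numpy()
    subtype_col = samples["subtype"].to_numpy()
    for j in range(n_samples):
        if tumor[j]:
            delta_mat[:, j] = subtype_delta[subtype_col[j]]
    comp = mf["component"].to_numpy()
    mean_logit = x0[:, None] + delta_mat + eps[np.arange(n_samples)[None, :], comp[:, None]]
    mean_beta = np.clip(_invlogit(mean_logit), 1e-4, 1.0 - 1e-4)

    # β draws and intensities
    prec = config.beta_precision
    beta = rng.beta(mean_beta * prec, (1.0 - mean_beta) * prec)
    is_t2 = (mf["design_type"] == "II").to_numpy()
    beta_obs = beta.copy()
    beta_obs[is_t2] = 0.5 + (beta[is_t2] - 0.5) * config.type2_compression
    # total fluorescence includes the GenomeStudio β offset, so that
    # β = meth/(meth+unmeth+offset) recovers the simulated value exactly
    total = rng.lognormal(np.log(config.total_intensity_median),
                          config.total_intensity_sigma, (n_probes, n_samples))
    meth = beta_obs * total
    unmeth = np.maximum((1.0 - beta_obs) * total - config.beta_offset_emulated, 0.0)
    green_t1 = ((mf["design_type"] == "I") & (mf["color_channel"] == "green")).to_numpy()
    meth[green_t1] *= config.color_bias_factor
    unmeth[green_t1] *= config.color_bias_factor

    # detection p-values: mostly confident, with planted failures
    det = rng.uniform(0.0, config.detection_p_scale, (n_probes, n_samples))
    sporadic = rng.random((n_probes, n_samples)) < config.sporadic_failure_rate
    dead = mf["dead"].to_numpy()
    dead_fail = dead[:, None] & (rng.random((n_probes, n_samples))
                                 < config.dead_probe_fail_fraction)
    fail = sporadic | dead_fail
    det[fail] = rng.uniform(0.011, 1.0, int(fail.sum()))

    signals = SignalMatrix(list(mf["probe_id"]), list(samples.index), meth, unmeth, det)

    # truth record: expected class scores over clean probes
    b_tumor = {s: _invlogit(x0 + subtype_delta[s]) for s in shifts}
    class_members: dict[str, np.ndarray] = {}
    for cls_name in EFFECT_CLASSES:
        if cls_name in ("R1", "R2", "R3"):
            class_members[cls_name] = clean & (mf["region"] == cls_name).to_numpy()
        else:
            class_members[cls_name] = clean & (mf["island_relation"] == cls_name).to_numpy()
    class_members["N"] = class_members["N_Shore"] | class_members["N_Shelf"]
    class_members["S"] = class_members["S_Shore"] | class_members["S_Shelf"]

    tumor_counts = {s: c for (t, s), c in config.n_samples.items() if t == "tumor"}
    n_tumor = sum(tumor_counts.values())
    expected, deltas, overall = {}, {}, {}
    for cls_name, mask in class_members.items():
        if not mask.any():
            continue
        base = float(b0[mask].mean())
        expected[cls_name] = {"normal": base}
        deltas[cls_name] = {}
        for s in shifts:
            ts = float(b_tumor[s][mask].mean())
            expected[cls_name][f"tumor/{s}"] = ts
            deltas[cls_name][s] = ts - base
        if n_tumor:
            overall[cls_name] = sum(
                tumor_counts.get(s, 0) * d for s, d in deltas[cls_name].items()
            ) / n_tumor

    truth = {
        "planted_effects": config.effects,
        "achieved_class_delta": achieved,
        "expected_class_score": expected,
        "tumor_normal_delta": deltas,
        "overall_tumor_normal_delta": overall,
        "n_probes": int(n_probes),
        "n_clean_probes": int(clean.sum()),
        "artifacts": {
            "color_bias_factor": config.color_bias_factor,
            "type2_compression": config.type2_compression,
            "dead_probe_rate": config.dead_probe_rate,
            "sporadic_failure_rate": config.sporadic_failure_rate,
        },
    }
    return SyntheticCohort(_frame_to_annotations(mf), mf, signals, samples, truth)


# ---------------------------------------------------------------------------
# fixtures on disk


def _manifest_csv_frame(mf: pd.DataFrame) -> pd.DataFrame:
    has_gene = mf["feature_group"].notna() & mf["tss"].notna()
    return pd.DataFrame({
        "IlmnID": mf["probe_id"],
        "CHR": mf["chrom"],
        "MAPINFO": mf["pos"],
        "Strand": np.where(has_gene, mf["strand"], ""),
        "UCSC_RefGene_Name": np.where(has_gene, mf["gene"], ""),
        "UCSC_RefGene_Group": np.where(has_gene, mf["feature_group"], ""),
        "TSS_Coord": np.where(has_gene, mf["tss"].map(
            lambda v: "" if pd.isna(v) else str(int(v))), ""),
        "Relation_to_UCSC_CpG_Island": mf["island_relation"],
        "Infinium_Design_Type": mf["design_type"],
        "Color_Channel": mf["color_channel"].replace({"none": ""}),
        "Is_SNP": mf["is_snp"].map(lambda b: "1" if b else "0"),
    })


def write_fixture(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write manifest CSV, signal TSV, sample sheet CSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.csv",
        "signals": out / "signals.tsv",
        "samples": out / "samples.csv",
        "truth": out / "truth.json",
    }
    _manifest_csv_frame(cohort.manifest_frame).to_csv(paths["manifest"], index=False)
    cohort.signals.write_tsv(paths["signals"])
    cohort.samples.to_csv(paths["samples"])
    with open(paths["truth"], "w") as fh:
        json.dump(_jsonable(cohort.truth), fh, indent=1)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_fixture(fixture_dir) -> tuple[list[ProbeAnnotation], SignalMatrix, pd.DataFrame, dict]:
    """Read a written fixture back (manifest, signals, sample sheet, truth)."""
    d = Path(fixture_dir)
    manifest = read_manifest(d / "manifest.csv")
    signals = SignalMatrix.read_tsv(d / "signals.tsv")
    samples = pd.read_csv(d / "samples.csv", index_col=0)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    return manifest, signals, samples, truth
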