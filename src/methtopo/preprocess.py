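"""Probe filtering and the intensity normalization chain.

The pipeline order is fixed: detection/SNP/sex-chromosome filtering, type-I
color-bias adjustment, between-sample quantile normalization of methylated
and unmethylated intensities separately, equalization of type-I/type-II
background levels, β / M computation, and finally an intra-sample three-state
quantile correction of the type-II β bias.  Each normalization step is
deterministic, rank-preserving within the population it rescales, and
idempotent on already-normalized input.

Steps are exposed both as scikit-learn-style transformers (composable with
``sklearn.pipeline.Pipeline``; ``fit`` learns nothing data-independent and
``transform`` applies the contract) and as plain functions mirroring them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .annotation import ProbeAnnotation
from .containers import BetaMatrix, MValueMatrix, SignalMatrix
from .errors import ValidationError

__all__ = [
    "ProbeFilter",
    "ColorBiasAdjuster",
    "QuantileNormalizer",
    "TypeBackgroundEqualizer",
    "BetaMixtureQuantileCorrector",
    "filter_probes",
    "adjust_color_bias",
    "quantile_normalize_samples",
    "equalize_type_backgrounds",
    "compute_beta",
    "compute_m",
    "correct_type2_bias",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24"}


def _annot_frame(annot: list[ProbeAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in annot],
            "design_type": [p.design_type for p in annot],
            "color_channel": [p.color_channel for p in annot],
            "is_snp": [p.is_snp_probe for p in annot],
        },
        index=pd.Index([p.probe_id for p in annot], name="probe_id"),
    )


def _aligned_annot(signals: SignalMatrix, annot: list[ProbeAnnotation]) -> pd.DataFrame:
    af = _annot_frame(annot)
    missing = [p for p in signals.probe_ids if p not in af.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} probes in the signal matrix lack annotation "
            f"(first: {missing[0]!r})"
        )
    return af.loc[signals.probe_ids]


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Retain confidently detected autosomal non-SNP probes.

    A probe is kept when its detection p-value is below ``detect_threshold``
    in at least ``sample_fraction`` of the samples, it is not a SNP-measuring
    probe, and it does not map to a sex chromosome.  Probe order is preserved.

    Fitted attributes
    -----------------
    counts_ : dict
        Probes removed per reason (``low_detection``, ``snp``, ``sex_chrom``;
        a probe failing several filters is charged to the first in that
        order) plus ``retained``.
    mask_ : ndarray of bool
        Retention mask over the input probes.
    """

    def __init__(self, annotations=None, detect_threshold: float = 0.01,
                 sample_fraction: float = 0.95):
        self.annotations = annotations
        self.detect_threshold = detect_threshold
        self.sample_fraction = sample_fraction

    def fit(self, X: SignalMatrix, y=None):
        af = _aligned_annot(X, self.annotations)
        detected = (X.detection_p < self.detect_threshold).mean(axis=1) >= self.sample_fraction
        snp = af["is_snp"].to_numpy(bool)
        sex = af["chrom"].isin(SEX_CHROMS).to_numpy()
        mask = detected & ~snp & ~sex
        self.counts_ = {
            "low_detection": int((~detected).sum()),
            "snp": int((snp & detected).sum()),
            "sex_chrom": int((sex & detected & ~snp).sum()),
            "retained": int(mask.sum()),
        }
        self.mask_ = mask
        return self

    def transform(self, X: SignalMatrix) -> SignalMatrix:
        if not hasattr(self, "mask_"):
            self.fit(X)
        if self.counts_["retained"] == 0:
            raise ValidationError("all probes filtered: nothing left to analyze")
        return X.subset_probes(self.mask_)


class ColorBiasAdjuster(BaseEstimator, TransformerMixin):
    """Equalize red- and green-channel type-I intensity medians per sample.

    The smaller-median channel is scaled onto the larger by the ratio of the
    two channel medians (a monotone map, so within-channel rank order is
    preserved).  Medians are taken over the pooled methylated+unmethylated
    type-I intensities of the channel.  Type-II probes are untouched.
    """

    def __init__(self, annotations=None):
        self.annotations = annotations

    def fit(self, X: SignalMatrix, y=None):
        return self

    def transform(self, X: SignalMatrix) -> SignalMatrix:
        af = _aligned_annot(X, self.annotations)
        red = ((af["design_type"] == "I") & (af["color_channel"] == "red")).to_numpy()
        green = ((af["design_type"] == "I") & (af["color_channel"] == "green")).to_numpy()
        out = X.copy()
        for j in range(X.n_samples):
            if red.sum() == 0 or green.sum() == 0:
                warnings.warn(
                    "color-bias adjustment skipped: a type-I channel has no probes",
                    stacklevel=2,
                )
                break
            med = {}
            for name, mask in (("red", red), ("green", green)):
                med[name] = np.median(
                    np.concatenate([X.meth[mask, j], X.unmeth[mask, j]])
                )
            if med["red"] == med["green"] or min(med.values()) <= 0:
                continue
            lo = "red" if med["red"] < med["green"] else "green"
            factor = max(med.values()) / med[lo]
            mask = red if lo == "red" else green
            out.meth[mask, j] *= factor
            out.unmeth[mask, j] *= factor
        return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Between-sample quantile normalization, meth and unmeth separately.

    The reference distribution is the across-sample mean of the order
    statistics; after transform, the sorted per-sample vectors are identical
    across samples within each of the two intensity matrices.  Ties are
    resolved by stable sort, making the map deterministic and idempotent.
    """

    def fit(self, X: SignalMatrix, y=None):
        return self

    @staticmethod
    def _qn(mat: np.ndarray) -> np.ndarray:
        order = np.argsort(mat, axis=0, kind="stable")
        ref = np.sort(mat, axis=0).mean(axis=1)
        out = np.empty_like(mat)
        for j in range(mat.shape[1]):
            out[order[:, j], j] = ref
        return out

    def transform(self, X: SignalMatrix) -> SignalMatrix:
        if X.n_samples < 2:
            warnings.warn("quantile normalization skipped: fewer than 2 samples", stacklevel=2)
            return X.copy()
        out = X.copy()
        out.meth = self._qn(X.meth)
        out.unmeth = self._qn(X.unmeth)
        return out


class TypeBackgroundEqualizer(BaseEstimator, TransformerMixin):
    """Equalize type-I and type-II background levels per sample.

    Background is summarized as the 5th percentile of total intensity
    (meth+unmeth) per design type.  The higher-background type receives an
    additive offset on its total intensity, spread over the two channels in
    proportion to their share and floored at zero, so that the 5th-percentile
    totals agree exactly afterwards and re-application is the identity.
    """

    def __init__(self, annotations=None, percentile: float = 5.0):
        self.annotations = annotations
        self.percentile = percentile

    def fit(self, X: SignalMatrix, y=None):
        return self

    def transform(self, X: SignalMatrix) -> SignalMatrix:
        af = _aligned_annot(X, self.annotations)
        t1 = (af["design_type"] == "I").to_numpy()
        t2 = ~t1
        if t1.sum() == 0 or t2.sum() == 0:
            warnings.warn(
                "type-background equalization skipped: a design type is absent",
                stacklevel=2,
            )
            return X.copy()
        out = X.copy()
        for j in range(X.n_samples):
            total = X.meth[:, j] + X.unmeth[:, j]
            p1 = np.percentile(total[t1], self.percentile)
            p2 = np.percentile(total[t2], self.percentile)
            if p1 == p2:
                continue
            hi = t1 if p1 > p2 else t2
            delta = abs(p1 - p2)
            tot_hi = total[hi]
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(tot_hi > 0, np.maximum(1.0 - delta / tot_hi, 0.0), 0.0)
            out.meth[hi, j] *= factor
            out.unmeth[hi, j] *= factor
        return out


def compute_beta(signals: SignalMatrix, offset: float = 100.0) -> BetaMatrix:
    """β = max(meth,0) / (max(meth,0) + max(unmeth,0) + offset).

    The positive offset (GenomeStudio default 100) keeps β defined at zero
    intensity and bounds it in [0, 1).
    """
    if offset <= 0:
        raise ValidationError("offset must be positive")
    m = np.maximum(signals.meth, 0.0)
    u = np.maximum(signals.unmeth, 0.0)
    return BetaMatrix(list(signals.probe_ids), list(signals.sample_ids), m / (m + u + offset))


def compute_m(signals: SignalMatrix, alpha: float = 100.0) -> MValueMatrix:
    """M = log2((max(meth,0) + alpha) / (max(unmeth,0) + alpha))."""
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    m = np.maximum(signals.meth, 0.0)
    u = np.maximum(signals.unmeth, 0.0)
    return MValueMatrix(
        list(signals.probe_ids), list(signals.sample_ids),
        np.log2((m + alpha) / (u + alpha)), alpha,
    )


class BetaMixtureQuantileCorrector(BaseEstimator, TransformerMixin):
    """Three-state quantile correction of the type-II β compression.

    Within each sample, type-II β values are split into unmethylated
    (< ``lo``), hemimethylated ([``lo``, ``hi``]) and methylated (> ``hi``)
    states and quantile-mapped onto the type-I β distribution of the same
    state; type-I values are left unchanged.  Mapping uses the rank position
    p = rank/(n-1) interpolated into the sorted type-I in-state values and is
    clipped to the state interval, so it preserves within-state rank order,
    keeps output in [0, 1], is exactly the identity when the two
    distributions coincide, and is idempotent.  States with fewer than
    ``min_state_probes`` type-I probes pass through unadjusted.
    """

    def __init__(self, annotations=None, lo: float = 0.2, hi: float = 0.8,
                 min_state_probes: int = 10):
        self.annotations = annotations
        self.lo = lo
        self.hi = hi
        self.min_state_probes = min_state_probes

    def fit(self, X: BetaMatrix, y=None):
        return self

    def _states(self, v: np.ndarray) -> list[np.ndarray]:
        return [v < self.lo, (v >= self.lo) & (v <= self.hi), v > self.hi]

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        af = _annot_frame(self.annotations)
        missing = [p for p in X.probe_ids if p not in af.index]
        if missing:
            raise ValidationError("beta matrix contains unannotated probes")
        af = af.loc[X.probe_ids]
        t1 = (af["design_type"] == "I").to_numpy()
        t2 = ~t1
        if t1.sum() == 0 or t2.sum() == 0:
            warnings.warn("type-II correction skipped: a design type is absent", stacklevel=2)
            return X.copy()
        bounds = [(0.0, np.nextafter(self.lo, 0.0)), (self.lo, self.hi),
                  (np.nextafter(self.hi, 1.0), 1.0)]
        out = X.copy()
        for j in range(len(X.sample_ids)):
            b1 = X.values[t1, j]
            b2 = X.values[t2, j]
            mapped = b2.copy()
            s1 = self._states(b1)
            s2 = self._states(b2)
            for state, (m1, m2) in enumerate(zip(s1, s2)):
                n_ref, n_tgt = int(m1.sum()), int(m2.sum())
                if n_tgt == 0:
                    continue
                if n_ref < self.min_state_probes:
                    warnings.warn(
                        f"type-II correction: state {state} has only {n_ref} "
                        "type-I probes; passing through unadjusted",
                        stacklevel=2,
                    )
                    continue
                ref = np.sort(b1[m1])
                vals = b2[m2]
                ranks = np.empty(n_tgt, dtype=float)
                ranks[np.argsort(vals, kind="stable")] = np.arange(n_tgt)
                p = ranks / (n_tgt - 1) if n_tgt > 1 else np.array([0.5])
                new = np.interp(p * (n_ref - 1), np.arange(n_ref), ref)
                lo_b, hi_b = bounds[state]
                mapped[m2] = np.clip(new, lo_b, hi_b)
            out.values[t2, j] = mapped
        return out


# ---------------------------------------------------------------------------
# functional wrappers


def filter_probes(signals, annot, detect_threshold=0.01, sample_fraction=0.95):
    return ProbeFilter(annot, detect_threshold, sample_fraction).fit(signals).transform(signals)


def adjust_color_bias(signals, annot):
    return ColorBiasAdjuster(annot).transform(signals)


def quantile_normalize_samples(signals):
    return QuantileNormalizer().transform(signals)


def equalize_type_backgrounds(signals, annot):
    return TypeBackgroundEqualizer(annot).transform(signals)


def correct_type2_bias(betas, annot):
    return BetaMixtureQuantileCorrector(annot).transform(betas)
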