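"""Global methylome scores: per-sample mean β per region class.

A score is the arithmetic mean of the β-values of all probes assigned to a
class (a TSS-distance window R1/R2/R3, an island-relative class, an N/S
composite, or a gene-feature group).  Scores live on the β scale, so the
values are directly interpretable as average fraction methylated.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BetaMatrix, ScoreTable
from .errors import ValidationError

__all__ = ["MethylomeScorer", "score_by_class", "score_deltas"]


class MethylomeScorer(BaseEstimator, TransformerMixin):
    """Transform a :class:`BetaMatrix` into a :class:`ScoreTable`.

    Parameters
    ----------
    membership : mapping class name -> set of probe ids
        Typically :func:`methtopo.annotation.region_membership` output.
        Classes with no probes present in the β matrix are omitted (with a
        warning); probes referenced but absent from the matrix raise.
    """

    def __init__(self, membership: Mapping[str, set] | None = None):
        self.membership = membership

    def fit(self, X: BetaMatrix, y=None):
        return self

    def transform(self, X: BetaMatrix) -> ScoreTable:
        if not self.membership:
            raise ValidationError("membership mapping is empty")
        known = set(X.probe_ids)
        pos = {p: i for i, p in enumerate(X.probe_ids)}
        classes, cols, n_probes = [], [], {}
        for cls_name, probes in self.membership.items():
            unknown = set(probes) - known
            if unknown:
                raise ValidationError(
                    f"class {cls_name!r} references {len(unknown)} probes absent "
                    f"from the beta matrix (e.g. {sorted(unknown)[0]!r})"
                )
            if not probes:
                warnings.warn(f"class {cls_name!r} has no probes; omitted", stacklevel=2)
                continue
            idx = np.fromiter((pos[p] for p in probes), dtype=int, count=len(probes))
            classes.append(cls_name)
            cols.append(X.values[idx].mean(axis=0))
            n_probes[cls_name] = len(probes)
        if not classes:
            raise ValidationError("no class has any probes in the beta matrix")
        return ScoreTable(list(X.sample_ids), classes, np.column_stack(cols), n_probes)


def score_by_class(betas: BetaMatrix, membership: Mapping[str, set]) -> ScoreTable:
    """Functional form of :class:`MethylomeScorer`."""
    return MethylomeScorer(membership).transform(betas)


def score_deltas(
    scores: ScoreTable,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "tissue",
) -> pd.DataFrame:
    """Per-class difference of group medians (median A − median B).

    ``meta`` is a sample sheet indexed by sample id with a ``group_col``
    column; ``contrast`` names the two levels (A, B).  Returns one row per
    class with group sizes, medians, IQRs and the median difference —
    the layout the contrast reports are built from.
    """
    a, b = contrast
    for level in (a, b):
        ids = meta.index[meta[group_col] == level]
        if len(ids) == 0:
            raise ValidationError(f"group {level!r} is empty in column {group_col!r}")
    sid = pd.Index(scores.sample_ids)
    mask_a = sid.isin(meta.index[meta[group_col] == a])
    mask_b = sid.isin(meta.index[meta[group_col] == b])
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValidationError("a contrast group has no samples in the score table")
    rows = []
    for k, cls_name in enumerate(scores.classes):
        va = scores.values[mask_a, k]
        vb = scores.values[mask_b, k]
        rows.append(
            {
                "class": cls_name,
                "n_a": int(mask_a.sum()),
                "n_b": int(mask_b.sum()),
                "median_a": float(np.median(va)),
                "median_b": float(np.median(vb)),
                "iqr_a": float(np.subtract(*np.percentile(va, [75, 25]))),
                "iqr_b": float(np.subtract(*np.percentile(vb, [75, 25]))),
                "median_difference": float(np.median(va) - np.median(vb)),
            }
        )
    return pd.DataFrame(rows).set_index("class")
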