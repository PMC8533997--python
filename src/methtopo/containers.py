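"""In-memory containers for methylation array data.

The containers are thin, validated wrappers around numpy arrays with ordered
probe and sample identifiers, plus TSV round-trip helpers for the plain-text
exchange formats used throughout the package:

* ``SignalMatrix`` — methylated / unmethylated fluorescence intensities and
  per-entry detection p-values (a GenomeStudio-export-like layout with
  ``<sample>.Methylated`` / ``<sample>.Unmethylated`` / ``<sample>.DetectionP``
  columns).
* ``BetaMatrix`` — β-values in [0, 1] (fraction methylated signal).
* ``MValueMatrix`` — log2 methylated/unmethylated ratios with offset ``alpha``.
* ``ScoreTable`` — per-sample mean β per region class (the global methylome
  scores), with the probe count behind each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["SignalMatrix", "BetaMatrix", "MValueMatrix", "ScoreTable"]


def _as_2d_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SignalMatrix:
    """Raw or normalized intensities, probes x samples."""

    probe_ids: list[str]
    sample_ids: list[str]
    meth: np.ndarray
    unmeth: np.ndarray
    detection_p: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(map(str, self.probe_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.meth = _as_2d_float(self.meth, "meth")
        self.unmeth = _as_2d_float(self.unmeth, "unmeth")
        self.detection_p = _as_2d_float(self.detection_p, "detection_p")
        shape = (len(self.probe_ids), len(self.sample_ids))
        for name in ("meth", "unmeth", "detection_p"):
            if getattr(self, name).shape != shape:
                raise ValidationError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if np.any(self.detection_p < 0) or np.any(self.detection_p > 1):
            raise ValidationError("detection_p entries must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(
            list(self.probe_ids),
            list(self.sample_ids),
            self.meth.copy(),
            self.unmeth.copy(),
            self.detection_p.copy(),
        )

    def subset_probes(self, mask_or_ids) -> "SignalMatrix":
        """Row subset by boolean mask or explicit probe-id list (order kept)."""
        mask = np.asarray(mask_or_ids)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            pos = {p: i for i, p in enumerate(self.probe_ids)}
            try:
                idx = np.array([pos[p] for p in mask_or_ids], dtype=int)
            except KeyError as e:  # pragma: no cover - defensive
                raise ValidationError(f"unknown probe id {e.args[0]!r}") from e
        return SignalMatrix(
            [self.probe_ids[i] for i in idx],
            list(self.sample_ids),
            self.meth[idx],
            self.unmeth[idx],
            self.detection_p[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for j, s in enumerate(self.sample_ids):
            cols[f"{s}.Methylated"] = self.meth[:, j]
            cols[f"{s}.Unmethylated"] = self.unmeth[:, j]
            cols[f"{s}.DetectionP"] = self.detection_p[:, j]
        return pd.DataFrame(cols, index=pd.Index(self.probe_ids, name="probe_id"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        samples: list[str] = []
        for c in df.columns:
            if c.endswith(".Methylated"):
                samples.append(c[: -len(".Methylated")])
        if not samples:
            raise FormatError("no '<sample>.Methylated' columns found in signal TSV")
        for s in samples:
            for suffix in (".Unmethylated", ".DetectionP"):
                if f"{s}{suffix}" not in df.columns:
                    raise FormatError(f"missing required column '{s}{suffix}'")
        meth = np.column_stack([df[f"{s}.Methylated"].to_numpy(float) for s in samples])
        unmeth = np.column_stack([df[f"{s}.Unmethylated"].to_numpy(float) for s in samples])
        det = np.column_stack([df[f"{s}.DetectionP"].to_numpy(float) for s in samples])
        return cls(list(df.index.astype(str)), samples, meth, unmeth, det)


@dataclass
class BetaMatrix:
    """β-values (fraction methylated), probes x samples, each entry in [0, 1]."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(map(str, self.probe_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = _as_2d_float(self.values, "values")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match probe/sample ids")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("beta values must lie in [0, 1]")

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(list(self.probe_ids), list(self.sample_ids), self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


@dataclass
class MValueMatrix:
    """M-values: log2((max(meth,0)+alpha) / (max(unmeth,0)+alpha))."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    alpha: float = 100.0

    def __post_init__(self) -> None:
        self.probe_ids = list(map(str, self.probe_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = _as_2d_float(self.values, "values")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match probe/sample ids")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )


@dataclass
class ScoreTable:
    """Per-sample mean methylation per region class.

    ``values`` is samples x classes; ``n_probes`` records how many probes
    back each reported class (always >= 1 — empty classes are dropped at
    construction time by the scorer).
    """

    sample_ids: list[str]
    classes: list[str]
    values: np.ndarray
    n_probes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.classes = list(map(str, self.classes))
        self.values = _as_2d_float(self.values, "values")
        if self.values.shape != (len(self.sample_ids), len(self.classes)):
            raise ValidationError("values shape does not match sample/class labels")
        for c in self.classes:
            if self.n_probes.get(c, 1) < 1:
                raise ValidationError(f"class {c!r} reported with zero probes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.classes,
        )

    def __getitem__(self, cls_name: str) -> np.ndarray:
        try:
            j = self.classes.index(cls_name)
        except ValueError:
            raise KeyError(cls_name) from None
        return self.values[:, j]

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))
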