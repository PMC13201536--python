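"""QC filtering and normalization.

Two normalization schemes are provided: a shifted logarithmic transform of
counts rescaled to a fixed per-cell total (imaging-based transcriptomics),
and an inverse-hyperbolic-sine compression followed by feature-wise
z-scoring (mass-cytometry intensities), optionally applied per sample and
re-applied within a reference cell subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "qc_filter",
    "shifted_log_normalize",
    "arcsinh_transform",
    "zscore",
    "zscore_per_sample",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality filters.

    Area bounds default to the plausible range of segmented skin cells;
    they are meant to be adjusted per sample.
    """

    area_min_um2: float = 5.0
    area_max_um2: float = 700.0
    max_negctrl_fraction: float = 0.1
    min_features: int = 10

    def __post_init__(self) -> None:
        if self.area_min_um2 >= self.area_max_um2:
            raise ValueError("area_min_um2 must be < area_max_um2")
        if not 0 <= self.max_negctrl_fraction <= 1:
            raise ValueError("max_negctrl_fraction must lie in [0, 1]")
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")


@dataclass
class NormalizedMatrix:
    """A cells x features real matrix with its provenance tag."""

    values: np.ndarray
    features: list[str]
    cell_ids: list[str]
    method: str  # shifted_log | arcsinh | zscore
    params: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.features)):
            raise ValueError("values shape does not match cell/feature index")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.features)


def qc_filter(
    cells: pd.DataFrame,
    counts: np.ndarray,
    genes: pd.DataFrame,
    thresholds: QCThresholds,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, int]]:
    """Remove cells failing area, negative-control and feature-count filters.

    Returns the filtered cell table, the matching count rows, and a tally of
    cells removed per criterion (a cell can count towards several).
    """
    counts = np.asarray(counts)
    if len(cells) != counts.shape[0]:
        raise ValueError("cell table and count matrix disagree on cell number")
    negctrl = genes["is_negctrl"].to_numpy()
    total = counts.sum(axis=1)
    neg_total = counts[:, negctrl].sum(axis=1)
    with np.errstate(invalid="ignore"):
        neg_frac = np.where(total > 0, neg_total / np.maximum(total, 1), 0.0)
    n_features = (counts[:, ~negctrl] > 0).sum(axis=1)
    area = cells["area_um2"].to_numpy()

    ok_area = (area >= thresholds.area_min_um2) & (area <= thresholds.area_max_um2)
    ok_neg = neg_frac <= thresholds.max_negctrl_fraction
    ok_feat = n_features >= thresholds.min_features
    keep = ok_area & ok_neg & ok_feat
    if not keep.any():
        raise ValueError("qc_filter removed every cell; thresholds too strict")
    removed = {
        "area": int((~ok_area).sum()),
        "negctrl_fraction": int((~ok_neg).sum()),
        "min_features": int((~ok_feat).sum()),
        "total_removed": int((~keep).sum()),
    }
    return cells.loc[keep].reset_index(drop=True), counts[keep], removed


def shifted_log_normalize(
    counts: np.ndarray,
    genes: pd.DataFrame,
    cell_ids: list[str],
    scale: float = 300.0,
) -> NormalizedMatrix:
    """``ln(1 + count * scale / cell_total)`` per entry.

    Each cell's counts are rescaled to sum to ``scale`` before the log, so
    the result is invariant to per-cell sequencing depth.
    """
    counts = np.asarray(counts, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    total = counts.sum(axis=1)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        bad = ", ".join(str(cell_ids[i]) for i in zero[:5])
        raise ValueError(f"cells with zero total count cannot be normalized: {bad}")
    values = np.log1p(counts * (scale / total[:, None]))
    return NormalizedMatrix(
        values, list(genes["gene"]), list(cell_ids), "shifted_log", {"scale": scale}
    )


def arcsinh_transform(
    values: np.ndarray,
    features: list[str],
    cell_ids: list[str],
    cofactor: float = 1.0,
) -> NormalizedMatrix:
    """Inverse hyperbolic sine compression, ``asinh(x / cofactor)``."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = np.arcsinh(np.asarray(values, dtype=float) / cofactor)
    return NormalizedMatrix(
        out, list(features), list(cell_ids), "arcsinh", {"cofactor": cofactor}
    )


def zscore(
    norm: NormalizedMatrix, reference_rows: np.ndarray | None = None
) -> NormalizedMatrix:
    """Standardize each feature against a reference cell subset.

    ``reference_rows`` is a boolean or integer row index (default: all
    cells).  Uses the unbiased (n-1) standard deviation.  In the
    mass-cytometry pipeline this is applied twice: globally, then restricted
    to fibroblasts.
    """
    x = norm.values
    if reference_rows is None:
        ref = x
    else:
        ref = x[np.asarray(reference_rows)]
    if ref.shape[0] < 2:
        raise ValueError("z-score reference needs at least 2 rows")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [norm.features[j] for j in flat]
        raise ValueError(f"zero-variance features in reference: {names}")
    return NormalizedMatrix(
        (x - mean) / sd,
        list(norm.features),
        list(norm.cell_ids),
        "zscore",
        {"parent": norm.method, **norm.params},
    )


def zscore_per_sample(norm: NormalizedMatrix, samples: pd.Series) -> NormalizedMatrix:
    """Standardize each sample's cells independently (per-sample scaling)."""
    samples = np.asarray(samples)
    if samples.shape[0] != norm.values.shape[0]:
        raise ValueError("sample labels must match cell rows")
    out = np.empty_like(norm.values)
    for s in pd.unique(samples):
        rows = np.flatnonzero(samples == s)
        sub = NormalizedMatrix(
            norm.values[rows],
            list(norm.features),
            [norm.cell_ids[i] for i in rows],
            norm.method,
            norm.params,
        )
        out[rows] = zscore(sub).values
    return NormalizedMatrix(
        out, list(norm.features), list(norm.cell_ids), "zscore",
        {"parent": norm.method, "per_sample": True},
    )
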