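"""Similarity measures between essential subspaces.

Implements the cross-variant comparison toolkit: per-PC squared inner
products, the eigenvalue crossing-over diagnostic (which variant PC best
matches a chosen reference PC), the root mean square inner product (RMSIP)
over the first D PCs, the cosine content sampling diagnostic, and the
boxplot statistics used to compare RMSIP distributions between variant
classes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import EssentialSubspace, ProjectionSeries
from .errors import ConsistencyError, InvalidArgumentError, UndefinedError

logger = logging.getLogger(__name__)


def _vectors(subspace: EssentialSubspace | np.ndarray) -> np.ndarray:
    if isinstance(subspace, EssentialSubspace):
        return subspace.eigenvectors
    v = np.asarray(subspace, dtype=np.float64)
    if v.ndim != 2:
        raise InvalidArgumentError("subspace must be a (dim, k) column matrix")
    return v


@dataclass
class CrossingTable:
    """Overlap profile of one reference PC against the first k variant PCs.

    ``overlaps[j-1]`` is the squared inner product with variant PC j; indices
    are 1-based to match PC naming.
    """

    reference_pc: int
    overlaps: np.ndarray
    best_match: int
    best_overlap: float


@dataclass
class BoxplotStats:
    """Tukey boxplot summary of one group of scalars."""

    label: str
    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def overlap_matrix(
    v: EssentialSubspace | np.ndarray,
    w: EssentialSubspace | np.ndarray,
    k1: int,
    k2: int,
) -> np.ndarray:
    """Matrix of squared inner products (v_i · w_j)², shape (k1, k2)."""
    vv, ww = _vectors(v), _vectors(w)
    if vv.shape[0] != ww.shape[0]:
        raise ConsistencyError(
            f"subspace dimensions differ: {vv.shape[0]} vs {ww.shape[0]}"
        )
    if k1 > vv.shape[1] or k2 > ww.shape[1]:
        raise InvalidArgumentError("k exceeds the number of available PCs")
    return (vv[:, :k1].T @ ww[:, :k2]) ** 2


def best_match_pc(
    reference_pc: np.ndarray,
    w: EssentialSubspace | np.ndarray,
    k_max: int = 10,
    reference_index: int = 1,
) -> CrossingTable:
    """Which of the first ``k_max`` PCs of *w* best matches a reference PC.

    This is the crossing-over diagnostic: a best match at an index other than
    the reference's own signals that the corresponding motion has migrated to
    a different eigenvalue rank in the other system.
    """
    if k_max < 1:
        raise InvalidArgumentError("k_max must be >= 1")
    ref = np.asarray(reference_pc, dtype=np.float64).ravel()
    norm = np.linalg.norm(ref)
    if norm == 0:
        raise InvalidArgumentError("reference PC must be a non-zero vector")
    ref = ref / norm
    ww = _vectors(w)
    if ww.shape[0] != ref.size:
        raise ConsistencyError("reference vector dimension does not match subspace")
    if k_max > ww.shape[1]:
        raise InvalidArgumentError("k_max exceeds the number of available PCs")
    overlaps = (ref @ ww[:, :k_max]) ** 2
    best = int(np.argmax(overlaps))
    return CrossingTable(
        reference_pc=reference_index,
        overlaps=overlaps,
        best_match=best + 1,
        best_overlap=float(overlaps[best]),
    )


def rmsip(
    v: EssentialSubspace | np.ndarray,
    w: EssentialSubspace | np.ndarray,
    d: int = 20,
) -> float:
    """Root mean square inner product over the first *d* PCs of each subspace.

    sqrt( (1/D) Σ_{i<=D} Σ_{j<=D} (v_i·w_j)² ); 1 for identical spans,
    0 for orthogonal ones.  Symmetric in its arguments.
    """
    vv, ww = _vectors(v), _vectors(w)
    if vv.shape[0] != ww.shape[0]:
        raise ConsistencyError("subspace dimensions differ")
    if d < 1 or d > vv.shape[1] or d > ww.shape[1]:
        raise InvalidArgumentError(
            f"D={d} exceeds available PCs ({vv.shape[1]}, {ww.shape[1]})"
        )
    inner = vv[:, :d].T @ ww[:, :d]
    return float(np.sqrt(np.sum(inner**2) / d))


def cosine_content(p: ProjectionSeries | np.ndarray, i: int | None = None) -> float:
    """Cosine content c_i of a PC projection time series, in [0, 1].

    c_i = (2/T) · (∫ p(t)·cos(iπt/T) dt)² / ∫ p(t)² dt with trapezoidal
    quadrature over the frame index (t = 0..T, unit spacing).  Values near 1
    indicate the projection resembles a half-period cosine — the signature of
    random-diffusion-like, insufficiently sampled motion.
    """
    if isinstance(p, ProjectionSeries):
        series = p.values
        idx = i if i is not None else p.pc_index
    else:
        series = np.asarray(p, dtype=np.float64).ravel()
        if i is None:
            raise InvalidArgumentError("PC index i required for a bare array")
        idx = i
    if idx < 1:
        raise InvalidArgumentError("PC index must be >= 1")
    if series.size < 4:
        raise InvalidArgumentError("cosine content requires at least 4 frames")
    t = np.arange(series.size, dtype=np.float64)
    span = series.size - 1.0
    denom = np.trapezoid(series * series, t)
    if denom == 0.0:
        raise UndefinedError("cosine content undefined for an all-zero projection")
    num = np.trapezoid(series * np.cos(idx * np.pi * t / span), t)
    return float(np.clip((2.0 / span) * num * num / denom, 0.0, 1.0))


def group_boxplot_stats(
    values: Mapping[str, float],
    grouping: Mapping[str, str],
) -> list[BoxplotStats]:
    """Tukey boxplot statistics per class of labelled scalars.

    ``grouping`` maps each value label to its class.  Quartiles use the
    linear-interpolation quantile convention; whiskers extend to the most
    extreme data point within 1.5×IQR of the quartiles; points beyond are
    outliers.  Classes with no values are skipped with a warning.  Results are
    ordered by first appearance of each class in ``grouping``.
    """
    classes: dict[str, list[float]] = {}
    for label, cls in grouping.items():
        classes.setdefault(cls, [])
        if label in values:
            classes[cls].append(float(values[label]))
    for label in values:
        if label not in grouping:
            raise InvalidArgumentError(f"value label {label!r} has no class in grouping")

    stats = []
    for cls, data in classes.items():
        if not data:
            logger.warning("class %r has no values; skipped", cls)
            continue
        arr = np.sort(np.asarray(data, dtype=np.float64))
        q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        whisker_low = float(inside.min()) if inside.size else float(arr.min())
        whisker_high = float(inside.max()) if inside.size else float(arr.max())
        outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
        stats.append(
            BoxplotStats(
                label=cls, n=arr.size, median=float(med), q25=float(q25),
                q75=float(q75), whisker_low=whisker_low, whisker_high=whisker_high,
                outliers=outliers,
            )
        )
    return stats
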