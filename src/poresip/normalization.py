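"""Per-read scaled-MAD normalization of nanopore current.

Nanopore traces carry per-read gain and offset drift ("machine noise").
Centering by the median and scaling by the median absolute deviation of the
basecalled signal removes this read-level location/scale nuisance while
staying robust to the heavy tails of raw current.  The non-basecalled signal
is normalized with the *same* per-read center and scale, so it stays
comparable to the basecalled portion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Gaussian consistency constant: mad * 1.4826 estimates sigma for normal data.
GAUSSIAN_CONSISTENCY = 1.4826


@dataclass
class NormalizedRead:
    """Normalized basecalled (R_hat) and non-basecalled (X_hat) signal."""

    read_id: str
    R_hat: np.ndarray
    X_hat: np.ndarray
    center: float
    scale: float


def mad(values: np.ndarray, consistency_c: float = 1.0) -> float:
    """Median absolute deviation, ``c * median(|v - median(v)|)``.

    Even-length medians use the midpoint convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    if not np.all(np.isfinite(values)):
        raise ValueError("mad requires finite values")
    med = np.median(values)
    return float(consistency_c * np.median(np.abs(values - med)))


def normalize_read(
    read_id: str,
    R_r: np.ndarray,
    X_r: np.ndarray,
    consistency_c: float = 1.0,
    zero_scale_epsilon: float = 1e-8,
) -> NormalizedRead:
    """Normalize one read: ``R_hat = (R_r - med(R_r)) / mad(R_r)``.

    ``X_r`` (which may be empty) is transformed with the same center and
    scale.  A degenerate scale below ``zero_scale_epsilon`` is clamped to it
    so constant synthetic inputs do not produce infinities.
    """
    R_r = np.asarray(R_r, dtype=float)
    X_r = np.asarray(X_r, dtype=float)
    if R_r.size == 0:
        raise ValueError(f"read {read_id!r}: no basecalled signal to normalize")
    center = float(np.median(R_r))
    scale = mad(R_r, consistency_c)
    if scale < zero_scale_epsilon:
        logger.info("read %r: near-zero MAD %.3g clamped", read_id, scale)
        scale = zero_scale_epsilon
    return NormalizedRead(
        read_id=read_id,
        R_hat=(R_r - center) / scale,
        X_hat=(X_r - center) / scale,
        center=center,
        scale=scale,
    )
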