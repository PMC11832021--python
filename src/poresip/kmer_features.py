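"""Per-read k-mer summary statistics and the Box-Cox transform.

The current through the pore is determined by the ~k nucleotides occupying
it, so after sequence effects are stratified by k-mer, residual differences
between reads reflect read-level perturbations such as heavy-isotope
incorporation.  For each read, three robust summary vectors over the 4^k
k-mers are extracted from the normalized signal:

* **signal median** ``m``: median of pooled normalized samples per k-mer,
* **signal MAD** ``d``: median absolute deviation of that pool (variability
  between occurrences of the same k-mer),
* **dwell-time median** ``l``: median number of raw samples per occurrence,

plus one scalar ``x``, the median of the normalized non-basecalled signal.
Signal MAD and dwell medians are strictly positive and right-skewed; both
are mapped to an approximately Gaussian scale by a Box-Cox transform whose
exponent λ is estimated from training data by profile maximum likelihood.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import boxcox as _boxcox_scipy

from .normalization import NormalizedRead, mad
from .signal_io import SegmentedRead

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_RANK = {b: i for i, b in enumerate(BASES)}

PoolingMode = Literal["pool_samples", "per_event_medians"]


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer with A<C<G<T (base-4 positional code)."""
    idx = 0
    for ch in kmer:
        try:
            idx = idx * 4 + _BASE_RANK[ch]
        except KeyError:
            raise ValueError(f"invalid k-mer character {ch!r} in {kmer!r}") from None
    return idx


def index_to_kmer(index: int, k: int) -> str:
    """Inverse of :func:`kmer_index`."""
    if not 0 <= index < 4**k:
        raise ValueError(f"index {index} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic (index) order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


@dataclass
class ReadStats:
    """Untransformed per-read statistics, prior to Box-Cox assembly."""

    read_id: str
    k: int
    m: np.ndarray  # signal median per k-mer (NaN where absent)
    mad_raw: np.ndarray  # raw signal MAD per k-mer
    dwell_med: np.ndarray  # dwell-time median per k-mer (samples)
    x: float  # median of X_hat; NaN when no non-basecalled signal
    present: np.ndarray  # boolean mask over the 4^k k-mers
    label: int | None = None


@dataclass
class ReadFeatures:
    """Model-ready features of one read: m, Box-Cox d and l, scalar x."""

    read_id: str
    k: int
    m: np.ndarray
    d: np.ndarray
    l: np.ndarray
    x: float
    present: np.ndarray
    c: int | None = None

    def __post_init__(self) -> None:
        n = 4**self.k
        for name in ("m", "d", "l"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (n,):
                raise ValueError(f"{name} must have length 4^k = {n}")
            setattr(self, name, vec)
        self.present = np.asarray(self.present, dtype=bool)

    @property
    def is_complete(self) -> bool:
        return bool(self.present.all())


@dataclass(frozen=True)
class BoxCoxFit:
    """A frozen Box-Cox exponent, fitted on training data only."""

    lam: float
    feature_family: str  # "signal_mad" | "dwell_median"
    n_train_values: int


def boxcox(y: float | np.ndarray, lam: float) -> float | np.ndarray:
    """Box-Cox transform: ``(y**lam - 1)/lam`` for lam != 0, ``log y`` at 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    out = _boxcox_scipy(y, lam)
    return float(out) if out.ndim == 0 else out


def boxcox_profile_loglik(values: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of the Box-Cox exponent.

    ``L(λ) = (λ-1)·Σ log y_i − (N/2)·log( Σ (b(λ) − mean b(λ))² / N )``
    where ``b(λ)`` are the transformed values.  The deviation sum is the
    (biased) variance of the transformed sample.
    """
    values = np.asarray(values, dtype=float)
    b = boxcox(values, lam)
    n = values.size
    var = np.mean((b - b.mean()) ** 2)
    if var <= 0:
        return -np.inf
    return float((lam - 1.0) * np.sum(np.log(values)) - 0.5 * n * np.log(var))


def fit_boxcox_lambda(
    values: Sequence[float] | np.ndarray,
    feature_family: str = "signal_mad",
    bounds: tuple[float, float] = (-2.0, 2.0),
) -> BoxCoxFit:
    """Estimate λ by maximizing the profile log-likelihood over ``bounds``.

    Bounded scalar search (Brent) to an absolute tolerance of 1e-4.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values to fit lambda")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("lambda fit requires finite, strictly positive values")
    res = minimize_scalar(
        lambda lam: -boxcox_profile_loglik(values, lam),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-4},
    )
    return BoxCoxFit(lam=float(res.x), feature_family=feature_family, n_train_values=values.size)


def extract_read_stats(
    norm: NormalizedRead,
    seg: SegmentedRead,
    k: int,
    pooling: PoolingMode = "pool_samples",
) -> ReadStats:
    """Per-k-mer robust statistics of one normalized, segmented read.

    With ``pooling="pool_samples"`` (default) all normalized samples of all
    occurrences of a k-mer are pooled before taking the median/MAD; with
    ``"per_event_medians"`` each occurrence is first reduced to its median
    and the statistics are taken over those per-occurrence medians.
    """
    n_kmers = 4**k
    sample_groups: dict[int, list[np.ndarray]] = {}
    dwell_groups: dict[int, list[int]] = {}
    offset = 0
    prev_end = -1
    for ev in seg.events:
        if len(ev.kmer) != k:
            raise ValueError(
                f"read {seg.read_id!r}: event k-mer {ev.kmer!r} does not match k={k}"
            )
        if ev.sample_start < prev_end:
            raise ValueError(f"read {seg.read_id!r}: overlapping event sample ranges")
        prev_end = ev.sample_end
        idx = kmer_index(ev.kmer)
        chunk = norm.R_hat[offset : offset + ev.dwell]
        offset += ev.dwell
        sample_groups.setdefault(idx, []).append(chunk)
        dwell_groups.setdefault(idx, []).append(ev.dwell)
    if offset != norm.R_hat.size:
        raise ValueError(
            f"read {seg.read_id!r}: events cover {offset} samples but R_hat has "
            f"{norm.R_hat.size}"
        )

    m = np.full(n_kmers, np.nan)
    mad_raw = np.full(n_kmers, np.nan)
    dwell_med = np.full(n_kmers, np.nan)
    present = np.zeros(n_kmers, dtype=bool)
    for idx, chunks in sample_groups.items():
        if pooling == "pool_samples":
            pool = np.concatenate(chunks)
        elif pooling == "per_event_medians":
            pool = np.array([np.median(c) for c in chunks])
        else:
            raise ValueError(f"unknown pooling mode {pooling!r}")
        m[idx] = np.median(pool)
        mad_raw[idx] = mad(pool)
        dwell_med[idx] = np.median(dwell_groups[idx])
        present[idx] = True

    x = float(np.median(norm.X_hat)) if norm.X_hat.size else float("nan")
    return ReadStats(
        read_id=seg.read_id,
        k=k,
        m=m,
        mad_raw=mad_raw,
        dwell_med=dwell_med,
        x=x,
        present=present,
        label=seg.label,
    )


def assemble_features(
    stats: ReadStats,
    mad_fit: BoxCoxFit,
    dwell_fit: BoxCoxFit,
    positivity_epsilon: float = 1e-6,
) -> ReadFeatures:
    """Apply the frozen Box-Cox fits to a read's raw statistics.

    Raw MAD entries of exactly 0 (a k-mer whose pooled samples are
    constant) are clamped to ``positivity_epsilon`` before the transform.
    """
    d = np.full_like(stats.mad_raw, np.nan)
    l = np.full_like(stats.dwell_med, np.nan)
    pres = stats.present
    mad_vals = stats.mad_raw[pres]
    n_clamped = int(np.sum(mad_vals < positivity_epsilon))
    if n_clamped:
        logger.info("read %r: %d zero-MAD entries clamped", stats.read_id, n_clamped)
    d[pres] = boxcox(np.maximum(mad_vals, positivity_epsilon), mad_fit.lam)
    l[pres] = boxcox(np.maximum(stats.dwell_med[pres], positivity_epsilon), dwell_fit.lam)
    return ReadFeatures(
        read_id=stats.read_id,
        k=stats.k,
        m=stats.m.copy(),
        d=d,
        l=l,
        x=stats.x,
        present=pres.copy(),
        c=stats.label,
    )


def fit_boxcox_on_stats(
    stats: Iterable[ReadStats],
    shared_lambda: bool = False,
) -> tuple[BoxCoxFit, BoxCoxFit]:
    """Fit the MAD-family and dwell-family λ on pooled present entries.

    With ``shared_lambda`` a single λ is fitted on the union of both
    families and returned for both.
    """
    mad_vals: list[np.ndarray] = []
    dwell_vals: list[np.ndarray] = []
    eps = 1e-6
    for st in stats:
        mad_vals.append(np.maximum(st.mad_raw[st.present], eps))
        dwell_vals.append(np.maximum(st.dwell_med[st.present], eps))
    mad_all = np.concatenate(mad_vals) if mad_vals else np.array([])
    dwell_all = np.concatenate(dwell_vals) if dwell_vals else np.array([])
    if shared_lambda:
        fit = fit_boxcox_lambda(np.concatenate([mad_all, dwell_all]), "shared")
        return (
            BoxCoxFit(fit.lam, "signal_mad", mad_all.size),
            BoxCoxFit(fit.lam, "dwell_median", dwell_all.size),
        )
    return (
        fit_boxcox_lambda(mad_all, "signal_mad"),
        fit_boxcox_lambda(dwell_all, "dwell_median"),
    )


def filter_complete_reads(features: Sequence[ReadFeatures]) -> list[ReadFeatures]:
    """Keep only reads in which every possible k-mer was observed."""
    return [f for f in features if f.is_complete]


def write_features(features: Sequence[ReadFeatures], path: str) -> None:
    """Serialize features to TSV (read_id, class, x, then named columns)."""
    if not features:
        raise ValueError("no features to write")
    k = features[0].k
    kmers = all_kmers(k)
    cols: dict[str, list] = {"read_id": [], "class": [], "x": []}
    for fam in ("m", "d", "l"):
        for km in kmers:
            cols[f"{fam}_{km}"] = []
    for km in kmers:
        cols[f"present_{km}"] = []
    for f in features:
        if f.k != k:
            raise ValueError("mixed k in feature list")
        cols["read_id"].append(f.read_id)
        cols["class"].append("" if f.c is None else f.c)
        cols["x"].append(f.x)
        for fam in ("m", "d", "l"):
            vec = getattr(f, fam)
            for i, km in enumerate(kmers):
                cols[f"{fam}_{km}"].append(vec[i])
        for i, km in enumerate(kmers):
            cols[f"present_{km}"].append(int(f.present[i]))
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_features(path: str) -> list[ReadFeatures]:
    """Load a feature TSV written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t")
    fam_cols = [c for c in df.columns if c.startswith("m_")]
    k = len(fam_cols[0]) - 2
    kmers = all_kmers(k)
    out = []
    for _, row in df.iterrows():
        present = np.array([bool(row[f"present_{km}"]) for km in kmers])
        label = row["class"]
        out.append(
            ReadFeatures(
                read_id=str(row["read_id"]),
                k=k,
                m=np.array([row[f"m_{km}"] for km in kmers]),
                d=np.array([row[f"d_{km}"] for km in kmers]),
                l=np.array([row[f"l_{km}"] for km in kmers]),
                x=float(row["x"]),
                present=present,
                c=None if pd.isna(label) else int(label),
            )
        )
    return out
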