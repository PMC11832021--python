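"""Posterior interpretation: k-mer effect ranking and positional importance.

Each k-mer's coefficient (signal-median weight β or signal-MAD weight γ)
summarizes how strongly that k-mer's statistic shifts between the labeled
and unlabeled class.  Ranking k-mers by absolute posterior mean identifies
the strongest responders; averaging a coefficient vector over all k-mers
sharing a nucleotide at a given position gives the marginalized positional
importance of that nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .kmer_features import BASES, all_kmers, kmer_index


@dataclass(frozen=True)
class KmerEffect:
    """Posterior summary of one k-mer's coefficient."""

    kmer: str
    posterior_mean: float
    q25: float
    q75: float
    hdi_low: float
    hdi_high: float


def rank_kmers(samples: np.ndarray, k: int, hdi_prob: float = 0.94) -> list[KmerEffect]:
    """Rank k-mers by |posterior mean|, descending; ties lexicographic.

    ``samples`` is the (S, 4^k) posterior sample array of one coefficient
    vector.  Quartiles are the central box; the HDI is the narrowest
    interval holding ``hdi_prob`` of the posterior mass.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 4**k:
        raise ValueError(f"expected samples of shape (S, {4**k})")
    kmers = all_kmers(k)
    means = samples.mean(axis=0)
    q25, q75 = np.percentile(samples, [25, 75], axis=0)
    if samples.shape[0] > 1:
        hdi = az.hdi(samples[None, :, :], hdi_prob=hdi_prob)
    else:
        hdi = np.repeat(samples[0][:, None], 2, axis=1)
    effects = [
        KmerEffect(
            kmer=kmers[i],
            posterior_mean=float(means[i]),
            q25=float(q25[i]),
            q75=float(q75[i]),
            hdi_low=float(hdi[i, 0]),
            hdi_high=float(hdi[i, 1]),
        )
        for i in range(len(kmers))
    ]
    return sorted(effects, key=lambda e: (-abs(e.posterior_mean), e.kmer))


def positions(k: int) -> list[int]:
    """Position labels centered on the k-mer midpoint (e.g. -2..+2 for k=5)."""
    half = k // 2
    return list(range(-half, k - half))


def marginal_importance(values: np.ndarray, nucleotide: str, position: int, k: int) -> float:
    """Mean of ``values`` over the 4^(k-1) k-mers with ``nucleotide`` at ``position``.

    ``position`` uses the centered convention of :func:`positions`.
    """
    if nucleotide not in BASES:
        raise ValueError(f"invalid nucleotide {nucleotide!r}")
    pos_labels = positions(k)
    if position not in pos_labels:
        raise ValueError(f"position {position} not in {pos_labels} for k={k}")
    offset = pos_labels.index(position)
    values = np.asarray(values, dtype=float)
    if values.shape != (4**k,):
        raise ValueError(f"expected vector of length {4**k}")
    # k-mer index is a base-4 code; select indices whose digit at `offset` matches
    idx = np.arange(4**k)
    digit = (idx // 4 ** (k - 1 - offset)) % 4
    mask = digit == kmer_index(nucleotide)
    return float(values[mask].mean())


def importance_table(
    values: np.ndarray, k: int, use_absolute: bool = True
) -> pd.DataFrame:
    """4 × k matrix of marginal importances (rows A/C/G/T, columns positions).

    ``values`` is typically the posterior-mean β vector; by default its
    absolute values are marginalized (importance reading), signed mode is
    available with ``use_absolute=False``.
    """
    vec = np.abs(values) if use_absolute else np.asarray(values, dtype=float)
    pos_labels = positions(k)
    data = {
        pos: [marginal_importance(vec, n, pos, k) for n in BASES] for pos in pos_labels
    }
    return pd.DataFrame(data, index=list(BASES))


def effects_to_frame(effects: list[KmerEffect]) -> pd.DataFrame:
    """Tabular view of ranked k-mer effects for TSV export."""
    return pd.DataFrame(
        {
            "kmer": [e.kmer for e in effects],
            "posterior_mean": [e.posterior_mean for e in effects],
            "q25": [e.q25 for e in effects],
            "q75": [e.q75 for e in effects],
            "hdi94_low": [e.hdi_low for e in effects],
            "hdi94_high": [e.hdi_high for e in effects],
        }
    )
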