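"""Convenience composition of the signal → features stages."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .kmer_features import (
    ReadFeatures,
    ReadStats,
    assemble_features,
    extract_read_stats,
    fit_boxcox_on_stats,
)
from .normalization import normalize_read
from .signal_io import RawRead, SegmentedRead, split_signal

logger = logging.getLogger(__name__)


def extract_stats(
    raw_store: Mapping[str, RawRead],
    segmented: Sequence[SegmentedRead],
    k: int,
    labels: Mapping[str, int] | None = None,
    consistency_c: float = 1.0,
    pooling: str = "pool_samples",
) -> list[ReadStats]:
    """Normalize each segmented read and extract its raw k-mer statistics.

    Reads without raw signal in the store raise ``KeyError``; labels, when
    given, are attached by read id.
    """
    out: list[ReadStats] = []
    for seg in segmented:
        raw = raw_store[seg.read_id]
        R_r, X_r = split_signal(raw, seg)
        norm = normalize_read(seg.read_id, R_r, X_r, consistency_c=consistency_c)
        if labels is not None and seg.label is None:
            seg.label = labels.get(seg.read_id)
        stats = extract_read_stats(norm, seg, k, pooling=pooling)
        stats.label = seg.label
        out.append(stats)
    return out


def stats_to_features(
    stats: Sequence[ReadStats], fit_on_complete_only: bool = True
) -> list[ReadFeatures]:
    """Fit Box-Cox λs on these reads' statistics and assemble features.

    For a train/test protocol use :func:`poresip.evaluation.crossvalidate`
    with ``raw_stats`` instead, which refits λ per training split.
    """
    pool = [s for s in stats if s.present.all()] if fit_on_complete_only else list(stats)
    if not pool:
        pool = list(stats)
    mad_fit, dwell_fit = fit_boxcox_on_stats(pool)
    logger.info(
        "Box-Cox lambda: signal MAD %.3f, dwell %.3f", mad_fit.lam, dwell_fit.lam
    )
    return [assemble_features(s, mad_fit, dwell_fit) for s in stats]
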