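"""Seeded synthetic nanopore datasets with known isotope-effect structure.

The generator emulates the statistical structure the classifier relies on,
at the level of segmented squiggles rather than pore physics:

* each k-mer has a baseline current level (drawn N(0,1) in normalized model
  units; a real pore-model table can be supplied instead),
* each read applies a private gain/offset (machine drift, removed later by
  MAD normalization), a non-basecalled aptamer prefix, and per-event dwell
  times with a geometric tail,
* in the labeled class a sparse subset of k-mers shifts its median level
  and rescales its within-event spread — the two families of effect the
  deuterium signal shows — scaled by ``labeling_fraction`` to mimic
  partial-labeling regimes (e.g. 30% D2O).

A :class:`SyntheticTruth` table records the injected per-k-mer shifts and
scale factors for parameter-recovery tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .kmer_features import ReadFeatures, all_kmers, kmer_index
from .signal_io import (
    KmerEvent,
    RawRead,
    SegmentedRead,
    save_raw_store,
    write_eventalign,
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a full-label (100% D2O analogue) run: long reads so
    that a realistic fraction contains every 5-mer, sparse per-k-mer
    effects, and per-read drift that normalization must remove.
    """

    n_reads_per_class: int = 2000
    k: int = 5
    read_length_mean: float = 20_000.0  # nt, log-normal
    read_length_cv: float = 1.0
    min_read_length: int = 50
    pore_level_sd: float = 1.0  # spread of baseline k-mer levels
    within_event_sd: float = 0.3  # current noise around the k-mer level
    dwell_mean: float = 7.0  # samples per k-mer event (~3 kHz / 450 bp/s)
    read_gain_sd: float = 0.1  # log-sd of per-read multiplicative gain
    read_offset_sd: float = 0.5  # sd of per-read additive offset
    aptamer_length_mean: float = 120.0  # samples, log-normal
    aptamer_length_cv: float = 0.3
    aptamer_level: float = -1.0  # mean level of non-basecalled signal
    effect_median_sd: float = 0.3  # tau_m: sd of labeled-class median shifts
    effect_mad_log_sd: float = 0.25  # tau_s: sd of log MAD-scale factors
    affected_fraction: float = 0.1
    labeling_fraction: float = 1.0
    per_site_stochastic: bool = False  # Bernoulli(labeling_fraction) per event
    incomplete_read_fraction: float = 0.0  # direct path: P(read misses >=1 k-mer)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("affected_fraction", "labeling_fraction", "incomplete_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "pore_level_sd",
            "within_event_sd",
            "read_gain_sd",
            "read_offset_sd",
            "effect_median_sd",
            "effect_mad_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 sample")


@dataclass
class SyntheticTruth:
    """Injected per-k-mer effects and read labels."""

    pore_levels: np.ndarray  # baseline level per k-mer
    median_shift: np.ndarray  # 0 for unaffected k-mers
    mad_scale: np.ndarray  # 1 for unaffected k-mers
    labels: dict[str, int]
    config: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        kmers = all_kmers(self.config.k)
        return pd.DataFrame(
            {
                "kmer": kmers,
                "pore_level": self.pore_levels,
                "median_shift": self.median_shift,
                "mad_scale": self.mad_scale,
            }
        )


def _draw_truth(config: GeneratorConfig, rng: np.random.Generator) -> SyntheticTruth:
    n = 4**config.k
    levels = rng.normal(0.0, config.pore_level_sd, n)
    affected = rng.uniform(size=n) < config.affected_fraction
    shift = np.where(affected, rng.normal(0.0, config.effect_median_sd, n), 0.0)
    log_scale = np.where(affected, rng.normal(0.0, config.effect_mad_log_sd, n), 0.0)
    return SyntheticTruth(
        pore_levels=levels,
        median_shift=shift,
        mad_scale=np.exp(log_scale),
        labels={},
        config=config,
    )


def _read_lengths(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    cv = max(config.read_length_cv, 1e-6)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    mu = np.log(config.read_length_mean) - 0.5 * sigma**2
    lengths = np.maximum(rng.lognormal(mu, sigma, n), config.min_read_length)
    return np.maximum(lengths.astype(int), config.k)


def generate(
    config: GeneratorConfig,
) -> tuple[dict[str, RawRead], list[SegmentedRead], dict[str, int], SyntheticTruth]:
    """Generate raw signals, segmentations and labels for one dataset.

    Returns ``(raw_store, segmented_reads, labels, truth)``.  The same seed
    yields identical output, and writing via :func:`write_dataset` is
    byte-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    lf = config.labeling_fraction

    raw_store: dict[str, RawRead] = {}
    segmented: list[SegmentedRead] = []
    labels: dict[str, int] = {}
    n_total = 2 * config.n_reads_per_class
    lengths = _read_lengths(config, n_total, rng)
    classes = np.repeat([0, 1], config.n_reads_per_class)

    kmers = all_kmers(config.k)
    geom_p = 1.0 / max(config.dwell_mean, 1.0)
    apt_sigma = np.sqrt(np.log(1.0 + max(config.aptamer_length_cv, 1e-6) ** 2))
    apt_mu = np.log(max(config.aptamer_length_mean, 1.0)) - 0.5 * apt_sigma**2

    for i in range(n_total):
        label = int(classes[i])
        read_id = f"read{i:06d}"
        length = int(lengths[i])
        seq = rng.integers(0, 4, length)
        # base-4 rolling code of the k-mer occupying the pore
        n_events = length - config.k + 1
        kmer_idx = np.zeros(n_events, dtype=int)
        code = 0
        for j in range(config.k):
            code = code * 4 + seq[j]
        kmer_idx[0] = code
        mod = 4 ** (config.k - 1)
        for j in range(1, n_events):
            code = (code % mod) * 4 + seq[j + config.k - 1]
            kmer_idx[j] = code

        gain = float(np.exp(rng.normal(0.0, config.read_gain_sd)))
        offset = float(rng.normal(0.0, config.read_offset_sd))
        apt_len = max(int(rng.lognormal(apt_mu, apt_sigma)), 0)
        dwells = 1 + rng.geometric(geom_p, n_events)

        if config.per_site_stochastic:
            effect_on = (rng.uniform(size=n_events) < lf).astype(float) * label
        else:
            effect_on = np.full(n_events, float(label) * lf)
        shift = truth.median_shift[kmer_idx] * effect_on
        mad_scale = truth.mad_scale[kmer_idx] ** effect_on
        level = truth.pore_levels[kmer_idx] + shift

        total_event_samples = int(dwells.sum())
        samples = np.empty(apt_len + total_event_samples)
        samples[:apt_len] = rng.normal(
            gain * config.aptamer_level + offset, gain * config.within_event_sd, apt_len
        )
        noise = rng.standard_normal(total_event_samples)
        means = np.repeat(gain * level + offset, dwells)
        sds = np.repeat(gain * config.within_event_sd * mad_scale, dwells)
        samples[apt_len:] = means + sds * noise

        ends = apt_len + np.cumsum(dwells)
        starts = ends - dwells
        events = [
            KmerEvent(
                position=j,
                kmer=kmers[kmer_idx[j]],
                sample_start=int(starts[j]),
                sample_end=int(ends[j]),
            )
            for j in range(n_events)
        ]
        raw_store[read_id] = RawRead(read_id=read_id, samples=samples)
        segmented.append(SegmentedRead(read_id=read_id, events=events, label=label))
        labels[read_id] = label

    truth.labels = labels
    return raw_store, segmented, labels, truth


def write_dataset(
    raw_store: dict[str, RawRead],
    segmented: Sequence[SegmentedRead],
    labels: dict[str, int],
    truth: SyntheticTruth,
    outdir: str,
) -> dict[str, str]:
    """Write the four dataset files; returns the path of each."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "eventalign": os.path.join(outdir, "eventalign.tsv"),
        "raw_store": os.path.join(outdir, "raw_signal.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_eventalign(segmented, paths["eventalign"])
    save_raw_store(raw_store, paths["raw_store"])
    pd.DataFrame(
        {"read_id": list(labels), "class": list(labels.values())}
    ).to_csv(paths["labels"], sep="\t", index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def generate_features_direct(
    config: GeneratorConfig,
) -> tuple[list[ReadFeatures], SyntheticTruth]:
    """Draw per-read features directly from the implied distributions.

    A fast path for model- and evaluation-level tests: skips signal
    synthesis and produces the class-conditional feature vectors the
    pipeline would extract from an ideal run.  Signal-MAD and dwell
    features are returned on the log scale (the Box-Cox λ=0 member), so the
    features plug straight into the model.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    lf = config.labeling_fraction
    n_kmers = 4**config.k

    # expected pooled samples per k-mer per read controls feature noise
    n_events = max(config.read_length_mean - config.k + 1, 1.0)
    occ_per_kmer = max(n_events / n_kmers, 1.0)
    pooled = occ_per_kmer * config.dwell_mean
    median_noise_sd = 1.2533 * config.within_event_sd / np.sqrt(pooled)
    mad_rel_noise_sd = 1.0 / np.sqrt(2.0 * pooled)

    features: list[ReadFeatures] = []
    labels: dict[str, int] = {}
    n_total = 2 * config.n_reads_per_class
    classes = np.repeat([0, 1], config.n_reads_per_class)
    for i in range(n_total):
        label = int(classes[i])
        read_id = f"read{i:06d}"
        eff = label * lf
        m = (
            truth.pore_levels
            + truth.median_shift * eff
            + rng.normal(0.0, median_noise_sd, n_kmers)
        )
        mad_raw = (
            config.within_event_sd
            * truth.mad_scale**eff
            * np.exp(rng.normal(0.0, mad_rel_noise_sd, n_kmers))
        )
        dwell = np.maximum(
            np.round(rng.normal(config.dwell_mean, 1.0, n_kmers)), 1.0
        )
        present = np.ones(n_kmers, dtype=bool)
        if rng.uniform() < config.incomplete_read_fraction:
            present[rng.integers(0, n_kmers)] = False
        m[~present] = np.nan
        mad_raw[~present] = np.nan
        dwell[~present] = np.nan
        x = float(rng.normal(config.aptamer_level, 0.1))
        with np.errstate(invalid="ignore"):
            features.append(
                ReadFeatures(
                    read_id=read_id,
                    k=config.k,
                    m=m,
                    d=np.log(mad_raw),
                    l=np.log(dwell),
                    x=x,
                    present=present,
                    c=label,
                )
            )
        labels[read_id] = label
    truth.labels = labels
    return features, truth
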