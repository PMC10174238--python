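"""Synthetic cohorts with planted time-varying spectral coupling.

Two generators live here:

* :func:`toy_pair` — a pair of equal-frequency sinusoids with a phase
  shift (pi/2 by default): near-zero time-domain correlation over an
  integer number of periods, yet identical power spectra.  This is the
  minimal illustration of why spectral coupling sees what time-domain
  correlation misses.

* :func:`simulate_cohort` — a 2-diagnosis x 2-sex cohort of C components
  x T timepoints whose spectral coupling is block-structured and group
  dependent.  Each network block owns K narrowband oscillators
  (frequencies in the resting-state BOLD band, 0.01-0.1 Hz).  A component
  in a block drives each oscillator with an amplitude envelope that is a
  convex mixture

      e = lambda * (shared block envelope) + (1 - lambda) * (private envelope)

  of a block-shared and a component-private slowly varying positive
  envelope; plus white measurement noise.  The mixing weight ``lambda``
  is ``coupling_hc`` or ``coupling_sz`` for components of the effect
  block (depending on the subject's diagnosis) and ``base_coupling``
  elsewhere.  Shared envelopes make the windowed power spectra of
  same-block components co-vary, which raises WW correlations and
  top-quartile occupancy — exactly the statistic the trSC pipeline
  measures, so a planted HC/SZ coupling difference is recoverable by the
  group regression.

  Envelopes are moving-average-smoothed Gaussian noise passed through a
  softplus, so they are strictly positive and vary on a ~20 TR timescale.
  Seeding spawns one child stream per subject from the master seed, so
  enlarging the cohort never changes earlier subjects' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    DOMAINS,
    CohortMetadata,
    NetworkLabels,
    TimecourseDataset,
    ValidationError,
)

#: default per-domain component counts at the 47-component study scale
DEFAULT_DOMAIN_SIZES = {"SC": 5, "AUD": 2, "VIS": 9, "SM": 9, "CC": 11, "DM": 7, "CB": 4}


@dataclass(frozen=True)
class ToySpec:
    """Configuration of the two-sinusoid toy example."""

    n_samples: int = 159
    tr_seconds: float = 2.0
    frequency_hz: float = 0.05
    phase_shift_rad: float = math.pi / 2
    noise_sd: float = 0.0
    seed: int = 0


def toy_pair(spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Two sinusoids x, y of equal frequency, phase-shifted, with optional noise.

    ``x(t) = sin(2*pi*f*t*TR) + e1``, ``y(t) = sin(2*pi*f*t*TR + phi) + e2``.
    """
    nyquist = 1.0 / (2.0 * spec.tr_seconds)
    if spec.frequency_hz >= nyquist:
        raise ValidationError(
            f"frequency {spec.frequency_hz} Hz is at/above Nyquist ({nyquist} Hz)"
        )
    if spec.noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    t = np.arange(spec.n_samples) * spec.tr_seconds
    rng = np.random.default_rng(spec.seed)
    x = np.sin(2 * np.pi * spec.frequency_hz * t)
    y = np.sin(2 * np.pi * spec.frequency_hz * t + spec.phase_shift_rad)
    if spec.noise_sd > 0:
        x = x + rng.normal(0, spec.noise_sd, spec.n_samples)
        y = y + rng.normal(0, spec.noise_sd, spec.n_samples)
    return x, y


def default_blocks(n_components: int) -> dict[str, list[int]]:
    """Partition component indices into the seven domains, sizes proportional
    to the 47-component defaults (every domain keeps at least one component)."""
    total = sum(DEFAULT_DOMAIN_SIZES.values())
    raw = {d: DEFAULT_DOMAIN_SIZES[d] * n_components / total for d in DOMAINS}
    if n_components < len(DOMAINS):
        # too few components for full coverage: fill the largest domains first
        order = sorted(DOMAINS, key=lambda d: -DEFAULT_DOMAIN_SIZES[d])
        sizes = {d: (1 if i < n_components else 0) for i, d in enumerate(order)}
    else:
        sizes = {d: max(1, int(raw[d])) for d in DOMAINS}
        # distribute the remainder by largest fractional part, deterministically
        while sum(sizes.values()) < n_components:
            d = max(DOMAINS, key=lambda d: (raw[d] - sizes[d], d))
            sizes[d] += 1
        while sum(sizes.values()) > n_components:
            d = max(
                (d for d in DOMAINS if sizes[d] > 1), key=lambda d: (sizes[d] - raw[d], d)
            )
            sizes[d] -= 1
    blocks: dict[str, list[int]] = {}
    start = 0
    for d in DOMAINS:
        blocks[d] = list(range(start, start + sizes[d]))
        start += sizes[d]
    return blocks


@dataclass
class SimulationConfig:
    """Cohort simulator settings; defaults mirror the study dimensions."""

    n_per_cell: int = 10
    n_components: int = 47
    n_timepoints: int = 159
    tr_seconds: float = 2.0
    network_blocks: dict[str, list[int]] | None = None
    base_coupling: float = 0.5
    effect_block: str = "VIS"
    coupling_hc: float = 0.5
    coupling_sz: float = 0.5
    noise_sd: float = 0.5
    n_oscillators: int = 4
    envelope_smooth_tr: int = 60
    envelope_gain: float = 2.0
    freq_band_hz: tuple[float, float] = (0.01, 0.1)
    seed: int = 0

    blocks: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.blocks = (
            dict(self.network_blocks) if self.network_blocks else default_blocks(self.n_components)
        )
        flat = sorted(i for ids in self.blocks.values() for i in ids)
        if flat != list(range(self.n_components)):
            raise ValidationError("network_blocks must partition component indices 0..C-1")
        if self.effect_block not in self.blocks:
            raise ValidationError(f"effect_block {self.effect_block!r} not among blocks")
        for name, lam in (
            ("base_coupling", self.base_coupling),
            ("coupling_hc", self.coupling_hc),
            ("coupling_sz", self.coupling_sz),
        ):
            if not 0.0 <= lam <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {lam}")
        if self.n_per_cell < 1:
            raise ValidationError("n_per_cell must be at least 1")


def _envelope(rng: np.random.Generator, n: int, smooth: int, gain: float) -> np.ndarray:
    """Strictly positive slowly varying envelope: softplus of MA-smoothed noise.

    The smoothing span sets the envelope timescale; it must be slower than
    the analysis window for windowed power to track the envelope (the
    default 60 TR exceeds the default 50-TR window).  ``gain`` scales the
    latent noise before the softplus and so sets the modulation depth.
    """
    z = rng.normal(0, 1, n + smooth - 1)
    z = np.convolve(z, np.ones(smooth) / smooth, mode="valid")
    z = z * math.sqrt(smooth)  # restore unit variance after averaging
    return np.log1p(np.exp(gain * z))  # softplus: positive, strong dynamic range


def _simulate_subject(
    cfg: SimulationConfig, diagnosis: str, seed_seq: np.random.SeedSequence
) -> np.ndarray:
    rng = np.random.default_rng(seed_seq)
    T, C = cfg.n_timepoints, cfg.n_components
    t = np.arange(T) * cfg.tr_seconds
    data = np.zeros((C, T))
    for block_name, members in cfg.blocks.items():
        if block_name == cfg.effect_block:
            lam = cfg.coupling_hc if diagnosis == "HC" else cfg.coupling_sz
        else:
            lam = cfg.base_coupling
        freqs = rng.uniform(*cfg.freq_band_hz, cfg.n_oscillators)
        shared = np.stack(
            [
                _envelope(rng, T, cfg.envelope_smooth_tr, cfg.envelope_gain)
                for _ in range(cfg.n_oscillators)
            ]
        )
        for c in members:
            phases = rng.uniform(0, 2 * np.pi, cfg.n_oscillators)
            for k in range(cfg.n_oscillators):
                private = _envelope(rng, T, cfg.envelope_smooth_tr, cfg.envelope_gain)
                env = lam * shared[k] + (1 - lam) * private
                data[c] += env * np.sin(2 * np.pi * freqs[k] * t + phases[k])
            data[c] += rng.normal(0, cfg.noise_sd, T)
    return data


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[TimecourseDataset, CohortMetadata, NetworkLabels]:
    """Simulate a balanced 2x2 (diagnosis x sex) cohort.

    Subjects are ordered by (diagnosis, sex) cell: HC/F, HC/M, SZ/F, SZ/M,
    ``n_per_cell`` subjects each.  Deterministic for a given config.
    """
    cells = [("HC", "F"), ("HC", "M"), ("SZ", "F"), ("SZ", "M")]
    rows = []
    matrices = []
    idx = 0
    for cell_idx, (dx, sex) in enumerate(cells):
        for k in range(cfg.n_per_cell):
            sid = f"sub{idx + 1:04d}"
            rows.append((sid, dx, sex))
            # substream keyed by (cell, within-cell index): growing the
            # cohort never changes earlier subjects' data
            child = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(cell_idx, k))
            matrices.append(_simulate_subject(cfg, dx, child))
            idx += 1
    component_ids = [f"comp{i + 1:03d}" for i in range(cfg.n_components)]
    dataset = TimecourseDataset(
        data=np.stack(matrices),
        subject_ids=[r[0] for r in rows],
        component_ids=component_ids,
        tr_seconds=cfg.tr_seconds,
    )
    metadata = CohortMetadata(pd.DataFrame(rows, columns=["subject_id", "diagnosis", "sex"]))
    labels = NetworkLabels(
        {component_ids[i]: d for d, ids in cfg.blocks.items() for i in ids}
    )
    return dataset, metadata, labels
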