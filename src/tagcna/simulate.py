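"""Synthetic tumor/normal cohorts with ground-truth consensus events.

Each subject's observed log2-ratio is built by mixing tumor and normal cells:
a marker with tumor copy number ``c_t`` in a sample with normal-cell fraction
``p`` reads ``log2(((1 - p) * c_t + 2 p) / 2)`` plus i.i.d. Gaussian marker
noise whose per-subject SD is drawn uniformly from ``noise_sd_range``.
Consensus events (SCEs) are intervals shared by a fixed fraction f of
subjects; passenger alterations are per-subject intervals at independent
uniformly random positions, so no locus is enriched across the cohort.
A background-only cohort (no SCEs) therefore realises the complete null.

Pure-tumor event "ratios" follow the copy-number annotation convention
0.585 = 3 copies, 1.322 = 5 copies: a spec ratio r maps to tumor copy number
``c_t = 2 * 2**r`` before mixing (so r < 0 encodes deletions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io_formats import AMP, DEL, MarkerMap, RatioMatrix

__all__ = [
    "SCESpec",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_null_cohort",
    "simulate_contamination_sweep",
    "power_config",
    "null_config",
    "contamination_config",
]

_GUARD_GAP = 100  # markers kept clear between consensus intervals
_MARKER_SPACING_BP = 1000


@dataclass(frozen=True)
class SCESpec:
    """One embedded consensus event: pure-tumor log2-ratio, length, frequency."""

    ratio: float
    length: int
    frequency: float
    polarity: str

    def __post_init__(self) -> None:
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must lie in (0, 1]")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.polarity not in (AMP, DEL):
            raise ValueError("polarity must be 'amp' or 'del'")
        if self.polarity == AMP and self.ratio <= 0:
            raise ValueError("amplification SCE needs ratio > 0")
        if self.polarity == DEL and self.ratio >= 0:
            raise ValueError("deletion SCE needs ratio < 0")

    @property
    def tumor_copies(self) -> float:
        return 2.0 * 2.0 ** self.ratio


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator settings; defaults are the study's standard conditions.

    ``normal_fraction_model`` is ``("uniform", lo, hi)``, ``("gaussian", mean,
    sd)`` (truncated to [0, 0.99]) or ``None`` for pure tumor samples.
    """

    n_subjects: int = 100
    n_markers: int = 10_000
    sce_specs: tuple = (
        SCESpec(0.585, 200, 0.15, AMP),
        SCESpec(1.0, 100, 0.15, AMP),
        SCESpec(1.322, 50, 0.15, AMP),
    )
    noise_sd_range: tuple = (0.1, 0.2)
    normal_fraction_model: Optional[tuple] = ("uniform", 0.3, 0.7)
    n_passenger_regions: int = 2
    passenger_length_range: tuple = (50, 500)
    passenger_ratio_range: tuple = (0.585, 1.322)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sce_specs", tuple(self.sce_specs))
        if self.n_subjects < 1 or self.n_markers < 2:
            raise ValueError("need n_subjects >= 1 and n_markers >= 2")
        lo, hi = self.noise_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("noise_sd_range must be a non-negative interval")
        total = sum(s.length for s in self.sce_specs)
        if total > self.n_markers:
            raise ValueError("SCE lengths exceed the marker count")
        m = self.normal_fraction_model
        if m is not None:
            kind = m[0]
            if kind not in ("uniform", "gaussian") or len(m) != 3:
                raise ValueError(
                    "normal_fraction_model must be ('uniform', lo, hi), "
                    "('gaussian', mean, sd) or None"
                )


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth tracks of a simulated cohort (marker-index coordinates)."""

    sce_intervals: tuple  # ((start, end), ...) half-open
    sce_polarity: tuple
    carrier_sets: tuple  # one subject-index array per SCE
    passenger_intervals: tuple  # per subject: ((start, end), ...)
    marker_labels: np.ndarray  # True inside any SCE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "marker_labels", np.asarray(self.marker_labels, dtype=bool)
        )


def _place_sces(rng, L: int, lengths: Sequence[int], gap: int = _GUARD_GAP):
    """Non-overlapping seeded-uniform interval placement with a guard gap."""
    if not lengths:
        return []
    if sum(lengths) + gap * (len(lengths) - 1) > L:
        raise ValueError("consensus intervals cannot fit on the simulated genome")
    for _ in range(10_000):
        starts = [int(rng.integers(0, L - ln + 1)) for ln in lengths]
        iv = sorted(zip(starts, lengths))
        ok = True
        prev_end = None
        for s, ln in iv:
            if prev_end is not None and s < prev_end + gap:
                ok = False
                break
            prev_end = s + ln
        if ok:
            return [(s, s + ln) for s, ln in zip(starts, lengths)]
    raise ValueError("could not place consensus intervals after 10000 attempts")


def _draw_normal_fractions(rng, model, n: int) -> np.ndarray:
    if model is None:
        return np.zeros(n)
    kind, a, b = model
    if kind == "uniform":
        return rng.uniform(a, b, n)
    p = rng.normal(a, b, n)
    return np.clip(p, 0.0, 0.99)  # truncation: a fraction must be a fraction


def _mix(c_t, p):
    """Observed log2-ratio of tumor copy number c_t at normal fraction p."""
    return np.log2(((1.0 - p) * c_t + 2.0 * p) / 2.0)


def simulate_cohort(config: SimConfig):
    """Generate one cohort; returns ``(RatioMatrix raw, SimTruth)``.

    Consensus-event positions are fixed across subjects; passenger intervals
    are drawn per subject, rejection-sampled so they never touch a consensus
    interval (keeping the truth labels unambiguous).
    """
    rng = np.random.default_rng(config.seed)
    N, L = config.n_subjects, config.n_markers

    sce_iv = _place_sces(rng, L, [s.length for s in config.sce_specs])
    carriers = tuple(
        np.sort(rng.choice(N, size=int(round(s.frequency * N)), replace=False))
        for s in config.sce_specs
    )

    copies = np.full((N, L), 2.0)
    for spec, (s, e), who in zip(config.sce_specs, sce_iv, carriers):
        copies[who, s:e] = spec.tumor_copies

    blocked = np.zeros(L, dtype=bool)
    for s, e in sce_iv:
        blocked[s:e] = True

    lo_len, hi_len = config.passenger_length_range
    lo_r, hi_r = config.passenger_ratio_range
    passengers = []
    for n in range(N):
        mine: list = []
        taken = blocked.copy()
        for _ in range(config.n_passenger_regions):
            for _attempt in range(1000):
                ln = int(rng.integers(lo_len, hi_len + 1))
                if ln > L:
                    raise ValueError("passenger region longer than the genome")
                s = int(rng.integers(0, L - ln + 1))
                if not taken[s : s + ln].any():
                    break
            else:
                raise ValueError("could not place a passenger region")
            r = rng.uniform(lo_r, hi_r)
            copies[n, s : s + ln] = 2.0 * 2.0 ** r
            taken[s : s + ln] = True
            mine.append((s, s + ln))
        passengers.append(tuple(mine))

    p = _draw_normal_fractions(rng, config.normal_fraction_model, N)
    signal = _mix(copies, p[:, None])
    sd = rng.uniform(config.noise_sd_range[0], config.noise_sd_range[1], N)
    values = signal + rng.standard_normal((N, L)) * sd[:, None]

    markers = MarkerMap(
        np.array([f"M{i + 1:06d}" for i in range(L)], dtype=object),
        np.array(["chr1"] * L, dtype=object),
        1 + _MARKER_SPACING_BP * np.arange(L, dtype=np.int64),
    )
    subjects = [f"S{i + 1:04d}" for i in range(N)]
    labels = blocked
    truth = SimTruth(
        sce_intervals=tuple(sce_iv),
        sce_polarity=tuple(s.polarity for s in config.sce_specs),
        carrier_sets=carriers,
        passenger_intervals=tuple(passengers),
        marker_labels=labels,
    )
    return RatioMatrix(values, subjects, markers), truth


def simulate_null_cohort(config: SimConfig):
    """Background-only cohort (no consensus events anywhere)."""
    if config.sce_specs:
        raise ValueError("null cohort config must not define SCEs")
    return simulate_cohort(config)


def simulate_contamination_sweep(sd_values: Sequence[float], base: SimConfig):
    """One cohort per contamination SD, identical apart from the spread.

    The normal-cell fraction follows a Gaussian with mean 0.6 and the given
    SD, truncated to [0, 0.99]; every cohort reuses the base seed so they
    differ only through the contamination model.
    """
    out = []
    for sd in sd_values:
        if sd <= 0:
            raise ValueError("contamination SD must be positive")
        cfg = replace(base, normal_fraction_model=("gaussian", 0.6, float(sd)))
        raw, truth = simulate_cohort(cfg)
        out.append((float(sd), raw, truth))
    return out


# ---------------------------------------------------------------------------
# presets


def _scaled_passenger_lengths(n_markers: int) -> tuple:
    """Passenger length range, shrunk in proportion to the genome size.

    The reference conditions are 50-500 markers on a 10,000-marker genome;
    smaller desk-scale genomes keep the same background *coverage rate* by
    scaling the lengths, not their count.
    """
    f = n_markers / 10_000
    return (max(2, round(50 * f)), max(5, round(500 * f)))


def power_config(noise=(0.1, 0.2), frequency: float = 0.15,
                 n_subjects: int = 100, n_markers: int = 10_000,
                 seed: int = 0) -> SimConfig:
    """Power-study preset: three amplification SCEs of stated ratio/length."""
    specs = tuple(
        SCESpec(r, ln, frequency, AMP)
        for r, ln in zip((0.585, 1.0, 1.322), (200, 100, 50))
    )
    return SimConfig(
        n_subjects=n_subjects,
        n_markers=n_markers,
        sce_specs=specs,
        noise_sd_range=tuple(noise),
        passenger_length_range=_scaled_passenger_lengths(n_markers),
        seed=seed,
    )


def null_config(noise=(0.1, 0.2), n_subjects: int = 100,
                n_markers: int = 10_000, seed: int = 0) -> SimConfig:
    """Background-only preset for type-I-error studies."""
    return SimConfig(
        n_subjects=n_subjects,
        n_markers=n_markers,
        sce_specs=(),
        noise_sd_range=tuple(noise),
        passenger_length_range=_scaled_passenger_lengths(n_markers),
        seed=seed,
    )


def contamination_config(sd: float = 0.1, n_subjects: int = 100,
                         n_markers: int = 10_000, seed: int = 0) -> SimConfig:
    """Contamination preset: one amplified and one deleted SCE at f = 0.15.

    The amplification sits at ratio 1.322 (5 copies) so that it stands clear
    of the passenger gains (which reach the same ratio) at low contamination;
    the deletion is a one-copy loss (ratio -1).
    """
    specs = (SCESpec(1.322, 100, 0.15, AMP), SCESpec(-1.0, 100, 0.15, DEL))
    return SimConfig(
        n_subjects=n_subjects,
        n_markers=n_markers,
        sce_specs=specs,
        noise_sd_range=(0.1, 0.2),
        normal_fraction_model=("gaussian", 0.6, float(sd)),
        passenger_length_range=_scaled_passenger_lengths(n_markers),
        seed=seed,
    )
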