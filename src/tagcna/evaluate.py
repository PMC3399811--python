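"""Evaluation of SCE calls against simulation truth.

Marker-level accounting throughout: a marker counts as "called" when it lies
inside a block whose tag's final p-value beats the threshold, and truth is
the per-marker SCE label of the simulator.  On top of that sit the three
study harnesses: ROC curves over significance levels, empirical type-I error
on background-only cohorts, and detection power across contamination levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pipeline import CohortAnalysis, RunConfig, analyze_cohort
from .simulate import SimConfig, simulate_cohort

__all__ = [
    "RocCurve",
    "marker_rates",
    "analysis_marker_rates",
    "roc_curve",
    "type_I_error",
    "sces_detected",
    "contamination_power",
    "average_marker_rates",
]


@dataclass(frozen=True)
class RocCurve:
    """TPR/FPR per significance threshold, averaged over replications."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "tpr", "fpr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.thresholds.size == self.tpr.size == self.fpr.size):
            raise ValueError("thresholds, tpr and fpr must align")
        if np.any((self.tpr < 0) | (self.tpr > 1) | (self.fpr < 0) | (self.fpr > 1)):
            raise ValueError("rates must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


def _rates_from_mask(called: np.ndarray, truth_labels: np.ndarray):
    truth_labels = np.asarray(truth_labels, dtype=bool)
    n_pos = int(truth_labels.sum())
    n_neg = truth_labels.size - n_pos
    tpr = float(called[truth_labels].sum() / n_pos) if n_pos else 0.0
    fpr = float(called[~truth_labels].sum() / n_neg) if n_neg else 0.0
    return tpr, fpr


def marker_rates(result, partition, truth, threshold: float):
    """Marker-level (TPR, FPR) of one peel-off result on one chromosome.

    A marker is called when its block's tag has final p-value < threshold;
    the degenerate level 1 accepts everything (so the ROC closes at (1, 1))
    while level 0 accepts nothing.
    """
    called = np.zeros(partition.n_markers, dtype=bool)
    for m, (s, e) in enumerate(partition.blocks):
        if result.p_values[m] < threshold or threshold >= 1.0:
            called[s:e] = True
    return _rates_from_mask(called, truth.marker_labels)


def analysis_marker_rates(analysis: CohortAnalysis, truth, threshold: float):
    """Marker-level (TPR, FPR) of a full two-polarity analysis."""
    called = analysis.called_marker_mask(threshold)
    return _rates_from_mask(called, truth.marker_labels)


def _spawn_seeds(seed: int, n: int, k: int = 2):
    """n x k deterministic child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [
        [int(v % (2**31)) for v in child.generate_state(k)] for child in ss.spawn(n)
    ]


def _replicate(config: SimConfig, run: RunConfig, rep_seeds):
    sim_seed, run_seed = rep_seeds
    raw, truth = simulate_cohort(replace(config, seed=sim_seed))
    analysis = analyze_cohort(raw, replace(run, seed=run_seed))
    return analysis, truth


def roc_curve(n_reps: int, config: SimConfig, run: RunConfig,
              thresholds=None) -> RocCurve:
    """TPR versus FPR at a grid of significance levels, averaged over reps."""
    if thresholds is None:
        thresholds = np.r_[0.0, np.geomspace(1e-3, 1.0, 25)]
    thresholds = np.asarray(thresholds, float)
    tpr = np.zeros_like(thresholds)
    fpr = np.zeros_like(thresholds)
    for seeds in _spawn_seeds(config.seed, n_reps):
        analysis, truth = _replicate(config, run, seeds)
        for i, t in enumerate(thresholds):
            a, b = analysis_marker_rates(analysis, truth, t)
            tpr[i] += a
            fpr[i] += b
    return RocCurve(thresholds, tpr / n_reps, fpr / n_reps)


def type_I_error(n_reps: int, null_config: SimConfig, run: RunConfig,
                 alpha: float = 0.05) -> float:
    """Fraction of null replications with any significant tag (either polarity)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if alpha <= 0:
        return 0.0
    hits = 0
    for seeds in _spawn_seeds(null_config.seed, n_reps):
        analysis, _ = _replicate(null_config, run, seeds)
        if analysis.any_significant(alpha):
            hits += 1
    return hits / n_reps


def sces_detected(analysis: CohortAnalysis, truth, alpha: float):
    """Per-SCE detection flags: a significant same-polarity block overlaps it."""
    flags = []
    for (s, e), pol in zip(truth.sce_intervals, truth.sce_polarity):
        called = analysis.called_marker_mask(alpha, polarity=pol)
        flags.append(bool(called[s:e].any()))
    return flags


def contamination_power(sd_values, base: SimConfig, run: RunConfig,
                        alpha: float = 0.05, n_reps: int = 100) -> pd.DataFrame:
    """Power per contamination SD: fraction of reps with every SCE detected."""
    sd_values = [float(s) for s in sd_values]
    power = np.zeros(len(sd_values))
    seeds = _spawn_seeds(base.seed, n_reps)
    for rep_seeds in seeds:
        sim_seed, run_seed = rep_seeds
        for i, sd in enumerate(sd_values):
            cfg = replace(
                base, normal_fraction_model=("gaussian", 0.6, sd), seed=sim_seed
            )
            raw, truth = simulate_cohort(cfg)
            analysis = analyze_cohort(raw, replace(run, seed=run_seed))
            if alpha > 0 and all(sces_detected(analysis, truth, alpha)):
                power[i] += 1
    return pd.DataFrame({"sd": sd_values, "power": power / n_reps})


def average_marker_rates(n_reps: int, config: SimConfig, run: RunConfig,
                         threshold: float = 0.05):
    """Mean (TPR, FPR) over replications at one significance threshold."""
    tprs = []
    fprs = []
    for seeds in _spawn_seeds(config.seed, n_reps):
        analysis, truth = _replicate(config, run, seeds)
        a, b = analysis_marker_rates(analysis, truth, threshold)
        tprs.append(a)
        fprs.append(b)
    return float(np.mean(tprs)), float(np.mean(fprs))
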