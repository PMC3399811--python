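"""Scoring, peel-off permutation null distributions and SCE calling.

Each tag marker m is scored by S_m = sum_n |t_nm|: subjects contribute the
magnitude of their aberration at the tag, so both the frequency and the
amplitude of alteration enter the statistic.  Significance is assessed against
the max-T permutation null: every subject's row of tag values is independently
shuffled across tag positions, and the distribution of the maximum column
score over E such permutations controls the family-wise error rate.

Because observed matrices mix true consensus events (false null hypotheses)
with background alterations, the first null distribution D_1 is right-shifted.
The peel-off scheme removes every tag significant under D_h, rebuilds the null
from the remaining columns, and iterates until no further tag is significant;
the null mean drifts left toward that of a background-only matrix.  Finally
all original tags are re-assessed against the last distribution D_H, which
both recovers less-extreme consensus events and corrects the p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AMP, DEL, CallMatrix, MarkerMap, RatioMatrix, SCERegion
from .tag_selection import BlockPartition, TagMatrix

__all__ = [
    "NullDistribution",
    "PeelOffResult",
    "split_by_threshold",
    "score_tags",
    "permute_tags",
    "null_distribution",
    "p_values",
    "peel_off",
    "call_sces",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NullDistribution:
    """E permutation maxima of the tag score, from peel-off iteration h."""

    maxima: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.maxima, dtype=np.float64)
        object.__setattr__(self, "maxima", m)
        if m.size < 1:
            raise ValueError("null distribution needs at least one permutation")
        if np.any(m < 0):
            raise ValueError("score maxima are non-negative by construction")

    @property
    def E(self) -> int:
        return self.maxima.size

    @property
    def mean(self) -> float:
        return float(self.maxima.mean())


@dataclass(frozen=True)
class PeelOffResult:
    """Outcome of the iterative peel-off procedure on one tag matrix.

    ``p_values`` are the final per-tag p-values of *all* original tags under
    the last null distribution D_H.  ``removed_at`` gives the iteration at
    which a tag was peeled (0 = never peeled).
    """

    p_values: np.ndarray
    scores: np.ndarray
    removed_at: np.ndarray
    distributions: tuple
    alpha: float
    E: int
    tag_matrix: TagMatrix

    @property
    def H(self) -> int:
        return len(self.distributions)

    @property
    def null_means(self) -> np.ndarray:
        return np.array([d.mean for d in self.distributions])

    @property
    def n_tags(self) -> int:
        return self.p_values.size


def split_by_threshold(X: RatioMatrix, theta_amp: float, theta_del: float):
    """Separate a ratio matrix into amplification and deletion call matrices.

    Cells with value >= theta_amp (resp. <= theta_del, both inclusive) keep
    their log2-ratio; every other cell becomes exactly zero.
    """
    if not (theta_amp > 0 > theta_del):
        raise ValueError("need theta_amp > 0 > theta_del")
    v = X.values
    amp = np.where(v >= theta_amp, v, 0.0)
    dele = np.where(v <= theta_del, v, 0.0)
    return (
        CallMatrix(amp, AMP, theta_amp, theta_del),
        CallMatrix(dele, DEL, theta_amp, theta_del),
    )


def score_tags(T: TagMatrix) -> np.ndarray:
    """S_m = sum over subjects of |t_nm| at each tag marker."""
    return np.abs(T.values).sum(axis=0)


def permute_tags(T: TagMatrix, seed=0) -> TagMatrix:
    """Independently permute each subject's values across tag positions."""
    if T.n_tags < 2:
        return TagMatrix(T.values.copy(), T.partition, T.polarity)
    rng = _as_rng(seed)
    return TagMatrix(rng.permuted(T.values, axis=1), T.partition, T.polarity)


def _null_maxima(A: np.ndarray, E: int, rng: np.random.Generator) -> np.ndarray:
    """Max column sum of |values| under E independent row-wise permutations."""
    N, M = A.shape
    if M < 2 or N == 0:
        # permutation cannot change anything
        return np.full(E, A.sum(axis=0).max() if A.size else 0.0)
    maxima = np.empty(E)
    chunk = max(1, int(4_000_000 // max(A.size, 1)))
    done = 0
    while done < E:
        c = min(chunk, E - done)
        tiled = np.tile(A, (c, 1))
        permuted = rng.permuted(tiled, axis=1).reshape(c, N, M)
        maxima[done : done + c] = permuted.sum(axis=1).max(axis=1)
        done += c
    return maxima


def null_distribution(T: TagMatrix, E: int, seed=0, iteration: int = 1) -> NullDistribution:
    """E permutation maxima of the tag score for matrix T."""
    if E < 1:
        raise ValueError("E must be >= 1")
    rng = _as_rng(seed)
    return NullDistribution(_null_maxima(np.abs(T.values), E, rng), iteration)


def p_values(scores, D: NullDistribution, add_one: bool = False) -> np.ndarray:
    """Right-tail permutation p-values of the scores under D.

    The default estimator is the plain exceedance fraction
    ``p = #{e : max_e >= S} / E`` (which can return 0); ``add_one=True``
    selects the (1 + count) / (1 + E) variant that is bounded away from zero.
    """
    s = np.asarray(scores, dtype=np.float64)
    srt = np.sort(D.maxima)
    counts = D.E - np.searchsorted(srt, s, side="left")
    if add_one:
        return (1.0 + counts) / (1.0 + D.E)
    return counts / D.E


def peel_off(T: TagMatrix, E: int, alpha: float, seed=0,
             add_one: bool = False) -> PeelOffResult:
    """Iterative peel-off permutation test on tag matrix T.

    At iteration h the null D_h is built from the current matrix T_h, every
    tag with p < alpha under D_h is removed, and the loop repeats until an
    iteration removes nothing (or every tag has been peeled, in which case
    the last non-empty matrix supplies D_H and a warning is emitted).  All
    original tags are then re-assessed against D_H.
    """
    if not (0 <= alpha < 1):
        raise ValueError("alpha must lie in [0, 1)")
    if E < 1:
        raise ValueError("E must be >= 1")
    rng = _as_rng(seed)
    M = T.n_tags
    scores = score_tags(T)
    active = np.ones(M, dtype=bool)
    removed_at = np.zeros(M, dtype=np.int64)
    dists: list = []
    h = 1
    while True:
        A = np.abs(T.values[:, active])
        D_h = NullDistribution(_null_maxima(A, E, rng), h)
        dists.append(D_h)
        p_cur = p_values(scores[active], D_h, add_one=add_one)
        sig = p_cur < alpha
        if not sig.any():
            break
        idx = np.flatnonzero(active)[sig]
        removed_at[idx] = h
        active[idx] = False
        if not active.any():
            warnings.warn(
                "peel-off removed every tag; null distribution kept from the "
                "last non-empty matrix",
                stacklevel=2,
            )
            break
        h += 1
    final_p = p_values(scores, dists[-1], add_one=add_one)
    return PeelOffResult(
        p_values=final_p,
        scores=scores,
        removed_at=removed_at,
        distributions=tuple(dists),
        alpha=float(alpha),
        E=int(E),
        tag_matrix=T,
    )


def call_sces(result: PeelOffResult, partition: BlockPartition,
              markers: MarkerMap, alpha: float) -> list:
    """Map significant tags to SCE regions spanning their blocks.

    ``markers`` must be the marker map of the same chromosome slice the
    partition was built on.
    """
    if len(markers) != partition.n_markers:
        raise ValueError("marker map does not match the partition")
    regions = []
    for m, ((s, e), tag) in enumerate(zip(partition.blocks, partition.tag_index)):
        if result.p_values[m] < alpha:
            col = result.tag_matrix.values[:, m]
            regions.append(
                SCERegion(
                    chrom=str(markers.chrom[s]),
                    start_pos=int(markers.pos[s]),
                    end_pos=int(markers.pos[e - 1]),
                    tag_marker_id=str(markers.marker_id[tag]),
                    polarity=result.tag_matrix.polarity,
                    score=float(result.scores[m]),
                    p_value=float(result.p_values[m]),
                    n_subjects_aberrant=int(np.count_nonzero(col)),
                )
            )
    return regions
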