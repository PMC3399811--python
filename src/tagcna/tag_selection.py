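"""Tag-marker selection from windowed inter-marker correlation blocks.

Adjacent copy-number markers are inherently correlated because alterations are
segmental.  To test blocks rather than individual markers, each marker k gets
a correlation value: the average Pearson correlation (across subjects) between
its column and every column within floor(w/2) markers on either side,
truncated at chromosome ends.  The profile is then partitioned with CBS into
correlation blocks, and the middle marker of each block becomes its tag.
Scoring and permutation downstream operate on tags only.

Columns with zero variance across subjects (no aberration anywhere) carry no
consensus signal; their correlation with anything is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CallMatrix
from .segmentation import cbs_segment

__all__ = [
    "CorrelationProfile",
    "BlockPartition",
    "TagMatrix",
    "pairwise_correlation",
    "correlation_profile",
    "partition_blocks",
    "build_tag_matrix",
]


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-marker averaged neighbour correlation for one chromosome."""

    values: np.ndarray
    window: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous marker blocks tiling one chromosome, one tag per block."""

    blocks: tuple  # ((start, end), ...) half-open marker-index pairs
    tag_index: np.ndarray
    n_markers: int

    def __post_init__(self) -> None:
        blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        tags = np.asarray(self.tag_index, dtype=np.int64)
        object.__setattr__(self, "tag_index", tags)
        if len(blocks) != tags.size:
            raise ValueError("one tag index per block required")
        expect = 0
        for (s, e), t in zip(blocks, tags):
            if s != expect or e <= s:
                raise ValueError("blocks must tile the marker range without gaps")
            if not (s <= t < e):
                raise ValueError(f"tag index {t} outside its block [{s}, {e})")
            expect = e
        if expect != self.n_markers:
            raise ValueError("blocks do not cover the full marker range")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class TagMatrix:
    """Subjects x tag-markers submatrix with its originating partition."""

    values: np.ndarray
    partition: BlockPartition
    polarity: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != self.partition.n_blocks:
            raise ValueError("tag matrix must have one column per block")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_tags(self) -> int:
        return self.values.shape[1]


def _column_values(X) -> np.ndarray:
    return X.values if isinstance(X, CallMatrix) else np.asarray(X, dtype=np.float64)


def pairwise_correlation(X, i: int, j: int) -> float:
    """Pearson correlation across subjects between marker columns i and j.

    Uses means and standard deviations over all N subjects; returns 0.0 when
    either column has zero variance.
    """
    v = _column_values(X)
    if i == j:
        raise ValueError("pairwise correlation requires i != j")
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    a = v[:, i]
    b = v[:, j]
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def correlation_profile(X, w: int) -> CorrelationProfile:
    """Average correlation of each marker with its window-w neighbourhood.

    The neighbour set of marker k is every j != k with ``|j - k| <= w // 2``,
    truncated at the chromosome ends (the divisor is the actual neighbour
    count).  One chromosome at a time.
    """
    v = _column_values(X)
    n, L = v.shape
    if w < 2:
        raise ValueError("window must be >= 2")
    if w > L:
        raise ValueError(f"window {w} exceeds the chromosome's {L} markers")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    half = w // 2
    mu = v.mean(axis=0)
    sd = v.std(axis=0)
    nz = sd > 0
    z = np.zeros_like(v)
    z[:, nz] = (v[:, nz] - mu[nz]) / sd[nz]
    sums = np.zeros(L)
    counts = np.zeros(L)
    for d in range(1, half + 1):
        if d >= L:
            break
        c = (z[:, :-d] * z[:, d:]).mean(axis=0)  # corr(k, k+d); 0 if zero-variance
        sums[: L - d] += c
        counts[: L - d] += 1
        sums[d:] += c
        counts[d:] += 1
    values = sums / counts
    return CorrelationProfile(np.clip(values, -1.0, 1.0), w)


def middle_site(start: int, end: int) -> int:
    """Tag position of block [start, end): left-of-centre for even lengths."""
    return start + (end - start - 1) // 2


def partition_blocks(profile: CorrelationProfile, seg_alpha: float = 0.01,
                     seg_min_width: int = 2, seg_n_perm: int = 200,
                     seed=0) -> BlockPartition:
    """Partition the correlation profile into blocks with CBS; tag = middle site."""
    seg = cbs_segment(profile.values, alpha=seg_alpha, min_width=seg_min_width,
                      n_perm=seg_n_perm, seed=seed)
    blocks = seg.blocks()
    tags = np.array([middle_site(s, e) for s, e in blocks], dtype=np.int64)
    return BlockPartition(tuple(blocks), tags, len(profile))


def build_tag_matrix(X, partition: BlockPartition) -> TagMatrix:
    """Column-subset of the call matrix at the tag indices."""
    v = _column_values(X)
    if v.shape[1] != partition.n_markers:
        raise ValueError("partition does not match the matrix's marker count")
    polarity = X.polarity if isinstance(X, CallMatrix) else "amp"
    return TagMatrix(v[:, partition.tag_index].copy(), partition, polarity)
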