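"""Reading and writing cohort copy-number data and consensus-event calls.

The on-disk conventions are deliberately plain text:

* ratio matrix — tab-separated, first row marker ids, first column subject ids;
* marker map — tab-separated ``marker_id, chrom, pos`` (1-based point positions);
* SEG input — ``sample, chrom, start, end, num_markers, seg_mean`` records that
  are expanded onto a marker map (inclusive 1-based segment bounds);
* SCE output — BED-detail (0-based half-open) with score, polarity, p-value and
  aberrant-subject count columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

AMP = "amp"
DEL = "del"

__all__ = [
    "AMP",
    "DEL",
    "ParseError",
    "DimensionError",
    "MarkerMap",
    "RatioMatrix",
    "CallMatrix",
    "SCERegion",
    "read_marker_map",
    "write_marker_map",
    "read_ratio_matrix",
    "write_ratio_matrix",
    "read_seg_segments",
    "write_sce_regions",
    "read_sce_regions",
]


class ParseError(ValueError):
    """Malformed input file (ragged row, non-numeric cell, bad record)."""


class DimensionError(ValueError):
    """Marker annotation and matrix shapes disagree."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker annotation: id, chromosome and 1-based position.

    Positions must be strictly increasing within each chromosome and each
    chromosome must occupy one contiguous run of rows.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        n = len(self.marker_id)
        if len(self.chrom) != n or len(self.pos) != n:
            raise DimensionError("marker_id, chrom and pos must have equal length")
        if n == 0:
            raise ValueError("marker map may not be empty")
        seen: set = set()
        prev_chrom = None
        prev_pos = None
        for i in range(n):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ParseError(
                        f"chromosome {c!r} appears in non-contiguous runs (row {i})"
                    )
                seen.add(c)
                prev_chrom = c
                prev_pos = None
            if prev_pos is not None and self.pos[i] <= prev_pos:
                raise ParseError(
                    f"positions not strictly increasing on {c!r} at row {i} "
                    f"({self.pos[i]} after {prev_pos})"
                )
            prev_pos = self.pos[i]

    def __len__(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> list:
        """Chromosome names in file order."""
        out: list = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, sl: slice) -> "MarkerMap":
        return MarkerMap(self.marker_id[sl], self.chrom[sl], self.pos[sl])


@dataclass(frozen=True)
class RatioMatrix:
    """Subjects x markers matrix of segmented log2 copy-number ratios."""

    values: np.ndarray
    subjects: tuple
    markers: MarkerMap

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if v.ndim != 2:
            raise DimensionError("values must be 2-D (subjects x markers)")
        n, l = v.shape
        if n < 1 or l < 2:
            raise DimensionError(f"need at least 1 subject and 2 markers, got {n}x{l}")
        if len(self.subjects) != n:
            raise DimensionError("subject labels do not match row count")
        if len(self.markers) != l:
            raise DimensionError(
                f"marker map length {len(self.markers)} != column count {l}"
            )
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise ParseError(
                f"non-finite cell at subject row {bad[0]}, marker column {bad[1]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CallMatrix:
    """Polarity-specific aberration calls.

    Aberrant cells keep their log2-ratio; non-aberrant cells are exactly zero.
    """

    values: np.ndarray
    polarity: str
    theta_amp: float
    theta_del: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if self.polarity not in (AMP, DEL):
            raise ValueError(f"polarity must be {AMP!r} or {DEL!r}")
        if not (self.theta_amp > 0 > self.theta_del):
            raise ValueError("need theta_amp > 0 > theta_del")
        nz = v[v != 0]
        if self.polarity == AMP and nz.size and np.min(nz) < self.theta_amp:
            raise ValueError("amplification matrix has nonzero cell below theta_amp")
        if self.polarity == DEL and nz.size and np.max(nz) > self.theta_del:
            raise ValueError("deletion matrix has nonzero cell above theta_del")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SCERegion:
    """A significant consensus event: the genome block represented by one tag.

    ``start_pos``/``end_pos`` are 1-based inclusive base-pair bounds of the
    block (first to last marker position).
    """

    chrom: str
    start_pos: int
    end_pos: int
    tag_marker_id: str
    polarity: str
    score: float
    p_value: float
    n_subjects_aberrant: int

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.polarity not in (AMP, DEL):
            raise ValueError(f"polarity must be {AMP!r} or {DEL!r}")


# ---------------------------------------------------------------------------
# marker map


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ParseError(f"{path}: marker map needs marker_id, chrom, pos columns")
    cols = list(df.columns[:3])
    return MarkerMap(
        df[cols[0]].to_numpy(dtype=object),
        df[cols[1]].astype(str).to_numpy(dtype=object),
        df[cols[2]].to_numpy(),
    )


def write_marker_map(markers: MarkerMap, path) -> None:
    df = pd.DataFrame(
        {"marker_id": markers.marker_id, "chrom": markers.chrom, "pos": markers.pos}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ratio matrix


def read_ratio_matrix(path, marker_path) -> RatioMatrix:
    """Load a TSV ratio matrix (rows = subjects) plus its marker annotation."""
    markers = read_marker_map(marker_path)
    text = Path(path).read_text().splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    header = text[0].split("\t")
    ncol = len(header)
    subjects: list = []
    rows: list = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ParseError(
                f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}"
            )
        subjects.append(parts[0])
        row = np.empty(ncol - 1)
        for ci, cell in enumerate(parts[1:], start=1):
            try:
                row[ci - 1] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, column {ci + 1}: "
                    f"non-numeric value {cell!r}"
                ) from None
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, ncol - 1))
    if values.shape[1] != len(markers):
        raise DimensionError(
            f"matrix has {values.shape[1]} marker columns but marker map "
            f"lists {len(markers)}"
        )
    return RatioMatrix(values, subjects, markers)


def write_ratio_matrix(x: RatioMatrix, path, marker_path=None) -> None:
    with open(path, "w") as fh:
        fh.write("subject\t" + "\t".join(map(str, x.markers.marker_id)) + "\n")
        for s, row in zip(x.subjects, x.values):
            fh.write(str(s) + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")
    if marker_path is not None:
        write_marker_map(x.markers, marker_path)


# ---------------------------------------------------------------------------
# SEG expansion


def read_seg_segments(path, marker_map: MarkerMap) -> RatioMatrix:
    """Expand SEG-style per-sample segments onto ``marker_map``.

    Each marker takes the seg_mean of the segment containing its position;
    markers covered by no segment are filled with 0.0 (no aberration) and the
    total uncovered cell count is reported as a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 6:
        raise ParseError(
            f"{path}: SEG input needs sample, chrom, start, end, num_markers, "
            "seg_mean columns"
        )
    df = df.iloc[:, :6]
    df.columns = ["sample", "chrom", "start", "end", "num_markers", "seg_mean"]
    df["chrom"] = df["chrom"].astype(str)
    known = set(map(str, marker_map.chromosomes()))
    subjects = list(dict.fromkeys(df["sample"].astype(str)))
    L = len(marker_map)
    values = np.zeros((len(subjects), L))
    covered = np.zeros((len(subjects), L), dtype=bool)
    row_of = {s: i for i, s in enumerate(subjects)}
    for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
        sample = str(sample)
        if chrom not in known:
            raise ParseError(
                f"{path}: sample {sample}: segment on unknown chromosome {chrom!r}"
            )
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        means = grp["seg_mean"].to_numpy(dtype=np.float64)
        prev_end = None
        prev = None
        for s, e in zip(starts, ends):
            if e < s:
                raise ParseError(f"{path}: sample {sample}: segment end {e} < start {s}")
            if prev_end is not None and s <= prev_end:
                raise ParseError(
                    f"{path}: sample {sample}: overlapping segments on {chrom}: "
                    f"{prev} and ({s}, {e})"
                )
            prev_end = e
            prev = (s, e)
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.pos[sl]
        ri = row_of[sample]
        for s, e, m in zip(starts, ends, means):
            lo = int(np.searchsorted(pos, s, side="left"))
            hi = int(np.searchsorted(pos, e, side="right"))
            values[ri, sl.start + lo : sl.start + hi] = m
            covered[ri, sl.start + lo : sl.start + hi] = True
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        warnings.warn(
            f"{n_uncovered} marker cells not covered by any segment; filled with 0.0",
            stacklevel=2,
        )
    return RatioMatrix(values, subjects, marker_map)


# ---------------------------------------------------------------------------
# SCE regions (BED-detail)

_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tpolarity\tp_value\tn_subjects_aberrant"


def write_sce_regions(regions: Sequence[SCERegion], path) -> None:
    """Write SCE calls as BED-detail, 0-based half-open, sorted by locus."""
    ordered = sorted(regions, key=lambda r: (str(r.chrom), r.start_pos, r.end_pos))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        str(r.chrom),
                        str(r.start_pos - 1),
                        str(r.end_pos),
                        str(r.tag_marker_id),
                        format(r.score, ".17g"),
                        r.polarity,
                        format(r.p_value, ".17g"),
                        str(r.n_subjects_aberrant),
                    ]
                )
                + "\n"
            )


def read_sce_regions(path) -> list:
    """Reparse a BED-detail file written by :func:`write_sce_regions`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ParseError(f"{path}: expected 8 fields, got {len(f)}")
            out.append(
                SCERegion(
                    chrom=f[0],
                    start_pos=int(f[1]) + 1,
                    end_pos=int(f[2]),
                    tag_marker_id=f[3],
                    score=float(f[4]),
                    polarity=f[5],
                    p_value=float(f[6]),
                    n_subjects_aberrant=int(f[7]),
                )
            )
    return out
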