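"""End-to-end analysis: thresholding, tag selection, peel-off, SCE calls.

Chromosomes are analysed independently (the series handed to CBS never
crosses a chromosome boundary) and amplifications and deletions are analysed
separately.  Permutations run per chromosome by default; the genome-wide
scope concatenates every chromosome's tag matrix into one peel-off run per
polarity, which favours broad events at the price of per-chromosome
sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    AMP,
    DEL,
    MarkerMap,
    RatioMatrix,
    write_sce_regions,
)
from .segmentation import segment_cohort
from .significance import call_sces, peel_off, split_by_threshold
from .tag_selection import build_tag_matrix, correlation_profile, partition_blocks

__all__ = ["RunConfig", "ChromResult", "CohortAnalysis", "analyze_cohort",
           "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All analysis parameters; defaults are the standard real-data settings.

    theta_amp / theta_del : log2-ratio call thresholds (0.848 and -0.737
        correspond to 3.6 and 1.2 copies).
    w : correlation window in markers.
    E : permutations per peel-off iteration.
    alpha : significance cutoff for peeling and final calls.
    genome_wide : permute across all chromosomes jointly instead of within
        each chromosome.
    segment_subjects : re-segment each subject's ratios with CBS before
        thresholding (for raw, marker-noise inputs such as simulated cohorts).
    """

    theta_amp: float = 0.848
    theta_del: float = -0.737
    w: int = 20
    E: int = 1000
    alpha: float = 0.05
    seed: int = 0
    genome_wide: bool = False
    add_one_pvalue: bool = False
    seg_alpha: float = 0.01
    seg_min_width: int = 10  # blocks narrower than ~w/2 are below the
    # correlation profile's smoothing scale and only fragment the tag set
    seg_n_perm: int = 200
    segment_subjects: bool = False
    subject_seg_alpha: float = 0.025
    subject_seg_min_width: int = 2
    subject_seg_n_perm: int = 40


@dataclass(frozen=True)
class ChromResult:
    """Per-chromosome, per-polarity analysis outcome."""

    chrom: str
    polarity: str
    markers: MarkerMap
    offset: int  # genome column offset of this chromosome
    partition: object
    peel: object  # PeelOffResult of this chromosome's tags
    p_values: np.ndarray  # final p-values of this chromosome's tags
    scores: np.ndarray
    removed_at: np.ndarray

    def regions(self, alpha: float):
        res = self.peel
        # genome-wide runs share one PeelOffResult; slice via stored arrays
        from .significance import PeelOffResult

        if res.n_tags != self.p_values.size:
            res = PeelOffResult(
                p_values=self.p_values,
                scores=self.scores,
                removed_at=self.removed_at,
                distributions=res.distributions,
                alpha=res.alpha,
                E=res.E,
                tag_matrix=self._tag_matrix,
            )
        return call_sces(res, self.partition, self.markers, alpha)

    # set after construction (dataclass frozen): the chromosome tag matrix
    @property
    def _tag_matrix(self):
        return self.__dict__["tag_matrix"]


@dataclass(frozen=True)
class CohortAnalysis:
    """Full two-polarity analysis of one cohort."""

    config: RunConfig
    n_markers: int
    results: tuple  # ChromResult for every (chrom, polarity)

    def polarity_results(self, polarity: str):
        return [r for r in self.results if r.polarity == polarity]

    def regions(self, alpha: float | None = None):
        alpha = self.config.alpha if alpha is None else alpha
        out = []
        for r in self.results:
            out.extend(r.regions(alpha))
        return out

    def any_significant(self, alpha: float | None = None) -> bool:
        alpha = self.config.alpha if alpha is None else alpha
        return any(np.any(r.p_values < alpha) for r in self.results)

    def called_marker_mask(self, threshold: float, polarity: str | None = None):
        """Genome-length boolean mask of markers inside significant blocks."""
        mask = np.zeros(self.n_markers, dtype=bool)
        for r in self.results:
            if polarity is not None and r.polarity != polarity:
                continue
            for m, (s, e) in enumerate(r.partition.blocks):
                if r.p_values[m] < threshold or threshold >= 1.0:
                    mask[r.offset + s : r.offset + e] = True
        return mask

    def tag_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for m, ((s, e), tag) in enumerate(
                zip(r.partition.blocks, r.partition.tag_index)
            ):
                rows.append(
                    {
                        "chrom": r.chrom,
                        "polarity": r.polarity,
                        "block_start_pos": int(r.markers.pos[s]),
                        "block_end_pos": int(r.markers.pos[e - 1]),
                        "tag_marker_id": str(r.markers.marker_id[tag]),
                        "score": float(r.scores[m]),
                        "p_value": float(r.p_values[m]),
                        "removed_at": int(r.removed_at[m]),
                    }
                )
        return pd.DataFrame(rows)

    def iteration_trace(self):
        """Peel-off trace per (chrom, polarity): H, peeled per iteration, null means."""
        trace = {}
        seen = set()
        for r in self.results:
            key = (r.chrom, r.polarity)
            peel = r.peel
            if id(peel) in seen:
                continue
            seen.add(id(peel))
            peeled = [
                int(np.sum(peel.removed_at == h)) for h in range(1, peel.H + 1)
            ]
            label = (
                f"{r.polarity}:genome-wide" if self.config.genome_wide
                else f"{r.polarity}:{r.chrom}"
            )
            trace[label] = {
                "H": peel.H,
                "tags_peeled": peeled,
                "null_means": [float(x) for x in peel.null_means],
            }
        return trace


def _make_chrom_result(chrom, polarity, markers, offset, partition, peel,
                       p_vals, scores, removed, tag_matrix) -> ChromResult:
    r = ChromResult(
        chrom=chrom,
        polarity=polarity,
        markers=markers,
        offset=offset,
        partition=partition,
        peel=peel,
        p_values=p_vals,
        scores=scores,
        removed_at=removed,
    )
    r.__dict__["tag_matrix"] = tag_matrix
    return r


def analyze_cohort(X: RatioMatrix, config: RunConfig) -> CohortAnalysis:
    """Run the full procedure on a cohort matrix.

    Per chromosome and per polarity: correlation profile -> CBS blocks ->
    tag matrix -> peel-off permutation -> final p-values.  Deterministic for
    a fixed config (all randomness flows from ``config.seed``).
    """
    ss = np.random.SeedSequence(config.seed)

    def next_rng():
        return np.random.default_rng(ss.spawn(1)[0])

    values = X.values
    if config.segment_subjects:
        out = values.copy()
        rng = next_rng()
        for chrom in X.markers.chromosomes():
            sl = X.markers.chrom_slice(chrom)
            out[:, sl] = segment_cohort(
                values[:, sl],
                alpha=config.subject_seg_alpha,
                min_width=config.subject_seg_min_width,
                n_perm=config.subject_seg_n_perm,
                seed=rng,
            )
        values = out
        X = RatioMatrix(values, X.subjects, X.markers)

    amp, dele = split_by_threshold(X, config.theta_amp, config.theta_del)
    chroms = X.markers.chromosomes()
    results = []
    for cm in (amp, dele):
        per_chrom = []
        for chrom in chroms:
            sl = X.markers.chrom_slice(chrom)
            sub = cm.values[:, sl]
            profile = correlation_profile(sub, config.w)
            partition = partition_blocks(
                profile,
                seg_alpha=config.seg_alpha,
                seg_min_width=config.seg_min_width,
                seg_n_perm=config.seg_n_perm,
                seed=next_rng(),
            )
            from .io_formats import CallMatrix

            sub_cm = CallMatrix(sub, cm.polarity, config.theta_amp, config.theta_del)
            T = build_tag_matrix(sub_cm, partition)
            per_chrom.append((chrom, sl, partition, T))

        if config.genome_wide and len(per_chrom) > 1:
            from .tag_selection import BlockPartition, TagMatrix

            cat = np.concatenate([T.values for _, _, _, T in per_chrom], axis=1)
            # build a flat partition purely to satisfy the tag-matrix contract
            sizes = [T.n_tags for _, _, _, T in per_chrom]
            bounds = np.cumsum([0] + sizes)
            flat = BlockPartition(
                tuple((i, i + 1) for i in range(cat.shape[1])),
                np.arange(cat.shape[1]),
                cat.shape[1],
            )
            joint = TagMatrix(cat, flat, cm.polarity)
            peel = peel_off(
                joint, config.E, config.alpha, seed=next_rng(),
                add_one=config.add_one_pvalue,
            )
            for (chrom, sl, partition, T), a, b in zip(
                per_chrom, bounds[:-1], bounds[1:]
            ):
                results.append(
                    _make_chrom_result(
                        chrom, cm.polarity, X.markers.subset(sl), sl.start,
                        partition, peel,
                        peel.p_values[a:b], peel.scores[a:b],
                        peel.removed_at[a:b], T,
                    )
                )
        else:
            for chrom, sl, partition, T in per_chrom:
                peel = peel_off(
                    T, config.E, config.alpha, seed=next_rng(),
                    add_one=config.add_one_pvalue,
                )
                results.append(
                    _make_chrom_result(
                        chrom, cm.polarity, X.markers.subset(sl), sl.start,
                        partition, peel,
                        peel.p_values, peel.scores, peel.removed_at, T,
                    )
                )
    return CohortAnalysis(config=config, n_markers=X.n_markers,
                          results=tuple(results))


def run_pipeline(X: RatioMatrix, config: RunConfig, outdir) -> CohortAnalysis:
    """Analyse a cohort and write SCE calls, tag statistics and a manifest.

    Outputs (all deterministic for a fixed config):
      ``amp_sces.bed`` / ``del_sces.bed`` — BED-detail SCE regions;
      ``tag_stats.tsv`` — per-tag block bounds, score, p-value, peel iteration;
      ``manifest.json`` — parameters, seed and the peel-off iteration trace.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = analyze_cohort(X, config)
    regions = analysis.regions()
    write_sce_regions([r for r in regions if r.polarity == AMP],
                      outdir / "amp_sces.bed")
    write_sce_regions([r for r in regions if r.polarity == DEL],
                      outdir / "del_sces.bed")
    analysis.tag_table().to_csv(outdir / "tag_stats.tsv", sep="\t", index=False)
    manifest = {
        "tool": "tagcna",
        "version": __version__,
        "config": asdict(config),
        "n_subjects": len(X.subjects),
        "n_markers": X.n_markers,
        "n_sce_amp": sum(1 for r in regions if r.polarity == AMP),
        "n_sce_del": sum(1 for r in regions if r.polarity == DEL),
        "iteration_trace": analysis.iteration_trace(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return analysis
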