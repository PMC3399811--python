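# tagcna

Identify **significant consensus copy-number events (SCEs)** — recurrent
somatic amplifications and deletions shared across a cancer cohort — from
segmented log2-ratio profiles, using tag-marker selection and an iterative
peel-off max-T permutation test.

## The problem and the method

Somatic copy-number alterations (CNAs) litter every tumor genome; most are
random *passengers*, a few recurrent ones harbor *drivers*. Given a cohort
matrix **X** (N subjects × L markers of segmented log2 tumor/normal ratios),
the task is to flag regions whose aberration across subjects exceeds what
random background CNAs produce, with family-wise error control.

The procedure has two stages:

1. **Tag-marker selection.** Adjacent markers are inherently correlated
   (alterations are segmental), so markers are not independent test units.
   For each marker *k* compute the average Pearson correlation (across
   subjects) with its neighbours within a window of *w* markers,

   r̄ₖ = mean over 0 < |j−k| ≤ ⌊w/2⌋ of corr(x·ₖ, x·ⱼ),

   partition the per-chromosome profile r̄ into blocks of homogeneous
   correlation with circular binary segmentation (CBS), and take the middle
   marker of each block as its **tag**. The N × M tag matrix **T** (M =
   number of blocks) carries one approximately independent unit per block.

2. **Peel-off max-T permutation test.** Each tag *m* is scored by
   Sₘ = Σₙ |tₙₘ| — the summed aberration magnitude, so both frequency and
   amplitude enter. Each subject's row of **T** is independently permuted
   across tag positions E times; the distribution D₁ of maxₘ Sₘ over
   permutations yields right-tail p-values, p(m) = (1/E) Σₑ I(maxₛ ≥ Sₘ).
   Because real cohorts mix true consensus events into D₁, every tag with
   p < α is *peeled* (removed), the null rebuilt, and the loop repeated
   until nothing more is significant; the null mean drifts left toward the
   background-only distribution D_H. Finally all tags are re-assessed
   against D_H, which both sharpens p-values and recovers less-extreme
   events. Blocks whose tag has final p < α are reported as SCEs.

Amplifications (cells ≥ θ^amp) and deletions (cells ≤ θ^del) are analysed
separately, chromosome by chromosome. Default parameters are the standard
real-data settings: θ^amp = 0.848 (3.6 copies), θ^del = −0.737 (1.2 copies),
w = 20, E = 1000, α = 0.05.

The package also ships the simulation framework used to characterise the
procedure — tumor/normal mixture cohorts with embedded ground-truth events,
background-only null cohorts, and contamination sweeps — plus evaluation
harnesses (type-I error, marker-level ROC, contamination power).

## Worked example

Simulate a small cohort with three embedded consensus gains and analyse it:

```sh
tagcna simulate --preset paper-power --n-subjects 50 --n-markers 2000 \
    --noise 0.1,0.2 --freq 0.2 --seed 7 -o sim/
tagcna run --matrix sim/matrix.tsv --markers sim/markers.tsv \
    --theta-amp 0.1 --theta-del -0.1 -w 20 -E 500 --alpha 0.05 \
    --segment-subjects --seed 7 -o out/
```

which prints

```
amp SCEs: 3  del SCEs: 0  -> out/
[amp:chr1] H=2 peeled=[3, 0] null means: 5.42, 5.14
[del:chr1] H=1 peeled=[0] null means: 0.181
```

Read: the amplification analysis peeled three tags in its first iteration
and the null mean fell from 5.42 to 5.14 as that embedded signal left the
permutation pool; the three significant blocks survive the final
re-assessment and all cover the strongest truth event (the 5-copy gain at
`chr1:108000-157001` in `sim/truth.bed` — its ten carriers produce the
score 7.22 against a null whose maxima centre on 5.1):

```
#chrom  start   end     name     score   polarity  p_value  n_subjects_aberrant
chr1    109000  118001  M000114  7.2226  amp       0.008    10
chr1    119000  147001  M000134  7.2226  amp       0.008    10
chr1    148000  157001  M000153  7.2226  amp       0.008    10
```

The weaker 3- and 4-copy events stay below the family-wise bar at this
cohort size, and the deletion channel is empty, as it should be for
gain-only simulated backgrounds. `out/manifest.json` records every
parameter and the iteration trace.

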