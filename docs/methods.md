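# Methods

## Model and procedure

The unit of inference is the *correlation block*: a run of adjacent markers
whose windowed inter-marker correlation is homogeneous, represented by its
middle ("tag") marker. The statistical claim being tested, per tag, is that
its column of the aberration call matrix is exchangeable with the other tag
columns under independent within-subject rearrangement — i.e. that the locus
is background. Significance is assessed against the max-T permutation null
(the distribution of the maximum tag score across E row-wise permutations),
which controls the family-wise error rate without per-marker multiplicity
corrections.

Pipeline per chromosome and per polarity:

1. threshold the segmented ratio matrix into an amplification call matrix
   (cells ≥ θ^amp, inclusive) and a deletion call matrix (cells ≤ θ^del);
   all other cells are exactly zero;
2. windowed correlation profile: marker k's value is the mean Pearson
   correlation (population moments over all N subjects) with every marker
   j ≠ k, |j−k| ≤ ⌊w/2⌋, truncated at chromosome ends with the divisor
   equal to the actual neighbour count; zero-variance columns correlate 0
   by convention (they carry no consensus signal and must not seed blocks);
3. CBS partition of the profile; tag = block start + ⌊(len−1)/2⌋
   (left-of-centre for even lengths, a deterministic tie-break);
4. peel-off: build D_h from the current tag matrix, remove all tags with
   p < α (strict), rebuild, stop when an iteration removes nothing, then
   re-assess *all* original tags against D_H. The removal loop cannot empty
   the matrix: the permuted maximum is never below the mean column score,
   so the weakest remaining tag always has p = 1 (a defensive guard for the
   empty case exists anyway).

P-values use the literal exceedance fraction count/E by default, which can
return 0; an add-one estimator ((1+count)/(1+E)) is available behind a flag
for downstream consumers that need positive p-values.

## The changepoint engine

CBS is implemented from first principles: at each recursion the pair of
split points (i, j) maximising the two-sample t statistic between the arc
y[i:j] and its complement (the series is treated as circular) is located,
and the split is accepted when its permutation p-value is below `alpha`
(values within the interval are shuffled; early stopping abandons the test
as soon as enough permuted maxima exceed the observed one to rule out
significance). Segments shorter than `min_width` are never created.

Numerical choices, all shared between observed and permuted series so the
permutation test stays exchangeable:

* intervals are centred before scanning; a variance floor (1e-18 relative
  to the interval's mean square) classifies degenerate pooled variances:
  zero variance with distinct group means scores +inf (a perfect split),
  with equal means 0;
* for intervals longer than 128 points the arc-length search uses a
  geometric grid (all lengths to 32, then ×1.12 steps, mirrored from both
  interval ends); arc starts are scanned with stride max(1, n/256);
* an accepted split is then re-localised exhaustively around the grid
  optimum (stride 1, arc lengths between the chosen length's grid
  neighbours) — placement only, the accept/reject decision is already made;
* argmax ties break to the leftmost pair, making results deterministic.

The hot kernel (cumulative-sum arc scan) is compiled with numba; a pure
recursion over ~10⁴-marker chromosomes with hundreds of permutations per
split would otherwise dominate the pipeline.

Defaults: α = 0.01, min_width = 2, n_perm = 200 for the correlation profile
(profiles are short, full permutation is cheap). Two pipeline-level
overrides, both deliberate:

* **profile partition min_width = 10** (≈ w/2): the profile is a moving
  average at scale w, so blocks narrower than its smoothing scale are
  artefacts of fragmentation; at desk scale they inflate the tag count M,
  thicken the max-T null and cost real power. Matches the canonical
  block-to-window proportion (1000 markers, w = 20 → 50 blocks).
* **per-subject re-segmentation** (`segment_subjects`) runs at
  α = 0.025, n_perm = 40, min_width = 2: with the acceptance rule
  "no permuted maximum may reach the observed one", rejections stop at the
  first exceedance, which makes denoising a 50 × 2,000 cohort affordable;
  the cost is a per-test false-split rate of ~1/41, harmless fragmentation
  for downstream block inference.

## Simulated cohorts

`simulate_cohort` mirrors a tumor/normal mixture design: tumor copy number
c_t = 2·2^r for an event of pure-tumor log2-ratio r (so 0.585 → 3 copies,
1.322 → 5, −1 → 1); a subject with normal-cell fraction p observes
log2(((1−p)·c_t + 2p)/2) plus i.i.d. Gaussian marker noise with per-subject
SD drawn uniformly from the configured interval. Reference conditions
(the generator defaults): 100 subjects × 10,000 markers; three embedded
consensus gains of ratio {0.585, 1, 1.322} and length {200, 100, 50}
markers at carrier frequency f (exactly round(f·N) carriers, drawn
independently per event); normal fraction ~ U(0.3, 0.7); two passenger
gains per subject, length U{50..500}, ratio U(0.585, 1.322), at uniformly
random per-subject positions.

Placement rules: consensus intervals sit at seeded-uniform offsets with a
guard gap of ≥ 100 markers; passengers are rejection-sampled so they never
touch a consensus interval in any subject, keeping marker truth labels
unambiguous for ROC accounting. The background-only null cohort is the same
generator with no consensus events; uniform passenger placement means no
locus is enriched, which the flatness test checks directly.

Contamination sweeps draw the normal fraction from a Gaussian with mean 0.6
and the swept SD, truncated to [0, 0.99] by clipping (a fraction must be a
fraction; the atom at the edges is physically a nearly-pure-normal sample).
The sweep's two events are a 100-marker amplification at ratio 1.322 —
placed at the top of the passenger ratio range so it stands clear of the
gain background at low contamination — and a 100-marker one-copy deletion
(ratio −1), both at f = 0.15, with marker noise U(0.1, 0.2).

What the generator does *not* emulate: marker-spacing heterogeneity,
GC/wave artefacts, chromosome-arm-scale broad events, correlated noise, or
resampling of real tumor profiles. Passing tests therefore certify the
statistical machinery under segmental-mixture assumptions, not robustness
to platform artefacts.

## Desk scales and evaluation choices

Evaluation harnesses run reduced problem sizes chosen as the package's
working scale, always keeping the reference cohort size of 100 subjects on
shrunken 1,500–2,000-marker genomes (type-I error: 100 × 1,500, E = 200,
100 replications per noise regime). The cohort size is not reducible the
way the genome is: with half the subjects, detection at f = 0.15 is
genuinely marginal (eight carriers cannot clear the passenger max-T null),
and the type-I rate inflates because tag selection — blocks chosen from the
very data being tested — biases the observed maximum upward relative to
the permuted one, an effect that grows as passenger pile-up fluctuations
get relatively larger in small cohorts. When the genome shrinks,
passenger *lengths* scale proportionally (50–500 on 10,000 markers becomes
8–75 on 1,500) so the background coverage rate — the quantity the null
distribution sees — matches the reference conditions; consensus-event
lengths are kept absolute.

The evaluation pipeline re-segments each subject before thresholding
(`segment_subjects=True`): simulated data carry marker-level noise, and
thresholding raw noise at ±0.1 would flood both call matrices with
isolated false cells — in particular it would activate the deletion family
on gain-only backgrounds and push the combined two-family type-I rate
toward 2α. After segmentation the deletion channel of a null cohort is
essentially empty (its tags all have p = 1), so the combined rate is the
amplification family's, slightly below α — the regime the reference rates
describe.

ROC accounting is marker-level: a marker is "called" when its block's tag
has final p below the threshold; TPR and FPR are fractions of truth and
non-truth markers called. Contamination power counts a replication as a
success only when *every* embedded event is overlapped (≥ 1 marker) by a
significant block of matching polarity.

## Known limitations

* The arc-length grid and start stride trade exact argmax localisation on
  long intervals for speed; the refinement pass restores boundary accuracy
  in practice but is not a global optimum guarantee.
* Permutation p-values are granular at 1/E; with the default strict
  comparison a tag can receive p = 0.
* Tag positions are selected from the same data that is then tested; under
  dense unsegmented backgrounds this selection can bias the observed score
  distribution relative to the permuted one (another reason the pipeline
  re-segments subjects before thresholding).
* Genome-wide permutation scope concatenates tag matrices across
  chromosomes; it favours broad events and is not the default.
* No FDR/q-value machinery: control is family-wise by construction.
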