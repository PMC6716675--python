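# Methods

## The scoring model

A transcript's association strength with an RBP is the weighted sum of
its CLIP peak-cluster intensities,

    S = Σᵢ rᵢ · exp(−dᵢ/d₀),

with `dᵢ` the distance from the cluster midpoint to a reference position
and `d₀` a decay constant. The model assumes (i) that a peak's
regulatory relevance decays smoothly and monotonically with distance
from one functionally meaningful anchor, (ii) that intensities are
comparable across peaks after optional control normalization, and
(iii) that all peaks on a transcript contribute — there is no hard
window. The exponential form mirrors the distance weighting long used
for transcription-factor ChIP peaks around TSSs; here the anchor is an
RNA landmark (most often the polyadenylation site for stability
regulators).

### Coordinate conventions

Genomic intervals are 0-based half-open; transcript positions are
0-based along the **spliced** transcript from its 5' end, strand-aware.
Distances are spliced-transcript distances, not genomic: for 3'-UTR
anchors the two usually coincide, but spliced distance generalizes
correctly when an intron separates a peak from the anchor. Anchors:
TSS = position 0; TES = last transcribed base (`L−1`); TIS = first CDS
base; TTS = last CDS base with the stop codon counted inside the CDS
(a separately annotated `stop_codon` feature is folded in at parse
time). One representative transcript is kept per gene, by default the
one with the longest 3' UTR (ties: longer spliced length, then smallest
transcript id) — the analyses are 3'-UTR-centric and isoform handling
is otherwise underdetermined; the policy is a flag.

### Peaks

Cross-link sites within `merge_gap` nt of each other merge transitively
into clusters (default 20 nt, measured as empty space between interval
ends); cluster intensity is the member sum, position the interval
midpoint. Clusters map to every representative transcript whose exons
contain the midpoint on the matching strand — a peak shared by two
overlapping genes deliberately counts for both, since no exclusion rule
is defensible without expression data. Control normalization replaces
`r` by `max(0, r·log₂((r+1)/(c+1)))`: a pseudocount of 1 guards `c = 0`
and non-enriched peaks clamp to zero, since the score presumes
non-negative intensities; `c` is the summed intensity of control sites
whose midpoints fall inside the cluster interval.

### Reference-site selection and d₀ estimation

Metagene profiles average peak-intensity coverage per anchor-relative
position over all transcripts with at least one mapped peak (positions
beyond a transcript's extent contribute zero). Profiles are built from
**site-level** coverage rather than merged clusters: painting a merged
cluster's summed intensity across its union span double-counts
positions where sites crowd together, which is exactly where the signal
is, and biases the decay estimate low (by ~20% on the reference
simulation). Profiles are smoothed with a 51-nt moving average
(half-width 25) before locating the maximum; the unsmoothed argmax of a
per-nt profile is fragile to single-transcript spikes.

Automatic selection returns the anchor with the largest total profile
mass within the window, ties broken TES > TTS > TIS > TSS (the
3'-UTR-associated anchors dominate among decay regulators). The window
should be on the scale of the anchor separations — a window much wider
than the 5' UTR cannot distinguish TSS from TIS, since both profiles
then cover the same positions.

`d₀` estimation inverts the weight formula: with profile maximum
`p_max` at `d_peak` and density `p_far` at `far_distance` (same side of
the anchor as the maximum), `w = p_far/p_max` and
`d₀ = −(far_distance − d_peak)/ln(w)`, rounded to the nearest nt. The
estimator is scale-invariant and monotone in `w`; it refuses to run
when there is no decay (`w ≥ 1`) or no far signal. Defaults:
`far_distance` 1000 nt; when no estimate is requested `d₀` defaults to
1000 nt, a value robust over a broad range for 3'-end-anchored RBPs
(performance degrades only when `d₀` is small enough to discard most
signal or large enough to approach uniform weighting).

### Comparators and evaluation

The expressRNA-style comparator sums intensity over peaks with
`d ≤ flank` (default 200 nt; boundary inclusive — the rule is stated as
"within" a flank without boundary semantics, so the inclusive choice is
fixed and documented). PPK is peak count per kilobase of spliced
transcript length; "per kilobase" of what is otherwise unspecified, and
spliced length is the denominator that matches the scoring frame.

Evaluation is rank-based throughout: ROC AUC (equal to the Mann-Whitney
probability that a random positive outscores a random negative, ties
half) on stabilized/degraded labels from LFC signs (knockout: LFC < 0 ⇔
stabilized; overexpression flips), and Spearman correlation between
score and LFC on gene subsets at the 19 |LFC| quantile cutoffs
0.05…0.95. Log-transforms of scores are for plotting only. The
cross-method test is a one-sided Mann-Whitney on two methods' |rho|
vectors: exact null when both n ≤ 20 without ties, normal approximation
otherwise, p = 0.5 by convention for fully tied input.

## The synthetic benchmark

`SimConfig` defaults define the reference simulation: 2000 coding genes
(5' UTR 100–300 nt, CDS 600–1800 nt, 3' UTR 1000–3000 nt, 1–4 exons,
mixed strands) on one toy chromosome; Poisson(5) sites per transcript,
10 nt wide, geometric intensities (mean 8); site distance to the true
anchor (TES) drawn from an exponential law with `d0_true = 500` nt
truncated to the transcript — truncation keeps sites on the transcript
but slightly shortens mean distances on short transcripts, which is why
the recovered `d₀` sits below the planted value (~475 at n = 2000);
uniform background control sites (mean 2 per gene); and knockout LFCs
`−coupling·z(log₁₀(1+S_true)) + N(0, noise_sd)` with coupling 1 and
noise 1. The noise default matters: it sets the full-population
score-LFC correlation near −0.7, leaving room for the correlation to
strengthen as the |LFC| cutoff tightens. At much lower noise the
baseline correlation saturates near its ceiling and the most-extreme
positive LFCs are pure noise among near-zero-score genes, so the curve
flattens or inverts — a property of one-sided planted coupling, not of
the scoring method.

What the generator does **not** emulate: multiple isoforms per gene,
non-coding transcripts, overlapping genes, crosslink-induced mutations
or read-level noise, intensity biases (GC, mappability), batch
structure in the control track, or genes regulated through anchors
other than the planted one. Passing the benchmark therefore shows the
pipeline recovers planted structure faithfully at realistic scales; it
does not certify performance on real CLIP libraries.

Problem sizes used by the test suite: one n = 2000 reference simulation
for anchor/d₀/coupling recovery, and 100 seeded replicates at n = 400
genes (noise 0.5) for the PRAS ≥ expressRNA ≥ PPK |rho| ordering; these
sizes give stable statistics while keeping the suite quick.

## Numerical and degenerate-input choices

* Merging with `gap = 0` still merges touching/overlapping intervals;
  merging is idempotent and conserves total intensity.
* A transcript with no mapped peaks is omitted from the score table
  (tallied, not an error); an empty peak set scores S = 0.
* Ranking ties break by larger peak count, then transcript id, so
  output order is total and deterministic.
* `estimate_d0` uses the exact density ratio `p_far/p_max`;
  `decay_constant(d, w)` exposes the bare inversion for use with an
  externally supplied weight.
* All simulation stages derive independent generators from the master
  seed via `SeedSequence`, so outputs are byte-identical per seed and
  stages can be regenerated independently.

## Known limitations

* One reference anchor per fit; RBPs acting through several positional
  modes (e.g. splice sites and 3' ends) need separate fits.
* Peak double-assignment to overlapping genes can inflate both genes'
  scores in dense loci.
* The control model attaches counts by midpoint containment; if the
  control track is peak-level with very wide intervals, counts may be
  undercounted relative to read-level controls.
* GTF support covers Ensembl/GENCODE attribute dialects; GFF3 is out of
  scope.
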