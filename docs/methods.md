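# Methods

This note documents the models, statistics and design choices behind
`triplexkit`, stage by stage, including what the synthetic-data generators
do and do not emulate.

## Triplex pairing model and search

A DNA:DNA:RNA triplex is modelled as a gapless, collinear alignment of a
third-strand window (the TFO, RNA or DNA) against the purine-rich strand
of duplex DNA. Pairing is governed by per-motif codes over unambiguous
bases (U ≡ T at comparison time; IUPAC ambiguity codes are rejected so hit
sets are deterministic):

* **antiparallel purine motif** (reverse Hoogsteen): G·G:C, A·A:T, T·A:T;
* **parallel pyrimidine motif** (Hoogsteen): C·G:C, T/U·A:T;
* **parallel mixed (GT) motif**: G·G:C, T·A:T — available but not in the
  default motif set.

`find_tts` enumerates, for every motif and both duplex strands, every
**maximal** window that (i) starts and ends on an allowed pair, (ii) has
length ≥ `min_len` (default 12 nt) and (iii) has mismatches ≤
`max_error_rate` × length (default 0.2). Maximality is defined within an
alignment frame (diagonal): no valid window on the same diagonal strictly
contains the reported one. Same-motif, same-strand hits overlapping on
both the RNA and DNA side are collapsed to the highest-scoring one
(score = matched positions), ties broken by leftmost DNA then leftmost RNA
coordinate, giving reproducible output ordering. The defaults are
mid-range values of published triplex-search conventions; because tools
in this space differ in their internal settings, all of them are exposed
in configuration. No bulges are modelled (Hoogsteen
pairing is positionally collinear) and no thermodynamic scoring is
attempted.

The implementation processes all diagonals of one or many duplexes in a
single vectorized pass; its correctness contract is exact equality with a
brute-force enumeration of every (offset, orientation, window) triple,
which the test suite enforces on a thousand random instances.

Purine tracts (`purine_tracts`) are reported separately as maximal
purine-endpoint intervals with a bounded number of pyrimidine
interruptions, on either strand, in plus-strand coordinates. They are a
descriptive/QC view; the search itself does not pre-filter by tract, since
every allowed pair already places a purine on the target strand.

## TFR discovery against a randomization null

Given an RNA, a set of candidate DNA regions and a genome, candidate TFR
windows are the maximal runs of RNA positions covered by at least one
match against any region (step 1 nt, variable width — not fixed tiles).
Window counting uses the unmerged set of maximal matches: the statistic
"region carries ≥ 1 hit overlapping the window" is unaffected by
same-motif overlap collapsing, and skipping the merge keeps the thousands
of null re-scans cheap. Each window is scored by the number of regions
hit; the null distribution re-scores the RNA against `n_randomizations`
(default 200) region sets shuffled by chromosome-preserving uniform
non-overlapping re-placement (identical lengths). Uniform placement is
exact, via ordered draws into the free space left after removing the
regions' total length.

The empirical p-value is the plus-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n)` — conservative, never zero,
minimum `1/(n+1)`. Windows with `p < alpha` (default 0.05) are reported;
no multiple-testing correction is applied across windows (raw-α
enrichment), a deliberate caveat. Shuffling within the source chromosome
is the stricter null; genome-wide placement is possible by passing
single-chromosome bounds.

**Calibration.** Because the count statistic is integer-valued, the
estimator's distribution under the null is lumpy and conservative; a
Kolmogorov–Smirnov test of the raw p-values against the continuous uniform
fails for any desk-scale region count, ties being the sole cause. The
suite therefore calibrates the *exchangeability* of the rank machinery
through the tie-randomized transform
`(#{null > obs} + U·(#{null = obs} + 1))/(n + 1)`, which is exactly
Uniform(0,1) iff observed and null scores are exchangeable — the property
a calibration should certify. The calibration fixes the candidate window
a priori (whole RNA, via the `windows=` parameter of `discover_tfrs`):
windows derived from observed hits are guaranteed ≥ 1 supporting region,
a scan-statistic selection effect that biases p small by construction and
is not a defect of the null. Calibration conditions: 3-kb genome with
purine-skewed plus strand (A 0.40, G 0.35), GA-rich 60-nt RNA, ten 40-bp
regions, 50 randomizations, 200 runs — a regime chosen so that a random
region hits the RNA with probability ≈ 0.35 and the count statistic is
informative.

Cross-TFR target overlap (`overlap_tts`) merges each hit set's genomic
intervals and intersects across all sets (≥ 1 bp), counting shared
*genomic intervals* — whether shared targets should be counted as loci or
per-gene entries is ambiguous in general, and the locus convention is
used here.

## Candidate screening

Peak enrichment follows a Poisson model: `fold = observed/expected` and
`p = P(X ≥ observed | λ = expected)`, the upper tail closed at the
observed count (so `observed = 0` gives p = 1). −log10 p is capped at 300
for finiteness. The cascade retains a lncRNA only if **all** hold, on its
best peak (per-lncRNA maxima of fold and −log10 p; "best vs any peak" is
configurable):

1. fold enrichment > 10 (strict),
2. −log10 p > 20 (strict),
3. present in both cell lines,
4. nuclear expression signal > 0,
5. signal > 0 in each of seven endothelial tissue columns
   (aorta, artery, lymphatic, microvascular, thoracic, umbilical vein,
   vein),
6. coding probability < 0.364 (a published human coding-potential cutoff;
   the non-coding rule is consumed as an input column, not computed),
7. no overlapping-gene conflict — the manual genome-browser inspection
   step is encoded as an input flag, never inferred from annotation.

Filters are pure row-wise predicates, so the retained set is independent
of row and filter order; the attrition report attributes each removed row
to the first failing filter in the fixed cascade order.

## qPCR statistics

ΔΔCt fold change: `E^−[(Ct_t − Ct_r) − (Ct_t,ctrl − Ct_r,ctrl)]` with
amplification efficiency E fixed at 2.0 (no efficiency curve is fitted;
configurable). Percent input shifts the input Ct by `log_E(1/fraction)`
cycles (10% or 5% aliquots in standard RIP/ChIP protocols) before
`100·E^(Ct_input,adj − Ct_IP)`; the dilution adjustment is switchable.
The RNase-H resistance ratio divides percent-input recovery with
treatment by recovery without; 1 marks fully resistant (triplex-like)
association, ≪ 1 heteroduplex-like sensitivity. Replicate folds aggregate
by geometric mean (arithmetic mean in Ct space). Group significance
testing (ANOVA etc.) is intentionally out of scope.

## Melting-curve model

Normalized ellipticity against temperature is modelled as a sum of two
logistic transitions

    f(x) = a/(1 + exp(−(x − x0)/b)) + c/(1 + exp(−(x − x2)/d)),

the biphasic signature of a triplex: the Hoogsteen strand releases at x0,
the Watson-Crick duplex melts at x2 > x0. Tm is reported as the midpoint
parameter, matching how the fitted values are quoted, not as a derivative
maximum. Normalization is min-max to [0, 1] with orientation chosen so
the signal rises with temperature; it is affine-invariant and rejects
constant input.

Fitting is least squares with a multi-start grid: midpoints every 5 °C
(pairs x0 < x2 for the biphasic model), amplitudes split evenly from the
observed range, slopes started at 3 °C; starts are ranked by initial
residual and the best eight optimized with bounded trust-region least
squares. Fits require ≥ 12 points spanning ≥ 30 °C. Midpoints are returned
in canonical order tm1 < tm2 regardless of initialization. Reported
uncertainties are asymptotic standard errors from the Jacobian at the
optimum. Near-zero total amplitude flags a degenerate (transition-free)
fit.

Model choice fits both forms and selects biphasic only when the corrected
information criterion (AICc, with the residual floor 1e-20 keeping exact
fits finite) improves by more than 10 **and** the midpoints are more than
5 °C apart — a parsimony guard against splitting one broad transition in
two, which is exactly the failure mode a very broad second melt invites.
A broad second transition could be fitted freely or constrained; it is
fitted freely here and the decision trace (ΔAICc, separation) is
returned.

## Synthetic data: what it emulates, what it does not

Generators are deterministic under their seed (identical calls give
byte-identical outputs) and record ground truth in a JSON manifest.
Coordinates are 0-based half-open everywhere; emitted BED follows the BED
standard.

* **Genomes** are i.i.d. bases at a requested GC fraction — no
  dinucleotide structure, repeats, or isochores. Sufficient for testing a
  pattern search; hit-rate estimates on real genomes will differ.
* **Planted TTSs** are perfect Hoogsteen partners of a TFO written at
  uniformly random non-overlapping positions on a random strand. Planting
  uses the *combined* pairing code (G→G, A→A, T→A, C→G, antiparallel
  frame) so mixed-sequence TFOs also have a well-defined perfect site;
  for a motif-pure purine TFO this is exactly the perfect antiparallel
  purine-motif site, recovered with zero mismatches. For TFO2-23 (two
  cytosines) the planted site is recovered full-length with two
  mismatches under the purine motif, within the default error budget.
  A requested mismatch rate mutates ⌊rate·L⌋ positions to bases
  disallowed under every motif.
* **Peak tables** draw Poisson(λ) background counts (default λ = 5) and
  Poisson(λ·fold) for planted enriched rows (default fold 20) — summary
  statistics only; no reads, fragment chemistry, or RNase-H kinetics are
  simulated.
* **Ct tables** lower the treated target Ct by log2(fold) cycles against
  a constant reference with optional homoscedastic Gaussian noise, so
  ΔΔCt recovers the planted folds exactly at zero noise.
* **Melting curves** are the double-sigmoid model plus homoscedastic
  Gaussian noise (default σ = 0.02 on the normalized scale) on a 5–95 °C
  grid at 0.5 °C steps — the simplest model consistent with normalized
  ellipticity; no baseline drift or wavelength dimension.

Passing tests on these inputs certify the statistical machinery —
planted-signal recovery, null calibration, false-positive control — not
performance on real sequencing data, whose background structure the
generators deliberately do not model. Genome-wide candidate counts from
real Triplex-Seq data depend on external accessions and annotation
versions and are not reproduced here; the intersection arithmetic is
covered by a constructed fixture (two id sets of 989 and 1363 built to
share 280).

## Orchestration and reproducibility

One global seed feeds per-stage child seeds derived with
`numpy.random.SeedSequence(seed).generate_state`, so stages also run
standalone reproducibly. Every run writes its effective configuration
(unknown keys rejected before any stage executes), the seed trace and
SHA-256 checksums of all outputs into `manifest.json`; repeated runs with
the same seed are byte-identical. The demo pipeline runs at deliberately
small problem sizes (3-kb genome, 6 planted sites, 500-row peak table,
100 randomizations) and completes in seconds on one CPU; each stage's
scale is configurable upward. The test suite's heavier studies use 200
calibration runs at 50 randomizations and 100 seeds for planted-TFR
power.

## Known limitations

* Gapless matching only; bulged or pH-dependent (C⁺·G:C protonation)
  triplexes are out of scope, as is thermodynamic stability scoring.
* The shuffle null preserves region lengths and chromosome but not local
  sequence composition; on real genomes a composition-matched null would
  be stricter.
* The screen consumes expression and coding-potential columns as given;
  it does not query external resources or re-implement coding-potential
  tools.
* The melting model has no baseline-slope terms; strongly drifting raw
  CD baselines should be corrected before normalization.
* One printed sequence-level discrepancy in the packaged constructs is
  resolved computationally: the GA/CT strand labels of one target's
  oligo table are swapped relative to their printed sequences, and the
  quoted GC content of the 23-nt TFO (50.9%) disagrees with its printed
  sequence (14/23 = 60.9%); `triplexkit.sequences` assigns strands by
  computed purine content and uses the computed GC value.
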