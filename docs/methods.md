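# Methods

## Model

`specklesplice` models the choice between two competing splice sites as a
two-state thermodynamic system.  An RNA reporter consists of fixed flanks,
two splice-site motifs, and a variable region between them.  In one state
the upstream site sits at the speckle–nucleoplasm interface; in the other
the downstream site does.  The fixed flanks occupy the same chemical
environment in both states, so the free-energy difference between states is
carried entirely by the variable region, and is approximated as additive
over the region's overlapping k-mers:

    ΔG = Σᵢ ΔGᵢ ,   ratio = p_up/p_down = e^(−ΔG/kT) = Πᵢ e^(−ΔGᵢ/kT).

The additive approximation is deliberate and inherited from the modeled
mechanism — splicing factors bind short stretches of RNA weakly and
transiently, so per-word contributions are treated as independent.  It is
not exact physics: overlapping occurrences double-count shared nucleotides,
and no interaction terms between words are modeled.

### Sign and orientation conventions

* Table energies ΔGᵢ are **speckle-transfer free energies**: negative =
  speckle-favoring (SR-protein-like word), positive = nucleoplasm-favoring
  (hnRNP-like word).  All energies are dimensionless multiples of kT
  (default kT = 1.0); no absolute energy scale is asserted.
* The reporter is oriented with the speckle phase on the **3′ side**: the
  upstream-site-at-interface state is the one with the variable region
  *inside* the speckle.  Hence `delta_g(region)` = Σ ΔGᵢ is the energy of
  the upstream state relative to the downstream state, the usage ratio is
  `e^(−Σ ΔGᵢ/kT)`, and speckle-favoring words *enhance* upstream usage
  (scores sᵢ = e^(−ΔGᵢ/kT) > 1).  The mirror-image orientation (speckle
  5′, hnRNP-like words upstream-enhancing) describes the identical physics
  with the two sites relabeled; fixing one orientation keeps the energy
  table, the simulator and the inferred scores mutually consistent, and is
  verified by the exact reduction of the two-cut positioning ensemble to
  the two-state ratio.
* Log space is canonical throughout: `log_ratio = −ΔG/kT` never overflows;
  the plain `ratio` is a presentation conversion that may return `inf`.
  A usage ratio from probabilities with `p_down = 0` is an error directing
  the caller to log-space accessors.

### k-mer decomposition

All overlapping windows count, with multiplicity: a region of length L
contributes L − k + 1 terms.  This matches how hexamer enrichment scores
are computed from reporter assays and keeps ΔG extensive in sequence
length.  Windows straddling a fixed boundary (flank/region junction, or an
interface cut in the positioning module) contribute to neither side — their
contributions are common to both states and cancel.  Input sequences may be
DNA or RNA; `T` is canonicalized to `U`, and IUPAC ambiguity codes are
rejected because the model is defined only over concrete words.

## Interface positioning along a transcript

A transcript is an exon/intron segmentation (0-based, half-open, tiling the
sequence, alternating labels).  The ensemble contains one interface state
per annotated splice site, with the adjacent exon segment immersed in the
speckle so the site itself lies on the interface; state energy is the sum
of window energies fully inside the speckle-side stretch, reported relative
to the all-nucleoplasm state (any shared constant cancels in the Boltzmann
weights, computed via log-sum-exp).  Two design points deserve emphasis:

* **Bulk states.** Intron windows belong to no splice-site state's speckle
  stretch, so with the site-only ensemble an intronic sequence change has
  no effect.  The optional all-speckle and all-nucleoplasm bulk states give
  intronic sequence its voice: an SR word inserted into an intron lowers
  the all-speckle state's energy and thereby drains occupancy from every
  splice-site state.  The position-dependence demonstrations therefore run
  with bulk states included.
* **Granularity.** Only single-interface states (plus the single-exon
  U state) are enumerated; simultaneous multi-interface configurations of
  multi-intron transcripts are out of scope.  The full per-cut-point
  landscape is exposed separately (computed from prefix sums in O(L)) for
  inspection, and the ensemble's claims are checked against brute-force
  window scans in the tests.

**Exon definition** is represented by a "U" state for an internal exon: the
exon interior in the speckle, both flanking introns outside, both splice
sites on the interface.  Its energy is the window sum over the exon, so SR
enrichment of the exon raises its weight and hnRNP enrichment lowers it.
How interface occupancy maps onto splicing probability for multi-intron
transcripts is left to the caller; only the two-competing-site case is
quantified.

## Reporter-assay simulator

The generator emulates a massively parallel two-splice-site reporter assay:
i.i.d. uniform random regions (default length 25 nt ≈ 20 overlapping
hexamers, enough for multi-SRE combination effects), true usage probability
from the two-state model under a ground-truth table, and per-reporter
upstream reads drawn `Binomial(reads, p_up)` (default 100 reads).  The
assay-scale default is 3×10⁵ reporters; the test suite and benchmark use
10⁴–5×10⁴ for desk-scale runtimes.  All draws flow from a single
`numpy.random.default_rng(seed)`, so identical seeds give byte-identical
libraries; ports to other generators must document theirs.  Not modeled,
by design: transcription/transfection efficiency, PCR noise or
overdispersion beyond the binomial, barcode collisions, RNA secondary
structure, and position-specific (as opposed to composition-specific)
effects.  Consequently, passing tests show that the inference machinery
recovers the model's own generative process — not that real assay data are
free of these extra noise sources.

The recovery benchmark hides 20 causal hexamers (ten at −1 kT, ten at
+1 kT) among 4096.  With uniform random regions a causal word occurs in
roughly `20·20/4096 ≈ 10%` of reporters, so most reporters are pure
sampling noise; this is a deliberately hard, sparse regime.

## Estimators

**Enrichment** (default): for each word i, with Uᵢ (Dᵢ) the sum over
reporters of upstream (downstream) reads × occurrence count of i, U and D
the totals, and α the pseudocount,

    sᵢ = [(Uᵢ + α)/(U + α·4ᵏ)] / [(Dᵢ + α)/(D + α·4ᵏ)] ,

a read-weighted smoothed frequency ratio.  The default α = 0.5
(Haldane–Anscombe) keeps all scores strictly positive and log ratios
finite.  Standard errors use the delta method for the smoothed log odds
ratio, `SE² = 1/(Uᵢ+α) + 1/(Dᵢ+α)`; under the null with mostly 0/1
occurrence counts this is calibrated (unit-variance z-scores), with mild
anticonservatism when words recur within one reporter.  Whether the
published assays weighted by reads or by reporters is not settled; this
package implements the read-weighted form and a regression alternative, and
claims neither as a replication of published effect sizes.

**Ridge regression** (cross-check): penalized least squares of empirical
log ratios on per-word occurrence counts.  No intercept by default — the
two-state model has no offset when flanks are fixed — with an optional
intercept flag for misspecification checks.  The default penalty follows a
fixed-prior MAP rule, λ = Var(y)/τ₀² with prior scale τ₀ = 0.1 kT on
per-word log scores (most words are expected to carry effects of a small
fraction of kT; the response variance bounds the noise variance).  λ = 0 on
a singular design raises a documented error rather than silently
pseudo-inverting.  Both estimators are consistent for the log-linear
generative model and agree closely on causal words; their residual noise on
null words is estimator-specific, which is why the regularized regression
is the better-behaved of the two on never-enriched words.

**Evaluation.**  Predicted log ratio of a reporter = Σ occurrences ×
log sᵢ.  Metrics (Pearson, Spearman, RMSE against observed; Pearson
against true when ground truth is attached) are computed on a seeded
held-out reporter fraction when requested, and parameter recovery
(correlation of log scores with −ΔGᵢ/kT) is restricted to words occurring
in at least `min_occurrence = 10` reporters to avoid undefined correlations
on never-seen words.  All filters are echoed into the evaluation report
header.

Two statistical facts bound what these metrics can show, independent of
implementation quality.  First, the correlation between predicted and
*empirical* (read-sampled) log ratios is capped at
`sqrt(Var_true/(Var_true + Var_read))` even for a perfect model; at the
benchmark's read depth the binomial noise on `ln(u/d)` is ≈ 4/reads, which
is comparable to the sparse benchmark's true-signal variance, and
estimation noise summed over a region's windows lowers the ceiling further.
Second, the maximum of ~4ᵏ approximately standard-normal per-word z-scores
grows like `sqrt(2·ln 4ᵏ)` ≈ 4 for k = 6, so under the null a handful of
words always lie beyond 3 SE; per-word calibration should be judged by the
z-score distribution (mean ≈ 0, variance ≈ 1), not by the extreme order
statistic.  The acceptance script reports both quantities as measured.

## File formats and reproducibility

All tabular formats are TSV with `#`-prefixed metadata lines; sequences are
FASTA (wrapped at 80 columns on write, any wrapping read).  Floats are
written as `%.17g` so every writer/reader pair round-trips to an identical
in-memory value and diffs are stable.  Score tables are written in
lexicographic word order (A < C < G < U).  Every CLI run writes a JSON
manifest with the subcommand, all parameters including the seed, and
SHA-256 checksums of inputs and outputs; manifests contain no timestamps or
absolute paths, so identically seeded runs are byte-identical end to end.

## Problem sizes

Defaults used by the test suite and the acceptance script: null-model
calibration at 10⁴ reporters; the sparse recovery benchmark at 5×10⁴
reporters with an 80/20 train/test split; the multiplicative-law identity
on 10³ random (region, table) pairs; positioning demonstrations on a
180-nt, 3-exon toy transcript with single-word motif tables.  These sizes
were chosen so the full suite runs in well under a minute on one CPU while
keeping Monte-Carlo error far below the effect sizes being tested.

## Known limitations

* The mapping from interface occupancy to splicing outcome is quantified
  only for the two-competing-site reporter geometry.
* No droplet geometry, 3D polymer physics, RNA relocalization kinetics, or
  spliceosome assembly steps; "accessibility" is represented solely by
  Boltzmann interface occupancy.
* Co-transcriptional, speckle-independent splicing is explicitly not
  modeled.
* The simulator's noise model is binomial only; real assays are
  overdispersed, so real-data standard errors would be wider than the
  delta-method values reported here.
* Scores are composition-based: a word's effect does not depend on its
  position within the region, and word–word interactions are absent by
  construction.
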