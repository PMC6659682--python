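# Methods

## Quantification model

Each phosphosite is quantified per condition and biological replicate as the
heavy/light (drug/vehicle) intensity ratio, divided by the heavy/light ratio
of the parent protein group, then log2-scaled. The protein division removes
abundance changes so that the normalized value reflects phosphorylation
stoichiometry: −1 is a 50% reduction. Conventions:

* **Intensity 0 = missing.** MaxQuant-style tables write 0 for channels that
  were not quantified; both 0 and empty cells map to NaN, never to a ratio
  of zero.
* **A replicate log2FC is missing** whenever either the phospho or the
  matching protein ratio is missing in that replicate. If a protein has no
  record at all, its sites are normalized against a ratio of 1.0 and flagged
  (`protein_quantified = False`) rather than dropped: phospho-only proteins
  are common, and silent dropping would hide real effectors. Users can
  filter on the flag.
* **Replicate summary = median** of the non-missing values (robust to a
  single outlying replicate). The moderated test consumes the per-replicate
  values, not the summary; the summary feeds only the fold-change threshold.
* The **class I filter** (localization probability ≥ 0.75 and score
  difference ≥ 5) uses inclusive cutoffs at both boundaries — the consistent
  reading of the conventional definition.
* The **medium (super-SILAC) channel** is parsed and carried through but
  excluded from every statistic; it exists only to stabilize searches.

## Moderated statistics

Each condition is tested against mean zero with the empirical-Bayes
moderated one-sample t-test. Per-site sample variances s² with d = n−1
residual df are assumed drawn from a scaled inverse-χ²(d₀, s₀²) prior; the
posterior variance `s²_post = (d0·s0² + d·s²)/(d0+d)` replaces s² in the t
statistic, which then has d₀+d degrees of freedom. Hyperparameters are
estimated per condition by the method of moments on log variances: with
e = log s² − ψ(d/2) + log(d/2), the excess spread var(e) − ψ′(d/2)
identifies d₀ through the trigamma function (inverted by Newton iteration)
and the mean of e identifies s₀². Implementation choices:

* When the excess spread is non-positive the prior is a point mass:
  d₀ = ∞, s₀² = mean of the observed variances, and the test becomes a
  z-test. This matches the reference empirical-Bayes implementation, against
  which the whole chain (d₀, s₀², t, p, FDR) was verified to printed
  precision on a 200×3 matrix (the test suite repeats this check).
* Zero or non-finite variances carry no information on the log scale and are
  excluded from prior estimation. If *no* usable variances remain (exactly
  noise-free data), the pipeline falls back to a point prior at zero
  variance; a guard defines t = ±∞ (p clamped to the smallest positive
  float) when the standard error is zero and the mean is not, and t = 0,
  p = 1 when both are zero. This keeps the zero-noise limit of the generator
  well-defined end-to-end, which is why the generator accepts
  `noise_sd = 0` even though ordinary use keeps it positive.
* With d₀ = 0 the test reduces exactly to the ordinary one-sample t
  (verified against an independent implementation to 1e-10).
* p-values are two-sided (both up- and down-modulation are called); extreme
  statistics are clamped into (0, 1] rather than underflowing to 0.
* Sites with fewer than two non-missing replicates in a condition get NA
  results and are excluded from FDR correction. The minimum is configurable
  (`min_replicates`, default 2); requiring all replicates would discard too
  many real sites, while n = 1 admits no variance estimate.
* **FDR is corrected per condition** (Benjamini–Hochberg step-up,
  hand-implemented and oracle-tested), matching how per-inhibitor results
  are usually presented. A `global_fdr` switch re-adjusts jointly across
  conditions for a study-wide correction; this is deliberately exposed
  because the choice is a genuine ambiguity in common practice.

The AP-MS bait-enrichment z-score, used to validate pull-down experiments,
is (mean(bait) − mean(control)) / sd(control) with missing controls imputed
at a floor (default: half the smallest observed nonzero intensity). Zero
control spread yields ±∞ with a warning rather than an error, since it
indicates enrichment beyond the controls' dynamic range.

## Thresholds and classification

Calls are strict: down means FDR < `fdr_call` **and** summary log2FC <
`log2fc_down` (defaults 0.1 and −0.7); up mirrors it. A site exactly at a
threshold is unchanged — the figure-caption convention ("<") wins over the
looser prose reading ("at least").

Calibration from positive controls takes the *loosest* control behaviour —
the least negative control log2FC and the largest control FDR — and rounds
each outward to a 0.1 grid (fold change toward zero, FDR up). If a control
sits exactly on the grid value, the threshold widens one further step so the
strict inequalities still admit every control. The unrounded values are
returned alongside the rounded thresholds. Rounding to a 0.1 grid reflects
how such thresholds are reported and used in practice; the grid is a
package constant.

Classification across conditions:

* `shared_effector`: down-called in **every** condition. A site with an NA
  result in any condition can never be shared — unobserved conditions are
  not imputed, mirroring how sites quantified in only one replicate of one
  condition must be excluded rather than guessed.
* `specific:<cond>`: passes the stricter cut (FDR < `fdr_specific`,
  default 0.05, and log2FC < `log2fc_down`) in one condition and is not
  down-called in any other. An alternative reading — "quiet elsewhere" means
  the fold change itself stays above the cut regardless of FDR — is
  available as `specific_requires_fc=True`.
* `partial`: down somewhere but not everywhere and not specific. This class
  is an addition that keeps the partition exhaustive; such sites (e.g. known
  feedback sites modulated under two of three inhibitors) are real and worth
  listing rather than folding into "none".
* `none`: everything else.

The classifier is property-tested against an exhaustive enumeration of all
5³ per-condition call patterns and against set-algebra identities (the
shared set equals the intersection of per-condition down sets; relaxing
`fdr_call` can only grow the down set).

## Synthetic data generator

The generator's defaults encode the emulated study design: 3 conditions ×
3 biological replicates; planted shared effectors (2% of sites) with a
−1.5 log2 effect in all conditions and per-condition specific effectors
(1% each) with the same effect in one condition; replicate noise sd 0.25
log2 units on the normalized ratio; 10% of site/condition/replicate
measurements missing completely at random; 10% of sites failing the class I
filter. Channel-level data are generated on the linear intensity scale
(light = lognormal base abundance with per-replicate variation; heavy =
light × 2^(protein drift + effect + noise)), because the pipeline consumes
intensities, not ratios. The protein-level log2 drift (sd 0.1) is shared
between a site and its parent protein record, so proteome normalization
removes it exactly — which is the point of the normalization. Sites are
placed at real positions in randomly generated protein sequences, so the
flank in each record agrees with the FASTA the generator can emit.

What the generator does **not** emulate: intensity-dependent missingness
(MCAR is the minimal assumption in the absence of a stated mechanism),
peptide-level identification and localization errors beyond the binary
class I flag, proline-conversion chemistry, correlated noise between sites
on the same peptide, and heavy-tailed contaminant ratios. Passing the
recovery tests therefore demonstrates that the statistical chain is correct
and well-calibrated under its stated model, not that real-data missingness
or identification artefacts are handled.

The replicate noise sd (0.25) is a free parameter of the emulation — the
underlying study does not report one — chosen as a plausible magnitude for
replicate variation of SILAC log ratios and exposed in the config. Under
these defaults the expected ceiling on shared-effector recall is roughly
0.9 × 0.97 ≈ 0.87 (class I survival × the chance of ≥2 replicates in all
three conditions), and measured recall ≈ 0.83; the detection step itself
loses almost nothing at effect −1.5 vs noise 0.25 (|t| ≈ 10).

## Peptide arrays and motif scoring

The array model: 180 mixtures (9 variable positions × 20 fixed residues)
around a central S/T acceptor, degenerate positions drawing from 17 amino
acids (no Cys/Ser/Thr). Quantifications are normalized to a per-position
linear mean of one and log2-transformed. Replicate assays are normalized
first and then averaged (the alternative order is available); with
identical replicates both orders coincide.

Scoring is additive log2 over the variable positions −5..−1, +1..+4 — the
standard PSSM log-odds model, chosen because only the matrix construction,
not the scorer, is externally specified. The acceptor position never
contributes, S and T centers are treated identically, and `_` padding or
unknown residues contribute zero. Cys/Ser/Thr rows still receive matrix
values (they occur as *fixed* residues even though absent from degenerate
mixtures) and need no special-casing. Kinase ranking sorts by score with
lexicographic tie-breaking on the kinase name.

`example_truth_matrix()` is a **synthetic** ground-truth motif used by the
simulations: hallmark preferences of a RAF-family serine kinase (Leu/Met at
−3, hydrophobic at +1, aromatic at +2) over a fixed-seed graded background
of ~0.35 log2-units spread, normalized per position. The graded background
matters: real arrays never quantify as perfectly flat, and correlation
between recovered and true matrices is only a meaningful statistic when the
truth has spread at every position.

## Problem sizes and numerical choices

The test suite and acceptance script use 2,000-site experiments over five
seeds for recovery statistics, 21,000 tests for the type-I-error
calibration, and 5,000 variances for prior recovery — sizes at which the
Monte-Carlo error of each checked statistic is several times smaller than
its acceptance band. Trigamma inversion runs Newton iterations to relative
tolerance 1e-10 with closed-form limits for extreme arguments. BH adjustment
uses the cumulative-minimum formulation and is compared against an O(n²)
literal step-up oracle and against statsmodels. All simulation randomness
flows through `numpy.random.default_rng` from explicit seeds; runs are
bit-reproducible for a fixed config.

## Known limitations

* The one-sample moderated test is the intercept-only special case of the
  general linear-model framework; contrasts, covariates, trended priors and
  observation weights are out of scope.
* Calibration assumes positive controls are down-modulated; it cannot
  calibrate an up-threshold independently (the up cut mirrors the down cut).
* Motif scoring is sequence-only; no network context, kinase abundance, or
  classifier ensemble is layered on top.
* The generator's MCAR missingness understates the difficulty of real
  intensity-dependent missingness; recall figures from simulations are
  upper bounds in that respect.
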