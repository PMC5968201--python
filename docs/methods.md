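# Methods

This note documents the statistical models implemented in `combiscreen`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the design
was genuinely open.

## Single-agent MAD screen

For one cell line, let `s_ij` be the signal of well `j` of miRNA `i`
(MTS optical density; only miRNA-transfected, drug-free wells count —
untransfected wells and scrambled controls are excluded from both the
means and the global median). The summary statistic is

    r_i = mean_j(s_ij) / median(all s_ij),

and the hit rule is `|r_i − median(r)| > k · MAD(r)` with `MAD(r)` the
**raw** median absolute deviation of the per-miRNA ratio distribution
(no 1.4826 consistency factor — the factor would silently widen the
bounds) and `k = 2` by default. Inequalities are strict. Because the same
wells define numerator and denominator, `median(r) ≈ 1` and the rule is
self-consistent on the ratio scale.

Three choices deserve comment:

* **The MAD referent.** A "MAD of a single ratio" is undefined, so the
  dispersion is computed over the per-miRNA ratio distribution, per cell
  line. An alternative reading (MAD over raw signals, or pooled across
  lines) exists; it is not implemented because it makes the ±2·MAD rule
  either scale-inconsistent or dependent on panel composition.
* **Degenerate dispersion.** When MAD = 0 (near-constant ratios) the rule
  is kept total: any ratio strictly off the median is a hit and the
  result table carries a degenerate flag.
* **The rule is liberal by construction.** For a continuous null the
  fraction of ratios outside ±2·raw-MAD is scale-free and ≈ 18%
  (2·Φ(−1.349) for Gaussian noise). Per-cell-line calls are therefore a
  *screening* instrument, not a controlled test; specificity comes from
  recurrence across the panel. `select_candidates` defaults to
  `min_cell_lines = 2` (the conventional "at least two lines" rule), but
  the package's *recovery protocol* — used in the acceptance suite —
  requires recurrence in at least half a 12-line panel (6 lines). From
  the binomial tail, a null miRNA reaches 6/12 hits with probability
  ≈ 0.01, giving an expected candidate-level false-discovery proportion
  of ≈ 0.05 against 6 broadly active planted miRNAs, while a strong
  effect (0.5× or 1.5× viability against ≈ 5% ratio noise) is detected
  per line with probability ≈ 1. At `min_cell_lines = 2`, by contrast,
  the null recurrence probability is ≈ 0.65, and no choice of noise
  level changes that (the exceedance rate is scale-free), so the 2-line
  rule is a sensitivity device, not a specificity one.

## Dose–response and the working concentration

The model is the four-parameter logistic in its inhibition orientation,

    y(x) = bottom + (top − bottom) / (1 + (x / IC50)^h),

with a **relative** IC50 (curve midpoint `(top+bottom)/2` — the identity
`y(IC50) = (top+bottom)/2` holds exactly and is asserted in tests), not
an absolute-viability IC50. Fitting is bounded trust-region least squares
(`scipy.optimize.least_squares`) on `(top, bottom, log10 IC50, h)`:

* initialization: `top`/`bottom` from the response extremes, IC50 at the
  dose whose response is nearest the midpoint, `h = 1`, with a
  multi-start over `h ∈ {0.5, 1, 2}` keeping the best residual;
* bounds: `bottom ≥ 0`, `h ∈ [0.1, 10]`,
  `IC50 ∈ [min dose/100, max dose·100]` — sparse 8-point series
  otherwise admit wild extrapolated optima;
* tolerances tightened to 1e-15 so noiseless data are recovered to
  better than 1e-6 relative error;
* constant responses raise a degenerate-fit error (no IC50 exists);
  optimizer failure is reported honestly via `converged = False`, and
  `working_concentration` refuses such fits unless overridden.

The dilution-series builder takes explicit top dose / factor / length
(an 8-point 5-fold series from 100 µM ends at 1.28 nM) rather than
assuming one scheme, because real assays mix schemes — e.g. a taxane
series running 0.64 nM–1 µM is not an integer power of 5.

The working concentration for combination assays is `min(IC50, 1 µM)`,
with the cap applied only when IC50 is **strictly** above 1 µM. The cap
reflects screening practice: above ~1 µM, "potency" is no longer the
regime of interest and solvent/off-target effects dominate.

## Interaction testing

Arm signals are pooled across experiment repeats: with duplicates × 3
repeats, each arm contributes n = 6 observations. Each well is treated as
one observation; this pseudo-replicates the repeat structure, which is
acceptable for a rank test used as a screen but would understate
between-repeat variance if repeats drifted systematically — a documented
caveat, not corrected here.

`rank_sum_p` enumerates all `C(n+m, n)` assignments of the pooled
mid-ranks whenever that count is ≤ 50,000 (all screen-scale groups;
6 vs 6 gives 924) and counts rank sums at least as extreme as the
observed one; ties therefore need no correction on the exact path. The
two-sided p is `min(1, 2·min(one-sided))`. Larger groups use the tie- and
continuity-corrected normal approximation. Comparisons are two-sided by
default — the conservative choice when the direction is asserted
separately — with one-sided alternatives available by flag.

A miRNA/drug pair is a **true interaction** iff all three comparisons
against the combination arm (miRNA-only, drug-only, untreated) fall
below the family alpha *and* the combination's median is strictly below
every other arm's median. The direction requirement prevents a
significantly *antagonistic* combination from being labeled an
interaction. The family alpha is `0.05 / n_drugs` at full precision
(0.05/7 = 0.00714… — verdicts never use the printed 3-decimal rounding,
which would flip borderline calls); single-agent miRNA effects use
`0.05 / n_miRNAs`. Note the resolution floor: at 2 vs 2 wells the
smallest attainable two-sided p is 1/3, so small pilot arms can never
reach screen alphas.

## Expression association

The variation filter keeps a gene when ≥ 20% of samples deviate from the
gene's median by ≥ 1.5-fold in either direction, boundaries inclusive,
on the linear scale. Zero-median genes are evaluated after adding the
smallest positive matrix value as a pseudocount, keeping the ratio rule
total on count-like data. Filtering runs **before** the Bonferroni
multiplier is fixed, so the correction counts only genes actually tested.

Spearman correlation uses mid-ranks; p-values come from the
t-distribution approximation (`t = ρ√((n−2)/(1−ρ²))`, df = n−2) for
cohort-sized n, and from exact enumeration of all n! driver permutations
for n ≤ 9, where the approximation is unreliable and the enumeration is
cheap. Constant genes have undefined ρ and are reported with p = 1 and a
degenerate flag rather than dropped, so output rows align with input
genes. A pass requires Bonferroni-corrected p < 0.05 and the requested
correlation sign.

The 3-level perturbation stage codes over-expression / control /
knock-down as 1 / 0 / −1 and keeps genes whose expression is negatively
rank-correlated with the level *and* which already pass the cohort
screen. With three conditions this cannot support inference; it is a
concordance filter by design. Gene-list intersection is case-normalized
set intersection, returned sorted.

## Synthetic data: what it emulates, and what it does not

Well noise is multiplicative log-normal,
`signal = baseline · effect · exp(N(−σ²/2, σ²))` with `σ² = ln(1+cv²)`,
so signals stay positive, the CV is constant across magnitudes (as in
plate readers), and planted effects equal expected signal ratios exactly.
Defaults are the study conditions the analysis assumes:

* screen: 38 miRNAs × 12 cell lines × 4 wells, baseline 1.0 OD,
  `noise_cv = 0.10` (a typical well-level CV for colorimetric viability
  assays); the planted variant places 6 strong miRNAs (0.5× / 1.5×)
  active across the whole panel, emulating broadly active hits;
* combination: 6 wells per arm (duplicates × 3 repeats), `noise_cv =
  0.05`, arm effects multiplicative on the untreated mean;
* dose–response: responses on the true 4PL curve plus additive Gaussian
  noise truncated at 0; recovery simulations use triplicate wells per
  dose, matching how sensitivity assays are run;
* expression cohort: standard-normal driver; planted genes drawn through
  a Gaussian copula whose latent Pearson correlation
  `r = 2 sin(π ρ_s / 6)` yields the target *Spearman* ρ_s — the right
  construction for a rank-based screen — then exponentiated to
  non-negative, log-normal-like expression.

Not modeled: plate spatial/edge effects, batch drift between repeats,
optical-density saturation, transfection-efficiency variation between
lines, and gene–gene correlation beyond the planted driver structure.
Passing tests therefore demonstrate that the *statistical machinery*
behaves as specified under its own assumptions — exactness, error
control, power, recovery — not that real plates are free of systematic
artifacts the generators omit.

## Problem sizes and determinism

The acceptance computations use 500 null and 200 planted combination
experiments, 100 dose–response and 100 screen replicates, and
2000-gene × 300-sample cohorts — sizes at which the Monte-Carlo rates are
stable to well under the margins being asserted while the whole script
runs in seconds. All simulations derive from explicit integer seeds;
hypothesis-based property tests run derandomized. Exact-test enumeration
matrices are cached per group-size pair (`C(12,6) × 6` integers at study
scale).

## Known limitations

* Pooling wells across repeats treats technical replicates as
  independent observations (see above).
* The MAD rule's per-line false-positive rate is an intrinsic ≈ 18% at
  k = 2; only recurrence filtering makes candidate lists specific.
* The 4PL fit reports a relative IC50; absolute-IC50 and GR-style
  metrics are out of scope.
* The interaction criterion is a rank-test conjunction, not a synergy
  surface model (Bliss/Loewe/HSA); it detects "combination beats both
  agents and vehicle", not formal synergy.
* The expression stage assumes samples are exchangeable; no covariate
  adjustment (subtype, batch) is performed.
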