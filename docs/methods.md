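# Methods

## The biphasic population model

Drug responses to high-dose DNA damage are modeled as growth followed by
death. A clone with growth rate `g` (doublings/hour) and drug-induced death
rate `d` (halvings/hour) has, in the treated arm,

    live(t) = N0 · 2^(g · min(t, t_arrest)) · S(t)
    S(t)    = 1                                        for t ≤ t_arrest
            = (1 − LFp) + LFp · 2^(−d (t − t_arrest))  for t > t_arrest
    dead(t) = N0 · 2^(g · t_arrest) · (1 − S(t))

and grows as `N0 · 2^(g t)` untreated. `LFp` is the maximum killable
fraction of the arrested cohort (`LFp = 1` means everyone can die). The
model is deterministic and closed-form; no birth–death stochasticity is
simulated.

Two unit conventions keep the algebra transparent: rates are base-2
(doublings and halvings per hour) and all fold changes are log2. With
`LFp = 1` the treated-vs-untreated log2 fold change is then *linear* in the
rates:

    L2FC_tx/unt = (g − g_wt)(t_arrest − T_tx) − (d − d_wt)(T_tx − t_arrest)
    L2FC_unt/T0 = (g − g_wt) · T_unt0

(the subtraction of the wild-type terms reflects normalization to the
non-targeting guide distribution, which pins the wild-type clone to 0).

**Key assumption.** Death occurs only after proliferation has arrested.
This is what makes the forward map `(g, d) → L2FC` strictly monotone in `d`
at fixed `g` and hence invertible. It is the experimentally observed
coordination for high-dose genotoxic stress; the model is *not* appropriate
for drugs that kill proliferating cells, and a knockout that decouples
growth from death violates the inversion's premise (its inferred `d` is
then a model-consistent effective rate, not a measured one).

If arrest is disabled (scenario modeling), growth continues throughout and
the death term still applies to the cohort present at the arrest time;
cohort conservation (`live + dead = cohort`) holds only in arrested
scenarios.

## Assay design defaults

`AssayDesign` defaults: `T_tx = T_unt0 = 96 h`, `t_arrest = 24 h`,
`g_wt = 1/24` doublings/h, `d_wt = 1/72` halvings/h, `LFp = 1`. These are
calibrated so the wild-type treated arm reaches a lethal fraction of ~0.5
at assay end (one doubling to arrest, then one halving of the cohort over
the remaining 72 h), matching the dosing target of a death-optimized
screen: strong enough to kill half the population, short enough that clone
evolution is driven by death rather than proliferation. All values are
overridable, e.g. from LED fits of the wild-type line (`t_arrest ≈ D0`,
`d_wt ≈ DR / ln 2`).

The screen's untreated passaging is treated as relative-abundance-preserving
dilution and therefore ignored in ratio space. The untreated-vs-T0 interval
is configurable (`T_unt0`); 96 h is the default.

## Inference

1. **Growth**: `ĝ = g_wt + L2FC_unt/T0 / T_unt0`, floored at 1e-5
   doublings/h (flagged) when the implied rate is non-positive.
2. **Death**: root of `predict_l2fc(ĝ, d) = L2FC_tx/unt` by Brent bisection
   on `[0, 10·d_wt]` (`xtol = 1e-12`). Observations outside the achievable
   range at `ĝ` — above the zero-death ceiling, or below the floor (for
   `LFp < 1`, the unkillable plateau bounds it) — are clipped to the
   boundary and flagged `on_manifold = False`, never dropped, so FDR
   accounting keeps the full gene set.
3. **Scoring**: genes are scored on `L2DR = log2(d̂ / d_wt)` (log ratios
   make the null symmetric) against the distribution of non-targeting
   pseudo-genes passed through the *identical* pipeline. For clones clipped
   to `d̂ = 0`, L2DR is computed with `d̂` floored at `d_wt/100`
   (L2DR ≈ −6.6, flagged `d_floored`) to keep the statistic finite.
4. **Error taxonomy**: the conventional call is `sign(−L2FC_tx/unt)` beyond
   a minimal effect `τ_fc = 0.25`; the rate call is `sign(L2DR)` beyond
   `τ_dr = 0.25`. Type I = fold-change call without a rate effect, Type II
   = rate effect invisible to fold change, Type III = opposite signs (the
   inverted inference that afflicts slow-growing sensitizers).

A `PhaseDiagram` (the L2FC surface over a (g, d) grid, default 0.1–2× the
wild-type rates) is built at fit time; its construction asserts the
monotonicity the inversion relies on. Inversion itself uses bisection, not
grid lookup; the diagram serves visualization and the build-time check.

## Screen count processing

- **Trimming**: bottom 5% of guides by total raw count summed across all
  samples (library-wide, not per-sample), ties at the cutoff broken by
  lexicographic sgRNA id; miRNA-targeting guides removed afterwards. An
  abort guard fires if trimming would erase >20% of genes entirely.
- **Depth normalization**: median-of-ratios over non-targeting guides with
  no zero count in any sample (guides with zeros are excluded from factor
  estimation only). Factors are rescaled to geometric mean 1, which makes
  normalization idempotent without changing any between-sample ratio.
- **L2FC**: `log2((mean_norm_numerator + pc) / (mean_norm_denominator + pc))`
  with pseudocount 1 on the normalized scale. This is a deliberate,
  documented substitution for a negative-binomial shrinkage fit: dispersion
  shrinkage is out of scope here, and because significance is referenced to
  the empirical pseudo-gene null — which passes through the same estimator —
  the slightly wider spread cancels out of the z-scores.
- **Gene collapse**: arithmetic mean of surviving guides; genes losing all
  guides are logged and dropped.
- **Null machinery**: `floor(n_NT / 6)` random 6-guide pseudo-genes
  (deterministic under the seed, leftovers discarded); z-scores against the
  pseudo-gene mean/sd; two-sided empiric p as the fraction of 10,000
  resamples of the null whose |z| reaches the gene's, floored at 1/10,000;
  Benjamini–Hochberg across targeting genes.

## Kinetic and dose-response fitting

- **Total-cell interpolation**: the lysed-plate totals at assay start and
  end are joined by a single exponential. Mid-assay totals of an arrested
  population are therefore biased (the true curve is piecewise); endpoint
  metrics are exact. This is the assay's standard approximation and the
  reason the synthetic plate generator also records noise-free truth.
- **LED fit**: bounded trust-region least squares (`LF0, LFp ∈ [0,1]`,
  `D0 ∈ [0, t_max]`, `DR ≥ 0`) with four deterministic starts (D0 at the
  octile midpoints of the window), ties broken by lowest RSS then lowest
  D0. Flat input (range < 1e-3) returns a degenerate fit (`DR = 0`, `D0`
  NaN); monotone-decreasing LF is refused as violating the model. AUC is
  the 512-point trapezoid of the fitted curve over the observed window.
- **4PL fit**: `response(x) = ECmax + (FV0 − ECmax)/(1 + 10^((x − EC50)·h))`
  on `x = log10(dose)`, Levenberg–Marquardt from three hill-slope starts;
  vehicle wells are excluded from the log-dose regression but anchor the
  `FV0` initial guess. Flat responses pin the slope to 0 and flag the fit.
- **GRADE**: FV is first normalized for basal (vehicle) death,
  `LF_norm = max(0, (LF − basal_LF)/(1 − basal_LF))`, pinning untreated
  wells to `FV_norm = 1`. A line through the doses with `GR ≥ 0` gives
  `m_drug`; the maximal observable slope over the same range is the chord
  from `(GR = 1, FV_norm = 1)` to `(GR_min, FV_norm = 0)`, i.e.
  `m_max = 1/(1 − GR_min)`; `GRADE = arctan(m_drug)/arctan(m_max)`. The
  basal normalization and the `m_max` construction are this package's
  documented conventions — the intent (normalize for basal death; steepest
  representable coupling) admits more than one formula. Note `|GRADE| ≤ 1`
  is guaranteed only when the fitted local slope does not exceed the
  anchored chord, which dose series confined to small GR values can violate.

## The synthetic generator

The generator emulates a GeCKOv2-like death-optimized screen: 6 guides per
gene (default 1,000 genes for tests; the 19,050-gene library scale is a
flag away), 1,000 non-targeting guides, 400× coverage, three replicates
each of T0 / untreated / treated, and a treated arm at ~half-lethal
fraction by 96 h under the default design.

Gene classes and log2-scale effect multipliers (mean, sd):

| class             | g multiplier | d multiplier | rationale |
|-------------------|-------------|--------------|-----------|
| neutral           | exactly 1   | exactly 1    | null background (75%) |
| essential         | (−1.0, 0.3) | 1            | dropout via slow growth |
| repair-like       | (−1.2, 0.2) | (+1.0, 0.25) | slow-growing sensitizers |
| death sensitizer  | 1           | (+1.0, 0.25) | pure death-rate increase |
| death suppressor  | 1           | (−1.0, 0.25) | pure death-rate decrease |

The repair-like class is placed so its growth-defect term
(≈ +1.7 doublings over the 72 h death phase) clearly exceeds its
death-excess term (≈ −1.0): that relation is what defines the class — it is
the region of the phase diagram where conventional fold-change analysis
inverts the inference — rather than a free parameter. Guide-level efficacy
jitter (0.1 log2 sd) perturbs multipliers of targeting guides; gene truth is
the class draw, consistent with mean-collapse scoring. Library
representation is lognormal (0.5 log2 sd), and counts are gamma-Poisson
with a single shared dispersion (0.01, a conventional value for screen
replicate scatter — the config knob exists because real screens vary).

What the generator does *not* model: PCR/sequencing error, guide
cross-mapping, copy-number artifacts, clone-to-clone variation in arrest
timing or killable fraction, and any decoupling of growth and death within
a clone. Passing recovery tests therefore demonstrate correctness of the
estimator under the model's own assumptions plus realistic counting noise —
not robustness to every failure mode of a real screen. The generator runs
only the forward model and shares no code with the inversion, so recovery
tests are not circular.

Plate timecourses are the same forward model scaled by a per-cell signal
constant with multiplicative lognormal noise of stated CV; untreated
companion wells are included, and all derived metrics are invariant to the
signal gain.

## Numerical choices and degenerate inputs

- Bisection tolerance `xtol = 1e-12` in `d` (forward/inverse roundtrips are
  exact to ~1e-12 relative with `LFp = 1`, ~1e-9 with `LFp < 1`).
- `score_vs_null` requires ≥ 30 pseudo-genes and a non-degenerate null sd;
  depth normalization requires ≥ 50 non-targeting guides and errors on a
  sample whose non-targeting guides are all zero.
- Fisher odds ratios use a Haldane correction (+0.5 per cell, flagged) only
  when a cell is zero; the p-value is the uncorrected one-tailed
  hypergeometric tail.
- Empiric p-values are floored at 1/n_boot; BH is applied across targeting
  genes only.
- Background subtraction clips negative signals to zero and logs the count;
  `dead > total` points clip live to zero with a warning.
- GR is undefined (NaN, counted in `attrs`) when the untreated reference
  has not grown past T0; complete kill maps to GR = −1.

## Problem sizes

Default test and acceptance scale is 1,000 genes × 6 guides + 1,000
non-targeting guides at 400× coverage (~7,000 guides, 9 samples), chosen as
the smallest screen at which class-level statistics (50-gene classes) are
stable; the full pipeline on it completes in well under a second, and the
whole acceptance run in a few seconds. Library-scale (123,411-guide)
generation is supported for stress testing via `n_genes=19050` or the CLI
`--full-scale` flag.

## Known limitations

- The inversion assumes the wild-type coordination (arrest-then-death) for
  every knockout; clones that keep proliferating under drug violate it and
  are mis-modeled rather than detected.
- L2FC uses replicate means without dispersion shrinkage; very low-count
  guides are noisier than a shrunken estimator would be (partially
  mitigated by the bottom-5% trim and the empirical null).
- The exponential total-cell interpolation biases mid-assay LF for arrested
  populations (endpoints exact).
- Rates are identified only up to the assay window: death rates beyond
  `10·d_wt` (default clip) or below the pseudocount noise floor saturate.
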