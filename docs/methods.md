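# Methods

## The resampling model of replicability

The object of study is a single Delphi round: `N` participants rate `J`
items on a `k`-point ordinal scale.  The question "would a smaller panel
have reached the same result?" is made operational by treating the observed
panel as the population and bootstrapping panels of size `n` from it with
replacement.  For each draw the per-item central statistic (median by
default) is compared item-by-item with the full pool's; the number of items
that agree is the draw's match count.  With `B` draws per size (default
1000) the match-count distribution is summarised by its median, IQR and
mean, and scaled to percentages of `J`.

Drawing **with replacement** keeps the statistic defined for `n > N`, which
matters for small stakeholder groups: a 34-person group can be probed at
n = 100, where the curve measures the residual instability of the group's
own medians rather than sampling depletion.  A warning (not an error) marks
grids exceeding the pool.

Only *complete* raters enter the analysis: any participant with at least one
missing cell — item skipped, or answered with an "unsure / no opinion"-style
token — is excluded wholly before resampling.  Exclusion is per participant,
not per item, because partial raters would otherwise contribute different
denominators to different items.  The filter is idempotent and its exclusions
are reported, never silent.

## Conventions that the numbers depend on

These are recorded in every run manifest:

* **Median.** Midpoint of the two central order statistics on even counts,
  so half-integer medians occur on integer data (a subsample median of 7.5
  does not match a pool median of 7).
* **Match.** Medians match on exact equality, with a 1e-9 float guard.
  Means almost surely never tie exactly, so mean-mode matching rounds both
  sides to `mean_match_decimals` places first (default 1); the choice is a
  config field and flagged in output metadata because no canonical
  convention exists.
* **IQR.** Q3 − Q1 of the B match counts with numpy's linear interpolation
  between order statistics; the estimator is configurable
  (`quantile_method`) since discrete conventions also produce the
  integer-valued IQRs seen in published tables.  Figures use the same
  convention as tables so whiskers and tabulated IQRs agree.
* **Percentages.** Rounded half-away-from-zero to integer percent for
  reporting (18/22 → 82%, 2/22 → 9%); unrounded match-count columns are
  retained in the CSV.
* **Bands.** [0, 60) below-moderate, [60, 80) moderate, [80, 90) high,
  [90, 100] very high.
* **Randomness.** One root seed; each sample size draws from its own
  substream keyed by `(seed, size)`, so editing the grid never changes the
  draws taken at other sizes, and identical inputs give bit-identical
  curves.  Participants are indexed in id-sorted order inside the engine,
  making every statistic invariant to input row order.

## Consensus rules

Consensus-for-inclusion: at least 70% of raters in the critical band AND
fewer than 15% in the not-important band; consensus-for-exclusion is the
mirror.  Shares are compared as exact rationals (count/n against 7/10 and
3/20), because the rules are thresholds, not rounded summaries; ≥ is
inclusive at 70% and < strict at 15%.  The two verdicts are mutually
exclusive by construction (two disjoint bands cannot both hold ≥ 70%).

Published rules are phrased for 9-point scales (critical 7–9,
not-important 1–3).  For other scales the package defaults to the top-3 and
bottom-3 categories — (8–10)/(1–3) on 10 points — an explicit convention
recorded in the manifest, since consensus counts on 10-point data depend
on it.

## Subgroup analysis

Built-in groupings: gender; merged professional roles (epidemiologists +
trial investigators → Researchers, statisticians + trial methodologists →
Methodologists, clinical/allied health → Clinicians); years of experience
split at 15; age split at 44/45; Europe vs Rest of the World; patient/carer
vs clinician/health professional; and the four World Bank country-income
classes.  Country → region and country → income tables ship as editable
CSVs (the income file is year-versioned) rather than hard-coded lists.
Participants a rule cannot place go to an explicit `unclassified` bucket
that is always reported — real panels include roles outside every scheme.

Each group's resamples are compared, by default, against the **group's own**
full-pool medians (`own_pool`): group-level replicability approaching 100%
as n approaches the group size is only coherent against the group's own
pool, and published subgroup tables head their columns with group-specific
N.  The alternative `overall_pool` reference — comparing a lone stakeholder
group against the whole panel's medians — is available behind a flag and
measures something different: the share of the panel-wide verdict a single
group reproduces, which plateaus at the fraction of items on which group
and panel medians agree.  The choice is recorded in the manifest.

## The synthetic panel generator

Participant i in stakeholder group g rates item j through a latent opinion

    z_ij = mu_j + gamma_g + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

discretized by k − 1 equally spaced thresholds spanning the fixed window
mu_0 ± 4·s_total (s_total² = tau² + sigma_u² + sigma_e²), so the number of
scale points controls granularity without rescaling the noise.  Item
locations are N(mu_0, tau²) except for a configurable fraction of
**knife-edge** items, whose location is placed so the latent population
median falls exactly on a threshold: their subsample medians flip between
adjacent categories at any n, which is the mechanism that keeps
replicability below 100% and makes small panels land in the moderate band.
A configurable share of participants receives 1–3 blanked cells to exercise
the completeness filter; every decision (locations, knife-edge items, group
labels, rater effects, incomplete ids, thresholds) is returned as ground
truth.

Preset panels mirror the shapes of three published multistakeholder
surveys: `surrogate-like` (175 × 22, 9-point), `spi-like` (333 × 77,
10-point), `cosb-like` (553 × 88, 9-point).  Their dispersion —
tau = 2.0, sigma_u = 0.8, sigma_e = 1.6, 20% knife-edge items, 5%
incomplete raters, stakeholder shifts +4.6/+5.0/+4.0 for
clinicians/researchers/patients — was fixed once so that n = 20
replicability falls in the 60–80% moderate band and rises toward ≈ 90%
by n = 500, the regime real panels show.  The shared positive stakeholder
shift emulates a fact about real consensus exercises: candidate items are
pre-screened, so most raters score most items favourably.  Without it a
symmetric mid-scale panel cannot produce meaningful consensus counts (under
Gaussian item locations fewer than ~8% of items can clear a 70% band
share), which would leave the consensus pipeline exercised only by
degenerate fixtures.

What the generator does **not** emulate: multi-round dynamics and feedback,
attrition, item-wording effects, correlated rater behaviour beyond the
single additive rater effect, non-Gaussian opinion distributions, and the
strongly skewed consensus levels of real panels (synthetic full-pool
consensus sits near 35–50% of items versus ~64–73% in real reporting
-guideline data).  Passing tests therefore demonstrate the statistical
machinery and its conventions, not the rating behaviour of any particular
real panel.

## Problem sizes used in the shipped checks

The test suite validates the bootstrap against exhaustive enumeration on
pools small enough to enumerate (all N^n ordered draws for N ≤ 4, n ≤ 3;
total-variation agreement < 0.02 at 50 000 draws), and runs the larger
stochastic checks — monotone-on-average curves, plateau behaviour, the
upward shift of the 80% crossing across residual-noise doses 0.8/1.6/3.2 —
on the `cosb-like` preset with 250–300 draws per size on thinned grids.
The acceptance script uses the full 20–500 step-10 grid with B = 1000 for
full-sample and consensus curves and the 20–100 step-10 grid for
subgroups.  These sizes were chosen so the whole analysis reruns from
scratch in minutes on a single CPU; B = 1000 matches the reporting design
the percentages are defined for.

## Known limitations

* The match statistic is all-or-nothing per item: a subsample median one
  category away counts the same as one three categories away.
* Half-integer pool medians (even N) systematically depress match rates at
  odd n and vice versa; this parity effect is inherent to the statistic.
* No confidence intervals accompany the curve — the analysis follows the
  descriptive design it implements; the IQR column is the dispersion
  summary.
* `min_size_for` reads the first grid point at or above the threshold; on
  noisy curves near the boundary the crossing can move by one grid step
  between seeds.
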