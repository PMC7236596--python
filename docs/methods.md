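# Methods

## Scales and scores

The EMES grades four mucosal features per colonic segment:

| item | categories | meaning |
|---|---|---|
| erythema | 0–3 | absent / mild / moderate / severe |
| vascular_pattern | 0–2 | normal / reduction / disappearance of the submucosal vascular pattern |
| erosions | 0–3 | absent / 1–5 / 6–10 / >10 lesions |
| ulcers | 0–3 | absent / 1–5 / 6–10 / >10 lesions |

The segment score is the plain sum (0–11); the global score sums the five
segments (0–55). The Mayo endoscopic subscore is a separate,
observer-assigned 0–3 grade per examination — it is *not* derived from the
EMES items, since in a reading study both scores are assigned independently
and blind. A global score is undefined for partial colonoscopies: no
rescaling by reached segments is attempted, because any such normalization
is itself a modelling choice that changes the score's meaning. Per-subject
across-rater summaries report the sample SD (ddof = 1), the usual choice
for a small rater panel treated as a sample of possible readers.

## Weighted multi-rater kappa

All agreement cells use the same chance-corrected coefficient. With
`n_ik` raters assigning category `k` to subject `i`, `r_i` raters on
subject `i`, and symmetric weights `w_kl` with unit diagonal:

    a_i = sum_kl w_kl n_ik (n_il - [k=l]) / (r_i (r_i - 1))
    pa  = mean_i a_i
    p_k = mean_i n_ik / r_i
    pe  = sum_kl w_kl p_k p_l
    kappa = (pa - pe) / (1 - pe)

Identity weights recover classical (unweighted) Fleiss' kappa; linear and
quadratic weights credit partial agreement between nearby ordinal grades.
**Linear is the default**: it is the most common non-trivial choice for
ordinal clinical grades and more conservative than quadratic. Chance
correction uses the pooled marginals (one marginal distribution shared by
all raters), as in Fleiss' original multi-rater coefficient. A consequence
worth stating: in the two-rater case this reduces to the weighted
Scott/Fleiss coefficient computed from the contingency table with
*averaged* margins — not to Cohen's kappa proper, whose chance term uses
the product of each rater's own margins. The test suite exploits this: the
two-rater specialization is verified to 1e-12 against an independent
contingency-table computation, and identity-weight kappa against a
brute-force enumeration of all rater pairs.

Scale handling:

* The category space is fixed by the scale definition (K = 4, 3, 4, 4, 4,
  12, 56), never by the observed categories. Truncating to observed
  categories would silently change the weight matrix — critical for rare
  grades such as ulcers.
* Derived scales (segment EMES 0–11, global EMES 0–55) are computed per
  rater first and then treated as ordinal categories on their full
  theoretical range with the chosen weights. No binning is applied.
* Subjects rated by fewer than two raters on a scale carry no pairwise
  agreement information and are dropped from that scale's computation;
  the count of dropped subjects is retained on the `CountMatrix`.
* If every rating in the study falls in one category, `pe = 1` and kappa
  is undefined. This is reported as a flagged degenerate result, never as
  a silent 0 or 1.

## Uncertainty

The default standard error is the subject-level linearization (the
influence-function variance used for multi-rater weighted coefficients,
Gwet-style). With `pi_ik = n_ik / r_i` and `wbar_k = sum_l w_kl p_l`:

    psi_i = [(a_i - pa) - 2 (1 - kappa) (pi_i . wbar - pe)] / (1 - pe)
    se^2  = sum_i psi_i^2 / (n (n - 1))

The second term propagates the subject's influence on the chance-agreement
marginals; `mean_i psi_i = 0` by construction. Two independent
cross-checks are kept in the package and exercised by the tests: a
delete-1 jackknife SE (agrees within ~10% at n = 16 on study-like data;
the jackknife runs slightly high at this n, as expected for a
nearly-unbiased resampling estimator against a first-order linearization)
and a subject-resampling percentile bootstrap CI (B = 2000, seeded,
degenerate resamples skipped and counted, with a warning flag if more
than 10% skip). The asymptotic 95% CI is kappa ± 1.96·se; either CI may
be selected per analysis. The p-value is the two-sided normal test of
H0: kappa = 0 — two-sided being the conservative reading when no
direction is pre-specified. When se = 0 with kappa ≠ 0 (all subjects
showing identical rating patterns) the p-value is reported at the
smallest positive float and flagged rather than as an exact zero.

Interpretation bands follow the conventional ladder: poor (κ < 0), slight
[0, 0.20], fair (0.20, 0.40], moderate (0.40, 0.60], substantial
(0.60, 0.80], almost perfect (0.80, 1]. Boundaries are half-open with ties
going to the lower band, matching the usual "0.41–0.60" presentation of
rounded values.

## Synthetic rating studies

The generator's defaults reproduce a 13-rater, 16-subject reading-study
design: disease extent 6 proctosigmoiditis / 4 left-sided / 6 pancolitis
and clinical activity 3 remission / 4 mild / 7 moderate / 2 severe, with
class labels assigned to subjects by independent seeded permutation so
the marginals hold exactly.

**Latent model.** Each subject has a per-segment severity θ ∈ [0, 1].
Segments proximal to the extent boundary are healthy (θ = 0:
proctosigmoiditis involves sigmoid + rectum only; left-sided adds the
descending colon; pancolitis involves all five). Involved segments draw θ
uniformly from the activity class's band — remission [0, 0.1], mild
(0.1, 0.4], moderate (0.4, 0.7], severe (0.7, 1]. True item grades are
threshold cuts of θ (`grade = #{cuts below θ}`):

* erythema: 0.25 / 0.50 / 0.75 (equally spaced — responds over the whole
  severity range);
* vascular pattern: 1/3 / 2/3 (likewise);
* erosions: 0.40 / 0.60 / 0.80 — mucosal breaks require at least moderate
  severity, so erosions occur only in moderate/severe subjects (9 of 16
  under the default mix);
* ulcers: 0.55 / 0.75 / 0.90 — deeper lesions need more severe disease
  than erosions, making ulcers the rarest finding, as in real UC cohorts.

The true Mayo grade cuts the maximum segment θ at 0.1 / 0.4 / 0.7, so it
coincides with the activity class. No severity-to-grade mapping is
standard; these equally spaced / shifted cuts are the simplest choice
consistent with the extent and activity structure, and they are frozen
constants, not tuning knobs.

**Rater model.** An observed grade is the true grade plus a rounded
Gaussian error (SD `noise_sd`, optionally scaled per item), clamped to the
scale. One scalar thus controls concordance: SD 0 reproduces the truth
(all 27 report kappas equal 1), large SD approaches guessing. The
`uniform_random` profile replaces grades by uniform draws over the scale —
the exact independence limit, under which the global-EMES kappa at 5000
subjects lies within ±0.02 of 0. Each rater's Mayo grade uses a fresh
noise draw, independent of that rater's EMES errors, mirroring blind,
separate assignment of the two scores. Per-item noise multipliers allow
differential reliability (e.g. inflating ulcer noise to mimic the common
finding that ulcer counts agree worst).

**Calibration.** `calibration_curve` sweeps `noise_sd` and records the
mean ± SD of the global-EMES kappa over replicate studies (fresh cohort
and fresh ratings per replicate; 200 replicates per grid point by
default, which puts the Monte-Carlo SE of each mean near 0.004). The mean
is non-increasing in the noise SD. The packaged default
`CALIBRATED_NOISE_SD = 1.25` comes from this curve: at the
13-rater / 16-subject design it gives mean global-EMES kappa ≈ 0.56
(moderate band), the agreement level typical of multi-reader endoscopic
scoring panels.

**What the generator does and does not emulate.** It reproduces the study
*design* (panel size, cohort composition, extent/activity structure, the
confinement of mucosal breaks to active disease) and a single-knob
concordance level. It does not model rater-specific bias or experience,
correlated errors across items or segments within a rater, video quality,
withdrawal time, or partial colonoscopies. Tests passing on synthetic
studies therefore validate the *statistical machinery* — scoring
arithmetic, kappa, variance, CIs, banding, serialization — not any claim
about how real endoscopists behave.

## Numerical choices and problem sizes

* All randomness flows through `numpy.random.default_rng` seeds;
  simulate → write CSV → read → analyze is deterministic end to end.
* Degenerate inputs (single-category studies, < 2 raters, < 2 subjects,
  empty selections) raise typed errors at the operation level and become
  flagged report rows at the study level, leaving the rest of the report
  intact.
* Routine test runs use 16-subject studies; the independence check uses
  5000 subjects (where the ±0.02 band is a few MC standard errors wide);
  SE cross-checks use 50 replicate studies; the calibration check uses
  200 replicates per noise level. These sizes give stable Monte-Carlo
  behaviour at interactive run times.

## Known limitations

* The linearized SE is first-order; at very small n or near-perfect
  agreement the bootstrap CI is the safer choice (both are provided).
* Printed kappas from published reading studies are not exact
  reproduction targets here: raw multi-reader rating data are rarely
  released, and reported values depend on the (usually unstated) weight
  scheme and variance estimator of the original software. The package
  instead pins down the statistic's exact limits and oracle equivalences
  and reproduces agreement *bands* under a calibrated noise level.
* The generator draws segment severities independently within a subject;
  real disease shows distal-to-proximal severity gradients.
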