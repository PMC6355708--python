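# Methods

## Isotope algebra and the renal Rayleigh model

Compositions are per-mil deltas, δ = 1000·(R_sample/R_ref − 1), against
NIST SRM-915a on the ⁴⁴Ca/⁴²Ca scale (conversion to ⁴⁴Ca/⁴⁰Ca multiplies by
2.05). Renal fractionation is modelled as Rayleigh distillation of the
primary-urine Ca pool: reabsorption removes Ca with a constant
fractionation factor α, so the excreted residue satisfies

    δ_urine = (δ_blood + 1000) · f^(α−1) − 1000,

with f ∈ (0, 1] the excreted fraction of the filtered load. α < 1 encodes
preferential reabsorption of light isotopes, making urine heavier than
blood and the reabsorbed pool lighter (mass balance:
f·δ_urine + (1−f)·δ_reab = δ_blood, which the implementation satisfies to
better than 1e−9 ‰). The inversion f(δ_urine, δ_blood, α) is exact for
α ≠ 1; an implied f outside (0, 1] raises an error rather than being
clamped, since it signals inputs inconsistent with the model.

**α default (0.99975).** The tubular fractionation factor is not known
independently; the default is fixed by the requirement that lowering
reabsorption from 98% to 97% of the filtered load shifts δ_urine by
−0.10 ‰, the canonical magnitude for that scenario. α is a parameter of
every API entry point, never hard-coded.

**Numerics.** f^(α−1) is evaluated as exp((α−1)·ln f), which is exact and
avoids underflow for f ≪ 1. Closed-form identities (round trips, mass
balance) are asserted at 1e−9–1e−12 ‰ in the tests.

**Absolute reference ratio.** The SRM-915a "absolute" 44/42 ratio enters
only when deltas are placed on a log₁₀-ratio axis for log-log baseline
fitting; it moves intercepts and cancels from slopes and per-mil offsets.
Its default (15.0) is an arbitrary plotting convention chosen so that
log-log intercepts near 1.18 — the scale on which published baseline trends
are quoted — correspond to deltas of order 1 ‰. It is not the natural
abundance ratio and must not be interpreted physically.

## Synthetic cohort generator

The generator emulates a 21-day head-down-tilt bed-rest study: sampling on
BDC−6/−2 (baseline), HDT 2/10/21 (bed rest), R+0/+2/+5 (inpatient
recovery) and R+14/+28 (follow-ups); seven male subjects of whom four
receive a KHCO₃ countermeasure. Day numbers count from the start of bed
rest (BDC−d = −d, HDTn = n, R+k = 21+k).

Per-subject physiology:

| parameter | default | rationale |
|---|---|---|
| f_excreted baseline | log-uniform [0.008, 0.055] | reproduces the observed factor ≈ 4.3 between-subject spread of daily Ca excretion and a baseline urinary δ span of ≈ 0.5 ‰ across seven subjects |
| blood δ⁴⁴/⁴² | Normal(0.40, 0.02) ‰ | mean anchored to the reported baseline level scale; the small scatter reflects tight homeostatic regulation of blood Ca and is required for the pooled baseline correlation (r² ≈ 0.9+) that the common-baseline diagnostic presumes |
| filtered load | 220 mmol/d, common | glomerular filtration of ionised Ca; excretion = load × f exactly |
| dietary Ca | uniform 25–28.7 mmol/d | the controlled 1000–1150 mg/d study diet |

Bed-rest response (both channels can be disabled independently to simulate
either hypothesis alone):

- **Bone channel.** Resorption releases bone Ca (δ_bone = blood − 0.3 ‰) at
  up to 5.9 mmol/d, ramping linearly over 7 days starting 12 days after the
  onset of bed rest and decaying 8 days after re-ambulation (linear ramps:
  only the delay windows, not the functional form, are constrained by
  observation). Blood δ is the flux-weighted linear mixture of absorbed
  dietary Ca (fraction 0.25 of intake, ≈ 6.7 mmol/d) and bone Ca; linear
  rather than ratio-space mixing errs by < 0.02 ‰ at these magnitudes.
- **Renal channel.** The excess Ca load raises the excreted fraction,
  f(t) = f₀·(1 + 0.15·flux_bone/flux_diet), moving samples *along* the
  Rayleigh trajectory (higher excretion, lower δ) without leaving the
  healthy baseline trend.

With these defaults the expected cohort-mean δ(HDT21) − δ(BDC) is ≈ −0.14 ‰
(≈ −0.17 ‰ control arm, ≈ −0.11 ‰ supplemented arm, the KHCO₃ flux
attenuation of 0.5 being illustrative rather than estimated), the vertical
drop below the excretion baseline is carried by the bone channel
(≈ −0.10 to −0.14 ‰), and onset is first detectable at the HDT21 sampling
day. Measurement noise is i.i.d. Gaussian with sd 0.05 ‰ (the 1SE scale of
replicate analyses); 24-h pools are independent analyses, so no
autocorrelation is modelled. NTX (bone-collagen marker) is simulated as a
subject baseline (450 ± 75 nmol/d) plus 67 nmol/d per mmol/d of bone flux
plus noise (sd 50), which yields the observed *weak* per-sample coupling
between the two markers.

**What the generator does not emulate:** hormone dynamics (PTH/calcitriol),
intestinal absorption kinetics, dietary isotopic variation, body-compartment
kinetics, female physiology, or assay drift. Passing tests on synthetic
cohorts therefore demonstrate statistical behaviour of the estimators under
the stated structure, not clinical performance on real patients.

## Excretion-baseline diagnostic

Ordinary least squares of y on x = log₁₀(daily Ca excretion), where y is
either δ ‰ (`SEMILOG_DELTA`) or log₁₀ of the absolute 44/42 ratio
(`LOGLOG_RATIO`). On noise-free Rayleigh data with common blood δ and α the
relation is affine to machine precision (the (1 + δ/1000) curvature factor
contributes ~0.1% to the slope), so r² = 1 and the slope is
1000·(α−1)·ln 10 ‰ per decade. Published slope/intercept pairs are
mode-specific constants; the two modes are never mixed, and vertical
offsets are always reported back-transformed to ‰ (log-ratio offsets via
1000·(10^Δy − 1); the two modes agree to < 0.005 ‰ for offsets ≤ 0.5 ‰).

Classification uses the **pointwise prediction band** (default 95%), not
the confidence band of the mean, because a diagnostic call concerns a
single new observation. A sample is "below" when its vertical offset is
beyond the band half-width t·s·√(1 + 1/n + (x−x̄)²/Sxx). No automatic
outlier removal is performed. Fitted baselines serialise to a small JSON
file so a population baseline can be shipped and reused.

## Mixed-effects time course

δ is modelled with a linear mixed model: sampling day as a categorical
fixed effect with the two baseline days lumped into one BDC level, and a
random intercept per subject (statsmodels `MixedLM`, REML). The BDC
coefficient is the baseline level; the other coefficients are a-priori
treatment contrasts against BDC. P-values are two-sided t tests with
residual degrees of freedom n_obs − n_fixed; no multiplicity adjustment is
applied (the contrasts are a-priori at the 0.05 level). On balanced data
the contrasts coincide with the per-day means of per-subject changes from
their own BDC mean, which the tests use as an independent oracle. Levels
observed in fewer than two subjects are dropped with a warning rather than
imputed.

Delay detection is quantised to the sampling grid: onset is the first
bed-rest or recovery day whose contrast is significantly *negative*;
recovery is the first outpatient follow-up day after onset at which the
contrast is no longer significant. Under default generator conditions the
null false-positive rate of the contrasts is ≈ 5% and a −0.15 ‰ step at
HDT21 is detected essentially always (both recomputed by the test suite:
1000 and 500 simulated studies respectively).

## Problem sizes and reproducibility

Monte-Carlo checks use 200–1000 simulated studies of 7 subjects × 10 days,
sizes at which the calibration statistics (median span, type-I rate,
classification rate) are stable to well within their acceptance windows.
All randomness flows through explicit integer seeds via
`numpy.random.SeedSequence` spawning; identical configurations produce
byte-identical CSV/JSON outputs end to end.

## Known limitations

- The Rayleigh model treats renal reabsorption as a single well-mixed
  distillation step with constant α; transcellular vs paracellular routes
  and hormone-driven α changes are not represented.
- The KHCO₃-arm attenuation factor is illustrative; no data constrain it.
- BLUP terminology: for the time factor the reported per-day estimates are
  the fixed-effect contrasts (on balanced data these equal the shrunken
  predictors); subject-level random effects are not reported.
- The excretion baseline is fitted per cohort; building a transferable
  population baseline would require many more healthy subjects than any
  simulated study here contains.
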