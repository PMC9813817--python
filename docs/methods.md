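# Methods

`hragree` implements the statistical validation of a test heart-rate device
(a wrist-worn optical sensor) against a reference device (ECG-derived bpm)
recorded simultaneously while subjects pass through a phased laboratory
stress protocol: relaxation, anticipation, oral speech, mental arithmetic,
relaxation. This note records the models, the estimators, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Data model and pairing

Inputs are long-format per-device bpm streams plus a per-subject phase
schedule, both in protocol-relative seconds. The two relaxation blocks
(session start and end) are merged into a single `relaxation` phase before
any statistic is computed. Pairing cuts the time axis into 0-based,
half-open epochs `[k·e, (k+1)·e)` (default `e` = 5 s, the wearable's typical
reporting granularity), averages each device within an epoch, and keeps
only epochs where both devices supply at least half their expected samples
and agree on the phase label. The between-device difference is oriented
`D = test − reference` throughout, so a device that under-reads shows a
negative bias. Samples outside the plausible range (20, 250) bpm are
dropped on read with a logged count. No clock-drift estimation or
cross-correlation alignment is attempted.

## Mixed models

All model-based quantities come from a linear mixed model with independent
scalar variance components nested within subject, fit by REML with the
variances constrained to be non-negative (L-BFGS-B on the variance scale;
singular fits sit on the zero boundary and are reported with a warning, not
dropped). Because every random factor is nested within subject, the
marginal covariance is block-diagonal and each block is handled with the
Woodbury identity on precomputed per-subject cross-products; subjects with
identical random-effect layouts are batched into stacked solves. This also
makes the subject-resampling bootstrap cheap: a resampled dataset only
changes an integer weight per subject.

Three model families share this engine:

* **Phase ANOVA** (per device): `bpm ~ phase` with random subject and
  subject-by-phase effects. The omnibus phase test is a Wald F with
  Satterthwaite denominator degrees of freedom, computed by
  eigen-decomposing the contrast covariance, assigning each principal
  one-degree contrast a moment-matched df from the REML variance-parameter
  covariance (inverse observed information, numerical Hessian), and
  combining. On balanced data this reproduces the exact
  `(p−1, (s−1)(p−1))` reference distribution to within a few percent, and
  a 1000-replicate null simulation puts the type-I error at the nominal
  5%. Effect size is partial eta squared with a 90% CI by noncentral-F
  inversion. Post hoc pairwise contrasts use the studentized-range (Tukey)
  distribution at each contrast's Satterthwaite df. Satterthwaite is used
  for the contrasts as well, rather than Kenward–Roger: it is available in
  closed form from the same machinery and the two agree closely at this
  design's size.
* **Difference model**: `D ~ 1` with random subject and subject-by-phase
  effects (subject only within a single phase, where the interaction is
  confounded). The fixed intercept is the bias; the total variance of `D`
  is the sum of the components.
* **Stacked concordance model**: `bpm ~ device + phase` over both devices'
  epochs with random subject, subject-by-phase and subject-by-device
  effects (the last dropped with a warning when a subject-device cell has
  fewer than two epochs).

## Agreement metrics

With bias `μ_d` and total difference variance `Var(D)` from the difference
model, and residual `σ²_e` from the stacked model:

* limits of agreement: `μ_d ± z_{(1+γ)/2}·√Var(D)` (γ = 0.95);
* mean squared deviation: `MSD = μ_d² + Var(D)`;
* coverage probability: `P(|D| ≤ CAD)` under `D ~ N(μ_d, MSD − μ_d²)`,
  CAD = 10 bpm (the cardiac-monitor standard's permitted readout error);
  a zero variance degenerates to the indicator `|μ_d| ≤ CAD`;
* total deviation index: `z_{(1+p)/2}·√MSD` (normal approximation,
  p = 0.95); no noncentral-χ² inversion is attempted;
* repeatability coefficient: `1.96·√(2σ²_e)`;
* coefficient of individual agreement: `CIA = 2σ²_e / MSD`, the expected
  squared difference of two within-device replicates relative to the
  between-device disagreement;
* CCC from the stacked model's variance components:
  `(σ²_subj + σ²_subj×phase) / (σ²_subj + σ²_subj×phase + σ²_subj×device
  + β²/2 + σ²_e)` with `β` the fixed device offset. Interpretation bands:
  < 0.90 poor, 0.90–0.95 moderate, 0.95–0.99 substantial, > 0.99 perfect.
  On large balanced two-device data with no phase structure this estimator
  agrees with Lin's moment CCC to within 2%.

Two conventions deserve a note. First, when the two device columns are
literally identical the variance-components CCC and CIA would charge shared
within-cell fluctuation against two indistinguishable devices; both are
therefore short-circuited to exactly 1 in that case, matching the moment
definition of perfect concordance. Second, CIA can exceed 1 when the two
devices track each other within subject-phase cells more tightly than their
own replication variance (strongly shared heart-rate wander with little
device-specific error); the index presumes independent replication errors,
and values near or above 1 should be read simply as "no between-device
disagreement beyond replication noise".

Per-phase reports refit both models within each phase. Phases failing the
fit preconditions produce a row marked unavailable rather than an error.

## Accuracy

MAE is the mean |D| over paired epochs with its SD; MAPE is the mean
|D|/reference in percent. A phase passes when MAE < CAD (10 bpm) and
MAPE < 10%. Overall rows pool epochs rather than averaging phase means.
MAE confidence intervals use the subject-level cluster bootstrap because
epoch-level resampling would ignore within-subject correlation.

## Bootstrap

All confidence intervals are bias-corrected and accelerated (BCa) over
subject resampling: a replicate draws subjects with replacement, keeps all
of a drawn subject's epochs, and relabels duplicates as distinct subjects.
`z₀` uses the fraction of replicates below the point estimate with ties
counted half; the acceleration comes from leave-one-subject-out jackknife
skewness; endpoints are order statistics of the replicate vector, never
extrapolations. The default is B = 5000 replicates; tests and the worked
example use B = 200–500, which changes endpoint Monte-Carlo noise, not the
method. Model-based metrics bootstrap through the weighted-REML fast path
(per-subject sufficient statistics are reused across replicates).

## Synthetic study generator

The generator emulates a 34-subject stress-protocol session sampled on a
5-s grid: two 5-min relaxations, 3-min anticipation, 5-min oral, 5-min
arithmetic. The latent heart rate is
`μ_p + a_s + g_sp + w(t)` with between-subject `a_s ~ N(0, 116.57)`,
subject-by-phase `g_sp ~ N(0, 14.47)` (one draw per merged phase, shared by
both relaxation blocks), and a stationary AR(1) wander with SD `√29.72`
bpm — the variance magnitudes reported for this kind of study. Default
phase means are 72 / 80 / 86 / 90 bpm for relaxation / anticipation /
arithmetic / oral; only their ordering is empirically constrained. A
single seed sequence is split per subject, so enlarging the study never
perturbs earlier subjects' draws.

The wander's lag-1 autocorrelation defaults to 0.5 on the 5-s grid. The
choice is deliberate: fitting an iid-residual mixed model to AR(1)
residuals inflates the subject-by-phase component by roughly
`σ²_w[(1+ρ)/(1−ρ) − 1]/n_cell` and deflates the residual estimate by the
same amount. At ρ = 0.9 with 36–120 epochs per cell that bias reaches
30–60%, destroying the interpretability of variance-component recovery; at
ρ = 0.5 it stays under ~7% pooled, small against Monte-Carlo noise, while
keeping the wander visibly smooth. The AR(1) persistence of real heart
rate is longer; the model trades that realism for estimator fidelity at
the epoch scale.

Devices observe the latent signal through an error model: constant bias; a
proportional bias acting above a knee (optical sensors under-read at
elevated heart rate); additive noise; a reporting lag; per-epoch dropout;
integer quantisation; and optionally a per-subject, per-phase constant
offset drawn `N(m, s²)` independently per device ("motion artifact"
susceptibility). The artifact term exists because device failure that is
heterogeneous across subjects but tied to a phase — fidgeting during an
anticipation period — cannot be expressed through the heart-rate-dependent
knee without also inflating the latent between-subject variance, which
moves the concordance coefficient in the wrong direction. Noise streams
are keyed by the full error model, so distinct devices draw independent
noise; dropout streams are keyed by the model's parameters only, so two
copies of the same device drop the same epochs.

`paper_like_scenario()` bundles the study conditions: a near-ideal ECG
reference against a wearable with slope −1.0 above 92 bpm, noise 3 bpm,
10-s lag, 2% dropout, integer output, and an anticipation artifact
`N(−8, 12²)`; phase means 72 / 80 / 89 / 90. Under these conditions
relaxation shows the best and anticipation the worst value on every
agreement metric — the qualitative per-phase pattern reported by wearable
validation studies — with the anticipation deficit driven by heterogeneous
artifacts plus the lag interacting with the sharp relaxation-to-
anticipation transition. The pattern is a population property; because
per-phase concordance estimates at 34 subjects carry ±25% relative noise in
their subject-variance numerator, the pattern test runs the scenario at 100
subjects, where the ordering is stable across seeds.

What the generator does not emulate: raw ECG/PPG waveforms, R-peak
detection, heart-rate-variability structure, circadian or posture effects,
missing-not-at-random dropout, and clock drift between devices. Passing
tests therefore certify the statistical pipeline against its own assumed
data-generating process, not the behaviour of any physical sensor.

## Numerical choices and degenerate inputs

* REML optimisation runs on a variance scale normalised by the OLS residual
  variance; a failed first start is retried from an inflated-components
  corner; remaining failures raise with the optimizer's message.
* A response with numerically zero residual variation (all differences
  equal) short-circuits to the obvious degenerate fit: OLS fixed effects,
  all components zero. The omnibus phase test refuses degenerate fits
  (zero residual variance) rather than reporting an infinite F.
* Satterthwaite dfs are capped at the residual df; boundary variance
  components get forward-shifted Hessian stencils and a pseudo-inverse,
  which errs conservative.
* Variance components estimated within 10⁻⁸ of the bound are snapped to
  exactly zero and reported as singular fits.
* Epoch windows with fewer than half a device's expected samples count as
  missing for that device; windows straddling a phase boundary are dropped.

## Problem sizes used by the test suite

Parameter recovery runs at 200 subjects (the full protocol, ~55k paired
epochs); oracle equivalence uses 10⁶ normal draws; the null calibration of
the omnibus test uses 1000 replicates at 20 subjects × 6 epochs per cell;
bootstrap coverage uses 500 simulated datasets at 15 subjects with B = 500;
the qualitative pattern runs at 100 subjects. These sizes keep every check
well-identified while the whole suite completes in a few minutes.

## Known limitations

* The fitted models assume iid residuals; the generator's AR(1) wander is
  a deliberate mild misspecification, and real epoch series are more
  persistent still. Variance components absorb part of such
  autocorrelation.
* The normal-approximation TDI understates the boundary when the bias is
  large relative to the spread; the exact noncentral-χ² version is out of
  scope.
* The per-phase difference model cannot separate subject and
  subject-by-phase variance; the subject term within a phase carries both.
* The label "within-subject variability" is sometimes attached, in this
  literature, to what is structurally a between-subject variance (σ² =
  116.57 here); the generator treats it as between-subject, which is the
  only reading consistent with a subject random intercept of that
  magnitude.
* CIA above 1 is possible (see above) and is reported as computed rather
  than clipped.
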