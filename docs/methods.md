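# Methods

## Dose-volume histograms

The canonical in-memory DVH is differential: strictly increasing bin
edges in Gy plus nonnegative relative volumes summing to one.  Cumulative
curves (fraction of volume receiving *at least* a dose, matching the
V95% / V30Gy convention) are derived at the bin edges and interpolated
linearly in between.  All radiobiological computation uses bin midpoints
as the bin dose; the default grid is 0.1 Gy bins, at which the midpoint
approximation contributes sub-percent response error at clinical dose
gradients.  Planning systems do not document their export bin width or
interpolation rule, so these are declared package conventions, not
inferences.

Quantile queries follow the Dx% convention — the minimum dose received by
the hottest x% of the volume — so D2% proxies the maximum and D98% the
minimum structure dose in reports, while acceptability rules that say
"maximum dose" use the true top of the occupied dose range.  On flat
cumulative segments ties resolve toward the lower dose, except at q = 1
where the minimum structure dose is wanted.  Cumulative input that rises
by up to 1e-8 (float noise from exports) is clipped silently; larger
violations are rejected.  A cumulative curve whose top deviates from 1 by
at most 1e-3 is renormalised, beyond that it is rejected.

## Dose-response models

The Poisson sigmoid `P(D) = 2^(−exp(e γ (1 − D/D50)))` is used for both
tumour control and normal-tissue response.  It satisfies `P(D50) = 1/2`
exactly and has normalised gradient `(e ln2 / 2) γ ≈ 0.9421 γ` at D50; γ
is interpreted as the parameter of this closed form, not re-fitted as a
maximum normalised gradient.  Physical bin doses are first converted to
EQD2 with the structure's α/β and the plan's fraction count, each bin's
dose assumed spread evenly over all fractions — the standard DVH-based
practice.  Computation on physical-dose DVHs is available via
`use_eqd2=False`; EQD2 is the default because the linear dose-response
formulation is defined on 2-Gy-equivalent dose.

TCP multiplies per-bin responses in relative-volume weights
(voxel-independence); with fine bins this is equivalent by construction
to a per-voxel product, and the test suite asserts agreement with
brute-force voxel products to 1e-10 on matched DVH/grid fixtures.  NTCP
uses the relative-seriality architecture parameter s; for uniform dose it
collapses to `P(D)` for every s, and at s = 1 it reduces to
`1 − Π (1 − P_i)^{v_i}`.  All probability products are accumulated as
sums of logs; probabilities below ~1e-300 underflow to exactly 0.

P+ combines one TCP with all NTCPs under independence,
`P+ = TCP · Π (1 − NTCP_j)`.  This is a declared policy: the
complication-free control probability is named but not printed as a
formula in the planning literature this package targets, and the
independence form is the conventional choice.

`invert_uniform_response` brackets the uniform EQD2 dose on
`[0, 3 D50]` and solves by Brent's method to 1e-6 Gy, evaluating the full
single-bin DVH path rather than the bare sigmoid so the whole machinery
is exercised.

## Plan indices and acceptability rules

CN (Van't Riet) uses the prescription dose as the reference dose.  The
uniformity constraint interprets its "std. dev %" threshold as the
coefficient of variation of dose within the structure, in percent.
"Less than 1%" dose-volume rules map to D1% ≤ the stated dose
(non-strict, tolerance 1e-9 Gy); "1 cc" variants query the dose to the
hottest 1 cm³ and require an absolute structure volume.  OR-style
clinical rules carry a primary limit plus a list of fallback branches and
report which branch satisfied them.  The "target conformance" constraint
of the optimizer's taxonomy describes spatial dose falloff, which a DVH
cannot measure; it parses but is rejected at evaluation.

## Paired comparison

The comparison model computes the full metric battery per plan (TCP for
the boost target with the stage-appropriate parameter row, NTCP per OAR,
physical indices), then per-metric arm mean ± sample SD (n − 1) and a
two-sided Wilcoxon matched-pair signed-rank p per stage stratum,
flagging at p ≤ 0.05 (no multiple-testing correction, matching common
planning-study practice).  Zero differences are dropped (classical
Wilcoxon, not Pratt); magnitude ties get midranks.  Up to 15 informative
pairs the null distribution of W+ is enumerated exactly over all 2^n
sign assignments — valid in the presence of ties — and beyond that a
normal approximation with midrank tie correction and no continuity
correction is used.  Differences below 1e-9 (float-rounding scale for
Gy/percent metrics) are treated as zero so that saturated metrics such as
V95% = 100 in both arms degenerate to p = 1 rather than testing float
noise.  Advanced-stage cohorts pool T3 and stage-4 tumours; each case
carries a tag selecting its TCP row, and the default synthetic advanced
cohort assigns half of the cases to each — a declared convention, since
pooled reports do not state the per-case assignment.

## Synthetic cohorts

The generator produces DVHs directly in histogram space as truncated
normal mixtures — the analysis consumes only DVHs, so this is the
minimal sufficient statistical structure; no phantom dose calculation is
involved (a small dose-grid path exists separately for oracle tests).
Three families:

* **Targets**: main lobe centred at ~102% of the prescription, supported
  above 95% of it (so V95% ≈ 100 by construction), plus a hot-spot lobe
  centred at prescription + 5.5 Gy and supported above 107% of the
  prescription, so V107% tracks the configured hot-spot weight and the
  weight is recoverable from generated cohorts.
* **Parallel organs** (parotid): low-dose bulk truncated at 40 Gy plus a
  tail component on [40, 72] Gy whose weight is the configured V40-region
  fraction.
* **Serial organs** (cord, stem, optics, and the low-dose lens/retina):
  a truncated normal ending at a shoulder dose, placing D1% within
  ~2 Gy below the shoulder and D5% a further ~1–2 Gy down.

Arms of one patient share the anatomy draws (structure volumes, lobe
centres, hot-spot and tail-weight offsets, conformity selectivity) and
differ through arm parameters plus independent arm noise; paired
differences are therefore sign-consistent where arm effects are nonzero
and exactly symmetric about zero under the null configuration (both arms
given the dose-volume arm's parameters), which is what makes the exact
signed-rank test exactly valid in the calibration study.  Default effect
sizes reproduce the published qualitative contrast pattern between
biologically and dose-volume optimized plans — hot-spot burden and HI up,
parotid high-dose tail and xerostomia NTCP down, serial organs
unchanged — at roughly the published magnitudes (e.g. hot-spot weight
0.15 early / 0.41 advanced vs 0 / 0.008; parotid tail 0.10 vs 0.25).
Exact published means are not a target: they depend on patient anatomy
that no generator of this kind can reproduce.  Between-patient and
within-arm noise scales were chosen to give between-patient SDs of the
order reported in planning studies and a cross-arm correlation of
per-case parotid mean dose above 0.7.

What passing tests show — and do not show.  The synthetic cohorts share
none of the spatial features of real plans (no anatomy, no dose
calculation, no correlated structures beyond the shared draws), so
passing calibration and pattern tests demonstrates that the evaluation
and testing machinery is correct and well-calibrated, not that any
clinical conclusion transfers to real patients.  Known gaps: TCP
between-patient spread is understated (no radiosensitivity
heterogeneity), so the synthetic early-stage TCP contrast can reach
significance where a real cohort's would not; target minimum-dose
variation is limited by the fixed 95%-of-prescription support.

## Numerical and testing choices

Seeds: every stochastic routine takes either an explicit
`numpy.random.Generator` or a seed stored in the generator config; no
global state.  The acceptance script derives all of its per-study seeds
from a single `--seed`.  Problem sizes in the test suite — 100 oracle
fixtures, 400 null-calibration replicates of 10-case cohorts, 50
recovery replicates — were chosen as the smallest sizes at which the
binomial/Monte-Carlo noise of each check is comfortably below its
assertion band.  Type-I calibration asserts the per-metric flag rate in
[0.03, 0.08]: with n = 10 pairs the exact two-sided test attains level
50/1024 ≈ 0.0488, and degenerate metrics (saturated coverage, underflowed
NTCP) never flag and are excluded from the band as conservative rather
than miscalibrated.
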