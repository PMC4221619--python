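# planbio

Radiobiological evaluation and paired statistical comparison of
radiotherapy treatment plans, computed entirely from dose-volume
histograms (DVHs).  Built for medical physicists and planning researchers
who want to score competing IMRT plans — e.g. biologically optimized
(BBTP) versus dose/dose-volume optimized (DVTP) head-and-neck plans — with
outcome models and the standard physical indices, and to test paired
cohorts of such plans for significant differences.

## What it computes

For each structure's DVH (bins `D_i` with relative volumes `v_i`,
converted per bin to the equivalent dose in 2-Gy fractions,
`EQD2 = D (d + α/β) / (2 + α/β)` with `d = D / n_fractions`):

* **Poisson dose response** `P(D) = 2^(−exp(e γ (1 − D/D50)))`, with
  `P(D50) = 1/2` and normalised slope `γ` at `D50`;
* **Tumour control probability** `TCP = Π_i P(EQD2(D_i))^{v_i}`;
* **Relative-seriality NTCP**
  `NTCP = [1 − Π_i (1 − P_i^s)^{v_i}]^{1/s}`, where `s` interpolates
  between parallel (`s → 0`) and serial (`s` large) organ architecture;
* **Generalized EUD** `(Σ_i v_i D_i^A)^{1/A}` and the complication-free
  control probability `P+ = TCP · Π_j (1 − NTCP_j)`;
* **Physical indices**: Dx% / VxGy queries, V95/V107/V110, D1%/D5%,
  mean/max/min dose, conformation number
  `CN = (V_T,ref/V_T)(V_T,ref/V_ref)` and homogeneity index
  `HI = (D2% − D98%)/D50%`;
* **Acceptability rules** for six organ-at-risk classes (primary dose
  limit with clinical fallback branches, e.g. parotid mean ≤ 26 Gy *or*
  V30Gy < 50%);
* **Paired cohort comparison**: per-metric arm means ± SD and a
  two-sided Wilcoxon matched-pair signed-rank test (exact 2^n enumeration
  up to n = 15, tie-corrected normal approximation beyond), flagged at
  p ≤ 0.05.

A parameter library ships with staged TCP rows (D50 = 57.4 Gy, γ = 6.3
for stage I/II; 60.2/4.2 for T3; 67.0/3.0 for stage 4; α/β = 10 Gy) and
relative-seriality NTCP rows for brain stem, spinal cord, optic
nerve/chiasm, retina, lens and parotid.

Because real paired planning cohorts are rarely shareable, the
`planbio.simulate` module generates seeded synthetic cohorts directly in
histogram space: paired arms share per-patient anatomy effects and differ
only through configurable arm effects (target hot-spot weight, parotid
high-dose tail, serial-organ shoulder), so the full pipeline is testable
end to end.

## Worked example

```sh
planbio simulate --stratum early --n-cases 10 --seed 7 --out demo/cohort
planbio evaluate --plan demo/cohort/early-01/BBTP --out demo/eval
planbio compare  --cohort demo/cohort --out demo/cmp
```

`evaluate` prints the constraint report for one plan (P+ combines the
plan's TCP with all NTCPs; each rule reports which branch satisfied it):

```
INFO planbio: P+ (complication-free control) = 0.9619
plan early-01-BBTP (BBTP): PASS
  brain stem             brain_stem      met via primary
  spinal cord            spinal_cord     met via primary
  optic nerves/chiasm    optic_nerve     met via primary
  optic nerves/chiasm    optic_chiasma   met via primary
  parotid glands         parotid         met via fallback
  eyes                   eye_retina      met via primary
  lens                   lens            met via fallback
```

`compare` prints one table per stage stratum (`*` = significant at
p ≤ 0.05, `~` = not significant).  Excerpt from the run above:

```
structure     metric            BBTP mean±SD        DVTP mean±SD         p  sig
-------------------------------------------------------------------------------
PTV70         tcp                 99.08±0.10          98.96±0.13    0.0059  *
PTV70         v107pct             14.23±8.42           2.69±4.71    0.0020  *
PTV70         hi                   0.10±0.01           0.07±0.02    0.0020  *
PTV70         cn                   0.84±0.04           0.82±0.06    0.6250  ~
```

Read: the biologically optimized arm carries a ~14% hot-spot volume above
107% of the prescription and a correspondingly higher homogeneity index
(both flagged), while conformity is indistinguishable between arms.  The
same table shows the parotid high-dose tail (V40Gy, V50Gy) and its
xerostomia NTCP significantly lower in the biological arm, and no
significant differences for the serial organs.

The same operations are available as a library:

```python
from planbio import ParamLibrary, FractionationScheme, tcp_poisson
from planbio.simulate import GeneratorConfig, make_cohort
from planbio.compare import PairedPlanComparison

cases = make_cohort(GeneratorConfig.default("early", seed=7))
results = PairedPlanComparison(cases).fit()
print(results.summary())
```

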