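# y90dose

Dosimetry and radiobiology toolkit for selective internal radiation therapy
(SIRT) of the liver with ⁹⁰Y-loaded microspheres.

Radioembolisation delivers β-emitting microspheres through the hepatic
artery; planning and analysing such treatments means turning an administered
activity (or an activity image) into absorbed doses for the tumour, the
normal liver and the lungs, and relating those doses to response and
toxicity. `y90dose` implements that chain end to end, for physicists and
researchers who want the standard models in one scriptable, tested package:

* **Region-based dosimetry.** Because the microspheres are permanently
  trapped, the cumulated activity is `Ã = A(0)/λ` and the absorbed dose in a
  compartment reduces to `D [Gy] = 50 · A [GBq] / M [kg]` (the rounded
  ⁹⁰Y constant, exact value 49.8 nJ/Bq from Δβ = 933 keV and
  λ = 3.00×10⁻⁶ s⁻¹). On top of this sit the three-compartment partition
  model driven by the lung shunt fraction (LSF) and tumour-to-normal uptake
  ratio `r`, multi-compartment dose coefficients `d_c = a_c·50/M_c` from
  fractions of injected activity, and the post-therapy concentration formula
  `D = c₀·50×10⁻⁶/ρ`.
* **Voxel dosimetry.** Dose maps by local energy deposition (each voxel
  absorbs what it emits) or by convolution with a packaged ⁹⁰Y dose-point
  kernel (0.05 mm tabulation to 12 mm in water, density-scalable), plus
  dose–volume histograms with D_X / V_YGy statistics.
* **Partial-volume vs β-transport study.** Digital sphere phantoms quantify
  how a Gaussian imaging PSF mimics β transport through the ratio of the
  recovery coefficient RC(d, FWHM) to the self-absorbed fraction φ(d).
* **Dose–response statistics.** A simulated 100-lesion cohort
  (doses 1–199 Gy, Bernoulli responses from a Gompertz-like sigmoid) with
  Wilcoxon rank-sum comparison, ROC/AUC (DeLong CI, Youden cutoff) and
  logistic ED50/ED80 fitting.
* **Radiobiology.** Linear-quadratic TCP with the Lea–Catcheside factor
  `G = λ/(λ+μ)`, equivalent uniform dose, Lyman NTCP with `TD50(v) = TD50/v`,
  the microscale (activity-per-sphere) liver TD50 model, the therapeutic
  index `TI = (TD50/ED50)·r` and the complication-free tumour control
  `P* = TCP·(1−NTCP)`.

## Worked example

```python
from y90dose import PartitionInput, partition_model
res = partition_model(PartitionInput(
    administered_activity_gbq=1.8, lsf=0.06, tn_ratio=2.5,
    tumour_mass_kg=0.30, normal_liver_mass_kg=1.40))
print(f"tumour dose      {res.dose_tumour_gy:6.1f} Gy")
print(f"normal liver dose{res.dose_normal_liver_gy:6.1f} Gy")
print(f"lung dose        {res.dose_lung_gy:6.1f} Gy")
```

```
tumour dose        98.4 Gy
normal liver dose  39.3 Gy
lung dose           5.4 Gy
```

1.8 GBq with a 6% lung shunt and a T/N ratio of 2.5 concentrates activity in
the 300 g tumour (98 Gy) while the 1.4 kg normal liver stays below 40 Gy; the
lung receives the shunted 0.108 GBq into its default 1 kg mass.

```python
from y90dose import simulate_cohort, roc_analysis, logistic_fit
c = simulate_cohort(seed=1)
roc = roc_analysis(c); fit = logistic_fit(c)
print(f"AUC {roc.auc:.3f} (95% CI {roc.auc_ci95[0]:.3f}-{roc.auc_ci95[1]:.3f})")
print(f"ED50 {fit.ed50_gy:.1f} Gy (95% CI {fit.ed50_ci95[0]:.1f}-{fit.ed50_ci95[1]:.1f})")
```

```
AUC 0.949 (95% CI 0.912-0.986)
ED50 98.0 Gy (95% CI 86.2-109.7)
```

A single simulated cohort: tumour dose separates responders from
non-responders with AUC ≈ 0.95 on this draw, and the logistic model places
the 50% response dose near 98 Gy. Single-cohort statistics scatter
substantially between seeds (the AUC sampling mean is ≈ 0.92); treat
one-draw numbers accordingly.

The same operations are available from the shell, e.g.

```bash
y90dose partition --activity-gbq 1.8 --lsf 0.06 --tn-ratio 2.5 \
    --tumour-mass-kg 0.30 --normal-mass-kg 1.40
y90dose table1 --out table1.csv
y90dose td50-micro --v 0.7 --sphere-activity-bq 50      # -> TD50 = 56.6 Gy
y90dose ti --td50 70 --ed50 70 --tn-ratio 2             # -> TI = 2.00
```

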