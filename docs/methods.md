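# Methods

## The measurement chain

The package estimates regional oxygen metabolism by combining four
independent measurements per subject:

1. **Perfusion kinetics.** The pCASL difference signal is modelled with a
   single blood compartment: a labelled bolus of duration τ arrives after
   the arterial transit time (ATT) and relaxes with the T1 of blood
   throughout, with no exchange into tissue. This deliberately ignores
   tissue T1 and dispersion; for the 3-delay product sequences modelled
   here (vascular crushing and background suppression absorbed into the
   labelling efficiency α) the blood-compartment assumption is the
   standard quantification choice. The voxel-wise M0 calibration is scaled
   to blood by the partition coefficient λ (m0_blood = m0_voxel/λ); in the
   post-bolus regime the model then reduces algebraically to the standard
   single-PLD quantification formula, which the tests assert as an
   identity.
2. **Venous oximetry.** Susceptibility of venous blood relative to CSF is
   linear in deoxyhaemoglobin: Δχ = (1−SvO2)·Δχ0·Hct + Δχ_HbH2O·Hct.
   Vein ROIs are thresholded to the 130–1000 ppb venous window and the
   90th percentile (linear interpolation between order statistics) of the
   surviving non-zero voxels is inverted for SvO2. The percentile, rather
   than a mean, suppresses the partial-volume voxels that survive the
   threshold at the vessel edge.
3. **Arterial saturation.** End-expiratory extrema of the exhaled-O2 trace
   are found as peaks of the negated trace with a minimum prominence
   (default 0.5 %O2) and minimum breath spacing (1.5 s); the median
   end-tidal percentage is converted to a dry-gas partial pressure,
   PO2 = EtO2/100·(P_bar − P_H2O) with 760/47 mmHg defaults, then to
   saturation through the Severinghaus curve. A configuration switch
   allows feeding the raw percentage path instead, for auditing.
4. **Combination.** OEF = (SaO2 − SvO2)/SaO2 and CMRO2 = CBF·[O2]a·OEF with
   [O2]a from [Hb] = Hct/3 and 55.6 µmol O2/g. CBF and ATT enter as
   pooled-voxel medians over composed venous territories so that the
   perfusion estimate drains into the same vein whose SvO2 is used.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| α (labelling efficiency) | 0.85 | – | overall label scaling |
| λ (partition coefficient) | 0.9 | ml/ml | voxel M0 → blood M0 |
| T1 of blood | 1/(0.52·Hct+0.38) | s | bolus decay; per subject |
| schedule | (573,885,2024) ms τ with PLDs (700,1297,2158) and (1000,1573,2024) | ms | joint 6-point fit |
| CBF bounds | [0, 200] | ml/100 ml/min | fit box |
| ATT bounds | [100, 3500] | ms | fit box |
| ATT multi-starts | 800/1200/1600/2000 | ms | avoids piecewise local minima |
| Δχ0, Δχ_HbH2O | 0.27, −0.03 (cgs) | ppm | oximetry relation |
| unit system | SI (×4π) | – | see below |
| ROI window | 130–1000 | ppb | vein inclusion |
| vein percentile | 90 | – | edge suppression |
| P_bar − P_H2O | 760 − 47 | mmHg | %→mmHg bridge |

**Unit convention.** The oximetry constants are quoted in cgs, but a
130-ppb lower ROI bound is only consistent with SI-scaled maps (a cgs
venous Δχ of ~45 ppb would never pass it), so the internal convention is SI
ppm with the 4π factor applied; cgs is supported end to end and the tests
assert that a matched-units chain gives identical SvO2 either way.

**Estimator determinism.** The voxel fit is bounded trust-region least
squares from a fixed multi-start grid; ties in residual go to the smallest
ATT. All-zero signals return CBF = 0 with ATT pinned at the lower bound and
`converged=False` — ATT carries no information there.

**Identifiability boundary.** For a schedule whose earliest measurement
time is t_min and shortest label duration τ₁, every ATT ≤ t_min − τ₁
(700 ms for the default schedule) places all points in the post-bolus
branch, where ATT cancels algebraically from the signal. In that regime ATT
is exactly unidentifiable — any value in [100, t_min − τ₁] reproduces the
data — while CBF remains exactly identifiable. Recovery guarantees
therefore apply to ATT ≥ 800 ms.

**Noise and bias.** Under additive Gaussian noise the least-squares
estimator is consistent but, at very low SNR, median-biased: at a noise SD
of 0.5% of M0 the 6-point difference signal has per-point SNR near one
(peak signal ≈ 0.8% of M0 at CBF 50) and the median CBF estimate inflates
by tens of percent. This is a property of the estimator at that SNR — an
exhaustive profiled global search reproduces it — not an optimisation
artefact; at 0.1–0.2% of M0 the same code recovers medians within a few
percent. The stochastic-recovery test and the acceptance script report the
measured biases at 0.5% unmodified.

## What the synthetic generators emulate — and what they do not

* **Cohort.** QRisk uniform on the observed range [5.1, 45.4]; territory
  ATT = baseline + slope·QRisk + a subject-level offset shared across
  territories (matching a random-intercept group model), with the
  generating slope defaulting to 13.2 ms/point. Territory means for ATT,
  CBF and OEF are documented regional constants of a 24-subject cohort;
  subject-offset SDs are those standard errors ×√24. No subject-level
  variance decomposition was available to copy, so these SDs are stated
  scale choices, not facts about real data.
* **ASL phantoms.** Voxels carry the exact forward kinetic signal of their
  territory truth plus i.i.d. Gaussian noise on the difference signal
  (difference images are approximately Gaussian; no Rician floor, no
  motion, no spatial correlation).
* **Susceptibility phantoms.** A cylinder at the exact forward Δχ of the
  generating SvO2, with linear partial-volume blending at the edge
  (fraction of voxel inside the cylinder); no dipole streaking, no
  background-field residuals.
* **Respiratory traces.** Trapezoidal breaths with exact end-tidal
  plateaus and seeded timing jitter; no sensor lag or drift.

Passing tests on these inputs therefore demonstrate correctness of the
estimation chain under its own model assumptions — recovery of known truth,
unit coherence, statistical calibration — and say nothing about robustness
to artefacts the generators do not produce (motion, off-resonance, QSM
streaking, imperfect registration).

## Group and repeatability stages

The group stage is thin glue over an off-the-shelf linear mixed model:
outcome ~ predictor + territory with a random intercept per subject. When
each subject contributes one row the random intercept is unidentifiable and
the stage uses OLS directly; singular or non-converged mixed fits also fall
back to OLS, with the reason recorded in the result's diagnostics.
Inference (type-III ANOVA, p-values) is intentionally not reimplemented —
the substance of this package is the measurement pipeline.

Repeatability uses the Bland–Altman within-subject SD
σ_inter = √(Σ(x1ᵢ−x2ᵢ)²/2n) and CoV = 100·σ_inter / grand mean of all 2n
measurements (per-subject means average to the same number, so the reading
of "mean across participants" is inert).

## Problem sizes

The default verification study uses phantoms of 8³–15³ voxels (about
200–2000 brain voxels), cohorts of 24 subjects and 100 study replicates at
the regional-measurement level, where measurement noise is injected at the
scale of the observed inter-session CoVs (ATT 6.5%, CBF 11%, SvO2 3%)
rather than re-running the image stage per replicate: the replicated
quantity under test is mixed-model slope recovery, which operates on the
regional table. These sizes are the package's own verification choices.

## Known limitations

* Single-compartment kinetics only; no dispersion, two-compartment or
  partial-volume modelling of ASL.
* The shipped vein→territory atlas is a synthetic phantom assignment;
  anatomical label lists must be supplied per study.
* Manual vein outlining is replaced by seed-ROI label volumes; the
  refinement step assumes the seed generously covers the vein.
* Dissolved arterial oxygen is neglected in [O2]a.
* SvO2 clamping to [0, 1] is flagged, and negative OEF is warned but not
  clamped, preserving noise structure for repeatability statistics.
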