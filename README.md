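# dbsi — diffusion basis spectrum imaging for post-treatment glioma assessment

After chemoradiotherapy for high-grade glioma, new or enlarging
contrast-enhancing lesions on MRI may be true tumor progression or
treatment effect (pseudoprogression / radiation necrosis), and
conventional imaging often cannot tell them apart in time to guide
therapy. Diffusion basis spectrum imaging (DBSI) models each
diffusion-MRI voxel as a mixture of tissue compartments and resolves an
isotropic-diffusivity spectrum whose **hindered** band (vasogenic edema
and necrosis) is elevated in treatment effect and depressed in viable
tumor. This package implements that analysis chain for imaging
scientists and methodologists: the forward multi-tensor signal model,
the per-voxel spectral fit, the lesion-ROI quantification and
classification pipeline, the small-cohort statistics, and synthetic
phantoms/cohorts that make every stage testable without patient data.

## Model

The normalized diffusion-weighted signal of voxel with gradient
direction ĝ_k and weighting b_k is

    S_k/S_0 = Σ_{i=1}^{N_aniso} f_i · exp(−b_k λ⊥i) · exp(−b_k (λ∥i − λ⊥i) cos²φ_ik)
              + ∫_a^b f(D) · exp(−b_k D) dD

where each anisotropic (axially symmetric) tensor has axial/radial
diffusivities λ∥, λ⊥ (µm²/ms), signal fraction f_i, and φ_ik is the
angle between ĝ_k and its axis; f(D) ≥ 0 is the isotropic diffusivity
spectrum on [a, b], discretized on a grid of exponentials
exp(−b_k D_j). Fitted spectrum weights are binned into

* restricted fraction, 0 ≤ D ≤ 1.0 µm²/ms — high cellularity (tumor),
* hindered fraction, 1.0 < D ≤ 1.5 µm²/ms — edema / necrosis,
* nonrestricted fraction, D > 1.5 µm²/ms — free (CSF-like) water,

and the summed anisotropic fraction is the fiber fraction; the four
fractions partition the voxel signal. The inverse problem is solved in
two stages: orientation screening by non-negative least squares (NNLS)
over a spherical candidate set plus a coarse isotropic basis, then a
spectrum solve with per-component bounded refinement of (axis, λ∥, λ⊥)
and NNLS over the full diffusivity grid. The acquisition scheme is the
q-space lattice (q_x² + q_y² + q_z² ≤ r², r = 3, b ∝ |q|², max
b = 1500 s/mm²).

## Worked example

Diagnosis timing on the published 12-patient table
(`python analysis/06_time_to_diagnosis.py`):

```
9 analyzed patients; assisted diagnosis earlier in 6 (66.7%)
overall median gain 7.7 weeks, IQR (0.0, 20.1)
  progression: n=5, median 7.7 weeks, IQR (0.0, 15.0)
```

The hindered-map-assisted read would have delivered the
progression-vs-treatment-effect diagnosis a median 7.7 weeks before
standard of care, and earlier in two thirds of patients.

An end-to-end phantom run (`python analysis/02_fit_phantom.py` then
`python analysis/03_classify_lesions.py --replicates 3`):

```
overall mean absolute error 0.00087 (expected < 0.02)
progression: 3/3 correct (100%), margin -0.231 +- 0.015
treatment_effect: 3/3 correct (100%), margin +0.175 +- 0.117
```

Noise-free voxelwise fraction recovery is essentially exact, and at
SNR 30 the hindered-map contrast between lesion and surrounding
parenchyma calls both lesion archetypes correctly: treatment-effect
lesions are hyperintense (positive margin), tumor cores hypointense
(negative margin).

Synthetic-cohort group comparison (`python analysis/05_cohort_stats.py`):
only the hindered fraction separates the groups (Welch t, p = 0.0043 <
0.05/9 = 0.0056 Bonferroni threshold); the eight other metrics,
generated with no group difference, are not flagged.

## Layout

```
src/dbsi/          library: acquisition, forward, fit, synthetic, roi, stats
analysis/          numbered drivers (simulate, fit, classify, noise floor,
                   cohort stats, timing) writing tables under results/
scripts/acceptance.py   end-to-end run of the main computations
tests/             pytest suite incl. tests/test_acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```

`scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computations from scratch — the timing analysis on the
published table, a noise-free phantom forward–inverse round trip, a
seeded SNR-30 lesion classification, and the synthetic-cohort group
comparison — printing each result; the JSON output lists no external
comparison targets for this artifact.
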