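# Methods

## Signal model

A voxel's normalized signal is a linear combination of discrete
axially symmetric anisotropic tensors and a spectrum of isotropic
tensors (see README for the equation). Units are ms/µm² for b-values
internally (1500 s/mm² = 1.5 ms/µm²) and µm²/ms for diffusivities, so
exponents are dimensionless; I/O accepts s/mm².

The isotropic integral is discretized as a weight-per-gridpoint sum on
a diffusivity grid (default 0 to 3.0 µm²/ms in steps of 0.1, 31
exponentials — spanning free water at body temperature); the grid
weights are the discrete signal fractions, and the continuous form is
recovered only in convergence tests. Band edges are inclusive above:
D = 1.0 µm²/ms counts as restricted, D = 1.5 as hindered; the
"nonrestricted" definition collapses to the single band D > 1.5.

The acquisition scheme enumerates integer q-space lattice points with
|q|² ≤ r² (r = 3 → 123 points including the origin), direction q/|q|
and b = b_max·|q|²/r² (b ∝ |q|², the q-space convention). Antipodal
pairs measure the same attenuation and are collapsed by default (61
directions + 1 b=0); the published protocol quotes 99 directions, and
how the vendor table reduces 123 grid points to 99 is not public — an
explicit user-supplied direction table is accepted for exact protocol
matching.

Measurement noise is Rician: magnitude of the clean signal plus
complex Gaussian noise of per-channel SD 1/SNR (S_0-normalized), the
standard magnitude-MR model; a Gaussian alternative is provided.

## The per-voxel inverse problem

Stage 1 (orientation screening): anisotropic basis signals at a fixed
nominal prior (λ∥, λ⊥) = (1.5, 0.3) µm²/ms on a 60-point deterministic
Fibonacci hemisphere, plus a 7-point coarse isotropic basis, enter one
NNLS solve. Candidates with positive weight are clustered by angular
proximity (default 30°, since crossings below ~40° are unresolvable at
b ≤ 1.5 ms/µm²); a cluster is retained when its summed weight exceeds
5% of the total, up to 3 components. The cluster orientation is the
principal eigenvector of the weight-averaged dyadic, which beats the
tessellation's angular resolution.

Stage 2 (component refinement + spectrum solve): each retained
component's axis and diffusivities are refined against the full
design (that component's column + other components + all 31 isotropic
exponentials):

1. coarse (λ∥, λ⊥) grid over the bound box [0.5, 2.5] × [0, 1.0];
2. two alternating passes of halving searches — axis on the tangent
   plane (0.5° down to ~0.008°) and (λ∥, λ⊥) (0.05 down to ~1e-3);
3. a final joint Nelder–Mead polish of (axis, λ∥, λ⊥).

The polish depth is not cosmetic: the isotropic band split is
extraordinarily sensitive to anisotropic-component mismatch. A 0.3°
axis error — the accuracy of the screening stage — leaves a structured
residual that reshuffles band masses by ~0.08 on mixed voxels, and
fiber-dominated voxels (fiber ≈ 0.9) need ~1e-5-level component
precision before their small isotropic share splits correctly. For a
single detected fiber the axis is initialized from the DTI principal
eigenvector: a single axially symmetric component plus any isotropic
mixture depends on the gradient only through (ĝ·axis)², so the tensor
eigenvector recovers the axis to a fraction of a degree.

A tentative anisotropic component is always carried through refinement
even when screening is below threshold (sub-threshold anisotropy
otherwise corrupts the band split) and dropped when its fitted weight
ends below 0.5%. The final design is solved by NNLS, weights
normalized to sum to one, and binned into the four fractions.

Regularization: a ridge term (relative to the squared largest singular
value of the isotropic design block) is exposed but defaults to **0**.
With this highly collinear exponential basis any appreciable ridge
spreads spectrum mass across band boundaries (a single compartment at
D = 1.2 loses half its hindered mass already at 1e-4 relative weight);
the non-negativity constraint itself provides the regularization that
matters. `FitConfig.refinement` selects the refinement depth: "full"
(default; the three steps above), "coarse" (grid search only — used
for map fitting at clinical noise, where the polish would chase
noise), "none" (nominal prior).

Degenerate inputs: all-zero signals raise; non-positive measured
signals are floored at machine epsilon before logs/division (magnitude
data can underflow after preprocessing); b=0 normalization uses the
mean of all b=0 volumes; fewer measurements than basis functions
triggers an under-determined warning. Exact ties in candidate ranking
break toward the lexicographically smaller vector, so the fit is
deterministic; voxels are independent and `fit_map` results do not
depend on evaluation order.

The DTI comparator is the standard log-linear tensor fit (7 unknowns),
ADC = mean eigenvalue, FA = √(3/2)·‖λ − λ̄‖/‖λ‖, negative eigenvalues
clamped at zero with a warning.

## Synthetic data: the stated world

**Voxels.** Tissue voxels are drawn from four archetypes — white
matter (fiber-dominant 0.5–0.8), tumor core (restricted-dominant
0.45–0.7 with hindered ≤ 0.1: densely cellular tissue has little
extracellular edema), edema/necrosis (hindered-dominant 0.5–0.8),
CSF (free-dominant 0.8–1.0) — plus a perilesional zone (hindered
0.3–0.5 with residual fibers) used as the tissue surrounding lesions.
Compartment diffusivities are drawn within their bands (restricted
0.2–0.6, hindered 1.15–1.35, free 2.0–3.0 µm²/ms; fiber λ∥ 1.2–2.0,
λ⊥ 0.1–0.4), not at band edges: the thresholds were chosen *between*
the characteristic diffusivities of cells, edema and free water, and a
generator placing compartments exactly on a threshold would make the
band assignment undefined rather than difficult. Off-grid diffusivities
are split across neighbouring grid points so the discretized spectrum
carries the same band mass.

**Phantoms.** Rectangular grids with spherical lesions; each region is
homogeneous (one parameter draw) or heterogeneous (independent draws
per voxel — the default for classification phantoms, matching the
regional heterogeneity of real lesions). The classification phantom
nests an enhancing lesion (treatment-effect → edema archetype;
progression → tumor archetype) inside a perilesional collar on a
white-matter background, the textbook post-treatment HGG geometry; the
surrounding-parenchyma reference shell therefore samples mildly
edematous tissue, as it does in patients.

**Cohorts.** Per-patient lesion-ROI metric means are Gaussian draws
per group. Defaults mirror the published group statistics where given
— hindered 0.17 ± 0.02 (treatment effect) vs 0.08 ± 0.03 (progression)
— and overlap (no group difference) for the other eight metrics,
mirroring the published null results. The timing model is a log-normal
surgery-to-assisted-diagnosis delay (median 15 weeks, σ_log 0.35,
matching the observed 11–32-week range) plus a standard-of-care extra
delay that is 0 with probability 1/3 (the observed ties at zero) and
log-normal otherwise (median 15 weeks, σ_log 0.9, spanning the
observed 7.7–52 weeks).

**What a green test does not establish.** The generator emulates
compartmental signal composition and magnitude noise only: no partial
volume between neighbouring voxels, no T2 weighting or multi-TE
effects, no eddy/motion/susceptibility artifacts (the pipeline
consumes preprocessed data by contract), no anatomically realistic
geometry, and single-fiber voxels only (crossings are representable
but not part of the stated world). Green round-trip tests establish
that the solver inverts its own forward model under stated noise — not
that the model captures everything in patient tissue.

## Statistics

Welch's unequal-variances t (two-tailed, Welch–Satterthwaite df;
identical constant groups give p = 1 by convention), Wilcoxon signed
rank for matched samples (zero differences dropped and counted —
Wilcoxon's original rule; exact 2ⁿ enumeration for n ≤ 12, normal
approximation with continuity correction above), Fisher's exact test
(two-sided by the minimum-likelihood rule), Bonferroni threshold α/m.
Significance flags are computed on unrounded p-values; p-values are
reported to 4 decimals.

Quantiles use linear interpolation of order statistics at position
1 + (n−1)p (numpy's default). This convention reproduces both
published interquartile ranges from the patient table — (0, 20.1) for
the 9 analyzed patients and (0, 15.0) for the 5 progression patients —
whereas Tukey hinges do not, which pins the convention. The patient
table's printed difference column is carried verbatim (it derives from
unrounded dates and disagrees with subtracting the rounded times by
0.1 weeks in one row); `time_to_diagnosis` prefers a supplied
difference column for the same reason.

The published headline group comparison (hindered 0.17 ± 0.02 vs
0.08 ± 0.03, p = .0004) derives from unpublished patient MRI and is
not recomputable from the printed summary statistics (a Welch test on
the rounded summaries gives p ≈ 0.001); group comparison is therefore
validated on synthetic cohorts.

## ROI pipeline

Rigid co-registration applies *supplied* world-coordinate transforms
(estimating them is out of scope): reference-grid voxel centers are
mapped through the transform into the moving volume and sampled with
trilinear (intensity) or nearest-neighbour (label) interpolation,
out-of-field voxels zero. New/enlarging enhancement is assessed per
26-connected component of the current lesion: components fully
contained in the prior segmentation contribute nothing; qualifying
components contribute their voxels outside the prior, so the output is
always a subset of the current mask. Slice sampling keeps every third
axial slice starting from the lowest occupied slice. ROI means are
pooled over all sampled voxels per patient. Classification compares
the lesion's mean hindered value with surrounding parenchyma (default
reference: a morphological shell 2–6 voxels outside the lesion,
excluding lesion/prior-lesion voxels and CSF-like voxels with
nonrestricted fraction > 0.8; a user-supplied reference overrides);
hyperintense → treatment effect, hypointense → progression, an exact
tie is surfaced as "indeterminate" rather than silently assigned.

## Known limitations

* **Noise floor of band-resolved fractions.** At SNR 30 with this
  62-measurement, b ≤ 1.5 ms/µm² acquisition, the four-fraction MAE of
  mixed multi-compartment voxels is bounded near 0.10 even when the
  true anisotropic component is supplied to the solver
  (`analysis/04_noise_floor.py`); only voxels with a ≥ 0.9 dominant
  compartment reach 0.03–0.05. Spectrum smoothing lowers the noisy
  floor to ~0.07 but destroys noise-free exactness. Per-voxel band
  fractions at clinical noise should therefore be read as ROI
  statistics, not voxel values — which is how the classification
  pipeline uses them, and why ROI-level contrast remains reliable (the
  end-to-end phantom classification is ≥ 95% accurate at SNR 30).
* The λ∥/λ⊥ refinement is per component, not global; whether the
  original in-house implementation shares diffusivities across
  components is unpublished.
* The exact 99-direction vendor table is not public; the grid scheme
  is reconstructed from its stated rule, with an explicit-table path
  for exact matching.
* Crossing-fiber accuracy is untested beyond representability; the
  clinical target (isotropic-band contrast in lesions) does not
  exercise it.
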