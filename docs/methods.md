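# Methods

## Image model and clustering energy

An axial slice of an unenhanced, non-fat-suppressed T1 breast acquisition is
modelled as

    U(x) = b(x) · J(x) + n(x),

where `J` is an ideal piecewise-constant tissue image taking K class values
`c_1 … c_K` (air, soft tissue(s), fat — fat is brightest in this contrast),
`b` a smooth, strictly positive multiplicative bias field (coil falloff and
B1 inhomogeneity), and `n` zero-mean Gaussian noise. Segmentation, centroids
and bias are estimated jointly by minimizing

    E(φ, c, b) = Σ_k Σ_x |U(x) − b(x) c_k|² m_k(x) + ν·Length(φ=0) + μ·Reg(φ).

One level-set function φ separates a designated bright phase (φ > 0, the fat
class) from the rest; the remaining classes partition the φ ≤ 0 phase by
nearest-centroid assignment on the bias-compensated residual. Memberships
are hard indicators, which makes each block update an exact minimization:

- centroids: `c_k = Σ U·b·m_k / Σ b²·m_k` (weighted least squares); an empty
  class is frozen and flagged rather than updated;
- bias: `b = G·w` in a tensor Legendre basis `G` of maximal degree 4 per
  axis (25 coefficients on a 2D slice); `w` solves the normal equations
  `(Gᵀ diag(c̄₂) G) w = Gᵀ(c̄₁ U)` with `c̄₁ = Σ c_k m_k`, `c̄₂ = Σ c_k² m_k`.
  Smoothness is guaranteed by the basis itself — no smoothing kernel;
- level set: with ν = μ = 0 the pointwise optimal reassignment of the phase
  (the scheme then reduces exactly to Lloyd's k-means with a bias term);
  otherwise a smoothed-Heaviside gradient step with a backtracking line
  search that only accepts energy-decreasing steps.

Each update is non-increasing in E, so the per-sweep energy trace is
monotone by construction — this is asserted in the tests rather than hoped
for. Iteration stops when the relative energy change drops below `1e-4`
(default) or after 200 sweeps. Bias/centroid scale is fixed by reporting `b`
with slice mean 1 and rescaling the centroids accordingly. The bias is
floored at `1e-6` before division; a non-positive reconstructed field raises
a numerical error.

**Sub-class refinement.** Real slices carry more intensity levels than the
K nominal classes (pectoral muscle vs. fibroglandular tissue differ by
~15 % here). After convergence, each non-fat, non-background class is given
two additional candidate centroids at the quartiles of its corrected
intensities — *keeping* the originals, so the pointwise argmin can only
decrease the energy and the trace stays monotone — and sweeping continues.
The darkest (air/background) class is never split: it has no tissue
substructure, and splitting it lets the bias fit noise in air-dominated
slice regions. This refinement removes a systematic distortion of the bias
estimate that is otherwise visible wherever an unmodelled tissue class
covers a large area.

Defaults: K = 3, basis order 4, ν = μ = 0 (the geometric terms are exposed
for noisy data but the clustering data term suffices at the noise levels
modelled here; in-plane holes and islands are handled morphologically
downstream), Otsu initialization of the phase sign, multi-Otsu class means
as initial centroids. Four named parameter profiles (`acr1`…`acr4`) expose a
stable surface for per-density-group tuning; they share defaults until tuned
on clinical material.

## Breast-mask refinement

The raw fat segmentation contains the breasts plus subcutaneous fat along
the body wall and occasional leakage into the pectoral muscle. Refinement
steps, in order, with defaults in `RefinementParams`:

1. **Largest component**: biggest 26-connected 3D component; ties broken by
   label order with a warning.
2. **Reference slice**: scanning triples (i−1, i, i+1) outward from the
   component's centroid slice, the first slice whose slice-difference
   connected components (both signs pooled) are all smaller than
   T = 5 % of its breast area is taken as reference; fallback to the
   centroid slice with a warning.
3. **Boundary propagation**: sweeping from the reference toward both ends,
   each slice is split at narrow necks by a watershed on its inverted
   Euclidean distance transform (markers at h-maxima, h = 1 voxel, to avoid
   over-fragmentation) and only pieces with ≥ 50 % area overlap against the
   already-refined neighbour are kept, plus watershed-ridge voxels between
   two kept pieces. The neighbour is first dilated by the in-plane
   equivalent of one slice step (2 voxels at 2×1×1 mm spacing): with
   anisotropic voxels a tissue boundary legitimately shifts several in-plane
   voxels between slices, and strict voxel overlap under-measures
   through-plane continuity.
4. **Hole filling and lower-part exclusion**: per-slice hole filling, then
   removal of everything posterior to 85 % of the bounding-box depth
   (lung and other irrelevant structures).
5. **Rolling-ball closing** with region-dependent radii: 12 mm in the
   anterior (nipple/areola) quarter of the bounding box, 8 mm for
   foreground in the posterior (pectoral-adjacent) quarter, 3 mm elsewhere
   (sides, skin folds). Implemented with two anisotropically-sampled
   Euclidean distance transforms — equivalent to closing with a true
   Euclidean ball of the given physical radius; a half-voxel radius
   inflation keeps half-space boundaries exactly invariant under distance
   quantization. Radii below one voxel are clamped with a warning.
6. **Sternum cut**: the posterior-most breast voxel within a midline window
   (±15 % of the bounding-box width around the centroid) marks the
   posterior sternum boundary; everything posterior to it is removed.

All fractions and radii are configuration knobs; none is hard-coded.

## Parenchyma and density

Fat-in-breast is `S ∧ B` (segmentation masked by the refined breast);
parenchyma is its exact complement inside the breast, `P = B ∧ ¬(S ∧ B)`.
The two partition `B` — asserted on every pipeline run. BV and PV are
non-zero voxel counts; liters via the voxel volume; percent density
`100·PV/BV`.

## Agreement statistics

With A the automatic and M the reference mask on domain Ω: Dice
`2|A∩M|/(|A|+|M|)`, delineation sensitivity `TPVF = |A∩M|/|M|`, and
specificity `TNVF = 1 − |A\M|/|Ω\M|`. Specificity is reported but flagged
unreliable: whenever the background dwarfs any plausible oversegmentation it
is pinned near 1 regardless of quality.

Bland–Altman analysis uses the difference convention automatic − manual and
the n−1 SD denominator; classic limits are bias ± 1.96 SD. When the bias
varies with the measured magnitude, regression-based limits are provided:
OLS of the differences on the averages gives D̂(a), OLS of the absolute
residuals gives R̂(a), and the limits are D̂(a) ± 1.96·√(π/2)·R̂(a) —
√(π/2) ≈ 1.2533 converts a mean absolute residual to an SD under normality.
The decision whether the slope is significant enough to prefer these over
the classic limits is left to the caller. OLS (p-values, 95 % CIs) comes
from statsmodels; tests cross-check it against a normal-equations oracle.

## The phantom generator

The phantom emulates a prone axial acquisition at 40×128×128 voxels,
2×1×1 mm (a typical dynamic-capable T1 protocol): two pendant
half-ellipsoidal breasts of bright fat (intensity 400) that slightly overlap
at the midline, sparse darker parenchyma (150) as a thresholded smoothed
Gaussian random field (isotropic 4 mm correlation — fibroglandular
structures are continuous across adjacent 2 mm slices) inside an inner
ellipsoid, occupancy tuned by bisection to the target density fraction
(default 20 %, the mid-range of clinical densities); a pectoral/body band
(130) behind the chest wall; air background (20). The multiplicative bias is
a logistic anterior→posterior decay times a cosine left–right modulation,
normalized to mean 1 (defaults 0.8 and 0.1, a moderate-to-strong coil
falloff giving an ~1.8:1 anterior/posterior intensity ratio across the
field of view); additive Gaussian noise defaults to 2 % of the fat
intensity. All randomness flows from one seed.

Clinical fat is not confined to the breasts, and the refinement's
bounding-box fractions (lower-part exclusion, closing bands) presume a fat
component that spans the posterior field of view. The phantom therefore
includes a posterior subcutaneous-fat layer, thin inframammary fat patches
under the breasts, and two single-slice lateral fat bridges tying them
together into one 3D-connected component — kept off most slices so the
pectoral band is never enclosed in-plane. The bridges double as built-in
leakage-like transients. `make_leakage_fixture` additionally injects a
fat-bright lobe (plus a thin neck) into the pectoral region on chosen
slices while leaving the truth masks uncorrupted.

What the phantom does **not** model: partial-volume voxels, k-space/coil
physics, Rician noise statistics, skin, lesions or implants, and anatomical
variability of the chest wall. Passing on phantoms therefore demonstrates
correctness of the algorithms under the stated image model — piecewise
near-constant tissue under smooth multiplicative bias — not clinical-grade
accuracy on patient data, for which per-protocol parameter adaptation is
expected.

## Operating regime and problem sizes

The pipeline mirrors the interactive practice of selecting start/end slices
around the breast: `breast_slice_range` keeps slices whose breast
cross-section is ≥ 5 % of the maximum. Slices outside that regime (near-tip
or breast-free) are dominated by air, where the bias estimate is only weakly
constrained by the data; validation quantities are therefore measured over
the selected range.

Validation problem sizes, chosen to exercise the full 3D pipeline at
realistic resolution: 20 phantoms of 40×128×128 for segmentation recovery,
10 leakage fixtures for repair rates, 2 phantoms (64 slices) for per-slice
bias recovery, 10 slices for energy monotonicity, and two full runs for
bitwise determinism; smaller 24×96×96 phantoms back the end-to-end
reproducibility checks.

## Known limitations

- The propagation sweep is one-directional from the reference slice: a
  structure absent on the reference-side neighbour is discarded at birth
  and cannot reappear. Fat pockets enclosed by parenchyma that nucleate
  mid-stack lose a fraction of a percent of breast fat this way (later
  recovered by hole filling/closing); conversely, leakage present on the
  reference slice itself is never removed — the reference is assumed clean.
- The reference-slice test cannot reject a slice whose leakage lobe is
  smaller than T times the breast area.
- Per-slice (2D) bias estimation does not enforce through-plane smoothness
  of the field; each slice is normalized independently.
- Density is a pure voxel ratio; no partial-volume correction is applied.
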