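# Methods

This note records the models, discretizations and design choices behind
`multitomo`, in the spirit of a statistical-software methods appendix: what
is computed, under which conventions, and what the synthetic studies do and
do not demonstrate.

## Discretization conventions

Arrays are channel-first, then spatial axes slowest-to-fastest
(`(t-or-z,) y, x`). The image is centred at the origin; voxel `(i, j)`
spans the half-open square `[j·h, (j+1)·h) × [i·h, (i+1)·h)` shifted so the
grid midpoint is 0. Angles are accepted in degrees (scanner metadata
convention) and converted to radians once.

All finite differences are forward differences with a Neumann (replicate)
boundary: `(Du)_i = u_{i+1} − u_i`, zero at the last sample. The adjoint is
then exactly the negative backward-difference divergence with zero boundary
flux, and every gradient-type operator (gradient, symmetrized gradient,
channel difference, weighted dTV gradient) is built from this one kernel
pair, so adjointness holds to rounding error by construction. The boundary
condition is a documented assumption: nothing in the problem class forces
replicate boundaries, but one fixed convention shared by the projector,
the gradients and the phantoms is what makes the operator algebra testable
against materialized matrices.

The symmetrized gradient of a 2D vector field `w = (w_y, w_x)` is stored as
three planes `(∂_y w_y, ∂_x w_x, √2·½(∂_x w_y + ∂_y w_x))`: the √2 weight
on the off-diagonal plane makes the plain Euclidean norm of the stored
block equal the full-tensor Frobenius norm (the off-diagonal entry occurs
twice in the tensor), preserving the isotropy of the TGV penalty with
minimal storage.

## Projector

The projector is ray-driven: one ray per (angle, detector-bin centre),
with exact ray–pixel intersection lengths from a vectorized Siddon-style
plane-crossing traversal. Fan-beam rays emanate from a source rotating at
radius `source_to_origin`; parallel rays are perpendicular to the detector.
The traversal is materialized once per geometry as a `scipy.sparse` CSR
matrix (cached), so the back-projection is the exact transpose — the
projector pair passes randomized adjoint tests at 1e-6 relative tolerance,
limited only by accumulation order. Channels share the matrix and never
mix. This model is exact for line integrals but, with one ray per bin, is
not an area-weighted (distance-driven) model: view sums track the image
mass to a few percent at oblique angles rather than exactly. At the 64×64
scales used here that mismatch is far below the regularization scale.

FBP supports parallel beam only (the dynamic study simulates parallel
geometry; fan data can be reconstructed iteratively). Projections are
filtered with the frequency response of the *discrete* band-limited ramp
kernel (`1/(4h²)` at lag 0, `−1/(πnh)²` at odd lags), zero-padded to the
next power of two — the naive `|ω|` sampling has a DC bias that visibly
depresses flat regions — then back-projected with linear interpolation and
scaled by `π/N_angles`, which is correct for equispaced angles covering
either 180° or 360°.

## Proximal maps and FGP

`prox_{τf}` is closed-form wherever possible (soft thresholding, group
soft thresholding across block components, `(x+τb)/(1+τ)`, clipping, the
positive root of the Kullback–Leibler quadratic). The KL fidelity carries
the additive constant that makes `f(b) = 0`; indicator violations return
`+inf` rather than raising, so objective traces stay computable.
`prox_{τf*}` always comes from the Moreau decomposition
`prox_{τf*}(x) = x − τ·prox_{f/τ}(x/τ)`; the identity is tested to 1e-8.

The TV and dTV proxes use the fast gradient projection (FGP) iteration on
the dual: alternate `v = clip(x − w·DᵀP)` and a projected gradient ascent
step on the dual variable with step `1/(w·L)`, `L = 4·(number of penalized
axes)` (the classical upper bound on `‖D‖²`), with Nesterov momentum.
Defaults: 100 inner iterations; the dual variable is warm-started across
repeated prox calls within one outer algorithm, which is what makes the
implicit-PDHG dTV reconstruction converge with 40 inner iterations per
outer step. An optional objective-change tolerance (checked every 10
iterations) can stop early; by default the iteration count is fixed, which
keeps runs bit-reproducible. The iteration count is our choice, not
prescribed by the problem: 100 iterations leave the two-point closed-form
prox exact to 1e-6 and the 16×16 ROF objective within 1e-4 of a 3000-
iteration PDHG solve.

Non-negativity inside the TV/dTV prox is imposed by projecting the primal
update; strictly this solves the constrained ROF problem approximately
(the dual bound is unchanged since projection is non-expansive), which is
the standard FGP treatment.

## Directional TV

The weight field is `ξ_v = ∇v / √(η² + |∇v|²)` with `η > 0`, computed with
the same forward-difference gradient as everywhere else and no
pre-smoothing of the reference; `|ξ_v| < 1` strictly, → 0 on flat regions.
The weighted operator is the composition (sitewise matrix `I − ξξᵀ`) ∘
gradient; the sitewise matrix is self-adjoint with eigenvalues in (0, 1],
so `‖D_v∇‖ ≤ ‖∇‖` and the plain gradient Lipschitz bound is reused for
step sizes. `η` has intensity units (it competes with `|∇v|`): the
dynamic study uses η = 0.3 for references whose edge gradients are ≈ 0.5
per pixel, i.e. edges well above η are kept, FBP streak noise below η is
suppressed. In the large-η limit `D_v → I` and the dTV prox coincides with
the TV prox (verified to 1e-4 relative objective).

## Solvers

* **PDHG** with steps `σ = 1`, `τ = 1/(σ‖K‖²)`; the power-method norm is
  inflated by `1 + 1e-3` so the strict inequality `στ‖K‖² < 1` holds even
  when the estimate slightly undershoots (the unmodified default would sit
  exactly on the boundary). Extrapolation `θ = 1` on the primal by
  default; a dual-extrapolated variant is available because it is the form
  whose trajectory SPDHG reproduces exactly at a single subset. User-
  supplied steps violating the bound warn rather than raise.
* **SPDHG** draws term `i` with probability `p_i`, updates only dual block
  `i`, and extrapolates the running back-projected dual sum with weight
  `1/p_i`. Steps follow the published safe rule `σ_i = γρ/‖A_i‖`,
  `τ = (ρ/γ)·min_i p_i/‖A_i‖`, `γ = 1`, `ρ = 0.99`. Balanced sampling:
  regularizer 0.5, each of S data subsets 0.5/S; an epoch (expected
  iterations to touch all data once) is 2S.
* **FISTA** with step `1/L`; **CGLS** stopping on the normal-equation
  residual; **SIRT** `x ← clip(x + C Aᵀ R (b − Ax))` with inverse row/
  column-sum weights, zero sums giving zero weight (rays and voxels the
  operator never touches are skipped). All solvers run a fixed iteration
  budget, log objectives at a configurable interval, and are deterministic
  given their seed.

## Synthetic phantoms — what they emulate and what they do not

The generators define the study conditions; ground truth is always
returned alongside corrupted data, and everything is reproducible from
(parameters, seed).

* **Colour**: smooth ramps (where TV staircases and TGV should not) plus
  sharp-edged shapes; Gaussian or salt-and-pepper corruption; a text-like
  missing-pixel mask confined to evenly spaced "text rows", i.i.d. within
  them so the missing fraction concentrates binomially at the requested
  density.
* **Dynamic gel** (default 64×64, 17 frames, 5 cavities): a static disc
  with circular cavities whose intensity rises as `1 − exp(−rate·t)`
  toward an asymptote — an osmosis-like uptake ramp, monotone per cavity.
  Acquisition: 360 parallel-beam angles over 360°, Gaussian sinogram noise
  with σ = 1% of the peak line integral, equi-angular undersampling by
  steps {5, 10, 20} → {72, 36, 18} views.
* **Hyperspectral** (default 64×64, 80 channels over [75.15, 93.37] keV):
  a rock disc with smoothly decaying spectra (~30% over the axis; the
  per-channel decrement is far below any jump) and two inclusions with
  flat spectra plus exact upward steps at the channels containing the Au
  (80.725 keV) and Pb (88.005 keV) K-edges — channels 24 and 56 of 80.
  Acquisition: 120 angles, 10 subsets of 12, Gaussian noise at 1% of peak.

What passing these studies shows: the solvers reach the minimizers they
should, the priors rank as theory predicts under heavy undersampling, and
K-edge localization survives realistic noise. What they do not show:
performance on real scanner data — no beam hardening, ring artifacts,
detector cross-talk, scatter, motion between frames, or Poisson counting
statistics in the dynamic/spectral studies (a Poisson transmission
simulator is provided but the headline studies use Gaussian sinogram noise,
which at 1% is the more conservative choice for comparing priors), and the
real datasets' fan/cone geometry is replaced by parallel beam, which FBP
and all variational methods traverse through the same projector interface.

## Regularization parameters

The dynamic-study defaults were chosen by grid search maximizing mean PSNR
against the ground-truth phantom at 18/360 angles — the same selection
rule the comparison itself reports — and then frozen: Tikhonov α = 1.0,
TV α = 1.6, dTV α = 5.0 with η = 0.3. All optima are interior points of
the searched grids. The hyperspectral defaults (α = β = 0.05) were chosen
once as the smallest values that visibly suppress spectral noise without
flattening the jumps; K-edge recovery is insensitive to a factor of a few
in either direction. These numbers are specific to the phantoms' intensity
scale; on data with different units the search should be re-run (the
`grid_search_regularization` helper automates it, including the β/α-ratio
search for TGV).

## Numerical details and edge cases

* Containers validate shape and finiteness at construction from user data;
  internal arithmetic skips the finiteness check for speed.
* `allocate` rejects non-finite fill values; `negative_log` names the
  first non-positive index; `slice_angles` requires `0 ≤ offset < step`.
* Power method: 100 iterations, tolerance 1e-5, fixed seed 42 by default,
  result cached on the operator; the zero operator returns 0 without
  error. Norm caches propagate through scaling and channelwise lifting.
* Group soft thresholding maps zero-magnitude sites to zero (the unique
  minimizer); KL's `0·log 0` is treated as 0; Poisson simulation floors
  transmission counts at one count so the log stays finite (a bias of
  order `e^{−I0·T}`, negligible at the default intensities).
* SSIM uses the standard Gaussian-window form (σ = 1.5); on images
  smaller than the 11-pixel window the window shrinks to the largest odd
  size that fits.

## Known limitations

2D geometries only (three spatial axes are accepted by the containers and
gradients, but the projector is 2D; the spectral study is therefore
2D+energy rather than the full 3D+energy problem, i.e. a scaled-down
instance of the same optimization structure). No detector offsets or
tilts, no helical trajectories, no vendor file formats. FBP refuses fan
data rather than rebinning. TGV inpainting uses the L1 fidelity suited to
impulsive noise; for Gaussian noise assemble the analogous triplet with a
squared-error term (as one of the tests does).
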