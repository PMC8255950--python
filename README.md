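# multitomo

Multichannel variational tomographic reconstruction in Python: a modular
optimization framework for imaging problems whose data carry a non-spatial
axis — colour planes, time frames in dynamic CT, or energy bins in
spectral (photon-counting) CT — where reconstructing each channel
independently wastes the strong correlation between channels.

The package is aimed at imaging scientists who want to assemble bespoke
regularized reconstructions from reusable parts rather than call a fixed
black-box: geometries and data containers, linear operators with verified
adjoints, a catalogue of proximal functions, first-order and algebraic
solvers, and three end-to-end case-study pipelines run on synthetic
phantoms that the package generates itself.

## The optimization framework

Every reconstruction is an instance of

```
min_u  f(K u) + g(u)
```

where `u` is a multichannel image, `K` a (block) linear operator, `f` a
(separable block) convex function holding the data fidelity and
regularizers, and `g` a simple term such as a non-negativity constraint.
Algorithms touch the problem only through three primitives:

* `K.direct / K.adjoint` — linear operators: the ray-driven projector `A`
  (parallel- and fan-beam, exact Siddon intersection lengths, adjoint pair
  verified to 1e-8/1e-6), finite-difference gradient `D` with
  space-only or space+channel coupling, symmetrized gradient `E`,
  masking `M`, channelwise lifting, and row-filled block composition;
* `prox_{τf}(x) = argmin_v ½‖v−x‖² + τ f(v)` — proximal maps: soft and
  group-soft thresholding (`‖·‖₁`, `‖·‖_{2,1}`), squared-error and
  Kullback–Leibler fidelities, box indicators, and total variation solved
  by the fast gradient projection (FGP) dual iteration;
* `prox_{τf*}` — the conjugate prox, always obtained from the Moreau
  decomposition.

On top sit the solvers: **PDHG** (explicit, or implicit with an inner FGP
solve in the prox), **SPDHG** with subset sampling (balanced sampling gives
the regularizer probability 0.5; an epoch is 2S iterations for S data
subsets), **FISTA**, **SIRT** (plain and warm-started channelwise),
**CGLS**, and **FBP** with a Ram–Lak filter.

Regularizers beyond TV:

* **TGV** `min_w α‖Du − w‖_{2,1} + β‖Ew‖_{2,1}` assembled as a 3×2 block
  saddle-point problem (no staircasing on smooth gradients);
* **directional TV** `dTV(u, v) = ‖D_v ∇u‖_{2,1}` with
  `D_v = I − ξ_v ξ_vᵀ`, `ξ_v = ∇v / √(η² + |∇v|²)` built from a reference
  image `v`, which makes edges parallel to the reference's cheap;
* **spatio-spectral TV** `α‖(D_e, D_y, D_x)u‖_{2,1}` and the **split**
  form `β‖D_e u‖₁ + α‖(D_y, D_x)u‖_{2,1}` for energy-resolved data.

## Worked example

`examples/dynamic_sparse_ct.py` builds a 64×64, 17-frame gel phantom with
contrast diffusing into five cavities, simulates a 360-angle parallel-beam
scan with Gaussian noise at 1% of the peak line integral, keeps only every
20th projection (18 views — a 20× reduction in dose or scan time), and
reconstructs four ways:

```
  method     mean PSNR   mean SSIM
  fbp          15.65 dB      0.397
  tikhonov     21.66 dB      0.604
  tv           30.33 dB      0.950
  dtv          35.74 dB      0.987

  centre-of-cavity time-activity curve (frames 0, 8, 16):
  truth: 0.400  0.880  0.976
  fbp   0.369  0.691  0.700   (excess oscillation 0.459)
  tv    0.410  0.896  0.973   (excess oscillation 0.000)
  dtv   0.400  0.874  0.974   (excess oscillation 0.000)
```

Channelwise FBP streaks badly at 18 views; Tikhonov (CGLS on the stacked
least-squares form with a space+time gradient) suppresses streaks but
oversmooths; spatio-temporal TV (explicit PDHG with non-negativity)
removes the noise at some cost in contrast; directional TV — solved
per-frame by implicit PDHG with an FGP inner solver, guided by dense-angle
FBP reconstructions of the first and last frames — recovers both the edges
and the monotone contrast-uptake curve almost exactly. The other examples
cover colour denoising/inpainting (`colour_denoise_inpaint.py`),
K-edge recovery in 80-channel spectral CT by SPDHG
(`hyperspectral_kedge.py`), and the raw building blocks with a three-solver
consistency check (`building_blocks.py`).

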