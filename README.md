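# vsmc3d

3D reconstruction and morphometry of vascular smooth muscle cells
(VSMCs) from two-channel confocal z-stacks.

VSMCs are slender, spindle-shaped cells wrapped around the artery wall;
their 3D size and orientation set the wall's mechanical response, but in
confocal stacks they grow in dense clumps where neighboring cells touch,
overlap and occlude one another.  `vsmc3d` implements a nucleus-seeded,
semi-automatic segmentation of such clumps and measures each cell's
length *L*, width *W*, thickness *T*, slenderness *L/W*, in-plane angle
β (against the circumferential direction, in [−90°, 90°)) and
out-of-plane tilt α (elevation from the imaging plane, in [0°, 90°]).

The core is an **edge blocking** model: rays are emitted from the
nucleus centroid *c₀* at scattering angles θ measured from the cell's
orientation vector, with an anisotropic emitting-length bound

    l(θ) = lc0 · (1 + lc1 · cos θ),      lc0 = 30 px, lc1 = 5 px

(clamped to its stated minimum/maximum; a |cos θ| variant keeps both
tails reachable).  Per ray only the first edge intersection is kept —
farther edges are "blocked" and attributed to other cells or noise.
Angular runs of hitless rays are boundary gaps: Type I (broken edge of
the same cell) is filled by *bilateral spline interpolation* — a
zero-tension spline swept over every admissible junction point in both
directions, the junction chosen by minimum accumulated or average
curvature and the final variant by the smallest SD of intersection-point
lengths; Type II (occlusion by a neighbor) falls back to *Laplace
verification PCA*, which finds the missed edge from the one-signed
second derivative of intensity along ray groups and grows it with a
sliding-window principal-component walk.  Boundaries propagate through
the stack via the stable-edge score

    O(eᵢ, e₀) = 1 − min d(eᵢ, e₀) / w,      S = (1/M) Σⱼ O

(window *w* = 5 px, *M* = 3 neighboring slices, 30 % stable-point
ratio), are stacked into a 3D volume, surfaced by marching cubes,
Laplacian-smoothed, and measured.  The tilt estimator — the first
eigenvector of the 3×3 covariance of surface coordinates — is validated
against a virtual ellipsoid phantom voxelized at predefined tilts.

There is no public VSMC stack to ship, so the package generates its own
ground-truth data: ellipsoid phantoms and synthetic two-channel stacks
of fusiform cells with the published population geometry (L 62.9±14.9,
W 4.6±0.6, T 6.2±1.8 µm; β a two-mode mixture at −19.4±9.3° and
10.9±4.7°; α half-normal with SD 7.6°).

## Worked example

```python
from vsmc3d import make_cell_stack, segment_stack, ImageStack

stack = make_cell_stack(n_cells=1, noise_sd=0.02, overlap_fraction=0.0,
                        seed=3, shape=(96, 384, 384))
truth = stack.truth[0]
records = segment_stack(ImageStack.from_synthetic(stack))
m = records[0].morphometry
print(f"measured: L={m.length:.1f} um  W={m.width:.2f} um  "
      f"T={m.thickness:.2f} um  slenderness={m.slenderness:.1f}  "
      f"beta={m.beta:.1f} deg  alpha={m.alpha:.1f} deg")
print(f"truth:    L={truth.length:.1f} um  W={truth.width:.2f} um  "
      f"T={truth.thickness:.2f} um  "
      f"beta={truth.beta_deg:.1f} deg  alpha={truth.alpha_deg:.1f} deg")
```

prints

```
measured: L=92.6 um  W=3.05 um  T=7.25 um  slenderness=30.4  beta=8.8 deg  alpha=1.6 deg
truth:    L=93.3 um  W=2.93 um  T=6.96 um  beta=8.8 deg  alpha=1.6 deg
```

i.e. the full pipeline — nucleus seeding, per-slice ray-fan blocking,
gap growing, stable-edge propagation, 3D stacking and morphometry —
recovers this cell's length within 1 %, width and thickness within a
few percent, and both orientation angles within a tenth of a degree.

A command-line interface mirrors the stages:

```bash
vsmc3d simulate --n-cells 8 --seed 42 --out sim/        # synthetic stack
vsmc3d segment --cell sim/cell.tif --nucleus sim/nucleus.tif --out out/
vsmc3d phantom --long-axis 70 --tilt 30 --out phantom.tif
vsmc3d validate-tilt                                    # phantom sweep
vsmc3d morphometry --volume out/cell_001.tif
```

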