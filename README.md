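# microves

Quantitative 3D analysis of perfused microvascular networks on a chip.

Self-assembled microvascular networks grown in microfluidic gel channels are
usually imaged by confocal microscopy after perfusing a fluorescent probe:
the bright signal is the vessel lumen itself. Most analysis tools reduce
those z-stacks to a 2D projection and lose exactly the information that
makes the model three-dimensional — vertical undulation of vessels and the
flattened, elliptical cross-sections typical of gel-embedded networks.
`microves` analyses the full volume. It is aimed at groups running
vasculature-on-a-chip experiments who want morphology *and* perfusion
metrics from the same stack.

## What it computes

From a multipage grayscale TIFF z-stack (anisotropic voxels are fine) the
pipeline produces, per vessel branch *i* and for the whole network:

* **geometry** — centerline graph (junctions, endpoints, branches) from
  topology-preserving 3D thinning, spline-smoothed;
* **length** L_i and **tortuosity** T_i = L_i / chord (1 = perfectly straight);
* **radius** r_i — at n_r stations the lumen mask is sliced perpendicular to
  the local tangent and r = half the equivalent diameter 2·√(A/π);
* **eccentricity** e_i — minor/major axis ratio b/a of least-squares ellipses
  fitted to the cross-section boundary (1 = circular; the classical
  convention √(1−(b/a)²) is available);
* **lateral area** A_i (frustum sum over the radius stations) and the network
  **S/V** = Σ A_i / extravascular volume in mm²/mm³;
* **hemodynamics** — with each branch a Poiseuille resistor
  R_i = 128 μ L_i /(π D_i⁴), imposing side pressures and mass conservation
  Σ Q = 0 at interior nodes yields branch flow rates Q_i, mean velocities
  v_i = Q_i/(π r_i²) and wall shear stress τ_i = 4 μ v_i / r_i;
* **uncertainty** — the radius uncertainty dr propagates as
  dv = (Δp/(8μl))·2r·dr and dτ = (Δp/(2l))·dr analytically, or by
  Monte-Carlo resampling of radii through the network solver;
* a plain-text node/segment export for external coupled 3D–1D flow solvers.

A phantom module generates ground-truthed synthetic volumes (tubes with
known centerlines, elliptical sections, junctions, noise), which is how the
whole pipeline is validated — no microscopy download required.

## Worked example

Analyse a synthetic vasculogenic-style network calibrated to an S/V of
4.5 mm²/mm³ (the density regime typical of these cultures):

```bash
microves run --outdir demo_run --config demo.yaml
```

with `demo.yaml`:

```yaml
phantom: {style: random-vasculogenic, target_sv: 4.5, n: 3, seed: 7, spacing: 2.5}
iterations: 40
seed: 7
```

prints the network summary (also written to `demo_run/summary.json`):

```json
{
 "n_branches": 8,
 "total_length_mm": 1.193,
 "mean_length_um": 149.1,
 "mean_radius_um": 9.7,
 "mean_tortuosity": 1.233,
 "mean_eccentricity": 0.874,
 "surface_over_volume_mm2_mm3": 4.85
}
```

The recovered S/V (4.85) sits within 10% of the generator's 4.5 target; the
12 generated ~100 μm tubes appear as 8 measured branches because straight
corner pairs merge into single curved branches, which is also why the mean
tortuosity exceeds 1. `demo_run/` additionally contains the mask, skeleton,
per-branch morphometry CSV, the flow solution under the default 100 Pa side
pressure drop (per-branch Q, v, τ and nodal pressures), the 1D-solver
export, and a provenance log of every effective parameter. On this
320-μm-wide phantom the median branch velocity is ~3.2 mm/s — far higher
than on a millimetre-scale chip at the same 100 Pa, as expected for a path
an order of magnitude shorter.

Library use mirrors the CLI:

```python
import microves as mv
img  = mv.read_stack("stack.tif", spacing=(0.98, 0.98, 5.0))
mask = mv.segment_active_contour(mv.isotropize(img))
graph = mv.build_graph(mv.skeletonize(mask))
table = mv.compute_morphometry(graph, mask)
```

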