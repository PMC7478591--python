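# vasrem

A two-phase self-propelled-particle (SPP) model of flow-driven vascular
remodelling, with synthetic vessel geometries, analytic flow/shear
fields, an image-based evaluation pipeline and grid-search calibration.

## The problem

During early development a uniform capillary plexus reorganises into a
hierarchy of enlarging and regressing vessels. The dominant driver is
wall shear stress: endothelial cells (ECs) migrate collectively
*against* the direction of flow, at speeds that depend on the local
shear, while they elongate along the flow axis and the avascular tissue
between vessels grows and pushes back. `vasrem` is for modellers and
quantitative biologists who want to simulate this process on a planar
vessel network and score predicted vessel shapes against observed binary
masks.

## The model

Vascular and avascular tissue are discretized into agents of diameter
r_e = 7 um. Each 5-minute step, agent i's heading is

    theta_i(t+1) = arg[ alpha * sum_j v_j  +  beta * sum_j f_ij
                        + kappa * sum_k f'_ik + zeta * sum_j (tau_j - tau_i) e_ij
                        + omega * sum_j f''_ij ]  +  nu * xi_i

where v_j are the neighbours' anti-flow preferred directions, f_ij is a
Lennard-Jones-type attraction/repulsion body force (repulsion below
r_c = 5 um, equilibrium at r_e = 7 um, attraction out to r_o = 11 um;
evaluated from the centre *and both foci* once agents elongate into
ellipses), f'_ik is the same force from avascular neighbours, the zeta
term follows the shear gradient, f''_ij is a remodelling force that
pushes crowded agents toward the vessel wall and sparse agents toward
the centreline, and xi_i ~ U[-pi, pi] is white noise. Positions advance
by X_i <- X_i + V_i dt (cos theta_i, sin theta_i), with the vascular
speed following a bell-shaped shear response
V(tau) = V_max (tau/tau_max) e^{1 - tau/tau_max} (defaults 12 um/h at
0.033 Pa). Vascular agents elongate additively (+30% length over 8 h)
along the flow; avascular clusters expand about their centroids
(+78.5% area over 8 h). See `docs/methods.md` for the full account.

Predictions are scored exactly as a time-lapse comparison would be:
rasterize agents, close small holes (25% "flexibility" disk), scale,
rigid-register (rotation + translation, Dice-maximizing), then report
the boundary Hausdorff distance d_H and Dice coefficient DSC.

## Worked example

```python
import numpy as np
import vasrem as vr

spec = vr.GeometrySpec(template="honeycomb", width=25, length=300, height=260,
                       pitch=100, inlet_speed=500)
mask = vr.make_vessel_mask(spec, pixel_size=1.0)
fields = vr.analytic_flow(mask, spec)          # Poiseuille + network solve
print(f"lumen fraction: {mask.grid.mean():.3f}")
print(f"wall shear range: {np.nanmin(fields.wall_shear):.3f}-"
      f"{np.nanmax(fields.wall_shear):.3f} Pa")

params = vr.ModelParams()                       # alpha=100, beta=40, ...
truth = vr.make_synthetic_timelapse(mask, fields, params, duration=4.0, seed=1000)

res = vr.simulate(mask, fields, params, duration=4.0, mode="full", seed=0)
rep = vr.evaluate_prediction(res.final, truth.final_mask, scale_factor=1.0)
print(f"full model:   d_H = {rep.hausdorff_um:.1f} um, DSC = {rep.dice:.3f}")

res_r = vr.simulate(mask, fields, params, duration=4.0, mode="random", seed=0)
rep_r = vr.evaluate_prediction(res_r.final, truth.final_mask, scale_factor=1.0)
print(f"random mode:  d_H = {rep_r.hausdorff_um:.1f} um, DSC = {rep_r.dice:.3f}")
```

prints

```
lumen fraction: 0.432
wall shear range: 0.000-1.020 Pa
full model:   d_H = 7.2 um, DSC = 0.986
random mode:  d_H = 16.8 um, DSC = 0.944
```

The honeycomb plexus carries shear between 0 (stagnant side channels)
and ~1 Pa (the direct inlet-outlet path). Re-simulating the 4-hour
ground truth with a different noise seed lands within 7 um (Hausdorff)
of the observed final mask, while the random-direction baseline — same
shear-dependent speeds, no directed migration — is more than twice as
far off. A command-line interface wraps the same steps
(`vasrem synth / simulate / evaluate / gridsearch / sensitivity`).

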