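# muellermc

Polarized Monte Carlo simulation of backscattering Mueller-matrix imaging
for brain-tissue-like optical phantoms.

Wide-field imaging Mueller polarimetry is being developed as an
intraoperative tool for delineating brain tumors: healthy white matter is
scattering *and* uniaxially birefringent (form birefringence of packed
myelinated fibers), while tumor tissue is optically isotropic and usually
less scattering.  Whether a subsurface anomaly is a tumor or merely a
crossing of fiber bundles is exactly the question maps of depolarization,
linear retardance and optic-axis azimuth are supposed to answer.
`muellermc` provides the numerical side of that program: a vector
radiative-transfer (VRTE) Monte Carlo solver for slab phantoms with box
inclusions, and the polarimetric post-processing that turns simulated
Mueller images into those three maps.

## What it computes

Photon packets with pure polarization states drawn uniformly from the
Poincaré sphere random-walk through a slab of Mie scatterers
(five-group polydisperse 50 nm spheres, n_p = 1.59, μ_s = 400 cm⁻¹,
λ = 633 nm) embedded in a negative uniaxial host
(Δn = n_e − n_o = −10⁻⁴, optic axis in-plane).  Per flight segment the
Stokes vector S picks up the uniaxial retardation
δ = 2πd(n(α) − n_o)/λ applied as a rotated linear retarder
R(−β)·M_R(δ)·R(β) in the photon's transverse frame.  A distant circular
detector registers near-vertically backscattered light; the per-pixel
Mueller matrix is the correlation estimator

    M = G · D⁻¹,  G = Σ S_out S_inᵀ,  D = Σ S_in S_inᵀ,

normalized by m₀₀, screened by the Cloude coherency-eigenvalue test and
factorized pixel-wise by the Lu–Chipman polar decomposition
M = M_Δ·M_R·M_D into

* total depolarization Δ = 1 − (|a|+|b|+|c|)/3,
* scalar linear retardance R = arccos(r − 1),
* optic-axis azimuth θ = ½·atan2 of the retarder's defining elements.

Two phantom families cover the study designs: a *crossing-fiber*
inclusion (same optics, orthogonal optic axis) and a *tumor* inclusion
(birefringence removed, optionally lower μ_s), each a box at a
configurable depth below the illuminated surface.

## Worked example

```python
from muellermc import ExperimentConfig, build_tumor_phantom, simulate_condition

phantom = build_tumor_phantom(depth_ls=1.0, host={"delta_n": -1e-3})
config = ExperimentConfig(photons=300_000, batches=6, seed=5)
cond = simulate_condition(phantom, config)

print(f"inclusion ROI: depol {cond.inclusion_stats['depolarization']:.3f}, "
      f"retardance {cond.inclusion_stats['retardance_avg']:.1f} deg, "
      f"azimuth {cond.inclusion_stats['azimuth_avg']:.0f} deg")
print(f"host ROI:      depol {cond.host_stats['depolarization']:.3f}, "
      f"retardance {cond.host_stats['retardance_avg']:.1f} deg, "
      f"azimuth {cond.host_stats['azimuth_avg']:.0f} deg")
c = cond.contrast
print(f"depolarization contrast: {c['contrast_pp']:.2f} +- {c['contrast_pp_se']:.2f} pp")
```

prints

```
inclusion ROI: depol 0.810, retardance 15.5 deg, azimuth 91 deg
host ROI:      depol 0.808, retardance 20.3 deg, azimuth 90 deg
depolarization contrast: -0.17 +- 0.16 pp
```

The isotropic tumor sits one scattering mean free path (25 µm) below the
surface.  Its zone loses the retardance the birefringent host accumulates
(15.5° vs 20.3°; only the thin host cap above the box retards), the
azimuth reads the host optic axis (90°), and the depolarization contrast
between host and tumor zones is the headline tumor-detection observable,
reported with its batch-based Monte Carlo standard error.

The same machinery is scriptable from the shell:

```
muellermc simulate --config examples/tumor_phantom.yaml --outdir results/
muellermc depth-sweep --photons 500000 --depths 1,4,6,8,16,32 --outdir results/
muellermc dn-sweep --outdir results/
```

writing float32 TIFF maps, CSV trend tables and JSON run manifests.

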