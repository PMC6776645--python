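# cubofuse

Single-particle TIRF analysis of lipid-nanoparticle (cubosome) fusion into
supported lipid bilayers (SLBs).

Cubosomes — nanoparticles of a bicontinuous cubic lipid phase — are
promising drug nanocarriers, and a central open question is whether they
dock onto a target membrane and act as a slow point source of cargo, or
fuse with it wholesale. The two scenarios leave different fingerprints in
total internal reflection fluorescence (TIRF) movies of dye-loaded
particles landing on an SLB: the peak fluorescence of a docked particle
decays as a power law *I* = *a·t*⁻ⁿ, and the exponent *n* discriminates
the mechanisms.

## The model

For a cubosome of side length *R* fusing into a bilayer of height *h*,
lipid/dye mass conservation under diffusion-dominated transport reads

    ρ R² (dR/dt) = −D h δc(t)

with ρ the particle density and *D* the lipid diffusion coefficient in the
bilayer. The fluorescent footprint left on the membrane spreads
diffusively, so its peak concentration decays as *c*max ∼ 1/*t* and its
lateral diameter grows as *L* ∼ √*t*; with zero concentration outside the
footprint, Fick's law gives the gradient

    δc = (c_max − c_{L/2}) / (L/2)  ∼  t^(−3/2).

Integrating the mass balance on the self-similar branch yields
*R*(t) ∼ (*Dh*/ρ)^(1/3) *t*^(−1/6), and since the observed peak intensity
is proportional to *R*,

    I_max ∼ t^(−1/6)        (whole-particle fusion, n = 1/6)
    I_max ∼ t^(−1)          (2-D point-source release, n = 1)

so a fitted exponent near 1/6 is the signature of complete fusion.

## What the package does

| module | role |
| --- | --- |
| `cubofuse.fusion_model` | the scaling model: closed-form branch, shrinkage ODE integrator, finite-difference 2-D diffusion oracle, footprint sizing |
| `cubofuse.synthetic_tirf` | seeded synthetic TIRF movies: bilayer background with domains/double layers, Brownian particles, power-law fusion events, EMCCD noise |
| `cubofuse.particle_tracking` | Crocker–Grier-style spot detection, Hungarian trajectory linking, MSD fitting, Stokes–Einstein sizing |
| `cubofuse.fusion_kinetics` | event segmentation, intensity-trace extraction, log–log power-law fits, fusion times, per-condition distributions |
| `cubofuse.bilayer_kinetics` | SLB formation: coverage sigmoid + error-function fit, domain counting, nucleation-growth simulator |
| `cubofuse.cli_io` / `cubofuse.cli` | TIFF (ImageJ dialect) I/O, YAML run configs, the `cubofuse` command line |

## Worked example

Render a movie of fusion events decaying with the finite-source law, then
recover the exponent with the full tracking pipeline:

```python
import numpy as np
from cubofuse import synthetic_tirf as st, fusion_kinetics as fk

batches = st.fusion_event_ensemble(n_events=40, seed=1)
exponents = []
for scene, events, movie, ground_truth in batches:
    found = fk.analyze_movie(movie, scene.pixel_size, scene.frame_interval)
    exponents.extend(ev.fit.n for ev in found if ev.fit is not None)

print(f"{len(exponents)} events, mean fitted n = {np.mean(exponents):.3f}")
```

```
40 events, mean fitted n = 0.170
```

Forty particles with lognormal sizes (mean 200 nm) landed, dwelt, and
decayed with the model's *t*^(−1/6) law under realistic camera noise; the
pipeline re-detected them and the mean fitted exponent lands on the
finite-source value (1/6 ≈ 0.167) rather than the point-source value 1 —
the whole-particle-fusion signature.

The same pipeline runs from the shell on any calibrated TIFF stack:

```sh
cubofuse all --seed 1 --out demo_run           # simulate + track + fuse
cubofuse fuse --input movie.tif --config run.yaml
cubofuse model-check --out checks              # analytic scaling oracles
```

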