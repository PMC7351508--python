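# shapereg

Groupwise point-set registration and statistical shape modelling for
bone-like surfaces.

Surgical planning and implant design need a notion of the *average*
bone and of how real bones vary around it. Given one reference surface
and a population of target surfaces (STL meshes, e.g. segmented from
CT), `shapereg` establishes dense point correspondence across the whole
population by non-rigidly deforming the reference onto every target,
then builds a point-distribution shape model: the mean shape plus
orthogonal modes of variation with their variance fractions. Deviation
maps and cross-section circumferences quantify how far any two shapes
— e.g. a +3σ mode shape and the mean — differ, in millimetres.

## Method

Point clouds subsampled from the meshes are modelled as Gaussian
mixtures D_i(x) = (1/n_i) Σ_j G(x | p_ij, σ). The reference cloud T_i
is deformed by a thin-plate spline, T_j ≈ T_i + φθ_j, with
φ(m,n) = ‖T_m − c_n‖ over control points c. Each subject's coefficients
minimize

    F(θ) = ∫ (D_ref∘θ − D_target)² dx  +  λ · tr(θᵀφᵀφθ)

by L-BFGS with analytic gradients; the L2 term is closed-form for
Gaussian mixtures and truncated to 6 nearest neighbours for speed.
Points deviating beyond a tolerance (0.4 mm by default) are re-minimized
separately until the mean closest-point error meets the tolerance. The
deformed reference clouds share the reference point ordering — a dense
correspondence — so PCA of their coordinates yields the mean shape,
eigenmodes and per-mode variance, with overall size free to appear as
the first mode.

A seeded synthetic-population generator (ellipsoid-with-protrusion
"bones" with a planted size mode, planted articular-like bump modes,
noise and pose jitter) provides ground truth for end-to-end validation;
no real imaging data is required anywhere.

## Worked example

```python
import numpy as np
from shapereg import (PopulationSpec, RegistrationConfig, generate_population,
                      groupwise_register, build_model, variance_explained,
                      evaluate_recovery)

spec = PopulationSpec(n_subjects=12, seed=5)       # talus-scale synthetic cohort
meshes, truth = generate_population(spec)
result = groupwise_register(truth.base_mesh, meshes, RegistrationConfig())
print(np.round(result.errors, 3))
model = build_model(result, cohort_label="synthetic")
print(np.round(model.variance_fraction[:3], 3))
rec = evaluate_recovery(model, truth)
print(round(rec["pc1_scale_correlation"], 4))
```

prints

```
[0.286 0.281 0.289 0.296 0.307 0.29  0.286 0.282 0.302 0.315 0.294 0.281]
[0.928 0.046 0.006]
1.0
```

Every subject registered to within 0.32 mm mean closest-point error
(tolerance 0.4 mm); the first mode carries 92.8% of the variance and
its subject scores correlate perfectly with the planted size factors —
size dominates, with the planted articular-like bump appearing as the
second mode.

The same pipeline is scriptable from the shell:

```sh
shapereg simulate --out pop --seed 3
shapereg register --reference pop/subject_000.stl --targets pop/*.stl --out reg
shapereg build-ssm --registered reg --out model
shapereg deviate --reference a.stl --test b.stl --match-volume 33540 --out dev
```

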