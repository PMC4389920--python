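# plaqstab

Stability analysis and simulation of a three-species reaction–diffusion–
chemotaxis model of early atherosclerotic plaque inflammation.  The model
tracks oxidized LDL (`L`), macrophages (`M`) and necrotic lipids (`N`) in
the arterial intima: LDL enters at a constant rate and diffuses,
macrophages enter at a concentration-dependent sigmoidal rate `f(L)`,
diffuse and chemotax up the LDL gradient, and the reaction `L + M -> N`
feeds an immobile necrotic species cleared at a constant rate.

The package provides:

- **model core** (`plaqstab.model`) — parameter sets, response-function
  families (identity / logistic / pinned), the spatially homogeneous
  equilibrium, and the linearization about it.
- **stability** (`plaqstab.stability`) — the spectral criterion for the
  space-integrated system (`k1*k4 > k2*k3`, equivalently `f'(L_e) > 0`),
  the chemotaxis bound (`chi_a^2 < 4*D_b*D_a*k3/k2`), and a fully explicit
  energy certificate (weights `x, y, z`, Cauchy weights `eps1..eps5`, five
  negative coefficients and an exponential decay-rate bound), with an
  independent verifier.
- **geometry** (`plaqstab.geometry`) — bipolar coordinates: the eccentric
  annulus between two nested off-center circles, metric scale factors and
  metric-weighted quadrature.
- **discretization** (`plaqstab.discretization`) — method-of-lines
  discretization of the nonlinear and linearized systems with one-sided
  no-flux boundary treatment and stiff (BDF) time integration.
- **diagnostics** (`plaqstab.diagnostics`) — seeded perturbation fixtures,
  the squared-perturbation energy integral `I(t)`, the certificate
  functional `phi(t)`, trajectory classification and the decay-bound check.
- **validation** (`plaqstab.validation`) — seeded end-to-end sweeps backing
  the acceptance criteria.

## CLI

Commands operate on a YAML run config (model constants, response family,
grid, perturbation, solver settings); see `tests/test_cli.py::write_config`
for the schema.  Every command writes its resolved config for provenance.

```
plaqstab analyze  config.yaml    # equilibrium, eigenvalues, both criteria
plaqstab certify  config.yaml    # energy certificate (exit 2 if not certifiable)
plaqstab simulate config.yaml [--overwrite] [--mode nonlinear|linearized]
```

`simulate` writes `energy.csv` (t, I, phi), per-time field snapshots and a
manifest with the stable/unstable classification.

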