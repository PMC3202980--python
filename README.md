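# arraysense

Decode chemical mixtures from the readout of a cross-specific biosensor
array, and design arrays that decode optimally.

Combinatorial sensor arrays — panels of receptors with overlapping,
non-orthogonal specificities, of which the olfactory system is the natural
archetype — can recognize many more analytes than they have sensors.  But
their response to a *mixture* is non-linear: ligands compete for binding
sites, and some act as antagonists that bind without signalling.
`arraysense` implements a physical model of competitive receptor–ligand
binding that turns this non-linearity into an asset.  Given calibrated
binding free energies ΔG<sub>ij</sub>, efficacies e<sub>ij</sub> ∈ [0, 1]
(1 = full agonist, 0 = full antagonist), backgrounds and noise scales, the
normalized reporter intensity of receptor *j* is

&nbsp;&nbsp;&nbsp;&nbsp;I<sub>j</sub> = bg<sub>j</sub> + Σ<sub>i</sub> e<sub>ij</sub> · w<sub>ij</sub>/Z<sub>j</sub>, &nbsp; w<sub>ij</sub> = exp((μ<sub>i</sub> − ΔG<sub>ij</sub>)/kT), &nbsp; Z<sub>j</sub> = 1 + Σ<sub>i</sub> w<sub>ij</sub>,

with μ<sub>i</sub> = kT ln(c<sub>i</sub>/1 M).  The package provides:

- **Calibration** — nested-sampling fits of (ΔG, e, bg, σ) from
  single-ligand dilution curves, including antagonist-in-mixture
  calibration and per-plate bias refits;
- **Mixture decoding** — Bayesian inference (with evidence) of the relative
  concentrations, total concentration, and hence the absolute concentration
  of *every* panel ligand, from any receptor subset, including absent-ligand
  calls;
- **A Fisher-information engine** — closed-form low-noise Hessians over the
  concentration parameters, D-optimal design of (ΔG, e), enumeration of
  symmetry-related optima, array diagnostics, and capacity scans showing
  that an N-receptor array discriminates at most 2N ligands (N if every
  ligand is forced to be an agonist);
- **Synthetic data** — seeded plate-style datasets for all of the above.

## Worked example

Simulate a 50/50 binary mixture (1 mM total) on a calibrated 4-receptor,
4-ligand array, then decode it:

```python
import numpy as np
from arraysense import (ArrayParams, MixtureComposition, ModelConstants,
                        generate_mixture_dataset, decode_mixture)
from arraysense.bayes import SamplerSettings

params = ArrayParams(
    ["R1", "R2", "R3", "R4"], ["L1", "L2", "L3", "L4"],
    dG=[[-8.5, -7.0, -6.0, -5.0], [-6.5, -8.0, -5.5, -7.5],
        [-5.0, -6.0, -8.5, -6.5], [-7.0, -5.5, -7.0, -8.0]],
    eff=[[0.9, 0.5, 0.3, 0.1], [0.2, 0.85, 0.6, 0.4],
         [0.5, 0.15, 0.9, 0.7], [0.7, 0.4, 0.2, 0.95]],
    bg=[0.05] * 4, sigma=[0.02] * 4)

const = ModelConstants()                       # kT = 0.6 kcal/mol
comp = MixtureComposition.equal_parts(list(params.ligand_ids), ["L1", "L2"])
mu0 = const.mu_of_concentration(1e-3)          # 1 mM total at the reference
data = generate_mixture_dataset(params, comp, mu0, seed=5)

res = decode_mixture(data, params,
                     settings=SamplerSettings(n_live=50, seed=6))
for lig in res.ligand_ids:
    print(f"{lig}: {res.conc_mean[lig]:.2e} +- {res.conc_std[lig]:.1e} M"
          f"  absent={res.absent[lig]}")
print(f"total: {res.total_conc_mean:.2e} M   logZ = {res.log_evidence:.1f}")
```

Output:

```
L1: 4.72e-04 +- 1.5e-05 M  absent=False
L2: 5.05e-04 +- 2.2e-05 M  absent=False
L3: 1.01e-07 +- 4.3e-08 M  absent=True
L4: 1.45e-06 +- 7.8e-07 M  absent=False
total: 9.78e-04 M   logZ = 332.2
```

The two present ligands are recovered at their true 5×10⁻⁴ M within a few
posterior standard deviations, and the decoded total is within 3% of the
true 1 mM.  L3 collapses to the prior floor and is flagged absent; L4 is
inferred at ~0.1% of the total — far below any real component, but with a
credible interval bounded away from the floor at this noise level, so it is
reported as a trace-level bound rather than a confident absence (see the
two-part absent-call rule in `docs/methods.md`).

The same pipeline is scriptable from the shell:

```sh
arraysense calibrate --data plates.csv --seed 1 --out params.json
arraysense decode --data mixture.csv --params params.json \
          --ref-ligand L1 --seed 2 --out result.json
arraysense design --receptors 2 --ligands 4 --out design.json
arraysense capacity --max-receptors 2 --out capacity.csv
```

Design of a one-receptor, two-ligand array illustrates the central design
principle: maximizing the determinant of the Fisher matrix drives one
efficacy to 1 and the other to 0 — the optimal sensor pairs a strong
agonist with a strong antagonist — and two label-swapped optima of equal
determinant exist.  See `docs/methods.md` for the model, priors, sampler
internals, and why the discrimination capacity is exactly twice the number
of receptors.

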