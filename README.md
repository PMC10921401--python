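# rhpmap

Composition and conformation mapping of four-monomer **random heteropolymer
(RHP)** ensembles.

Statistical copolymers of three or more monomers are widely used as
protein-mimetic materials, but they are designed by *average* composition
while every chain in the ensemble carries a different stochastic sequence.
`rhpmap` is a toolkit for asking, quantitatively, what happens to monomer
composition and single-chain conformation across an RHP's whole life cycle —
design, synthesis, purification, and depolymerization — for the
methacrylate system MMA / EHMA / OEGMA / NHSMA (`M`/`E`/`O`/`N`).  It is
aimed at polymer chemists and modellers who want the in-silico half of such a
campaign to be reproducible and testable.

Four connected stages:

1. **Reactivity ratios** (`rhpmap.jaacks`).  With one monomer in large
   excess, the terminal-model kinetics integrate to a zero-intercept log-log
   law, `ln([M_ex]₀/[M_ex]) = r_{ex,j} · ln([M_j]₀/[M_j])`, so one quaternary
   experiment yields a full row of the reactivity matrix
   `r_ij = k_ii/k_ij` by through-origin regression, and four experiments the
   full matrix.  The finite-excess approximation bias is itself measurable
   by simulation (`jaacks_bias`).
2. **Sequence simulation** (`rhpmap.simulate`).  Kinetic Monte Carlo on an
   exact integer monomer pool: a chain ending in monomer *i* adds *j* with
   probability ∝ `count_j / r_ij` (Mayo–Lewis terminal model), with an
   optional early-biased termination hazard producing realistic living/dead
   subpopulations.  Mass balance is an integer identity in every run.
3. **Composition tracking** (`rhpmap.composition`).  Feed → conversions →
   composition arithmetic with volatile-monomer loss correction,
   purification filters (molar-mass cutoff, HLB window) that are exact
   partitions, and the living/dead split whose living side is what ideal
   chain-end depolymerization would regenerate.
4. **Chain conformation** (`rhpmap.scft`).  Single-chain self-consistent
   field theory in implicit selective solvent: the modified diffusion
   equation `∂q/∂s = (b²/6)∇²q − w_{m(s)} q` solved spectrally on a radial
   grid, Flory–Huggins fields `wᵢ = −ln(1−φ_p) − χᵢφ_p − Σⱼχⱼφⱼ`, and a
   pair-identity radius-of-gyration estimator
   `Rg² = (1/2N²) Σ_{s,s'}⟨(r_s−r_{s'})²⟩` that is exact in the ideal-chain
   limit.  Ideal chains give `Rg = b√(N/6)`; poor-solvent globules scale as
   `Rg ~ N^{1/3}`.

A synthetic-data module (`rhpmap.synthetic`) generates every input — noisy
excess-monomer kinetics, pre/post signal-integral tables with volatile loss,
and the four named feed designs RHP1–RHP4 of increasing hydrophobicity — so
the entire pipeline is testable without laboratory data.  See
`docs/methods.md` for models, parameters, and limitations.

## Worked example

```python
import numpy as np
from rhpmap import (build_monomer_registry, default_reactivity_matrix,
                    rhp_design_fixtures, simulate_batch, split_living_dead,
                    purification_filter, SCFTParams, ensemble_rg)

registry = build_monomer_registry()
ratios = default_reactivity_matrix(registry)

designs = rhp_design_fixtures(registry, n_chains=2000, seed=0, dead_fraction=0.05)
feed, config = designs["RHP1"]          # MMA 10%, EHMA 20%, OEGMA 45%, NHSMA 25%
ensemble = simulate_batch(feed, ratios, config, registry=registry)
comp = dict(zip(registry.codes, ensemble.composition().round(3).tolist()))
print("global conversion:", round(ensemble.global_conversion, 3))
print("raw composition  :", comp)

retained, removed, shift = purification_filter(ensemble, registry, mwco=3000)
print(f"purification     : {len(removed.chains)} chains below MWCO removed, "
      f"max shift {shift['max']:.2f} pct points")

f_living, f_dead, diff = split_living_dead(ensemble)
print(f"living-dead MMA  : {diff['M']:+.2f} pct points")

params = {"water": SCFTParams.for_solvent("water", registry)}
table = ensemble_rg(ensemble, params, sample_size=10, seed=1)
print(f"Rg in water      : {table.Rg_nm.mean():.2f} +/- {table.Rg_nm.std():.2f} nm (10 chains)")
```

Output:

```
global conversion: 0.6
raw composition  : {'M': 0.131, 'E': 0.19, 'O': 0.395, 'N': 0.284}
purification     : 45 chains below MWCO removed, max shift 0.01 pct points
living-dead MMA  : -1.65 pct points
Rg in water      : 2.33 +/- 0.20 nm (10 chains)
```

Reading it: at the 60% target conversion the polymerized composition has
drifted from the 10/20/45/25 feed — MMA is enriched (13.1%) because every
cross-propagation ratio toward MMA is below 1, while slow-adding OEGMA lags
its feed fraction.  Dialysis at MWCO 3000 Da removes only short chains and
barely shifts composition (0.01 percentage points).  The living chains carry
1.65 points *less* MMA than the dead ones (the `-` sign: dead chains
terminate early, when MMA-rich sequences are being made).  In water this
OEGMA-rich design stays near the theta point, giving relatively large,
variable single-chain sizes.

The same stages are scriptable from a shell:

```bash
rhpmap simulate --design RHP1 --n-chains 2000 --seed 0 --out rhp1.fasta
rhpmap track --ensemble rhp1.fasta --mwco 3000 --out composition.csv
rhpmap scft --ensemble rhp1.fasta --sample-size 50 --solvent water --out rg.csv
rhpmap report --out report/ --seed 0 --scft-sample 25
```

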