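# packrate

Side-chain packing density and the elastic-network stress model of
site-specific evolutionary rate variation.

Protein sites do not evolve at a uniform rate: buried, tightly packed
residues accept far fewer substitutions than exposed ones. The two classic
structural predictors of this variation are relative solvent accessibility
(RSA) and the weighted contact number (WCN), the cutoff-free packing measure

    WCN_i = sum_{j != i} 1 / d_ij^2 .

Classically WCN is computed between C-alpha atoms, making it a *main-chain*
packing measure — yet mutations replace *side chains*. `packrate` implements
a two-node-per-residue treatment of this question: each residue contributes a
main-chain node alpha at its C-alpha and a side-chain node rho at the
geometric center of its side-chain heavy atoms (glycine has a single node).
Four WCN variants follow, written `WCN_sub^super` with the subscript naming
the focal node and the superscript the neighbor nodes summed over:

| measure | sum, over j != i |
| --- | --- |
| `WCN_rho_alpharho` | 1/d(rho_i, alpha_j)^2 + 1/d(rho_i, rho_j)^2 |
| `WCN_alpha_alpharho` | 1/d(alpha_i, alpha_j)^2 + 1/d(alpha_i, rho_j)^2 |
| `WCN_alpha_alpha` | 1/d(alpha_i, alpha_j)^2 (the classical WCN) |
| `WCN_rho_rho` | 1/d(rho_i, rho_j)^2 |

The stress model ties the first of these to evolution. Build a
parameter-free anisotropic elastic network (pfANM) over all nodes: every
node pair of distinct sites is joined by a spring with equilibrium length d
and force constant k = 1/d^2. A mutation at site i perturbs the equilibrium
lengths of the springs incident to rho_i by independent zero-mean increments
of variance sigma^2. Evaluated at the fixed native (active) conformation,
the expected destabilization is

    <dV*>_i = (sigma^2 / 2) * WCN_rho_alpharho(i),

and under weak selection the substitution rate K_i decreases linearly with
<dV*>_i, hence with the side-chain contact density — whatever the
perturbation distribution. The package verifies this proportionality
exactly, and reproduces the statistical machinery used to test it on real
data: per-protein squared Pearson correlations R^2(K, x) for each predictor
x, squared semipartial correlations rho^2(K, x | WCN_rho_alpharho)
measuring each predictor's *unique* contribution, and protein-level
bootstrap aggregation with one-sided p-values and win counts.

## Worked example

Generate a synthetic 120-site protein whose rates follow the stress-model
law at population R^2 = 0.4, then score all five predictors:

```python
import numpy as np
from packrate import *

sites = make_sites(GeometryRecipe(n_sites=120, gly_fraction=0.1, seed=42),
                   label="demo")
rates = make_rates(sites, RateRecipe(predictor="WCN_rho_alpharho",
                                     target_r2=0.4, seed=7))
pdb = write_fixture_pdb(sites)
parsed = parse_structure(pdb, chain="A", label="demo")
predictors = all_measures(parsed, pdb_source=pdb, chain="A")
comp = compare_protein(parsed, rates, predictors,
                       control="WCN_rho_alpharho")
print(f"n_sites: {comp.n_sites}")
for name in predictors:
    line = f"R2[{name}] = {comp.r2[name]:.3f}"
    line += "   (control)" if name == comp.control else f"   sp2 = {comp.sp2[name]:.4f}"
    print(line)

net = build_network(parsed)
stress = expected_stress_closed_form(net, MutationModel(sigma=0.3))
print("corr(<dV*>, WCN_rho_alpharho) =",
      np.corrcoef(stress.dvstar, wcn_rho_alpharho(parsed).values)[0, 1])
```

Output:

```
n_sites: 120
R2[WCN_rho_alpharho] = 0.460   (control)
R2[WCN_alpha_alpharho] = 0.262   sp2 = 0.0002
R2[WCN_alpha_alpha] = 0.231   sp2 = 0.0000
R2[WCN_rho_rho] = 0.421   sp2 = 0.0003
R2[RSA] = 0.134   sp2 = 0.0139
corr(<dV*>, WCN_rho_alpharho) = 1.0
```

The generating predictor explains the most rate variation (R^2 = 0.46 on
this single protein, scattered around the population value 0.4); the other
measures correlate with rates only through their correlation with the
side-chain contact density, so their unique (semipartial) contributions are
near zero; and the closed-form expected destabilization is exactly
proportional to `WCN_rho_alpharho`.

## Command line

```sh
packrate simulate --n-proteins 20 --n-sites 150 --target-r2 0.4 \
    --seed 1 --out-dir fixtures/
packrate profile fixtures/synth_000.pdb --out profile.csv
packrate stress fixtures/synth_000.pdb --n-mutations 1000 --seed 2 \
    --rates fixtures/synth_000.rates.tsv --out stress.csv
packrate compare --manifest fixtures/manifest.json --n-boot 10000 \
    --seed 3 --out-dir comparison/
```

`compare` writes a per-protein table (one row per protein with R^2 and
semipartial columns for every predictor), an aggregate summary (means,
bootstrap SDs and p-values) and a pairwise table (delta-R^2, p-values, win
counts). Real inputs work the same way: point the manifest at PDB files and
Rate4Site grades output (`"rates_dialect": "rate4site_grades"`).

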