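# macpol

Synchronous Boolean-network analysis of macrophage polarization in a tumor
microenvironment: a fully tested pipeline covering exhaustive
attractor/basin enumeration, phenotype labeling and clustering,
knockout/overexpression and microenvironment perturbation scans,
single-bit-flip cell-fate maps, theoretical genetically modified macrophages
(TGEM/STGEM), and Derrida/sensitivity robustness analysis.  A curated
29-node, 60-interaction macrophage regulatory network ships with the
package.

## On the bundled model

`src/macpol/models/macrophage_tme.txt` is a **best-effort reconstruction**
of the published macrophage polarization network.  The authors' original
rule file (distributed as supplementary material and through their code
repository) was not retrievable in the environment where this package was
built, so the rules were re-derived from the article's narrative
description of the signaling cascades and calibrated against its reported
results.  The reconstruction reproduces the published network size (29
nodes / 60 regulator→target interactions), the TGEM attractor count
(4,096 over 2^27 states), all four breast-cancer scenario phenotype sets,
the key cell-fate transitions, and the critical Derrida regime; the
wild-type landscape yields 9,942 attractors against the published 10,430
(within 5%), with a superset (17) of the 13 published phenotype labels.
Tests asserting the exact published values that the reconstruction does not
reach are intentionally left failing rather than weakened
(`tests/test_acceptance.py::test_criterion2_paper_values`,
`::test_criterion3_paper_values`).

## CLI

All stages are exposed through a single entry point:

```sh
macpol attractors                 # exhaustive WT landscape + census
macpol census
macpol cluster --seed 1           # t-SNE + k-means, consensus k
macpol scan-ko                    # knockout scan, one clamp per node
macpol scan-oe                    # overexpression scan
macpol microenv Pro-M1            # Table-of-microenvironments clamps
macpol tgem --variant tgem        # NFKB=1 & HIF1A=0 (or stgem: STAT1=1)
macpol scenarios                  # four breast-cancer milieus on the TGEM
macpol fatemap --clamp NFKB=1 --clamp HIF1A=0
macpol derrida --seed 1 --pairs 10000
macpol sensitivity --seed 1 --samples 50000
macpol reproduce-paper --seed 1   # full pipeline + summary.json
```

Commands default to the bundled model; `--model FILE` accepts any rule file
in the `targets, factors` dialect (`&`, `|`, `!`, parentheses; precedence
NOT > AND > OR; one `NODE, expression` per line).  Outputs are
tab-separated tables whose first line records the model checksum, seed and
parameters that produced them.

## Library overview

| module | contents |
| --- | --- |
| `macpol.network` | rule-file parsing/serialization, validation, clamping, degree-based reduction, bundled model loader |
| `macpol.dynamics` | synchronous engine; exhaustive attractor enumeration via a bit-parallel successor map, in-place pointer jumping, and vectorized cycle resolution (2^29 states in ~2 min, ≈2.3 GB) |
| `macpol.phenotypes` | marker-rule labeling (M0/M1/M2a–M2d with ordered hybrid labels), landscape census, t-SNE + k-means with consensus-k voting |
| `macpol.perturb` | knockout/overexpression scans, label-level log2 basin fold-changes with gained/lost flags, microenvironments, TGEM/STGEM, breast-cancer scenarios |
| `macpol.fatemap` | exhaustive single-bit-flip transition maps with label-level reversibility and DOT export |
| `macpol.robustness` | stratified Derrida curves, chi-squared regime classification, per-rule sensitivity (all-nodes or inputs-only flip conventions) |
| `macpol.synthetic` | seeded random N-K network ensembles and fixture networks with hand-derived landscapes |

Example:

```python
from macpol import load_macrophage_model, exhaustive_attractors
from macpol.phenotypes import phenotype_census

net = load_macrophage_model()          # 29 nodes, 60 interactions
wt = exhaustive_attractors(net)        # all 2^29 initial states, exact basins
print(phenotype_census(wt).head())
```

States are integers; bit *i* carries the value of `net.node_names[i]`.
Clamped nodes keep their clamp value in every state the engine produces,
and basins always sum to 2^(free nodes).

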