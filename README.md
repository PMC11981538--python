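# trophoweb

Trophic-network analysis for before/after disturbance comparisons of
aquatic ecosystems: food-web assembly and functional-group aggregation,
global and node-level topology indices, trophic levels by exact linear
solve, and steady-state energy fluxes from biomasses and allometric
metabolic rates. A niche-model generator produces synthetic webs with the
same structural properties, so the whole pipeline is testable without
field data.

The package is built around the kind of question posed by the Comacchio
Lagoon (northern Adriatic), where a severe eutrophication event in the
early 1980s replaced seagrass meadows with cyanobacteria and reorganized
the food web: given two binary predator–prey networks describing the same
ecosystem at two times, what changed in their topology, their trophic
structure, and their energy flows?

## The models

**Topology.** Webs are binary directed graphs with edges in the direction
of energy flow (prey → predator). For whole-web indices the web is
symmetrized (i and j linked iff either feeds on the other) and described by
node count *N*, link count *L*, density *D* = 2*L*/*N*(*N*−1),
degree-weighted overall clustering *CL* = Σᵢ kᵢcᵢ / Σᵢ kᵢ, mean geodesic
distance *d*, and the small-world ratio *SW* = *CL*/*d*. Per node:
normalized degree centrality nDC = k/(N−1) and normalized betweenness nBC
(percent of (N−1)(N−2)/2, exact geodesic counting).

**Trophic levels.** Producers, cyanobacteria and detritus are fixed at
TL = 1; a consumer sits one level above the mean of its prey:
TLᵢ = 1 + (1/kᵢ) Σ_{j∈prey(i)} TLⱼ. The system is solved exactly (dense
LU), which handles omnivory loops among consumers without iteration.

**Energy fluxes.** Writing Gⱼ for the total consumption of consumer j,
Wᵢⱼ for biomass-scaled feeding preferences and eᵢ for the prey-category
assimilation efficiency (animal 0.906, producer/cyanobacteria 0.545,
detritus 0.158), steady state requires

    Gⱼ · Σᵢ Wᵢⱼ eᵢ = Xⱼ + Σₖ Wⱼₖ Gₖ

where Xⱼ = a·Mⱼᵇ·Bⱼ is the allometric metabolic loss (default a = 0.71,
b = −0.25). Basal nodes are unlimited sources (placeholder biomass 1,
metabolic rate 0). The balance is linear in G and solved exactly;
individual fluxes are Fᵢⱼ = Wᵢⱼ·Gⱼ.

## Worked example

```python
from trophoweb import (FoodWeb, NodeAttributes, compute_fluxes,
                       global_metrics, symmetrize, trophic_levels)

nodes = [
    NodeAttributes(name="Detritus", category="detritus"),
    NodeAttributes(name="Cyanobacteria", category="cyanobacteria"),
    NodeAttributes(name="Copepoda", category="animal", biomass=2.0, body_mass=1e-4),
    NodeAttributes(name="Shrimp", category="animal", biomass=3.0, body_mass=1.5),
    NodeAttributes(name="Anchovy", category="animal", biomass=1.5, body_mass=8.0),
]
edges = [("Detritus", "Copepoda"), ("Cyanobacteria", "Copepoda"),
         ("Copepoda", "Shrimp"), ("Detritus", "Shrimp"),
         ("Copepoda", "Anchovy"), ("Shrimp", "Anchovy")]
web = FoodWeb(nodes, edges, directed=True)

print(global_metrics(symmetrize(web)).as_series())
print(trophic_levels(web).as_series())
print(compute_fluxes(web)[0].to_long())
```

prints (abridged)

```
Network density (D)                                     0.6
Weighted overall graph clustering coefficient (CL)    0.611
Small world index (CL/d)                              0.437
...
Anchovy          3.25
Copepoda         2.00
Shrimp           2.50
...
            prey  predator       flux
0       Copepoda   Anchovy   0.279582
2  Cyanobacteria  Copepoda  23.981967
3       Detritus  Copepoda  23.981967
```

Anchovy sits a quarter level above shrimp because half of its diet is the
lower copepod; the detrital flux is large because detritus assimilates at
only 0.158, so detritivores must ingest a lot to cover their metabolism.
The two basal fluxes into Copepoda are equal because basal sources enter
preference weighting with the placeholder biomass 1.

`examples/` holds one short script per capability (topology, trophic
levels, fluxes, synthetic disturbance pairs, the published Comacchio
tables), and the `trophoweb` CLI exposes the same steps as subcommands
(`simulate`, `metrics`, `tl`, `flux`, `aggregate`, `compare`, `run`).

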