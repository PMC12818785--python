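# ppiresil

Entropy-based resilience analysis of protein–protein interaction (PPI)
networks: how hard is it to fragment an interactome by knocking out
proteins at random, and which individual proteins hold it together?

Static centrality measures (degree, betweenness, closeness, eigenvector)
describe a protein's position in the intact network but say nothing about
the cascade of fragmentation its loss triggers. `ppiresil` quantifies that
dynamic side for systems biologists working with undirected, unweighted PPI
graphs (e.g., the SNAP tree-of-life bacterial interactomes, distributed as
plain-text edge lists).

## The metrics

Failure is modelled as **node isolation**: a failed protein loses all its
interactions but remains as a size-1 component. After isolating a fraction
*f* of the *N* proteins, the network splits into *k* components with sizes
|c₁|, …, |c_k| and proportions pᵢ = |cᵢ|/N, scored by the modified Shannon
diversity

    H_msh(G_f) = −(1/log N) Σᵢ pᵢ log pᵢ ,

which is 0 for an intact connected network and 1 when every protein is
isolated. Integrating over the whole failure range gives the **network
resilience**

    R(G) = 1 − ∫₀¹ H_msh(G_f) df ,

evaluated by the trapezoid rule on a 1 % failure grid with 100 independent
Monte-Carlo failure sets per grid point (both configurable). High R means
fragmentation is delayed: the network keeps a giant component under heavy
random failure.

**Node Resilience** of protein vᵢ is the resilience of the network that
remains after deleting vᵢ:

    NRᵢ = R(G \ {vᵢ}) ,

so low NR marks proteins whose loss most fragments the network. The lowest
decile by NR are the *Key Component Nodes* (KCNs); the highest decile by
betweenness are the *Key Bridge Nodes* (KBNs); their overlap measures how
far the dynamic and static notions of criticality agree.

The package also simulates **progressive degradation** — delete a growing
random fraction of nodes, re-measure the resilience of the surviving
largest component — and estimates the critical failure ratio where gentle
decline turns into accelerated collapse, via a two-segment continuous
least-squares fit of the trajectory.

## Worked example

A synthetic modular interactome — 4 modules of 25 proteins whose only
inter-module routes run through 3 bridge proteins — shows the machinery:

```python
from ppiresil import (planted_modular_graph, resilience, node_resilience_all,
                      detect_outliers, key_component_nodes, correlate)
from ppiresil.centrality import centralities, key_bridge_nodes, overlap_report

g = planted_modular_graph(modules=4, module_size=25, bridges=3, seed=7)
res = resilience(g, step=0.01, reps=100, seed=7)
nr = detect_outliers(node_resilience_all(g, step=0.01, reps=100, seed=7))
cent = centralities(g)
report = correlate(nr, cent, method="spearman")
ov = overlap_report(key_component_nodes(nr, 0.10), key_bridge_nodes(cent, 0.10))
```

which prints (via the accompanying `print` calls):

```
network: 103 proteins, 277 interactions
R(G) = 0.3938
outliers outside the 95% band: 2.9% of nodes
 node       nr  rank  outlier
  b02 0.382988     1     True
  b00 0.383369     2     True
  b01 0.383679     3     True
m1_03 0.389171     4    False
m0_01 0.389204     5    False
NR vs DC: rho = -0.816
NR vs BC: rho = -0.871
NR vs CC: rho = -0.732
NR vs EC: rho = -0.383
KCN/KBN overlap: 8/11 (fraction 0.73)
```

The three planted bridges (`b00`–`b02`) occupy the three lowest NR ranks
and are exactly the nodes flagged outside the 95 % confidence band: their
loss decouples modules, which is why NR anti-correlates most strongly with
betweenness centrality while the correlation with eigenvector centrality is
weak. R(G) ≈ 0.39 says the trapezoid of the entropy curve is ≈ 0.61 —
random failure fragments this sparse network well before all nodes are
gone.

The same analyses are available from the shell on any edge-list file:

```
ppiresil synth --family planted_modular --modules 4 --module-size 25 \
    --bridges 3 --seed 7 --out net.txt
ppiresil pipeline --edge-list net.txt --seed 7 --out run/
```

The pipeline bundle contains the entropy curve, degradation trajectory,
breakpoint fit, NR table, centralities, correlations, key-node overlap, a
`manifest.json` that reproduces the run bit-for-bit, and a timing log.

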