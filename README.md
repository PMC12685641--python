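# stingnet

Kinetic modeling and network analysis of cGAS–STING/IL-6/FOXO-driven
autophagy signaling in non-small cell lung cancer (NSCLC).

In NSCLC, cytosolic double-stranded DNA activates the cGAS–STING axis,
which both induces type-I interferon / IL-6 inflammatory signaling and
triggers noncanonical autophagy through ERGIC membrane donation. The FOXO
transcription factors FOXO1 and FOXO3a, mobilized by IL-6/JAK/STAT3
signaling, transcribe the autophagy genes (ATG5/7/12, LC3-2) that mature
the phagophore into an autophagosome. `stingnet` implements this system as
a curated compartmental ODE model — 6 compartments, 72 dynamic species,
83 reactions with mass-action, Michaelis–Menten and Hill kinetics — plus
the complete analysis stack a systems biologist would run on it:

* stiff deterministic simulation of `dx/dt = N v(x)` over a 100 s horizon;
* forward local sensitivity analysis (`dS/dt = J_x S + J_p`), aggregated
  into a score matrix and ranked by PCA with a banded key-species filter;
* per-reaction kinetic flux ranking and threshold filtering (a verbatim
  transcription of the published 27-row high-flux table ships as a
  fixture);
* quasi-potential model reduction combining sensitivity, flux and peak
  concentration into a combined rank (the curated model reduces 83 → 12
  retained reactions, 86%);
* interaction-network construction (reactants/modifiers → products) with
  twelve CytoHubba-style centralities (degree, closeness, betweenness,
  bottleneck, clustering coefficient, MNC, DMNC, eccentricity, EPC, MCC,
  radiality, stress) and frequency-of-occurrence hub selection;
* pathway crosstalk scoring (total degree minus within-pathway degree);
* SBML L3V2 import/export, and seeded generators of synthetic models and
  graphs for property-based validation.

The package is a library first (`import stingnet`) with a thin `stingnet`
command-line tool on top.

## Worked example

Run the whole pipeline on the curated model and read the manifest:

```bash
stingnet pipeline --out results/ --seed 1
```

```json
{
 "boundary_species": 17,
 "compartments": 6,
 "crosstalk_point_nodes": ["foxo1_n", "foxo3_n", "jak1tyk2", "phag", "pi3k", "stat3d"],
 "crosstalk_points": 6,
 "network_avg_clustering": 0.034,
 "network_avg_degree": 2.292,
 "network_diameter": 19,
 "network_edges": 102,
 "network_nodes": 89,
 "network_radius": 11,
 "reactions": 83,
 "reduction_percent": 86,
 "retained_reactions": 12,
 "species": 72
}
```

Reading: the curated model carries 72 dynamic species and 83 reactions in
6 compartments. Its interaction network (89 nodes including gene loci and
constant inputs; 102 deduplicated edges) has radius 11, diameter 19 and a
mean local clustering coefficient of 0.034 — a sparse, cascade-like web
with a few dense spots. Exactly six nodes bridge otherwise separate
pathways (crosstalk points): JAK1/TYK2, the STAT3 dimer, PI3K, nuclear
FOXO1 and FOXO3a, and the phagophore. Quasi-potential reduction keeps the
12 reactions that are simultaneously high-flux, high-concentration and of
near-unit sensitivity — an 86% reduction.

The same stages are available individually (`stingnet simulate`,
`sensitivity`, `pca`, `flux`, `reduce`, `network`, `crosstalk`,
`generate`, `export-model`) and as library calls:

```python
import stingnet as sn

model = sn.build_nsclc_model()
traj = sn.simulate(model, t_end=100.0)
print(traj.net_change().head(3))
# autoph        378086.2   # autophagosome
# cgsting_er    238855.4   # ER-membrane cGAMP-STING
# foxo1_n       217747.0   # nuclear FOXO1
```

At 100 s the strongest accumulating species are the autophagosome, the
ER-membrane cGAMP–STING complex and nuclear FOXO1/FOXO3a — the model's
qualitative signature: DNA sensing ends in autophagosome formation under
FOXO control. Rate constants are calibrated defaults (none are published
for this system), so absolute numbers are illustrative; see
`docs/methods.md` for the calibration contract and every algorithmic
convention.

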