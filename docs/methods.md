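# Methods

## The model

`stingnet` ships a curated compartmental kinetic model of the signaling web
that couples cytosolic DNA sensing to autophagy in non-small cell lung
cancer (NSCLC). The biology, briefly: cytosolic dsDNA activates cGAS, which
synthesizes the second messenger cGAMP from ATP and GTP; cGAMP activates
STING on the ER membrane. Activated cGAMP–STING traffics through the ERGIC
to the Golgi, where it (together with the LPS/TLR4/MYD88/IRAK4/TRAF3 arm)
activates TBK1 and IKK. TBK1 phosphorylates IRF3 (→ type-I interferon
transcription); IKK releases NF-κB p65/p50 (→ IL-6 transcription). IFN and
IL-6/IL-10 receptor engagement feed JAK/STAT signaling: the STAT1/2/IRF9
complex transcribes STING (a positive feedback loop), while STAT3
dimerization drives FOXO1/FOXO3a nuclear translocation. Nuclear FOXOs
transcribe the autophagy genes (ATG5, ATG7, ATG12, LC3-2), whose products
assemble the ATG12/5/16L–LC3 conjugation machinery. In parallel, the ERGIC
donates an isolation membrane (noncanonical, STING-driven autophagy) that
matures into the phagophore and finally the autophagosome; the
EGF/PI3K/AKT/mTORC1/HIF-1α and ADP/AMPK/ULK1 energy-stress arms feed the
same phagophore machinery and the STING expression program.

The model has:

* **6 compartments** — plasma membrane, cytoplasm, nucleus, ER membrane,
  Golgi, ERGIC — all with unit volume, so molecule count equals
  concentration.
* **72 dynamic species** (the state variables) plus **17 boundary
  entities**: 7 gene loci and 10 constant inputs/reservoirs (dsDNA, ATP,
  GTP, LPS, IL-10, EGF, extracellular ADP, the ERGIC membrane pool,
  SEC12/TMED9, ATG16L). Boundary species are held constant during
  integration; they give transcription reactions a fixed template and
  source arms a fixed drive. Dynamic initial abundances lie in the
  10^3–10^6 molecules band typical of signaling proteins.
* **83 irreversible reactions** with three rate-law families:
  mass action `v = k·∏[R_i]^s_i` for association/dissociation/
  translocation, Michaelis–Menten `v = Vmax·[S]/(Km+[S])` for enzymatic
  conversion, and Hill `v = Vmax·[S]^n/(K^n+[S]^n)` for gene expression,
  driven by the transcription-factor modifier. Hill with `n = 1` reduces
  exactly to Michaelis–Menten.

Cascade activation follows the conversion idiom of this model family
(compare the shipped reference reaction "IFN activated -> JAK1/TYK2"):
activating the next pathway member is written as a conversion with the
upstream activator as reactant. A few inactive precursor pools (TLR4,
TRAF6, IRF9, EGFR, cytoplasmic TBK/IKK/STAT3/ULK1) are therefore absorbed
into their cascades rather than modeled as separate nodes.

**Parameter provenance.** No rate constants for this system are published;
every parameter here is a documented default, calibrated once so that
(i) trajectories are bounded and non-negative over the 100 s horizon,
(ii) the strongest accumulating species at 100 s include the autophagosome,
nuclear FOXO1/FOXO3a and the ER-membrane cGAMP–STING complex, and (iii)
autophagosome formation from the LC3/ATG12/5/16L conjugate sits among the
highest-flux reactions. Absolute fluxes and abundances are therefore
illustrative; the structural analyses (network topology, crosstalk) do not
depend on them.

## Simulation

`simulate` integrates `dx/dt = N v(x)` (N the net stoichiometric matrix,
boundary rows zero) with scipy's BDF — an implicit variable-order multistep
method appropriate for stiff kinetics. Defaults: `t_end = 100 s`,
`rel_tol = 1e-6`, `abs_tol = 1e-9`, 201 evenly spaced output points.
States are clipped to zero after integration when undershoots stay within
100× the absolute tolerance; larger undershoots raise an error. An
analytic Jacobian assembled from per-reaction rate gradients is supplied to
the solver.

## Local sensitivity analysis

Forward sensitivity equations: for inputs p (rate parameters and/or
initial amounts), `S(t) = ∂x/∂p` obeys `dS/dt = J_x S + J_p` with
`S(0) = ∂x0/∂p`, where `J_x`, `J_p` are assembled analytically. Small
systems co-integrate the augmented ODE with BDF (`rtol 1e-8`); systems
above ~4000 augmented equations (the curated model against all of its
~170 inputs would need >10^4) use a staggered scheme — state solve with
dense output, then A-stable trapezoidal steps (20 substeps per output
interval) for the linear sensitivity ODE, sharing one LU factorization per
step across all input columns. The test suite validates both paths against
central finite differences (step `1e-4·p`, agreement `1e-4` relative with
a columnwise `1e-4·max` absolute floor for entries that are numerically
zero on the problem scale) and against analytic solutions (exponential
decay, matrix-exponential fundamental solutions of linear systems).

The default normalization is dedimensionalized, `(p_j/x_i)·∂x_i/∂p_j`,
with entries defined as 0 where `x_i(t) = 0`; this puts species of very
different abundances on one scale before PCA. Raw sensitivities remain
available for oracle comparisons.

Aggregation over time (default `L2_over_time`, the square root of the
trapezoidal integral of S²; alternatives `time_integral_abs` and
`final_time`) produces the m×n score matrix consumed by PCA.

## PCA ranking

Columns of the score matrix are mean-centered (no variance scaling,
matching classical `princomp`) and decomposed by SVD; component signs are
fixed by forcing the largest-magnitude loading positive. Because no
published convention maps component scores to a per-species scalar, the
package defines the **PCA score** as the variance-weighted L2 norm of a
species' component scores over the leading components covering ≥ 90% of
variance, rescaled to unit median. On that scale the selection band
[0.8, 1.2] — inclusive on both ends — picks species of typical-to-high
leverage regardless of the model's absolute sensitivity magnitudes. This
is a documented interpretation, not a reproduction of any published score
table; on the curated model the band contains, among others, the ULK1
complex and cytoplasmic ADP.

## Flux analysis

Kinetic flux is the instantaneous reaction rate (mol/s) at the final
simulated state (default) or its trapezoidal time average. Tables are
sorted descending with ties broken by reaction id; `top_reactions` filters
at a threshold (default 500 mol/s). The published 27-row high-flux table
is shipped verbatim as a packaged CSV fixture
(`stingnet/data/high_flux_reactions.csv`) so the threshold-filter analysis
is reproducible without simulation.

## Quasi-potential landscape and model reduction

Each reaction gets a landscape triple: sensitivity (max aggregated
sensitivity over its own rate parameters, rescaled to unit median across
reactions, so "close to one" means "typical leverage"), flux, and the
time-peak abundance of its first product. The combined rank is the mean of
the three per-axis descending ranks. Default retention criteria: rescaled
sensitivity within 1 ± 0.2, flux ≥ 500 mol/s, product peak at or above the
0.85 concentration quantile, plus the top 12 reactions by combined rank.
On the curated model these defaults retain exactly 12 of 83 reactions — an
86% reduction — with the autophagosome-formation reaction inside the apex
region. The reduced submodel (retained reactions only) must still
integrate cleanly; because pruning removes upstream sources, the stability
check demands only a bounded shift (four orders of magnitude) in retained
products' final amounts, a deliberately loose no-blow-up bound.

## Interaction network and centralities

The network view maps every reaction's reactants **and modifiers** to
sources and products to targets, collapsing parallel duplicates. All
metrics run on the undirected simple view (the convention under which the
radius/diameter/clustering statistics are mutually consistent); the
directed graph is preserved for export. The curated network has 89 nodes,
102 edges, radius 11, diameter 19 (largest component), and mean local
clustering 0.0337 (nodes of degree < 2 contribute 0). Average degree is
reported as both 2E/N and mean neighbor count.

Twelve node metrics: degree; harmonic closeness (sums 1/d, handling
disconnection); betweenness (raw pair counts, Brandes); stress (number of
shortest paths through a node); eccentricity score (reciprocal of the
node's eccentricity on its component); radiality
(Σ_w (Δ+1−d(v,w))/(n_comp−1), Δ the component diameter); local clustering
coefficient; MNC (order of the largest connected component of the open
neighborhood); DMNC (edges of that component divided by its order^1.7);
MCC (sum of (|C|−1)! over maximal cliques containing the node); bottleneck
(number of deterministic BFS shortest-path trees — sorted neighbor order,
first-found parent — in which the node's subtree exceeds a quarter of the
component); EPC (mean component size of the node over seeded random
edge-retention realizations, default 1000 realizations at keep probability
0.5; the seed is a required argument and is recorded in the table's
metadata). Betweenness, stress, MCC, MNC and DMNC are verified exactly
against exhaustive-enumeration oracles on seeded 10-node random graphs.

Hub selection: for each metric take the top-k nodes (k = 20 by default;
ties broken by node id), and count for each node the number of metrics in
whose list it appears (frequency of occurrence, 0–12). On the curated
network the phagophore attains the maximal frequency 12/12 and the STAT3
dimer sits in the leading tier at 9/12 — it participates in no triangle,
so the three neighborhood-density metrics necessarily place it in their
zero tier.

## Crosstalk

Pathway membership is a hand-assigned, editable two-column table
(`stingnet/data/nsclc_pathway_annotation.csv`; nine pathways, multi-
membership allowed). The crosstalk score of a node is total degree minus
within-pathway degree, where a neighbor counts as within-pathway if it
shares at least one label (a stricter all-labels variant is available).
The relation "shares no label" is symmetric, so crosstalk points arise in
adjacent pairs; on the curated network exactly six nodes score non-zero:
JAK1/TYK2, STAT3 dimer, PI3K, nuclear FOXO1, nuclear FOXO3a, and the
phagophore.

## Synthetic data

The generator emulates the structural statistics the analyses assume:
compartmentalized species with log-uniform initial abundances in
10^3–10^6 molecules, a configurable mass-action/Michaelis–Menten/Hill mix
(default 60/25/15), one- and two-reactant stoichiometries, and a connected
reaction graph guaranteed by a spanning construction. Mass-action rate
constants are drawn log-uniformly (second-order constants scaled by 1e-4
so rates stay comparable across orders); all values are rounded to 12
significant digits so SBML round trips are exact. Determinism under the
seed is the master invariant. What the generator does **not** emulate:
feedback-loop structure, conservation moieties beyond those implied by the
drawn stoichiometries, or any real parameter distribution — so passing
property tests demonstrate correctness of the *machinery* (integration,
sensitivities, centralities), not biological fidelity of random models.

## Numerical and design notes

* Compartment volumes are fixed at 1; amounts are dimensionless molecule
  counts; fluxes are labeled mol/s for continuity with the reference table.
* All reactions are irreversible; reversibility is modeled as two
  reactions (nucleocytoplasmic shuttling, recycling and deactivation steps
  carry small rate constants of 0.01 /s).
* Saturable rate laws need exactly one driving species: the single
  reactant for Michaelis–Menten, the first dynamic (non-boundary) modifier
  for Hill, with a typed error otherwise. Modifiers beyond the driver
  influence the network projection but not the rate — the "saturating
  catalyst" simplification.
* Degenerate inputs: a constant (zero-variance) score matrix is rejected
  by PCA; criteria that retain zero reactions produce a warning, not an
  error; an empty network is rejected by the topology summary.
* Problem sizes used by the validation suite: synthetic models of 6–20
  species for the finite-difference oracle (20 seeds), 10-node random
  graphs for the centrality oracles (30 seeds), and the full curated model
  for the end-to-end checks.

## Known limitations

* Parameter values are calibrated defaults; quantitative trajectories and
  absolute fluxes should not be read as predictions.
* Local sensitivities only; no global (Sobol/Morris) analysis.
* Deterministic ODE semantics only; no stochastic simulation, events,
  delays or dosing.
* The reduction rule (per-axis thresholds plus combined rank) is a stated
  convention; no formal model-order reduction (lumping, timescale
  separation) is attempted.
* GO-term enrichment of hub sets requires external annotation databases
  and is out of scope.
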