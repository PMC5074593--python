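# Methods

This note documents the models, conventions and numerical choices behind
`dynapath`, including the points where the underlying protocol is
genuinely open and the package had to commit to a design.

## Coarse-grained node model

Protein residues are represented by a single node at the Cα; every
nucleotide (free ATP/ADP or a nucleic-acid residue) contributes two
nodes, one on the base side and one on the phosphate side.
Representative atoms: Cα; N9 for purines / N1 for pyrimidines; Pα for
free nucleotides / P for a polynucleotide backbone.  The two-node split
of a nucleotide's heavy atoms is: ring system + exocyclic substituents +
the glycosidic C1′ on the base side, phosphates + remaining sugar atoms
on the phosphate side.  Only the two representative atoms are dictated
by the standard protocol; the heavy-atom split is this package's
deterministic choice, needed because contacts are evaluated over member
heavy atoms.  Residue numbers are reported exactly as authored in the
input structure so that residue labels (F36, K620, N497 …) match the
literature; internal node ids are 0-based.  Altloc handling keeps the
highest-occupancy conformer; missing residues are simply absent nodes.

## Superposition

Displacement correlations require removal of rigid-body motion, but the
fitting protocol of the original workflow is not specified anywhere we
could pin down.  `dynapath` fits every frame to the *iterated ensemble
mean*: fit → recompute mean → fit, repeated until the mean stabilises
(tolerance 1e−9 Å, minimum two passes, maximum 50).  Rotations are
proper (determinant +1).  The fit selection defaults to all atoms; the
pipeline uses all representative atoms.  The protocol is recorded in
every run manifest.  Per-domain fits are not implemented.

## DCCM

`C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^½` with Δr_i the
representative-atom position minus its time average *over the analysed
window* (not frame 0), all frames pooled without decimation.  A node
with zero displacement variance has undefined correlations; it is
flagged, its rows are NaN, and network construction refuses contacts
that involve it.  Whether multi-copy simulations should be pooled or
averaged per trajectory is ambiguous in the source protocol; `dynapath`
computes one DCCM per trajectory ensemble (pool) and windowed prefixes
for convergence.  Convergence is reported as the RMS difference of
matrix elements and the Pearson correlation of off-diagonal elements
between consecutive cumulative windows (¼, ½, ¾, 1 by default) — the
published record only shows matrices side by side, so these two metrics
are this package's construction.

## Contacts and edge weights

A pair of non-neighbouring nodes is a contact when the minimum distance
between their member heavy atoms is ≤ 4.5 Å in **strictly more than**
75% of pooled frames ("more than 75%" read literally).  "Neighbouring"
means sequence-adjacent residues of the same chain (|Δresnum| = 1) and
the two nodes of one nucleotide — covalently tethered pairs whose
trivially high correlation would otherwise dominate every path.  Whether
the original contact criterion used heavy atoms or node points is
unstated; heavy-atom distances follow the established dynamical-network
protocol and a `node-point` mode is available for sensitivity checks.
Contact fractions are computed over all pooled frames.

Edge weights are `w_ij = −ln|C_ij|`, with |C| floored at 1e−6 so weights
stay finite.  **The natural logarithm is deliberate**: the published
path tables that this package mirrors satisfy the necessary bound
`100·(−ln min) ≤ W ≤ 100·N·(−ln min)` for every printed row, while under
base-10 logs several rows (e.g. an ATPase→clamp path with N = 28,
W = 209, min = 0.86: 28 × 100 × (−log₁₀ 0.86) ≈ 183 < 209) would be
impossible.  The consistency suite in
`tests/test_network.py::TestPublishedTableConsistency` pins this.  The
signed correlation is kept on every edge for reporting positive versus
negative coupling.

## Paths

All-pairs shortest paths use an in-package Floyd–Warshall with a
successor matrix; only strict improvements are applied, with
intermediate nodes in increasing order, so reconstruction is
deterministic.  Tests cross-check distances against an independent
Dijkstra implementation, `scipy.sparse.csgraph.floyd_warshall`, and
brute-force enumeration of all simple paths on small graphs.

Path statistics follow the table conventions: `N` counts **edges**
("hops" most naturally counts steps; no printed row discriminates
between the edge and node conventions), `W = 100·Σ(−ln|c|)` and `min` is
the weakest edge correlation.  `W` is rounded to an integer only in
human-readable tables.

Suboptimal ensembles contain *all* simple paths with
`W ≤ W_opt + offset`, found by depth-first search pruned with the exact
distance-to-sink table (an admissible bound), never by sampling — this
keeps the ensemble testable against brute force.  Offsets are on the
×100 reported-weight scale (offset 10 ≡ 0.10 raw): on the raw −ln scale
the conventional offsets 3–10 would admit essentially every path in the
graph, which is incompatible with the curated ensembles the method is
known for.  Default offsets 3 / 5 / 10 for MBD–ATPase, ATPase–ATPase and
ATPase–clamp queries.  A configurable cap (10⁶) aborts combinatorial
blow-ups with advice to lower the offset.

A path is *effective* iff `min ≥ 0.7`: a single poorly coupled link
breaks the communication value of an otherwise light path.  Anchors are
resolved by taking all nodes with any member heavy atom within 10 Å of
the site atoms (mismatch site, bound nucleotide, DNA contact region) on
a designated reference frame — the first analysed frame by default,
since the original choice of reference structure is unstated — and
selecting the candidate pair with the shortest optimal path, ties broken
by lowest node-id pair.

## Communities

Girvan–Newman: iteratively remove the edge with the highest edge
betweenness computed with the −ln|C| weights as distances
(lexicographically smallest edge on ties), then return the partition
with maximal modularity along the dendrogram.  Modularity is evaluated
with |C_ij| as the strength weight, because modularity expects an
affinity, not a distance; on equal modularity the coarser partition
wins.  The number of communities is therefore data-driven — the
original workflow never states how many communities were kept.
Edgeless graphs yield singleton communities with modularity 0.
Inter-community edges are ranked by how many ensemble paths traverse
them; these are the candidate switching points of the network.

## Synthetic correlated-motion generator

The generator is the package's test-bed and stands in for undeposited
production trajectories.  What it emulates: multi-chain node geometries
whose declared contacts are < 4.5 Å and whose non-contacts are > 6 Å;
per-node isotropic Gaussian displacements with a specified cross-node
correlation applied independently per Cartesian axis (amplitude
0.3 Å/axis by default), sampled at a fixed 1 ps frame interval; a
planted two-block community structure; and a planted chain of
high-correlation contacts between two anchors.

Geometry.  Linear chains use 3.8 Å backbone-like spacing.  Compact
"helical" chains (twist 130°, rise 1.3 Å, bond 3.8 Å) additionally put
sequence offsets 2 and 3 at 3.98/4.03 Å — *non-adjacent* intra-chain
contacts that survive neighbour exclusion, which is what allows a
planted path to run through a chain in steps of 2–3 residues.  Declared
inter-chain contacts must join terminal nodes of both chains (placed
collinearly, 4.0 Å gap): an interior node flanked by two 3.8 Å
neighbours cannot keep both of them > 6 Å from a partner placed 4 Å
away, so interior attachments are rejected with a diagnostic rather than
silently violating the contact contract.  All placements are verified by
exhaustive pairwise distance checks and rejected loudly on failure.

Covariance.  The naive target — consecutive planted-path edges at
ρ_path = 0.9 while the same nodes are ρ_block = 0.6 correlated with
their whole block — is not positive semi-definite (a 3×3 minor has
negative determinant), so exact nominal values everywhere are
impossible.  The construction is a factor model, PSD by design, with no
eigenvalue clipping: a global background factor (ρ_bg), one factor per
block (mass ρ_block − ρ_bg for ordinary nodes, a reduced mass
m = (ρ_path − ρ_block)/2 for path nodes), and an AR(1)-style chain
factor along the planted path whose lag-one coefficient is chosen so
that consecutive in-block path edges land at **exactly** ρ_path.  The
exact consequences, all closed-form and exposed by `ground_truth`:
cross-block planted edges (the bridge) have correlation ρ_path − m;
path/non-path in-block pairs have ρ_bg + √(m(ρ_block − ρ_bg)).  With
the defaults (0.9 / 0.6 / 0.1) the weakest planted edge (bridge, 0.75)
still exceeds the strongest background contact (0.6) by a margin of
0.15, so the planted path is the unique minimum-weight route on the
expected-weight graph — verified by brute-force enumeration — and is
recovered by the full pipeline from sampled data.

Sampling uses a Cholesky (or symmetric eigen-)factor of the covariance
and an explicit integer seed; running without a seed is an error.  The
same-seed run is byte-reproducible.

What the generator does **not** emulate: anharmonicity, conformational
substates and state switching, solvent damping and time correlation
(frames are i.i.d.), anisotropic fluctuations, and real side-chain
packing.  Passing the recovery tests therefore demonstrates the
correctness of the analysis machinery, not the physics of any real
protein; conclusions about a real system still require real
trajectories.

## Problem sizes and defaults

Synthetic benchmarks use two 10-node blocks (20 nodes, 31 contacts) with
20,000 frames (nominally 20 ns at 1 ps) for recovery runs and 50,000
frames for correlation-convergence checks; at those sizes the maximum
DCCM error against the specified matrix is below 0.01, an order of
magnitude inside the 0.05 acceptance band.  Random-graph oracle checks
run on graphs of 3–9 nodes where exhaustive simple-path enumeration is
exact and cheap.  Defaults everywhere mirror the established protocol:
4.5 Å / 75% contacts, 10 Å anchor shells, offsets 3/5/10, effectiveness
threshold 0.7.

## Known limitations

* Floyd–Warshall is O(n³) dense; for very large complexes (> ~3000
  nodes) repeated single-source Dijkstra would be preferable.  The
  Girvan–Newman loop recomputes betweenness after every removal and is
  likewise quadratic-to-cubic; it is the canonical algorithm of this
  workflow, not the fastest available.
* Mutation mapping consumes a published alignment table; no alignment is
  computed.
* No flow/communicability path models, no time-lagged or
  mutual-information correlations, no per-domain superposition.
* The enrichment tail probability (hypergeometric) is an extension
  beyond the published expectation arithmetic and is labelled as such in
  reports.
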