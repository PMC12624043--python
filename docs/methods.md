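# Methods

This note documents the models, parameters and numerical choices behind
`cryptosite`, and what the synthetic fixtures do and do not establish.

## Solvent accessibility and the cryptic classification

Per-atom solvent-accessible surface area (SASA) is computed with the
Shrake-Rupley test-point algorithm. Each heavy atom is surrounded by a
deterministic golden-spiral lattice of `n_sphere_points` (default 960)
points on its solvent-expanded sphere (van der Waals radius + 1.4 Å water
probe); a point is occluded iff it lies *strictly* inside another atom's
expanded sphere, so a point exactly on a neighboring surface counts as
exposed and the coincident-sphere case is well defined. The lattice is
attached in a fixed global orientation — output is deterministic and
seedless; an optional rotation of the lattice exists so that rigid-body
objectivity can be verified exactly. Neighbor search uses a k-d tree
restricted to atoms within the sum of expanded radii.

Embedded data:

- heavy-atom van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å —
  a standard heavy-atom set appropriate for models without hydrogens;
- maximum per-residue SASA in an extended Gly-X-Gly tripeptide (the Tien et
  al. 2013 "theoretical" values), used to normalize residue SASA to
  relative solvent accessibility (RSA). RSA is not clamped: an isolated
  residue has no tripeptide neighbors, so values slightly above 1 occur and
  are logged, not truncated.

Classification thresholds (all configurable, defaults in
`PipelineConfig`): a site is kept only where the model is confident
(pLDDT ≥ 65, inclusive) and called **cryptic** when RSA ≤ 0.15
(inclusive). Both boundary conventions are inclusive on the keeping side;
the numerically sensitive cases (pLDDT 64.9 vs 65.0, RSA 0.150 vs 0.1501)
are pinned by tests.

A known discretization limit: the SASA estimator is quantized at about
4πR²/960 ≈ 0.13 Å² per test point, so atoms whose true SASA is a few Å²
cannot converge to 2 % in relative terms when the lattice is refined. The
convergence test therefore allows 2 % relative or ~1 Å² absolute,
whichever is larger. Independent checks: the exact isolated-sphere and
two-sphere spherical-cap closed forms (2 % at 960 points), and agreement
with biotite's independent Shrake-Rupley implementation on fixture
structures.

## Dynamical filtering

A site that is buried in a static model can still be exposed by
thermally activated relative motion of quasi-rigid domains. The filter:

1. **Prune** maximal runs of residues with pLDDT < 65 (loops, linkers,
   disorder) — normal-mode analysis is ill-defined there.
2. **Merge** remaining segments into entries when ≥ 5 inter-segment residue
   pairs have minimal heavy-atom distance ≤ 5 Å (transitive, connected
   components). Pair counting is used because it is the only symmetric,
   well-defined reading of "five residues within 5 Å of one another".
3. **Size gate**: entries with fewer than 40 residues are dropped (inclusive
   at 40) and their candidate sites excluded — short polypeptides do not
   support reliable mode analysis.
4. **Re-filter RSA** on the isolated, pruned entry; sites whose burial
   depended on a removed low-confidence segment now show RSA > 0.15 and are
   excluded as `exposed_after_pruning`.
5. **Quasi-rigid decomposition** (below) and the **Pidc filter**: the
   proportion of intra-domain contacts of a site is the fraction of
   residues within 6 Å of its side-chain heavy atoms that share its domain
   label; sites with Pidc < 0.80 sit on domain boundaries and are excluded
   (0.80 exactly is retained). Sequence-adjacent residues count as
   neighbors. A mapped site with zero spatial neighbors is physically
   impossible for a buried residue and is flagged as a data error rather
   than silently kept.

### Elastic network and decomposition

The elastic network is a β-Gaussian-style model: one node per Cα plus one
per side-chain centroid (mean of side-chain heavy atoms; residues without
side-chain heavy atoms contribute no extra node), uniform springs between
nodes within 7.5 Å. Side-chain degrees of freedom are condensed out by a
Schur complement, giving an effective Cα Hessian whose six-dimensional
rigid-body null space is verified (first six eigenvalues < 1e-8 of the
seventh) before the lowest `n_modes` (default 10) nonzero modes are
retained.

Pairwise distance fluctuations to quadratic order are
σ²_ij = Σ_m λ_m⁻¹ [ê_ij · (v_i^m − v_j^m)]², with mode amplitudes weighted
by inverse eigenvalue (equipartition). Similarity is
s_ij = exp(−σ²_ij/σ̄²) with σ̄ the mean σ over spatially proximal pairs
(Cα distance ≤ the network cutoff). Sequence-adjacent pairs keep a floor
similarity of 0.5: covalently bonded neighbors never decouple completely,
and without the floor a highly flexible segment becomes a near-isolated
graph component that dominates the spectral embedding instead of being
split along its length by the normalized cut.

For each k in 2..k_max (default 10), the rows of the first k eigenvectors
of the normalized Laplacian are length-normalized and clustered by k-means
with 25 seeded restarts; quality(k) is the mean silhouette in that
embedding and the decomposition with the highest quality is used
(ties and flat profiles fall back to the smallest k). Labels are reported
even when quality is low — a single rigid body has no meaningful
subdivision, but its deep-core sites then trivially satisfy the Pidc
filter because their whole neighborhood is co-labelled.

Determinism: identical inputs give identical labels (seeded k-means);
σ is invariant (≤ 1e-8 relative) under rigid-body transforms of the input.

## Conservation scoring

The entropic score of an alignment column is the Shannon entropy of its
symbol frequencies normalized by ln K:
S = −Σ_α p_α ln p_α / ln K ∈ [0, 1].

K is the *fixed alphabet size*, default 22 = 20 amino acids + gap +
pooled ambiguity symbol (B/Z/U/O map to X). A per-column distinct count
would make a fully conserved column's score 0/0; only a fixed K satisfies
both limit cases (identical column → 0, uniform column → 1). The score is
independent of logarithm base (ratio form). Human positions map to columns
by counting non-gap characters of the designated human row (1-based).

Proteome QC uses the standard extreme-outlier rule: organisms whose
completeness score falls strictly below Q1 − 1.5·IQR are dropped;
quartiles use linear interpolation (the common "type 7" convention, stated
explicitly because conventions differ).

Effect size is Cohen's d with the pooled sample standard deviation;
distribution comparisons report group medians, their difference, d and a
two-sided Mann-Whitney U p-value plus a histogram table.

## Mutation cross-referencing

Screen rows are preprocessed by dropping negative screens and collapsing
identical (accession, position, reference, alternate, CDS change) rows
into one record with a sample count, so counts always sum to the number
of positive input rows. Protein changes accept `p.S417E` and bare `S417E`.
A substitution is phosphomimetic iff it replaces S, T or Y with D or E
(the substitution mimics the phosphate's charge and bulk). Cross-referencing
is an inner join on (accession, position) that rejects hits whose reference
residue disagrees with the site's residue. A two-proportion z statistic is
provided for comparing disease-mutation rates between cryptic and
non-cryptic sites.

## Ratchet-and-pawl dynamics and the bias functional

The progress variable is the overlap between instantaneous and native
continuous contact maps,
Q(X) = Σ_{|i−j|>sep_min} [C_ij(native)² − (C_ij(X) − C_ij(native))²],
with the switching function C(r) = (1−(r/r₀)⁶)/(1−(r/r₀)¹⁰) for r < r_c,
6/10 at the removable singularity r = r₀ = 7.5 Å, and 0 for
r ≥ r_c = 12.3 Å (the small ≈ 0.13 step at r_c is accepted as part of the
definition). The ratchet force is
F_i = −k ∇_i Q · (Q − Q_m) when Q < Q_m and zero otherwise, where Q_m is
the running maximum of Q: the system evolves freely whenever it
spontaneously progresses and feels a restoring force only when it
backtracks. ∇Q is analytic (verified against central differences at 1e-5).
The bias functional T = Σ_i (m_i γ_i)⁻¹ ∫ |F_i^B|² dτ is accumulated as a
discrete sum per step; it is exactly zero for unbiased runs and additive
over trajectory segments.

### Scale adaptation for the bead-chain toy

`BiasParams` defaults carry the all-atom constants (k = 1e-4,
sep_min = 35 atomic indices). The bundled simulator is a one-bead-per-
residue Gō-like chain in reduced units (mass = friction = ε = 1), so two
constants are adapted once (`toy_bias_params`): sep_min = 3 bead indices,
and k = 6.0 in reduced units, chosen so the ratchet force stays below the
physical force scale of the toy potential while remaining effective — the
same calibration criterion used at the all-atom scale, where the printed
k applies to a progress variable many orders of magnitude larger.

The toy potential: harmonic bonds (k_bond 50 ε/Ų, b = 3.8 Å), Gaussian
wells of depth 1 ε and width 1 Å at the native distances of all contacts
with |i−j| ≥ 3 closer than 1.5 b in the native state, and a soft r⁻¹²
repulsion between all other non-bonded pairs. Dynamics is overdamped
Langevin (Euler-Maruyama, dt = 0.004 reduced time by default) at
temperature 1.0 ε — above the toy's folding midpoint, so that unbiased
refolding within the default 4000 steps is rare and the ratchet's uplift
is measurable. Unfolded starts come from seeded dynamics at temperature
6.0. Per-frame solvent exposure of the designated core bead uses the same
Shrake-Rupley core on 2.0 Å beads, normalized by the isolated-bead area.

## Synthetic fixtures: what they emulate and what they do not

All fixtures are geometric lattice constructions (3.8 Å spacing), not
physical simulations: ground truth must be exact and cheap.

- **Globule**: a dumbbell of two lobes joined by a thin waist. Core serines/
  threonines at the lobe centers have RSA ≤ 0.10 and survive every filter
  regardless of which k the decomposition picks, because the waist pins
  the domain boundary to the midplane. Surface sites (RSA ≥ 0.3) and
  surface lysines (decoy rows for other PTM classes) sit on the least-
  coordinated boundary points. Optionally a 12-residue pLDDT-50 ring+cap
  loop is packed over one surface serine, burying it until pruning removes
  the loop.
- **Hinge**: two 80-residue bodies facing across a 4.4 Å gap (a narrow
  slit excludes the water probe, so a serine recessed into the gap is
  buried) joined by an elevated zigzag linker; residue numbering ends/
  starts at the linker anchors so chain neighbors are spatial neighbors.
  Truth labels: body membership, with linker residues unlabelled — they
  may legitimately go to either domain.
- **Tables**: PTM rows in the bulk-download dialect (3-line preamble,
  `ACC_ID`/`MOD_RSD`, one malformed row for parser tests), mutation screens
  with duplicates, negative screens and planted phosphomimetic hits, and
  aligned FASTA with conserved/noisy/mixed/gap column categories.
- **ES sets**: Beta-distributed score samples whose medians match the
  buried/exposed medians of the motivating analysis (0.43 vs 0.52,
  planted shift −0.09), used for the recovery check at n = 2000 per group.

Passing these tests shows the machinery is correct on noiseless geometry
with planted truth; it does not show robustness to real-protein features —
irregular packing, partial burial, continuous flexibility spectra,
alignment errors — which have no ground truth at this scale.

## Problem sizes and defaults

The bundled test battery uses 120-residue globules, 168-residue hinges,
five seeds, a 30-bead folding toy and 20 paired folding seeds; the whole
suite runs in about a minute on one CPU. All thresholds default to the
canonical values (RSA 0.15, pLDDT 65, 40 residues, 5 Å / 5 pairs,
Pidc 0.80, ENM cutoff 7.5 Å, 10 modes, k ≤ 10) and are configurable
through `PipelineConfig` or the CLI's JSON config.

## Known limitations

- PDB input is the single-chain AlphaFold dialect only (no altLocs,
  insertion codes, multi-model or multi-chain files); mmCIF is out of scope.
- The decomposition quality score (mean silhouette in the spectral
  embedding) is one reasonable choice among several; the chain-adjacency
  similarity floor (0.5) regularizes floppy segments and its exact value is
  not critical on the fixtures, but has not been tuned against real
  proteins.
- RSA uses whole-residue heavy-atom SASA (not side-chain-only).
- The folding toy makes no claim of physical kJ/mol fidelity; it exercises
  the bias mathematics, not protein energetics.
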