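"""Dynamical and structural refinement of cryptic-site candidates.

A site that looks buried in a static model can still become solvent exposed
through thermally activated relative motion of quasi-rigid protein domains.
This module implements the multi-step filter that removes such
"post-translationally exposed" sites:

1. prune low-confidence segments (pLDDT < 65: loops, linkers, disorder);
2. merge remaining segments into entries when they are in spatial contact
   (at least five inter-segment residue pairs within 5 A);
3. drop entries with fewer than 40 residues (normal-mode analysis is
   unreliable on short polypeptides);
4. recompute RSA on the pruned entries and drop sites now above 0.15;
5. build a beta-Gaussian elastic network (C-alpha nodes plus side-chain
   centroids), extract the low-frequency normal modes, decompose each entry
   into quasi-rigid domains by spectral clustering of the pairwise
   distance-fluctuation matrix, and
6. drop sites whose side chain makes fewer than 80% intra-domain contacts
   (Pidc < 0.80) - these sit on domain boundaries and can be exposed by
   hinge motions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .accessibility import SasaParams, Thresholds, residue_rsa
from .errors import ConfigError, DataError, StateError
from .structio import Residue, SiteRecord, Structure

logger = logging.getLogger(__name__)


@dataclass
class Entry:
    """A pruned/merged sub-structure submitted to dynamical filtering."""

    parent_accession: str
    residues: list[Residue]
    index_map: list[int] = field(default_factory=list)  # entry index -> chain position

    def __post_init__(self) -> None:
        if not self.index_map:
            self.index_map = [r.position for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> set[int]:
        return set(self.index_map)

    def substructure(self) -> Structure:
        return Structure(chain_id="A", residues=self.residues,
                         source_name=f"{self.parent_accession}:entry")

    def residue_at(self, position: int) -> Residue | None:
        for r in self.residues:
            if r.position == position:
                return r
        return None


@dataclass
class Modes:
    """Low-frequency normal modes of an entry's effective C-alpha network."""

    eigenvalues: np.ndarray           # (n_modes,) ascending, nonzero modes only
    eigenvectors: np.ndarray          # (n_res, 3, n_modes) C-alpha displacements
    ca_coords: np.ndarray             # (n_res, 3)
    cutoff: float
    all_eigenvalues: np.ndarray       # full spectrum incl. rigid-body null space


@dataclass
class RigidDecomposition:
    """Quasi-rigid domain labels with per-k quality scores."""

    labels: dict[int, int]            # chain position -> domain id (chosen k)
    quality: dict[int, float]         # k -> mean silhouette in spectral space
    chosen_k: int
    labels_per_k: dict[int, dict[int, int]] = field(default_factory=dict)


@dataclass
class PidcResult:
    """Proportion of a site's spatial neighbors sharing its quasi-rigid domain."""

    position: int
    n_neighbors: int
    n_same_domain: int

    @property
    def pidc(self) -> float:
        return self.n_same_domain / self.n_neighbors


# ---------------------------------------------------------------------------
# pruning / merging / gating
# ---------------------------------------------------------------------------

def prune_low_confidence(structure: Structure, plddt_min: float = 65.0) -> list[list[Residue]]:
    """Maximal runs of consecutive residues with pLDDT >= plddt_min."""
    segments: list[list[Residue]] = []
    current: list[Residue] = []
    for r in structure.residues:
        if r.plddt >= plddt_min:
            current.append(r)
        elif current:
            segments.append(current)
            current = []
    if current:
        segments.append(current)
    return segments


def _min_residue_distances(seg_a: list[Residue], seg_b: list[Residue]) -> np.ndarray:
    """(len_a, len_b) matrix of minimal heavy-atom distances between residues."""
    coords_a = [r.coords() for r in seg_a]
    coords_b = [r.coords() for r in seg_b]
    out = np.empty((len(seg_a), len(seg_b)))
    for i, ca in enumerate(coords_a):
        for j, cb in enumerate(coords_b):
            out[i, j] = cdist(ca, cb).min()
    return out


def merge_entries(segments: list[list[Residue]], parent_accession: str = "",
                  contact_dist: float = 5.0, min_pairs: int = 5) -> list[Entry]:
    """Merge segments that are in spatial contact into single entries.

    Two segments merge when at least ``min_pairs`` inter-segment residue
    pairs have a minimal heavy-atom distance <= ``contact_dist``; merging is
    transitive (connected components of the contact graph).
    """
    if not segments:
        raise DataError("no segments to merge")
    n = len(segments)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            dmat = _min_residue_distances(segments[i], segments[j])
            if int((dmat <= contact_dist).sum()) >= min_pairs:
                adj[i, j] = adj[j, i] = True
    n_comp, comp = connected_components(adj, directed=False)
    entries = []
    for c in range(n_comp):
        residues = [r for k in range(n) if comp[k] == c for r in segments[k]]
        residues.sort(key=lambda r: r.position)
        entries.append(Entry(parent_accession=parent_accession, residues=residues))
    entries.sort(key=lambda e: e.index_map[0])
    return entries


def size_gate(entries: list[Entry], sites: list[SiteRecord] | None = None,
              min_size: int = 40) -> tuple[list[Entry], list[SiteRecord]]:
    """Drop entries with fewer than ``min_size`` residues.

    Cryptic candidates inside dropped entries become ``excluded:small_domain``.
    """
    kept = [e for e in entries if len(e) >= min_size]
    dropped_positions = {p for e in entries if len(e) < min_size for p in e.index_map}
    affected: list[SiteRecord] = []
    for site in sites or []:
        if site.status == "cryptic" and site.position in dropped_positions:
            site.mark("excluded:small_domain")
            affected.append(site)
    return kept, affected


def refilter_rsa(entry: Entry, sites: list[SiteRecord],
                 th: Thresholds | None = None,
                 params: SasaParams | None = None) -> list[SiteRecord]:
    """Recompute RSA on the isolated (pruned) entry and re-apply the burial test.

    A site that was buried only by a since-removed low-confidence segment
    now shows RSA > 0.15 and is excluded as ``exposed_after_pruning``.
    """
    th = th or Thresholds()
    rsa_map = residue_rsa(entry.substructure(), params)
    for site in sites:
        if site.status != "cryptic":
            continue
        if site.position not in entry.positions:
            raise StateError(f"site {site.position} is not part of this entry")
        sasa, rsa = rsa_map[site.position]
        site.sasa, site.rsa = sasa, rsa
        if rsa is not None and rsa > th.rsa_cryptic:
            site.mark("excluded:exposed_after_pruning")
    return sites


# ---------------------------------------------------------------------------
# elastic network modes
# ---------------------------------------------------------------------------

def _entry_nodes(entry: Entry) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha coordinates plus side-chain centroid coordinates.

    Residues without side-chain heavy atoms (Gly, or minimal fixture
    residues) contribute only their C-alpha node.
    """
    ca = []
    sc = []
    for r in entry.residues:
        try:
            ca.append(r.atom("CA").xyz)
        except KeyError as exc:
            raise DataError(f"residue {r.position} lacks a CA atom") from exc
        side = r.side_chain_atoms()
        if side:
            sc.append(np.mean([a.xyz for a in side], axis=0))
    return np.array(ca, dtype=float), (np.array(sc, dtype=float)
                                       if sc else np.empty((0, 3)))


def _anm_hessian(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Uniform-spring anisotropic-network Hessian for nodes within cutoff."""
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    hess = np.zeros((3 * n, 3 * n))
    for a, b in pairs:
        d = coords[a] - coords[b]
        r2 = d @ d
        if r2 < 1e-12:
            continue  # coincident nodes carry no defined spring direction
        block = np.outer(d, d) / r2
        sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
        hess[sa, sa] += block
        hess[sb, sb] += block
        hess[sa, sb] -= block
        hess[sb, sa] -= block
    return hess


def enm_modes(entry: Entry, cutoff: float = 7.5, n_modes: int = 10) -> Modes:
    """Lowest nonzero normal modes of the entry's beta-Gaussian network.

    The network has one node per C-alpha plus one per side-chain centroid,
    with uniform springs between nodes within ``cutoff``.  Side-chain
    degrees of freedom are condensed out (Schur complement), yielding an
    effective C-alpha Hessian whose six-dimensional rigid-body null space is
    verified before the nonzero modes are returned.
    """
    ca, sc = _entry_nodes(entry)
    n_ca = len(ca)
    nodes = np.vstack([ca, sc])
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    if len(pairs):
        adj[pairs[:, 0], pairs[:, 1]] = True
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise DataError(
            f"elastic network disconnected at cutoff {cutoff} A: "
            f"{n_comp} components of sizes {sizes.tolist()}")

    hess = _anm_hessian(nodes, cutoff)
    cc = slice(0, 3 * n_ca)
    ss = slice(3 * n_ca, 3 * len(nodes))
    h_cc = hess[cc, cc]
    if len(sc):
        h_ss = hess[ss, ss]
        h_cs = hess[cc, ss]
        # side-chain nodes have no zero mode of their own: h_ss is positive
        # definite once the network is connected
        h_eff = h_cc - h_cs @ linalg.solve(h_ss, h_cs.T, assume_a="pos")
    else:
        h_eff = h_cc
    h_eff = 0.5 * (h_eff + h_eff.T)
    evals, evecs = linalg.eigh(h_eff)
    if evals[0] < -1e-9 * max(1.0, abs(evals[-1])):
        raise DataError("effective Hessian is not positive semidefinite")
    if n_modes + 6 > 3 * n_ca:
        raise ConfigError("entry too small for the requested number of modes")
    scale = evals[6]
    if scale <= 0 or (evals[:6] > 1e-8 * scale).any():
        logger.warning("rigid-body null space not cleanly separated "
                       "(eigenvalues %s vs 7th %s)", evals[:7], scale)
    sel = slice(6, 6 + n_modes)
    vectors = evecs[:, sel].reshape(n_ca, 3, n_modes)
    return Modes(eigenvalues=evals[sel].copy(), eigenvectors=vectors,
                 ca_coords=ca, cutoff=cutoff, all_eigenvalues=evals)


# ---------------------------------------------------------------------------
# quasi-rigid decomposition
# ---------------------------------------------------------------------------

def distance_fluctuations(modes: Modes) -> np.ndarray:
    """Pairwise fluctuation of inter-residue distances to quadratic order.

    sigma_ij^2 = sum_m (1/lambda_m) [e_ij . (v_i^m - v_j^m)]^2 where e_ij is
    the unit vector between the C-alphas and mode amplitudes scale with the
    inverse eigenvalue (equipartition).
    """
    ca = modes.ca_coords
    n = len(ca)
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, 1.0)
    e = diff / dist[:, :, None]
    sigma2 = np.zeros((n, n))
    for m in range(len(modes.eigenvalues)):
        v = modes.eigenvectors[:, :, m]
        dv = v[:, None, :] - v[None, :, :]
        proj = np.einsum("ijk,ijk->ij", e, dv)
        sigma2 += proj ** 2 / modes.eigenvalues[m]
    np.fill_diagonal(sigma2, 0.0)
    return np.sqrt(sigma2)


#: similarity floor for chain-adjacent residue pairs, keeping the graph
#: connected across flexible segments (a normalized-cut then splits a floppy
#: linker somewhere along its length instead of isolating it)
CHAIN_SIMILARITY_FLOOR = 0.5


def quasi_rigid_decompose(entry: Entry, modes: Modes, k_max: int = 10,
                          seed: int = 0, n_restarts: int = 25) -> RigidDecomposition:
    """Spectral clustering of the distance-fluctuation similarity graph.

    Pairs whose distance fluctuates little are similar
    (s_ij = exp(-sigma_ij^2 / sigma_bar^2), sigma_bar the mean fluctuation
    over spatially proximal pairs); sequence-adjacent pairs keep a floor
    similarity so highly flexible segments stay attached to the graph.
    Normalized-Laplacian embeddings for k = 2..k_max are clustered by seeded
    k-means with ``n_restarts`` restarts, and quality(k) is the mean
    silhouette of residues in the spectral embedding.  Labels are reported
    even when quality is flat (chosen_k falls back to 2).
    """
    n = len(entry)
    if k_max >= n:
        raise ConfigError(f"k_max ({k_max}) must be smaller than the entry size ({n})")
    sigma = distance_fluctuations(modes)
    ca = modes.ca_coords
    dist = cdist(ca, ca)
    proximal = (dist <= modes.cutoff) & ~np.eye(n, dtype=bool)
    sigma_bar = sigma[proximal].mean() if proximal.any() else sigma.mean()
    if sigma_bar <= 0:
        sigma_bar = 1.0
    sim = np.exp(-(sigma / sigma_bar) ** 2)
    positions = np.asarray(entry.index_map)
    adjacent = np.abs(positions[:, None] - positions[None, :]) == 1
    sim = np.where(adjacent, np.maximum(sim, CHAIN_SIMILARITY_FLOOR), sim)
    np.fill_diagonal(sim, 1.0)

    deg = sim.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * sim * d_inv_sqrt[None, :]
    lap = 0.5 * (lap + lap.T)
    evals, evecs = linalg.eigh(lap)

    quality: dict[int, float] = {}
    labels_per_k: dict[int, dict[int, int]] = {}
    for k in range(2, k_max + 1):
        emb = evecs[:, :k]
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        emb = emb / norms
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(emb)
        if len(set(lab)) < 2:
            quality[k] = -1.0
        else:
            quality[k] = float(silhouette_score(emb, lab))
        labels_per_k[k] = {pos: int(l) for pos, l in zip(entry.index_map, lab)}

    best = max(quality.values())
    chosen_k = min(k for k, q in quality.items() if q == best)
    return RigidDecomposition(labels=labels_per_k[chosen_k], quality=quality,
                              chosen_k=chosen_k, labels_per_k=labels_per_k)


def compute_pidc(site: SiteRecord, entry: Entry, decomposition: RigidDecomposition,
                 radius: float = 6.0) -> PidcResult:
    """Proportion of intra-domain contacts around a site's side chain.

    A neighbor is any other entry residue whose heavy atoms come within
    ``radius`` of the site's side-chain heavy atoms.  Zero neighbors is a
    data error: a genuinely buried residue always has spatial contacts.
    """
    residue = entry.residue_at(site.position)
    if residue is None:
        raise StateError(f"site {site.position} is not part of this entry")
    side = residue.side_chain_atoms() or residue.atoms
    side_coords = np.array([a.xyz for a in side])
    own_domain = decomposition.labels[site.position]
    n_neighbors = n_same = 0
    for other in entry.residues:
        if other.position == site.position:
            continue
        if cdist(side_coords, other.coords()).min() <= radius:
            n_neighbors += 1
            if decomposition.labels[other.position] == own_domain:
                n_same += 1
    if n_neighbors == 0:
        raise DataError(f"site {site.position} has no neighbors within {radius} A")
    return PidcResult(position=site.position, n_neighbors=n_neighbors,
                      n_same_domain=n_same)


def apply_dynamic_filter(sites: list[SiteRecord], entry: Entry,
                         decomposition: RigidDecomposition,
                         pidc_min: float = 0.80,
                         radius: float = 6.0) -> dict[int, PidcResult]:
    """Final gate: keep cryptic sites with Pidc >= pidc_min, exclude the rest.

    Sites exactly at the threshold are retained (the rule excludes sites
    making *fewer than* 80% intra-domain contacts).
    """
    results: dict[int, PidcResult] = {}
    for site in sites:
        if site.status != "cryptic" or site.position not in entry.positions:
            continue
        try:
            res = compute_pidc(site, entry, decomposition, radius)
        except DataError:
            site.mark("excluded:no_neighbors")
            continue
        results[site.position] = res
        if res.pidc < pidc_min:
            site.mark("excluded:boundary")
        else:
            site.mark("cryptic")  # reaffirm terminal status
    return results
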