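"""Seeded generators for every input the pipeline consumes, with ground truth.

The fixtures are geometric constructions, not physical simulations: residues
are placed on a 3.8 A cubic lattice so that burial, domain membership and
boundary proximity are exact by construction and cheap to verify.  Each
generator is a pure function of its arguments and seed.

Structures carry minimal residues (CA plus a CB pseudo-side-chain; planted
phosphosites additionally carry their hydroxyl oxygen), which is all the
accessibility and elastic-network machinery needs.

Planted-site labels:

- ``core_cryptic``: deep in a rigid body; must survive the whole pipeline.
- ``surface``: solvent exposed (RSA >= 0.3); classified non-cryptic.
- ``boundary``: buried at the interface between two quasi-rigid bodies;
  must be removed by the intra-domain-contact filter.
- ``low_confidence_occluded``: buried only by a low-confidence loop; must be
  removed when RSA is recomputed after pruning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .folding_bias import ToyChain
from .structio import Atom, Residue, Structure

LATTICE = 3.8  # A, typical C-alpha spacing


@dataclass
class FixtureTruth:
    """Ground truth planted by a generator, verifiable stage by stage."""

    accession: str
    planted_sites: list[tuple[int, str]] = field(default_factory=list)
    domain_labels: dict[int, int] = field(default_factory=dict)  # -1 = linker
    surface_lysines: list[int] = field(default_factory=list)
    low_confidence_positions: list[int] = field(default_factory=list)

    def positions_with(self, label: str) -> list[int]:
        return [pos for pos, lab in self.planted_sites if lab == label]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _residue(position: int, aa: str, ca: np.ndarray, plddt: float,
             cb_dir: np.ndarray | None = None,
             tip_name: str | None = None) -> Residue:
    atoms = [Atom("CA", "C", tuple(np.round(ca, 3)))]
    if cb_dir is not None:
        cb = ca + 1.5 * cb_dir
        atoms.append(Atom("CB", "C", tuple(np.round(cb, 3))))
        if tip_name:
            tip = ca + 2.9 * cb_dir
            atoms.append(Atom(tip_name, "O", tuple(np.round(tip, 3))))
    return Residue(position=position, aa=aa, atoms=atoms, plddt=plddt)


_SITE_TIP = {"S": "OG", "T": "OG1", "Y": "OH"}


def _lattice_blob(n: int, axis_ratio: float = 1.0) -> np.ndarray:
    """n integer lattice points filling a (possibly prolate) ellipsoid,
    ordered lexicographically; returned in Angstrom."""
    r = 6
    grid = np.array([(x, y, z)
                     for x in range(-2 * r, 2 * r + 1)
                     for y in range(-r, r + 1)
                     for z in range(-r, r + 1)])
    norm = np.sqrt((grid[:, 0] / axis_ratio) ** 2 + grid[:, 1] ** 2 + grid[:, 2] ** 2)
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], norm))
    chosen = grid[order[:n]]
    chosen = chosen[np.lexsort((chosen[:, 2], chosen[:, 1], chosen[:, 0]))]
    return chosen.astype(float) * LATTICE


def _dumbbell_blob(n: int, lobe_offset: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """n lattice points forming two lobes joined by a thin waist.

    Returns (coordinates in Angstrom, lobe centers in Angstrom).  The waist
    pins any sensible quasi-rigid bipartition to the midplane, keeping the
    lobe centers far from every domain boundary.
    """
    r = 7
    grid = np.array([(x, y, z)
                     for x in range(-2 * r, 2 * r + 1)
                     for y in range(-r, r + 1)
                     for z in range(-r, r + 1)])
    c1 = np.array([-lobe_offset, 0, 0], dtype=float)
    c2 = np.array([lobe_offset, 0, 0], dtype=float)
    key = np.minimum(np.linalg.norm(grid - c1, axis=1),
                     np.linalg.norm(grid - c2, axis=1))
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], key))
    chosen = grid[order[:n]]
    chosen = chosen[np.lexsort((chosen[:, 2], chosen[:, 1], chosen[:, 0]))]
    return chosen.astype(float) * LATTICE, np.array([c1, c2]) * LATTICE


def _interior_mask(points: np.ndarray) -> np.ndarray:
    """True for points whose six lattice neighbors are all present."""
    cells = {tuple(np.round(p / LATTICE).astype(int)) for p in points}
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        c = np.round(p / LATTICE).astype(int)
        out[i] = all(tuple(c + d) in cells
                     for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)])
    return out


def make_globule_fixture(n_res: int = 120, n_core_sites: int = 2,
                         n_surface_sites: int = 2, seed: int = 0,
                         low_conf_loop: bool = False,
                         accession: str | None = None,
                         ) -> tuple[Structure, FixtureTruth]:
    """A compact dumbbell-shaped globule with planted buried and exposed sites.

    The body consists of two lobes joined by a thin waist, which pins any
    sensible quasi-rigid bipartition to the midplane; core sites sit at the
    lobe centers, far from every plausible domain boundary.  With
    ``low_conf_loop`` a 12-residue pLDDT-50 loop is packed over one
    additional surface serine, burying it until the loop is pruned.
    """
    if n_res < 60:
        raise DataError("globule fixture needs at least 60 residues")
    rng = np.random.default_rng(seed)
    accession = accession or f"SYNG{seed:04d}"
    loop_len = 12 if low_conf_loop else 0
    n_main = n_res - loop_len
    points, lobe_centers = _dumbbell_blob(n_main)
    interior = _interior_mask(points)
    x = points[:, 0]

    # deepest interior point of each lobe, alternating lobes
    interior_idx = np.flatnonzero(interior)
    if len(interior_idx) < n_core_sites:
        raise DataError("cannot place the requested number of core sites")
    core_idx: list[int] = []
    for j in range(n_core_sites):
        center = lobe_centers[j % 2]
        by_depth = interior_idx[np.argsort(
            np.linalg.norm(points[interior_idx] - center, axis=1))]
        pick = next(int(i) for i in by_depth if int(i) not in core_idx)
        core_idx.append(pick)

    boundary_idx = np.flatnonzero(~interior)
    # most exposed first: fewest occupied lattice neighbors
    cells = {tuple(np.round(p / LATTICE).astype(int)) for p in points}
    n_nb = np.array([sum(tuple(np.round(p / LATTICE).astype(int) + d) in cells
                         for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)])
                     for p in points])
    exposed_order = boundary_idx[np.argsort(n_nb[boundary_idx])]
    surface_idx = [int(i) for i in exposed_order[:n_surface_sites]]
    lysine_idx = [int(i) for i in exposed_order[n_surface_sites:n_surface_sites + 4]]

    # loop-occluded site: the boundary point with maximum z near the midplane
    occluded_idx = None
    if low_conf_loop:
        cand = np.flatnonzero(~interior & (np.abs(x) <= 2 * LATTICE))
        occluded_idx = int(cand[np.argmax(points[cand, 2])])

    centroid = points.mean(axis=0)
    residues = []
    truth = FixtureTruth(accession=accession)
    site_letters = ["S", "T", "Y"]
    for i, p in enumerate(points):
        pos = i + 1
        outward = _unit(p - centroid) if np.linalg.norm(p - centroid) > 1e-9 \
            else np.array([0.0, 0.0, 1.0])
        if i in core_idx:
            aa = site_letters[core_idx.index(i) % 3]
            direction = _unit(rng.normal(size=3))
            residues.append(_residue(pos, aa, p, 90.0, direction, _SITE_TIP[aa]))
            truth.planted_sites.append((pos, "core_cryptic"))
        elif i in surface_idx:
            aa = site_letters[surface_idx.index(i) % 3]
            residues.append(_residue(pos, aa, p, 90.0, outward, _SITE_TIP[aa]))
            truth.planted_sites.append((pos, "surface"))
        elif occluded_idx is not None and i == occluded_idx:
            residues.append(_residue(pos, "S", p, 90.0, outward, "OG"))
            truth.planted_sites.append((pos, "low_confidence_occluded"))
        elif i in lysine_idx:
            residues.append(_residue(pos, "K", p, 90.0, outward))
            truth.surface_lysines.append(pos)
        else:
            direction = _unit(rng.normal(size=3))
            residues.append(_residue(pos, "A", p, 90.0, direction))
        truth.domain_labels[pos] = 0

    if low_conf_loop:
        assert occluded_idx is not None
        anchor = points[occluded_idx]
        out_dir = _unit(anchor - centroid)
        # orthonormal frame around the outward normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(out_dir @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(out_dir, helper))
        v = np.cross(out_dir, u)
        offsets = [3.6 * math.cos(t) * u + 3.6 * math.sin(t) * v + 3.2 * out_dir
                   for t in np.linspace(0.0, 2.0 * math.pi, 9)[:-1]]
        offsets += [1.6 * math.cos(t) * u + 1.6 * math.sin(t) * v + 5.6 * out_dir
                    for t in np.linspace(0.0, 2.0 * math.pi, 5)[:-1]]
        for k, off in enumerate(offsets[:loop_len]):
            pos = n_main + k + 1
            residues.append(_residue(pos, "A", anchor + off, 50.0, out_dir))
            truth.low_confidence_positions.append(pos)

    return Structure(chain_id="A", residues=residues, source_name=accession), truth


def make_hinge_fixture(n_per_body: int = 80, linker_len: int = 8, seed: int = 0,
                       gap: float = 4.4, accession: str | None = None,
                       ) -> tuple[Structure, FixtureTruth]:
    """Two compact rigid bodies joined by a flexible elevated linker.

    The bodies face each other across a small gap (a few inter-body elastic
    couplings act as the hinge); ground-truth domain labels are the body
    memberships, with linker residues labelled -1 (they may legitimately go
    to either side).  One serine is planted deep inside body 1
    (``core_cryptic``); another sits on body 1's face toward body 2, buried
    by the opposing body but surrounded by cross-domain neighbors
    (``boundary``).
    """
    if n_per_body < 40:
        raise DataError("each hinge body needs at least 40 residues")
    rng = np.random.default_rng(seed)
    accession = accession or f"SYNH{seed:04d}"
    blob = _lattice_blob(n_per_body, axis_ratio=1.0)
    shift = (blob[:, 0].max() - blob[:, 0].min()) + gap
    top1 = blob[np.argmax(blob[:, 2] - 0.01 * np.abs(blob[:, 0]))]
    # sequence order ends at the linker anchor (body 1) / starts there (body 2),
    # so chain neighbors are also spatial neighbors at the linker junctions
    order1 = np.argsort(-np.linalg.norm(blob - top1, axis=1), kind="stable")
    body1 = blob[order1]
    body2 = blob[order1[::-1]] + np.array([shift, 0.0, 0.0])

    centroid1 = body1.mean(axis=0)
    deep_idx = int(np.argmin(np.linalg.norm(body1 - centroid1, axis=1)))
    face = np.flatnonzero(body1[:, 0] == body1[:, 0].max())
    lateral = np.abs(body1[face, 1]) + np.abs(body1[face, 2])
    iface_idx = int(face[np.argmin(lateral)])

    residues: list[Residue] = []
    truth = FixtureTruth(accession=accession)
    pos = 0
    for i, p in enumerate(body1):
        pos += 1
        if i == deep_idx:
            residues.append(_residue(pos, "S", p, 90.0,
                                     _unit(rng.normal(size=3)), "OG"))
            truth.planted_sites.append((pos, "core_cryptic"))
        elif i == iface_idx:
            # recessed into the inter-body gap, side chain toward body 2
            residues.append(_residue(pos, "S", p + np.array([1.4, 0.0, 0.0]),
                                     90.0, np.array([1.0, 0.0, 0.0]), "OG"))
            truth.planted_sites.append((pos, "boundary"))
        else:
            residues.append(_residue(pos, "A", p, 90.0, _unit(rng.normal(size=3))))
        truth.domain_labels[pos] = 0

    top2 = top1 + np.array([shift, 0.0, 0.0])
    e1 = top1 + np.array([0.0, 0.0, 4.0])
    e2 = top2 + np.array([0.0, 0.0, 4.0])
    for k in range(linker_len):
        pos += 1
        t = (k + 1) / (linker_len + 1)
        p = e1 + t * (e2 - e1)
        p = p + np.array([0.0, 0.9 * (-1) ** k, 2.5 * math.sin(math.pi * t)])
        residues.append(_residue(pos, "G", p, 90.0))
        truth.domain_labels[pos] = -1

    for p in body2:
        pos += 1
        residues.append(_residue(pos, "A", p, 90.0, _unit(rng.normal(size=3))))
        truth.domain_labels[pos] = 1

    return Structure(chain_id="A", residues=residues, source_name=accession), truth


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

PTM_PREAMBLE = ("Synthetic PTM dataset\n"
                "For pipeline testing only\n"
                "\n")


def make_ptm_fixture(structures: list[tuple[Structure, FixtureTruth]],
                     extra_classes: bool = True, seed: int = 0) -> str:
    """PhosphoSitePlus-dialect TSV covering every planted site.

    Adds decoy rows of other PTM classes at surface lysines (to exercise the
    per-class RSA distributions) and exactly one malformed row for parser
    tests.
    """
    lines = ["GENE\tACC_ID\tMOD_RSD"]
    for structure, truth in structures:
        gene = truth.accession.replace("SYN", "GENE")
        for pos, _label in truth.planted_sites:
            residue = structure.residue_at(pos)
            assert residue is not None
            lines.append(f"{gene}\t{truth.accession}\t{residue.aa}{pos}-p")
        if extra_classes:
            for j, pos in enumerate(truth.surface_lysines):
                suffix = ["ub", "ac", "m1", "sm"][j % 4]
                lines.append(f"{gene}\t{truth.accession}\tK{pos}-{suffix}")
    lines.append("BROKEN\tQBROKEN\t??")
    return PTM_PREAMBLE + "\n".join(lines) + "\n"


def make_msa_fixture(n_seq: int = 50, n_col: int = 40,
                     conserved_cols: int = 10, noisy_cols: int = 10,
                     seed: int = 0, n_gap_cols: int = 3,
                     ) -> tuple[str, dict]:
    """Aligned FASTA with per-column conservation ground truth.

    Column categories: ``conserved`` (identical in all rows), ``noisy``
    (uniform over the 20 amino acids), ``gap`` (human row gapped, to
    exercise position mapping), ``mixed`` (two symbols).  Returns the FASTA
    text and a truth dict with the category of each 0-based column and the
    human-position -> column map.
    """
    if n_seq < 10:
        raise DataError("MSA fixture needs at least 10 sequences")
    if conserved_cols + noisy_cols + n_gap_cols > n_col:
        raise DataError("column categories exceed the requested width")
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    cols = []
    categories = []
    order = rng.permutation(n_col)
    cat_of = {}
    for rank, col in enumerate(order):
        if rank < conserved_cols:
            cat_of[col] = "conserved"
        elif rank < conserved_cols + noisy_cols:
            cat_of[col] = "noisy"
        elif rank < conserved_cols + noisy_cols + n_gap_cols:
            cat_of[col] = "gap"
        else:
            cat_of[col] = "mixed"
    for col in range(n_col):
        cat = cat_of[col]
        categories.append(cat)
        if cat == "conserved":
            c = np.full(n_seq, rng.choice(aas))
        elif cat == "noisy":
            c = rng.choice(aas, size=n_seq)
        elif cat == "gap":
            c = rng.choice(aas, size=n_seq)
            c[0] = "-"
        else:
            two = rng.choice(aas, size=2, replace=False)
            c = np.where(rng.random(n_seq) < 0.5, two[0], two[1])
        cols.append(c)
    matrix = np.column_stack(cols)
    ids = ["HUMAN_SYN"] + [f"ORG{i:03d}_SYN" for i in range(1, n_seq)]
    records = []
    for i, sid in enumerate(ids):
        records.append(f">{sid}\n{''.join(matrix[i])}")
    human_cols = [c for c in range(n_col) if categories[c] != "gap"]
    truth = {
        "categories": categories,
        "human_position_to_column": {pos + 1: col
                                     for pos, col in enumerate(human_cols)},
    }
    return "\n".join(records) + "\n", truth


def make_mutation_fixture(cryptic_sites: dict[str, list[tuple[int, str]]],
                          seed: int = 0) -> tuple[str, dict]:
    """COSMIC-like screen rows with planted phosphomimetic hits.

    ``cryptic_sites`` maps accession -> [(position, residue letter)].  The
    table plants 2 phosphomimetic and 3 other substitutions at cryptic
    positions, decoys elsewhere, duplicate positive rows (count collapsing)
    and negative-screen rows that must never be counted.  Returns TSV text
    and the expected summary.
    """
    rng = np.random.default_rng(seed)
    flat = [(acc, pos, aa) for acc, sites in sorted(cryptic_sites.items())
            for pos, aa in sites]
    if len(flat) < 2:
        raise DataError("need at least two cryptic sites to plant hits")
    mimetic_to = {"S": "E", "T": "D", "Y": "E"}
    rows = []

    def add(acc, pos, aa_from, aa_to, screen, annotation, times=1):
        change = f"p.{aa_from}{pos}{aa_to}"
        cds = f"c.{3 * pos - 1}A>G"
        gene = acc.replace("SYN", "GENE")
        for _ in range(times):
            rows.append(f"{acc}\t{gene}\t{change}\t{cds}\t{screen}\t{annotation}")

    picks = [flat[i % len(flat)] for i in range(5)]
    n_mimetic = 0
    for i, (acc, pos, aa) in enumerate(picks):
        if i < 2:
            add(acc, pos, aa, mimetic_to[aa], "positive", "cancer-related",
                times=int(rng.integers(1, 4)))
            n_mimetic += 1
        else:
            alt = "A" if aa != "A" else "G"
            add(acc, pos, aa, alt, "positive", "cancer-related")
    # negative screens at the first cryptic site: must be dropped
    acc0, pos0, aa0 = flat[0]
    add(acc0, pos0, aa0, mimetic_to[aa0], "negative", "cancer-related", times=2)
    # decoys away from any cryptic site
    for j in range(4):
        acc = sorted(cryptic_sites)[j % len(cryptic_sites)]
        taken = {p for p, _ in cryptic_sites[acc]}
        decoy_pos = max(taken) + 100 + j
        add(acc, decoy_pos, "L", "P", "positive", "")
    header = "accession\tgene\tprotein_change\tcds_change\tscreen_status\tannotation"
    unique_hits = {(acc, pos, aa, mimetic_to[aa] if i < 2 else ("A" if aa != "A" else "G"))
                   for i, (acc, pos, aa) in enumerate(picks)}
    truth = {"expected_hits": len(unique_hits), "expected_phosphomimetic": 2}
    return header + "\n" + "\n".join(rows) + "\n", truth


def make_es_sets(n_per_group: int = 2000, median_cryptic: float = 0.43,
                 median_noncryptic: float = 0.52, seed: int = 0,
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Synthetic entropic-score sets with a planted median shift.

    Scores are drawn from Beta distributions whose medians match the
    requested values (buried sites conserved, hence lower ES).  Returns
    (cryptic scores, non-cryptic scores, planted median difference).
    """
    rng = np.random.default_rng(seed)
    nu = 12.0

    def draw(median: float) -> np.ndarray:
        a = median * (nu - 2.0 / 3.0) + 1.0 / 3.0  # median ~ (a-1/3)/(nu-2/3)
        return rng.beta(a, nu - a, size=n_per_group)

    return (draw(median_cryptic), draw(median_noncryptic),
            median_cryptic - median_noncryptic)


def make_toy_chain_native(n_beads: int = 30, seed: int = 0,
                          jitter: float = 0.04) -> ToyChain:
    """Compact self-avoiding bead chain on a lattice, with a core bead.

    The chain snakes through a 3 x 3 x L block (boustrophedon), giving a
    maximally compact native state whose central bead is solvent-buried
    (the toy "cryptic site").  Native contacts are all pairs |i-j| >= 3
    closer than 1.5 bond lengths in the native state.
    """
    if n_beads < 10:
        raise DataError("toy chain needs at least 10 beads")
    layer = []
    for y in range(3):
        xs = range(3) if y % 2 == 0 else range(2, -1, -1)
        layer.extend((x1, y) for x1 in xs)
    n_layers = math.ceil(n_beads / 9)
    cells = []
    for z in range(n_layers):
        seq = layer if z % 2 == 0 else layer[::-1]
        cells.extend((x1, y, z) for x1, y in seq)
    coords = np.array(cells[:n_beads], dtype=float) * LATTICE
    rng = np.random.default_rng(seed)
    coords = coords + jitter * rng.standard_normal(coords.shape)

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    i_idx, j_idx = np.triu_indices(n_beads, k=3)
    close = dist[i_idx, j_idx] < 1.5 * LATTICE
    contacts = np.column_stack([i_idx[close], j_idx[close]])
    contact_d = dist[i_idx[close], j_idx[close]]

    centroid = coords.mean(axis=0)
    core_index = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
    return ToyChain(native_coords=coords, contacts=contacts,
                    contact_distances=contact_d, bond_length=LATTICE,
                    core_index=core_index)
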