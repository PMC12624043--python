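"""Solvent accessibility: Shrake-Rupley SASA, RSA normalization, site mapping.

SASA is computed with the Shrake-Rupley test-point algorithm: each atom is
surrounded by a deterministic golden-spiral lattice of points on its
solvent-expanded sphere (van der Waals radius + probe radius), and the
accessible area is the fraction of points not strictly inside any other
atom's expanded sphere.  RSA divides a residue's summed heavy-atom SASA by
the maximum SASA the same residue type attains in an extended Gly-X-Gly
tripeptide, so 0 means fully buried and values near (or slightly above) 1
mean fully exposed.

A phosphosite (or any PTM site) is called *cryptic* when its RSA is at or
below 0.15 in a confidently modelled region (pLDDT >= 65).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError, StateError
from .structio import SiteRecord, Structure

logger = logging.getLogger(__name__)

#: heavy-atom van der Waals radii, Angstrom
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: Tien et al. (2013) theoretical maximum SASA in an extended GXG tripeptide, A^2
MAX_ASA_GXG = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class SasaParams:
    """Parameters of the Shrake-Rupley computation."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    #: optional 3x3 rotation applied to the test-point lattice (the lattice is
    #: otherwise attached in a fixed global orientation, making output
    #: deterministic and seedless)
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ConfigError("probe_radius must be positive")
        if self.n_sphere_points < 60:
            raise ConfigError("n_sphere_points must be >= 60")


@dataclass
class Thresholds:
    """Classification thresholds: RSA <= rsa_cryptic and pLDDT >= plddt_min."""

    rsa_cryptic: float = 0.15
    plddt_min: float = 65.0

    def __post_init__(self) -> None:
        if not 0 < self.rsa_cryptic < 1:
            raise ConfigError("rsa_cryptic must be in (0, 1)")
        if not 0 <= self.plddt_min <= 100:
            raise ConfigError("plddt_min must be in [0, 100]")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, approximately uniform points on the unit sphere.

    Golden-spiral construction: z descends uniformly while the azimuth
    advances by the golden angle, giving a seedless lattice whose centroid
    is within 0.01 of the origin for n >= 100.
    """
    if n <= 0:
        raise ConfigError("number of sphere points must be positive")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa_of_spheres(coords: np.ndarray, radii: np.ndarray,
                    probe_radius: float = 1.4, n_points: int = 960,
                    orientation: np.ndarray | None = None) -> np.ndarray:
    """Per-sphere solvent-accessible area for arbitrary spheres.

    This is the algorithmic core shared by the all-atom path and the
    coarse-grained bead path.  A test point is occluded iff it lies strictly
    inside another sphere's solvent-expanded radius (points exactly on a
    surface count as exposed, which makes coincident spheres well-defined).
    The point lattice is attached in a fixed global orientation, so output
    is deterministic and invariant (to ~1e-9) under rigid-body transforms.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe_radius
    n_atoms = len(coords)
    unit = sphere_points(n_points)
    if orientation is not None:
        unit = unit @ np.asarray(orientation, dtype=float).T
    areas = np.empty(n_atoms)
    tree = cKDTree(coords)
    max_exp = expanded.max() if n_atoms else 0.0
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        # any occluder satisfies |c_i - c_j| < R_i + R_j
        for j in tree.query_ball_point(coords[i], expanded[i] + max_exp):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 >= expanded[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.sum() / n_points * 4.0 * math.pi * expanded[i] ** 2
    return areas


def shrake_rupley_sasa(structure: Structure,
                       params: SasaParams | None = None) -> dict[tuple[int, str], float]:
    """Per-atom SASA of a structure, keyed by (residue position, atom name)."""
    params = params or SasaParams()
    keys: list[tuple[int, str]] = []
    coords: list[tuple[float, float, float]] = []
    radii: list[float] = []
    for r in structure.residues:
        for a in r.atoms:
            radius = params.radii_table.get(a.element)
            if radius is None:
                raise ConfigError(f"no van der Waals radius configured for element {a.element!r}")
            keys.append((r.position, a.name))
            coords.append(a.xyz)
            radii.append(radius)
    areas = sasa_of_spheres(np.array(coords), np.array(radii),
                            params.probe_radius, params.n_sphere_points,
                            params.orientation)
    return dict(zip(keys, areas.tolist()))


def residue_rsa(structure: Structure, params: SasaParams | None = None,
                table: dict[str, float] | None = None,
                ) -> dict[int, tuple[float, float | None]]:
    """Per-residue (SASA, RSA).  RSA is *not* clamped: an isolated residue has
    no GXG neighbors to occlude it, so values slightly above 1 are possible
    and are logged rather than truncated.  Residues with unknown type (X)
    get RSA None.
    """
    if not structure.residues:
        raise DataError("empty structure")
    table = table or MAX_ASA_GXG
    atom_sasa = shrake_rupley_sasa(structure, params)
    out: dict[int, tuple[float, float | None]] = {}
    for r in structure.residues:
        sasa = sum(atom_sasa[(r.position, a.name)] for a in r.atoms)
        max_asa = table.get(r.aa)
        if max_asa is None:
            logger.warning("residue %d has type %r without a MaxASA entry; RSA undefined",
                           r.position, r.aa)
            out[r.position] = (sasa, None)
            continue
        rsa = sasa / max_asa
        if rsa > 1.0:
            logger.debug("residue %d: RSA %.3f exceeds 1 (sparse context)", r.position, rsa)
        out[r.position] = (sasa, rsa)
    return out


def map_ptm_sites(sites: list[SiteRecord], structure: Structure,
                  params: SasaParams | None = None,
                  table: dict[str, float] | None = None) -> list[SiteRecord]:
    """Attach pLDDT/SASA/RSA to each site; mismatches become per-record exclusions.

    A site whose stated residue letter disagrees with the structure at that
    position is excluded (``excluded:mismatch``); positions outside the chain
    are ``excluded:out_of_range``.  Nothing is fatal: the counts are logged.
    """
    rsa_map = residue_rsa(structure, params, table)
    n_mismatch = n_range = 0
    for site in sites:
        residue = structure.residue_at(site.position)
        if residue is None:
            site.mark("excluded:out_of_range")
            n_range += 1
            continue
        if residue.aa != site.aa:
            site.mark("excluded:mismatch")
            n_mismatch += 1
            continue
        site.plddt = residue.plddt
        site.sasa, site.rsa = rsa_map[site.position]
        site.mark("mapped")
    if n_mismatch or n_range:
        logger.info("map_ptm_sites: %d mismatched, %d out of range of %d sites",
                    n_mismatch, n_range, len(sites))
    return sites


def classify_site(site: SiteRecord, th: Thresholds | None = None) -> SiteRecord:
    """Confidence gate then burial test: cryptic iff pLDDT >= 65 and RSA <= 0.15.

    Both boundaries are inclusive on the keeping side: pLDDT exactly at the
    minimum is kept, RSA exactly at the cutoff is cryptic.
    """
    th = th or Thresholds()
    if site.status != "mapped":
        raise StateError(f"site {site.accession}:{site.position} is {site.status!r}, not mapped")
    if site.plddt is None or site.rsa is None:
        raise StateError("mapped site lacks pLDDT or RSA")
    if site.plddt < th.plddt_min:
        site.mark("excluded:low_confidence")
    elif site.rsa <= th.rsa_cryptic:
        site.mark("cryptic")
    else:
        site.mark("confident")
    return site


def rsa_distribution(sites: list[SiteRecord], bin_width: float = 0.05,
                     rsa_cryptic: float = 0.15) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-PTM-class histogram of RSA plus the buried fraction per class.

    Returns (histogram table with columns ptm_class/bin_lo/bin_hi/count,
    {ptm_class: fraction of sites with RSA <= rsa_cryptic}).
    """
    rows = []
    fractions: dict[str, float] = {}
    with_rsa = [s for s in sites if s.rsa is not None]
    if not with_rsa:
        return pd.DataFrame(columns=["ptm_class", "bin_lo", "bin_hi", "count"]), {}
    classes = sorted({s.ptm_class for s in with_rsa})
    max_rsa = max(s.rsa for s in with_rsa)
    n_bins = max(1, math.ceil(max_rsa / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    for cls in classes:
        values = np.array([s.rsa for s in with_rsa if s.ptm_class == cls])
        counts, _ = np.histogram(values, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"ptm_class": cls, "bin_lo": round(float(lo), 10),
                         "bin_hi": round(float(hi), 10), "count": int(c)})
        fractions[cls] = float((values <= rsa_cryptic).mean())
    return pd.DataFrame(rows), fractions
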