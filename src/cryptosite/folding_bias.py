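"""Ratchet-and-pawl biased dynamics and the bias-functional score.

The progress variable Q(X) measures the overlap between the instantaneous
and the native continuous contact map,

    Q(X) = sum_{|i-j| > sep_min} [ C_ij(native)^2 - (C_ij(X) - C_ij(native))^2 ],

where C_ij is a switching function of the pair distance that interpolates
smoothly from 1 (in contact) to 0 (beyond a cutoff).  The ratchet applies a
restoring force only when the system backtracks below the best progress
Q_m reached so far,

    F_i = -k grad_i Q (Q - Q_m)   if Q < Q_m,  else 0,

so the dynamics is plain (unbiased) whenever it spontaneously progresses.
The bias-functional score

    T = sum_i 1/(m_i gamma_i) integral |F_i^B|^2 dtau

accumulates the squared bias work along a trajectory; smaller T means a
less-biased, more realistic path, and T = 0 exactly for unbiased runs.

The module exercises this machinery with an overdamped Langevin simulator
of a Go-like bead chain (harmonic bonds, native-contact attractions, soft
excluded volume) whose native state buries a designated "cryptic" bead.
All quantities are in reduced units (bead mass = friction = thermal energy
scale = 1); the contact-map length constants keep their Angstrom values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accessibility import sasa_of_spheres
from .errors import ConfigError, DataError

#: default bead radius for coarse-grained solvent accessibility, Angstrom
BEAD_RADIUS = 2.0


@dataclass
class BiasParams:
    """Constants of the bias: strength k, switching radii, index separation.

    The defaults are the all-atom-scale values (k in reduced energy units,
    r0 = 7.5 A, rc = 12.3 A, |i-j| > 35); the one-bead-per-residue toy uses
    a smaller index separation and a rescaled k (see ``toy_bias_params``).
    """

    k: float = 1.0e-4
    r0: float = 7.5
    rc: float = 12.3
    sep_min: int = 35
    mass: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError("bias strength k must be nonnegative")
        if not 0 < self.r0 < self.rc:
            raise ConfigError("switching radii must satisfy 0 < r0 < rc")
        if self.sep_min < 1:
            raise ConfigError("sep_min must be >= 1")


def toy_bias_params(k: float = 6.0, sep_min: int = 3, **kwargs) -> BiasParams:
    """Bias constants adapted to the one-bead-per-residue scale.

    ``sep_min`` counts bead (residue) indices instead of atom indices, and k
    is rescaled so the bias force stays about an order of magnitude below
    the physical forces of the toy potential.
    """
    return BiasParams(k=k, sep_min=sep_min, **kwargs)


# ---------------------------------------------------------------------------
# switching function and contact-map progress variable
# ---------------------------------------------------------------------------

def switching_value(r, p: BiasParams):
    """Smooth contact indicator: (1-(r/r0)^6)/(1-(r/r0)^10), 6/10 at r = r0,
    0 for r >= rc.  Accepts scalars or arrays."""
    r = np.asarray(r, dtype=float)
    x = r / p.r0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (1.0 - x ** 6) / (1.0 - x ** 10)
    h = x - 1.0
    near = np.abs(h) < 1e-6
    series = 0.6 - 1.2 * h + 0.2 * h * h  # removable singularity at r0
    out = np.where(near, series, raw)
    out = np.where(r >= p.rc, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def switching_derivative(r, p: BiasParams):
    """dC/dr of the switching function (0 beyond rc, finite at r0)."""
    r = np.asarray(r, dtype=float)
    x = r / p.r0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 1.0 - x ** 10
        raw = (-6 * x ** 5 * g + 10 * x ** 9 * (1.0 - x ** 6)) / (g * g)
    h = x - 1.0
    near = np.abs(h) < 1e-4
    series = -1.2 + 0.4 * h
    out = np.where(near, series, raw) / p.r0
    out = np.where(r >= p.rc, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class NativeMap:
    """Native contact map restricted to pairs with |i-j| > sep_min."""

    i_idx: np.ndarray
    j_idx: np.ndarray
    c_nat: np.ndarray
    n_particles: int

    @property
    def q_nat(self) -> float:
        """Progress value of the native configuration itself."""
        return float((self.c_nat ** 2).sum())


def native_contact_map(native_coords: np.ndarray, p: BiasParams) -> NativeMap:
    coords = np.asarray(native_coords, dtype=float)
    n = len(coords)
    i_idx, j_idx = np.triu_indices(n, k=p.sep_min + 1)
    d = np.linalg.norm(coords[i_idx] - coords[j_idx], axis=1)
    return NativeMap(i_idx=i_idx, j_idx=j_idx,
                     c_nat=np.asarray(switching_value(d, p)), n_particles=n)


def progress_Q(X: np.ndarray, native_map: NativeMap, p: BiasParams) -> float:
    """Contact-map overlap with the native state (larger = more native)."""
    X = np.asarray(X, dtype=float)
    if len(X) != native_map.n_particles:
        raise DataError("configuration and native map have different particle counts")
    d = np.linalg.norm(X[native_map.i_idx] - X[native_map.j_idx], axis=1)
    c = switching_value(d, p)
    return float((native_map.c_nat ** 2 - (c - native_map.c_nat) ** 2).sum())


def grad_Q(X: np.ndarray, native_map: NativeMap, p: BiasParams) -> np.ndarray:
    """Analytic gradient of Q with respect to every particle coordinate."""
    X = np.asarray(X, dtype=float)
    diff = X[native_map.i_idx] - X[native_map.j_idx]
    d = np.linalg.norm(diff, axis=1)
    d = np.maximum(d, 1e-12)
    c = switching_value(d, p)
    dc = switching_derivative(d, p)
    # dQ/dr for each pair: -2 (C - C_nat) dC/dr
    coeff = -2.0 * (c - native_map.c_nat) * dc / d
    contrib = coeff[:, None] * diff
    grad = np.zeros_like(X)
    np.add.at(grad, native_map.i_idx, contrib)
    np.add.at(grad, native_map.j_idx, -contrib)
    return grad


def bias_force(X: np.ndarray, native_map: NativeMap, Q: float, Q_m: float,
               p: BiasParams) -> tuple[np.ndarray, float]:
    """Ratchet force and updated running maximum.

    Returns (per-particle force array, new Q_m).  The force vanishes both
    when the system has just matched its best progress (Q = Q_m) and when it
    spontaneously progresses beyond it (Q > Q_m, which updates Q_m).
    """
    if Q >= Q_m:
        return np.zeros_like(np.asarray(X, dtype=float)), float(Q)
    force = -p.k * grad_Q(X, native_map, p) * (Q - Q_m)
    return force, float(Q_m)


def bias_score_T(bias_forces: list[np.ndarray] | np.ndarray, dt: float,
                 p: BiasParams) -> float:
    """Discretized bias functional: sum of squared bias forces over time."""
    total = 0.0
    for f in bias_forces:
        f = np.asarray(f, dtype=float)
        total += float((f ** 2).sum())
    return total * dt / (p.mass * p.gamma)


# ---------------------------------------------------------------------------
# Go-like toy chain
# ---------------------------------------------------------------------------

@dataclass
class ToyChain:
    """A coarse-grained bead chain with a Go-like native-centric potential."""

    native_coords: np.ndarray                 # (n, 3)
    contacts: np.ndarray                      # (m, 2) int pairs |i-j| >= 3
    contact_distances: np.ndarray             # (m,) native distances
    bond_length: float = 3.8
    core_index: int = 0                       # the designated cryptic bead

    @property
    def n_beads(self) -> int:
        return len(self.native_coords)


@dataclass
class ToyPotential:
    """Force-field constants of the toy chain, reduced units."""

    k_bond: float = 50.0
    eps_contact: float = 1.0
    eps_rep: float = 1.0
    sigma_rep: float = 3.8
    well_width: float = 1.0


def toy_forces(X: np.ndarray, chain: ToyChain,
               pot: ToyPotential) -> tuple[np.ndarray, float]:
    """Physical forces and potential energy of the toy chain."""
    n = chain.n_beads
    force = np.zeros_like(X)
    energy = 0.0
    # bonds
    dvec = X[1:] - X[:-1]
    d = np.linalg.norm(dvec, axis=1)
    d = np.maximum(d, 1e-9)
    stretch = d - chain.bond_length
    energy += float(pot.k_bond * (stretch ** 2).sum())
    fpair = (-2.0 * pot.k_bond * stretch / d)[:, None] * dvec
    force[1:] += fpair
    force[:-1] -= fpair
    # native contacts: Gaussian wells at the native distances
    ci, cj = chain.contacts[:, 0], chain.contacts[:, 1]
    dvec = X[ci] - X[cj]
    d = np.maximum(np.linalg.norm(dvec, axis=1), 1e-9)
    dev = d - chain.contact_distances
    w2 = pot.well_width ** 2
    gauss = np.exp(-dev ** 2 / (2 * w2))
    energy += float((-pot.eps_contact * gauss).sum())
    fmag = -pot.eps_contact * gauss * dev / w2  # -dU/dr
    fpair = (fmag / d)[:, None] * dvec
    np.add.at(force, ci, fpair)
    np.add.at(force, cj, -fpair)
    # soft repulsion between non-bonded, non-native pairs (cached on the chain)
    rep = getattr(chain, "_rep_pairs", None)
    if rep is None:
        ri, rj = np.triu_indices(n, k=2)
        native = set(map(tuple, np.sort(chain.contacts, axis=1)))
        mask = np.array([(a, b) not in native for a, b in zip(ri, rj)])
        rep = (ri[mask], rj[mask])
        object.__setattr__(chain, "_rep_pairs", rep)
    ri, rj = rep
    dvec = X[ri] - X[rj]
    d = np.maximum(np.linalg.norm(dvec, axis=1), 0.3 * pot.sigma_rep)
    close = d < 2.5 * pot.sigma_rep
    if close.any():
        dc = d[close]
        inv = (pot.sigma_rep / dc) ** 12
        energy += float((pot.eps_rep * inv).sum())
        fmag = 12.0 * pot.eps_rep * inv / dc
        fpair = (fmag / dc)[:, None] * dvec[close]
        np.add.at(force, ri[close], fpair)
        np.add.at(force, rj[close], -fpair)
    return force, energy


@dataclass
class ToyTrajectory:
    """Output of a ratchet run: frames, progress series, bias score."""

    frames: np.ndarray            # (n_frames, n_beads, 3)
    frame_steps: np.ndarray       # (n_frames,) step index of each frame
    q_series: np.ndarray          # (n_steps + 1,) Q at every step
    q_m_series: np.ndarray        # (n_steps + 1,) running maximum
    T: float                      # accumulated bias-functional score
    q_nat: float


def run_toy_ratchet(chain: ToyChain, start_config: np.ndarray,
                    p: BiasParams | None = None, n_steps: int = 4000,
                    temperature: float = 1.0, seed: int = 0,
                    dt: float = 0.004, record_every: int = 50,
                    potential: ToyPotential | None = None) -> ToyTrajectory:
    """Overdamped Langevin dynamics of the toy chain with the ratchet bias.

    With p.k = 0 this is plain dynamics and T = 0 exactly.  Identical
    arguments and seed give a bitwise-identical Q series.
    """
    p = p or toy_bias_params()
    pot = potential or ToyPotential()
    rng = np.random.default_rng(seed)
    X = np.array(start_config, dtype=float, copy=True)
    if X.shape != chain.native_coords.shape:
        raise DataError("start configuration does not match the chain size")
    native_map = native_contact_map(chain.native_coords, p)
    mobility = dt / (p.mass * p.gamma)
    noise_scale = np.sqrt(2.0 * temperature * mobility)

    q = progress_Q(X, native_map, p)
    q_m = q
    q_series = [q]
    q_m_series = [q_m]
    frames = [X.copy()]
    frame_steps = [0]
    t_score = 0.0

    for step in range(1, n_steps + 1):
        f_phys, energy = toy_forces(X, chain, pot)
        if not np.isfinite(energy) or abs(energy) > 1e8:
            raise DataError("timestep instability: energy diverged; reduce dt")
        if p.k > 0:
            f_bias, q_m = bias_force(X, native_map, q, q_m, p)
            t_score += float((f_bias ** 2).sum()) * dt / (p.mass * p.gamma)
        else:
            f_bias = 0.0
            q_m = max(q_m, q)
        X = X + (f_phys + f_bias) * mobility \
            + noise_scale * rng.standard_normal(X.shape)
        q = progress_Q(X, native_map, p)
        q_series.append(q)
        q_m_series.append(q_m)
        if step % record_every == 0 or step == n_steps:
            frames.append(X.copy())
            frame_steps.append(step)

    return ToyTrajectory(frames=np.array(frames), frame_steps=np.array(frame_steps),
                         q_series=np.array(q_series), q_m_series=np.array(q_m_series),
                         T=t_score, q_nat=native_map.q_nat)


def thermal_unfold(chain: ToyChain, seed: int, n_steps: int = 4000,
                   temperature: float = 6.0, dt: float = 0.002,
                   potential: ToyPotential | None = None) -> np.ndarray:
    """Generate an unfolded start configuration by high-temperature dynamics."""
    traj = run_toy_ratchet(chain, chain.native_coords,
                           p=BiasParams(k=0.0, sep_min=3), n_steps=n_steps,
                           temperature=temperature, seed=seed, dt=dt,
                           record_every=n_steps, potential=potential)
    return traj.frames[-1]


def exposure_along_path(frames: np.ndarray, site_index: int,
                        bead_radius: float = BEAD_RADIUS,
                        probe_radius: float = 1.4,
                        n_points: int = 240) -> np.ndarray:
    """Bead-level RSA of the designated site for every frame.

    The bead SASA is normalized by the area of an isolated bead, so an
    unoccluded site scores 1 and a fully buried one 0.
    """
    frames = np.asarray(frames, dtype=float)
    n_beads = frames.shape[1]
    if not 0 <= site_index < n_beads:
        raise DataError(f"site index {site_index} outside chain of {n_beads} beads")
    radii = np.full(n_beads, bead_radius)
    iso_area = 4.0 * np.pi * (bead_radius + probe_radius) ** 2
    out = np.empty(len(frames))
    for t, frame in enumerate(frames):
        areas = sasa_of_spheres(frame, radii, probe_radius, n_points)
        out[t] = areas[site_index] / iso_area
    return out


def exposure_histogram(q_values: np.ndarray, rsa_values: np.ndarray,
                       q_bins: int = 10, rsa_bins: int = 10):
    """Joint (Q, RSA) occupancy table along a transition path."""
    import pandas as pd

    q_values = np.asarray(q_values, dtype=float)
    rsa_values = np.asarray(rsa_values, dtype=float)
    counts, q_edges, r_edges = np.histogram2d(q_values, rsa_values,
                                              bins=[q_bins, rsa_bins])
    rows = []
    for a in range(q_bins):
        for b in range(rsa_bins):
            if counts[a, b]:
                rows.append({"q_lo": q_edges[a], "q_hi": q_edges[a + 1],
                             "rsa_lo": r_edges[b], "rsa_hi": r_edges[b + 1],
                             "count": int(counts[a, b])})
    return pd.DataFrame(rows)
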