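"""Canonical and grand-canonical Metropolis Monte Carlo for CF1 water.

The system is a periodic cubic box of charged O and H sites (number ratio
1:2).  Canonical sampling uses single-site displacements (uniform in a
cube of half-width ``max_disp``); grand-canonical sampling alternates one
displacement attempt with one attempt to insert or remove a whole water
molecule (one O plus two H placed in the admissible geometry windows
0.875 <= r_OH/Å <= 1.075 and 1.3 <= r_HH/Å <= 1.7).

Insertion/deletion acceptance uses

    Y(N -> N+1) = exp(B - beta dU) / ((N_O+1)(N_H+1)(N_H+2)),
    B = beta mu + 3 ln( L^3 / (Lambda_H^2 Lambda_O) ),

with thermal de Broglie wavelengths Lambda_i = h/sqrt(2 pi m_i k_B T).
Deletion removes a random oxygen together with its two nearest hydrogens
and is accepted with min[1, 1/Y] evaluated for the reverse insertion.

Energies are cached and updated incrementally (tabulated short-range +
erfc real-space term; reciprocal-space via structure factors); a full
refresh is performed periodically to bound floating-point drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, ewald
from .model import (
    CF1Parameters,
    R_GAS_KJ,
    N_AVOGADRO,
    WATER_MOLAR_MASS,
    thermal_wavelength,
)
from .ewald import EwaldParameters

__all__ = [
    "ParticleConfiguration",
    "GCMCParameters",
    "MCState",
    "SampleStream",
    "factorial_ratio",
    "b_parameter",
    "displacement_step",
    "gcmc_insert_attempt",
    "gcmc_delete_attempt",
    "run_cmc",
    "run_gcmc",
    "mass_density",
]

# GCMC insertion geometry windows (Å), as printed
R_OH_WINDOW = (0.875, 1.075)
R_HH_WINDOW = (1.3, 1.7)


def mass_density(n_molecules: int, box_length: float) -> float:
    """Mass density in g/mL of n water molecules in a cubic box (Å)."""
    v_ml = box_length**3 * 1e-24
    return n_molecules * WATER_MOLAR_MASS / N_AVOGADRO / v_ml


@dataclass
class ParticleConfiguration:
    """Coordinates and species of all O/H sites in a periodic cubic box.

    ``species`` uses integer codes 0 = O, 1 = H.  The hydrogen count must
    be exactly twice the oxygen count and every coordinate lies in [0, L).
    """

    box_length: float
    positions: np.ndarray
    species: np.ndarray

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.species.shape[0] != self.positions.shape[0]:
            raise ValueError("species and positions length mismatch")
        if self.n_H != 2 * self.n_O:
            raise ValueError("require N_H = 2 N_O (water stoichiometry)")
        self.positions %= self.box_length

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_O(self) -> int:
        return int(np.sum(self.species == 0))

    @property
    def n_H(self) -> int:
        return int(np.sum(self.species == 1))

    @property
    def n_molecules(self) -> int:
        return self.n_O

    @property
    def charges(self) -> np.ndarray:
        """Per-site charges in e0 (default CF1 parameterization)."""
        m = CF1Parameters()
        return np.where(self.species == 0, m.q_O, m.q_H)

    @property
    def density(self) -> float:
        """Mass density in g/mL."""
        return mass_density(self.n_molecules, self.box_length)

    @classmethod
    def random_molecular(cls, n_molecules: int, box_length: float,
                         rng: np.random.Generator,
                         min_oo_sep: float = 2.4, min_oh_sep: float = 1.5,
                         min_hh_sep: float = 1.2,
                         max_tries: int = 5000) -> "ParticleConfiguration":
        """Pre-formed H2O triplets at random positions and orientations.

        Each molecule (O plus two H drawn from the admissible
        insertion-geometry windows) is accepted only when all its sites
        clear exclusion distances against previously placed molecules
        (foreign O-O, O-H and H-H); the exclusions relax gradually when
        the box is too dense to satisfy them.  Keeping foreign O...H
        above ~1.5 Å avoids seeding shared-hydrogen defects that anneal
        out extremely slowly under small-step Metropolis sampling; the
        equilibrium ensemble is unaffected by the initializer.
        """
        L = float(box_length)
        pos = np.empty((3 * n_molecules, 3))
        species = np.empty(3 * n_molecules, dtype=np.int8)
        sep = np.array([min_oo_sep, min_oh_sep, min_hh_sep])
        placed = 0  # molecules placed
        tries = 0
        while placed < n_molecules:
            tries += 1
            if tries > max_tries:
                sep = sep * 0.9  # too dense for current exclusions
                tries = 0
            o = rng.random(3) * L
            try:
                h1, h2 = _sample_h_pair(o, L, rng)
            except RuntimeError:
                continue
            cand = np.vstack([o, h1, h2]) % L
            if placed:
                prev = pos[: 3 * placed]
                prev_sp = species[: 3 * placed]
                d = prev[:, None, :] - cand[None, :, :]
                d -= L * np.round(d / L)
                dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
                # pair class: 0 OO, 1 OH, 2 HH from species sums
                cls_idx = prev_sp[:, None] + np.array([0, 1, 1])[None, :]
                if np.any(dist < sep[cls_idx]):
                    continue
            pos[3 * placed: 3 * placed + 3] = cand
            species[3 * placed: 3 * placed + 3] = (0, 1, 1)
            placed += 1
            tries = 0
        return cls(L, pos, species)

    @classmethod
    def random_atomic(cls, n_molecules: int, box_length: float,
                      rng: np.random.Generator,
                      min_sep: float = 0.6) -> "ParticleConfiguration":
        """Fully random insertion of 3N independent sites (with a small
        hard-core exclusion to avoid numerically absurd overlaps)."""
        L = float(box_length)
        n = 3 * n_molecules
        pos = np.empty((n, 3))
        placed = 0
        while placed < n:
            cand = rng.random(3) * L
            if placed:
                d = pos[:placed] - cand
                d -= L * np.round(d / L)
                if np.min(np.einsum("ij,ij->i", d, d)) < min_sep * min_sep:
                    continue
            pos[placed] = cand
            placed += 1
        species = np.zeros(n, dtype=np.int8)
        species[n_molecules:] = 1
        return cls(L, pos, species)


def _sample_h_pair(o_pos, L, rng, max_retry: int = 200):
    lo, hi = R_OH_WINDOW
    hlo, hhi = R_HH_WINDOW
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    h1 = o_pos + (lo + rng.random() * (hi - lo)) * u
    for _ in range(max_retry):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        h2 = o_pos + (lo + rng.random() * (hi - lo)) * v
        d = h1 - h2
        d -= L * np.round(d / L)
        dd = math.sqrt(float(d @ d))
        if hlo <= dd <= hhi:
            return h1, h2
    raise RuntimeError("H-pair geometry sampling failed")


def factorial_ratio(n_O: int, n_H: int) -> float:
    """N_O! N_H! / ((N_O+1)! (N_H+2)!) in closed form.

    This is the prefactor of the insertion acceptance Y(N -> N+1); the
    closed form 1/((N_O+1)(N_H+1)(N_H+2)) avoids large factorials.
    """
    if n_O < 0 or n_H < 0:
        raise ValueError("site counts must be non-negative")
    if n_H != 2 * n_O:
        raise ValueError("require N_H = 2 N_O")
    return 1.0 / ((n_O + 1.0) * (n_H + 1.0) * (n_H + 2.0))


def b_parameter(mu: float, T: float, L: float,
                m_H: float = 1.008, m_O: float = 15.999) -> float:
    """Dimensionless activity parameter B = beta*mu + 3 ln(L^3/(Λ_H^2 Λ_O)).

    ``mu`` in kJ/mol, ``T`` in K, ``L`` in Å, masses in u.
    """
    if T <= 0 or L <= 0:
        raise ValueError("T and L must be positive")
    beta = 1.0 / (R_GAS_KJ * T)
    lam_h = thermal_wavelength(m_H, T)
    lam_o = thermal_wavelength(m_O, T)
    return beta * mu + 3.0 * math.log(L**3 / (lam_h**2 * lam_o))


@dataclass(frozen=True)
class GCMCParameters:
    """Chemical potential, temperature and derived activity for GCMC."""

    mu: float  # kJ/mol
    T: float  # K
    L: float  # Å
    m_H: float = 1.008
    m_O: float = 15.999
    r_oh_window: tuple = R_OH_WINDOW
    r_hh_window: tuple = R_HH_WINDOW
    max_geometry_retries: int = 100
    B_override: float | None = None  # pin B directly (reference tests)

    @property
    def B(self) -> float:
        if self.B_override is not None:
            return self.B_override
        return b_parameter(self.mu, self.T, self.L, self.m_H, self.m_O)


class CF1Energy:
    """Cached CF1 total-energy machinery for one box size.

    total = (tabulated short-range + erfc real-space Coulomb over minimum
    images) + reciprocal Ewald + self-energy.  The tables combine the
    non-Coulomb CF1 terms with the screened real-space term so the hot
    loop does a single lookup per pair.
    """

    def __init__(self, box_length: float,
                 model: CF1Parameters | None = None,
                 ewald_params: EwaldParameters | None = None,
                 table_dr: float = 5e-5, table_r_floor: float = 0.28,
                 check_screening: bool = False):
        from scipy.special import erfc as _erfc

        self.model = model or CF1Parameters()
        self.ewald_params = ewald_params or EwaldParameters()
        self.L = float(box_length)
        self.alpha = self.ewald_params.resolved_alpha(self.L)
        self.r_cut = self.ewald_params.resolved_r_cut(self.L)
        if check_screening:
            self.ewald_params.check_screening(self.L)
        self.kmax = self.ewald_params.k_cutoff
        self.kn, self.Ak = ewald.build_kvectors(self.L, self.ewald_params,
                                                self.model)
        # pair-type tables: index 0 = OO, 1 = OH, 2 = HH
        ntab = int(self.r_cut / table_dr) + 2
        r = np.arange(ntab) * table_dr
        r_eval = np.maximum(r, table_r_floor)
        m = self.model
        k_kj = m.coulomb_constant_kj
        utab = np.empty((3, ntab))
        charges = {0: m.q_O, 1: m.q_H}
        pairs = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for p, (si, sj) in pairs.items():
            u_nc = (m.pair_potential_kcal(si, sj, r_eval)
                    - m.coulomb_coefficient_kcal(si, sj) / r_eval) * m.kcal_to_kJ
            u_scr = (k_kj * charges[si] * charges[sj]
                     * _erfc(self.alpha * r_eval) / r_eval)
            u = u_nc + u_scr
            # repulsive linear ramp below the floor keeps energies finite
            core = r < table_r_floor
            u[core] += 1e4 * (table_r_floor - r[core])
            utab[p] = u
        self.utab = utab
        self.inv_dr = 1.0 / table_dr
        self.rcut2 = self.r_cut**2
        # self-energy per unit charge^2 and per molecule
        self._self_coef = -k_kj * self.alpha / math.sqrt(math.pi)
        self.dself_mol = self._self_coef * (m.q_O**2 + 2 * m.q_H**2)

    def charges_for(self, species: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(species) == 0, self.model.q_O, self.model.q_H)

    def total_energy(self, pos, species, qs, n) -> tuple:
        """(U_total, S_k) recomputed from scratch."""
        e_sr = _kernels.total_sr_energy(pos, species, n, self.L, self.utab,
                                        self.inv_dr, self.rcut2)
        Sk = np.zeros(self.kn.shape[0], dtype=np.complex128)
        _kernels.structure_factors(pos, qs, n, self.L, self.kn, self.kmax, Sk)
        e_rec = _kernels.recip_energy(Sk, self.Ak)
        e_self = self._self_coef * float(np.sum(qs[:n] ** 2))
        return e_sr + e_rec + e_self, Sk


@dataclass
class MCState:
    """Mutable Monte Carlo state: configuration + cached energy + counters.

    Capacity arrays allow GCMC particle-number changes without realloc.
    ``energy_kind`` is 'cf1' (full model), 'ideal' (all interactions zero)
    or 'custom' (an object with ``delta_displacement(state, i, new_pos)``).
    """

    box_length: float
    positions: np.ndarray  # capacity x 3
    species: np.ndarray  # capacity
    charges_arr: np.ndarray  # capacity
    n_sites: int
    T: float
    seed: int
    energy_kind: str = "cf1"
    energy: object | None = None
    total_energy: float = 0.0
    Sk: np.ndarray | None = None
    counters: dict = field(default_factory=lambda: {
        "disp_attempted": 0, "disp_accepted": 0,
        "insert_attempted": 0, "insert_accepted": 0,
        "delete_attempted": 0, "delete_accepted": 0,
        "geometry_failures": 0,
    })
    steps_since_refresh: int = 0
    refresh_interval: int = 1_000_000
    py_rng: np.random.Generator | None = None

    @property
    def beta(self) -> float:
        return 1.0 / (R_GAS_KJ * self.T) if self.T > 0 else 0.0

    @property
    def n_O(self) -> int:
        return int(np.sum(self.species[: self.n_sites] == 0))

    @property
    def n_H(self) -> int:
        return int(np.sum(self.species[: self.n_sites] == 1))

    @property
    def n_molecules(self) -> int:
        return self.n_O

    @property
    def density(self) -> float:
        return mass_density(self.n_molecules, self.box_length)

    @property
    def configuration(self) -> ParticleConfiguration:
        n = self.n_sites
        return ParticleConfiguration(self.box_length,
                                     self.positions[:n].copy(),
                                     self.species[:n].copy())

    @classmethod
    def create(cls, config: ParticleConfiguration, T: float, seed: int,
               energy: str | object = "cf1",
               model: CF1Parameters | None = None,
               ewald_params: EwaldParameters | None = None,
               capacity: int | None = None,
               beta_override: float | None = None) -> "MCState":
        if T <= 0:
            raise ValueError("temperature must be positive")
        n = config.n_sites
        if capacity is None:
            # room for ~3 g/mL worth of molecules, GCMC never plausibly more
            n_max_mol = int(3.0 * config.box_length**3 * 1e-24
                            * N_AVOGADRO / WATER_MOLAR_MASS) + 8
            capacity = max(3 * n_max_mol, n + 30)
        pos = np.zeros((capacity, 3))
        sp = np.zeros(capacity, dtype=np.int8)
        pos[:n] = config.positions
        sp[:n] = config.species
        state = cls(box_length=config.box_length, positions=pos, species=sp,
                    charges_arr=np.zeros(capacity), n_sites=n, T=T, seed=seed)
        if beta_override is not None:
            state._beta_override = beta_override
        if isinstance(energy, str):
            state.energy_kind = energy
            if energy == "cf1":
                state.energy = CF1Energy(config.box_length, model, ewald_params)
            elif energy == "ideal":
                state.energy = None
            else:
                raise ValueError(f"unknown energy kind {energy!r}")
        else:
            state.energy_kind = "custom"
            state.energy = energy
        if state.energy_kind == "cf1":
            state.charges_arr[:n] = state.energy.charges_for(sp[:n])
        state.py_rng = np.random.default_rng(seed)
        _kernels.seed_rng(seed % 2**31)
        state.recompute_energy()
        return state

    def recompute_energy(self) -> float:
        """Full refresh of the cached total energy and structure factors."""
        if self.energy_kind == "cf1":
            n = self.n_sites
            self.charges_arr[:n] = self.energy.charges_for(self.species[:n])
            U, Sk = self.energy.total_energy(self.positions, self.species,
                                             self.charges_arr, n)
            self.total_energy = U
            self.Sk = Sk
        elif self.energy_kind == "ideal":
            self.total_energy = 0.0
            self.Sk = np.zeros(1, dtype=np.complex128)
        else:
            self.total_energy = self.energy.total_energy(self)
            self.Sk = np.zeros(1, dtype=np.complex128)
        self.steps_since_refresh = 0
        return self.total_energy

    def _effective_beta(self) -> float:
        ov = getattr(self, "_beta_override", None)
        return self.beta if ov is None else ov


def displacement_step(state: MCState, max_disp: float = 0.5) -> bool:
    """One Metropolis single-site displacement attempt.  Returns accept flag."""
    state.counters["disp_attempted"] += 1
    if state.energy_kind == "cf1":
        eng = state.energy
        U, n_acc = _kernels.run_displacement_chunk(
            state.positions, state.species, state.charges_arr, state.n_sites,
            state.box_length, state._effective_beta(), max_disp,
            eng.utab, eng.inv_dr, eng.rcut2, eng.kn, eng.Ak, state.Sk,
            eng.kmax, 1, state.total_energy)
        state.total_energy = U
        state.counters["disp_accepted"] += n_acc
        state.steps_since_refresh += 1
        return bool(n_acc)
    # generic (ideal gas or custom energy) path
    rng = state.py_rng
    n = state.n_sites
    i = int(rng.integers(n))
    old = state.positions[i].copy()
    new = (old + (rng.random(3) - 0.5) * 2.0 * max_disp) % state.box_length
    if state.energy_kind == "ideal":
        dU = 0.0
    else:
        dU = state.energy.delta_displacement(state, i, new)
    beta = state._effective_beta()
    accept = dU <= 0.0 or rng.random() < math.exp(-min(beta * dU, 700.0))
    if accept:
        state.positions[i] = new
        state.total_energy += dU
        state.counters["disp_accepted"] += 1
    return accept


def _gc_chunk(state: MCState, params: GCMCParameters, n_pairs: int,
              max_disp: float) -> None:
    eng = state.energy
    ideal = state.energy_kind == "ideal"
    if ideal:
        utab = np.zeros((3, 2))
        inv_dr = 1.0
        rcut2 = 0.0
        kn = np.zeros((1, 3), dtype=np.int64)
        Ak = np.zeros(1)
        kmax = 1
        dself = 0.0
        q_O, q_H = -0.65966, 0.32983
    else:
        utab, inv_dr, rcut2 = eng.utab, eng.inv_dr, eng.rcut2
        kn, Ak, kmax = eng.kn, eng.Ak, eng.kmax
        dself = eng.dself_mol
        q_O, q_H = eng.model.q_O, eng.model.q_H
    counters = np.zeros(7, dtype=np.int64)
    n, U = _kernels.run_gcmc_chunk(
        state.positions, state.species, state.charges_arr, state.n_sites,
        state.box_length, state._effective_beta(), max_disp, params.B,
        utab, inv_dr, rcut2, kn, Ak, state.Sk, kmax,
        q_O, q_H, dself, ideal,
        params.r_oh_window[0], params.r_oh_window[1],
        params.r_hh_window[0], params.r_hh_window[1],
        params.max_geometry_retries, n_pairs, state.total_energy, counters)
    state.n_sites = int(n)
    state.total_energy = U
    c = state.counters
    c["disp_attempted"] += int(counters[0])
    c["disp_accepted"] += int(counters[1])
    c["insert_attempted"] += int(counters[2])
    c["insert_accepted"] += int(counters[3])
    c["delete_attempted"] += int(counters[4])
    c["delete_accepted"] += int(counters[5])
    c["geometry_failures"] += int(counters[6])
    state.steps_since_refresh += 2 * n_pairs


def gcmc_insert_attempt(state: MCState, params: GCMCParameters) -> bool:
    """One molecule-insertion attempt (O + 2 H in the geometry windows)."""
    before = state.counters["insert_accepted"]
    _gc_single_exchange(state, params, want_insert=True)
    return state.counters["insert_accepted"] > before


def gcmc_delete_attempt(state: MCState, params: GCMCParameters) -> bool:
    """One molecule-deletion attempt (random O + its two nearest H)."""
    before = state.counters["delete_accepted"]
    _gc_single_exchange(state, params, want_insert=False)
    return state.counters["delete_accepted"] > before


def _gc_single_exchange(state: MCState, params: GCMCParameters,
                        want_insert: bool) -> None:
    # The chunk kernel flips a coin between insert and delete; run single
    # GC attempts (with a zero-length displacement) until the requested
    # move type has been attempted once, rolling back counts of the other.
    for _ in range(10000):
        before = dict(state.counters)
        _gc_chunk(state, params, 1, 0.0)
        # undo the forced displacement bookkeeping
        state.counters["disp_attempted"] = before["disp_attempted"]
        state.counters["disp_accepted"] = before["disp_accepted"]
        key = "insert_attempted" if want_insert else "delete_attempted"
        if state.counters[key] > before[key]:
            return
    raise RuntimeError("failed to draw requested GC move type")


@dataclass
class SampleStream:
    """Output of a run: time series + configuration snapshots."""

    series: pd.DataFrame
    frames: np.ndarray | list
    species: np.ndarray | list
    box_length: float
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def run_cmc(state: MCState, n_equil: int, n_prod: int,
            sample_interval: int = 10_000, max_disp: float = 0.5,
            frame_interval: int | None = None) -> SampleStream:
    """Displacement-only (canonical) sampling.

    Runs ``n_equil`` attempted moves, then ``n_prod`` production moves,
    recording the energy/density time series every ``sample_interval``
    moves and a configuration snapshot every ``frame_interval`` moves
    (default: same as ``sample_interval``).  Deterministic under a fixed
    state seed.
    """
    frame_interval = frame_interval or sample_interval
    eng = state.energy
    n = state.n_sites

    def _chunked(total, chunk):
        done = 0
        while done < total:
            step = min(chunk, total - done)
            yield step
            done += step

    fast = state.energy_kind == "cf1"
    for steps in _chunked(n_equil, sample_interval):
        if fast:
            U, n_acc = _kernels.run_displacement_chunk(
                state.positions, state.species, state.charges_arr, n,
                state.box_length, state._effective_beta(), max_disp,
                eng.utab, eng.inv_dr, eng.rcut2, eng.kn, eng.Ak, state.Sk,
                eng.kmax, steps, state.total_energy)
            state.total_energy = U
            state.counters["disp_attempted"] += steps
            state.counters["disp_accepted"] += n_acc
            state.steps_since_refresh += steps
        else:
            for _ in range(steps):
                displacement_step(state, max_disp)
        if state.steps_since_refresh >= state.refresh_interval:
            state.recompute_energy()

    rows = []
    frames = []
    step_count = 0
    since_frame = frame_interval  # snapshot at the first sample point
    for steps in _chunked(n_prod, sample_interval):
        if fast:
            U, n_acc = _kernels.run_displacement_chunk(
                state.positions, state.species, state.charges_arr, n,
                state.box_length, state._effective_beta(), max_disp,
                eng.utab, eng.inv_dr, eng.rcut2, eng.kn, eng.Ak, state.Sk,
                eng.kmax, steps, state.total_energy)
            state.total_energy = U
            state.counters["disp_attempted"] += steps
            state.counters["disp_accepted"] += n_acc
            state.steps_since_refresh += steps
        else:
            for _ in range(steps):
                displacement_step(state, max_disp)
        step_count += steps
        since_frame += steps
        rows.append((step_count, state.n_molecules, state.total_energy,
                     state.density))
        if since_frame >= frame_interval:
            frames.append(state.positions[:n].copy())
            since_frame = 0
        if state.steps_since_refresh >= state.refresh_interval:
            state.recompute_energy()

    series = pd.DataFrame(rows, columns=["step", "n_molecules", "energy",
                                         "density"])
    return SampleStream(series=series, frames=np.array(frames),
                        species=state.species[:n].copy(),
                        box_length=state.box_length,
                        meta={"counters": dict(state.counters),
                              "T": state.T, "seed": state.seed,
                              "ensemble": "canonical"})


def run_gcmc(state: MCState, params: GCMCParameters, n_equil: int, n_prod: int,
             sample_interval: int = 10_000, max_disp: float = 0.5,
             keep_frames: bool = False) -> SampleStream:
    """Grand-canonical sampling: displacement and insert/delete attempts
    alternate one-for-one.  ``n_equil``/``n_prod`` count every attempted
    elementary move (a displacement+GC pair is two moves)."""
    def _pairs(total):
        return max(total // 2, 0)

    chunk_pairs = max(sample_interval // 2, 1)
    done = 0
    total = _pairs(n_equil)
    while done < total:
        step = min(chunk_pairs, total - done)
        _gc_chunk(state, params, step, max_disp)
        done += step
        if state.steps_since_refresh >= state.refresh_interval:
            state.recompute_energy()

    rows = []
    frames = []
    species_frames = []
    done = 0
    total = _pairs(n_prod)
    while done < total:
        step = min(chunk_pairs, total - done)
        _gc_chunk(state, params, step, max_disp)
        done += step
        rows.append((2 * done, state.n_molecules, state.total_energy,
                     state.density))
        if keep_frames:
            frames.append(state.positions[: state.n_sites].copy())
            species_frames.append(state.species[: state.n_sites].copy())
        if state.steps_since_refresh >= state.refresh_interval:
            state.recompute_energy()

    series = pd.DataFrame(rows, columns=["step", "n_molecules", "energy",
                                         "density"])
    return SampleStream(series=series, frames=frames, species=species_frames,
                        box_length=state.box_length,
                        meta={"counters": dict(state.counters),
                              "T": state.T, "mu": params.mu, "B": params.B,
                              "seed": state.seed, "ensemble": "grand-canonical"})
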