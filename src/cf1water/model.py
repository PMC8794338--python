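"""CF1 central-force water model: charges and site-site pair potentials.

The CF1 model represents water as a fluid of charged oxygen (q_O = -2 q_H)
and hydrogen (q_H = +0.32983 e0) sites interacting purely through three
spherically symmetric pair potentials (O-O, H-H, O-H).  There are no bonds
or angle terms: H2O molecules are emergent ion triplets held together by the
deep O-H well near 1 Å.

The potentials are defined with r in Å and yield kcal/mol; every public
function converts to kJ/mol (factor 4.184) at evaluation time.  The 1/r
coefficients printed in the model definition (144.538, 36.1345, -72.269)
are exactly k*q_i*q_j for a single Coulomb constant k = 36.1345/q_H^2
(kcal Å/mol per e^2); that derived constant, not a CODATA value, is used
throughout so that the Coulomb/short-range split recombines to the printed
formulas exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CF1Parameters",
    "pair_potential",
    "coulomb_potential",
    "short_range_potential",
    "KCAL_TO_KJ",
    "R_GAS_KJ",
]

#: exact thermochemical calorie conversion
KCAL_TO_KJ = 4.184
#: molar gas constant in kJ/(mol K) (CODATA 2018, exact)
R_GAS_KJ = 8.31446261815324e-3
#: Avogadro constant, 1/mol (exact)
N_AVOGADRO = 6.02214076e23
#: Planck constant, J s (exact)
PLANCK_H = 6.62607015e-34
#: Boltzmann constant, J/K (exact)
BOLTZMANN_KB = 1.380649e-23
#: atomic mass unit, kg
ATOMIC_MASS_KG = 1.66053906660e-27
#: molar mass of water, g/mol
WATER_MOLAR_MASS = 18.015

_SPECIES_CODE = {"O": 0, "o": 0, 0: 0, "H": 1, "h": 1, 1: 1}


def _species_code(s) -> int:
    try:
        return _SPECIES_CODE[s]
    except (KeyError, TypeError):
        raise ValueError(f"unknown species label {s!r}; expected 'O' or 'H'") from None


def _safe_fermi(amplitude: float, steepness: float, center: float, r):
    """amplitude / (1 + exp(steepness*(r - center))) without overflow."""
    x = steepness * (np.asarray(r, dtype=float) - center)
    x = np.clip(x, -700.0, 700.0)
    return amplitude / (1.0 + np.exp(x))


@dataclass(frozen=True)
class CF1Parameters:
    """Charges and potential coefficients of the CF1 water model.

    All coefficient tables are stored in their printed kcal/mol, Å form.
    ``coulomb_constant_kcal`` is derived from the printed H-H 1/r
    coefficient as 36.1345/q_H^2 so that k q_i q_j reproduces each printed
    Coulomb coefficient exactly.
    """

    q_H: float = 0.32983
    kcal_to_kJ: float = KCAL_TO_KJ
    # printed 1/r coefficients (kcal Å/mol)
    coul_OO: float = 144.538
    coul_HH: float = 36.1345
    coul_OH: float = -72.269
    # O-O: power-law repulsion + two Gaussian wells
    oo_rep_coef: float = 24082.38
    oo_rep_exp: float = 8.8591
    oo_gauss: tuple = ((-0.25, 4.0, 3.4), (-0.25, 1.5, 4.5))  # (amp, width, center)
    # H-H: Fermi shoulder + Gaussian well
    hh_fermi: tuple = (18.0, 40.0, 2.0)  # (amp, steepness, center)
    hh_gauss: tuple = (-17.0, 7.62177, 1.45251)
    # O-H: power-law repulsion + two Fermi wells
    oh_rep_coef: float = 6.23403
    oh_rep_exp: float = 9.19912
    oh_fermi: tuple = ((-10.0, 40.0, 1.05), (-4.0, 5.49305, 2.2))

    def __post_init__(self):
        if abs(self.q_O + 2.0 * self.q_H) > 0.0:
            raise ValueError("electroneutrality violated: q_O must equal -2 q_H")
        k = self.coulomb_constant_kcal
        for printed, qq in (
            (self.coul_OO, self.q_O * self.q_O),
            (self.coul_HH, self.q_H * self.q_H),
            (self.coul_OH, self.q_O * self.q_H),
        ):
            if abs(k * qq / printed - 1.0) > 1e-5:
                raise ValueError(
                    "derived Coulomb constant inconsistent with printed coefficients"
                )

    @property
    def q_O(self) -> float:
        return -2.0 * self.q_H

    @property
    def coulomb_constant_kcal(self) -> float:
        """Coulomb constant in kcal Å/(mol e^2), derived from 36.1345/q_H^2."""
        return self.coul_HH / (self.q_H * self.q_H)

    @property
    def coulomb_constant_kj(self) -> float:
        """Coulomb constant in kJ Å/(mol e^2)."""
        return self.coulomb_constant_kcal * self.kcal_to_kJ

    def charge(self, species) -> float:
        """Charge (in e0) of a species label."""
        return self.q_O if _species_code(species) == 0 else self.q_H

    def coulomb_coefficient_kcal(self, si: int, sj: int) -> float:
        return (self.coul_OO, self.coul_OH, self.coul_HH)[si + sj]

    # -- kcal/mol evaluators (vectorized over r) ------------------------------

    def _u_oo_kcal(self, r):
        r = np.asarray(r, dtype=float)
        u = self.coul_OO / r + self.oo_rep_coef * r ** (-self.oo_rep_exp)
        for amp, width, center in self.oo_gauss:
            u = u + amp * np.exp(-width * (r - center) ** 2)
        return u

    def _u_hh_kcal(self, r):
        r = np.asarray(r, dtype=float)
        amp, width, center = self.hh_gauss
        return (
            self.coul_HH / r
            + _safe_fermi(*self.hh_fermi, r)
            + amp * np.exp(-width * (r - center) ** 2)
        )

    def _u_oh_kcal(self, r):
        r = np.asarray(r, dtype=float)
        u = self.coul_OH / r + self.oh_rep_coef * r ** (-self.oh_rep_exp)
        for amp, steep, center in self.oh_fermi:
            u = u + _safe_fermi(amp, steep, center, r)
        return u

    def pair_potential_kcal(self, si: int, sj: int, r):
        return (self._u_oo_kcal, self._u_oh_kcal, self._u_hh_kcal)[si + sj](r)

    def to_dict(self) -> dict:
        """Plain-dict form for serialization into run configs."""
        return {
            "q_H": self.q_H,
            "kcal_to_kJ": self.kcal_to_kJ,
            "coul_OO": self.coul_OO,
            "coul_HH": self.coul_HH,
            "coul_OH": self.coul_OH,
            "oo_rep_coef": self.oo_rep_coef,
            "oo_rep_exp": self.oo_rep_exp,
            "oo_gauss": [list(g) for g in self.oo_gauss],
            "hh_fermi": list(self.hh_fermi),
            "hh_gauss": list(self.hh_gauss),
            "oh_rep_coef": self.oh_rep_coef,
            "oh_rep_exp": self.oh_rep_exp,
            "oh_fermi": [list(f) for f in self.oh_fermi],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CF1Parameters":
        d = dict(d)
        for key in ("oo_gauss", "oh_fermi"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        if "hh_fermi" in d:
            d["hh_fermi"] = tuple(d["hh_fermi"])
        if "hh_gauss" in d:
            d["hh_gauss"] = tuple(d["hh_gauss"])
        return cls(**d)


_DEFAULT = CF1Parameters()


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("pair separation r must be positive")
    return r


def pair_potential(species_i, species_j, r, params: CF1Parameters = _DEFAULT):
    """Full CF1 site-site pair energy in kJ/mol at separation ``r`` (Å).

    Symmetric in species order; continuous and finite for every r > 0.
    Scalar in, scalar out; array in, array out.
    """
    si, sj = _species_code(species_i), _species_code(species_j)
    rr = _check_r(r)
    u = params.pair_potential_kcal(si, sj, rr) * params.kcal_to_kJ
    return float(u) if np.isscalar(r) or np.ndim(r) == 0 else u


def coulomb_potential(species_i, species_j, r, params: CF1Parameters = _DEFAULT):
    """Bare 1/r Coulomb part, k q_i q_j / r, in kJ/mol (printed coefficient)."""
    si, sj = _species_code(species_i), _species_code(species_j)
    rr = _check_r(r)
    u = params.coulomb_coefficient_kcal(si, sj) / rr * params.kcal_to_kJ
    return float(u) if np.isscalar(r) or np.ndim(r) == 0 else u


def short_range_potential(
    species_i, species_j, r, r_cut: float | None = None, params: CF1Parameters = _DEFAULT
):
    """Non-Coulombic remainder of the CF1 pair energy, in kJ/mol.

    Equals ``pair_potential - coulomb_potential`` for r <= ``r_cut`` and 0
    beyond it (no cutoff if ``r_cut`` is None).  Decays faster than 1/r,
    which is what makes the Ewald-resolved Coulomb split possible.
    """
    si, sj = _species_code(species_i), _species_code(species_j)
    rr = _check_r(r)
    u = (
        params.pair_potential_kcal(si, sj, rr)
        - params.coulomb_coefficient_kcal(si, sj) / rr
    ) * params.kcal_to_kJ
    if r_cut is not None:
        u = np.where(rr <= r_cut, u, 0.0)
    return float(u) if np.isscalar(r) or np.ndim(r) == 0 else u


def thermal_wavelength(mass_u: float, T: float) -> float:
    """Thermal de Broglie wavelength h/sqrt(2 pi m k_B T) in Å."""
    m = mass_u * ATOMIC_MASS_KG
    lam_m = PLANCK_H / math.sqrt(2.0 * math.pi * m * BOLTZMANN_KB * T)
    return lam_m * 1e10
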