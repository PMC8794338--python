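import math

import numpy as np
import pytest

# ---------------------------------------------------------------------------
# independent transcriptions of the printed CF1 pair potentials (kcal/mol);
# these are the oracles -- they share no code with the package.
# ---------------------------------------------------------------------------

KCAL = 4.184


def oracle_u_oo_kcal(r):
    r = np.asarray(r, dtype=float)
    return (144.538 / r + 24082.38 * r**-8.8591
            - 0.25 * np.exp(-4.0 * (r - 3.4) ** 2)
            - 0.25 * np.exp(-1.5 * (r - 4.5) ** 2))


def oracle_u_hh_kcal(r):
    r = np.asarray(r, dtype=float)
    x = np.clip(40.0 * (r - 2.0), -700, 700)
    return (36.1345 / r + 18.0 / (1.0 + np.exp(x))
            - 17.0 * np.exp(-7.62177 * (r - 1.45251) ** 2))


def oracle_u_oh_kcal(r):
    r = np.asarray(r, dtype=float)
    x1 = np.clip(40.0 * (r - 1.05), -700, 700)
    return (-72.269 / r + 6.23403 * r**-9.19912
            - 10.0 / (1.0 + np.exp(x1))
            - 4.0 / (1.0 + np.exp(5.49305 * (r - 2.2))))


def oracle_pair_kj(si, sj, r):
    t = si + sj
    if t == 0:
        return KCAL * oracle_u_oo_kcal(r)
    if t == 1:
        return KCAL * oracle_u_oh_kcal(r)
    return KCAL * oracle_u_hh_kcal(r)


@pytest.fixture(scope="session")
def oracle_potentials():
    return {"OO": oracle_u_oo_kcal, "HH": oracle_u_hh_kcal,
            "OH": oracle_u_oh_kcal, "pair_kj": oracle_pair_kj}


# ---------------------------------------------------------------------------
# hand-built molecular fixtures
# ---------------------------------------------------------------------------


def make_molecule(o, direction1, direction2, l1=0.96, l2=0.96):
    o = np.asarray(o, dtype=float)
    d1 = np.asarray(direction1, dtype=float)
    d2 = np.asarray(direction2, dtype=float)
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    return np.vstack([o, o + l1 * d1, o + l2 * d2])


@pytest.fixture(scope="session")
def hbond_dimer():
    """Two molecules in a donor-acceptor geometry; the 9-term pair energy
    is -23.92 kJ/mol (frozen from the independent oracle sum) and the
    shortest intermolecular O...H contact is 1.80 Å."""
    th = math.radians(102.0)
    a = make_molecule([0, 0, 0], [1, 0, 0], [math.cos(th), 0, math.sin(th)])
    c52, s52 = math.cos(math.radians(52)), math.sin(math.radians(52))
    b = make_molecule([2.76, 0, 0], [c52, s52, 0], [c52, -s52, 0])
    pos = np.vstack([a, b])
    species = np.array([0, 1, 1, 0, 1, 1], dtype=np.int8)
    return pos, species


@pytest.fixture(scope="session")
def kernels_warm():
    """Force numba compilation early so individual tests time cleanly."""
    from cf1water import _kernels

    _kernels.seed_rng(0)
    _kernels.u_oo_kcal(1.0)
    return _kernels
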