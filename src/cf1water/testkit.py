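"""Independent fixtures and oracles for validating the simulator.

Everything here is deliberately naive and shares no energy or geometry
routines with the engine modules: brute-force periodic Coulomb sums,
analytic grand-canonical reference moments, and exact geometric
generators.  Sizes are capped -- these are correctness oracles, not tools.
"""

from __future__ import annotations

import math

import numpy as np

from .model import CF1Parameters

__all__ = [
    "brute_force_coulomb",
    "perfect_tetrahedron",
    "ideal_gas_gcmc_reference",
]

_K_COULOMB_KJ = CF1Parameters().coulomb_constant_kj


def brute_force_coulomb(positions, charges, box_length, n_image_shells: int = 8,
                        coulomb_constant: float = _K_COULOMB_KJ,
                        conducting_correction: bool = True,
                        tail_average: int = 0):
    """Direct periodic Coulomb sum over spherically ordered image cells.

    Sums q_i q_j / |r_ij + n L| over all image vectors with |n| <=
    ``n_image_shells`` (spherical ordering).  The spherically ordered
    direct sum converges to the vacuum-boundary value; with
    ``conducting_correction`` the 2 pi k |M|^2 / (3V) dipole term is
    subtracted so the result is comparable to tinfoil Ewald.

    The truncated sum oscillates around its limit as shells are added;
    with ``tail_average`` > 0 the reported energy is the mean of the last
    that many per-shell partial sums, which accelerates convergence for
    dipolar configurations.

    Returns (energy_kJ_per_mol, per_shell_partial_sums) so convergence can
    be inspected shell by shell.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    L = float(box_length)
    n = positions.shape[0]
    if n > 50:
        raise ValueError("brute-force oracle capped at 50 sites")
    if n_image_shells < 3:
        raise ValueError("need at least 3 image shells")
    S = n_image_shells
    rng = np.arange(-S, S + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    n2 = nx**2 + ny**2 + nz**2
    order = np.argsort(n2.ravel(), kind="stable")
    cells = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)[order]
    shells = n2.ravel()[order]
    keep = shells <= S * S  # spherical ordering/cutoff
    cells, shells = cells[keep], shells[keep]

    qq = charges[:, None] * charges[None, :]
    rij = positions[:, None, :] - positions[None, :, :]
    partials = []
    e = 0.0
    current_shell = 0
    for cell, sh in zip(cells, shells):
        if sh != current_shell:
            partials.append(e)
            current_shell = sh
        shift = cell * L
        d = rij + shift
        r = np.sqrt((d**2).sum(axis=-1))
        if (cell == 0).all():
            iu = np.triu_indices(n, 1)
            e += float(np.sum(qq[iu] / r[iu]))
        else:
            e += 0.5 * float(np.sum(qq / r))
    partials.append(e)
    e *= coulomb_constant
    partials = coulomb_constant * np.asarray(partials)
    if conducting_correction:
        M = (charges[:, None] * positions).sum(axis=0)
        corr = 2.0 * math.pi * coulomb_constant * float(M @ M) / (3.0 * L**3)
        e -= corr
        partials = partials - corr
    if tail_average > 0:
        e = float(np.mean(partials[-tail_average:]))
    return e, partials


def perfect_tetrahedron(center=(0.0, 0.0, 0.0), bond_length: float = 2.8):
    """Five oxygen positions: a central site plus 4 perfect tetrahedral
    vertices (all cos psi_ij = -1/3)."""
    c = np.asarray(center, dtype=float)
    verts = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]) / math.sqrt(3.0)
    return np.vstack([c, c + bond_length * verts])


def ideal_gas_gcmc_reference(B: float, n_max: int = 2000,
                             tail_tol: float = 1e-15):
    """Moments of the non-interacting GCMC molecule-number distribution.

    P(N) ∝ exp(B N) / (N! (2N)!), normalized by direct summation truncated
    at ``n_max``.  Raises if the truncation tail is not negligible.

    Returns (mean_N, var_N, P) with P the normalized probabilities.
    """
    logw = np.empty(n_max + 1)
    from math import lgamma
    for N in range(n_max + 1):
        logw[N] = B * N - lgamma(N + 1.0) - lgamma(2.0 * N + 1.0)
    logw -= logw.max()
    w = np.exp(logw)
    if w[-1] > tail_tol * w.max():
        raise ValueError("n_max too small: truncated tail is not negligible")
    P = w / w.sum()
    Ns = np.arange(n_max + 1)
    mean = float((P * Ns).sum())
    var = float((P * Ns**2).sum() - mean**2)
    return mean, var, P
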