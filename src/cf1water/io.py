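"""Plain-text I/O: extended-XYZ trajectories, TSV series, JSON checkpoints."""

from __future__ import annotations

import json

import numpy as np

__all__ = ["write_xyz", "read_xyz", "write_checkpoint", "read_checkpoint"]

_NAMES = {0: "O", 1: "H"}
_CODES = {"O": 0, "H": 1}


def write_xyz(path, frames, species_per_frame, box_length, mode="w"):
    """Write an extended-XYZ trajectory (Lattice in the comment line).

    ``frames`` is an iterable of (n, 3) arrays; ``species_per_frame`` a
    matching iterable of species-code arrays (or a single array reused for
    every frame).
    """
    L = float(box_length)
    lattice = f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}"'
    single = isinstance(species_per_frame, np.ndarray)
    with open(path, mode) as fh:
        for k, pos in enumerate(frames):
            sp = species_per_frame if single else species_per_frame[k]
            fh.write(f"{len(pos)}\n{lattice} Properties=species:S:1:pos:R:3\n")
            for s, (x, y, z) in zip(sp, pos):
                fh.write(f"{_NAMES[int(s)]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path):
    """Read an extended-XYZ trajectory written by :func:`write_xyz`.

    Returns (frames, species_per_frame, box_length).
    """
    frames, species = [], []
    L = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            if L is None and 'Lattice="' in comment:
                L = float(comment.split('Lattice="')[1].split()[0])
            pos = np.empty((n, 3))
            sp = np.empty(n, dtype=np.int8)
            for i in range(n):
                parts = fh.readline().split()
                sp[i] = _CODES[parts[0]]
                pos[i] = [float(p) for p in parts[1:4]]
            frames.append(pos)
            species.append(sp)
    return frames, species, L


def write_checkpoint(path, state, extra: dict | None = None):
    """JSON checkpoint of an MCState (coordinates, species, T, seed, U)."""
    n = state.n_sites
    payload = {
        "box_length": state.box_length,
        "T": state.T,
        "seed": state.seed,
        "total_energy": state.total_energy,
        "species": state.species[:n].tolist(),
        "positions": np.round(state.positions[:n], 12).tolist(),
        "counters": state.counters,
    }
    if extra:
        payload["extra"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_checkpoint(path):
    """Load a checkpoint; returns a dict with a ParticleConfiguration."""
    from .engine import ParticleConfiguration

    with open(path) as fh:
        payload = json.load(fh)
    config = ParticleConfiguration(
        payload["box_length"],
        np.asarray(payload["positions"], dtype=float),
        np.asarray(payload["species"], dtype=np.int8),
    )
    payload["configuration"] = config
    return payload
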