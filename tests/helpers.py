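"""Shared test helpers: independent oracles and fixture-file builders.

The oracles here deliberately re-derive quantities through a different
route than the package (Monte Carlo surface integration instead of a
Fibonacci lattice, explicit entropy sums instead of vectorized ones,
exhaustive O(n²) pair scans) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np

from dimerfeat.structure import Residue
from dimerfeat.surface import DEFAULT_RADIUS, VDW_RADII


def monte_carlo_asa(
    residues: list[Residue],
    probe_radius: float = 1.4,
    n_points: int = 12000,
    seed: int = 20240101,
) -> dict:
    """Per-residue ASA by Monte Carlo integration on random sphere points.

    Independent of the package path: random (not lattice) directions, a
    plain exhaustive neighbour scan, and its own accumulation loop.
    """
    rng = np.random.default_rng(seed)
    atoms = [(res, a) for res in residues for a in res.heavy_atoms()]
    coords = np.array([a.position for _, a in atoms])
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_RADIUS) + probe_radius
                      for _, a in atoms])
    out = {res.key: 0.0 for res in residues}
    for i, (res, _) in enumerate(atoms):
        half = rng.normal(size=(n_points // 2, 3))
        dirs = np.concatenate([half, -half])  # antithetic pairs reduce variance
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * dirs
        free = np.ones(n_points, dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= radii[i] + radii[j]:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) >= radii[j] ** 2
        out[res.key] += free.mean() * 4.0 * math.pi * radii[i] ** 2
    return out


def jsd_direct(p, f) -> float:
    """Direct scalar evaluation of the three entropy terms (log base 2)."""

    def entropy(v):
        total = 0.0
        for x in v:
            if x > 0.0:
                total -= x * math.log2(x)
        return total

    m = [(pi + fi) / 2.0 for pi, fi in zip(p, f)]
    return entropy(m) - 0.5 * entropy(p) - 0.5 * entropy(f)


def brute_force_interchain_pairs(dimer, cutoff: float) -> dict:
    """Exhaustive per-residue interchain heavy-atom pair counts."""
    counts = {r.key: 0 for r in dimer.residues()}
    for ra in dimer.chain_a:
        for rb in dimer.chain_b:
            for a in ra.heavy_atoms():
                for b in rb.heavy_atoms():
                    if np.linalg.norm(a.position - b.position) <= cutoff:
                        counts[ra.key] += 1
                        counts[rb.key] += 1
    return counts


def random_rotation(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation matrix and a translation."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-30, 30, size=3)


def transform_dimer(dimer, rot: np.ndarray, trans: np.ndarray):
    """Rigid-body copy of a dimer."""
    from copy import deepcopy

    moved = deepcopy(dimer)
    for res in moved.residues():
        for a in res.atoms:
            a.position = rot @ a.position + trans
    return moved


def write_pssm_text(path, rows: list[tuple[str, dict[str, float]]]) -> None:
    """Write a PSI-BLAST-style ASCII PSSM.

    ``rows`` is a list of (query residue letter, {aa: weighted percent}).
    """
    aa = "ARNDCQEGHILKMFPSTWYV"
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(aa) + "    " + "   ".join(aa),
    ]
    for i, (letter, pcts) in enumerate(rows, start=1):
        log_odds = " ".join(f"{0:3d}" for _ in aa)
        pct = " ".join(f"{int(round(pcts.get(a, 0.0))):4d}" for a in aa)
        lines.append(f"{i:5d} {letter}  {log_odds} {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    path.write_text("\n".join(lines))
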