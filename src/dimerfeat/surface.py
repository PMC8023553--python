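"""Accessible surface areas, ASA descriptors and surface/interface classes.

The ASA engine is a rolling-probe numerical surface: each atom's sphere of
radius r_vdw + r_probe is sampled on a deterministic Fibonacci lattice and a
sample point counts as accessible when it lies outside every neighbour's
expanded sphere.  At the default 960 points per atom the per-residue error
against dense integration is well under 2% for protein-like packing, and
the isolated-sphere limit recovers the closed form 4π(r + r_probe)².

Relative solvent accessibility (RSA) normalizes a residue's ASA by its
Sander–Rost Gly-X-Gly extended-tripeptide reference area; residues with
monomer-form RSA above 0.20 are surface, and a surface residue is
interfacial when any of its heavy atoms lies within 5 Å of the partner
chain.  ΔASA = compASA − monASA is non-positive wherever complexation
buries area; relASA = ΔASA / monASA by default, with an optional
buried-fraction convention (−ΔASA/monASA, optionally ×100).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import DimerStructure, Residue

logger = logging.getLogger("dimerfeat")

#: Van der Waals radii (Å), Bondi-like; elements not listed fall back to DEFAULT_RADIUS.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
                               "H": 1.20, "D": 1.20, "SE": 1.90}
DEFAULT_RADIUS = 1.80

#: Sander–Rost Gly-X-Gly reference areas (Å²) used for RSA normalization.
MAX_AREA: dict[str, float] = {
    "ALA": 106.0, "ARG": 248.0, "ASN": 157.0, "ASP": 163.0, "CYS": 135.0,
    "GLN": 198.0, "GLU": 194.0, "GLY": 84.0, "HIS": 184.0, "ILE": 169.0,
    "LEU": 165.0, "LYS": 205.0, "MET": 188.0, "PHE": 197.0, "PRO": 136.0,
    "SER": 130.0, "THR": 142.0, "TRP": 227.0, "TYR": 222.0, "VAL": 142.0,
}

NON_SURFACE = "non_surface"
SURFACE = "surface_non_interfacial"
INTERFACE = "surface_interfacial"
CLASS_LABELS = (NON_SURFACE, SURFACE, INTERFACE)


class SurfaceError(ValueError):
    pass


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden-angle increment
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _gather(residues: list[Residue], include_hydrogens: bool,
            radii: dict[str, float] | None, strict_elements: bool):
    radii = VDW_RADII if radii is None else radii
    coords, rads, owner = [], [], []
    for ri, res in enumerate(residues):
        atoms = res.atoms if include_hydrogens else res.heavy_atoms()
        for a in atoms:
            if a.element not in radii:
                if strict_elements:
                    raise SurfaceError(f"no van der Waals radius configured for element "
                                       f"{a.element!r} (atom {a.name} of {res.residue_name})")
                rads.append(DEFAULT_RADIUS)
            else:
                rads.append(radii[a.element])
            coords.append(a.position)
            owner.append(ri)
    if not coords:
        raise SurfaceError("no atoms to compute a surface for")
    return np.asarray(coords), np.asarray(rads), np.asarray(owner)


def compute_asa(
    residues: list[Residue],
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
    radii: dict[str, float] | None = None,
    points: np.ndarray | None = None,
) -> dict[tuple[str, int, str], float]:
    """Per-residue accessible surface area (Å²) of the given residue set.

    ``points`` lets callers substitute their own unit sphere sampling (the
    high-resolution test oracle does); by default a Fibonacci lattice of
    ``n_points`` directions is used, making the result deterministic.
    """
    coords, rads, owner = _gather(residues, include_hydrogens, radii, strict_elements=True)
    if points is None:
        points = fibonacci_sphere(n_points)
    ext = rads + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()

    per_residue = {res.key: 0.0 for res in residues}
    for i in range(len(coords)):
        sphere = coords[i] + ext[i] * points
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach)
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        accessible = np.ones(len(points), dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", sphere - coords[j], sphere - coords[j])
            # Points exactly on a neighbour's expanded sphere (degenerate
            # coincident atoms) are owned by the lower-index atom, so the
            # union area is counted once rather than twice or zero times.
            if j > i:
                accessible &= d2 >= ext[j] ** 2 - 1e-9
            else:
                accessible &= d2 > ext[j] ** 2 + 1e-9
            if not accessible.any():
                break
        frac = accessible.mean()
        area = frac * 4.0 * math.pi * ext[i] ** 2
        per_residue[residues[owner[i]].key] += area
    return per_residue


def rsa(asa: float, residue_name: str) -> float:
    """ASA divided by the residue's Gly-X-Gly reference area.

    Not clamped at 1: distorted conformations can exceed the extended
    reference, which is logged rather than hidden.
    """
    if residue_name not in MAX_AREA:
        raise SurfaceError(f"no reference area for residue {residue_name!r}")
    value = asa / MAX_AREA[residue_name]
    if value > 1.0:
        logger.info("RSA %.3f > 1 for %s (ASA %.1f Å²)", value, residue_name, asa)
    return value


def delta_and_rel_asa(
    mon_asa: float,
    comp_asa: float,
    convention: str = "literal",
    percent: bool = False,
) -> tuple[float, float]:
    """ΔASA and relASA for one residue.

    ``convention='literal'`` gives relASA = ΔASA/monASA (≤ 0 at buried
    positions); ``'buried_fraction'`` gives −ΔASA/monASA (the fraction of
    monomer area lost on complexation), ×100 when ``percent`` is set.
    monASA = 0 with a non-zero ΔASA has no defined ratio and yields NaN
    with a warning; 0/0 is defined as 0.
    """
    if mon_asa < 0 or comp_asa < 0:
        raise SurfaceError("areas must be non-negative")
    delta = comp_asa - mon_asa
    if mon_asa == 0.0:
        if delta == 0.0:
            rel = 0.0
        else:
            logger.warning("relASA undefined: monomer ASA 0 with ΔASA %.2f", delta)
            rel = float("nan")
    else:
        rel = delta / mon_asa
        if convention == "buried_fraction":
            rel = -rel
    if convention == "buried_fraction" and percent:
        rel *= 100.0
    elif convention not in ("literal", "buried_fraction"):
        raise SurfaceError(f"unknown relASA convention {convention!r}")
    return delta, rel


def min_distances_to_partner(dimer: DimerStructure, heavy_only: bool = True) -> dict:
    """Minimum distance from each residue to any atom of the partner chain."""
    out = {}
    for own, partner in ((dimer.chain_a, dimer.chain_b), (dimer.chain_b, dimer.chain_a)):
        pcoords = np.concatenate([r.coords(heavy_only=heavy_only) for r in partner])
        tree = cKDTree(pcoords)
        for res in own:
            d, _ = tree.query(res.coords(heavy_only=heavy_only), k=1)
            out[res.key] = float(np.min(d))
    return out


def classify(
    dimer: DimerStructure,
    rsa_cutoff: float = 0.20,
    interface_cutoff: float = 5.0,
    probe_radius: float = 1.4,
    n_points: int = 960,
    rel_asa_convention: str = "literal",
    rel_asa_percent: bool = False,
) -> pd.DataFrame:
    """Full ASA table and residue classes for one dimer.

    Classification uses the monomer-form RSA (each chain's surface computed
    alone), so that interface residues buried by the partner are still
    recognized as surface; RSA strictly above ``rsa_cutoff`` is surface, and
    a surface residue with partner distance strictly below
    ``interface_cutoff`` is interfacial.
    """
    mon: dict = {}
    for chain in (dimer.chain_a, dimer.chain_b):
        mon.update(compute_asa(chain, probe_radius, n_points))
    comp = compute_asa(dimer.residues(), probe_radius, n_points)
    min_dist = min_distances_to_partner(dimer)

    rows = []
    for res in dimer.residues():
        m, c = mon[res.key], comp[res.key]
        delta, rel = delta_and_rel_asa(m, c, rel_asa_convention, rel_asa_percent)
        r_mon = rsa(m, res.residue_name)
        r_comp = rsa(c, res.residue_name)
        d = min_dist[res.key]
        if r_mon > rsa_cutoff:
            label = INTERFACE if d < interface_cutoff else SURFACE
        else:
            label = NON_SURFACE
        rows.append({
            "pdb_id": dimer.source_id,
            "chain": res.chain_id,
            "resi": res.residue_seq,
            "icode": res.insertion_code,
            "resn": res.residue_name,
            "class": label,
            "mon_asa": m,
            "comp_asa": c,
            "delta_asa": delta,
            "rel_asa": rel,
            "rsa_mon": r_mon,
            "rsa_comp": r_comp,
            "min_interchain_dist": d,
        })
    return pd.DataFrame(rows)
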