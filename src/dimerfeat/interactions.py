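"""Intermolecular interaction detectors for a two-chain dimer.

Eight interaction kinds are counted between (and only between) the two
chains: close contacts at 2.5 Å and 4.0 Å, hydrophobic (apolar-carbon)
contacts, hydrogen bonds, salt bridges, and the three π classes (π–π
stacking, T-stacking, cation–π).  All criteria are purely geometric, with
thresholds collected in :class:`InteractionThresholds` so every one of them
is a configuration key:

==============  =========================================================
close contacts  interchain heavy-atom pairs within 2.5 / 4.0 Å
hydrophobic     apolar carbon ↔ apolar carbon within 4.0 Å
hydrogen bond   donor–acceptor heavy atoms ≤ 4.0 Å; when the donor's
                hydrogen is present, D–H–A within 40° of linear —
                otherwise distance-only, flagged
salt bridge     cationic group ↔ anionic group, closest atoms ≤ 5.5 Å
π–π stacking    ring centroids ≤ 7.5 Å, plane normals ≤ 30° apart,
                projected centroid offset ≤ ring radius + 0.75 Å
T-stacking      centroids ≤ 5.0 Å, normals within 90° ± 30°
cation–π        cation charge centre ≤ 6.0 Å from a ring centroid with
                its projection inside the ring + 0.75 Å padding
==============  =========================================================

Each ring pair is assigned at most one π class, with π–π taking precedence
over T-stacking.  Histidine counts as cationic only when both of its ring
nitrogens carry hydrogens in the input, or when explicitly requested —
protonation cannot be inferred from heavy atoms alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Atom, DimerStructure, Residue

logger = logging.getLogger("dimerfeat")

KINDS = ("close_25", "close_40", "hydrophobic", "hbond",
         "salt_bridge", "pi_pi", "t_stack", "cation_pi")


# ---------------------------------------------------------------------------
# atom typing


#: Side-chain hydrogen-bond donor heavy atoms; every residue additionally
#: donates through its backbone N (except proline).
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}

#: Side-chain acceptors; every residue additionally accepts through its
#: backbone carbonyl O (and terminal OXT).
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "MET": {"SD"},
}

CATIONIC_GROUPS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE", "CZ"},
    "HIS": {"ND1", "NE2", "CE1", "CD2", "CG"},  # only when protonated / forced
}

ANIONIC_GROUPS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2", "CG"},
    "GLU": {"OE1", "OE2", "CD"},
}

#: Aromatic ring atom sets; TRP contributes two rings.
AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

#: Carbon atoms bonded only to carbon or hydrogen, per standard residue
#: topology.  These are the "apolar carbons" of the hydrophobic-contact rule.
APOLAR_CARBONS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG"},
    "ASN": {"CB"},
    "ASP": {"CB"},
    "CYS": set(),
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLY": set(),
    "HIS": {"CB"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD"},
    "MET": {"CB"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"},
    "SER": set(),
    "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"},
}


@dataclass
class InteractionThresholds:
    """Geometric cutoffs; distances in Å, angles in degrees."""

    close_short: float = 2.5
    close_long: float = 4.0
    hydrophobic: float = 4.0
    hbond_dist: float = 4.0
    hbond_angle_dev: float = 40.0
    salt_bridge: float = 5.5
    pi_pi_dist: float = 7.5
    pi_pi_angle: float = 30.0
    t_stack_dist: float = 5.0
    t_stack_angle_dev: float = 30.0
    cation_pi_dist: float = 6.0
    ring_padding: float = 0.75
    his_charged: bool = False

    def validate(self) -> None:
        bad = [k for k, v in asdict(self).items()
               if k != "his_charged" and not (isinstance(v, (int, float)) and v > 0)]
        if bad:
            raise ValueError(f"thresholds must be positive: {bad}")


@dataclass
class RingGeometry:
    """Least-squares plane fit of an aromatic ring."""

    residue: Residue
    centroid: np.ndarray
    normal: np.ndarray
    radius: float
    rms_residual: float


@dataclass
class InteractionRecord:
    kind: str
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    resn_a: str
    resn_b: str
    distance: float
    angle: float | None = None
    atom_a: str = ""
    atom_b: str = ""
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# geometry helpers


def fit_ring(residue: Residue, atom_names: list[str]) -> RingGeometry | None:
    """Fit centroid + least-squares plane normal; None if atoms are missing."""
    atoms = [residue.atom(n) for n in atom_names]
    if any(a is None for a in atoms):
        logger.warning("ring atoms missing in %s %s%d; ring skipped",
                       residue.residue_name, residue.chain_id, residue.residue_seq)
        return None
    coords = np.array([a.position for a in atoms])
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    radius = float(np.linalg.norm(centered, axis=1).mean())
    return RingGeometry(residue, centroid, normal / np.linalg.norm(normal), radius, rms)


def rings_of(chain: list[Residue]) -> list[RingGeometry]:
    out = []
    for res in chain:
        for names in AROMATIC_RINGS.get(res.residue_name, []):
            ring = fit_ring(res, names)
            if ring is not None:
                out.append(ring)
    return out


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two planes' normals, folded into [0, 90]°."""
    c = abs(float(np.clip(n1 @ n2, -1.0, 1.0)))
    return math.degrees(math.acos(c))


def _offset_in_plane(point: np.ndarray, ring: RingGeometry) -> float:
    """Distance from a ring's centroid to ``point`` projected onto its plane."""
    v = point - ring.centroid
    return float(np.linalg.norm(v - (v @ ring.normal) * ring.normal))


def _pairs_within(coords_a, coords_b, cutoff, method="kdtree"):
    """Index pairs (i, j) with ||a_i − b_j|| ≤ cutoff."""
    if method == "brute":
        d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
        return [(i, j, d[i, j]) for i, j in zip(*np.nonzero(d <= cutoff))]
    tree = cKDTree(coords_b)
    out = []
    for i, js in enumerate(cKDTree(coords_a).query_ball_tree(tree, cutoff)):
        for j in js:
            out.append((i, j, float(np.linalg.norm(coords_a[i] - coords_b[j]))))
    return out


def _chain_atoms(chain: list[Residue], predicate) -> tuple[np.ndarray, list[tuple[Residue, Atom]]]:
    picked = [(r, a) for r in chain for a in r.atoms if predicate(r, a)]
    coords = np.array([a.position for _, a in picked], float).reshape(-1, 3)
    return coords, picked


# ---------------------------------------------------------------------------
# detectors


def close_contacts(
    dimer: DimerStructure, cutoff: float, method: str = "kdtree"
) -> dict[tuple[str, int, str], int]:
    """Per-residue counts of interchain heavy-atom pairs within ``cutoff``.

    ``method='brute'`` forces exhaustive O(n²) enumeration; the spatial
    index must produce identical counts.
    """
    ca, pa = _chain_atoms(dimer.chain_a, lambda r, a: not a.is_hydrogen)
    cb, pb = _chain_atoms(dimer.chain_b, lambda r, a: not a.is_hydrogen)
    counts = {r.key: 0 for r in dimer.residues()}
    for i, j, _ in _pairs_within(ca, cb, cutoff, method):
        counts[pa[i][0].key] += 1
        counts[pb[j][0].key] += 1
    return counts


def hydrophobic_contacts(
    dimer: DimerStructure, cutoff: float = 4.0, method: str = "kdtree"
) -> list[InteractionRecord]:
    """Interchain apolar-carbon pairs within ``cutoff``."""

    def apolar(r: Residue, a: Atom) -> bool:
        return a.element == "C" and a.name in APOLAR_CARBONS.get(r.residue_name, set())

    ca, pa = _chain_atoms(dimer.chain_a, apolar)
    cb, pb = _chain_atoms(dimer.chain_b, apolar)
    if not len(ca) or not len(cb):
        return []
    records = []
    for i, j, d in _pairs_within(ca, cb, cutoff, method):
        ra, aa = pa[i]
        rb, ab = pb[j]
        records.append(InteractionRecord("hydrophobic", ra.key, rb.key,
                                         ra.residue_name, rb.residue_name, d,
                                         atom_a=aa.name, atom_b=ab.name))
    return records


def _donors(chain: list[Residue]):
    for r in chain:
        names = set(SIDECHAIN_DONORS.get(r.residue_name, set()))
        if r.residue_name != "PRO":
            names.add("N")
        for a in r.atoms:
            if a.name in names:
                hydrogens = [h for h in r.atoms
                             if h.is_hydrogen and np.linalg.norm(h.position - a.position) < 1.3]
                yield r, a, hydrogens


def _acceptors(chain: list[Residue]):
    for r in chain:
        names = set(SIDECHAIN_ACCEPTORS.get(r.residue_name, set())) | {"O", "OXT"}
        for a in r.atoms:
            if a.name in names:
                yield r, a


def hydrogen_bonds(
    dimer: DimerStructure,
    dist_cutoff: float = 4.0,
    angle_cutoff: float = 40.0,
) -> list[InteractionRecord]:
    """Interchain donor–acceptor pairs satisfying distance (and angle) rules.

    The angle rule — deviation of D–H–A from linear at most ``angle_cutoff``
    — applies only when the donor carries an explicit hydrogen; heavy-atom
    only inputs fall back to the distance criterion with a
    ``no_hydrogen`` flag on the record.
    """
    records = []
    for donors, acceptors in (
        (_donors(dimer.chain_a), list(_acceptors(dimer.chain_b))),
        (_donors(dimer.chain_b), list(_acceptors(dimer.chain_a))),
    ):
        for rd, d_atom, hydrogens in donors:
            for ra, a_atom in acceptors:
                dist = float(np.linalg.norm(d_atom.position - a_atom.position))
                if dist > dist_cutoff:
                    continue
                if hydrogens:
                    best_dev = None
                    for h in hydrogens:
                        v1 = d_atom.position - h.position
                        v2 = a_atom.position - h.position
                        cosang = float(np.clip(
                            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
                        dev = 180.0 - math.degrees(math.acos(cosang))
                        if best_dev is None or dev < best_dev:
                            best_dev = dev
                    if best_dev > angle_cutoff:
                        continue
                    records.append(InteractionRecord(
                        "hbond", rd.key, ra.key, rd.residue_name, ra.residue_name,
                        dist, angle=best_dev, atom_a=d_atom.name, atom_b=a_atom.name))
                else:
                    records.append(InteractionRecord(
                        "hbond", rd.key, ra.key, rd.residue_name, ra.residue_name,
                        dist, atom_a=d_atom.name, atom_b=a_atom.name,
                        flags=("no_hydrogen",)))
    return records


def _his_is_protonated(res: Residue) -> bool:
    found = set()
    for n_name, h_names in (("ND1", ("HD1",)), ("NE2", ("HE2",))):
        n = res.atom(n_name)
        if n is None:
            return False
        for a in res.atoms:
            if a.is_hydrogen and a.name in h_names:
                found.add(n_name)
            elif a.is_hydrogen and np.linalg.norm(a.position - n.position) < 1.25:
                found.add(n_name)
    return found == {"ND1", "NE2"}


def _charged_groups(chain: list[Residue], table: dict[str, set[str]],
                    his_charged: bool = False, terminus: str | None = None):
    """(residue, group atoms) pairs; HIS gated by protonation/flag."""
    groups = []
    for r in chain:
        names = table.get(r.residue_name)
        if not names:
            continue
        if r.residue_name == "HIS" and not (his_charged or _his_is_protonated(r)):
            continue
        atoms = [a for a in r.atoms if a.name in names]
        if atoms:
            groups.append((r, atoms))
    # termini: charged backbone groups at chain ends
    if terminus == "N" and chain:
        first = chain[0]
        n = first.atom("N")
        if n is not None:
            groups.append((first, [n]))
    if terminus == "C" and chain:
        last = chain[-1]
        atoms = [a for a in last.atoms if a.name in ("OXT", "O")]
        if last.atom("OXT") is not None:
            groups.append((last, atoms))
    return groups


def salt_bridges(
    dimer: DimerStructure,
    cutoff: float = 5.5,
    his_charged: bool = False,
    include_termini: bool = True,
) -> list[InteractionRecord]:
    """Cationic ↔ anionic group pairs across the interface.

    One record per residue pair, keyed by the closest inter-group atom
    distance.
    """
    records = {}
    for cat_chain, an_chain in ((dimer.chain_a, dimer.chain_b),
                                (dimer.chain_b, dimer.chain_a)):
        cats = _charged_groups(cat_chain, CATIONIC_GROUPS, his_charged,
                               terminus="N" if include_termini else None)
        ans = _charged_groups(an_chain, ANIONIC_GROUPS,
                              terminus="C" if include_termini else None)
        for rc, cat_atoms in cats:
            for ra, an_atoms in ans:
                best = None
                pair = None
                for a1 in cat_atoms:
                    for a2 in an_atoms:
                        d = float(np.linalg.norm(a1.position - a2.position))
                        if best is None or d < best:
                            best, pair = d, (a1.name, a2.name)
                if best is not None and best <= cutoff:
                    key = (rc.key, ra.key)
                    if key not in records or best < records[key].distance:
                        records[key] = InteractionRecord(
                            "salt_bridge", rc.key, ra.key, rc.residue_name,
                            ra.residue_name, best, atom_a=pair[0], atom_b=pair[1])
    return list(records.values())


def pi_systems(
    dimer: DimerStructure,
    thresholds: InteractionThresholds | None = None,
) -> list[InteractionRecord]:
    """π–π stacking, T-stacking and cation–π records across the interface.

    A ring pair gets at most one class, π–π before T-stack; cation–π is
    evaluated independently between each chain's cations and the partner's
    rings.
    """
    th = thresholds or InteractionThresholds()
    rings_a = rings_of(dimer.chain_a)
    rings_b = rings_of(dimer.chain_b)
    records = []

    seen_pairs = set()
    for ra in rings_a:
        for rb in rings_b:
            pair = (ra.residue.key, rb.residue.key)
            d = float(np.linalg.norm(ra.centroid - rb.centroid))
            ang = _plane_angle(ra.normal, rb.normal)
            kind = None
            if d <= th.pi_pi_dist and ang <= th.pi_pi_angle:
                off = min(_offset_in_plane(rb.centroid, ra), _offset_in_plane(ra.centroid, rb))
                if off <= max(ra.radius, rb.radius) + th.ring_padding:
                    kind = "pi_pi"
            if kind is None and d <= th.t_stack_dist and abs(ang - 90.0) <= th.t_stack_angle_dev:
                kind = "t_stack"
            if kind is not None and pair not in seen_pairs:
                seen_pairs.add(pair)
                records.append(InteractionRecord(
                    kind, ra.residue.key, rb.residue.key,
                    ra.residue.residue_name, rb.residue.residue_name, d, angle=ang))

    for cat_chain, ring_list, flip in ((dimer.chain_a, rings_b, False),
                                       (dimer.chain_b, rings_a, True)):
        cats = _charged_groups(cat_chain, CATIONIC_GROUPS, th.his_charged)
        for rc, atoms in cats:
            centre = np.mean([a.position for a in atoms], axis=0)
            for ring in ring_list:
                d = float(np.linalg.norm(centre - ring.centroid))
                if d > th.cation_pi_dist:
                    continue
                if _offset_in_plane(centre, ring) > ring.radius + th.ring_padding:
                    continue
                a_key, b_key = (rc.key, ring.residue.key)
                a_n, b_n = rc.residue_name, ring.residue.residue_name
                if flip:  # keep residue_a on chain A for a stable record layout
                    a_key, b_key, a_n, b_n = b_key, a_key, b_n, a_n
                records.append(InteractionRecord("cation_pi", a_key, b_key, a_n, b_n, d))
    return records


# ---------------------------------------------------------------------------
# aggregation


def detect_all(
    dimer: DimerStructure,
    thresholds: InteractionThresholds | None = None,
    method: str = "kdtree",
) -> list[InteractionRecord]:
    """All interaction records of every kind for one dimer."""
    th = thresholds or InteractionThresholds()
    th.validate()
    records: list[InteractionRecord] = []
    records += hydrophobic_contacts(dimer, th.hydrophobic, method)
    records += hydrogen_bonds(dimer, th.hbond_dist, th.hbond_angle_dev)
    records += salt_bridges(dimer, th.salt_bridge, th.his_charged)
    records += pi_systems(dimer, th)
    return records


def fingerprint(
    dimer: DimerStructure,
    thresholds: InteractionThresholds | None = None,
    method: str = "kdtree",
) -> pd.DataFrame:
    """One row per residue with the eight per-kind interaction counts."""
    th = thresholds or InteractionThresholds()
    th.validate()
    counts = {r.key: dict.fromkeys(KINDS, 0) for r in dimer.residues()}
    for cutoff, kind in ((th.close_short, "close_25"), (th.close_long, "close_40")):
        for key, n in close_contacts(dimer, cutoff, method).items():
            counts[key][kind] = n
    for rec in detect_all(dimer, th, method):
        counts[rec.residue_a][rec.kind] += 1
        counts[rec.residue_b][rec.kind] += 1
    rows = []
    for res in dimer.residues():
        row = {"pdb_id": dimer.source_id, "chain": res.chain_id,
               "resi": res.residue_seq, "icode": res.insertion_code,
               "resn": res.residue_name}
        row.update(counts[res.key])
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records: list[InteractionRecord], pdb_id: str = "") -> pd.DataFrame:
    """Long-format interactions table (one row per record)."""
    rows = []
    for r in records:
        rows.append({
            "pdb_id": pdb_id, "kind": r.kind,
            "chain_a": r.residue_a[0], "resi_a": r.residue_a[1], "resn_a": r.resn_a,
            "chain_b": r.residue_b[0], "resi_b": r.residue_b[1], "resn_b": r.resn_b,
            "distance": r.distance, "angle": r.angle,
            "atom_a": r.atom_a, "atom_b": r.atom_b,
            "flags": ";".join(r.flags),
        })
    cols = ["pdb_id", "kind", "chain_a", "resi_a", "resn_a", "chain_b", "resi_b",
            "resn_b", "distance", "angle", "atom_a", "atom_b", "flags"]
    return pd.DataFrame(rows, columns=cols)
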