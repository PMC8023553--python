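"""Synthetic PDB-format structures with analytically known geometry.

Every downstream computation — the solvent-surface engine and each
interaction detector — is exercised against structures built here, whose
advertised geometric quantities (donor–acceptor distances, ring plane
angles, centroid separations) are realized exactly by construction.  Rings
are ideal 1.39 Å hexagons mimicking phenylalanine; charged groups carry real
residue atom names (ARG NH1/NH2/CZ, GLU OE1/OE2/CD) so the atom-typing
tables are exercised rather than bypassed.

All motifs are deterministic for a given :class:`FixtureSpec` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, DimerStructure, Residue

MOTIFS = (
    "isolated_atom",
    "sphere_pair",
    "extended_tripeptide",
    "hbond_pair",
    "salt_bridge_pair",
    "parallel_rings",
    "t_rings",
    "cation_ring",
    "hydrophobic_pair",
    "two_chain_slab",
)

RING_BOND = 1.39  # aromatic C-C bond length, Å


class FixtureError(ValueError):
    """Inconsistent fixture parameters."""


@dataclass
class FixtureSpec:
    motif: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise FixtureError(f"unknown motif {self.motif!r}; choose from {MOTIFS}")
        for key, val in self.parameters.items():
            if "angle" in key or key == "dihedral":
                if not 0 <= val <= 180:
                    raise FixtureError(f"{key} must be in [0, 180], got {val}")
            elif ("dist" in key or key.startswith("d_")
                  or key in ("separation", "height", "radius")):
                if val <= 0:
                    raise FixtureError(f"{key} must be > 0, got {val}")


class _Builder:
    """Accumulates residues with sequential serial numbers."""

    def __init__(self):
        self.serial = 0
        self.chains: dict[str, list[Residue]] = {}

    def residue(self, chain: str, seq: int, name: str,
                atoms: list[tuple[str, str, np.ndarray]], b: float = 20.0) -> Residue:
        res = Residue(chain, seq, "", name)
        for atom_name, element, pos in atoms:
            self.serial += 1
            res.atoms.append(Atom(self.serial, atom_name, element, "", name, chain,
                                  seq, "", np.asarray(pos, float), 1.0, b))
        self.chains.setdefault(chain, []).append(res)
        return res


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = RING_BOND) -> np.ndarray:
    """Six ring vertices in the plane through ``center`` with unit ``normal``."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = np.deg2rad(np.arange(0, 360, 60))
    return center + radius * (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))


def _phe_ring(b: _Builder, chain: str, seq: int, center, normal, cb_dir=None) -> None:
    """A PHE residue: ideal aromatic hexagon plus CB/CA stub off the ring."""
    verts = _hexagon(np.asarray(center, float), np.asarray(normal, float))
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = [(n, "C", p) for n, p in zip(names, verts)]
    cg = verts[0]
    out = cg - np.asarray(center, float)
    nrm = np.linalg.norm(out)
    out = out / nrm if nrm > 0 else np.array([1.0, 0, 0])
    if cb_dir is not None:
        out = np.asarray(cb_dir, float) / np.linalg.norm(cb_dir)
    atoms.append(("CB", "C", cg + 1.51 * out))
    atoms.append(("CA", "C", cg + 1.51 * out + 1.53 * out))
    b.residue(chain, seq, "PHE", atoms)


def build_fixture(spec: FixtureSpec) -> DimerStructure | list[Residue]:
    """Realize a motif; two-chain motifs return a :class:`DimerStructure`."""
    p = spec.parameters
    b = _Builder()
    motif = spec.motif

    if motif == "isolated_atom":
        element = p.get("element", "C")
        b.residue("A", 1, "ALA", [("CA", element, np.zeros(3))])
        return b.chains["A"]

    if motif == "sphere_pair":
        d = p.get("distance", 3.4)
        element = p.get("element", "C")
        b.residue("A", 1, "ALA", [("CA", element, np.zeros(3))])
        b.residue("A", 2, "ALA", [("CA", element, np.array([d, 0.0, 0.0]))])
        return b.chains["A"]

    if motif == "extended_tripeptide":
        # Gly-Ala-Gly in an idealized extended (zig-zag) conformation.
        names = ["GLY", "ALA", "GLY"]
        for i, resn in enumerate(names):
            x0 = 3.8 * i
            up = 0.6 if i % 2 == 0 else -0.6
            atoms = [
                ("N", "N", np.array([x0 - 1.2, up * 0.5, 0.0])),
                ("CA", "C", np.array([x0, up, 0.0])),
                ("C", "C", np.array([x0 + 1.3, up * 0.4, 0.0])),
                ("O", "O", np.array([x0 + 1.4, up * 0.4, 1.2])),
            ]
            if resn == "ALA":
                atoms.append(("CB", "C", np.array([x0, up + 1.0, 1.2])))
            b.residue("A", i + 1, resn, atoms)
        return b.chains["A"]

    if motif == "hbond_pair":
        d_da = p.get("d_DA", 2.9)
        theta = np.deg2rad(p.get("angle", 180.0))  # D-H-A angle at the hydrogen
        # Donor: glycine backbone N-H; H 1.0 Å from N along +x.
        n_pos = np.zeros(3)
        h_pos = np.array([1.0, 0.0, 0.0])
        c = np.cos(theta)
        r = c + np.sqrt(max(c * c - 1.0 + d_da * d_da, 0.0))  # |H-A| from law of cosines
        u = np.array([-c, np.sin(theta), 0.0])  # unit vector at angle theta to H->D(-x)
        a_pos = h_pos + r * u
        b.residue("A", 1, "GLY", [
            ("N", "N", n_pos), ("H", "H", h_pos),
            ("CA", "C", np.array([-0.9, -1.2, 0.0])),
            ("C", "C", np.array([-2.3, -1.0, 0.0])),
            ("O", "O", np.array([-3.0, -2.0, 0.0])),
        ])
        b.residue("B", 1, "SER", [
            ("OG", "O", a_pos),
            ("CB", "C", a_pos + np.array([0.6, 1.2, 0.4])),
            ("CA", "C", a_pos + np.array([1.2, 2.4, 0.8])),
        ])
        return DimerStructure(b.chains["A"], b.chains["B"], source_id="hbond_pair")

    if motif == "salt_bridge_pair":
        d = p.get("distance", 4.0)  # closest inter-group atom distance (NH1..OE1)
        # ARG guanidinium in the xy plane, NH1 pointing +x.
        cz = np.zeros(3)
        nh1 = np.array([1.33, 0.0, 0.0])
        nh2 = np.array([-0.66, 1.15, 0.0])
        ne = np.array([-0.66, -1.15, 0.0])
        b.residue("A", 1, "ARG", [
            ("CZ", "C", cz), ("NH1", "N", nh1), ("NH2", "N", nh2), ("NE", "N", ne),
            ("CD", "C", ne + np.array([-1.2, -0.9, 0.0])),
            ("CG", "C", ne + np.array([-2.4, -1.8, 0.0])),
            ("CB", "C", ne + np.array([-3.6, -2.7, 0.0])),
            ("CA", "C", ne + np.array([-4.8, -3.6, 0.0])),
        ])
        oe1 = nh1 + np.array([d, 0.0, 0.0])
        cd_ = oe1 + np.array([1.0, 0.75, 0.0])
        oe2 = cd_ + np.array([0.3, 1.2, 0.0])
        b.residue("B", 1, "GLU", [
            ("OE1", "O", oe1), ("CD", "C", cd_), ("OE2", "O", oe2),
            ("CG", "C", cd_ + np.array([1.4, -0.6, 0.0])),
            ("CB", "C", cd_ + np.array([2.8, -1.2, 0.0])),
            ("CA", "C", cd_ + np.array([4.2, -1.8, 0.0])),
        ])
        return DimerStructure(b.chains["A"], b.chains["B"], source_id="salt_bridge_pair")

    if motif in ("parallel_rings", "t_rings"):
        d = p.get("centroid_dist", 3.6 if motif == "parallel_rings" else 5.0)
        dihedral = p.get("dihedral", 0.0 if motif == "parallel_rings" else 90.0)
        phi = np.deg2rad(dihedral)
        _phe_ring(b, "A", 1, center=[0, 0, 0], normal=[0, 0, 1], cb_dir=[1, 0, 0])
        n2 = np.array([0.0, np.sin(phi), np.cos(phi)])  # angle `dihedral` to ring-1 normal
        _phe_ring(b, "B", 1, center=[0, 0, d], normal=n2, cb_dir=[1, 0, 0])
        return DimerStructure(b.chains["A"], b.chains["B"], source_id=motif)

    if motif == "cation_ring":
        h = p.get("height", 4.0)
        _phe_ring(b, "A", 1, center=[0, 0, 0], normal=[0, 0, 1], cb_dir=[1, 0, 0])
        nz = np.array([0.0, 0.0, h])
        b.residue("B", 1, "LYS", [
            ("NZ", "N", nz),
            ("CE", "C", nz + np.array([0.0, 1.3, 0.6])),
            ("CD", "C", nz + np.array([0.0, 2.6, 1.2])),
            ("CG", "C", nz + np.array([0.0, 3.9, 1.8])),
            ("CB", "C", nz + np.array([0.0, 5.2, 2.4])),
            ("CA", "C", nz + np.array([0.0, 6.5, 3.0])),
        ])
        return DimerStructure(b.chains["A"], b.chains["B"], source_id="cation_ring")

    if motif == "hydrophobic_pair":
        d = p.get("distance", 3.8)
        b.residue("A", 1, "LEU", [
            ("CD1", "C", np.zeros(3)),
            ("CG", "C", np.array([-1.0, 1.1, 0.0])),
            ("CD2", "C", np.array([-2.4, 1.0, 0.6])),
            ("CB", "C", np.array([-1.0, 2.2, -1.1])),
            ("CA", "C", np.array([-2.1, 3.2, -1.2])),
        ])
        b.residue("B", 1, "VAL", [
            ("CG1", "C", np.array([d, 0.0, 0.0])),
            ("CB", "C", np.array([d + 1.0, 1.1, 0.0])),
            ("CG2", "C", np.array([d + 2.4, 0.9, 0.5])),
            ("CA", "C", np.array([d + 1.0, 2.2, 1.1])),
        ])
        return DimerStructure(b.chains["A"], b.chains["B"], source_id="hydrophobic_pair")

    if motif == "two_chain_slab":
        n = int(p.get("n_residues", 6))
        sep = p.get("separation", 8.0)
        for i in range(n):
            x0 = 3.8 * i
            b.residue("A", i + 1, "ALA", _ala_atoms(np.array([x0, 0.0, 0.0])))
        for i in range(n):
            x0 = 3.8 * i
            b.residue("B", i + 1, "ALA", _ala_atoms(np.array([x0, sep, 0.0])))
        return DimerStructure(b.chains["A"], b.chains["B"], source_id="two_chain_slab")

    raise FixtureError(motif)  # pragma: no cover


def _ala_atoms(ca: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    return [
        ("N", "N", ca + np.array([-1.2, -0.6, 0.3])),
        ("CA", "C", ca),
        ("C", "C", ca + np.array([1.3, -0.5, 0.2])),
        ("O", "O", ca + np.array([1.5, -0.6, 1.4])),
        ("CB", "C", ca + np.array([0.0, 1.2, 1.0])),
    ]


_AA20 = "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()


def _random_walk(n: int, rng: np.random.Generator, origin: np.ndarray) -> np.ndarray:
    """Self-avoiding CA trace with 3.8 Å steps."""
    pts = [origin]
    while len(pts) < n:
        for _ in range(200):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = pts[-1] + step
            if all(np.linalg.norm(cand - q) > 3.5 for q in pts[:-1]):
                pts.append(cand)
                break
        else:  # restart tail on a dead end (rare at these sizes)
            pts = [origin]
    return np.array(pts)


def build_random_dimer(
    n_residues_per_chain: int,
    separation: float = 6.0,
    seed: int = 0,
) -> DimerStructure:
    """Two self-avoiding random-coil chains with plausible bond lengths.

    Chain B is the mirror strategy of chain A displaced by ``separation``
    along x; residue identities and B-factors are drawn from the seeded
    generator, so a given (n, separation, seed) is fully deterministic.
    """
    if n_residues_per_chain < 1:
        raise FixtureError("n_residues_per_chain must be >= 1")
    rng = np.random.default_rng(seed)
    b = _Builder()
    for chain_id, origin in (("A", np.zeros(3)), ("B", np.array([separation, 0.0, 0.0]))):
        trace = _random_walk(n_residues_per_chain, rng, origin)
        for i, ca in enumerate(trace):
            resn = _AA20[rng.integers(0, 20)]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            atoms = [
                ("N", "N", ca + 1.46 * u),
                ("CA", "C", ca),
                ("C", "C", ca - 1.52 * u),
                ("O", "O", ca - 1.52 * u + 1.23 * v),
                ("CB", "C", ca + 1.53 * np.cross(u, v) / max(np.linalg.norm(np.cross(u, v)), 1e-9)),
            ]
            if resn == "GLY":
                atoms = atoms[:4]
            b.residue(chain_id, i + 1, resn, atoms, b=float(rng.uniform(5.0, 60.0)))
    return DimerStructure(b.chains["A"], b.chains["B"], source_id=f"random-{seed}")
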