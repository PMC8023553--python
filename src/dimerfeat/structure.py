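"""Read, sanitize and slice PDB structures into analysis-ready dimers.

Structures are held as plain dataclasses (:class:`Atom`, :class:`Residue`,
:class:`DimerStructure`) so every geometric computation downstream consumes
one simple, explicit unit.  Parsing and serialization of the PDB format are
delegated to :mod:`gemmi`; this module owns the sanitization policy
(heteroatom removal, non-standard residue reversal, alt-loc resolution) and
the dimer enumeration / transmembrane-trimming steps.

Author residue numbering and insertion codes are preserved throughout so
output rows can be matched back to the source entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("dimerfeat")

#: The 20 standard amino acids (3-letter codes).
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Reversal table for common chemically modified residues.  Values are
#: (standard 3-letter name, {old atom name: new atom name}).  Selenium
#: atoms are renamed to the sulfur they replace so downstream atom typing
#: sees canonical names.
NONSTANDARD_MAP: dict[str, tuple[str, dict[str, str]]] = {
    "MSE": ("MET", {"SE": "SD"}),   # selenomethionine
    "SEC": ("CYS", {"SE": "SG"}),   # selenocysteine
    "SEP": ("SER", {}),             # phosphoserine (phosphate atoms dropped)
    "TPO": ("THR", {}),             # phosphothreonine
    "PTR": ("TYR", {}),             # phosphotyrosine
    "CSO": ("CYS", {}),             # S-hydroxycysteine
    "HYP": ("PRO", {}),             # hydroxyproline
    "MLY": ("LYS", {}),             # N-dimethyl-lysine
    "M3L": ("LYS", {}),
    "KCX": ("LYS", {}),
    "CME": ("CYS", {}),
    "PCA": ("GLU", {}),             # pyroglutamate
}

#: Atoms belonging only to the modification, removed when the parent
#: residue is reverted (e.g. phosphate of SEP).
_MODIFICATION_ATOMS = {"P", "O1P", "O2P", "O3P", "OP1", "OP2", "OP3"}


class StructureError(ValueError):
    """Raised for unusable structure input (empty model, unknown format)."""


@dataclass
class Atom:
    """One atom record; coordinates in Å, B-factor in Å²."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """One residue: identity keys plus its atoms."""

    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)

    def mean_b_factor(self) -> float:
        heavy = self.heavy_atoms()
        if not heavy:
            return float("nan")
        return float(np.mean([a.b_factor for a in heavy]))


@dataclass
class DimerStructure:
    """A pair of chains analysed as one dimer."""

    chain_a: list[Residue]
    chain_b: list[Residue]
    source_id: str = ""
    tm_mask: set[tuple[str, int]] | None = None

    def __post_init__(self):
        if not self.chain_a or not self.chain_b:
            raise StructureError("both chains of a dimer must be non-empty")
        ida, idb = self.chain_a[0].chain_id, self.chain_b[0].chain_id
        if ida == idb:
            raise StructureError(f"dimer chains must have distinct IDs, got {ida!r} twice")

    @property
    def chain_ids(self) -> tuple[str, str]:
        return self.chain_a[0].chain_id, self.chain_b[0].chain_id

    def residues(self) -> list[Residue]:
        return list(self.chain_a) + list(self.chain_b)

    def swapped(self) -> "DimerStructure":
        return DimerStructure(self.chain_b, self.chain_a, self.source_id, self.tm_mask)


# ---------------------------------------------------------------------------
# reading


def _resolve_alt_locs(atoms: list[Atom]) -> list[Atom]:
    # Keep the highest-occupancy alternate location; ties break alphabetically
    # (blank alt-loc sorts first, so unmodified atoms win ties).
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occupancy, a.alt_loc))
        kept.append(replace(group[0], alt_loc=""))
    kept.sort(key=lambda a: a.serial)
    return kept


def read_structure(path: str | Path, model_index: int = 0) -> list[list[Residue]]:
    """Read one model of a PDB file as chains of residues.

    Alternate locations are resolved (highest occupancy, alphabetical
    tie-break), hydrogens are retained, HETATM records are kept for
    :func:`sanitize` to deal with.  Raises :class:`StructureError` for
    unreadable files or an empty model.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureError(f"unparseable PDB file {path}: {exc}") from exc
    if model_index >= len(st):
        raise StructureError(f"model {model_index} absent ({len(st)} model(s) in {path})")
    model = st[model_index]

    chains: list[list[Residue]] = []
    n_atoms = 0
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            icode = res.seqid.icode.strip()
            r = Residue(ch.name, res.seqid.num, icode, res.name.strip())
            raw: list[Atom] = []
            for at in res:
                raw.append(
                    Atom(
                        serial=at.serial,
                        name=at.name.strip(),
                        element=at.element.name.upper() or _infer_element(at.name),
                        alt_loc=at.altloc.strip() if isinstance(at.altloc, str) else (at.altloc or ""),
                        residue_name=r.residue_name,
                        chain_id=ch.name,
                        residue_seq=res.seqid.num,
                        insertion_code=icode,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ),
                        b_factor=max(float(at.b_iso), 0.0),
                    )
                )
            r.atoms = _resolve_alt_locs(raw)
            n_atoms += len(r.atoms)
            if r.atoms:
                residues.append(r)
        if residues:
            chains.append(residues)
    if n_atoms == 0:
        raise StructureError(f"no ATOM records in {path}")
    return chains


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise StructureError("atom with empty name and no element")
    if name[0].isdigit():  # e.g. 1HB
        name = name.lstrip("0123456789")
    return name[0].upper()


# ---------------------------------------------------------------------------
# sanitization


_SOLVENT = {"HOH", "DOD", "WAT"}


def sanitize(
    chains: list[list[Residue]],
    mapping_table: dict[str, tuple[str, dict[str, str]]] | None = None,
) -> list[list[Residue]]:
    """Remove heteroatom ligands/waters and revert modified residues.

    Residues named in ``mapping_table`` (default :data:`NONSTANDARD_MAP`)
    are renamed to their parent standard residue, with modification-specific
    atoms renamed or dropped (e.g. selenomethionine SE becomes methionine SD).
    Residues that are neither standard nor mapped are dropped with a warning;
    so are residues left without heavy atoms.
    """
    table = NONSTANDARD_MAP if mapping_table is None else mapping_table
    out: list[list[Residue]] = []
    n_dropped = 0
    for ch in chains:
        kept: list[Residue] = []
        for res in ch:
            name = res.residue_name
            if name in _SOLVENT:
                continue
            if name in table:
                std_name, atom_map = table[name]
                atoms = []
                for a in res.atoms:
                    if a.name in _MODIFICATION_ATOMS and a.name not in atom_map:
                        continue
                    new_name = atom_map.get(a.name, a.name)
                    element = "S" if new_name in ("SD", "SG") and a.element == "SE" else a.element
                    atoms.append(replace(a, name=new_name, element=element, residue_name=std_name))
                res = Residue(res.chain_id, res.residue_seq, res.insertion_code, std_name, atoms)
            elif name not in STANDARD_RESIDUES:
                n_dropped += 1
                logger.warning("dropping non-standard residue %s %s%d%s",
                               name, res.chain_id, res.residue_seq, res.insertion_code)
                continue
            if not res.heavy_atoms():
                n_dropped += 1
                logger.warning("dropping residue with no heavy atoms: %s %s%d",
                               res.residue_name, res.chain_id, res.residue_seq)
                continue
            kept.append(res)
        if kept:
            out.append(kept)
    if n_dropped:
        logger.warning("sanitize dropped %d residue(s)", n_dropped)
    return out


# ---------------------------------------------------------------------------
# dimer enumeration / TM trimming


def _chain_heavy_coords(chain: list[Residue]) -> np.ndarray:
    return np.concatenate([r.coords(heavy_only=True) for r in chain])


def min_interchain_distance(chain_a: list[Residue], chain_b: list[Residue]) -> float:
    """Minimum heavy-atom distance between two chains."""
    xa, xb = _chain_heavy_coords(chain_a), _chain_heavy_coords(chain_b)
    tree = cKDTree(xb)
    d, _ = tree.query(xa, k=1)
    return float(np.min(d))


def enumerate_dimers(
    chains: list[list[Residue]],
    contact_cutoff: float = 5.0,
    source_id: str = "",
) -> list[DimerStructure]:
    """All unordered chain pairs that are in heavy-atom contact.

    Pairs whose closest interchain heavy-atom distance is not below
    ``contact_cutoff`` are excluded and logged.  A single chain yields an
    empty list with a warning.
    """
    if len(chains) < 2:
        warnings.warn("enumerate_dimers: fewer than two chains, no dimers")
        return []
    dimers = []
    for ca, cb in combinations(chains, 2):
        if min_interchain_distance(ca, cb) < contact_cutoff:
            dimers.append(DimerStructure(ca, cb, source_id=source_id))
        else:
            logger.info("chain pair %s/%s not in contact at %.1f Å, skipped",
                        ca[0].chain_id, cb[0].chain_id, contact_cutoff)
    return dimers


def read_tm_annotation(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a per-chain transmembrane range file: ``chain<TAB>start<TAB>end``."""
    ranges: dict[str, list[tuple[int, int]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise StructureError(f"{path}:{i}: expected 'chain start end', got {line!r}")
        ranges.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return ranges


def apply_tm_mask(
    dimer: DimerStructure,
    annotation: dict[str, list[tuple[int, int]]] | None,
) -> DimerStructure:
    """Trim residues outside annotated transmembrane ranges.

    Chains absent from the annotation keep all residues (with a warning);
    ranges matching no residue are warned about and ignored.
    """
    if not annotation:
        return dimer

    def trim(chain: list[Residue]) -> list[Residue]:
        cid = chain[0].chain_id
        if cid not in annotation:
            warnings.warn(f"no TM annotation for chain {cid}; keeping all residues")
            return list(chain)
        ranges = annotation[cid]
        kept = [r for r in chain if any(lo <= r.residue_seq <= hi for lo, hi in ranges)]
        if not kept:
            warnings.warn(f"TM ranges {ranges} match no residue of chain {cid}; ignored")
            return list(chain)
        return kept

    a, b = trim(dimer.chain_a), trim(dimer.chain_b)
    mask = {(r.chain_id, r.residue_seq) for r in a + b}
    return DimerStructure(a, b, dimer.source_id, tm_mask=mask)


# ---------------------------------------------------------------------------
# writing


def write_pdb(chains: list[list[Residue]] | DimerStructure, path: str | Path) -> None:
    """Write chains to a PDB file (fixed columns, via gemmi)."""
    if isinstance(chains, DimerStructure):
        chains = [chains.chain_a, chains.chain_b]
    st = gemmi.Structure()
    st.name = "dimerfeat"
    model = gemmi.Model("1")
    for ch in chains:
        gch = gemmi.Chain(ch[0].chain_id)
        for res in ch:
            gres = gemmi.Residue()
            gres.name = res.residue_name
            gres.seqid = gemmi.SeqId(res.residue_seq, res.insertion_code or " ")
            for a in res.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.serial = a.serial
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.position)
                gat.occ = a.occupancy
                gat.b_iso = a.b_factor
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)
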