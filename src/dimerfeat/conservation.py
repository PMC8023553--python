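"""Per-position conservation scores from PSSMs via Jensen–Shannon divergence.

A position's weighted-percentage row of a PSI-BLAST PSSM, renormalized to a
probability vector p, is compared against a background amino-acid
distribution f with

    JSD(p, f) = H((p + f) / 2) − H(p)/2 − H(f)/2

where H is Shannon entropy in bits, so the score lies in [0, 1]; a higher
value means the observed distribution departs more from background, i.e. a
more conserved position.  Three named backgrounds are shipped: the BLOSUM62
marginals, and synthetic stand-ins for the α-helical-TM (SLIM-like) and
β-barrel-TM (bbTM-like) compositions; any 20-vector can be supplied
instead.  The "appropriate" background for a protein is chosen by its fold:
α-helical bundles get the TM-helical background, β-barrels the barrel one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger("dimerfeat")

#: Canonical amino-acid order for all 20-vectors in this package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_BACKGROUND_FILES = {
    "blosum62": "blosum62_background.txt",
    "slim": "slim_background.synthetic.txt",
    "bbtm_tm": "bbtm_tm_background.synthetic.txt",
}

_LOG_FLOOR = 1e-10


class ConservationError(ValueError):
    pass


class PSSMParseError(ConservationError):
    pass


@dataclass
class BackgroundDistribution:
    """A named background frequency 20-vector (order :data:`AA_ORDER`)."""

    name: str
    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (20,):
            raise ConservationError("background must be a 20-vector")
        if np.any(self.f <= 0):
            raise ConservationError("background frequencies must be strictly positive")
        if abs(self.f.sum() - 1.0) > 1e-4:  # printed-precision slack; renormalized below
            raise ConservationError(f"background {self.name!r} sums to {self.f.sum():.6f}")
        self.f = self.f / self.f.sum()


@dataclass
class PSSM:
    """Per-position amino-acid probability rows plus the query sequence."""

    p: np.ndarray          # (length, 20), rows sum to 1
    sequence: str

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != 20:
            raise ConservationError("PSSM probabilities must be (L, 20)")
        if len(self.sequence) != self.p.shape[0]:
            raise ConservationError("sequence length does not match matrix")
        if np.any(self.p < 0):
            raise ConservationError("PSSM probabilities must be non-negative")
        sums = self.p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ConservationError("PSSM rows must sum to 1 after renormalization")

    @property
    def length(self) -> int:
        return self.p.shape[0]


def get_background(name: str) -> BackgroundDistribution:
    """Load a shipped background distribution by name."""
    if name not in _BACKGROUND_FILES:
        raise ConservationError(
            f"unknown background {name!r}; choose from {sorted(_BACKGROUND_FILES)}")
    text = resources.files("dimerfeat.data").joinpath(_BACKGROUND_FILES[name]).read_text()
    return BackgroundDistribution(name, _parse_background_text(text))


def read_background(path: str | Path, name: str | None = None) -> BackgroundDistribution:
    """Read a background 20-vector from a name/value text file."""
    path = Path(path)
    return BackgroundDistribution(name or path.stem, _parse_background_text(path.read_text()))


def _parse_background_text(text: str) -> np.ndarray:
    vec = np.full(20, np.nan)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split()
        vec[_AA_INDEX[aa]] = float(val)
    if np.any(np.isnan(vec)):
        missing = [a for a in AA_ORDER if np.isnan(vec[_AA_INDEX[a]])]
        raise ConservationError(f"background file missing amino acids: {missing}")
    return vec


def appropriate_background(protein_fold: str) -> BackgroundDistribution:
    """Fold-matched background: α-helical → TM-helical, β-barrel → barrel-TM."""
    if protein_fold == "alpha_helical":
        return get_background("slim")
    if protein_fold == "beta_barrel":
        return get_background("bbtm_tm")
    raise ConservationError(
        f"unknown fold {protein_fold!r}: declare 'alpha_helical' or 'beta_barrel', "
        "or choose a background explicitly in the configuration")


# ---------------------------------------------------------------------------
# PSSM parsing (PSI-BLAST -out_ascii_pssm layout)


def read_pssm(path: str | Path, background: BackgroundDistribution | None = None) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM.

    The weighted-percentage block (columns 23–42 of each data row) is taken,
    divided by 100 and renormalized per position.  All-zero rows (positions
    PSI-BLAST could not weight) are replaced by the background distribution
    — BLOSUM62 if none is given — with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    header_line = 0
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 40 and all(t in _AA_INDEX for t in toks[:40]):
            header_cols = toks[:40]
            header_line = i
            break
    if header_cols is None:
        raise PSSMParseError(f"{path}: no 40-column amino-acid header found")
    pct_order = header_cols[20:]

    rows: list[np.ndarray] = []
    seq: list[str] = []
    for i, line in enumerate(lines[header_line + 1:], start=header_line + 2):
        toks = line.split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].isdigit():
            break  # footer (Lambda/K statistics)
        if len(toks) < 42:
            raise PSSMParseError(f"{path}:{i}: truncated PSSM row ({len(toks)} fields, need ≥42)")
        aa = toks[1]
        if aa not in _AA_INDEX:
            raise PSSMParseError(f"{path}:{i}: unknown residue letter {aa!r}")
        try:
            pct = np.array([float(t) for t in toks[22:42]])
        except ValueError as exc:
            raise PSSMParseError(f"{path}:{i}: non-numeric percentage field: {exc}") from exc
        vec = np.zeros(20)
        for col_aa, val in zip(pct_order, pct):
            vec[_AA_INDEX[col_aa]] = val / 100.0
        rows.append(vec)
        seq.append(aa)
    if not rows:
        raise PSSMParseError(f"{path}: matrix block is empty")

    p = np.array(rows)
    zero = p.sum(axis=1) == 0
    if zero.any():
        if background is None:
            background = get_background("blosum62")
        warnings.warn(f"{path}: {int(zero.sum())} all-zero PSSM row(s) replaced "
                      f"by the {background.name} background")
        p[zero] = background.f
    p = p / p.sum(axis=1, keepdims=True)
    return PSSM(p=p, sequence="".join(seq))


# ---------------------------------------------------------------------------
# scoring


def _entropy_bits(v: np.ndarray) -> float:
    # 0·log 0 ≡ 0, handled by masking before the floored log.
    nz = v > 0
    return float(-(v[nz] * np.log2(np.maximum(v[nz], _LOG_FLOOR))).sum())


def jsd_score(p: np.ndarray, background: BackgroundDistribution | np.ndarray) -> float:
    """Jensen–Shannon divergence (bits, base 2) between ``p`` and a background.

    Symmetric in its arguments, zero iff the distributions coincide, and
    bounded by 1.
    """
    f = background.f if isinstance(background, BackgroundDistribution) else np.asarray(background, float)
    p = np.asarray(p, dtype=float)
    for name, v in (("p", p), ("background", f)):
        if v.shape != (20,):
            raise ConservationError(f"{name} must be a 20-vector")
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ConservationError(f"{name} is not a probability distribution (sum {v.sum():.6f})")
    m = 0.5 * (p + f)
    return _entropy_bits(m) - 0.5 * _entropy_bits(p) - 0.5 * _entropy_bits(f)


def conservation_profile(pssm: PSSM, background: BackgroundDistribution) -> np.ndarray:
    """JSD conservation score for every PSSM position."""
    return np.array([jsd_score(pssm.p[i], background) for i in range(pssm.length)])
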