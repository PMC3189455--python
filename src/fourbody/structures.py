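"""Read and write C-alpha traces in PDB format.

A protein chain is abstracted as its C-alpha trace: one point per residue,
carrying the amino-acid type and the alpha-carbon coordinates.  This is the
geometric substrate for Delaunay tessellation; everything downstream (the
four-body potential, potential profiles, residual profiles) operates on these
traces.

Reading goes through :mod:`Bio.PDB`; writing emits the CA-only subset of
wwPDB v3.3 fixed-width ATOM records so that traces round-trip through plain
text files.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "AA_ALPHABET",
    "ResiduePoint",
    "CAlphaTrace",
    "GapFlag",
    "PDBParseError",
    "parse_pdb_calpha",
    "check_gaps",
    "write_pdb_calpha",
]

#: The 20 standard amino-acid one-letter codes, alphabetically sorted.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {k: v for k, v in protein_letters_3to1.items() if v in AA_ALPHABET}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised when PDB text cannot be turned into a usable C-alpha trace."""


@dataclass(frozen=True)
class ResiduePoint:
    """One residue of a C-alpha trace.

    Parameters
    ----------
    seq_index
        1-based ordinal position in the (validated) chain.
    residue_id
        Author-assigned residue number plus insertion code, as a string
        (used for gap reporting only; ordering follows file order).
    aa
        One-letter code, one of the 20 standard types.
    coord
        Alpha-carbon position in Angstrom, shape ``(3,)``.
    """

    seq_index: int
    residue_id: str
    aa: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        if self.aa not in AA_ALPHABET:
            raise ValueError(f"nonstandard amino-acid type {self.aa!r}")
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coord must be 3 finite components")
        object.__setattr__(self, "coord", c)


@dataclass
class CAlphaTrace:
    """An ordered C-alpha trace of a single chain."""

    chain_id: str
    residues: list[ResiduePoint]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        """All coordinates as an ``(N, 3)`` array."""
        return np.array([r.coord for r in self.residues], dtype=float)

    def sequence(self) -> str:
        """The amino-acid sequence as a one-letter-code string."""
        return "".join(r.aa for r in self.residues)

    def validate(self) -> None:
        """Check the invariants needed for tessellation."""
        if len(self.residues) < 4:
            raise PDBParseError(
                f"trace has {len(self.residues)} residues; tessellation needs >= 4"
            )
        for i, r in enumerate(self.residues, start=1):
            if r.seq_index != i:
                raise PDBParseError("seq_index values must be consecutive 1..N")


def parse_pdb_calpha(pdb_text: str, chain_id: str | None = None) -> CAlphaTrace:
    """Parse PDB-format text into a C-alpha trace.

    One :class:`ResiduePoint` is produced per residue, taken from atoms named
    ``CA``.  Nonstandard residues and HETATM records are skipped (the
    potential is defined over exactly the 20 standard types, so e.g. MSE is
    dropped rather than translated).  For alternate locations the
    first-listed altLoc is kept.  Only the first model of multi-model files
    is read.

    Parameters
    ----------
    pdb_text
        Raw PDB-format text.
    chain_id
        Chain to extract; if ``None`` the first chain containing CA atoms of
        standard residues is used.

    Raises
    ------
    PDBParseError
        If no CA atoms are found, the requested chain is absent, or fewer
        than 4 residues survive filtering.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("pdb", io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise PDBParseError(f"unreadable PDB text: {exc}") from exc
    models = list(structure)
    if not models:
        raise PDBParseError("no ATOM records / no CA atoms found")
    model = models[0]

    chains = list(model)
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise PDBParseError(f"chain {chain_id!r} not present")

    for chain in chains:
        residues: list[ResiduePoint] = []
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            resname = residue.get_resname().strip()
            if resname not in _THREE_TO_ONE:
                continue
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]
            residues.append(
                ResiduePoint(
                    seq_index=len(residues) + 1,
                    residue_id=f"{resseq}{icode.strip()}",
                    aa=_THREE_TO_ONE[resname],
                    coord=np.asarray(atom.get_coord(), dtype=float),
                )
            )
        if residues:
            if len(residues) < 4:
                raise PDBParseError(
                    f"chain {chain.id!r} has only {len(residues)} standard "
                    "CA residues; tessellation needs >= 4"
                )
            trace = CAlphaTrace(chain_id=chain.id, residues=residues)
            trace.validate()
            return trace
    raise PDBParseError("no ATOM records / no CA atoms found")


@dataclass(frozen=True)
class GapFlag:
    """A flagged consecutive residue pair (possible chain break)."""

    first_seq_index: int
    second_seq_index: int
    distance: float
    numbering_jump: bool


_NUM_RE = re.compile(r"^(-?\d+)")


def _author_number(residue_id: str) -> int | None:
    m = _NUM_RE.match(residue_id)
    return int(m.group(1)) if m else None


def check_gaps(trace: CAlphaTrace, max_gap: float = 4.5) -> list[GapFlag]:
    """Flag consecutive residue pairs that look like chain breaks.

    A pair is flagged when its CA-CA distance exceeds ``max_gap`` or when the
    author residue numbering jumps by more than 1.  An empty report means the
    trace is gap-free.  The default of 4.5 Angstrom is a generous bound above
    the ~3.8 Angstrom CA-CA virtual bond of a continuous chain.
    """
    flags: list[GapFlag] = []
    for a, b in zip(trace.residues, trace.residues[1:]):
        dist = float(np.linalg.norm(b.coord - a.coord))
        na, nb = _author_number(a.residue_id), _author_number(b.residue_id)
        jump = na is not None and nb is not None and (nb - na) > 1
        if dist > max_gap or jump:
            flags.append(GapFlag(a.seq_index, b.seq_index, dist, jump))
    return flags


def write_pdb_calpha(trace: CAlphaTrace) -> str:
    """Emit CA-only ATOM records (wwPDB v3.3 columns) for a trace.

    The output is parseable by :func:`parse_pdb_calpha` with identical
    residue types and coordinates at the printed precision (3 decimals).
    """
    if len(trace.residues) == 0:
        raise ValueError("cannot write an empty trace")
    chain = (trace.chain_id or "A")[0]
    lines = []
    for r in trace.residues:
        num = _author_number(r.residue_id)
        resseq = num if num is not None else r.seq_index
        icode = r.residue_id[len(str(num)):][:1] if num is not None else ""
        x, y, z = r.coord
        lines.append(
            f"ATOM  {r.seq_index:>5d}  CA  {_ONE_TO_THREE[r.aa]:>3s} {chain}"
            f"{resseq:>4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
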