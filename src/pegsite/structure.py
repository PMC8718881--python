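"""Protein structure model: PDB I/O, missing-residue (disorder) detection,
and B-factor flexibility primitives.

The model keeps author (PDB) residue numbering as authoritative, because
engineering literature cites sites in full-length coordinates (K139, R329,
...).  The declared per-chain sequence comes from SEQRES records when
present; every resolved polymer residue is mapped to a declared-sequence
position (``seqres_pos``), which is what disorder detection operates on.

Parsing and the SEQRES-to-coordinates alignment are delegated to ``gemmi``;
alternate conformations are resolved here to the highest-occupancy conformer
(ties broken alphabetically by altloc) for determinism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "DisorderSegment",
    "PdbParseError",
    "EmptyStructureError",
    "parse_pdb",
    "write_pdb",
    "unresolved_segments",
    "bfactor_zscores",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class PdbParseError(ValueError):
    """Malformed PDB content (reports the offending line number)."""


class EmptyStructureError(ValueError):
    """PDB content without any polymer ATOM record."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int           # author numbering
    icode: str            # insertion code, "" if none
    name: str             # three-letter code
    atoms: list[Atom] = field(default_factory=list)
    seqres_pos: int | None = None  # 1-based position in declared sequence
    is_standard: bool = True

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def label(self) -> str:
        """Site label in the field's notation, e.g. ``K139``."""
        return f"{self.one_letter}{self.number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def mean_bfactor(self) -> float:
        return float(np.mean([a.bfactor for a in self.atoms]))


@dataclass
class DisorderSegment:
    chain_id: str
    start: int       # declared-sequence index, 1-based
    end: int         # inclusive
    terminal: str    # "N", "C", or "internal"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinStructure:
    """Chains of resolved polymer residues plus per-chain declared sequences.

    ``declared_sequence`` maps chain id -> one-letter sequence (from SEQRES
    when present, otherwise reconstructed from resolved residues with ``X``
    filling author-numbering gaps).  Waters are dropped; other non-polymer
    residues are kept in ``het_groups`` for active-site definitions.
    """

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    declared_sequence: dict[str, str] = field(default_factory=dict)
    het_groups: list[Residue] = field(default_factory=list)

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain: str | None = None) -> list[Residue]:
        if chain is not None:
            if chain not in self.chains:
                raise KeyError(f"no chain {chain!r}")
            return list(self.chains[chain])
        return [r for ch in self.chains.values() for r in ch]

    def find_residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.number == number and r.icode == icode:
                return r
        return None

    def all_atoms(self, include_het: bool = True) -> list[tuple[Residue, Atom]]:
        out = [(r, a) for r in self.residues() for a in r.atoms]
        if include_het:
            out += [(r, a) for r in self.het_groups for a in r.atoms]
        return out


def _validate_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PdbParseError(f"line {lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PdbParseError(f"line {lineno}: malformed ATOM/HETATM record ({exc})") from None


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate conformers: highest occupancy, ties alphabetically."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc))
        picked.append(group[0])
    return picked


def parse_pdb(text: str) -> ProteinStructure:
    """Read PDB-format text into a :class:`ProteinStructure`.

    The declared sequence is taken from SEQRES when present; resolved
    residues are aligned to it (via gemmi's label_seq assignment) so that
    missing-residue segments can be reported in declared-sequence indices.
    """
    _validate_atom_lines(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    try:
        st.assign_label_seq_id()
    except Exception:  # pragma: no cover - gemmi failure fallback
        pass

    out = ProteinStructure()
    if len(st) == 0:
        raise EmptyStructureError("no model in PDB content")
    model = st[0]

    for chain in model:
        polymer: list[Residue] = []
        for gres in chain:
            name = gres.name.strip()
            if name in WATER_NAMES:
                continue
            info = gemmi.find_tabulated_residue(name)
            is_aa = bool(info and info.is_amino_acid())
            atoms = []
            for ga in _pick_altlocs(gres):
                el = ga.element.name if ga.element else ""
                atoms.append(Atom(ga.name, el, np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                  max(ga.b_iso, 0.0), min(max(ga.occ, 0.0), 1.0)))
            res = Residue(
                chain_id=chain.name,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                name=name,
                atoms=atoms,
                seqres_pos=(gres.label_seq if gres.label_seq else None),
                is_standard=name in THREE_TO_ONE,
            )
            if is_aa and gres.het_flag != "H":
                polymer.append(res)
            elif is_aa and gres.het_flag == "H" and name in THREE_TO_ONE:
                # modified/standard residue recorded as HETATM inside a chain
                polymer.append(res)
            else:
                out.het_groups.append(res)
        if polymer:
            out.chains[chain.name] = polymer

    if not out.chains:
        raise EmptyStructureError("no polymer ATOM records found")

    # declared sequences
    for chain in model:
        if chain.name not in out.chains:
            continue
        seq3: list[str] = []
        try:
            ent = st.get_entity_of(chain.get_polymer())
        except Exception:
            ent = None
        if ent is not None and ent.full_sequence:
            seq3 = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
        residues = out.chains[chain.name]
        if seq3:
            declared = "".join(THREE_TO_ONE.get(m, "X") for m in seq3)
            out.declared_sequence[chain.name] = declared
            # Prefer the author-number-as-SEQRES-index convention when it is
            # consistent (covers entries whose author numbering counts from
            # the declared N-terminus); otherwise keep gemmi's
            # sequence-alignment assignment.  Repetitive sequences make the
            # alignment ambiguous, author numbering is not.
            if _author_numbering_consistent(residues, declared):
                for r in residues:
                    r.seqres_pos = r.number
            elif any(r.seqres_pos is None for r in residues):
                _fallback_positions(residues, len(seq3))
        else:
            # No SEQRES: declared sequence from resolved residues, with X
            # filling internal author-numbering gaps (N/C disorder is then
            # undetectable -- documented limitation).
            seq, pos = [], {}
            prev_num = None
            for r in residues:
                if prev_num is not None and r.icode == "" and r.number > prev_num + 1:
                    seq.extend("X" * (r.number - prev_num - 1))
                seq.append(r.one_letter)
                pos[id(r)] = len(seq)
                if r.icode == "":
                    prev_num = r.number
            out.declared_sequence[chain.name] = "".join(seq)
            for r in residues:
                r.seqres_pos = pos[id(r)]
    return out


def _author_numbering_consistent(residues: list[Residue], declared: str) -> bool:
    if any(r.icode for r in residues):
        return False
    nums = [r.number for r in residues]
    if nums != sorted(set(nums)):
        return False
    return all(1 <= r.number <= len(declared)
               and (declared[r.number - 1] == r.one_letter or declared[r.number - 1] == "X")
               for r in residues)


def _fallback_positions(residues: list[Residue], declared_len: int) -> None:
    """Assign declared positions by author numbering offset when gemmi could not."""
    known = [(r.number, r.seqres_pos) for r in residues if r.seqres_pos]
    offset = known[0][1] - known[0][0] if known else 1 - residues[0].number
    for r in residues:
        if r.seqres_pos is None:
            p = r.number + offset
            r.seqres_pos = p if 1 <= p <= declared_len else None


def write_pdb(structure: ProteinStructure) -> str:
    """Emit standard 80-column SEQRES/ATOM/HETATM/TER records."""
    lines: list[str] = []
    for cid, seq in structure.declared_sequence.items():
        names = [ONE_TO_THREE.get(c, "UNK") for c in seq]
        for i in range(0, len(names), 13):
            chunk = " ".join(f"{n:>3}" for n in names[i:i + 13])
            lines.append(f"SEQRES {i // 13 + 1:>3} {cid:1} {len(names):>4}  {chunk}".ljust(80))
    serial = 1

    def fmt(record: str, a: Atom, r: Residue) -> str:
        name = a.name if len(a.name) == 4 else f" {a.name:<3}"
        return (f"{record:<6}{serial:>5} {name:<4}{'':1}{r.name:>3} {r.chain_id:1}"
                f"{r.number:>4}{r.icode or ' ':1}   "
                f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
                f"{a.element:>2}  ")

    for cid, residues in structure.chains.items():
        for r in residues:
            for a in r.atoms:
                lines.append(fmt("ATOM", a, r))
                serial += 1
        last = residues[-1]
        lines.append(f"TER   {serial:>5}      {last.name:>3} {cid:1}{last.number:>4}".ljust(80))
        serial += 1
    for r in structure.het_groups:
        for a in r.atoms:
            lines.append(fmt("HETATM", a, r))
            serial += 1
    lines.append("END".ljust(80))
    return "\n".join(lines) + "\n"


def unresolved_segments(structure: ProteinStructure, chain: str) -> list[DisorderSegment]:
    """Maximal runs of declared residues without coordinates.

    The N-terminal run is flagged ``terminal="N"``, the C-terminal run
    ``"C"``, others ``"internal"``.  A chain that is fully resolved (or has
    no usable declared sequence) yields an empty list.
    """
    if chain not in structure.chains:
        raise KeyError(f"no chain {chain!r}")
    declared = structure.declared_sequence.get(chain, "")
    if not declared:
        return []
    resolved = {r.seqres_pos for r in structure.chains[chain] if r.seqres_pos}
    segments: list[DisorderSegment] = []
    start = None
    for pos in range(1, len(declared) + 2):
        missing = pos <= len(declared) and pos not in resolved
        if missing and start is None:
            start = pos
        elif not missing and start is not None:
            end = pos - 1
            terminal = "N" if start == 1 else ("C" if end == len(declared) else "internal")
            segments.append(DisorderSegment(chain, start, end, terminal))
            start = None
    return segments


def bfactor_zscores(structure: ProteinStructure, chain: str) -> dict[str, float]:
    """Per-residue B-factor z-scores over a chain.

    Per-residue B is the mean over the residue's atoms; z uses the chain
    mean and sample standard deviation (ddof=1).  Large positive z marks
    flexible regions.  Keys are residue labels (e.g. ``K139``).
    """
    residues = structure.residues(chain)
    if len(residues) < 3:
        raise ValueError("need >= 3 resolved residues for B-factor z-scores")
    b = np.array([r.mean_bfactor() for r in residues])
    sd = float(np.std(b, ddof=1))
    if sd == 0 or not math.isfinite(sd):
        warnings.warn("zero B-factor variance; returning all-zero z-scores")
        z = np.zeros_like(b)
    else:
        z = (b - b.mean()) / sd
    return {r.label: float(zi) for r, zi in zip(residues, z)}
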