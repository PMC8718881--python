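"""Per-column conservation from a multiple sequence alignment, mapped onto
structure residues.

The primary metric is the identity-to-query fraction: for each alignment
column, the fraction of non-gap symbols equal to the query's symbol there.
Shannon entropy (bits) is reported as a secondary metric.  No sequence
weighting is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from io import StringIO

from Bio import SeqIO

from .structure import ProteinStructure

__all__ = ["Alignment", "ConservationProfile", "read_alignment",
           "column_conservation", "map_to_structure"]

GAP_CHARS = {"-", "."}


@dataclass
class Alignment:
    records: list[tuple[str, str]]  # (id, gapped sequence), order preserved
    length: int

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(f"no record {rid!r} in alignment")


@dataclass
class ConservationProfile:
    """Per-column scores; ``None`` marks columns inapplicable for the query
    (query gapped, or all-gap column)."""
    identity: list[float | None]
    entropy: list[float | None]   # bits
    query_id: str


def read_alignment(text: str) -> Alignment:
    """Parse aligned FASTA; all records must have equal gapped length."""
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(StringIO(text), "fasta")]
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 records")
    length = len(records[0][1])
    for rid, seq in records:
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment: record {rid!r} has length {len(seq)}, expected {length}")
    seen: dict[str, int] = {}
    deduped = []
    for rid, seq in records:
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            warnings.warn(f"duplicate record id {rid!r} renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 0
        deduped.append((rid, seq))
    return Alignment(deduped, length)


def column_conservation(aln: Alignment, query_id: str) -> ConservationProfile:
    """Identity-to-query fraction and Shannon entropy per column.

    Gaps are excluded from denominators; columns where the query itself is
    gapped (and all-gap columns) are marked inapplicable (``None``).
    """
    query = aln.sequence(query_id)
    identity: list[float | None] = []
    entropy: list[float | None] = []
    for col in range(aln.length):
        symbols = [seq[col] for _, seq in aln.records if seq[col] not in GAP_CHARS]
        q = query[col]
        if q in GAP_CHARS or not symbols:
            identity.append(None)
            entropy.append(None)
            continue
        identity.append(sum(1 for s in symbols if s == q) / len(symbols))
        counts: dict[str, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        n = len(symbols)
        entropy.append(-sum((c / n) * math.log2(c / n) for c in counts.values()))
    return ConservationProfile(identity, entropy, query_id)


def map_to_structure(
    profile: ConservationProfile,
    aln: Alignment,
    structure: ProteinStructure,
    chain: str,
    offset: int = 0,
) -> dict[str, float]:
    """Assign each resolved residue its column's identity fraction.

    The ungapped query must match the chain's declared sequence, either
    exactly or shifted by ``offset`` (declared position p reads query
    position p - offset; positive offset means the query lacks an
    N-terminal stretch present in the declared sequence).  Residues whose
    query column is inapplicable are omitted (missing, never imputed).
    """
    query = aln.sequence(profile.query_id)
    ungapped_cols = [i for i, s in enumerate(query) if s not in GAP_CHARS]
    ungapped = "".join(query[i] for i in ungapped_cols)
    declared = structure.declared_sequence.get(chain, "")
    if not declared:
        raise ValueError(f"chain {chain!r} has no declared sequence")
    for pos in range(1, len(declared) + 1):
        q = pos - offset
        if 1 <= q <= len(ungapped) and declared[pos - 1] != "X":
            if ungapped[q - 1] != declared[pos - 1]:
                raise ValueError(
                    f"query/chain sequence mismatch at declared position {pos}: "
                    f"chain {declared[pos - 1]!r} vs query {ungapped[q - 1]!r} "
                    f"(offset {offset})")
    out: dict[str, float] = {}
    for res in structure.chains[chain]:
        if res.seqres_pos is None:
            continue
        q = res.seqres_pos - offset
        if not 1 <= q <= len(ungapped):
            continue
        score = profile.identity[ungapped_cols[q - 1]]
        if score is not None:
            out[res.label] = score
    return out
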