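"""N-terminal truncation construct design.

Poorly expressed human enzymes often carry disordered N-terminal extensions
absent from their bacterial orthologs; removing them (together with
ribosome-stalling proline runs near the start codon) can improve soluble
expression several-fold.  This module enumerates truncation start sites
from three signals: structural disorder (declared residues with no
coordinates), proline-run/stalling motifs, and the position aligned to an
ortholog's N-terminus in a global pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import ProteinStructure, unresolved_segments

__all__ = ["PairwiseAlignmentResult", "TruncationCandidate", "global_align",
           "proline_run_flags", "proline_runs", "propose_truncations"]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PairwiseAlignmentResult:
    aligned_query: str
    aligned_subject: str
    identity_pct: float          # matches / aligned columns (incl. gaps), %
    identity_pct_shorter: float  # matches / shorter input length, %
    score: float

    def query_position_at_subject_start(self) -> int | None:
        """1-based query position aligned to the subject's first residue
        (the next query residue if the subject start falls in a query gap)."""
        qpos = 0
        for qc, sc in zip(self.aligned_query, self.aligned_subject):
            if qc != "-":
                qpos += 1
            if sc != "-":
                return qpos if qc != "-" else qpos + 1
        return None


@dataclass
class TruncationCandidate:
    start_position: int          # full-length residue number of new start
    removed_prefix: str
    rationale: dict[str, bool] = field(default_factory=dict)
    new_n_terminal_window: str = ""

    @property
    def n_flags(self) -> int:
        return sum(self.rationale.values())


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignmentResult:
    """Needleman-Wunsch global alignment with affine gaps.

    A gap of length L costs gap_open + L * gap_extend.  The first alignment
    in Biopython's deterministic traceback order is reported.  Identity is
    matches / aligned columns (including gap columns), with matches /
    shorter-sequence-length reported alongside.
    """
    for seq, tag in ((seq_a, "seq_a"), (seq_b, "seq_b")):
        if not seq:
            raise ValueError(f"{tag} is empty")
        bad = set(seq.upper()) - AA20
        if bad:
            raise ValueError(f"{tag} contains non-amino-acid symbols: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    qa, sa = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(qa, sa) if x == y and x != "-")
    return PairwiseAlignmentResult(
        aligned_query=qa,
        aligned_subject=sa,
        identity_pct=100.0 * matches / len(qa),
        identity_pct_shorter=100.0 * matches / min(len(seq_a), len(seq_b)),
        score=float(aln.score),
    )


def proline_run_flags(sequence: str, window: int = 5, min_pro: int = 3) -> list[bool]:
    """Flag positions covered by any ``window`` containing >= ``min_pro`` prolines.

    Such proline-dense stretches near the N-terminus can stall ribosome
    translocation and depress expression.
    """
    if not (window >= min_pro >= 2):
        raise ValueError("require window >= min_pro >= 2")
    seq = sequence.upper()
    n = len(seq)
    flags = [False] * n
    for start in range(0, max(n - window + 1, 1)):
        win = seq[start:start + window]
        if win.count("P") >= min_pro:
            for i in range(start, min(start + window, n)):
                flags[i] = True
    return flags


def proline_runs(flags: list[bool]) -> list[tuple[int, int]]:
    """Maximal flagged stretches as 1-based inclusive (start, end) pairs."""
    runs, start = [], None
    for i, f in enumerate(flags, start=1):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def propose_truncations(
    structure: ProteinStructure,
    full_sequence: str,
    ortholog_alignment: PairwiseAlignmentResult | None = None,
    chain: str | None = None,
    window: int = 5,
    min_pro: int = 3,
    max_start: int = 60,
) -> list[TruncationCandidate]:
    """Enumerate and rank N-terminal truncation start sites.

    Candidate starts: the residue after the N-terminal disorder segment,
    the residue after each flagged proline run, and the query residue
    aligned to the ortholog's first residue.  Each candidate carries
    rationale flags (computed uniformly: ends_disorder when the start is at
    or past the disorder segment's end, removes_proline_run when a flagged
    run lies entirely in the removed prefix, aligns_to_ortholog_start when
    the start is the ortholog-derived position).  Ranked by number of true
    flags, ties broken by larger start (more aggressive truncation).
    Enumeration is bounded to the first ``max_start`` residues.
    """
    chain = chain or next(iter(structure.chains))
    segs = [s for s in unresolved_segments(structure, chain) if s.terminal == "N"]
    disorder_end = segs[0].end if segs else None

    flags = proline_run_flags(full_sequence, window=window, min_pro=min_pro)
    runs = proline_runs(flags)

    starts: set[int] = set()
    if disorder_end is not None and disorder_end + 1 <= max_start:
        starts.add(disorder_end + 1)
    for _, run_end in runs:
        if run_end + 1 <= max_start:
            starts.add(run_end + 1)
    ortho_start = None
    if ortholog_alignment is not None:
        ortho_start = ortholog_alignment.query_position_at_subject_start()
        if ortho_start is not None and 2 <= ortho_start <= max_start:
            starts.add(ortho_start)

    # never start a construct inside a flagged proline run: shift to run end + 1
    def _shift(start: int) -> int:
        for run_start, run_end in runs:
            if run_start <= start <= run_end:
                return run_end + 1
        return start

    starts = {s for s in (_shift(s) for s in starts) if s <= max_start}
    if ortho_start is not None:
        ortho_start = _shift(ortho_start)

    if not starts:
        return [TruncationCandidate(
            start_position=1, removed_prefix="",
            rationale={"ends_disorder": False, "removes_proline_run": False,
                       "aligns_to_ortholog_start": False},
            new_n_terminal_window=full_sequence[:5])]

    candidates = []
    for start in sorted(starts):
        rationale = {
            "ends_disorder": disorder_end is not None and start >= disorder_end,
            "removes_proline_run": any(end < start for _, end in runs),
            "aligns_to_ortholog_start": ortho_start is not None and start == ortho_start,
        }
        candidates.append(TruncationCandidate(
            start_position=start,
            removed_prefix=full_sequence[:start - 1],
            rationale=rationale,
            new_n_terminal_window=full_sequence[start - 1:start + 4],
        ))
    candidates.sort(key=lambda c: (-c.n_flags, -c.start_position))
    return candidates
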