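"""The engineer-in / engineer-out criteria engine.

Engineer-in: surface arginines suitable for Arg->Lys substitution to add a
PEG-reactive primary amine.  An arginine passes only if it (1) is not
highly conserved among orthologs, (2) has solvent-accessible surface area
strictly above the threshold, (3) is not on a loop (rigidification of
flexible loops upon conjugation can harm catalysis), (4) forms no salt
bridge with Asp/Glu (a bridged amine's perturbed pKa would demand harsher
conjugation pH), and (5) is not near the active site.

Engineer-out: lysines whose PEGylation would likely harm activity, to be
substituted Lys->Arg.  A lysine is flagged when it is PEG-accessible (SASA
above threshold) AND sits either on a flexible loop (coil with elevated
B-factor z) or near the active site.

All criteria are hard AND-ed; no weighting is invented.  Criteria whose
inputs are missing (no alignment, no active-site definition) are reported
as inapplicable and excluded from the conjunction, with the audit trail
flagging the partial evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

from .features import ResidueFeatureRow

__all__ = ["SelectionCriteria", "CriterionOutcome", "SiteRecommendation",
           "evaluate_engineer_in", "evaluate_engineer_out",
           "apply_substitutions", "SubstitutionError"]


@dataclass
class SelectionCriteria:
    """Thresholds for the selection rules (defaults documented per field).

    sasa_min: minimum SASA in A^2; the comparison is strict (>), so a site
        exactly at the threshold fails and the audit reports the margin.
    conservation_max: identity-to-query fraction at or above which a column
        counts as highly conserved.
    active_site_min_distance: minimum atom-pair distance (A) an engineer-in
        site must keep from the active site; engineer-out sites within this
        distance count as "near the active site".
    loop_bz_min: B-factor z at or above which a coil residue counts as a
        flexible loop (engineer-out rule).
    engineer_out_sasa_min: separate accessibility threshold for lysines;
        defaults to sasa_min.
    use_sidechain_sasa: apply thresholds to side-chain instead of total SASA.
    """
    sasa_min: float = 75.0
    conservation_max: float = 0.7
    active_site_min_distance: float = 10.0
    require_non_loop: bool = True
    forbid_salt_bridge: bool = True
    loop_bz_min: float = 1.0
    engineer_out_sasa_min: float | None = None
    use_sidechain_sasa: bool = False

    def __post_init__(self) -> None:
        for name in ("sasa_min", "conservation_max", "active_site_min_distance", "loop_bz_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def out_sasa_min(self) -> float:
        return self.engineer_out_sasa_min if self.engineer_out_sasa_min is not None else self.sasa_min

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CriterionOutcome:
    name: str
    passed: bool | None          # None = inapplicable (missing input)
    measured: float | str | None
    threshold: float | str | None

    @property
    def applicable(self) -> bool:
        return self.passed is not None


@dataclass
class SiteRecommendation:
    chain_id: str
    residue: str                 # label, e.g. "R329"
    direction: str               # "engineer_in" or "engineer_out"
    outcomes: dict[str, CriterionOutcome] = field(default_factory=dict)
    verdict: bool = False
    rank_key: float = 0.0        # SASA used for ordering
    partial: bool = False        # some criterion was inapplicable

    def audit(self) -> dict:
        return {
            "chain": self.chain_id,
            "residue": self.residue,
            "direction": self.direction,
            "verdict": self.verdict,
            "partial_evaluation": self.partial,
            "criteria": {k: {"passed": o.passed, "measured": o.measured,
                             "threshold": o.threshold}
                         for k, o in self.outcomes.items()},
        }


def _sasa_of(row: ResidueFeatureRow, criteria: SelectionCriteria) -> float:
    return row.sidechain_sasa if criteria.use_sidechain_sasa else row.total_sasa


def _finish(rec: SiteRecommendation) -> SiteRecommendation:
    applicable = [o.passed for o in rec.outcomes.values() if o.passed is not None]
    rec.verdict = bool(applicable) and all(applicable)
    rec.partial = any(o.passed is None for o in rec.outcomes.values())
    return rec


def evaluate_engineer_in(
    features: list[ResidueFeatureRow], criteria: SelectionCriteria | None = None
) -> list[SiteRecommendation]:
    """Score every arginine against the engineer-in criteria.

    Returns one recommendation per arginine, sorted by SASA descending
    (ties by residue number ascending), each carrying the measured value
    behind every pass/fail.
    """
    criteria = criteria or SelectionCriteria()
    rows = [r for r in features if r.aa == "R"]
    if not rows:
        warnings.warn("no arginine residues in feature table")
    recs = []
    for row in rows:
        sasa = _sasa_of(row, criteria)
        outcomes = {
            "not_conserved": CriterionOutcome(
                "not_conserved",
                None if row.conservation is None
                else bool(row.conservation < criteria.conservation_max),
                row.conservation, criteria.conservation_max),
            "sasa": CriterionOutcome("sasa", bool(sasa > criteria.sasa_min),
                                     sasa, criteria.sasa_min),
            "not_on_loop": CriterionOutcome(
                "not_on_loop",
                (not row.loop) if criteria.require_non_loop else None,
                row.ss, "ss != C"),
            "no_salt_bridge": CriterionOutcome(
                "no_salt_bridge",
                (not row.salt_bridge_partners) if criteria.forbid_salt_bridge else None,
                ";".join(row.salt_bridge_partners) or "none", "no Asp/Glu bridge"),
            "active_site_distance": CriterionOutcome(
                "active_site_distance",
                None if math.isinf(row.active_site_distance)
                else bool(row.active_site_distance >= criteria.active_site_min_distance),
                row.active_site_distance, criteria.active_site_min_distance),
        }
        recs.append(_finish(SiteRecommendation(
            row.chain_id, row.label, "engineer_in", outcomes, rank_key=sasa)))
    recs.sort(key=lambda r: (-r.rank_key, int(r.residue[1:].rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ") or 0)))
    return recs


def evaluate_engineer_out(
    features: list[ResidueFeatureRow], criteria: SelectionCriteria | None = None
) -> list[SiteRecommendation]:
    """Score every lysine against the engineer-out criteria.

    Verdict true means: PEG-accessible (SASA above the accessibility
    threshold) AND (on a flexible loop, i.e. coil with B-factor z >=
    loop_bz_min, OR within the active-site distance threshold).
    """
    criteria = criteria or SelectionCriteria()
    rows = [r for r in features if r.aa == "K"]
    if not rows:
        warnings.warn("no lysine residues in feature table")
    recs = []
    for row in rows:
        sasa = _sasa_of(row, criteria)
        accessible = bool(sasa > criteria.out_sasa_min)
        flexible_loop = bool(row.loop and row.bfactor_z >= criteria.loop_bz_min)
        near_as = (None if math.isinf(row.active_site_distance)
                   else bool(row.active_site_distance <= criteria.active_site_min_distance))
        harm = flexible_loop or bool(near_as)
        outcomes = {
            "accessible": CriterionOutcome("accessible", accessible, sasa, criteria.out_sasa_min),
            "flexible_loop": CriterionOutcome(
                "flexible_loop", flexible_loop,
                f"ss={row.ss},bz={row.bfactor_z:.2f}", f"coil & bz >= {criteria.loop_bz_min}"),
            "near_active_site": CriterionOutcome(
                "near_active_site", near_as,
                row.active_site_distance, criteria.active_site_min_distance),
        }
        rec = SiteRecommendation(row.chain_id, row.label, "engineer_out", outcomes,
                                 rank_key=sasa)
        rec.verdict = accessible and harm
        rec.partial = near_as is None
        recs.append(rec)
    recs.sort(key=lambda r: (-r.rank_key, int(r.residue[1:].rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ") or 0)))
    return recs


class SubstitutionError(ValueError):
    """A substitution's 'from' residue does not match the sequence (guards
    numbering-offset mistakes)."""


def apply_substitutions(
    sequence: str,
    subs: list[tuple[int, str, str]],
    offset: int = 0,
) -> tuple[str, str]:
    """Apply point substitutions to a one-letter sequence.

    ``subs`` holds (position, from_aa, to_aa) in the numbering the positions
    are cited in; ``offset`` converts to sequence index (index = position -
    offset).  Returns (variant sequence, mutation string in K139R notation,
    positions sorted ascending).
    """
    seq = list(sequence)
    labels = []
    for pos, src, dst in sorted(subs, key=lambda s: s[0]):
        idx = pos - offset - 1
        if not 0 <= idx < len(seq):
            raise SubstitutionError(f"position {pos} outside sequence (offset {offset})")
        if seq[idx] != src:
            raise SubstitutionError(
                f"position {pos}: sequence has {seq[idx]!r}, substitution expects {src!r}")
        seq[idx] = dst
        labels.append(f"{src}{pos}{dst}")
    return "".join(seq), "-".join(labels)
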