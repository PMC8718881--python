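"""Engineer-in / engineer-out criteria engine and substitution bookkeeping."""

import pytest

import pegsite as pg
from pegsite.selection import SelectionCriteria, SubstitutionError, apply_substitutions
from fixture_utils import evaluate_fixture


@pytest.fixture(scope="module")
def fixture_eval():
    return evaluate_fixture(seed=1)


def test_engineer_in_recovers_planted_sites(fixture_eval):
    truth, _, ein, _ = fixture_eval
    verdicts = {r.residue for r in ein if r.verdict}
    assert verdicts == set(truth["engineer_in_true"])


def test_each_decoy_fails_its_planted_criterion(fixture_eval):
    truth, _, ein, _ = fixture_eval
    reason_to_criterion = {
        "R_bridge": "no_salt_bridge", "R_buried": "sasa", "R_loop": "not_on_loop",
        "R_conserved": "not_conserved", "R_nearAS": "active_site_distance",
    }
    by_label = {r.residue: r for r in ein}
    for label, reason in truth["engineer_in_decoys"].items():
        rec = by_label[label]
        assert not rec.verdict
        assert rec.outcomes[reason_to_criterion[reason]].passed is False
        # and it fails ONLY that criterion (clean single-violation decoys)
        others = [o for k, o in rec.outcomes.items() if k != reason_to_criterion[reason]]
        assert all(o.passed for o in others if o.passed is not None)


def test_engineer_out_recovers_planted_sites(fixture_eval):
    truth, _, _, eout = fixture_eval
    verdicts = {r.residue for r in eout if r.verdict}
    assert verdicts == set(truth["engineer_out_true"])


def test_output_sorted_by_sasa_descending(fixture_eval):
    _, _, ein, _ = fixture_eval
    sasas = [r.rank_key for r in ein]
    assert sasas == sorted(sasas, reverse=True)


def test_all_buried_yields_no_engineer_in(fixture_eval):
    truth, rows, _, _ = fixture_eval
    crit = SelectionCriteria(sasa_min=1e6)
    assert not any(r.verdict for r in pg.evaluate_engineer_in(rows, crit))


def test_tightening_thresholds_never_grows_verdict_set(fixture_eval):
    _, rows, _, _ = fixture_eval
    base = SelectionCriteria()
    loose = {r.residue for r in pg.evaluate_engineer_in(rows, base) if r.verdict}
    for tighter in (
        SelectionCriteria(sasa_min=120.0),
        SelectionCriteria(conservation_max=0.35),
        SelectionCriteria(active_site_min_distance=30.0),
    ):
        tight = {r.residue for r in pg.evaluate_engineer_in(rows, tighter) if r.verdict}
        assert tight <= loose


def test_verdict_reproducible_from_audit_trail(fixture_eval):
    _, _, ein, eout = fixture_eval
    for rec in ein:
        audit = rec.audit()
        applicable = [c["passed"] for c in audit["criteria"].values() if c["passed"] is not None]
        assert audit["verdict"] == (bool(applicable) and all(applicable))
    for rec in eout:
        audit = rec.audit()
        c = audit["criteria"]
        assert audit["verdict"] == (
            c["accessible"]["passed"]
            and (c["flexible_loop"]["passed"] or bool(c["near_active_site"]["passed"])))


def test_missing_conservation_marks_partial_evaluation(fixture_eval):
    _, rows, _, _ = fixture_eval
    import copy

    stripped = copy.deepcopy(rows)
    for r in stripped:
        r.conservation = None
    recs = pg.evaluate_engineer_in(stripped)
    assert all(r.outcomes["not_conserved"].passed is None for r in recs)
    assert all(r.partial for r in recs)
    # verdicts computed from the remaining criteria, not auto-failed
    assert any(r.verdict for r in recs)


def test_sasa_comparison_is_strict():
    from pegsite.features import ResidueFeatureRow

    row = ResidueFeatureRow("A", 10, "", "R", total_sasa=75.0, sidechain_sasa=50.0,
                            ss="H", loop=False, bfactor_z=0.0,
                            active_site_distance=50.0, conservation=0.1)
    rec = pg.evaluate_engineer_in([row])[0]
    assert rec.outcomes["sasa"].passed is False  # exactly at threshold fails
    row.total_sasa = 75.01
    assert pg.evaluate_engineer_in([row])[0].outcomes["sasa"].passed is True


def test_apply_substitutions_examples():
    assert apply_substitutions("AKRA", []) == ("AKRA", "")
    variant, label = apply_substitutions("AKRA", [(2, "K", "R"), (3, "R", "K")])
    assert variant == "ARKA" and label == "K2R-R3K"


def test_substitution_mismatch_names_position():
    with pytest.raises(SubstitutionError, match="position 2"):
        apply_substitutions("AKRA", [(2, "R", "K")])


def test_substitutions_with_numbering_offset():
    # positions cited in full-length numbering against a truncated sequence
    seq = "KQR"  # full-length positions 34..36, construct index 1..3
    variant, label = apply_substitutions(seq, [(36, "R", "K")], offset=33)
    assert variant == "KQK" and label == "R36K"
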