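"""Structure model: PDB parsing, SEQRES/disorder bookkeeping, B-factor z."""

import numpy as np
import pytest

import pegsite as pg
from pegsite.structure import PdbParseError, EmptyStructureError

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 12.00           C
END
"""

# SEQRES declares 50 residues; only 35-50 carry coordinates
PARTIAL_PDB = "".join(
    f"SEQRES {i // 13 + 1:>3} A   50  " + " ".join("GLY" for _ in range(min(13, 50 - i))) + "\n"
    for i in range(0, 50, 13)
) + "".join(
    f"ATOM  {n - 34:>5}  CA  GLY A{n:>4}    {3.8 * n:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 20.00           C\n"
    for n in range(35, 51)
) + "END\n"


def test_minimal_pdb_round_trip_identity():
    st = pg.parse_pdb(MINIMAL_PDB)
    assert st.chain_ids() == ["A"]
    (res,) = st.residues("A")
    assert res.name == "ALA" and res.number == 1
    np.testing.assert_allclose(res.atoms[0].coord, [1.0, 2.0, 3.0])
    assert res.atoms[0].bfactor == 12.0


def test_seqres_longer_than_resolved():
    st = pg.parse_pdb(PARTIAL_PDB)
    assert len(st.declared_sequence["A"]) == 50
    assert len(st.residues("A")) == 16
    segs = pg.unresolved_segments(st, "A")
    assert [(s.start, s.end, s.terminal) for s in segs] == [(1, 34, "N")]


def test_unresolved_segments_fully_resolved_chain():
    st = pg.parse_pdb(MINIMAL_PDB)
    assert pg.unresolved_segments(st, "A") == []


def test_segment_lengths_partition_declared_sequence():
    st, _ = pg.make_toy_structure(pg.FixtureSpec(seed=2, disorder_prefix=34))
    segs = pg.unresolved_segments(st, "A")
    assert sum(len(s) for s in segs) + len(st.residues("A")) == len(st.declared_sequence["A"])


def test_malformed_atom_line_reports_line_number():
    bad = MINIMAL_PDB.replace("   1.000", "   x.000")
    with pytest.raises(PdbParseError, match="line 1"):
        pg.parse_pdb(bad)


def test_no_polymer_atoms_is_error():
    with pytest.raises(EmptyStructureError):
        pg.parse_pdb("HETATM    1  O   HOH A 501       0.000   0.000   0.000  1.00  0.00           O\nEND\n")


def test_altloc_keeps_highest_occupancy():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 11.00           C\n"
        "END\n")
    st = pg.parse_pdb(text)
    (res,) = st.residues("A")
    assert len(res.atoms) == 1
    np.testing.assert_allclose(res.atoms[0].coord, [5.0, 0.0, 0.0])


def test_write_parse_round_trip_preserves_everything():
    st, _ = pg.make_toy_structure(pg.FixtureSpec(seed=5))
    st2 = pg.parse_pdb(pg.write_pdb(st))
    assert st2.declared_sequence == st.declared_sequence
    for a, b in zip(st.residues("A"), st2.residues("A")):
        assert (a.chain_id, a.number, a.icode, a.name) == (b.chain_id, b.number, b.icode, b.name)
        np.testing.assert_allclose(a.coords(), b.coords(), atol=1.5e-3)
        np.testing.assert_allclose([x.bfactor for x in a.atoms],
                                   [x.bfactor for x in b.atoms], atol=5e-3)
        assert a.seqres_pos == b.seqres_pos
    assert len(st2.het_groups) == len(st.het_groups)


def _chain_with_bfactors(values):
    residues = [
        pg.Residue("A", i + 1, "", "GLY",
                   [pg.Atom("CA", "C", np.array([3.8 * i, 0.0, 0.0]), b)])
        for i, b in enumerate(values)
    ]
    return pg.ProteinStructure(chains={"A": residues},
                               declared_sequence={"A": "G" * len(values)})


def test_bfactor_z_hand_example():
    # B = {10,10,10,40}: mean 17.5, sample SD 15 -> z of the outlier is 1.5
    z = pg.bfactor_zscores(_chain_with_bfactors([10, 10, 10, 40]), "A")
    assert z["G4"] == pytest.approx(1.5)
    assert np.mean(list(z.values())) == pytest.approx(0.0, abs=1e-12)


def test_bfactor_z_zero_variance_warns():
    with pytest.warns(UserWarning, match="zero B-factor variance"):
        z = pg.bfactor_zscores(_chain_with_bfactors([7, 7, 7]), "A")
    assert all(v == 0.0 for v in z.values())


def test_bfactor_z_affine_invariance():
    vals = [12.0, 19.0, 33.0, 21.0, 40.0]
    z1 = pg.bfactor_zscores(_chain_with_bfactors(vals), "A")
    z2 = pg.bfactor_zscores(_chain_with_bfactors([3.0 * v + 7.0 for v in vals]), "A")
    for k in z1:
        assert z1[k] == pytest.approx(z2[k])


def test_flexible_loop_has_top_z_in_fixture():
    st, truth = pg.make_toy_structure(pg.FixtureSpec(seed=4))
    z = pg.bfactor_zscores(st, "A")
    flex = set()
    for num in truth["flexible_loop_blocks"]:
        res = st.find_residue("A", num)
        flex.add(res.label)
    k = len(flex)
    top_k = sorted(z, key=z.get, reverse=True)[:k]
    assert set(top_k) == flex
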