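"""Shared helpers for the test suite: a Monte-Carlo SASA oracle independent
of the package's deterministic implementation, small hand-built structures,
and an end-to-end fixture evaluation used by the selection tests."""

from __future__ import annotations

import numpy as np

import pegsite as pg
from pegsite.features import VDW_RADII


def mc_sasa(coords, elements, probe=1.4, n_samples=200_000, seed=0):
    """Brute-force Monte-Carlo surface integrator.

    For each atom, random directions are drawn and the point on the
    expanded sphere is kept if it is outside every other atom's expanded
    sphere; the exposed fraction times the sphere area estimates SASA.
    Independent of the golden-spiral quadrature used by the package.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII[e] for e in elements]) + probe
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * dirs
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        out[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


def single_atom_structure(element="C", name="CA", resname="GLY"):
    res = pg.Residue("A", 1, "", resname, [pg.Atom(name, element, np.zeros(3), 10.0)])
    return pg.ProteinStructure(chains={"A": [res]},
                               declared_sequence={"A": "G"})


def structure_from_atoms(atom_specs):
    """One-residue-per-atom structure from (element, xyz) pairs (chain A)."""
    residues = [
        pg.Residue("A", i + 1, "", "GLY",
                   [pg.Atom("CA", el, np.asarray(xyz, dtype=float), 10.0)])
        for i, (el, xyz) in enumerate(atom_specs)
    ]
    return pg.ProteinStructure(chains={"A": residues},
                               declared_sequence={"A": "G" * len(residues)})


def evaluate_fixture(seed, criteria=None):
    """Full pipeline on one synthetic fixture; returns (truth, rows, in, out)."""
    spec = pg.FixtureSpec(seed=seed)
    st, truth = pg.make_toy_structure(spec)
    sasa = pg.compute_sasa(st)
    ss = pg.assign_secondary_structure(st)
    bridges = pg.find_salt_bridges(st)
    site = pg.active_site_set(st, truth["active_site"])
    bz = {"A": pg.bfactor_zscores(st, "A")}
    aln = pg.make_msa(truth["query_sequence"], spec.msa_depth,
                      truth["conservation_targets"], seed)
    profile = pg.column_conservation(aln, "query")
    cons = {"A": pg.map_to_structure(profile, aln, st, "A")}
    rows = pg.build_feature_table(st, sasa, ss, bridges, site, bz, cons)
    ein = pg.evaluate_engineer_in(rows, criteria)
    eout = pg.evaluate_engineer_out(rows, criteria)
    return truth, rows, ein, eout
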