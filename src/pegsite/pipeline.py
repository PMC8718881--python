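"""End-to-end selection pipeline: features -> conservation -> selection ->
amine inventory and PEG ladders, with provenance-stamped reports.

Output is a pure function of (inputs, config): the feature table goes to
TSV, the per-residue selection audit and the ladder model to JSON, each
embedding the full configuration and tool version.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import structure as _structure
from .conservation import column_conservation, map_to_structure, read_alignment
from .features import (active_site_set, assign_secondary_structure,
                       build_feature_table, compute_sasa,
                       feature_table_to_frame, find_salt_bridges)
from .pegylation import amine_inventory, monomer_mass, peg_ladder, variant_inventory
from .selection import SelectionCriteria, evaluate_engineer_in, evaluate_engineer_out

__all__ = ["RunConfig", "run_selection_pipeline"]


@dataclass
class RunConfig:
    structure_path: str
    out_dir: str
    chains: list[str] | None = None          # None = all chains
    msa_path: str | None = None
    msa_query_id: str | None = None          # default: first record
    msa_offset: int = 0
    active_site: list[str] | dict | None = None
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    sasa_context: str = "assembly"
    sasa_points: int = 960
    probe_radius: float = 1.4
    salt_bridge_cutoff: float = 4.0
    peg_mass: float = 5000.0
    base_mass: float | None = None           # default: monomer mass of chain sequence
    seed: int = 0

    def provenance(self) -> dict:
        from . import __version__
        d = dataclasses.asdict(self)
        d["tool"] = f"pegsite {__version__}"
        return d


def run_selection_pipeline(config: RunConfig) -> dict:
    """Run the full selection pipeline and write the report bundle.

    Writes ``features.tsv``, ``selection.json`` and ``peg_ladder.json``
    into ``config.out_dir`` and returns the in-memory bundle.  Missing MSA
    or active-site definition downgrades the affected criterion to
    "inapplicable" with a prominent warning rather than failing.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_text = Path(config.structure_path).read_text()
    st = _structure.parse_pdb(pdb_text)
    chains = config.chains or st.chain_ids()

    sasa = compute_sasa(st, probe_radius=config.probe_radius,
                        points_per_atom=config.sasa_points,
                        context=config.sasa_context)
    ss = assign_secondary_structure(st)
    bridges = find_salt_bridges(st, cutoff=config.salt_bridge_cutoff)
    bz = {cid: _structure.bfactor_zscores(st, cid) for cid in chains}

    conservation = None
    if config.msa_path:
        aln = read_alignment(Path(config.msa_path).read_text())
        query_id = config.msa_query_id or aln.records[0][0]
        profile = column_conservation(aln, query_id)
        conservation = {cid: map_to_structure(profile, aln, st, cid, offset=config.msa_offset)
                        for cid in chains}
    else:
        warnings.warn("no MSA supplied: conservation criterion will be inapplicable "
                      "(partial evaluation)")

    if config.active_site:
        site = active_site_set(st, config.active_site)
    else:
        warnings.warn("no active-site definition: distance criterion will be "
                      "inapplicable (partial evaluation)")
        site = []

    features = build_feature_table(st, sasa, ss, bridges, site, bz, conservation)
    features = [r for r in features if r.chain_id in chains]

    engineer_in = evaluate_engineer_in(features, config.criteria)
    engineer_out = evaluate_engineer_out(features, config.criteria)

    inventory = amine_inventory(features, config.criteria.out_sasa_min,
                                chain=chains[0],
                                use_sidechain_sasa=config.criteria.use_sidechain_sasa)
    base = config.base_mass or monomer_mass(
        "".join(r.one_letter for r in st.chains[chains[0]] if r.one_letter != "X"))
    parent_ladder = peg_ladder(base, inventory, config.peg_mass)
    subs = ([f"{r.residue}R" for r in engineer_out if r.verdict]
            + [f"{r.residue}K" for r in engineer_in if r.verdict])
    arg_sasa = {r.residue: r.rank_key for r in engineer_in}
    variant = variant_inventory(inventory, subs, arg_sasa)
    variant_ladder = peg_ladder(base, variant, config.peg_mass)

    prov = config.provenance()
    bundle = {
        "provenance": prov,
        "features": features,
        "engineer_in": engineer_in,
        "engineer_out": engineer_out,
        "inventory": inventory,
        "variant_inventory": variant,
        "substitutions": subs,
        "parent_ladder": parent_ladder,
        "variant_ladder": variant_ladder,
    }

    frame = feature_table_to_frame(features)
    with open(out_dir / "features.tsv", "w") as fh:
        fh.write("# " + json.dumps(prov, default=str) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    with open(out_dir / "selection.json", "w") as fh:
        json.dump({
            "provenance": prov,
            "engineer_in": [r.audit() for r in engineer_in],
            "engineer_out": [r.audit() for r in engineer_out],
            "substitutions": subs,
        }, fh, indent=1, default=str)
    with open(out_dir / "peg_ladder.json", "w") as fh:
        json.dump({
            "provenance": prov,
            "parent": {"sites": inventory.lysine_sites,
                       "n_terminus": inventory.n_terminus_site,
                       "total_sites": inventory.total_sites,
                       "species_masses": parent_ladder.species_masses},
            "variant": {"sites": variant.lysine_sites,
                        "n_terminus": variant.n_terminus_site,
                        "total_sites": variant.total_sites,
                        "species_masses": variant_ladder.species_masses},
        }, fh, indent=1, default=str)
    return bundle
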