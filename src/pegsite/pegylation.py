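"""Amine-targeted PEG conjugation model.

NHS-ester PEG reagents react with primary amines: surface-accessible lysine
epsilon-amines and the N-terminal alpha-amine.  The accessible-site
inventory plus a per-chain PEG adduct mass gives the expected conjugate
mass ladder (the band pattern seen on a gel); engineered substitutions
(Lys->Arg removals, Arg->Lys additions) edit the inventory.

The PEG adduct is treated as its nominal polymer mass (e.g. 5,000 Da for
mPEG-5kDa; the succinimidyl linker mass is ignored) - the approximation
behind "~25 kDa added over five sites".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .features import ResidueFeatureRow

__all__ = ["AmineInventory", "PegLadder", "amine_inventory", "peg_ladder",
           "monomer_mass", "variant_inventory", "AVERAGE_RESIDUE_MASS",
           "WATER_MASS"]

#: Average (isotope-abundance-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.02


@dataclass
class AmineInventory:
    lysine_sites: list[str]          # labels, e.g. "K43", sorted by number
    n_terminus_site: bool
    sasa_threshold: float

    @property
    def total_sites(self) -> int:
        return len(self.lysine_sites) + (1 if self.n_terminus_site else 0)


@dataclass
class PegLadder:
    base_mass: float                 # Da
    peg_mass: float                  # Da
    species_masses: list[float] = field(default_factory=list)

    @property
    def max_mass(self) -> float:
        return self.species_masses[-1]


def amine_inventory(
    features: list[ResidueFeatureRow],
    sasa_threshold: float = 75.0,
    include_n_terminus: bool = True,
    chain: str | None = None,
    use_sidechain_sasa: bool = False,
) -> AmineInventory:
    """Lysines with SASA strictly above threshold, plus the N-terminal amine."""
    rows = [r for r in features if r.aa == "K" and (chain is None or r.chain_id == chain)]
    sites = [r.label for r in rows
             if (r.sidechain_sasa if use_sidechain_sasa else r.total_sasa) > sasa_threshold]
    sites.sort(key=lambda s: int(re.sub(r"\D", "", s)))
    return AmineInventory(sites, include_n_terminus, sasa_threshold)


def peg_ladder(base_mass: float, inventory: AmineInventory, peg_mass: float) -> PegLadder:
    """Masses of the 0..total_sites conjugate species."""
    if base_mass <= 0 or peg_mass <= 0:
        raise ValueError("masses must be positive")
    masses = [base_mass + k * peg_mass for k in range(inventory.total_sites + 1)]
    return PegLadder(base_mass, peg_mass, masses)


def monomer_mass(sequence: str) -> float:
    """Average-isotope mass of a polypeptide chain, Da (residue masses + water)."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[c] for c in sequence.upper())
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None
    return total + WATER_MASS


_MUT = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def variant_inventory(
    inventory: AmineInventory,
    subs: list[str] | list[tuple[int, str, str]],
    arg_sasa: dict[str, float] | None = None,
) -> AmineInventory:
    """Inventory after engineered substitutions.

    ``subs`` are mutations either as "K139R" strings or (position, from, to)
    tuples.  K->R removes the site if present (warning otherwise); R->K adds
    a site iff that arginine's SASA passed the accessibility threshold
    (``arg_sasa`` maps "R329"-style labels to SASA; if omitted, every R->K
    at an engineer-in-selected site is assumed accessible).  Idempotent for
    repeated identical substitutions.
    """
    sites = set(inventory.lysine_sites)
    for sub in subs:
        if isinstance(sub, str):
            m = _MUT.match(sub)
            if not m:
                raise ValueError(f"bad mutation string {sub!r}")
            src, pos, dst = m.group(1), int(m.group(2)), m.group(3)
        else:
            pos, src, dst = sub
        if src == "K" and dst == "R":
            label = f"K{pos}"
            if label in sites:
                sites.discard(label)
            else:
                warnings.warn(f"{label}R: lysine not in accessible inventory; no effect")
        elif src == "R" and dst == "K":
            sasa = None if arg_sasa is None else arg_sasa.get(f"R{pos}")
            if arg_sasa is None or (sasa is not None and sasa > inventory.sasa_threshold):
                sites.add(f"K{pos}")
    ordered = sorted(sites, key=lambda s: int(re.sub(r"\D", "", s)))
    return AmineInventory(ordered, inventory.n_terminus_site, inventory.sasa_threshold)
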