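"""Synthetic fixtures with known ground truth for every pipeline stage.

:func:`make_toy_structure` builds a single-chain toy protein from canonical
backbone templates (helix rise 1.5 A / 100 deg twist, radius 2.3 A; coil
segments as straight 3.6 A Calpha traces) with planted, labelled features:

* engineer-in arginines placed mid-helix with solvent-facing side chains,
  alongside decoy arginines that each violate exactly one selection
  criterion (salt-bridged, buried inside a dummy-atom shell, on a loop,
  highly conserved, near the active site);
* engineer-out lysines on a high-B-factor coil or next to the planted
  active site, with rigid-helix and buried lysine decoys;
* a salt-bridge pair at 3.5 A N-O distance;
* an N-terminal disordered prefix present in the declared (SEQRES)
  sequence but without coordinates.

Unplanted residues are glycines carrying only a Calpha; burial is enforced
by icosahedral shells of dummy carbon "CAG" het atoms, which occlude the
probe completely.  Side chains are reduced to the atoms the feature
computations read (Cbeta-direction pseudo-atoms; full guanidinium /
epsilon-amine / carboxylate tips where salt-bridge or SASA ground truth
requires them).  Everything is a pure function of the spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, ProteinStructure, Residue
from .kinetics import RateDataset, ProgressCurve, mm_velocity, MMParams
from .conservation import Alignment

__all__ = ["FixtureSpec", "make_toy_structure", "make_msa",
           "simulate_mm_dataset", "simulate_progress_curve"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# icosahedron vertices (unit sphere); a shell of these at 3.0 A around an
# atom leaves no exposed point for a 1.4 A probe against 1.7 A carbons
_PHI = (1 + math.sqrt(5)) / 2
_ICO = np.array([(0, 1, _PHI), (0, -1, _PHI), (0, 1, -_PHI), (0, -1, -_PHI),
                 (1, _PHI, 0), (-1, _PHI, 0), (1, -_PHI, 0), (-1, -_PHI, 0),
                 (_PHI, 0, 1), (-_PHI, 0, 1), (_PHI, 0, -1), (-_PHI, 0, -1)])
_ICO = _ICO / np.linalg.norm(_ICO[0])


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic structure/MSA/kinetics case."""
    seed: int = 0
    n_residues: int = 60            # resolved residues
    disorder_prefix: int = 34       # declared-only N-terminal residues
    msa_depth: int = 50
    bfactor_base: float = 20.0      # rigid-region mean B, A^2
    bfactor_flexible: float = 55.0  # flexible-loop mean B, A^2
    bfactor_sd: float = 2.0
    conservation_default: float = 0.5
    conservation_low: float = 0.3   # planted engineer-in columns
    conservation_high: float = 0.95  # conserved-decoy column
    kinetics: tuple[float, float] = (5.0, 25.0)   # kcat s^-1, KM uM

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if self.disorder_prefix < 0:
            raise ValueError("disorder_prefix must be >= 0")


def _prefix_sequence(n: int) -> str:
    """Disordered prefix with a proline-run stalling motif when long enough."""
    if n == 0:
        return ""
    if n < 9:
        return "M" + "T" * (n - 1)
    core = "M" + "T" * 9 + "APPAP"      # proline run at prefix positions 11-15
    if n <= len(core):
        return core[:n]
    return core + "S" * (n - len(core))


def _blocks(n: int) -> list[tuple[str, int]]:
    """Alternating helix(12)/coil(6) layout covering n residues."""
    out, left, helix = [], n, True
    while left > 0:
        length = min(12 if helix else 6, left)
        out.append(("H" if helix else "C", length))
        left -= length
        helix = not helix
    return out


def _ico_shell(center: np.ndarray, dist: float = 3.0) -> list[np.ndarray]:
    return [center + dist * v for v in _ICO]


def make_toy_structure(spec: FixtureSpec) -> tuple[ProteinStructure, dict]:
    """Build the toy structure and its ground-truth labels.

    Returns ``(structure, truth)`` where ``truth`` maps label lists for
    every planted feature (keys: engineer_in_true, engineer_in_decoys,
    engineer_out_true, engineer_out_decoys, lysines_exposed,
    lysines_buried, salt_bridges, active_site, flexible_loop_blocks,
    disorder, conservation_targets, query_sequence).  Planting requires the
    default-size layout (n_residues >= 60); smaller structures carry
    geometry and disorder only.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    prefix = spec.disorder_prefix
    blocks = _blocks(n)

    # per-residue block class and x-advance
    klass: list[str] = []
    for kind, length in blocks:
        klass += [kind] * length
    x = np.zeros(n)
    for i in range(1, n):
        x[i] = x[i - 1] + (1.5 if klass[i] == "H" else 3.6)
    theta = np.deg2rad(100.0) * np.arange(n)
    ca = np.zeros((n, 3))
    for i in range(n):
        if klass[i] == "H":
            ca[i] = (x[i], 2.3 * math.cos(theta[i]), 2.3 * math.sin(theta[i]))
        else:
            ca[i] = (x[i], 0.0, 0.0)
    radial = np.column_stack([np.zeros(n), np.cos(theta), np.sin(theta)])
    tangent = np.column_stack([np.zeros(n), -np.sin(theta), np.cos(theta)])

    # planted slots (1-based resolved indices); only for the full layout
    full = n >= 60
    plants: dict[int, str] = {}
    if full:
        plants = {6: "R_in", 9: "R_bridge", 12: "E_partner", 15: "K_flexloop",
                  17: "R_loop", 21: "R_buried", 24: "R_conserved",
                  30: "R_nearAS", 33: "K_nearAS", 42: "R_in", 44: "K_helix",
                  46: "R_in", 51: "K_buried"}
    active_site_idx = [31] if full else []
    flexible_blocks = ({13, 14, 15, 16, 17, 18} | {49, 50, 51, 52, 53, 54}) if full else set()

    def aa_of(role: str) -> str:
        return {"R": "ARG", "K": "LYS", "E": "GLU"}[role[0]]

    residues: list[Residue] = []
    cage_centers: list[np.ndarray] = []
    for i in range(1, n + 1):
        role = plants.get(i, "")
        name = aa_of(role) if role else "GLY"
        u, t = radial[i - 1], tangent[i - 1]
        c = ca[i - 1]
        b = float(max(1.0, rng.normal(
            spec.bfactor_flexible if i in flexible_blocks else spec.bfactor_base,
            spec.bfactor_sd)))
        atoms = [Atom("CA", "C", c, b)]
        if role.startswith("R") and role != "R_buried":
            atoms += [Atom("CB", "C", c + 1.5 * u, b),
                      Atom("NE", "N", c + 3.8 * u, b),
                      Atom("NH1", "N", c + 5.0 * u + 0.6 * t, b),
                      Atom("NH2", "N", c + 5.0 * u - 0.6 * t, b)]
        elif role == "R_buried":
            atoms += [Atom("CB", "C", c - 1.2 * u, b),
                      Atom("NE", "N", c - 2.0 * u, b),
                      Atom("NH1", "N", c - 2.8 * u + 0.5 * t, b),
                      Atom("NH2", "N", c - 2.8 * u - 0.5 * t, b)]
            for a in atoms:
                cage_centers.extend(_ico_shell(a.coord))
        elif role.startswith("K") and role != "K_buried":
            atoms += [Atom("CB", "C", c + 1.5 * u, b),
                      Atom("NZ", "N", c + 5.0 * u, b)]
        elif role == "K_buried":
            atoms += [Atom("CB", "C", c + 1.5 * u, b),
                      Atom("NZ", "N", c + 2.5 * u, b)]
            for a in atoms:
                cage_centers.extend(_ico_shell(a.coord))
        elif role == "E_partner":
            # carboxylate oxygens placed 3.5 A from the bridge arginine's NH1
            nh1 = ca[9 - 1] + 5.0 * radial[9 - 1] + 0.6 * tangent[9 - 1]
            u9 = radial[9 - 1]
            atoms += [Atom("CB", "C", c + 1.5 * u, b),
                      Atom("OE1", "O", nh1 + 3.5 * u9, b),
                      Atom("OE2", "O", nh1 + 3.5 * u9 + 1.1 * tangent[9 - 1], b)]
        residues.append(Residue("A", prefix + i, "", name, atoms,
                                seqres_pos=prefix + i))

    het: list[Residue] = []
    if full:
        lig_center = ca[31 - 1] + np.array([0.0, 0.0, 3.2])
        het.append(Residue("A", 901, "", "LIG", [
            Atom("C1", "C", lig_center, 20.0),
            Atom("O1", "O", lig_center + np.array([0.0, 0.9, 0.7]), 20.0),
            Atom("N1", "N", lig_center + np.array([0.0, -0.9, 0.7]), 20.0),
        ], is_standard=False))
    if cage_centers:
        # deduplicate near-coincident shell atoms
        kept: list[np.ndarray] = []
        for p in cage_centers:
            if all(np.dot(p - q, p - q) > 1.0 for q in kept):
                kept.append(p)
        for j, p in enumerate(kept, start=1):
            het.append(Residue("X", j, "", "CAG", [Atom("C", "C", p, 20.0)],
                               is_standard=False))

    resolved_seq = "".join(r.one_letter for r in residues)
    declared = _prefix_sequence(prefix) + resolved_seq
    structure = ProteinStructure(
        chains={"A": residues},
        declared_sequence={"A": declared},
        het_groups=het,
    )

    def lab(i: int) -> str:
        return f"{residues[i - 1].one_letter}{prefix + i}"

    cons_targets = {p: spec.conservation_default for p in range(1, len(declared) + 1)}
    if full:
        for i, role in plants.items():
            if role.startswith("R"):
                cons_targets[prefix + i] = (spec.conservation_high if role == "R_conserved"
                                            else spec.conservation_low)
            elif role.startswith("K"):
                cons_targets[prefix + i] = 0.4

    truth = {
        "engineer_in_true": [lab(i) for i, r in plants.items() if r == "R_in"],
        "engineer_in_decoys": {lab(i): r for i, r in plants.items()
                               if r.startswith("R") and r != "R_in"},
        "engineer_out_true": [lab(i) for i, r in plants.items()
                              if r in ("K_flexloop", "K_nearAS")],
        "engineer_out_decoys": {lab(i): r for i, r in plants.items()
                                if r in ("K_helix", "K_buried")},
        "lysines_exposed": sorted((lab(i) for i, r in plants.items()
                                   if r in ("K_flexloop", "K_nearAS", "K_helix")),
                                  key=lambda s: int(s[1:])),
        "lysines_buried": [lab(i) for i, r in plants.items() if r == "K_buried"],
        "salt_bridges": [(lab(9), lab(12))] if full else [],
        "active_site": [lab(i) for i in active_site_idx],
        "flexible_loop_blocks": sorted(prefix + i for i in flexible_blocks),
        "disorder": (1, prefix) if prefix else None,
        "conservation_targets": cons_targets,
        "query_sequence": declared,
    }
    return structure, truth


def make_msa(
    query: str,
    depth: int,
    conservation_profile: dict[int, float] | list[float] | float,
    seed: int,
    query_id: str = "query",
) -> Alignment:
    """Gapless MSA whose realized per-column identity matches the targets.

    ``conservation_profile`` gives per-column identity-to-query targets
    (1-based dict, list, or one scalar for all columns), each in
    [1/20, 1].  The number of matching sequences per column is the rounded
    target count (query included), so the realized fraction is within
    1/(2*depth) of the target; which sequences match is seed-randomized.
    """
    rng = np.random.default_rng(seed)
    ncol = len(query)
    if isinstance(conservation_profile, dict):
        targets = [conservation_profile.get(i + 1, 1.0) for i in range(ncol)]
    elif isinstance(conservation_profile, (int, float)):
        targets = [float(conservation_profile)] * ncol
    else:
        targets = list(conservation_profile)
        if len(targets) != ncol:
            raise ValueError("profile length must equal query length")
    if any(not (1 / 20 <= t <= 1) for t in targets):
        raise ValueError("conservation targets must be in [1/20, 1]")
    if depth < 2:
        raise ValueError("depth must be >= 2")

    rows = [[c for c in query]]
    rows += [[None] * ncol for _ in range(depth - 1)]
    for col, tgt in enumerate(targets):
        q = query[col]
        k = max(1, round(tgt * depth))          # matches incl. the query
        others = rng.permutation(depth - 1)
        match_rows = set(others[:k - 1] + 1)
        alternatives = [a for a in AA_ALPHABET if a != q] or ["A"]
        for r in range(1, depth):
            if r in match_rows:
                rows[r][col] = q
            else:
                rows[r][col] = alternatives[rng.integers(len(alternatives))]
    records = [(query_id, query)]
    records += [(f"homolog_{r:03d}", "".join(rows[r])) for r in range(1, depth)]
    return Alignment(records, ncol)


def simulate_mm_dataset(
    kcat: float,
    km: float,
    s_list,
    noise_cv: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
) -> RateDataset:
    """Initial-velocity data from the rate law with multiplicative noise.

    v/[E] = kcat*[S]/(KM+[S]) * (1 + eps), eps ~ Normal(0, noise_cv),
    clipped at zero (the clip count is recorded on the dataset).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    s = np.repeat(np.asarray(s_list, dtype=float), replicates)
    rep = np.tile(np.arange(replicates), len(s_list))
    v_true = mm_velocity(MMParams(kcat, km), s)
    v = v_true * (1.0 + rng.normal(0.0, noise_cv, size=s.shape)) if noise_cv > 0 else v_true.copy()
    n_clipped = int(np.count_nonzero(v < 0))
    return RateDataset(s, np.maximum(v, 0.0), rep, n_clipped)


def simulate_progress_curve(
    kcat: float,
    km: float,
    enzyme_um: float,
    s0_um: float,
    delta_epsilon: float = 1000.0,
    pathlength_cm: float = 1.0,
    duration_s: float = 120.0,
    n_points: int = 121,
    a0: float = 1.0,
) -> ProgressCurve:
    """Noiseless absorbance trace from exact integration of the rate law.

    Substrate depletion follows dS/dt = -kcat*[E]*S/(KM+S) (uM/s); the
    absorbance decreases by delta_epsilon * pathlength per molar substrate
    converted.
    """
    from scipy.integrate import solve_ivp

    t = np.linspace(0.0, duration_s, n_points)
    sol = solve_ivp(lambda _, s: -kcat * enzyme_um * s / (km + s),
                    (0.0, duration_s), [s0_um], t_eval=t,
                    rtol=1e-10, atol=1e-12)
    s_t = sol.y[0]
    absorbance = a0 - delta_epsilon * pathlength_cm * (s0_um - s_t) * 1e-6
    return ProgressCurve(t, absorbance, s0_um, delta_epsilon, pathlength_cm)
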