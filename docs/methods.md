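# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `pegsite`, module by module.

## Structure model

PDB content is parsed with `gemmi`; the package keeps its own light data
model (chains → residues → atoms) because the analyses only need author
numbering, coordinates, B-factors and the declared (SEQRES) sequence.
Author numbering is authoritative throughout — engineering literature cites
sites in full-length coordinates — and a configurable integer offset
reconciles construct numbering where needed (`apply_substitutions`,
`map_to_structure`).

* **Alternate conformations** are resolved to the highest-occupancy
  conformer, ties broken alphabetically by altloc, for determinism.
* **Declared-sequence mapping.**  When SEQRES is present, resolved residues
  are mapped to declared positions by the author-number-as-index convention
  whenever that is consistent (monotone numbering, letters match); highly
  repetitive sequences make alignment-based assignment ambiguous while
  author numbering is not.  Otherwise gemmi's sequence alignment is used.
  Without SEQRES, the declared sequence is reconstructed from resolved
  residues with `X` filling author-numbering gaps, so only internal
  disorder is detectable — N/C-terminal disorder needs SEQRES.  This is a
  documented limitation, not an error.
* **Disorder segments** are maximal runs of declared positions without
  coordinates; the invariant `sum(segment lengths) + resolved = declared
  length` holds by construction.
* **B-factor z-scores** use the per-residue mean over atoms and the chain's
  sample standard deviation (ddof = 1); they are invariant under positive
  affine rescaling of all B-factors.  Zero variance yields all-zero z with
  a warning.
* Waters are dropped; other het groups are kept for active-site definitions
  and as SASA occluders.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral (Fibonacci-lattice) point
set, 960 points per atom by default.  Van der Waals radii: C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80 Å (overridable per call); probe radius
1.4 Å.  A test point lying exactly on a neighbor's expanded sphere counts
as buried (deterministic tie-break).  Unknown elements raise an error
naming the offending atoms rather than guessing a radius.

Context: `assembly` (default) scores each residue inside the full deposited
assembly including het occluders — appropriate because the selection
criteria concern the biologically active oligomer (e.g. a homodimer);
`monomer` scores each chain in isolation.  Per-residue assembly SASA is
never larger than monomer SASA.

The 75 Å² accessibility threshold is applied to **total** residue SASA by
default with a switch for side-chain-only SASA (atoms outward of Cβ);
whether published supplementary values used total or side-chain areas, and
which oligomeric context, is not knowable from the primary text, so both
modes are provided and the default is declared rather than inferred.

The test suite checks the implementation against two independent oracles:
the closed form 4π(r + r_probe)² for an isolated atom (exact for any
quadrature) and a Monte-Carlo surface integrator (random directions on each
expanded sphere) on small atom clusters, with 2% agreement required.

## Secondary structure

A Cα-geometry assigner in the P-SEA family, chosen because engineering
inputs are often Cα-complete but hydrogen-free, which rules out DSSP-exact
hydrogen-bond assignment.  A helix window starts at residue *i* when
d(i,i+3) ∈ [4.5, 6.0] Å and d(i,i+4) ∈ [5.0, 6.6] Å (canonical α-helix:
5.3 / 6.2 Å) and marks residues i..i+4 as H; strand windows use
d(i,i+2) ∈ [6.2, 7.05] Å and d(i,i+4) ∈ [11.9, 13.9] Å (pleated strand:
6.7 / 13.3 Å; a fully extended straight 3.8 Å trace is deliberately
excluded) and mark i..i+2 as E.  Everything else, chains shorter than five
residues, and residues lacking Cα are coil.  Windows are a dataclass
(`SSWindows`) so they can be tuned without touching code.  A single
junction residue adjacent to a resuming helix can be claimed by the helix
window — a boundary effect shared by geometric assigners generally.

"Located on a loop" means coil class; "flexible loop" means coil **and**
B-factor z ≥ 1.0.  The flexibility cutoff is a declared default: published
practice assessed loop flexibility by B-factors without quoting a number.

## Salt bridges and active site

A salt bridge is a contact between a basic side-chain nitrogen (Lys NZ,
Arg NE/NH1/NH2, His ND1/NE2) and an acidic carboxylate oxygen (Asp OD1/OD2,
Glu OE1/OE2) with minimum N–O distance ≤ 4.0 Å (configurable).  Residues
with missing side-chain atoms are skipped with a warning.  Detection is
symmetric, deduplicated per residue pair, and invariant under rigid-body
motion.

The active site is either an explicit residue list (verified to exist) or a
ligand-proximity rule (residues with any atom within a cutoff, default
4.5 Å, of a named het group).  Distances to the set are minima over all
atom pairs; an empty set gives +inf, which downgrades the distance
criterion to "inapplicable" rather than passing or failing it silently.

## Conservation

Primary metric: per-column identity-to-query fraction over non-gap symbols,
matching the practice of judging residue conservation from ortholog
alignments; Shannon entropy (bits) is secondary.  Columns where the query
is gapped are inapplicable.  No sequence weighting is applied (an
extension point).  "Highly conserved" defaults to identity ≥ 0.7 — a
documented, overridable default; no published cutoff exists for this
analysis.  Mapping onto a structure requires the ungapped query to match
the chain's declared sequence exactly or at a declared offset; any other
mismatch is an error naming the first differing position, which guards
against numbering-offset mistakes.

## Site selection

All engineer-in criteria are hard AND-ed; no scoring or weighting is
invented.  The SASA comparison is strict (>) so a residue exactly at the
threshold fails and the audit shows the margin — relevant because
borderline sites occur in practice.  Missing inputs (no MSA, no active-site
definition) make the affected criterion inapplicable: the verdict is
computed from the remaining criteria and the recommendation is flagged as a
partial evaluation.  Engineer-out uses the same accessibility threshold by
default but it is separately configurable, because published
lysine-exposure judgments were visual rather than numeric.  Output is
sorted by SASA descending (ties: residue number ascending), and every
verdict is reproducible from its persisted audit trail alone.

## Truncation design

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62, gap open 11, extend 1, i.e. a length-L gap
costs 11 + L); identity is reported both per aligned column (including gap
columns) and per shorter-sequence length, because published identity
percentages rarely state their denominator — pairwise identity figures are
therefore treated as soft (±2 percentage point) checks.  Proline runs:
a position is flagged when any 5-residue window covering it contains ≥ 3
prolines (both parameters configurable); such runs near the start codon
stall translation.  Candidate starts are the residue after the N-terminal
disorder segment, the residue after each flagged proline run, and the query
position aligned to the ortholog's first residue; a candidate falling
inside a flagged run is shifted past it.  Rationale flags are computed
uniformly per candidate (`ends_disorder` accepts starting at the disorder
segment's final residue, since constructs in practice retain that anchor
residue).  Ranking: more true flags first, then larger start (more
aggressive truncation).  Enumeration is bounded to the first 60 residues —
N-terminal design scope.  Translation-initiation-rate rescoring is
intentionally not performed; the report leaves a TIR column blank for
manual entry from external predictors.

## PEGylation model

The amine inventory is the set of lysines with SASA strictly above the
accessibility threshold plus (optionally) the N-terminal α-amine; the
ladder is `m_k = m_base + k·m_PEG` for k = 0..sites.  The PEG adduct is its
nominal polymer mass (5,000 Da for mPEG-5kDa); the succinimidyl-succinate
linker is ignored, the approximation behind "~25 kDa over five sites".
Base mass defaults to the average-isotope sequence mass (+ 18.02 Da water)
of the construct actually supplied — His-tags and cloning scars count iff
they are in the given sequence; constructs are explicit inputs, never
inferred.  Variant arithmetic: K→R removes a site (warning if absent),
R→K adds one iff that arginine's SASA cleared the threshold; the operation
is idempotent.  Gel-migration modelling (apparent vs true mass) and PEG
polydispersity are out of scope.

## Kinetics

The model is v/[E] = k_cat[S]/(K_M+[S]) with [S] in μM and v/[E] in s⁻¹;
efficiency k_cat/K_M is reported in M⁻¹s⁻¹ with the 10⁶ unit factor applied
in exactly one function.  Initial rates: least-squares slope of absorbance
vs time over the points with < 10% substrate conversion (inferred from the
absorbance change via Δε and pathlength; defaults Δε = 1,000 M⁻¹cm⁻¹ at
290 nm for thymidine, 1,370 at 282 nm for deoxyuridine, 1 cm path); fewer
than 4 admissible points is an error advising a shorter interval.

Fitting is nonlinear least squares (Levenberg–Marquardt via
`scipy.optimize.curve_fit`, xtol = ftol = 1e-10, 5000 function-evaluation
cap) initialized at k_cat⁰ = max v/[E], K_M⁰ = median [S]; standard errors
come from the Jacobian-based covariance at the optimum.  Replicates are
pooled by default, with a fit-to-means mode (whether published fits pooled
replicates or means is typically unstated; both are supported and agree
exactly on noiseless data).  The fit is unweighted: under multiplicative
noise this understates the reported SEs relative to the empirical estimator
spread by up to ~50%, which the test suite asserts as a same-scale check
rather than equality.  When K_M's SE exceeds K_M itself the fit warns that
K_M is poorly identified (all [S] below K_M).  Efficiency SE uses
first-order (delta-method) propagation ignoring the k_cat–K_M covariance.
Fold changes are reported raw and rounded to 2 significant figures, the
precision at which such ratios are quoted.

## Synthetic fixtures

The generator emulates exactly the statistical and geometric structure the
analysis reads, nothing more.  Backbone templates: helix rise 1.5 Å /
100° twist / 2.3 Å radius; coils as straight 3.6 Å Cα traces; blocks of
12-residue helices alternating with 6-residue coils.  Unplanted residues
are Cα-only glycines.  Planted residues carry the minimal side-chain atoms
the feature computations read: radial Cβ/NZ (lysine) or Cβ/NE/NH1/NH2
(arginine) pseudo-atoms at up to 5 Å from Cα for exposure; inward-pointing
side chains enclosed in icosahedral shells of dummy carbons (12 vertices at
3.0 Å per atom, deduplicated) for burial — a 1.4 Å probe cannot pass such
a shell, so buried SASA is essentially zero; a carboxylate placed at
exactly 3.5 Å N–O distance for the salt-bridge pair; a 3-atom het ligand
defining the active site.  B-factors are seeded draws: N(20, 2) on rigid
segments, N(55, 2) on the two designated flexible coils, giving flexible-
loop z-scores near +2.  The declared sequence gains a
coordinate-free N-terminal prefix (default 34 residues, mirroring the
disordered N-terminus of the human enzyme) containing an APPAP
proline-run motif for the truncation stage.  Decoy sites each violate
exactly one criterion, so the selection tests verify criterion isolation,
not just aggregate verdicts.  MSA generation fixes the number of matching
sequences per column to the rounded target count (query included), so
realized identity is within 1/(2·depth) of the target; mismatch symbols
are seeded uniform draws over the other 19 amino acids.  Kinetic datasets
apply multiplicative Gaussian noise to exact rate-law values, clipping at
zero with a recorded clip count; progress curves come from tight-tolerance
numerical integration of the depletion ODE.

What the fixtures do **not** emulate: real packing density (burial is
all-or-nothing), rotamer geometry, strand-rich topologies, correlated
B-factor noise, phylogenetic tree structure in the MSA, and instrument
drift in progress curves.  Passing the fixture suite therefore demonstrates
that each computation reads the right signal and applies the stated rule —
not that the default thresholds are optimal for any particular real
protein, where conservation and distance cutoffs remain tuning-sensitive.

## Problem sizes

Defaults keep every stage at desk scale: 60-residue fixtures (~230 atoms,
960 SASA points/atom), depth-50 MSAs, 20-seed ground-truth recovery sweeps,
and 200-seed kinetics recovery studies (7 concentrations × 3 replicates);
the full suite and the benchmark script each run in well under a minute.
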