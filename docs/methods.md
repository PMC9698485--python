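# Methods

`pocketmif` characterises protein binding pockets with molecular
interaction fields (MIFs): 3D lattices of interaction energy between a
chemical probe and the protein.  Five probes are used, with the standard
GRID-style semantics — **H** maps the steric shape of the pocket, **CRY**
its hydrophobic/lipophilic surfaces, **N1** (an H-bond *donor* probe) the
protein's acceptor sites, **O** (an H-bond *acceptor* probe) the protein's
donor sites, and **OH2** a water molecule.  On top of the fields sit three
analyses: pocket-pair similarity, per-residue energetic attribution, and
water-network placement with free-energy classification.

## The interaction model

The reference GRID force field is proprietary and its equations are not
published in a reproducible form, so the field engine implements a
declared, fully parameterised empirical model with the same structure.
The probe–atom pair energy is

```
E(r) = E_LJ + E_el + E_hb,   clamped at +5 kcal/mol
E_LJ = eps_mix [ (rmin_mix/r)^12 − 2 (rmin_mix/r)^6 ]
E_el = 332.0636 q_p q_a / (4 r^2)        # dielectric eps(r) = 4r, shifted
                                          # to 0 at the cutoff
E_hb = −emax [ 5 (d0/r)^12 − 6 (d0/r)^10 ] cos²θ,   d0 = 2.9 Å
```

with geometric-mean well depths and additive `rmin/2` radii
(Lorentz–Berthelot-style mixing).  The H-bond term acts only between
complementary partners (donor probe ↔ acceptor-capable atom and vice
versa); its well depth is `emax ≤ 0` at `r = d0` with ideal geometry, and
it is repulsive at short range.  The angle θ is measured at the protein
atom, between its idealised lone-pair/H direction — pointing away from
the mean of its bonded heavy-atom neighbours (bonds detected at ≤ 1.9 Å,
2.2 Å to sulfur) — and the direction to the probe; beyond 90° the factor
is zero, and atoms with no resolvable neighbour get factor 1.

Protein atoms use an extended-atom (implicit hydrogen) representation:
explicit H atoms are dropped on read and each heavy atom carries one
interaction class (`hydrophobic`, `donor`, `acceptor`, `donor_acceptor`,
`cation`, `anion`, `polar`) from a (residue, atom-name) table covering the
20 standard residues and water, with element fallback for anything else.
Formal charges (±0.5 e) sit only on cationic/anionic classes; probe
charges are small (±0.2 e on N1/O) so electrostatics perturbs rather than
dominates.  Probe-specific behaviour: H is steric-only; CRY is LJ-only
with its dispersion against polar-class atoms scaled to 25%; N1/O/OH2 add
the H-bond term.

All constants live in `src/pocketmif/data/probes.toml` (printed by
`pocketmif params`).  The probe well depths were chosen once so that each
probe's standard contour level — H +0.10, CRY −0.6, N1 −4.5, O −3.5
kcal/mol, the levels at which these fields are conventionally displayed —
falls inside the physically meaningful range of the model: a single
hydrophobic contact contributes roughly −0.27 kcal/mol to CRY so only
multi-atom lipophilic walls cross −0.6, while a single well-oriented
H-bond (≈ −5 to −6 kcal/mol) crosses the polar contours on its own.  No
numeric equality with the proprietary reference is claimed; field values
are defined by this model.

### Grids

Fields live on axis-aligned cubic lattices (default spacing 0.5 Å,
padding 3 Å) whose origin snaps down to the spacing lattice, so identical
inputs give identical grids.  Pair sums use an 8 Å cutoff; the
electrostatic term is shift-truncated to zero there, so deleting an atom
provably never changes grid points beyond the cutoff.  The summed field
is clamped at +5 kcal/mol to keep repulsive cores finite for similarity
and attribution.  Translation equivariance holds to float round-off
(~1e-13 kcal/mol), since absolute coordinates enter the distances.

Alongside the energy, each grid point records the *max contributor*: the
atom whose single pair term is most favourable there (ties go to the
first atom in input order; the synthetic generator deliberately avoids
exactly degenerate geometries).

## Pocket similarity

Two pockets, superposed into one frame by the caller (Kabsch
least-squares on user-supplied correspondences), are evaluated on one
shared grid covering both.  Each probe field is binarised at its contour
level and restricted to the pocket envelope — the union of pocket-atom
spheres (vdW `rmin/2` + 3 Å shell) — so far-field bulk cannot inflate the
score.  Channels are compared with the Tanimoto coefficient
|A∧B|/|A∨B|, with the convention that two *empty* channels score 1.0
(two pockets lacking, say, donor hotspots are identical in that respect;
the event is logged).  The Global-Sum score is the weight-normalised mean
of the per-probe values (equal weights over H/CRY/N1/O by default), which
keeps it in [0, 1] for any nonnegative weights.

## Per-residue attribution

Each favourable grid point is attributed to its max contributor's residue
— deliberately ignoring all other atoms' contributions at that point —
and the attributed single-atom energies accumulate per residue and probe.
Because the prose tradition for this analysis mentions both an
accumulated value and a per-residue best value, the table reports both
statistics per cell: the `sum` over attributed points (the default for
heatmap rendering; darker = more negative = stronger) and the `best`
single attributed point.  Conservation is exact by construction: per
probe, the residue cells sum to the total attributed point energy, and
the attributed points partition (each belongs to exactly one residue).

One subtlety is significance: the polar probes feel a small
dispersion-only attraction (≈ −0.15 kcal/mol) to *any* atom, which would
make every hydrophobic residue a nominal "contributor" to the donor and
acceptor maps.  Attribution therefore applies a per-probe significance
level (`ATTRIBUTION_SIGNIFICANCE`: 0 for CRY/H, −0.5 kcal/mol for
N1/O/OH2 — deeper than any dispersion-only term can reach): a residue
counts toward a polar map only through actual H-bond or electrostatic
chemistry.  Residues that never pass the level are flagged
no-contribution (CSV `NA`, rendered grey).

Tables from two pockets are aligned with a user-supplied residue pairing
(insertions/deletions flagged and excluded); deltas are `cell_B −
cell_A`.

## Water networks

Waters are placed greedily on the OH2 field: take the most favourable
unexcluded lattice point of the *current* field; stop if its standalone
energy (OH2s) is above the placement cutoff (−5 kcal/mol — at least one
good H-bond); refine the position by at most 10 steepest-descent steps of
0.1 Å on the trilinearly interpolated field; add the water to the
receptor (typed donor+acceptor, water LJ parameters, neutral) so later
placements feel it; mask a 2.4 Å exclusion sphere; repeat up to 30
waters.  Everything is deterministic — lattice argmin ties break
lexicographically by (z, y, x) index — and invariant to atom input order.

Each water records four components:

* **OH2s** — its OH2 energy against receptor (+ ligand) alone;
* **OH2n** — the same including the previously placed waters;
* **CRY** — the lipophilic field at its position;
* **ENTR** — an entropy penalty in [0, k_S]: for each of 26 directions
  the OH2 enthalpy is walked out to 2.8 Å (4 interpolated steps); a
  direction is *free* if the enthalpy never rises above the start value
  by more than 0.5 kcal/mol, and ENTR = k_S × (constrained fraction)
  with k_S = 1.5 kcal/mol.  Walks leaving the grid count as constrained.
  A water free to drift loses less entropy on binding than one locked in
  a tight well.

These combine into a relative free-energy score against a bulk-water
reference,

```
DG_WAT = α·OH2n + β·OH2s + γ·CRY − E_bulk + ENTR
```

with defaults α = 0.7, β = 0.3, γ = 0.2, E_bulk = −9.0 kcal/mol.  The
combination rule is this package's declared choice (the reference
implementation does not publish one); the weights favour the in-network
energy because a structural water's partners include its neighbours, and
E_bulk is set near the depth of a well-solvated site so that a water no
better bound than bulk scores ≈ 0.  Classification uses the standard
four half-open intervals: happy (DG_WAT < −2.0), bulk-like [−2.0, 1.5),
unhappy [1.5, 3.0), very-unhappy (≥ 3.0 kcal/mol).

## Synthetic pockets

The generator (`fixtures`) emulates the features of a binding site that
these analyses actually consume: a concave wall of typed chemistry.  It
places residue-like clusters (LEU, GLN, ASN, GLU, LYS templates with
roughly bonded local geometry, so the production typing table and H-bond
neighbour detection apply unchanged) on a hemispherical shell, tips
pointing inward, classes drawn deterministically from a composition and
seed.  Shell radii are modulated ±4% per residue because a mathematically
perfect sphere would make the pocket centre exactly equidistant from
symmetric atoms and the max-contributor argmin degenerate — a measure-zero
pathology real pockets do not have.  An optional two-atom ligand
(hydrophobic C + acceptor O) sits at the centre.  `perturb` adds seeded
isotropic Gaussian jitter without touching typing.

What the toys do **not** emulate: backbone connectivity, rotamer
statistics, secondary structure, crystallographic waters, or real pocket
topography.  Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms (oracle equivalence, metric
axioms, conservation, determinism, monotone degradation under noise) —
not predictive accuracy on real proteins, which depends on the force
field these toys cannot validate.

## Numerical choices and degenerate inputs

* Distances are floored at 0.05 Å when an atom sits on a lattice point;
  the clamp keeps the result finite.
* Altloc resolution: highest occupancy, ties by altloc id.  Only model 1
  of multi-model files is read.
* Superposition accepts 2 correspondence pairs but is then degenerate
  (rotation about the pair axis unconstrained); ≥ 3 non-collinear pairs
  give a unique proper rotation (reflections are never returned).
* Sequence identity/similarity use global alignment with BLOSUM62, gap
  open 10 / extend 0.5 (EMBOSS-needle-like), identity = identical pairs /
  alignment length (gaps included), similarity = positive-substitution
  pairs / alignment length.
* Empty structures yield zero fields; empty pockets yield empty water
  networks; an all-zero-weight Global-Sum, a NaN DG_WAT, and a
  non-positive grid spacing are errors.

## Problem sizes

The shipped tests and the acceptance script run on synthetic pockets of
5–12 residues with grids of roughly 2,000–15,000 points (spacing
0.8–1.5 Å), sizes at which the brute-force oracles remain exact
cross-checks; the engine itself is vectorised per atom and handles
0.5 Å production grids of a few hundred thousand points comfortably.

## Known limitations

* Field magnitudes are model-defined; only orderings and internal
  consistency are meaningful across parameter sets.
* H-bond geometry uses a single idealised direction per atom; sp³
  acceptors with multiple lone pairs are approximated by one cone.
* Waters are point particles — no orientation, no explicit hydrogens, no
  sampling-based hydration thermodynamics.
* Pocket comparison assumes a caller-supplied common frame; no pose
  search is attempted.
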