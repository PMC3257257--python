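# Methods

## Model

A design instance is a fixed template (backbone plus non-design side
chains), a set of design positions, and per-position candidate rotamers.
A *rigid* rotamer is the modal chi-angle vector of a side-chain cluster; a
*continuous* rotamer is the axis-aligned voxel `chi_modal ± h` per dihedral
(default half-width `h = 9°`, configurable; the width is treated as a
modelling choice, not an empirical constant). All chi arithmetic is in
degrees on `(−180, 180]` with periodic wrap; internally every optimization
runs in *delta* space (offsets from the modal point inside `[−h, h]`), so
wrap never enters the box algebra.

Energies decompose pairwise:
`E(A) = E_template + Σ_i E(i_r) + Σ_{i<j} E(i_r, j_s)`, each term a
function of the participating chi vectors. The rigid energy evaluates at
the modal points; the minimized energy `E_T(A)` jointly minimizes over all
voxels. `E_T` is not pairwise-decomposable (minimizing one side chain moves
the optimum of its neighbours), which is exactly why minimization-aware
pruning needs voxel bounds:

* `⌊E⌋` — lower bound: bounded multi-start minimization of the term over
  its voxel (pairs minimize jointly over both rotamers' chi);
* `⌈E⌉` — upper bound: the analogous maximization, computed only when
  MinDEE asks for it (the interval criterion never needs maxima).

Sums of `⌊E⌋`/`⌈E⌉` sandwich `E_T(A)` for every fully assigned `A`.

## Pruning criteria

All criteria share the Goldstein pattern — a candidate rotamer is pruned
when some competitor at the same position provably beats it in every
context — and differ in the matrix fields compared:

* **rigid**: `E(i_r) − E(i_t) + Σ_j min_s [E(i_r,j_s) − E(i_t,j_s)] > 0`.
* **MinDEE**: `⌊E(i_r)⌋ − ⌈E(i_t)⌉ + Σ_j min_s [⌊E(i_r,j_s)⌋ − ⌈E(i_t,j_s)⌉]`
  must exceed the sum of maximum-range terms
  `Σ_j max_s(⌈E(j_s)⌉−⌊E(j_s)⌋) + Σ_{j<k} max_{s,u}(⌈E(j_s,k_u)⌉−⌊E(j_s,k_u)⌋)`
  over the other positions. The pair comparison keeps a *shared witness*
  `s` on both sides; this form is tighter than bounding the two sums
  separately and is the one whose decisions collapse exactly onto rigid
  DEE when the voxel width goes to zero.
* **iMinDEE**: `⌊E(i_r)⌋ − ⌊E(i_t)⌋ + Σ_j min_s [⌊E(i_r,j_s)⌋ − ⌊E(i_t,j_s)⌋] > I`,
  sound whenever `I ≥ E_T(c*) − E_⊖(c_b)` (minGMEC energy minus the lowest
  sum-of-lower-bounds).

Around the singles criteria sit: an initial steric filter on
`⌊E(i_r)⌋ > threshold` (default 100 kcal/mol — a rotamer that can minimize
away from a template clash survives); Goldstein **pairs flagging** (the
pair analogue; flagged pairs are excluded from singles minima and from A*);
**split flags** with a single splitting position (per split rotamer, a
possibly different competitor must dominate); and **(Min)Bounds pruning**
against a known conformation energy, using the admissible A*-style
completion bound `template + B(i_r) + Σ_j min_s [B(j_s) + B(i_r,j_s) +
Σ_{k>j} min_u B(j_s,k_u)]` (the simpler bound that drops the unassigned-
pair terms is not admissible when pair energies can be negative). A small
absolute tie guard (1e-9 kcal/mol) keeps float summation-order noise from
pruning an exact tie.

Criteria iterate to fixpoint — a prune at one position enables prunes at
others — with synchronous updates inside each pass (decisions are taken
against the state at pass start), competitors restricted to currently
unpruned rotamers, and strict inequalities throughout so ties never prune.

## A* and the stop rule

Conformations are enumerated best-first under the admissible completion
heuristic (for each unassigned position, the best rotamer's single energy
plus its interactions with the assigned part plus optimistic pair terms to
later unassigned positions), yielding every unpruned, unflagged
conformation exactly once in nondecreasing bound order. The expansion
order is static (fewest unpruned rotamers first); equal bounds break
lexicographically; the queue has a configurable capacity and fails with a
partial log when exhausted.

With `energy_kind="rigid"` the first emission is the rigid GMEC. With
lower bounds, each emitted conformation is continuously minimized and
enumeration stops at the first bound strictly above the lowest minimized
energy seen — no unseen conformation can beat it. In GEM phase 1 the stop
threshold is `min(best_minimized, E_⊖(c_b) + I₀)`, so the enumeration also
covers every conformation within the initial interval of the lowest bound.

## GEM

Phase 1 prunes with `I₀` (default 0.5 kcal/mol, configurable; the driver
logs `E_⊖(c_b)` and `E_T(c′)` so users can retune), searches, and computes
`I₁ = E_T(c′) − E_⊖(c_b)`. `I₁` is always a valid interval, because
`E_T(c′) ≥ E_T(c*)` and `c_b` survives any nonnegative interval (pruning
`c_b`'s rotamers would contradict its bound minimality, and the first A*
emission therefore measures `E_⊖(c_b)` correctly even under an invalid
`I₀`). If `I₁ ≤ I₀` the phase-1 winner is the minGMEC; otherwise one rerun
prunes afresh from the *original* unpruned matrix with `I₁` (phase-1
prunes under the invalid interval are not trusted) and uses the standard
stop rule. Two phases are a structural maximum.

## Minimization

All voxel optimizations use bounded multi-start local descent: the modal
point, the voxel corners (dimension ≤ 4), seeded random interior starts,
and — for vectorized models — a dense pre-sample (13 points/dim up to 3
dims); the best candidates get an L-BFGS-B polish. Full-conformation
minimization is cyclic coordinate descent (dense 1D sweeps per position
for vectorized models) run from the modal point plus 2 random joint
starts, followed by a joint L-BFGS-B polish; convergence tolerance 1e-6
kcal/mol (well below every comparison tolerance used in validation).

Local search cannot certify a *global* voxel minimum for arbitrary
energies. The guarantees are therefore validated on synthetic landscapes
whose smoothness makes the pre-sample density effectively exact; molecular
runs inherit the same approximation the lineage of this method has always
carried, and the matrix records its minimizer settings.

## Synthetic instances and the oracle

The generator emits seeded instances with one chi dihedral per rotamer and
analytic energies: per-rotamer `a + b(1 − cos(W(δ − μ)))` and per-pair
constants plus coupled cosine terms, all with a 72° wavelength so a voxel
sees at most one well of any term. Two motifs reproduce the phenomena the
algorithms exist for:

* a **modal clash** on about half the rotamer pairs of coupled instances —
  a strong cosine in `δ_i − δ_j` whose minimum sits 11-17° off the modal
  diagonal: expensive at the modal points, relaxable inside the voxels.
  This is what makes rigid (modal-point) energies a misleading guide, so
  that the minGMEC usually differs from — and beats — the minimized rigid
  GMEC, as a packed protein core does;
* an optional **trouble spot**: a hub position whose pairs with two
  partners each minimize well alone but pull the hub's chi in opposite
  directions, so no joint assignment realizes both pair bounds. This
  inflates `E_T − E_⊖` (hence `I₁`) and forces the GEM rerun.

Separable instances (`coupling_strength = 0`) have constant pair functions
and exactly tight bounds. What the generator does **not** emulate:
molecular-mechanics magnitudes, multi-dihedral side chains, backbone
strain, or solvation physics — passing the suite certifies the *search
logic* (pruning soundness, equivalence, termination, orderings), not the
chemistry of any force field.

The brute-force oracle computes the rigid GMEC by exhaustive evaluation
and the minGMEC by a per-conformation joint chi grid (step 1°, refined by
local descent). Conformations are scanned in order of an exact
sum-of-grid-minima lower bound with a small smoothness slack, so provably
non-optimal conformations are skipped without changing the result; a
budget guard refuses instances whose conformations × grid points exceed
capacity.

The frozen validation suite holds 100 instances: 40 small (2-3 positions,
2-4 rotamers), 40 medium (4 positions, 3-4 rotamers), and 20 large (5
positions with 2-3 rotamers, plus four 6-position instances with 2
rotamers) — sizes chosen so the exhaustive oracle remains affordable; 15
instances are separable, and a quarter of the coupled ones carry the
trouble-spot motif. Validation tolerances: 1e-3 kcal/mol against the
oracle minGMEC (two independent optimizers), 1e-6 for MinDEE vs iMinDEE
equivalence and for energy orderings, exact conformation identity for the
rigid comparisons.

## Molecular model

Energy terms: 6-12 van der Waals with geometric-mean well depths and
combined radii scaled by `radius_scale`; Coulomb with distance-dependent
dielectric `ε(r) = D·r` (332.0636·q_aq_b/(D r²)); EEF1-style
Gaussian-exclusion desolvation plus per-atom reference terms scaled by
`solvation_weight`; per-amino-acid reference energies and entropy
penalties folded into the intra term. The parameter tables (vdW radii and
well depths by element, simplified partial charges, EEF1 constants by atom
class, Gly-X-Gly side-chain reference areas, residue volumes and masses)
are a minimal self-consistent vendored set: they are configuration. The
defaults `D = 6`, `solvation_weight = 0.5`, `radius_scale = 0.95` are
placeholders for weights that would normally come from training, which is
out of scope here. Energies above 1e6 kcal/mol are capped for numerical
stability; pruning treats capped values as ordinary numbers.

Side chains are built from ideal-geometry templates (heavy atoms only) by
NeRF placement, with every chi set exactly by rotation about its bond;
branch and ring atoms carry fixed offsets. Consequences: ring geometries
are idealized, the proline ring is left open at the CD-N bond, and
hydrogens are not built (those present in an input file are kept as
template atoms). Within a residue, atom pairs fewer than three bonds apart
are excluded; across a peptide bond the 1-2/1-3 pairs are excluded.

Design sites are residues whose side-chain relative SASA (internal
Shrake-Rupley, 960 sphere points, 1.4 Å probe, Gly-X-Gly reference areas)
falls under the smallest of 5/10/20% that yields at least 12 positions —
or all such residues when fewer. Substitution sets are the wild type plus
the k = 5-7 best BLOSUM62 substitutions (ties broken in the standard
matrix order; Cys/Pro/Gly excluded as substitutions by default, a toggle).
Glycine positions are skipped by SASA selection (no side-chain area to
measure). Sequence-recovery reports classify residues by flexible-dihedral
count and by residue-mass class (small < 100 Da, medium 100-130 Da, large
> 130 Da; Cys and Pro, absent from the canonical listing, classify by
their masses as medium and small).

## Degenerate inputs and tie-breaks

Ties never prune and never flag (strict inequalities plus the 1e-9 tie
guard in bounds pruning). A position whose rotamers are all pruned marks
the state infeasible — reported, not raised. A rotamer left without any
usable partner at some position (all pairs flagged) belongs to no valid
conformation and is pruned outright. Matrix serialization (zip archive
with a JSON header and raw float64 blocks) round-trips bit-exact.

## Known limitations

* Bounds from local search are not certified global voxel minima on
  arbitrary energy functions; the provable-soundness surface is the
  synthetic suite.
* Split flags use one splitting position; higher-order splits and
  higher-order (beyond pairwise) bounds are out of scope.
* The molecular energy function is deliberately minimal (no hydrogen-bond
  or statistical terms, simplified charges); it supports end-to-end
  molecular runs and unit tests, not quantitative redesign claims.
* Backbone flexibility, ensembles/partition functions, and
  backbone-dependent rotamer libraries are not modelled.
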