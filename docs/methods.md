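# Methods

This note documents the models, numerical choices and limitations of
`ssefold` at the level a maintainer or reviewer needs. Default values
quoted here are the package defaults; all of them are overridable through
`RunConfig` (YAML).

## Protein representation

Residues carry five atoms: N, CA, C, O and CB. Glycine receives a
pseudo-CB placed with the same tetrahedral geometry as every other residue
(bond 1.521 Å, angle N–CA–CB 110.4°, improper C–N–CA–CB −122.6°), so pair
potentials and contact metrics treat all residues uniformly; in PDB output
this atom is written with the name `HA2` and mapped back to the CB slot on
reading. Indices are 1-based and ranges are closed intervals, matching
PDB/DSSP conventions.

An SSE is a contiguous segment with idealized backbone geometry built by
natural-extension (NeRF) forward construction from fixed dihedrals — helix
φ=−57°, ψ=−47°; strand φ=−135°, ψ=+135°; ω=180° — and textbook covalent
parameters (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; N–CA–C
109.5°, CA–C–N 116.2°, C–N–CA 121.7°). With these values the helix rise is
1.503 Å per residue and the strand rise 3.43 Å; the tetrahedral N–CA–C
angle was chosen from the textbook range precisely because it lands the
rises at their canonical values (1.50/3.40). Each SSE stores a rigid body
frame; its coordinates are always exactly the canonical template (CA
centroid at the origin, screw axis on +z via a least-squares circle fit,
first residue at negative z) mapped by that frame, so re-deriving the
frame from coordinates by Kabsch superposition is exact to machine
precision. The axis direction of a regular trace is computed from the null
space of the scatter matrix of second differences of CA positions, which
is exact for ideal helices and strands and avoids the tilt a principal
component axis shows on partial turns.

A `ProteinModel` is an ordered list of non-overlapping SSEs over one
sequence. Loop residues are absent by design: the search operates on the
rigid arrangement only.

## SSE pool

Per method (two slots, a PSIPRED `.ss2` dialect and a generic 3-column
TSV), each residue takes its argmax state, demoted to coil when the
winning helix/strand probability is below 0.5. Maximal H/E runs form pool
entries; helices shorter than 5 and strands shorter than 3 residues are
dropped; the union over methods is returned with duplicates collapsed.

Refinement minimizes the agreement score — the sum over residues, averaged
over methods, of −log p(assigned state) with a 10⁻⁴ probability floor — by
1000 greedy single-residue label flips (a flip may also divide an SSE);
proposals creating under-length runs are rejected, so the score is
monotonically non-increasing and minimum lengths always hold. Greedy
descent (temperature 0) is used because the procedure is a minimization of
a cheap, local objective; no uphill moves are needed in practice.

Pool evaluation: Q3 resolves overlapping entries by letting helix/strand
beat coil, and resolves rare H-vs-E double coverage by the higher mean
predicted probability (helix on ties when no prediction is supplied). A
native SSE counts as "found" when at least one same-type entry overlaps it
by one residue or more; its shift is the minimum |Δfirst| + |Δlast| over
those entries, and the reported shift averages over matched native SSEs
only.

## Composite energy

Twelve terms, each with a non-negative weight (all 1.0 by default), in
arbitrary score units (su); lower is better. The functional forms are
compact analytic stand-ins — the term inventory and the role of each term
are fixed, but the shapes were designed here and every constant is
config-exposed:

* **aa_clash**: Σ over CB pairs in different SSEs of max(0, 3.0 − d)²·10.
* **aa_pair_distance**: for pairs with sequence separation ≥ 5 and
  d < 12 Å, −(KDᵢ·KDⱼ/4.5²)·(1 − d/12), a Kyte–Doolittle
  hydrophobicity-product attraction.
* **aa_solvation**: neighbor counts n (CB within 10 Å). Each residue
  prefers a burial level n* = 14 + KD, and pays
  (|KD|/4.5)·((n − n*)/4)² − |KD|/4.5. The two-sided well penalizes both
  exposed hydrophobics and over-buried polars; a one-sided burial reward
  was rejected because it makes indiscriminate compaction a global
  minimum. The reference level 14 matches the measured mean neighbor
  count at a 10 Å radius in compact ~50-residue bundles.
* **sse_pair_clash**: quadratic penalty when the axis segment distance of
  an SSE pair falls below type minima (H–H 7.0, H–E 6.0, E–E 4.0 Å).
* **sse_packing**: for pairs within 12 Å, −well(d; d₀, width 3 Å)·(0.5 +
  0.5·|cos θ|) with ideal axis distances H–H 9.5 Å and H–E 10.0 Å and θ
  the inter-axis angle.
* **strand_pairing**: per strand pair, −max(0, 1 − ((d − 4.75)/1.0)²) on
  the mean nearest-CA pairing distance.
* **loop_length**: per adjacent SSE pair with gap (euclid, n), the excess
  of euclid/√(n+1) over 2.5 Å, squared.
* **loop_closure**: a fixed 1000 su when euclid > 2.56·(n+1) + 2.0 Å
  (unclosable by an n-residue loop), else 0.
* **radius_of_gyration**: ((Rg − Rgₑ)/Rgₑ)² with Rgₑ = 2.2·N^0.38 Å over
  modeled CA atoms.
* **ss_agreement (×2, one per prediction method)**: Σ over all residues of
  −log p(modeled state), unmodeled residues scored as coil.
* **contact_order**: ((RCO − 0.3)/0.15)², RCO computed over modeled CB
  contacts (|i−j| ≥ 1, < 8 Å) and normalized by the full sequence length.

The unfolded part contributes coil agreement and a flat solvation
reference of 0 su, so "add SSE" moves compete fairly with leaving a region
unmodeled. The total is rigid-motion invariant and equals the weighted sum
of raw terms to 10⁻⁹.

## Move registry and search

Twenty-eight registered behaviors cover the six categories: adds
(random placement, next-to-SSE at ideal packing distance, short-loop-aware
placement within the closability limit, strand-next-to-sheet), removes
(random, unpaired strand), swaps (placement exchange of same-type SSEs,
replacement by an overlapping pool alternative), single-SSE
translate/rotate/transform in large (≤ 8 Å, ≤ 90°) and small (≤ 1.5 Å,
≤ 15°) amplitudes plus strand axis shifts, resizes at either terminus
(the only moves in both stages) and splits, SSE-pair translations and
hinge rotations plus strand pairing, and domain moves (sheet shuffle, sheet
flip, sheet divide into a sandwich, subset translations). Sheets are
detected as transitive closures of strand pairs with mean nearest-CA
distance < 6 Å. Category weights default to add 0.25 / remove 0.05 /
swap 0.10 / single 0.30 / pair 0.15 / domain 0.15 in assembly and
single 0.50 / pair 0.25 / domain 0.15 / resize 0.10 in refinement, split
evenly within a category; strand/sheet moves drop to zero weight for
all-helix pools. Weights are static during a run. A move either returns a
fresh, valid model or the `skipped` marker; inputs are never mutated.

The Metropolis reference energy is the **best** energy observed so far,
and a rejection resumes from the best model. This is deliberate and
unconventional (a conventional last-accepted comparison is available via
`compare_to_best=False`): it makes the search strongly exploitative around
the incumbent while the adaptive temperature restores exploration.
Termination counts consecutive **non-improving** steps (accepted, rejected
and skipped all count), which is the reading consistent with the stage
descriptions; skipped steps are excluded from the acceptance-ratio
denominator since no energy is evaluated. Temperature updates are
multiplicative (±5%, clamped to [10⁻³, 10⁶]) toward the linearly falling
cumulative-acceptance target; a ratio exactly on target cools.

Per-model random streams derive from (seed, model index) through NumPy's
`SeedSequence`, making every run reproducible byte-for-byte.

## Loop building

SSEs are first trimmed one residue per side (skipped at minimum length).
Loops grow from the N-terminal anchor with (φ, ψ) drawn from analytic
Ramachandran tables — per-residue-type mixtures of wrapped Gaussians on a
10° grid around the α_R, β and α_L basins, broader and symmetric for
glycine, φ-restricted for proline. These tables are design choices, not a
PDB survey; closure correctness does not depend on their exact shape. Per
loop, K = 20 candidates are sampled and the best kept by clash + crowding
+ anchor-distance bias.

CCD closure adjusts one dihedral at a time to the closed-form angle
minimizing the RMSD between a grown copy of the downstream residue's
(N, CA, C) and their fixed positions: the upstream anchor's ψ, φ/ψ of
every loop residue, and — essential for convergence — the downstream
residue's own φ, realized as a spin of the grown C about the grown N–CA
axis. Without that last degree of freedom one rigid orientation component
of the anchor triad is frozen and closure systematically stalls around
0.5–1.5 Å. The anchor RMSD is monotonically non-increasing within each
sweep (each step is an exact 1-D minimizer). Defaults: tolerance 0.08 Å,
200 sweeps, 5 force-close rounds that re-grow an open loop with fresh
dihedrals and re-run CCD, keeping the best conformation and flagging loops
that stay open. Terminal tails grow without CCD. SSE atoms are never
moved, grown peptide bonds are ideal to ±0.01 Å, and geometrically
unclosable gaps are reported, not raised.

## Metrics

Kabsch superposition (SVD with reflection guard) for RMSD; RMSD100 =
RMSD/(1 + ln √(n/100)), undefined for n ≤ 13 where the denominator is not
positive; contact order family with a minimum sequence separation of 1
(configurable — the contact recovery metric uses 12) and an 8 Å CB cutoff,
with RCO normalized by full sequence length (this also reproduces the
filtered-set RCO columns of the bundled reference tables); contact
recovery over the residues present in both structures. Benchmark summaries
use strict inequalities at the 8.0 Å and 20% cutoffs and sample standard
deviations. The move-correlation statistic C(i→j) = log₁₀(f₁/f₃), where
f₁ is the fraction of j-improved steps preceded by an i accepted-or-
improved step within the previous 50 steps and f₃ the fraction of i moves
leading to improved-or-accepted; the value floors at −3 when f₁, f₂
(fraction of i moves improving) or f₃ is zero. f₂ participates only in the
floor rule; the combination rule is a documented design decision since
only the three fractions, not their combination, are fully specified.

## Synthetic toy proteins

The fixture generator places idealized SSEs at explicit offsets and
orientations, designs a sequence (heptad-patterned hydrophobics for
helices, alternating for strands, glycine/serine loops), verifies every
junction against the closability rule, and emits the native SSE-only
model, a loop-built complete structure, perfect 3-state predictions
(p = 0.95 on the true state, two identical method slots), the native pool
and per-residue labels. Where a spin about an SSE's own axis is left free,
a deterministic greedy design step (24 angles, 2 sweeps) orients
hydrophobic faces into the core so the designed native sits near the
optimum of the sequence-dependent energy terms — as a real native would.

The standard toy is an antiparallel three-helix bundle: 3 × 16 residues,
9.5 Å spacing (the packing ideal), 5-residue loops, 1-residue tails — 48
modeled residues of 58. What passing tests on it show: the search
machinery recovers a designed compact topology from a correct pool, and
all bookkeeping/energy/closure contracts hold. What they do not show:
performance on real sequences with noisy predictions, β-sheet registry
accuracy at scale, or discrimination on proteins whose native state is
unknown to the energy designer.

## Problem sizes in the test suite

The folding experiment in the test suite runs 10 seeded repetitions of 25
models each (the acceptance script runs one 50-model ensemble) on the toy
bundle, asserting the best model by RMSD100 is below 5 Å in at least 9 of
10 repetitions; with the measured per-model hit rate of roughly 20–25%
below 5 Å this bound has a large safety margin. Loop-closure statistics
use 100 seeded two-helix fixtures whose chain-break distance is fixed at
12 Å over 8 loop residues (inside the closability rule — fixtures that
violate it stall by geometry, not by solver failure). Oracle-equivalence
checks (contact metrics vs O(n²) recounts, Kabsch vs a nested rotation
grid) run on 100 and 3 random fixtures respectively.

## Known limitations

* Energy terms are analytic stand-ins, not histogram potentials derived
  from the PDB; absolute score scales are not comparable to
  database-derived knowledge-based functions.
* No backbone flexibility within SSEs beyond resize/split (no bending), no
  side chains beyond CB, single chain only, no membrane environment.
* CCD is a local minimizer: a stalled loop needs the force-close restarts,
  and loops near the maximal span for their length may remain open
  (flagged in the output).
* Move weights are static; the registry is representative rather than
  exhaustive, with per-category multiplicities configurable.
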