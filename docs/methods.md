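# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `pseudocycle` package.

## Screw-axis closure model

A pseudocycle is an N-repeat single chain whose backbone approximates
C_N symmetry. The per-unit relationship is modelled as a rigid screw
motion and its deviation from ideal closure (rotation 360°/N, rise 0 Å)
is the design objective.

**Residue frames.** Each residue's frame has origin at Cα, x̂ = unit(C −
Cα), ẑ = unit((C − Cα) × (N − Cα)), ŷ = ẑ × x̂. Collinear backbone atoms
(cross-product norm below 1e−6) raise a degenerate-geometry error.

**Relative transforms.** For matched residues (k of unit i → k of unit
i+1) the transform is expressed as a *global-frame* (left-action) motion
R = B_dst·B_srcᵀ, t = o_dst − R·o_src. Under this convention an exactly
symmetric structure yields the *identical* transform for every matched
pair, which is what makes averaging across pairs well-posed. All
(N−1)·L transforms are pooled into one flat average; averaging
per-unit-pair first and then across pairs would give the same result for
rigidly replicated units and nearly the same for realistic ones.

**Quaternion averaging.** Quaternions are sign-aligned to the first
element (dot ≥ 0), arithmetically averaged, and renormalised;
translations are arithmetically averaged. This chordal mean is accurate
for tightly clustered rotations — the only regime that matters here,
since per-pair transforms of a plausible repeat protein agree to a few
degrees. A spread beyond 90° triggers a warning; a mean-quaternion norm
below 1e−6 is an error. The eigen-decomposition (Markley) average is
implemented alongside as an independent cross-check and agrees within
0.2° on 5°-perturbed clouds (tested).

**Screw decomposition.** With the canonical quaternion sign (w ≥ 0) the
rotation angle 2·arccos(w) lies in [0°, 180°]; the axis is the
normalised vector part, the rise is |t·axis|, and a point on the axis
solves the in-plane fixed-point equation (I − R)p = t⊥ by least squares
(exact, since t⊥ lies in the range of I − R). Rotations below 1° are
flagged degenerate: the axis is undefined, the rise is reported as ‖t‖,
and the rotation delta falls back to 360/N − θ. N = 2 (θ = 180°) is
handled by the same canonicalisation without a special case.

The screw invariants are conjugation-invariant and the
compose→decompose round-trip recovers angle and rise to ~1e−13 over
1,000 random transforms (measured by `scripts/acceptance.py`).

## Closure score and loss

Deviations Δrise (Å) and Δrotation (degrees) are rescaled by the
logistic 1/(1 + e^(−s(x−m))) with (m, s) = (2, 2) for rise and (4, 1.5)
for rotation, and averaged. Units are fixed as Å and degrees — the only
reading under which those midpoints sit in the dynamic range of typical
protein geometry. Consequences worth knowing:

- perfect closure scores (1/(1+e⁴) + 1/(1+e⁶))/2 ≈ 0.01023, not 0;
- deltas (2 Å, 4°) score exactly 0.5;
- a *single* saturated deviation caps the score near 0.5; a score above
  0.9 requires both deviations to be large.

The hallucination loss is `w_closure·closure + w_confidence·(1 −
pLDDT/100)` with both weights defaulting to 1. pTM is carried in
`ConfidenceMetrics` but excluded from the default loss. Trajectory
selection cutoffs default to closure < 0.1 and pLDDT ≥ 80; both are
configuration values, not fitted quantities.

## MCMC hallucination

Sequences are constrained to exact repeat symmetry: an L-residue unit
repeated N times. Each step draws k ~ Uniform{1..3} distinct unit
positions, substitutes each with a different residue (20-letter
canonical alphabet by default, `--no-cys` available), propagates the
substitutions to all units (full-sequence Hamming distance exactly k·N),
and accepts by the standard Metropolis rule (Δloss ≤ 0 always accepted;
else probability e^(−Δ/T)). The temperature default is a constant
T = 0.03, chosen because the loss is O(1) and this gives useful uphill
mobility without random-walk behaviour; it is configurable, and no
annealing is applied by default. Predictions are cached by full
sequence, so rejected/reproposed states cost no predictor call. A fixed
seed reproduces a trajectory bit-for-bit.

**Toy predictor.** The shipped test double maps the unit's hydrophobic
fraction h (AILMFVWY) and charged fraction c (DEKR) to a synthetic C_N
backbone with injected Δrise = 10·|h − 0.4| Å, Δrotation = 40·|c −
0.25|°, and pLDDT = 100·max(0, 1 − |h−0.4| − |c−0.25|). The optimum
(h = 0.4, c = 0.25) is exactly attainable at L = 20, composition moves
in 1/L steps under single substitutions, and the landscape is smooth, so
300-step trajectories reliably converge — by construction this validates
the *optimizer and scoring machinery*, not any predictor's folding
physics. The emitted backbone uses an all-helix unit template; the
choice is arbitrary since only the injected screw deviations carry
signal. `filter_designs` applies the 2 Å superposed Cα-RMSD
design-vs-prediction filter.

## Pocket annotation

The structure is reduced to polyalanine (backbone + Cβ; Cβ constructed
at ideal tetrahedral geometry when absent, e.g. glycine) so cavity
detection is sequence-independent. On a 1.0 Å grid, voxels within
(atom radius 1.8 + probe 1.4) Å of a heavy atom form the protein mask.
Because pseudocycle pockets are often solvent-open channels, a naive
flood fill would wash them out; the mask is therefore morphologically
closed with a 4.0 Å ball to seal channel mouths before the border flood
fill labels the exterior. Cavity voxels are those empty in the
*original* mask and unreachable from outside; the largest 26-connected
component (ties broken by lowest flat voxel index) is the pocket.
Components below 5 Å³ are discarded — the closing stage inevitably traps
single-voxel dimples on the molecular surface, and no physically
meaningful pocket is below water size. Lining residues are those with
any heavy atom within 4.5 Å of a cavity voxel centre. On a hollow-shell
fixture of inner radius 10 Å the measured volume is within 2% of the
analytic reduced-sphere volume (4/3)π(10 − 1.8 − 1.4)³; volumes are
grid-dependent at the ±10% level under rigid motion of the input.

## Comparison, clustering, coverage

**Superposition** is closed-form Kabsch (SVD, reflections excluded).

**TM score** is a simplified fragment-seeded implementation: seed
superpositions from contiguous fragments (full/half/quarter length),
iterate superposition on residue pairs within d0, and keep the maximum
of (1/L_ref)·Σ 1/(1 + (d_i/d0)²) with d0 = 1.24·(L_ref − 15)^⅓ − 1.8
floored at 0.5. Both normalisations are computed and averaged
(`tm_avg`), which makes the score symmetric. This is *not* a parity
port of TM-align; it is validated on self/noise/family fixtures, and
scores for unrelated folds land well below the 0.45 singleton
threshold. Unequal-length pairs are aligned by gapless-shift seeding
plus Needleman–Wunsch refinement on the TM-weighted distance matrix
(linear gap −0.6).

**Secondary structure** uses dihedral windows (helix: φ∈(−100°,−30°),
ψ∈(−80°,−5°); strand: φ∈(−180°,−80°), ψ∈(80°,180°)∪(−180°,−170°)), with
H runs < 4 and E runs < 3 demoted to loop and termini loop. No
hydrogen-bond energetics are used, so assignments at element boundaries
can flicker under Å-scale coordinate noise; the clustering group-by-SS
step is therefore most meaningful for idealised or relaxed models.

**Clustering** groups scaffolds by repeat number and repeat-unit SS
string, then runs average-linkage agglomerative clustering on
1 − tm_avg within each group. The cluster count is scanned over the full
range and chosen to minimise the singleton fraction subject to the
pooled mean intra-cluster TM staying ≥ 0.85 (the all-singleton solution
is vacuously feasible, so a feasible choice always exists). The full
scan is kept in the report so users can re-select under different
constraints. **Coverage** samples subsets without replacement and
reports the fraction of members whose best TM to every other subset
member falls below 0.45; the expected fraction is non-increasing in
subset size.

## Synthetic backbones

Units are built from (φ, ψ) templates — helix (−57°, −47°), strand
(−120°, 120°), loop (−80°, 150°) — with ≤3° seeded uniform jitter,
standard bond lengths/angles, and ω = 180°, via natural-extension
internal-to-Cartesian placement. The unit centroid is placed
`ring_radius` Å from the global z axis and copies are generated by the
screw operation (360/N + inject_rotation about z, inject_rise along z),
so the ground-truth screw parameters are known *exactly*: because the
units are rigid copies, every matched residue pair yields the identical
relative transform and recovery is limited only by floating point (or
by PDB coordinate precision, ~0.002°, after file round-trips). Units
are placed rigidly with **no loop closure between units** — chain-break
geometry at unit boundaries is tolerated because closure scoring uses
only intra-unit frames. These fixtures exercise the geometry, scoring,
optimisation, and clustering machinery; they do not emulate packing,
side chains beyond Cβ, or predictor error, so passing tests demonstrate
algorithmic correctness, not design viability on real predictors.

## Pipeline and reproducibility

`RunConfig` (TOML, unknown keys rejected, validated at load) drives
hallucinate → pocket → cluster. One master seed is split into per-stage
streams via `SeedSequence.spawn`, so reordering or skipping stages does
not reshuffle randomness; identical config + seed gives byte-identical
outputs. A manifest JSON lists every file written, per-stage status, and
wall time; a failed stage halts downstream stages but preserves the
manifest.

## Problem sizes

The bundled analyses run at fixture scale, chosen to exercise every
code path with exact ground truth: 1,000 random transforms for the
screw round-trip; N = 2…7 generators plus a 5×5 injection sweep; 10
MCMC trajectories of 300 steps (N = 5, L = 20); 10,000 Metropolis
trials and a 40,000-step two-state chain; a 42-structure population
(8 families of 5 plus 2 uniques) with subset sizes 10/20/40 × 10
replicates for coverage. Library-scale analyses (thousands of scaffolds,
subsets of 500–5,000) use the same code paths via the precomputed
TM-matrix entry points.

## Known limitations

- No real structure predictor or fixed-backbone sequence designer is
  bundled; those stages are interface contracts (`StructurePredictor`),
  and the external resurfacing/re-validation steps of a production
  pipeline are represented only as adapter hooks.
- The TM implementation trades exactness for simplicity; absolute values
  can differ from reference TM-align by a few hundredths on distant
  pairs.
- mmCIF, multi-model files, insertion codes, and non-standard residues
  are out of scope for I/O (the first three rejected or ignored, the
  last dropped with a warning).
- Cavity volumes are voxel counts: grid-orientation dependence of ±10%
  is inherent at 1 Å spacing.
- Repeat boundaries (N, L) are inputs; the package does not detect
  internal symmetry de novo.
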