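# Methods

This note records the models, parameter choices, numerical details and
known limitations of the hingescan pipeline, in the order data flows
through it.

## Structures and trajectories

Trajectories are multi-model PDB files over a fixed topology (same atoms,
same order, every model). Residue numbering is taken verbatim from the
records and never renumbered, so user-facing residue numbers (e.g. 228)
always mean the input's own numbering. Parsing is strict: unparsable
records fail with their line number, a model whose atom count disagrees
with the topology fails naming that model, insertion codes are rejected,
and altLoc letters other than blank/"A" are dropped with a warning. The
writer emits fixed-width records, so a write→read round trip preserves
coordinates to the format's 3-decimal precision and atom order exactly.

The default subdomain decomposition of the DnaK NBD is I-A (1–36, 111–180),
I-B (37–110), II-A (181–226, 311–383), II-B (230–310); residues 227–229,
the II-A/II-B tether coil, deliberately belong to no group. A residue can
belong to at most one group. For synthetic chains of other lengths the
boundaries are rescaled proportionally, preserving the tether gap.

## The synthetic generator

The generator emulates the *statistical* structure the analysis assumes and
nothing else — no force field, no solvent, no side chains, no thermostat.
Per frame:

1. every residue's (φ, ψ) is drawn from a von Mises pair around its mean
   (independent in φ and ψ); hinge residues first pick mode 1 or mode 2 by
   a Bernoulli draw with state-dependent mode-2 occupancy. Background means
   alternate helix/strand blocks so the chain is crumpled rather than
   collinear. κ = ∞ is accepted and means exact, noise-free torsions;
2. the backbone (N, Cα, C; ω = 180°, ideal bond lengths 1.458/1.525/1.329 Å
   and angles 111.2/116.2/121.7°) is rebuilt by sequential internal-
   coordinate placement, vectorized across frames; rebuilt chains return
   the sampled torsions to machine precision;
3. the II-B block is rigidly translated along the line joining the II-B and
   I-A+I-B+II-A Cα centers of mass so the COM distance equals a
   Normal(openness_mean, openness_sd) draw. Defaults per state: apo 32.0 Å,
   ATP 27.3 Å, ADP+Pi 26.1 Å, sd 1.0 Å. No rotation is planted;
4. i.i.d. Normal(0, noise_sd) jitter is added to every atom coordinate.
   The default is 0.05 Å: jitter stands in for fast coordinate noise, and
   at 0.05 Å it contributes ≈ 6° of circular noise to the measured
   dihedrals, safely below the width of a κ = 20 mode (≈ 13°). Larger
   values blur torsion statistics — at 0.3 Å the induced dihedral noise
   (≳ 25°) rivals typical mode separations;
5. the ligand pseudo-particle is Σ_r w_r · (Cα displacement of residue r
   from its time mean) over the coupled residues, plus isotropic
   Normal(0, noise_sd), positioned at the coupled residues' mean Cα.

One integer seed drives one `Generator`; run k of an ensemble uses
seed + k; pipeline state i uses seed + 1000·i. Identical spec + seed gives
identical output.

**Seam masking.** The rigid II-B translation necessarily breaks the two
peptide bonds at the block boundary. A dihedral spanning a broken bond is
physically meaningless, so torsion extraction flags any consecutive-residue
C–N "bond" whose median length across frames exceeds 1.5× the chain-typical
bond length *or* whose length fluctuates more than 3× the chain-typical
fluctuation (a real peptide bond is stiff; a seam breathes with the block).
Both tests are relative to the chain's own statistics, which keeps the
dihedral computation invariant under uniform scaling. The four residues
flanking the two seams lose one angle each and drop out of clustering;
plants are therefore placed away from the seam.

What the generator does **not** emulate: anharmonic backbone coupling
between φ and ψ (real Ramachandran basins are tilted), correlated
side-chain packing, rotational II-B motion, solvent friction, and any
free-energy realism. Passing recovery tests therefore demonstrates that the
analysis recovers the signal class it targets at realistic signal-to-noise,
not that it would behave identically on all-atom MD output.

## Openness

Openness is the Euclidean distance between *unweighted Cα* centers of mass
of II-B and of I-A+I-B+II-A, per frame, with no superposition (COM
distances are rigid-motion invariant). Cα-only is a documented choice —
mass weighting is not assumed. The open/closed threshold defaults to
29.5 Å, the midpoint of the open (31.9 Å) and ATP-closed (27.3 Å) ensemble
means; the boundary itself classifies as closed. With planted sd = 1 Å the
recovered ensemble mean is within 2·sd/√F of the plant (two standard
errors; this is a ≈ 95%-coverage statistical bound, not a deterministic
one).

## Superposition and essential dynamics

Rigid fits use the quaternion/SVD least-squares solution
(`scipy.spatial.transform.Rotation.align_vectors`), always a proper
rotation; fits require ≥ 3 non-collinear atoms. Combined runs are
concatenated in run order and every frame is superposed onto the running
mean until the mean moves < 1e-4 Å (minimum two passes).

The ED covariance is over Cα coordinates only (3N × 3N), unweighted,
computed on deviations from the post-fit mean and decomposed with a
symmetric eigensolver. Eigenvector signs are fixed (largest-magnitude
component positive) so projections are reproducible. A motionless input
yields all-zero eigenvalues and a degenerate flag rather than an error.
On synthetic ensembles where the planted II-B translation dominates the
jitter (openness_sd/noise_sd ≥ 5), mode 1 concentrates > 70% of its squared
loading on the II-B block — less than 100% because the all-Cα fit
redistributes a coherent translation of 1/3 of the chain partly onto the
counter-moving remainder (share ≈ n_rest/n_total for the block residues).

## Torsion clustering on the torus

Per residue, defined (φ, ψ) frames (≥ 50 required) are histogrammed in 10°
bins and smoothed with a wrap-around Gaussian (σ = 1 bin), so modes
straddling ±180° stay contiguous. Modes are found by **topological
persistence**: cells are swept from high to low density, merging into
periodic 8-connected components; a local maximum counts as a mode only if
the saddle at which it merges into a higher mode is ≤ 0.6 of its own peak
density. This kills shot-noise ripples on a blob's shoulder (which die
within a few percent of their height) while keeping genuinely separated
modes, balanced or not. Surviving maxima closer than 30° geodesic are
merged (denser wins) — the method's resolution limit; frames go to the
nearest mode by toroidal geodesic; modes holding < 5% of frames
(min_occupancy) are dropped and their frames reassigned; centers are
circular means of assigned frames.

A plain fixed-mass-cover threshold with connected components was evaluated
first and rejected: for von Mises modes at κ = 20 separated by 60–105°, the
level that covers 80% of the mass lies *below* the inter-mode saddle, so
the components merge and planted bimodality is lost. Mode-seeking with
persistence recovers modes ≥ 60° apart with occupancies in [0.05, 0.95]
and is equally deterministic and prior-free.

State comparison matches the two cluster sets greedily by geodesic center
distance within a 40° radius; a residue is shifted when a cluster on either
side is unmatched, or a matched pair's occupancy differs by ≥ 0.3
(Δ_occ). Both numbers are configuration keys echoed into every report; no
published values exist for them.

## Correlation to the nucleotide

DCC uses the 3-D dot-product normalization (not per-coordinate Pearson),
after superposing frames onto the run mean on all Cα — the same reference
as ED. The nucleotide enters as pseudo-site rows/columns; a residue's
nucleotide score is the max |C| over ligand sites; ties at the top-k
boundary break by ascending residue number. A zero-variance site is zeroed
off-diagonal and flagged. The vectorized path agrees with a brute-force
double loop to 1e-10.

The tally marks a residue significant when it is in the per-run top-60 in
≥ 4 of the runs. Note a structural property of this statistic: with full
backbone motion, torsional fluctuations propagate along the chain, so
residues near a coupled residue are *genuinely* correlated with the ligand
and a top-60 list on a 120-residue chain necessarily sweeps in much of the
flexible arm. The calibrated coupling-recovery study therefore uses a
torsionally quiescent chain (κ = ∞, openness_sd = 0, jitter only), which
isolates the planted coupling channel: coupled residues (w ≥ 0.7) then
score C ≈ w/√(w²+1) ≈ 0.57 against a noise floor of ≈ 0.07, and the
remaining false-positive rate is the combinatorial floor of the tally
itself (≈ 3.5% with 10 plants: Binomial(10, 50/373) ≥ 4).

Set enrichment is the one-sided hypergeometric tail (universe N, list k,
reference m), exact per `scipy.stats.hypergeom`; ligand proximity is the
per-residue minimum atom distance with a strict < 8 Å "near" flag.

## Conservation

"Conservative substitution" is a non-identical letter with BLOSUM62
score > 0 against the reference letter — the closest reconstructable
version of alignment-search "positives". Gaps and X count in the
denominator as non-conservative mismatches. The conservation filter is
*inclusive* (≥ identity_min): the published highlighted set treats a 90%
row as passing a 90% threshold, and the inclusive rule reproduces it;
a strict > would drop S203 (bacteria exactly 90%). Both the identity-only
and the combined (identity + conservative) rule are first-class because the
identity-only rule cannot reproduce the published five-mutant choice (one
mutated residue has 31%/5% identity but 95%/95% combined); reports carry
both flags rather than silently choosing.

The MSA generator fixes the identical/conservative row *counts* per column
(rounded target percentage of group size) and randomizes only their
placement, so realized percentages match targets to rounding — tighter than
the ±2-point binomial bound it is tested against.

## Helix geometry

The helix axis is the null direction (smallest principal component) of the
Cα second differences: for an ideal helix every local curvature vector is
exactly perpendicular to the axis, so the estimator is exact at any helix
length. (The plain principal axis of the coordinates was evaluated and
rejected: on 9–11-residue helices with fractional turns it tilts 1–6°
depending on phase, which is material when checking a 70–80° crossing
band.) Curvature-free straight segments fall back to coordinate PCA; axes
are oriented N→C. Inter-helical angles are folded to [0°, 90°]; the bend
angle of a helix about a pivot is the angle between the proximal and distal
sub-segment axes, flagged "bent" above a configurable 30° threshold
(straight-helix noise is < 5°; no published threshold exists).

The crossed-helix validation plants a known crossing angle between two
ideal helices and recovers it; the deposited DnaK NBD crystal structure is
not bundled, so the 70–80° band is demonstrated on the synthetic
construction, not measured on the real structure.

## Pipeline

`hingescan run` executes simulate → openness → ED → torsion clustering →
state comparison → correlation/tally → (conservation) → report from one
YAML config. Unknown keys are rejected and out-of-range parameters fail
validation; every default is echoed into the outputs. Correlation uses the
nucleotide-bound states only (the apo ensemble has no ligand site). A
residue is state-shifted if any state pair shows a shift; the per-pair
calls are written to `state_shifts.csv`. Reports are byte-identical across
reruns of the same config (timestamps only in the log). Exit codes: 0
success, 2 config error, 3 stage failure (named).

Evidence tiers: A = multimodal ∧ shifted ∧ tally-significant, B =
multimodal ∧ (shifted ∨ significant), C = multimodal only. Adding evidence
never lowers a tier. Candidate selection filters by a conservation rule
(and multimodality) and never drops a residue that satisfies the criteria —
choosing which candidates to take to the bench is outside this package.

## Study sizes

The standing validation studies (used by the tests and the acceptance
script) are: hinge recovery — 20 replicates × 3 states × 5 runs × 300
frames on 120 residues with 3 planted hinges (κ = 20, mode separations
≥ 60°, occupancies 0.2–0.8); coupling recovery — 20 replicates × 10 runs ×
200 frames on 383 residues with 10 coupled residues (w 0.7–0.95); openness
recovery — 500 frames per state. Together they run in a few minutes on one
CPU.

## Known limitations

* The generator's independence assumptions (φ ⊥ ψ, i.i.d. jitter) make the
  clustering problem cleaner than real Ramachandran statistics.
* The clustering resolution limit is the 30° merge radius; modes closer
  than that are reported as one.
* The tally's false-positive floor is combinatorial (k/N per run) and
  cannot be pushed to zero by more data; interpret significance against
  that floor.
* ED mode shapes are compared qualitatively only; no RMSIP against external
  mode sets is attempted.
* DCD input and mmCIF are not supported; multi-model PDB is the trajectory
  dialect.
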