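# hingescan

Detection of nucleotide-sensitive **hinge residues** in trajectory ensembles
of the Hsp70/DnaK nucleotide-binding domain (NBD) — and of synthetic
ensembles with planted, recoverable ground truth for validating every stage.

## The scientific problem

DnaK, the *E. coli* Hsp70 chaperone, couples ATP turnover in its NBD to
substrate binding in a separate domain. The NBD's four subdomains (I-A, I-B,
II-A, II-B) form a nucleotide cleft that is **open** without nucleotide and
**closed** with ATP or ADP+Pi bound. The conversion between these
conformations is mediated by a handful of residues in the coil tethering
subdomains II-A and II-B whose backbone switches between discrete (φ, ψ)
conformations — hinge residues. This package implements the full
trajectory-analysis chain used to find them:

1. **Openness** — per-frame distance between the Cα center of mass of
   subdomain II-B and that of I-A + I-B + II-A; ensembles classify as open
   (apo, ≈ 32 Å) or closed (ATP ≈ 27.3 Å, ADP+Pi ≈ 26.1 Å) at a 29.5 Å
   threshold (midpoint of the open/closed means).
2. **Essential dynamics** — eigen-decomposition of the 3N × 3N Cα
   fluctuation covariance of runs combined after iterative superposition;
   cumulative variance, mode projections, per-residue loadings.
3. **Torsion analysis** — φ = C′(i−1)–N–Cα–C′ and ψ = N–Cα–C′–N(i+1) time
   series; density estimation and deterministic mode-seeking clustering on
   the periodic (φ, ψ) torus; residues with ≥ 2 clusters are *multimodal*;
   cluster sets are matched across nucleotide states (geodesic matching,
   40° radius) and a residue is *state-shifted* when a cluster appears,
   disappears, or changes occupancy by ≥ 0.3.
4. **Nucleotide correlation** — dynamic cross-correlation
   C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with the nucleotide as a
   pseudo-site; per run, the 60 residues with the largest |C| to the
   nucleotide are tallied, and residues in the top-60 in ≥ 4 of 10 runs are
   significant. Anti-correlation counts exactly as much as correlation.
   Partner queries and hypergeometric set enrichment (e.g. against the
   proline-switch set K70, R71, P143, A144, Y145, F146, R151, E171) are
   included.
5. **Conservation** — per-column identity % and conservative-substitution %
   (BLOSUM62 score > 0 vs the reference letter) by taxon group, from an
   aligned FASTA; filters at ≥ 90% in bacteria **and** animals, in
   identity-only and combined (identity + conservative) modes.
6. **Hinge calling** — evidence tiers (A: multimodal ∧ shifted ∧
   tally-significant; B: two of those with multimodality; C: multimodal
   only) and candidate selection under a conservation rule, with candidates
   split by nucleotide-correlation significance.

Because real DnaK production trajectories are not shipped, the
`hingescan.synth` generator builds backbone ensembles from internal
coordinates with planted hinges (two-mode von Mises mixtures with
state-dependent occupancies), planted subdomain-II-B openness, a ligand
pseudo-particle linearly coupled to chosen residues, and alignments with
prescribed column conservation — every planted fact is stored as ground
truth so recovery can be scored.

## Worked example

```bash
cat > config.yaml <<'YAML'
seed: 1
out_dir: out
simulate:
  n_residues: 120
  n_runs: 5
  n_frames: 300
  hinges:
    - residue: 23           # bimodal but state-invariant (a G74 analog)
      mode1: [-70, -40]
      mode2: [60, 50]
      occupancy2: 0.5
    - residue: 70           # occupancy swaps with nucleotide (a G228 analog)
      mode1: [-70, -40]
      mode2: [60, 50]
      occupancy2: {apo: 0.2, ATP: 0.2, ADP_Pi: 0.8}
  coupled: {70: 0.9}        # residue 70 drives the nucleotide pseudo-site
YAML
hingescan run --config config.yaml
```

`out/report.json` from this exact run contains

```
multimodal:     [23, 70]
state_shifted:  [70]
candidates:     [70, 23]      # tier A first, then tier C
```

and `out/openness.csv` recovers the planted state means (mean ± sd over the
five runs): apo 31.97 ± 0.05 Å (open), ATP 27.30 ± 0.07 Å (closed),
ADP+Pi 26.08 ± 0.06 Å (closed). Both planted hinges are found, only the
occupancy-swapping one is called state-shifted, and it ranks first. Every
stage also writes its own CSV (`ed_eigen.csv`, `clusters.csv`,
`state_shifts.csv`, `tally.csv`, `conservation.csv`) and all thresholds
(60, 4/10, 8 Å, 29.5 Å, …) are echoed into `report.json`.

The stages are also available as standalone subcommands
(`hingescan simulate / geometry / edyn / torsions / rama / correlate /
tally / conserve / call`) and as plain library functions.

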