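# Methods

## Problem setting

Given only the ordered Cα coordinates of a protein chain, assign each
residue one of three secondary-structure states: helix (H), strand of a
sheet (E), or loop (L). The package treats the problem as union-of-
subspaces classification on a geometric descriptor, with a per-residue
machine-learning ensemble as an independent second route.

## The 39-feature descriptor

Each residue is described by seven blocks computed from Cα positions
alone (all angles in degrees, distances in Å):

| block | size | content |
|-------|------|---------|
| R | 3 | interior angles of the triples centered at i−1, i, i+1 |
| E | 4 | d(i−3,i), d(i−2,i), d(i,i+2), d(i,i+3) |
| D | 8 | axis distances (below) |
| V | 4 | angles between displacement vectors across the window |
| T | 4 | signed pseudo-torsions of the quadruples ending/starting at i |
| M | 5 | amino-acid type code (0–19, alphabetical) + the four V+T sums |
| N | 11 | neighborhood block (below) |

Torsions follow the IUPAC sign convention (right-handed positive),
cross-checked against mdtraj in the test suite. A right-handed ideal
helix gives T ≈ +50.04°; mirroring a trace negates exactly the torsion
content, which the tests assert.

**Axis distances.** Each D element projects one or both of a residue
pair onto a "virtual axis" through two flanking Cαs. Three of the
eight constructions are canonical (axis Cα(i−2)→Cα(i+1) for
axisDist(i−2,i−1) and axisDist(i,i+1); axis Cα(i−2)→Cα(i+2) for
axisDist2(i,i+1)); the remaining five are generated by shifting the
same patterns along the chain so that every axis stays inside the
i−3…i+3 context. What matters for classification is that the same
table is used at train and test time.

**Neighborhood block.** Candidates are residues at least 3 apart in
sequence and closer than 6.31 Å in space, pruned to those with a
sequence-adjacent fellow candidate; the final list keeps candidates
whose perpendicular onto the segment (Cα(i−1), Cα(i+1)) is shorter
than 5.81 Å and lands inside the segment. On an ideal helix this
yields exactly {i−3, i+3} (d ≈ 5.05 Å; i±4 are candidates at 6.20 Å
but project outside the segment); on a straight chain it is empty; on
paired strands it finds the opposite-strand partners. The block stores
the member count, the singular values of the centered member cloud, the
closest member j with d(i,j) and the signed sequence offset, four
flank-pair distances, and the angle between the two strand axes.

With no final-list member the block is all-zero but *valid* (a usable
"no pairing" signal). The five distances are undefined in that case,
so the post-processing close-distance count treats them as "none
short" — otherwise the all-zero sentinel would read as five distances
under 6 Å and the loop→helix rule would fire on every isolated loop
residue.

**Validity.** Every element carries a flag; an element is invalid when
a residue it needs is missing (chain ends) or its span crosses a chain
break (sequence gap or implausible consecutive Cα distance outside
2.0–4.5 Å). Masked entries never enter statistics, windows, or
training sets.

## Rank estimation and feature reduction

Effective rank is estimated from the singular spectrum by either the
cumulative-energy rule (smallest k carrying ≥ τ of the squared
spectrum; τ = 0.95 default) or the spectral-gap rule (argmax of
consecutive singular-value ratios, with the numerical-rank cut acting
as a terminal gap so exact-low-rank and full-rank inputs resolve
correctly). The gap rule recovers planted ranks 1–5 under 1e−6 noise
in ≥ 99% of seeded trials.

`reduce_features` selects k = effective-rank(F) rows of the feature
matrix whose submatrix again has effective rank k, via a deterministic
greedy span-growing sweep (lowest index first) with seeded random
restarts. The gap rule is the default criterion here: under the energy
rule a valid submatrix provably need not exist — every k-row subset of
a real feature matrix can concentrate its spectrum faster than the full
matrix — and in that case the search raises, reporting its best
attempt rather than looping forever.

## Subspace models

Windows: the z-scored descriptors (mean/scale per feature, estimated
on training residues and stored in the model file) of q = 7 consecutive
residues are stacked into a 273-dimensional column; a window exists
only where all 7 member descriptors are fully valid, so a clean
N-residue chain yields max(0, N−12) windows. q = 7 balances context
against end losses and matches the descriptor's own ±3 reach;
window size and slide are configurable.

Per class, the window matrix W_c is decomposed by SVD and truncated at
the energy rank (τ = 0.95) to an orthonormal basis Ũ_c.

**Model 1** labels a window by the smallest projection residual
‖(I − Ũ_c Ũ_cᵀ) w‖₂. Exact ties prefer L, then E, then H (loop is the
"neither" class).

**Model 2** compares subspaces instead of vectors: the windows of the
N_l = 3 sequence-nearest residues form a local matrix whose center
column is doubled in weight (a triangular kernel), and its leading
left singular vector — the consensus direction of the local geometry —
is compared with each class subspace by the chordal Grassmannian
distance √Σ sin²θ_j over principal angles (computed from the SVD of
Ũ_localᵀ Ũ_c, cosines clipped to [0,1]). The distance carries the
square root; dropping it, as a squared variant would, changes no
argmin.

Design choices that were genuinely open, and why they landed here:

* *Local neighborhood size.* Wide flat neighborhoods (5–7 windows)
  blur segment boundaries badly — each window already spans 13
  residues of context, so 5 windows reach across whole short strands;
  on the synthetic benchmark they cost 8–12 accuracy points. Three
  windows with a doubled center keep the local subspace anchored to
  the query residue while still denoising it.
* *Local rank.* Fixed rank 1 (the consensus direction) by default:
  higher local ranks re-admit the boundary contamination the weighting
  suppresses. `local_rank="estimate"` restores effective-rank
  truncation for experimentation.
* Sequence-adjacent rather than spatial neighborhoods; a spatial kNN
  variant is a possible extension, not implemented.

Models serialize to versioned JSON (bases, standardization, window
config); classification refuses version or dimension mismatches.

## Post-processing

Four rules repair systematic confusions, using the neighborhood count
and how many of the five N-block distances are under 6 Å
(strict inequalities as thresholds are configured):

1. H with count > 2 → E if ≥ 3 distances short, else L;
2. L with count > 4 and > 2 short → E;
3. L with count < 3 and exactly 5 short → H;
4. a singleton differing from a uniform 2-residue flank on both sides
   flips to the flank label — *unless* rules 1–3 would immediately
   revert the flip (without this guard the isolation rule undoes every
   single-residue correction and the step oscillates);
5. residues without any valid window inherit the nearest resolved
   label (ties to the left) and are then themselves passed through
   rules 1–3.

The guard in rule 4 and the re-application in rule 5 make the whole
step idempotent, which the tests assert on crafted fixtures and on
classifier output. Rules are intentionally minimal; no HMM or median
smoothing is applied.

## Stacked ensemble

Per-residue pipeline: quantile transform to a normal output
distribution (200 bins; several raw features are heavily skewed) →
ANOVA best-k selection (k = 39 keeps everything by default; the
machinery exists for ablation) → stacking of RF (1500 trees, 5 max
features), k-NN, MLP (one hidden layer of 50), XGBoost (η = 0.2,
depth 6, 300 rounds) under a logistic-regression meta-learner fed
class probabilities, 10-fold stacking CV. A plain logistic regression
can be kept as a fifth base model (`keep_lr`); it is dropped by default
as the weakest. Classes are balanced by seeded downsampling before
training. `EMLConfig.scaled()` (200/100 trees, 5-fold) is the preset
used for the few-thousand-sample synthetic corpora in the tests and
acceptance script; unspecified base-model details are library defaults
recorded in the serialized pipeline.

## Synthetic data

The generator emulates the three geometries at the Cα level:

* helices from the ideal parameterization (radius 2.3 Å, rise 1.5 Å,
  twist 100°; bond 3.83 Å, d(i,i+3) = 5.05 Å emerge);
* strands from internal coordinates (3.8 Å, 123°, alternating ±170°),
  planarized and mirrored at 4.8 Å separation into antiparallel
  hairpins with a 2-residue turn, so the neighborhood thresholds fire
  exactly as for real sheets;
* coils from wide random internal coordinates (angles U(85°,140°),
  torsions U(−180°,180°)) with self-intersection rejection (min
  pairwise distance 3.5 Å, 100 retries).

Multi-segment proteins connect segments at the standard 3.8 Å virtual
bond, oriented away from the existing structure with a 6.5 Å clearance
check so cross-segment contacts never counterfeit strand pairing.
Gaussian jitter models coordinate noise; displacements that would push
a virtual bond outside the plausible 2.0–4.5 Å range are locally
redrawn so generated traces always satisfy the trace invariants. All
randomness flows from explicit seeds.

Benchmark conditions: corpora of proteins with one helix (8–16
residues), one strand hairpin (5–8 per strand), one coil (5–10) and
optionally one extra segment, in random order, at jitter 0.1 Å; 60
training and 20 held-out proteins. What the synthetic benchmark does
*not* probe: real Ramachandran statistics, 3₁₀/π helices, bulged or
mixed parallel sheets, long-range packing contacts, and the label
noise of experimental HELIX/SHEET annotations — synthetic accuracies
are therefore upper bounds on real-data behavior, and the paper-scale
corpus path (PDB files through `trace.read_ca_trace`) exists for real
evaluation.

A known structural property of the benchmark: with q = 7 the first and
last six residues of a chain have no window and are filled by rule 5,
so on short synthetic chains (~30–50 residues) chain-end fill, not the
classifier, dominates the residual error of both subspace models.

## Numerical choices

* Angles clip cosines to [−1, 1] before arccos; torsion output range
  (−180°, 180°].
* Principal-angle cosines clip to [0, 1]; bases are defensively
  re-orthonormalized by QR.
* Standardization floors tiny scales at 1 to keep constant features
  inert.
* Rank-1 floors: every class subspace and local subspace has rank ≥ 1
  regardless of the estimate.
* Ties in the class argmin prefer L, then E, then H.
* Empty neighbor list → all-zero valid N block (see above).
* Altloc resolution: blank or 'A', else highest occupancy, first on
  ties; HELIX beats SHEET on overlapping truth records; any HELIX
  class counts as H.

## Limitations

* Truth is whatever the PDB HELIX/SHEET records say — no DSSP/STRIDE
  harmonization, no 8-state alphabet.
* Chains shorter than 13 residues produce no windows at all; the
  subspace models then return only filled labels and the evaluation
  counts them as ordinary (usually wrong) predictions.
* mmCIF, insertion codes and multi-model ensembles are out of scope
  (first model only; chains with insertion codes are rejected unless
  lenient mode skips them).
* The ensemble's paper-scale configuration (600 K balanced residues)
  is supported but not exercised by the offline tests.
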