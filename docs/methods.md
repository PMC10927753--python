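# Methods

This note records the models and conventions behind each analysis stage,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Ensemble verdict-rate classifier

Each variant carries exactly 15 verdicts, one per predictor, each
benign (B), pathogenic (P) or missing (NA). The classifier computes the
benign rate r = B/(B+P); NA verdicts drop out of both numerator and
denominator, and a variant with all 15 verdicts missing has no defined
rate (an error, not a silent 0). The mode verdict is **P** iff r ≤ t with
t ∈ {0.40 high-coverage, 0.24 intermediate, 0.08 low-FPR}, else **VUS**.

Conventions that the bundled verdict table forces:

- *Tie rule.* A rate exactly at the threshold calls P, and the comparison
  uses the unrounded rate: a 1/15 rate (0.0667) must remain pathogenic at
  the 0.08 threshold even though it displays as 0.07.
- *Display rounding* is half-up to two decimals (0.0667 → 0.07,
  0.1333 → 0.13); classification never uses the rounded value. All
  user-facing rounding in the package is half-up (`utils.round_half_up`),
  because Python's banker's rounding would print 0.135 → 0.13-style
  surprises in exactly the values users check by hand.
- *Verdicts are inputs, not derived from scores.* The bundled table shows
  the same numeric score issued as benign by one predictor and pathogenic
  by another (each predictor has its own optimized cutoff, which this
  package deliberately does not re-derive), so scores are carried as
  metadata only.
- The classifier's codomain is {P, VUS}; no benign-side threshold is
  defined, so it never emits "benign".

The reported false-positive rates of the stricter modes (11.5 % low-FPR,
20 % intermediate) are stored as metadata and never used in computation.

## Alignment conservation

Frequencies at a column are computed over the 20 canonical residues;
gaps — including ambiguity codes B/Z/X, which are treated as gaps — are
excluded from frequencies but reported as a gap fraction, and columns with
gap fraction > 0.5 are flagged unreliable. Information content is
IC = log₂20 − H bits, bounded by [0, 4.322]. An optional small-sample
correction subtracts (20−1)/(2 ln2 · n). The logo matrix export offers
both bit scaling (frequency × IC, the usual logo letter height) and
probability scaling, since either convention is common.

The categorical label of a mutated position uses the reference residue's
frequency f and rank:

- **high**: rank 1 and f ≥ 0.80 (the position is dominated by the
  reference residue);
- **moderate**: rank ≤ 3 and f ≥ 0.05 (e.g. the reference residue is the
  second most prevalent behind a dominating other residue);
- **low**: otherwise.

The 0.80 / rank ≤ 3 / 0.05 cutoffs are calibration choices that reproduce
the qualitative "highly conserved" vs "moderately conserved" reading of a
logo on synthetic analogues; they are configurable because no published
cutoff exists for these labels.

## Structure auditing

All detectors operate on static coordinates in Å. Geometric criteria
follow common structural-biology practice, are explicit keyword arguments,
and default to:

| interaction | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor N/O heavy-atom distance | ≤ 3.5 Å |
| (with explicit H) | D–H…A angle | ≥ 120° |
| salt bridge | min charged-group N–O distance | ≤ 4.0 Å |
| cation/π | cation to ring centroid | ≤ 6.0 Å |
| | angle off ring normal | ≤ 60° |
| burial | Shrake–Rupley probe, sphere points | 1.4 Å, 192 |
| clash screen | neighbourhood radius / density | 5 Å / 30 heavy atoms |

Crystal structures usually lack hydrogens, so the hydrogen-bond test is
distance-only by default; the angle test activates only when explicit
hydrogens are present and requested. Histidine is accepted as a cation
donor for cation/π detection (toggleable), and as an aromatic ring.
Tryptophan's six-membered ring is used as its aromatic plane. Ring normals
come from an SVD plane fit, and the normal angle is folded to [0°, 90°] so
contacts on either ring face are equivalent.

Relative side-chain exposure is side-chain SASA divided by a tabulated
Gly-X-Gly maximum (Miller-style reference values), clamped to [0, 1];
labels: exposed ≥ 0.25, buried < 0.10, intermediate between. Glycine uses
its α-carbon as "side chain" with a small reference area. The substitution
clash screen compares tabulated mean residue volumes (Zamyatnin) and flags
"potential clash" only when the replacement is bulkier **and** the
side-chain centroid sits in a crowded neighbourhood; the report always
carries the raw numbers and never a pathogenicity verdict.

Residue numbering follows the source file's author numbering; nothing is
renumbered. Altloc records resolve to the highest occupancy (first on
ties).

## Trajectory stability

Coordinates are Å internally; every reported length is nm. Superposition
is closed-form least-squares (Kabsch, SVD with reflection guard); the
pairwise 2D-RMSD matrix superposes every frame pair independently and is
computed with a batched SVD over all pairs, so a 200×200 matrix on a
~100-atom selection costs well under a second.

- *Native contacts*: heavy-atom pairs < 4.5 Å in frame 0 between residues
  ≥ 4 apart in sequence (any separation across chains); a contact is
  retained in a frame while its distance ≤ 1.2× its reference value.
  The fraction at frame 0 is 1 by construction.
- *TM-score*: computed on the Kabsch superposition of Cα atoms with
  d₀ = 1.24(L−15)^⅓ − 1.8 — a lower bound on the full TM-score
  maximization, sufficient for its use here as a coarse fold-retention
  flag (> 0.5); undefined for L ≤ 15.
- *Secondary structure*: backbone-dihedral bins — α: φ ∈ [−100°, −30°],
  ψ ∈ [−80°, −5°]; β: φ ∈ [−180°, −40°], ψ ∈ [60°, 180°]; else coil;
  chain-terminal residues count as coil.
- *Global stability flag*: all-frame RMSD < 1.0 nm.

The local verdict chain: the selection is every residue with a heavy atom
within 1 nm of the site's heavy atoms in the reference frame (site
included); the pairwise RMSD matrix on the selection's heavy atoms is
clustered GROMOS-style (iteratively take the frame with the most
neighbours within 0.15 nm as a medoid, ties to the lowest frame index —
deterministic); the **basal cluster** is the cluster containing frame 0,
even if not the most populated, because stability is anchored to the
starting (crystal-like) conformation. The verdict is **unstable** iff at
least 50 % of the frames in the final 25 % of the trajectory lie outside
the basal cluster — "sustained departure" — so brief excursions that
return to the basal cluster remain stable. The departure frame is the
first frame of the terminal run of non-basal frames, reported in original
frame numbering when the matrix is strided.

Open parameters the underlying procedure leaves unstated — stride, cluster
cutoff, heavy-atom vs Cα selection, and whether the local superposition
uses the local selection or the whole chain — are config keys; defaults:
stride 1 (5 in the long-trajectory tests), 0.15 nm, heavy atoms, local
selection.

Dimer state: **unbound** iff the mean number of inter-chain heavy-atom
pairs < 4.5 Å over the final 25 % window drops below 10; the state
therefore depends only on the final window. Replica aggregation is
worst-case over chains (any unstable chain makes the replica unstable) and
formats "k/n (p%)" with p rounded half-up, e.g. 2/3 → "2/3 (67%)".

## Cohort and cosegregation

Prevalence is 100 × matching probands / n tested, half-up to 2 dp; ages
are summarised as half-up 1-dp means and min–max ranges. Cosegregation is
a qualitative tally, not a likelihood or Bayes-factor method — the
procedure being reproduced performs none, and inventing one would
misrepresent the evidence: **excluded** if any tested affected relative is
a non-carrier; **consistent** if at least one tested affected relative
besides the proband carries the variant and none excludes; otherwise
**uninformative**. Exclusion dominates, untested individuals never
influence the verdict, and the proband must be a tested carrier.

Two summary values previously reported for the bundled cohort are not
reproducible under these consistent rules: the pathogenic-carrier
prevalence (3/396 = 0.7576 → 0.76 %, reported as 0.75 %, consistent with
counting the 2 distinct variants rather than 3 carriers) and the VUS mean
age (340/7 = 48.6, reported 45.2, which matches only the 6 records under
age 60). `cohort.flag_discrepancies` surfaces both against the bundled
`published_summary.json`; computed values are never adjusted to match.

## Synthetic data: what it emulates, and what it does not

Every generator takes one explicit integer seed (no global RNG state) and
identical spec + seed reproduce byte-identical files. The generators are
the oracles for the parameter-recovery tests: each planted parameter is
recoverable by the corresponding analysis stage.

- *Predictor tables*: i.i.d. B/NA/P verdicts with stated probabilities;
  uniform scores as metadata. Real predictor panels are strongly
  correlated; the i.i.d. mixture tests bookkeeping, not panel behaviour.
- *Alignments*: at column j each sampled row carries the consensus residue
  with the planted probability c, else a residue uniform over the other
  19, so the consensus frequency converges to c itself; a leading target
  row carries the reference sequence (optionally divergent from the
  consensus, to emulate a moderately conserved mutation site). Real
  alignments have phylogenetic correlation and indel structure; only gap
  rate is modelled (i.i.d. per symbol).
- *Structures*: backbones are built by internal-coordinate (NeRF)
  chaining with standard bond lengths/angles — an ideal α-helix uses
  φ = −57°, ψ = −47° — and interaction probes are placed at exactly the
  requested distances/angles, far apart so each probe is the only
  detection of its kind. The toy dimer is two parallel helices with chain
  B translated perpendicular to the helix axis until the minimum
  inter-chain distance equals the requested value exactly (root-finding to
  1e-9 Å). Side chains beyond Cβ exist only on the probe residues.
- *Trajectories* are statistical stand-ins, not physics: no force field,
  no solvent, no thermostat. `noise_sigma` is the per-atom RMS
  displacement from the reference in Å (per-coordinate std σ/√3), chosen
  so that at the 1 Å noise level frame-pair RMSDs (~√2 × 0.1 nm ≈
  0.14 nm) still fall inside the 0.15 nm clustering cutoff — i.e. plain
  thermal-like jitter clusters as one basal state. `local_departure`
  rigidly displaces the residues within 10 Å of the site (inside the 1 nm
  analysis window by construction) from frame t₀ on; `dissociation`
  translates one chain at a constant Å/frame velocity.

Passing tests on these inputs therefore demonstrate that the analysis
chain recovers planted signals of the stated kind and magnitude; they say
nothing about force-field accuracy, sampling convergence, or correlated
noise in real trajectories.

## Problem sizes and budgets

The test suite runs desk-scale: 2¹⁵-pattern classifier enumeration;
500-sequence alignments for conservation recovery; 50-residue random
fixtures for the O(n²) geometry oracles; 24-residue helices with
1000-frame trajectories (stride 5 → 200×200 RMSD matrices) for the
stability-verdict properties, 20 seeds per condition. These sizes make the
statistical assertions (3 SE bands, median departure error < 5 %) sharp
while keeping the whole suite under a minute of CPU apart from the
trajectory block.

## Known limitations

- The classifier cannot audit the upstream predictor cutoffs; a
  transcription error in a verdict flag propagates directly.
- The conservation categories are calibrated labels, not statistics with
  sampling distributions.
- The clash screen is a volume/crowding proxy; it does not model rotamers,
  backbone relaxation, or ΔΔG.
- The TM-score lower bound can under-report similarity for strongly
  displaced substructures.
- Cosegregation is qualitative and treats each family independently; it
  provides supporting context, never a standalone classification.
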