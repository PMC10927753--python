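# vuscope

Computational interpretation of *CHEK2* missense variants of uncertain
significance (VUS), for clinical-genetics and structural-bioinformatics
analysts who need reproducible, auditable supporting evidence (in the ACMG
PP3 sense) rather than a black-box call.

A missense VUS in the Chk2 checkpoint kinase can be interrogated along five
independent evidence lines, and `vuscope` implements each as a separate,
composable stage:

1. **Ensemble verdict-rate classification** (`vuscope.metaclassifier`).
   Each variant carries a benign/pathogenic/missing verdict from 15
   established predictors (SIFT … CADD). The benign rate
   *r* = B/(B+P) over non-missing verdicts is compared to a mode threshold
   *t*: the call is **P** (pathogenic) iff *r* ≤ *t*, else **VUS**. Three
   operating modes trade sensitivity against false-positive rate:
   high-coverage (*t* = 0.40), intermediate (0.24) and low-FPR (0.08).
2. **Alignment conservation** (`vuscope.conservation`). Per-column
   information content IC = log₂20 − H, H = −Σ fₐ log₂ fₐ over the residue
   frequencies of a multiple sequence alignment; the mutated position is
   labelled high / moderate / low from the reference residue's frequency
   and rank (the labels one reads off a sequence logo).
3. **Static structure auditing** (`vuscope.structgeo`). Hydrogen bonds
   (donor–acceptor N/O ≤ 3.5 Å), salt bridges (charged-group N–O ≤ 4.0 Å),
   cation/π contacts (cation ≤ 6 Å of an aromatic ring centroid, ≤ 60° off
   the ring normal), Shrake–Rupley relative side-chain exposure,
   inter-monomer distances, and a steric screen for proposed substitutions
   (side-chain volume change in a crowded neighbourhood).
4. **Trajectory stability analysis** (`vuscope.trajstab`). Global per-frame
   metrics (RMSD, Rg, SASA, native-contact fraction, TM-score, H-bond
   counts, secondary structure), per-residue RMSF, and the local verdict
   chain: residues within 1 nm of the mutation site → pairwise 2D-RMSD
   matrix → GROMOS neighbour-counting clustering (0.15 nm cutoff) →
   stable/unstable from basal-cluster occupancy of the final trajectory
   window, plus dimer bound/unbound from inter-chain contacts and
   "k/n (p%)" replica summaries.
5. **Cohort and cosegregation statistics** (`vuscope.cohort`). Prevalence
   and descriptive summaries of proband tables, and a qualitative
   per-family cosegregation verdict (consistent / excluded /
   uninformative).

`vuscope.synth` generates every input the stages consume — verdict tables
with controlled mixtures, alignments with planted per-column conservation,
toy structures with interactions at exact geometry, and trajectories that
are stable, locally departing, or dimer-dissociating — so the whole
pipeline runs and is tested without downloads. `vuscope.pipeline` merges
the stages into per-variant evidence dossiers; evidence lines are reported
side by side and never auto-combined into a single pathogenicity call.

## Worked example

The bundled `table2.tsv` transcribes the per-predictor verdicts for seven
Chk2 VUS found in a breast-cancer cohort:

```console
$ vuscope classify --table src/vuscope/data/table2.tsv
Q100H   0.47    VUS/VUS/VUS     (B=7 P=8 NA=0)
T168I   0.00    P/P/P           (B=0 P=15 NA=0)
H282D   0.07    P/P/P           (B=1 P=14 NA=0)
H345Y   0.07    P/P/P           (B=1 P=14 NA=0)
A392V   0.07    P/P/P           (B=1 P=13 NA=1)
P471L   0.13    P/P/VUS         (B=2 P=13 NA=0)
R474C   0.00    P/P/P           (B=0 P=15 NA=0)
```

Reading one line: P471L drew 2 benign verdicts from 15 predictors, so its
benign rate is 2/15 = 0.13; that is at or below the high-coverage (0.40)
and intermediate (0.24) thresholds — pathogenic under both — but above the
strict low-FPR threshold (0.08), where it stays a VUS. H282D's unrounded
rate 1/15 = 0.0667 sits below 0.08, so it is pathogenic even in low-FPR
mode (classification always uses the unrounded rate; 0.07 is display
rounding). A392V's MutPred verdict is missing, so its denominator is 14.

The trajectory chain recovers planted instabilities from synthetic
trajectories. A 1000-frame trajectory of an ideal helix whose neighbourhood
of residue 12 is rigidly displaced by 6 Å from frame 500 on:

```python
from vuscope import synth, trajstab
helix = synth.gen_structure("ideal_helix", {"length": 24})
traj = synth.gen_trajectory(helix, "local_departure", 1000, 0.5,
    {"site": ("A", 12), "t0": 500, "displacement": 6.0}, seed=7)
v = trajstab.analyze_replica(traj, ("A", 12), stride=5)[0]
print(v.verdict, v.departure_frame, v.final_outside_fraction)
# unstable 500 1.0
```

The verdict is "unstable" because 100 % of the frames in the final quarter
of the trajectory lie outside the basal cluster (the cluster containing the
starting conformation), and the estimated departure frame recovers the
planted switch point exactly.

Cohort statistics on the bundled proband table (`table1.tsv`, 10 carriers
found among 396 tested patients):

```console
$ vuscope cohort --table src/vuscope/data/table1.tsv --n-tested 396 \
    --pedigree src/vuscope/data/pedigree8.json
```

reports a VUS prevalence of 1.77 % (7/396), a pathogenic/likely-pathogenic
prevalence of 0.76 % (3/396), mean ages per class, and per-family
cosegregation verdicts (family 8: "consistent" — the affected sister also
carries the variant). Where a previously reported summary value cannot be
reproduced under consistent rounding rules, the computed value is reported
and the disagreement flagged (see `docs/methods.md`), never silently
matched.

A full multi-stage run is driven by a YAML config:

```bash
vuscope run --config run.yaml   # writes dossiers/*.json, dossiers.tsv, manifest.json
```

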