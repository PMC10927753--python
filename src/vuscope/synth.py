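"""Synthetic inputs with known, planted structure for every pipeline stage.

Each generator takes an explicit integer seed (no global RNG state) and
plants parameters that the corresponding analysis stage must recover:
predictor tables with controlled benign/pathogenic/missing mixtures,
alignments with per-column conservation levels, toy coordinate sets with
interactions at exact distances/angles, and trajectories that are stable
noise, depart locally after a programmed frame, or dissociate a dimer by
rigid-body separation.  The generators are therefore the oracles for the
parameter-recovery tests; they are statistical stand-ins, not physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from . import cohort as cohort_mod
from . import conservation as cons_mod
from .metaclassifier import PREDICTORS, PredictorEntry, VariantScoreSet
from .structgeo import Structure
from .trajstab import Trajectory
from .utils import place_atom

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

TOPOLOGIES = ("ideal_helix", "beta_hairpin", "planted_interactions", "toy_dimer")
TRAJECTORY_MODES = ("stable", "local_departure", "dissociation")


@dataclass(frozen=True)
class SynthSpec:
    """Declarative description of one synthetic artifact."""
    seed: int
    kind: str          # predictor_table | msa | structure | trajectory | pedigree
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Predictor tables

def gen_predictor_table(n_variants: int, benign_prob: float, na_prob: float,
                        seed: int) -> list[VariantScoreSet]:
    """Variants with 15 i.i.d. verdicts: B w.p. ``benign_prob``, NA w.p.
    ``na_prob``, else P; uniform [0,1] scores as metadata."""
    if not (0 <= benign_prob <= 1 and 0 <= na_prob <= 1
            and benign_prob + na_prob <= 1):
        raise ValueError("benign_prob and na_prob must be probabilities "
                         "summing to <= 1")
    rng = np.random.default_rng(seed)
    out = []
    for v in range(n_variants):
        u = rng.random(len(PREDICTORS))
        scores = rng.random(len(PREDICTORS))
        entries = []
        for k, p in enumerate(PREDICTORS):
            if u[k] < benign_prob:
                verdict = "B"
            elif u[k] < benign_prob + na_prob:
                verdict = "NA"
            else:
                verdict = "P"
            score = None if verdict == "NA" else float(round(scores[k], 4))
            entries.append(PredictorEntry(p, verdict, score))
        out.append(VariantScoreSet(
            variant_id=f"SYN{v + 1:03d}", cdna=f"c.{3 * v + 1}A>G",
            entries=tuple(entries)))
    return out


def write_predictor_table(table: Sequence[VariantScoreSet],
                          path: str | Path) -> None:
    """Write the TSV dialect consumed by the meta-classifier parser."""
    header = ["variant_id", "cdna"]
    for p in PREDICTORS:
        header += [f"{p}_verdict", f"{p}_score"]
    lines = ["\t".join(header)]
    for vs in table:
        cells = [vs.variant_id, vs.cdna]
        for e in vs.entries:
            cells += [e.verdict, "" if e.score is None else f"{e.score:.4f}"]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments

def gen_msa(n_seqs: int, length: int, conservation, consensus: str,
            seed: int, gap_prob: float = 0.0,
            target_seq: str | None = None) -> cons_mod.Alignment:
    """Alignment of ``n_seqs`` sampled rows plus a leading target row.

    At column j a sampled sequence carries ``consensus[j]`` with probability
    ``conservation[j]`` and otherwise a residue uniform over the 19 others;
    a symbol is gapped with probability ``gap_prob``.  Row 0 is the
    reference (target) sequence — the consensus itself unless
    ``target_seq`` plants a reference that differs from the consensus at
    some positions (a moderately conserved mutation site).
    """
    conservation = np.broadcast_to(np.asarray(conservation, float), (length,))
    if len(consensus) != length:
        raise ValueError(f"consensus length {len(consensus)} != length {length}")
    if not ((conservation >= 0) & (conservation <= 1)).all():
        raise ValueError("conservation values must be probabilities")
    consensus = consensus.upper()
    if any(c not in AA20 for c in consensus):
        raise ValueError("consensus must use the 20 canonical residues")
    if target_seq is not None and len(target_seq) != length:
        raise ValueError("target_seq length mismatch")
    rng = np.random.default_rng(seed)
    others = {c: [a for a in AA20 if a != c] for c in set(consensus)}
    seqs = [consensus if target_seq is None else target_seq.upper()]
    ids = ["target"]
    for s in range(n_seqs):
        row = []
        for j in range(length):
            if gap_prob > 0 and rng.random() < gap_prob:
                row.append("-")
            elif rng.random() < conservation[j]:
                row.append(consensus[j])
            else:
                pool = others[consensus[j]]
                row.append(pool[rng.integers(len(pool))])
        seqs.append("".join(row))
        ids.append(f"seq{s + 1:04d}")
    return cons_mod.Alignment(sequences=seqs, ids=ids, target_index=0)


# ---------------------------------------------------------------------------
# Structures

_BOND = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
         "CA_CB": 1.521}
_ANGLE = {"N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7,
          "CA_C_O": 120.5, "N_CA_CB": 110.6}


def _build_backbone(dihedrals: Sequence[tuple[float, float]],
                    chain: str = "A", start_res: int = 1,
                    res_name: str = "ALA", with_cb: bool = True,
                    offset=(0.0, 0.0, 0.0)) -> dict:
    """Peptide backbone (N, CA, C, O[, CB]) from per-residue (phi, psi),
    omega fixed at 180, standard bond lengths/angles."""
    n_res = len(dihedrals)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["N_CA"], 0.0, 0.0])]
    ang = np.radians(_ANGLE["N_CA_C"])
    C = [CA[0] + _BOND["CA_C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        phi_i, _ = dihedrals[i]
        _, psi_prev = dihedrals[i - 1]
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1],
                            _BOND["C_N"], _ANGLE["CA_C_N"], psi_prev))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i],
                             _BOND["N_CA"], _ANGLE["C_N_CA"], 180.0))
        C.append(place_atom(C[i - 1], N[i], CA[i],
                            _BOND["CA_C"], _ANGLE["N_CA_C"], phi_i))
    atoms = []  # (res_id, atom_name, coord)
    for i in range(n_res):
        atoms.append((start_res + i, "N", N[i]))
        atoms.append((start_res + i, "CA", CA[i]))
        atoms.append((start_res + i, "C", C[i]))
        psi_i = dihedrals[i][1]
        atoms.append((start_res + i, "O", place_atom(
            N[i], CA[i], C[i], _BOND["C_O"], _ANGLE["CA_C_O"], psi_i + 180.0)))
        if with_cb and res_name != "GLY":
            atoms.append((start_res + i, "CB", place_atom(
                N[i], C[i], CA[i], _BOND["CA_CB"], _ANGLE["N_CA_CB"], 122.6)))
    off = np.asarray(offset, float)
    return {
        "chain_id": [chain] * len(atoms),
        "res_id": [a[0] for a in atoms],
        "res_name": [res_name] * len(atoms),
        "atom_name": [a[1] for a in atoms],
        "coord": [a[2] + off for a in atoms],
    }


def _merge(blocks: list[dict]) -> Structure:
    chain_id, res_id, res_name, atom_name, coord = [], [], [], [], []
    for b in blocks:
        chain_id += b["chain_id"]
        res_id += b["res_id"]
        res_name += b["res_name"]
        atom_name += b["atom_name"]
        coord += [np.asarray(c, float) for c in b["coord"]]
    element = [("H" if a.startswith("H") else a[0]) for a in atom_name]
    return Structure(
        chain_id=np.array(chain_id, dtype=object),
        res_id=np.array(res_id, dtype=int),
        res_name=np.array(res_name, dtype=object),
        atom_name=np.array(atom_name, dtype=object),
        element=np.array(element, dtype=object),
        coord=np.array(coord, dtype=float))


def _residue_block(chain, res_id, res_name, named_coords: dict,
                   offset=(0.0, 0.0, 0.0)) -> dict:
    off = np.asarray(offset, float)
    names = list(named_coords)
    return {
        "chain_id": [chain] * len(names),
        "res_id": [res_id] * len(names),
        "res_name": [res_name] * len(names),
        "atom_name": names,
        "coord": [np.asarray(named_coords[n], float) + off for n in names],
    }


def _ideal_helix(params: dict) -> Structure:
    n = int(params.get("length", 20))
    chain = params.get("chain", "A")
    phi = float(params.get("phi", -57.0))
    psi = float(params.get("psi", -47.0))
    return _merge([_build_backbone([(phi, psi)] * n, chain=chain)])


def _beta_hairpin(params: dict) -> Structure:
    n = int(params.get("strand_length", 6))
    strand = [(-120.0, 130.0)] * n
    turn = [(-60.0, -30.0), (-90.0, 0.0)]
    return _merge([_build_backbone(strand + turn + strand,
                                   chain=params.get("chain", "A"))])


def _hbond_block(distance: float, offset) -> list[dict]:
    ser = _residue_block("A", 1, "SER", {
        "OG": (0.0, 0.0, 0.0), "CB": (-1.42, 0.0, 0.0),
        "CA": (-2.15, 1.25, 0.0), "N": (-3.58, 1.05, 0.0),
        "C": (-1.95, 2.45, 0.9), "O": (-2.45, 3.55, 0.9)}, offset)
    gly = _residue_block("A", 2, "GLY", {
        "O": (distance, 0.0, 0.0), "C": (distance + 1.05, 0.65, 0.0),
        "CA": (distance + 2.45, 0.15, 0.0), "N": (distance + 3.5, 1.05, 0.0)},
        offset)
    return [ser, gly]


def _salt_bridge_block(distance: float, interchain: bool, offset) -> list[dict]:
    arg = _residue_block("A", 3, "ARG", {
        "NH1": (0.0, 0.0, 0.0), "CZ": (-1.33, 0.0, 0.0),
        "NH2": (-2.0, -1.15, 0.0), "NE": (-2.0, 1.15, 0.0),
        "CD": (-3.45, 1.2, 0.0), "CG": (-4.15, 2.4, 0.0),
        "CB": (-5.65, 2.35, 0.0), "CA": (-6.35, 3.6, 0.2),
        "N": (-7.8, 3.5, 0.2), "C": (-5.95, 4.95, 0.6),
        "O": (-6.75, 5.85, 0.8)}, offset)
    glu = _residue_block("B" if interchain else "A", 4, "GLU", {
        "OE1": (distance, 0.0, 0.0), "CD": (distance + 0.8, 1.0, 0.0),
        "OE2": (distance + 2.05, 0.85, 0.0), "CG": (distance + 0.3, 2.4, 0.0),
        "CB": (distance + 1.3, 3.55, 0.0), "CA": (distance + 0.75, 4.95, 0.2),
        "N": (distance + 1.7, 6.05, 0.2), "C": (distance - 0.65, 5.25, 0.6),
        "O": (distance - 1.15, 6.35, 0.8)}, offset)
    return [arg, glu]


def _cation_pi_block(distance: float, angle_deg: float, offset) -> list[dict]:
    ring = {}
    for name, theta in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
                           (0, 60, 120, 180, 240, 300)):
        t = np.radians(theta)
        ring[name] = (1.39 * np.cos(t), 1.39 * np.sin(t), 0.0)
    ring.update({"CB": (2.92, 0.0, 0.0), "CA": (3.65, 1.25, 0.0),
                 "N": (5.08, 1.05, 0.0), "C": (3.45, 2.65, 0.9),
                 "O": (3.95, 3.75, 0.9)})
    phe = _residue_block("A", 5, "PHE", ring, offset)
    t = np.radians(angle_deg)
    nz = np.array([distance * np.sin(t), 0.0, distance * np.cos(t)])
    step = np.array([0.35, 0.9, 1.1])
    lys_atoms = {"NZ": nz}
    for k, name in enumerate(("CE", "CD", "CG", "CB", "CA", "N"), start=1):
        lys_atoms[name] = nz + k * step
    lys_atoms["C"] = nz + 5 * step + np.array([1.4, 0.4, 0.4])
    lys_atoms["O"] = nz + 5 * step + np.array([2.0, 1.2, 0.8])
    lys = _residue_block("A", 6, "LYS", lys_atoms, offset)
    return [phe, lys]


def _his_residue(chain, res_id, offset) -> dict:
    ring = {}
    for name, theta in zip(("CG", "ND1", "CE1", "NE2", "CD2"),
                           (90, 162, 234, 306, 18)):
        t = np.radians(theta)
        ring[name] = (1.32 * np.cos(t), 1.32 * np.sin(t), 0.0)
    ring.update({"CB": (0.0, 2.85, 0.0), "CA": (1.1, 3.9, 0.0),
                 "N": (0.75, 5.3, 0.0), "C": (2.5, 3.6, 0.4),
                 "O": (3.4, 4.45, 0.4)})
    return _residue_block(chain, res_id, "HIS", ring, offset)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return radius * np.stack([np.sin(phi) * np.cos(theta),
                              np.sin(phi) * np.sin(theta),
                              np.cos(phi)], axis=1)


def _cage_block(center, chain, start_res, radii=(4.0, 6.0),
                counts=(42, 72)) -> list[dict]:
    """Shells of occluding pseudo-atoms (glycine CA) around ``center``."""
    blocks = []
    rid = start_res
    center = np.asarray(center, float)
    for radius, count in zip(radii, counts):
        for p in _fibonacci_sphere(count, radius):
            blocks.append(_residue_block(chain, rid, "GLY",
                                         {"CA": center + p}))
            rid += 1
    return blocks


def _planted_interactions(params: dict) -> Structure:
    """Probe groups at exactly specified geometry, far apart from each other.

    Recognised params (only requested probes are built):
    ``hbond_distance``, ``salt_bridge_distance`` (+ ``salt_bridge_interchain``),
    ``cation_pi_distance`` + ``cation_pi_angle_deg``, ``buried_his``,
    ``exposed_his``.  With no params, all probes are planted at defaults.
    """
    p = dict(params)
    if not p:
        p = {"hbond_distance": 2.7, "salt_bridge_distance": 3.5,
             "cation_pi_distance": 4.0, "cation_pi_angle_deg": 0.0,
             "buried_his": True, "exposed_his": True}
    blocks: list[dict] = []
    if "hbond_distance" in p:
        blocks += _hbond_block(float(p["hbond_distance"]), (0.0, 0.0, 0.0))
    if "salt_bridge_distance" in p:
        blocks += _salt_bridge_block(float(p["salt_bridge_distance"]),
                                     bool(p.get("salt_bridge_interchain", False)),
                                     (60.0, 0.0, 0.0))
    if "cation_pi_distance" in p:
        blocks += _cation_pi_block(float(p["cation_pi_distance"]),
                                   float(p.get("cation_pi_angle_deg", 0.0)),
                                   (120.0, 0.0, 0.0))
    if p.get("buried_his"):
        his = _his_residue("A", 7, (180.0, 0.0, 0.0))
        side = np.array([c for n, c in zip(his["atom_name"], his["coord"])
                         if n not in ("N", "CA", "C", "O")])
        blocks.append(his)
        blocks += _cage_block(side.mean(axis=0), "A", 100)
    if p.get("exposed_his"):
        blocks.append(_his_residue("A", 8, (260.0, 0.0, 0.0)))
    if not blocks:
        raise ValueError(f"no recognised probe parameters in {sorted(p)}")
    return _merge(blocks)


def _toy_dimer(params: dict) -> Structure:
    """Two parallel helices, chain B translated so that the minimum
    inter-chain heavy-atom distance equals ``min_distance`` exactly."""
    n = int(params.get("length", 12))
    target = float(params.get("min_distance", 4.0))
    a = _build_backbone([(-57.0, -47.0)] * n, chain="A")
    b = _build_backbone([(-57.0, -47.0)] * n, chain="B")
    coords_a = np.array(a["coord"])
    coords_b0 = np.array(b["coord"])
    # translate B perpendicular to the helix principal axis so the two
    # helices touch along their whole length, not at a single point
    centered = coords_a - coords_a.mean(axis=0)
    axis = np.linalg.svd(centered)[2][0]
    direction = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(direction) < 1e-6:
        direction = np.cross(axis, [0.0, 1.0, 0.0])
    direction /= np.linalg.norm(direction)

    def min_dist(delta: float) -> float:
        shifted = coords_b0 + delta * direction
        d = np.linalg.norm(coords_a[:, None, :] - shifted[None, :, :], axis=2)
        return float(d.min())

    lo, hi = 0.0, 200.0
    while min_dist(hi) < target:
        hi *= 2
    delta = brentq(lambda x: min_dist(x) - target, lo, hi, xtol=1e-9)
    b["coord"] = [c + delta * direction for c in coords_b0]
    b["res_id"] = [r for r in b["res_id"]]
    return _merge([a, b])


def gen_structure(topology: str, params: dict | None = None) -> Structure:
    """Build a toy coordinate set; see the per-topology helpers for params."""
    params = params or {}
    builders = {"ideal_helix": _ideal_helix, "beta_hairpin": _beta_hairpin,
                "planted_interactions": _planted_interactions,
                "toy_dimer": _toy_dimer}
    if topology not in builders:
        raise ValueError(f"unknown topology {topology!r}; "
                         f"expected one of {TOPOLOGIES}")
    return builders[topology](params)


# ---------------------------------------------------------------------------
# Trajectories

def gen_trajectory(reference: Structure, mode: str, n_frames: int,
                   noise_sigma: float, params: dict | None = None,
                   seed: int = 0, replica_id: str = "r1") -> Trajectory:
    """Trajectory around ``reference`` with a planted behaviour.

    stable: reference + i.i.d. Gaussian noise; ``noise_sigma`` is the RMS
    displacement of each atom from its reference position in A (each
    Cartesian component has std ``noise_sigma / sqrt(3)``), so a 1 A noise
    level yields frame-pair RMSDs of ~0.14 nm.
    local_departure: stable until frame ``t0``, then the residues within
    ``radius`` (default 10 A) of residue ``site`` are rigidly displaced by
    ``displacement`` A (plus noise).
    dissociation: chain ``chain`` translates away at ``velocity`` A/frame
    from ``t0`` on.
    """
    if mode not in TRAJECTORY_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    params = params or {}
    rng = np.random.default_rng(seed)
    base = np.repeat(reference.coord[None, :, :], n_frames, axis=0)
    if mode == "local_departure":
        site = params["site"]
        t0 = int(params["t0"])
        displacement = float(params["displacement"])
        radius = float(params.get("radius", 10.0))
        site_mask = reference.residue_mask(*site) & reference.heavy
        site_coords = reference.coord[site_mask]
        from scipy.spatial.distance import cdist
        d = cdist(reference.coord, site_coords).min(axis=1)
        moved = d <= radius
        centroid = reference.coord.mean(axis=0)
        site_centroid = site_coords.mean(axis=0)
        direction = site_centroid - centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        base[t0:, moved, :] += displacement * direction
    elif mode == "dissociation":
        chain = params["chain"]
        t0 = int(params.get("t0", 0))
        velocity = float(params["velocity"])
        mask = reference.chain_id == chain
        if not mask.any():
            raise ValueError(f"chain {chain!r} not in reference")
        shift = velocity * np.clip(np.arange(n_frames) - t0, 0, None)
        base[:, mask, 0] += shift[:, None]
    if noise_sigma > 0:
        base += rng.normal(0.0, noise_sigma / np.sqrt(3.0), size=base.shape)
    return Trajectory(reference=reference, frames=base, replica_id=replica_id)


# ---------------------------------------------------------------------------
# Pedigrees and cohorts

def gen_pedigree_and_cohort(spec: dict, seed: int = 0
                            ) -> tuple[cohort_mod.Pedigree,
                                       list[cohort_mod.CohortRecord]]:
    """Build a pedigree (and optional cohort rows) from a declarative map.

    ``spec["individuals"]`` lists founders and offspring with carrier /
    affection status; statuses are taken verbatim (no transmission
    simulation) unless ``spec["random_transmission"]`` is set, in which case
    untyped children of carriers receive a 50% Mendelian draw.
    """
    individuals = [cohort_mod.Individual(
        id=d["id"], sex=d.get("sex", "U"), father=d.get("father"),
        mother=d.get("mother"), affected=bool(d.get("affected", False)),
        cancer_type=d.get("cancer_type"), age_dx=d.get("age_dx"),
        tested=bool(d.get("tested", False)), carrier=d.get("carrier"),
    ) for d in spec["individuals"]]
    ped = cohort_mod.Pedigree(
        family_id=str(spec.get("family_id", "SYN")),
        individuals=individuals, proband=spec["proband"],
        variant=spec.get("variant"))
    if spec.get("random_transmission"):
        rng = np.random.default_rng(seed)
        carriers = {i.id for i in ped.individuals if i.carrier}
        updated = []
        for ind in ped.individuals:
            if ind.carrier is None and (ind.father in carriers
                                        or ind.mother in carriers):
                from dataclasses import replace as _rep
                ind = _rep(ind, carrier=bool(rng.random() < 0.5))
            updated.append(ind)
        ped = cohort_mod.Pedigree(ped.family_id, updated, ped.proband,
                                  ped.variant)
    records = [cohort_mod.CohortRecord(**row) for row in spec.get("cohort", [])]
    return ped, records


def write_pedigree(ped: cohort_mod.Pedigree, path: str | Path) -> None:
    data = {
        "family_id": ped.family_id, "variant": ped.variant,
        "proband": ped.proband,
        "individuals": [{
            "id": i.id, "sex": i.sex, "father": i.father, "mother": i.mother,
            "affected": i.affected, "cancer_type": i.cancer_type,
            "age_dx": i.age_dx, "tested": i.tested, "carrier": i.carrier,
        } for i in ped.individuals],
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Dispatch

def generate(spec: SynthSpec):
    """Build the artifact a :class:`SynthSpec` describes (in memory)."""
    p = dict(spec.params)
    if spec.kind == "predictor_table":
        return gen_predictor_table(
            n_variants=p.get("n_variants", 10),
            benign_prob=p.get("benign_prob", 0.3),
            na_prob=p.get("na_prob", 0.0), seed=spec.seed)
    if spec.kind == "msa":
        return gen_msa(n_seqs=p.get("n_seqs", 500),
                       length=p.get("length", 30),
                       conservation=p.get("conservation", 0.9),
                       consensus=p.get("consensus", "A" * p.get("length", 30)),
                       seed=spec.seed, gap_prob=p.get("gap_prob", 0.0))
    if spec.kind == "structure":
        return gen_structure(p.pop("topology"), p)
    if spec.kind == "trajectory":
        reference = p.pop("reference")
        return gen_trajectory(reference, p.pop("mode"),
                              p.pop("n_frames"), p.pop("noise_sigma", 0.5),
                              params=p, seed=spec.seed)
    if spec.kind in ("pedigree", "cohort"):
        return gen_pedigree_and_cohort(p, seed=spec.seed)
    raise ValueError(f"unknown kind {spec.kind!r}")
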