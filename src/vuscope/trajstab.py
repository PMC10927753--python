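"""Trajectory stability analysis around a mutation site.

Implements the analysis chain used to read out local conformational
stability from a trajectory: global per-frame metrics (RMSD, radius of
gyration, SASA, native-contact fraction, TM-score, hydrogen-bond counts,
secondary-structure fractions), per-residue RMSF, selection of the residues
within 1 nm of the mutation site, the pairwise 2D-RMSD matrix over frames on
that local selection, GROMOS-style neighbour-counting clustering of the
matrix, a stable/unstable verdict from occupancy of the basal cluster (the
cluster containing the starting frame) in the final trajectory window,
dimer bound/unbound state from inter-chain contacts, and aggregation over
replicas into the "k/n (p%)" summaries.

Coordinates are Angstrom internally; every reported length is nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import structgeo
from .structgeo import Structure, NotApplicableError
from .utils import dihedral, round_half_up

A_PER_NM = 10.0


class TrajectoryInputError(ValueError):
    pass


class DegenerateSelectionError(ValueError):
    pass


@dataclass
class Trajectory:
    """Frame-indexed coordinates congruent with a reference structure."""

    reference: Structure
    frames: np.ndarray                 # (n_frames, n_atoms, 3) Angstrom
    replica_id: str = "r1"
    temperature_label: Optional[str] = None
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryInputError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 2:
            raise TrajectoryInputError("need at least 2 frames")
        if self.frames.shape[1] != self.reference.n_atoms:
            raise TrajectoryInputError(
                f"atom count mismatch: frames {self.frames.shape[1]} vs "
                f"reference {self.reference.n_atoms}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def chain_ids(self) -> list[str]:
        seen = dict.fromkeys(self.reference.chain_id.tolist())
        return list(seen)


def load_trajectory(path: str | Path, reference_path: str | Path,
                    replica_id: str = "r1") -> Trajectory:
    """Load a multi-model PDB trajectory against a reference PDB."""
    ref = structgeo.parse_pdb(reference_path)
    traj_struct = structgeo.parse_pdb(path)
    frames = traj_struct.models
    if frames is None:
        frames = [traj_struct.coord]
    frames = np.stack(frames)
    if frames.shape[1] != ref.n_atoms:
        raise TrajectoryInputError(
            f"atom count mismatch: trajectory {frames.shape[1]} vs "
            f"reference {ref.n_atoms}")
    mismatch = (traj_struct.atom_name != ref.atom_name)
    if mismatch.any():
        raise TrajectoryInputError("atom identity mismatch with reference")
    return Trajectory(reference=ref, frames=frames, replica_id=replica_id)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as a multi-model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    arr = traj.reference.to_biotite()
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# Superposition

def _kabsch(mobile: np.ndarray, reference: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation, translation and RMSD (Angstrom) mapping mobile onto
    reference in the least-squares sense."""
    mc, rc = mobile.mean(0), reference.mean(0)
    a, b = mobile - mc, reference - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = (u @ diag @ vt).T
    moved = a @ rot.T
    rmsd = float(np.sqrt(((moved - b) ** 2).sum() / len(b)))
    return rot, rc - rot @ mc, rmsd


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None
              ) -> tuple[np.ndarray, float]:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    ``selection`` (atom index array) restricts the fit; the transform is
    applied to all atoms.  Returns (rotated coordinates, RMSD in nm over the
    selection).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise DegenerateSelectionError("need >= 3 atoms to superpose")
    pts = mobile[sel] - mobile[sel].mean(0)
    if np.linalg.matrix_rank(pts, tol=1e-8) < 2:
        raise DegenerateSelectionError("selection is collinear")
    rot, trans, rmsd = _kabsch(mobile[sel], reference[sel])
    return mobile @ rot.T + trans, rmsd / A_PER_NM


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs least-squares RMSD (same units as input) via batched Kabsch.

    ``coords``: (F, N, 3).  Each pair is superposed independently.
    """
    x = coords - coords.mean(axis=1, keepdims=True)
    ssq = (x ** 2).sum(axis=(1, 2))
    n = x.shape[1]
    # cross-covariance for every frame pair: (F, F, 3, 3)
    h = np.einsum("iak,jal->ijkl", x, x)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    trace = s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]
    msd = (ssq[:, None] + ssq[None, :] - 2.0 * trace) / n
    out = np.sqrt(np.clip(msd, 0.0, None))
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


# ---------------------------------------------------------------------------
# Global metrics

def _native_contact_pairs(ref: Structure, cutoff: float = 4.5,
                          min_separation: int = 4
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heavy-atom contact pairs in the reference: distance < cutoff between
    residues separated by >= min_separation in sequence (or on different
    chains)."""
    heavy = np.nonzero(ref.heavy & ref.protein_mask)[0]
    coords = ref.coord[heavy]
    d = cdist(coords, coords)
    chain = ref.chain_id[heavy]
    resid = ref.res_id[heavy]
    ii, jj = np.nonzero(np.triu(d < cutoff, k=1))
    same_chain = chain[ii] == chain[jj]
    sep_ok = np.where(same_chain, np.abs(resid[ii] - resid[jj]) >= min_separation,
                      True)
    ii, jj = ii[sep_ok], jj[sep_ok]
    return heavy[ii], heavy[jj], np.linalg.norm(
        ref.coord[heavy[ii]] - ref.coord[heavy[jj]], axis=1)


def native_contact_fraction(traj: Trajectory, cutoff: float = 4.5,
                            min_separation: int = 4,
                            retention_factor: float = 1.2) -> np.ndarray:
    """Per-frame fraction of reference contacts retained.

    The reference contact set is defined on frame 0; a contact is retained
    in a frame when its distance stays within ``retention_factor`` times its
    reference distance.
    """
    ref_struct = traj.reference
    i, j, dref = _native_contact_pairs(
        Structure(ref_struct.chain_id, ref_struct.res_id, ref_struct.res_name,
                  ref_struct.atom_name, ref_struct.element, traj.frames[0],
                  ref_struct.hetero.copy()),
        cutoff, min_separation)
    if len(i) == 0:
        return np.ones(traj.n_frames)
    d = np.linalg.norm(traj.frames[:, i, :] - traj.frames[:, j, :], axis=2)
    return (d <= retention_factor * dref).mean(axis=1)


def tm_score(mobile: np.ndarray, reference: np.ndarray,
             ca_indices: np.ndarray) -> float:
    """TM-score over C-alpha positions after Kabsch superposition.

    d0 = 1.24 (L-15)^(1/3) - 1.8 with L the residue count; the score of a
    structure against itself is 1.  Undefined for L <= 15.
    """
    L = len(ca_indices)
    if L <= 15:
        raise ValueError("TM-score undefined for <= 15 residues")
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    moved, _ = superpose(mobile, reference, ca_indices)
    d = np.linalg.norm(moved[ca_indices] - reference[ca_indices], axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def _backbone_indices(ref: Structure) -> list[tuple]:
    """(chain, res_id, N_idx, CA_idx, C_idx) per protein residue, in order."""
    out = []
    for chain, rid, _ in ref.residues():
        mask = (ref.chain_id == chain) & (ref.res_id == rid) & ref.protein_mask
        names = {str(ref.atom_name[k]): k for k in np.nonzero(mask)[0]}
        if all(a in names for a in ("N", "CA", "C")):
            out.append((chain, rid, names["N"], names["CA"], names["C"]))
    return out


def ss_fractions(coords: np.ndarray, ref: Structure) -> dict:
    """Coarse secondary-structure fractions from backbone dihedral bins.

    alpha: phi in [-100,-30], psi in [-80,-5]; beta: phi in [-180,-40],
    psi in [60,180]; everything else coil.  Terminal residues (no phi or
    psi) are counted as coil.
    """
    bb = _backbone_indices(ref)
    counts = {"alpha": 0, "beta": 0, "coil": 0}
    total = 0
    for k in range(len(bb)):
        chain, rid, n_i, ca_i, c_i = bb[k]
        prev_ = bb[k - 1] if k > 0 and bb[k - 1][0] == chain else None
        next_ = bb[k + 1] if k + 1 < len(bb) and bb[k + 1][0] == chain else None
        total += 1
        if prev_ is None or next_ is None:
            counts["coil"] += 1
            continue
        phi = dihedral(coords[prev_[4]], coords[n_i], coords[ca_i], coords[c_i])
        psi = dihedral(coords[n_i], coords[ca_i], coords[c_i], coords[next_[2]])
        if -100 <= phi <= -30 and -80 <= psi <= -5:
            counts["alpha"] += 1
        elif -180 <= phi <= -40 and 60 <= psi <= 180:
            counts["beta"] += 1
        else:
            counts["coil"] += 1
    if total == 0:
        return {"alpha": 0.0, "beta": 0.0, "coil": 0.0}
    return {k: v / total for k, v in counts.items()}


def _hbond_count(s_template: Structure, coords: np.ndarray,
                 d_max: float = 3.5) -> tuple[int, int]:
    """(intra-protein, protein-water) donor/acceptor pair counts for one frame."""
    donors, acceptors = structgeo._donor_acceptor_indices(
        s_template, include_water=True)
    if len(donors) == 0 or len(acceptors) == 0:
        return 0, 0
    water = s_template.is_water
    d = cdist(coords[donors], coords[acceptors])
    close = d <= d_max
    intra = pw = 0
    for di, ai in zip(*np.nonzero(close)):
        i, j = donors[di], acceptors[ai]
        if i == j:
            continue
        if (s_template.chain_id[i] == s_template.chain_id[j]
                and s_template.res_id[i] == s_template.res_id[j]):
            continue
        wi, wj = water[i], water[j]
        if not wi and not wj:
            intra += 1
        elif wi != wj:
            pw += 1
    return intra, pw


def global_series(traj: Trajectory, sasa_point_number: int = 64,
                  rmsd_stable_cutoff_nm: float = 1.0,
                  include_sasa: bool = True,
                  include_hbonds: bool = True) -> pd.DataFrame:
    """Per-frame global metric table.

    Columns: rmsd (nm, heavy atoms vs frame 0 after Kabsch), radius_of_gyration
    (nm), sasa (nm^2), native_contact_fraction, tm_score (C-alpha; NaN when
    the chain is too short), intra_hbonds, protein_water_hbonds, alpha /
    beta / coil fractions.  The attached ``.attrs['global_stable']`` flags
    whether every frame stays below ``rmsd_stable_cutoff_nm``.
    """
    ref = traj.reference
    heavy = np.nonzero(ref.heavy & ref.protein_mask)[0]
    ca = np.nonzero((ref.atom_name == "CA") & ref.protein_mask)[0]
    ref_coords = traj.frames[0]
    ncf = native_contact_fraction(traj)
    rows = []
    use_tm = len(ca) > 15
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        _, rmsd_nm = superpose(coords, ref_coords, heavy)
        centered = coords[heavy] - coords[heavy].mean(0)
        rg_nm = float(np.sqrt((centered ** 2).sum(axis=1).mean())) / A_PER_NM
        row = {
            "frame": f, "rmsd": rmsd_nm, "radius_of_gyration": rg_nm,
            "native_contact_fraction": float(ncf[f]),
            "tm_score": tm_score(coords, ref_coords, ca) if use_tm else np.nan,
        }
        if include_sasa:
            tmp = Structure(ref.chain_id, ref.res_id, ref.res_name,
                            ref.atom_name, ref.element, coords,
                            ref.hetero.copy())
            row["sasa"] = float(
                structgeo.sasa_per_atom(tmp, point_number=sasa_point_number).sum()
            ) / A_PER_NM ** 2
        if include_hbonds:
            tmp = Structure(ref.chain_id, ref.res_id, ref.res_name,
                            ref.atom_name, ref.element, coords,
                            ref.hetero.copy())
            intra, pw = _hbond_count(tmp, coords)
            row["intra_hbonds"] = intra
            row["protein_water_hbonds"] = pw
        row.update({f"ss_{k}": v for k, v in ss_fractions(coords, ref).items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["global_stable"] = bool((df["rmsd"] < rmsd_stable_cutoff_nm).all())
    return df


def rmsf(traj: Trajectory) -> pd.DataFrame:
    """Per-residue RMSF (nm) about the mean position, after superposing every
    frame on the reference C-alpha set (heavy atoms if no CA present)."""
    if traj.n_frames < 2:
        raise TrajectoryInputError("RMSF undefined for a single frame")
    ref = traj.reference
    ca = np.nonzero((ref.atom_name == "CA") & ref.protein_mask)[0]
    if len(ca) < 3:
        ca = np.nonzero(ref.heavy & ref.protein_mask)[0]
    aligned = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        aligned[f], _ = superpose(traj.frames[f], traj.frames[0], ca)
    mean = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))  # per atom
    rows = []
    for chain, rid, rname in ref.residues():
        mask = (ref.chain_id == chain) & (ref.res_id == rid) & ref.heavy
        if not mask.any():
            continue
        rows.append({"chain": chain, "res_id": rid, "res_name": rname,
                     "rmsf": float(np.sqrt((fluct[mask] ** 2).mean())) / A_PER_NM})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Local clustering

def local_selection(reference: Structure, site: tuple[str, int],
                    radius_nm: float = 1.0) -> list[tuple[str, int]]:
    """Residues with any heavy atom within ``radius_nm`` of any heavy atom of
    ``site`` in the reference frame (the site itself included)."""
    chain, rid = site
    site_mask = reference.residue_mask(chain, rid) & reference.heavy
    radius = radius_nm * A_PER_NM
    site_coords = reference.coord[site_mask]
    out = []
    for c, r, _ in reference.residues():
        mask = (reference.chain_id == c) & (reference.res_id == r) & reference.heavy
        if not mask.any():
            continue
        if cdist(reference.coord[mask], site_coords).min() <= radius:
            out.append((c, r))
    return out


def _selection_atom_indices(ref: Structure, selection: Sequence[tuple[str, int]]
                            ) -> np.ndarray:
    keys = set(selection)
    idx = [i for i in range(ref.n_atoms)
           if (str(ref.chain_id[i]), int(ref.res_id[i])) in keys and ref.heavy[i]]
    return np.array(idx, dtype=int)


def rmsd_matrix(traj: Trajectory, selection: Sequence[tuple[str, int]],
                stride: int = 1) -> np.ndarray:
    """Pairwise 2D-RMSD matrix (nm) over (strided) frames on the heavy atoms
    of ``selection``; each frame pair is superposed independently."""
    if not selection:
        raise TrajectoryInputError("empty residue selection")
    idx = _selection_atom_indices(traj.reference, selection)
    if len(idx) < 3:
        raise TrajectoryInputError("selection has fewer than 3 heavy atoms")
    coords = traj.frames[::stride][:, idx, :] / A_PER_NM
    return _pairwise_rmsd(coords)


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # cluster id per (strided) frame
    medoids: list[int]          # frame index (strided space) per cluster id
    basal_cluster: int          # id of the cluster containing frame 0
    cutoff: float               # nm
    stride: int = 1

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)


def cluster_frames(matrix: np.ndarray, cutoff: float = 0.15,
                   stride: int = 1) -> ClusterAssignment:
    """GROMOS-style (neighbour counting) clustering of an RMSD matrix.

    Iteratively pick the unassigned frame with the most unassigned
    neighbours within ``cutoff`` (ties: lowest frame index), form a cluster
    from it and its neighbourhood, remove them, repeat.  Deterministic for a
    given matrix.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    labels = np.full(n, -1, dtype=int)
    medoids: list[int] = []
    unassigned = np.ones(n, dtype=bool)
    neighbors = m <= cutoff
    cid = 0
    while unassigned.any():
        counts = (neighbors & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        medoid = int(np.argmax(counts))   # argmax returns lowest index on ties
        members = neighbors[medoid] & unassigned
        members[medoid] = True
        labels[members] = cid
        medoids.append(medoid)
        unassigned &= ~members
        cid += 1
    return ClusterAssignment(labels=labels, medoids=medoids,
                             basal_cluster=int(labels[0]), cutoff=cutoff,
                             stride=stride)


@dataclass(frozen=True)
class StabilityVerdict:
    replica_id: str
    chain: str                         # chain id or "all"
    verdict: str                       # stable | unstable
    departure_frame: Optional[int]     # original-frame index
    final_outside_fraction: float


def stability_verdict(assignment: ClusterAssignment,
                      window_fraction: float = 0.25,
                      outside_threshold: float = 0.5,
                      replica_id: str = "r1",
                      chain: str = "all") -> StabilityVerdict:
    """Stable/unstable from basal-cluster occupancy of the final window.

    The verdict is "unstable" when at least ``outside_threshold`` of the
    frames in the last ``window_fraction`` of the trajectory lie outside the
    basal cluster — i.e. sustained departure.  Brief excursions that return
    to the basal cluster stay "stable".  ``departure_frame`` is the first
    frame of the terminal run of non-basal frames (original frame indexing),
    or None when the trajectory ends in the basal cluster.
    """
    labels = assignment.labels
    n = len(labels)
    if n < 4:
        raise TrajectoryInputError("need >= 4 frames for a stability verdict")
    window = max(1, int(np.ceil(window_fraction * n)))
    tail = labels[-window:]
    outside = float((tail != assignment.basal_cluster).mean())
    verdict = "unstable" if outside >= outside_threshold else "stable"
    departure = None
    if labels[-1] != assignment.basal_cluster:
        k = n - 1
        while k > 0 and labels[k - 1] != assignment.basal_cluster:
            k -= 1
        departure = k * assignment.stride
    return StabilityVerdict(replica_id=replica_id, chain=chain,
                            verdict=verdict, departure_frame=departure,
                            final_outside_fraction=outside)


# ---------------------------------------------------------------------------
# Dimer association

def dimer_state(traj: Trajectory, contact_cutoff: float = 4.5,
                min_contacts: int = 10, window_fraction: float = 0.25,
                chains: tuple[str, str] | None = None) -> str:
    """"bound" or "unbound" from inter-chain heavy-atom contacts.

    Unbound iff the mean number of inter-chain atom pairs closer than
    ``contact_cutoff`` over the final window drops below ``min_contacts``.
    """
    ref = traj.reference
    chain_ids = traj.chain_ids
    if len(chain_ids) < 2:
        raise NotApplicableError("dimer state needs >= 2 chains")
    ca_chain, cb_chain = chains if chains else (chain_ids[0], chain_ids[1])
    a = np.nonzero((ref.chain_id == ca_chain) & ref.heavy & ref.protein_mask)[0]
    b = np.nonzero((ref.chain_id == cb_chain) & ref.heavy & ref.protein_mask)[0]
    window = max(1, int(np.ceil(window_fraction * traj.n_frames)))
    counts = []
    for f in range(traj.n_frames - window, traj.n_frames):
        d = cdist(traj.frames[f][a], traj.frames[f][b])
        counts.append(int((d < contact_cutoff).sum()))
    return "unbound" if float(np.mean(counts)) < min_contacts else "bound"


@dataclass(frozen=True)
class ReplicaSummary:
    n_stable: int
    n_total: int
    fraction_text: str                 # e.g. "2/3 (67%)"
    dimer_states: tuple = ()


def replica_summary(verdicts: Sequence[StabilityVerdict],
                    dimer_states: Sequence[str] = ()) -> ReplicaSummary:
    """Aggregate per-chain verdicts into per-replica counts.

    A replica is unstable when any of its chains is unstable (worst case
    over chains).  ``fraction_text`` rounds the percentage half-up.
    """
    if not verdicts:
        raise ValueError("no verdicts to summarize")
    by_replica: dict[str, bool] = {}
    for v in verdicts:
        stable = v.verdict == "stable"
        by_replica[v.replica_id] = by_replica.get(v.replica_id, True) and stable
    n_total = len(by_replica)
    n_stable = sum(by_replica.values())
    pct = int(round_half_up(100.0 * n_stable / n_total, 0))
    return ReplicaSummary(
        n_stable=n_stable, n_total=n_total,
        fraction_text=f"{n_stable}/{n_total} ({pct}%)",
        dimer_states=tuple(dimer_states))


def analyze_replica(traj: Trajectory, site: tuple[str, int],
                    radius_nm: float = 1.0, cluster_cutoff: float = 0.15,
                    stride: int = 1, window_fraction: float = 0.25,
                    outside_threshold: float = 0.5,
                    per_chain: bool = True) -> list[StabilityVerdict]:
    """Full local-stability chain for one replica: selection around the site,
    2D-RMSD matrix, clustering, verdict — per chain when the site's residue
    number exists on several chains and ``per_chain`` is set."""
    ref = traj.reference
    chains = [site[0]]
    if per_chain:
        chains = [c for c in traj.chain_ids
                  if ((ref.chain_id == c) & (ref.res_id == site[1])
                      & ref.protein_mask).any()]
        if not chains:
            raise TrajectoryInputError(f"residue {site[1]} on no chain")
    out = []
    for chain in chains:
        sel = local_selection(ref, (chain, site[1]), radius_nm)
        mat = rmsd_matrix(traj, sel, stride=stride)
        assign = cluster_frames(mat, cutoff=cluster_cutoff, stride=stride)
        out.append(stability_verdict(
            assign, window_fraction, outside_threshold,
            replica_id=traj.replica_id, chain=chain))
    return out
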