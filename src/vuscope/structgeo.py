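"""Static structural auditing of missense sites on protein coordinates.

Detects the interaction geometry relevant to interpreting a substitution:
hydrogen bonds (donor/acceptor heavy-atom distance, optional D-H...A angle
when hydrogens are present), salt bridges (charged-group nitrogen-oxygen
distance), cation/pi contacts (cation to aromatic-ring-centroid distance and
ring-normal angle), residue burial (Shrake-Rupley relative side-chain
exposure), inter-monomer proximity, and a steric screen for a proposed
substitution (side-chain volume change in a crowded neighbourhood).

Cutoffs follow common structural-biology practice and are explicit keyword
arguments throughout; crystal structures usually lack hydrogens, so the
default hydrogen-bond test is distance-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

from .utils import fit_plane_normal

WATER_NAMES = {"HOH", "WAT", "H2O", "TIP3", "SOL"}

# Side-chain hydrogen-bond donors / acceptors (N and O heavy atoms only).
SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
BACKBONE_DONOR = "N"            # except proline
BACKBONE_ACCEPTORS = {"O", "OXT"}

CATION_GROUPS = {              # residue -> atoms whose centroid carries the charge
    "ARG": ("CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),   # optional, see find_cation_pi
}
ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
CATION_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}

AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),   # six-membered ring
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Maximum side-chain solvent accessibility (A^2) in an extended Gly-X-Gly
#: context (Miller et al.-style reference values; Gly uses its alpha carbon).
MAX_SIDECHAIN_SASA = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 25.0, "HIS": 151.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}

#: Mean residue volumes (A^3, Zamyatnin); differences proxy steric demand.
RESIDUE_VOLUME = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class PDBFormatError(ValueError):
    pass


class NotApplicableError(ValueError):
    """Operation requires structure features that are absent (e.g. 2 chains)."""


class ResidueTypingError(KeyError):
    pass


@dataclass
class Structure:
    """Atomic coordinates in Angstrom with per-atom annotations.

    ``models`` holds every coordinate set of a multi-model file; ``coord``
    is the first model.  Waters and other heteroatoms are retained but
    tagged via ``hetero`` / ``is_water``.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    hetero: np.ndarray = None
    models: Optional[list[np.ndarray]] = None

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.isfinite(self.coord).all():
            raise PDBFormatError("non-finite coordinates")
        if self.hetero is None:
            self.hetero = np.zeros(len(self.coord), dtype=bool)
        key = list(zip(self.chain_id.tolist(), self.res_id.tolist(),
                       self.atom_name.tolist()))
        if len(set(key)) != len(key):
            raise PDBFormatError("(chain, residue, atom name) not unique")

    # -- masks -------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.res_name, list(WATER_NAMES))

    @property
    def heavy(self) -> np.ndarray:
        return (self.element != "H") & (self.element != "D")

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.hetero & ~self.is_water

    def residue_mask(self, chain: str, res_id: int) -> np.ndarray:
        mask = (self.chain_id == chain) & (self.res_id == res_id)
        if not mask.any():
            raise KeyError(f"residue {chain}:{res_id} not in structure")
        return mask

    def residue_name(self, chain: str, res_id: int) -> str:
        return str(self.res_name[self.residue_mask(chain, res_id)][0])

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, res_id, res_name) in atom order."""
        seen, out = set(), []
        for c, r, n in zip(self.chain_id, self.res_id, self.res_name):
            if (c, r) not in seen:
                seen.add((c, r))
                out.append((str(c), int(r), str(n)))
        return out

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            chain_id=self.chain_id[mask], res_id=self.res_id[mask],
            res_name=self.res_name[mask], atom_name=self.atom_name[mask],
            element=self.element[mask], coord=self.coord[mask],
            hetero=self.hetero[mask])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        new = replace(self, coord=self.coord @ rotation.T + translation)
        if self.models is not None:
            new.models = [m @ rotation.T + translation for m in self.models]
        return new

    # -- biotite bridge ----------------------------------------------------
    def to_biotite(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_id.astype(int)
        arr.res_name = self.res_name.astype("U5")
        arr.atom_name = self.atom_name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = self.hetero
        arr.coord = self.coord.astype(np.float32)
        return arr

    @classmethod
    def from_biotite(cls, arr) -> "Structure":
        if isinstance(arr, struc.AtomArrayStack):
            models = [np.asarray(c, dtype=float) for c in arr.coord]
            first = arr[0]
        else:
            models = None
            first = arr
        return cls(
            chain_id=np.asarray(first.chain_id, dtype=object),
            res_id=np.asarray(first.res_id, dtype=int),
            res_name=np.asarray(first.res_name, dtype=object),
            atom_name=np.asarray(first.atom_name, dtype=object),
            element=np.asarray(first.element, dtype=object),
            coord=np.asarray(first.coord, dtype=float),
            hetero=np.asarray(first.hetero, dtype=bool),
            models=models)


def parse_pdb(path: str | Path) -> Structure:
    """Read a PDB file; altlocs resolved by highest occupancy (tie: first)."""
    pdbf = PDBFile.read(str(path))
    try:
        model_count = pdbf.get_model_count()
    except Exception as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if model_count == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    obj = pdbf.get_structure(model=None, altloc="occupancy")
    if obj.array_length() == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    return Structure.from_biotite(obj)


def write_pdb(s: Structure, path: str | Path) -> None:
    pdbf = PDBFile()
    pdbf.set_structure(s.to_biotite())
    pdbf.write(str(path))


@dataclass(frozen=True)
class InteractionRecord:
    kind: str                       # hbond | salt_bridge | cation_pi
    partner_a: tuple                # (chain, res_id, res_name, atom-or-group)
    partner_b: tuple
    distance: float                 # Angstrom
    angle: Optional[float] = None   # degrees
    interchain: bool = False


def _atom_label(s: Structure, i: int) -> tuple:
    return (str(s.chain_id[i]), int(s.res_id[i]), str(s.res_name[i]),
            str(s.atom_name[i]))


def _donor_acceptor_indices(s: Structure, include_water: bool = True
                            ) -> tuple[np.ndarray, np.ndarray]:
    donors, acceptors = [], []
    water = s.is_water
    for i in range(s.n_atoms):
        rn, an = str(s.res_name[i]), str(s.atom_name[i])
        if water[i]:
            if include_water and an.startswith("O"):
                donors.append(i)
                acceptors.append(i)
            continue
        if s.hetero[i]:
            continue
        if an == BACKBONE_DONOR and rn != "PRO":
            donors.append(i)
        if an in BACKBONE_ACCEPTORS:
            acceptors.append(i)
        if an in SIDECHAIN_DONORS.get(rn, ()):
            donors.append(i)
        if an in SIDECHAIN_ACCEPTORS.get(rn, ()):
            acceptors.append(i)
    return np.array(donors, dtype=int), np.array(acceptors, dtype=int)


def find_hbonds(s: Structure, d_max: float = 3.5, angle_min: float = 120.0,
                require_h: bool = False, include_water: bool = False
                ) -> list[InteractionRecord]:
    """Hydrogen bonds as donor/acceptor N,O pairs within ``d_max``.

    When ``require_h`` and the donor carries an explicit hydrogen, the
    D-H...A angle must also reach ``angle_min`` degrees.  Pairs within one
    residue are skipped.  Records are sorted by distance.
    """
    donors, acceptors = _donor_acceptor_indices(s, include_water)
    records = []
    if len(donors) == 0 or len(acceptors) == 0:
        return records
    dmat = cdist(s.coord[donors], s.coord[acceptors])
    hydro = ~s.heavy
    for di, ai in zip(*np.nonzero(dmat <= d_max)):
        d_idx, a_idx = donors[di], acceptors[ai]
        if d_idx == a_idx:
            continue
        if (s.chain_id[d_idx] == s.chain_id[a_idx]
                and s.res_id[d_idx] == s.res_id[a_idx]):
            continue
        angle = None
        if require_h and hydro.any():
            h_angle = _best_dha_angle(s, d_idx, a_idx)
            if h_angle is not None:
                if h_angle < angle_min:
                    continue
                angle = h_angle
        records.append(InteractionRecord(
            kind="hbond",
            partner_a=_atom_label(s, d_idx), partner_b=_atom_label(s, a_idx),
            distance=float(dmat[di, ai]), angle=angle,
            interchain=s.chain_id[d_idx] != s.chain_id[a_idx]))
    records.sort(key=lambda r: r.distance)
    return records


def _best_dha_angle(s: Structure, donor: int, acceptor: int) -> Optional[float]:
    """Largest D-H...A angle over hydrogens covalently bound to the donor."""
    mask = ((s.chain_id == s.chain_id[donor]) & (s.res_id == s.res_id[donor])
            & ~s.heavy)
    hs = np.nonzero(mask)[0]
    hs = [h for h in hs if np.linalg.norm(s.coord[h] - s.coord[donor]) < 1.3]
    if not hs:
        return None
    best = -1.0
    for h in hs:
        v1 = s.coord[donor] - s.coord[h]
        v2 = s.coord[acceptor] - s.coord[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    return best


def find_salt_bridges(s: Structure, d_max: float = 4.0) -> list[InteractionRecord]:
    """Salt bridges: min charged-group N-O distance <= ``d_max`` per residue pair."""
    cations, anions = {}, {}
    for chain, rid, rname in s.residues():
        mask = s.residue_mask(chain, rid)
        if rname in CATION_ATOMS:
            idx = [i for i in np.nonzero(mask)[0]
                   if s.atom_name[i] in CATION_ATOMS[rname]]
            if idx:
                cations[(chain, rid, rname)] = np.array(idx)
        if rname in ANION_ATOMS:
            idx = [i for i in np.nonzero(mask)[0]
                   if s.atom_name[i] in ANION_ATOMS[rname]]
            if idx:
                anions[(chain, rid, rname)] = np.array(idx)
    records = []
    for ckey, cidx in cations.items():
        for akey, aidx in anions.items():
            d = cdist(s.coord[cidx], s.coord[aidx])
            dmin = float(d.min())
            if dmin <= d_max:
                records.append(InteractionRecord(
                    kind="salt_bridge",
                    partner_a=(*ckey, "+group"), partner_b=(*akey, "-group"),
                    distance=dmin, interchain=ckey[0] != akey[0]))
    records.sort(key=lambda r: r.distance)
    return records


def find_cation_pi(s: Structure, d_max: float = 6.0, angle_max: float = 60.0,
                   his_as_cation: bool = True) -> list[InteractionRecord]:
    """Cation/pi contacts: cation within ``d_max`` of a ring centroid and
    within ``angle_max`` degrees of the ring normal (measured at the centroid)."""
    cations, rings = [], []
    for chain, rid, rname in s.residues():
        mask = s.residue_mask(chain, rid)
        idx = np.nonzero(mask)[0]
        names = {str(s.atom_name[i]): i for i in idx}
        if rname in CATION_GROUPS and (rname != "HIS" or his_as_cation):
            group = [names[a] for a in CATION_GROUPS[rname] if a in names]
            if len(group) == len(CATION_GROUPS[rname]):
                cations.append(((chain, rid, rname),
                                s.coord[group].mean(axis=0)))
        if rname in AROMATIC_RINGS:
            ring = [names[a] for a in AROMATIC_RINGS[rname] if a in names]
            if len(ring) == len(AROMATIC_RINGS[rname]):
                pts = s.coord[ring]
                rings.append(((chain, rid, rname), pts.mean(axis=0),
                              fit_plane_normal(pts)))
    records = []
    for ckey, cpos in cations:
        for rkey, centroid, normal in rings:
            if ckey[:2] == rkey[:2]:
                continue
            v = cpos - centroid
            dist = float(np.linalg.norm(v))
            if dist > d_max or dist == 0:
                continue
            cosang = abs(np.dot(v / dist, normal))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if ang <= angle_max:
                records.append(InteractionRecord(
                    kind="cation_pi",
                    partner_a=(*ckey, "cation"), partner_b=(*rkey, "ring"),
                    distance=dist, angle=ang,
                    interchain=ckey[0] != rkey[0]))
    records.sort(key=lambda r: r.distance)
    return records


def min_interchain_distance(s: Structure, residue: tuple[str, int]) -> float:
    """Minimum heavy-atom distance from ``residue`` to any other chain."""
    chain, rid = residue
    chains = set(s.chain_id[s.protein_mask].tolist())
    if len(chains) < 2:
        raise NotApplicableError("structure has a single chain")
    res_mask = s.residue_mask(chain, rid) & s.heavy
    other = (s.chain_id != chain) & s.heavy & s.protein_mask
    if not other.any():
        raise NotApplicableError("no heavy atoms on other chains")
    return float(cdist(s.coord[res_mask], s.coord[other]).min())


def sasa_per_atom(s: Structure, probe_radius: float = 1.4,
                  point_number: int = 192) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface per atom (A^2, NaN for H)."""
    arr = s.to_biotite()
    values = struc.sasa(arr, probe_radius=probe_radius,
                        point_number=point_number, vdw_radii="Single")
    return np.nan_to_num(np.asarray(values, dtype=float))


def relative_exposure(s: Structure, residue: tuple[str, int],
                      probe_radius: float = 1.4, point_number: int = 192,
                      exposed_threshold: float = 0.25,
                      buried_threshold: float = 0.10) -> tuple[float, str]:
    """Relative side-chain exposure in [0,1] and a burial label.

    Side-chain SASA divided by the residue's tabulated Gly-X-Gly maximum,
    clamped to [0,1]; labels: exposed (>= 0.25), buried (< 0.10),
    intermediate otherwise.
    """
    chain, rid = residue
    rname = s.residue_name(chain, rid)
    if rname not in MAX_SIDECHAIN_SASA:
        raise ResidueTypingError(f"no reference exposure for residue {rname}")
    per_atom = sasa_per_atom(s, probe_radius, point_number)
    mask = s.residue_mask(chain, rid) & s.heavy
    if rname == "GLY":
        side = mask & (s.atom_name == "CA")
    else:
        side = mask & ~np.isin(s.atom_name, list(BACKBONE_ATOMS))
    ratio = float(per_atom[side].sum() / MAX_SIDECHAIN_SASA[rname])
    ratio = min(max(ratio, 0.0), 1.0)
    if ratio >= exposed_threshold:
        label = "exposed"
    elif ratio < buried_threshold:
        label = "buried"
    else:
        label = "intermediate"
    return ratio, label


@dataclass(frozen=True)
class ClashReport:
    residue: tuple
    old_residue: str
    new_residue: str
    delta_volume: float          # A^3; positive = bulkier substitution
    neighbor_count: int          # heavy atoms within radius of side-chain centroid
    radius: float
    density_threshold: int
    potential_clash: bool


def substitution_clash_screen(s: Structure, residue: tuple[str, int],
                              new_residue_name: str, radius: float = 5.0,
                              density_threshold: int = 30) -> ClashReport:
    """Steric screen for replacing ``residue`` by ``new_residue_name``.

    Flags a potential clash when the substitution is bulkier (positive
    volume change) and the side-chain centroid sits in a crowded
    neighbourhood (>= ``density_threshold`` heavy atoms within ``radius``).
    The report carries raw numbers only, never a pathogenicity verdict.
    """
    chain, rid = residue
    old = s.residue_name(chain, rid)
    new = new_residue_name.upper()
    if old not in RESIDUE_VOLUME or new not in RESIDUE_VOLUME:
        raise ResidueTypingError(f"unknown residue type {old}/{new}")
    mask = s.residue_mask(chain, rid) & s.heavy
    side = mask & ~np.isin(s.atom_name, list(BACKBONE_ATOMS))
    if not side.any():
        side = mask & (s.atom_name == "CA")
    centroid = s.coord[side].mean(axis=0)
    own = s.residue_mask(chain, rid)
    neighbors = s.heavy & ~own
    dist = np.linalg.norm(s.coord[neighbors] - centroid, axis=1)
    count = int((dist <= radius).sum())
    dv = RESIDUE_VOLUME[new] - RESIDUE_VOLUME[old]
    return ClashReport(
        residue=(chain, rid, old), old_residue=old, new_residue=new,
        delta_volume=dv, neighbor_count=count, radius=radius,
        density_threshold=density_threshold,
        potential_clash=dv > 0 and count >= density_threshold)


def interaction_table(records: Sequence[InteractionRecord]):
    """Flatten interaction records for TSV export."""
    import pandas as pd
    return pd.DataFrame([{
        "kind": r.kind,
        "chain_a": r.partner_a[0], "res_a": r.partner_a[1],
        "resname_a": r.partner_a[2], "atom_a": r.partner_a[3],
        "chain_b": r.partner_b[0], "res_b": r.partner_b[1],
        "resname_b": r.partner_b[2], "atom_b": r.partner_b[3],
        "distance_A": round(r.distance, 3),
        "angle_deg": None if r.angle is None else round(r.angle, 1),
        "interchain": r.interchain,
    } for r in records])
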