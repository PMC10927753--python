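"""Brute-force plain-loop oracles and random fixtures for the geometry
detectors, shared by the unit and acceptance suites.  These deliberately
re-derive every quantity with O(n^2) loops, independent of the vectorised
implementation they check."""

import numpy as np
from scipy.spatial.transform import Rotation

from vuscope import structgeo as sg
from vuscope import synth


def random_residue_fixture(n_residues=50, seed=0):
    """Random spatial arrangement of charged/aromatic/polar residue templates."""
    rng = np.random.default_rng(seed)
    blocks = []
    kinds = ["ARG", "GLU", "LYS", "ASP", "PHE", "SER", "HIS", "TYR"]
    for i in range(n_residues):
        kind = kinds[rng.integers(len(kinds))]
        center = rng.uniform(0, 55, 3)
        chain = "A" if i < n_residues // 2 else "B"
        block = _template(kind, chain, i + 1)
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        block["coord"] = [rot @ np.asarray(c) + center for c in block["coord"]]
        blocks.append(block)
    return synth._merge(blocks)


def _template(kind, chain, res_id):
    coords = {
        "ARG": {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
                "O": (1.6, 2.3, 0.2), "CB": (2.2, -1.2, 0.4),
                "NE": (3.6, -1.3, 0.4), "CZ": (4.4, -2.3, 0.6),
                "NH1": (5.7, -2.2, 0.6), "NH2": (3.9, -3.5, 0.8)},
        "GLU": {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
                "O": (1.6, 2.3, 0.2), "CB": (2.2, -1.2, 0.4),
                "CD": (3.7, -1.3, 0.4), "OE1": (4.4, -0.3, 0.4),
                "OE2": (4.3, -2.4, 0.6)},
        "LYS": {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
                "O": (1.6, 2.3, 0.2), "CB": (2.2, -1.2, 0.4),
                "NZ": (4.8, -1.9, 0.8)},
        "ASP": {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
                "O": (1.6, 2.3, 0.2), "CB": (2.2, -1.2, 0.4),
                "OD1": (3.6, -1.1, 0.4), "OD2": (1.7, -2.3, 0.6)},
        "SER": {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.2, 1.3, 0),
                "O": (1.6, 2.3, 0.2), "CB": (2.2, -1.2, 0.4),
                "OG": (3.5, -1.3, 0.5)},
    }
    if kind in coords:
        return synth._residue_block(chain, res_id, kind, coords[kind])
    if kind == "PHE":
        block = synth._cation_pi_block(4.0, 0.0, (0, 0, 0))[0]
    elif kind == "TYR":
        block = synth._cation_pi_block(4.0, 0.0, (0, 0, 0))[0]
        block["atom_name"] = list(block["atom_name"]) + ["OH"]
        block["coord"] = list(block["coord"]) + [np.array([-2.8, 0.0, 0.0])]
        n = len(block["atom_name"])
        block["res_name"] = ["TYR"] * n
        block["chain_id"] = [chain] * n
        block["res_id"] = [res_id] * n
        return block
    else:  # HIS
        block = synth._his_residue(chain, res_id, (0, 0, 0))
    block["chain_id"] = [chain] * len(block["chain_id"])
    block["res_id"] = [res_id] * len(block["res_id"])
    return block


def brute_hbonds(s, d_max=3.5):
    donors, acceptors = [], []
    for i in range(s.n_atoms):
        rn, an = s.res_name[i], s.atom_name[i]
        if rn in sg.WATER_NAMES:
            continue
        if an == "N" and rn != "PRO":
            donors.append(i)
        if an in ("O", "OXT"):
            acceptors.append(i)
        if an in sg.SIDECHAIN_DONORS.get(rn, ()):
            donors.append(i)
        if an in sg.SIDECHAIN_ACCEPTORS.get(rn, ()):
            acceptors.append(i)
    out = set()
    for i in donors:
        for j in acceptors:
            if i == j or (s.chain_id[i] == s.chain_id[j]
                          and s.res_id[i] == s.res_id[j]):
                continue
            if np.linalg.norm(s.coord[i] - s.coord[j]) <= d_max:
                out.add((s.chain_id[i], s.res_id[i], s.atom_name[i],
                         s.chain_id[j], s.res_id[j], s.atom_name[j]))
    return out


def brute_salt_bridges(s, d_max=4.0):
    out = set()
    residues = s.residues()
    for ca, ra, na in residues:
        if na not in sg.CATION_ATOMS:
            continue
        for cb, rb, nb in residues:
            if nb not in sg.ANION_ATOMS:
                continue
            best = np.inf
            for i in range(s.n_atoms):
                if (s.chain_id[i], s.res_id[i]) != (ca, ra) \
                        or s.atom_name[i] not in sg.CATION_ATOMS[na]:
                    continue
                for j in range(s.n_atoms):
                    if (s.chain_id[j], s.res_id[j]) != (cb, rb) \
                            or s.atom_name[j] not in sg.ANION_ATOMS[nb]:
                        continue
                    best = min(best, np.linalg.norm(s.coord[i] - s.coord[j]))
            if best <= d_max:
                out.add((ca, ra, cb, rb))
    return out


def brute_cation_pi(s, d_max=6.0, angle_max=60.0):
    out = set()
    residues = s.residues()
    for ca, ra, na in residues:
        if na not in sg.CATION_GROUPS:
            continue
        idx = [i for i in range(s.n_atoms)
               if (s.chain_id[i], s.res_id[i]) == (ca, ra)
               and s.atom_name[i] in sg.CATION_GROUPS[na]]
        if len(idx) != len(sg.CATION_GROUPS[na]):
            continue
        cpos = s.coord[idx].mean(axis=0)
        for cb, rb, nb in residues:
            if nb not in sg.AROMATIC_RINGS or (ca, ra) == (cb, rb):
                continue
            ridx = [i for i in range(s.n_atoms)
                    if (s.chain_id[i], s.res_id[i]) == (cb, rb)
                    and s.atom_name[i] in sg.AROMATIC_RINGS[nb]]
            if len(ridx) != len(sg.AROMATIC_RINGS[nb]):
                continue
            pts = s.coord[ridx]
            centroid = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - centroid)
            normal = vt[2]
            v = cpos - centroid
            dist = np.linalg.norm(v)
            if dist == 0 or dist > d_max:
                continue
            ang = np.degrees(np.arccos(
                np.clip(abs(np.dot(v / dist, normal)), -1, 1)))
            if ang <= angle_max:
                out.add((ca, ra, cb, rb))
    return out
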