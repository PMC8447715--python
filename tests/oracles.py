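"""Independent brute-force oracles for the interaction detectors.

Deliberately naive: plain Python double loops over every atom pair, with the
chemistry dictionaries restated locally, sharing no code with the package's
detectors. Each oracle returns {frozenset({key_a, key_b}): min_distance}.
"""

from __future__ import annotations

import math

BASIC = {"ARG": ["NH1", "NH2", "NE"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}
ACIDIC = {"GLU": ["OE1", "OE2"], "ASP": ["OD1", "OD2"]}
DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"], "ASN": ["ND2"],
    "GLN": ["NE2"], "TRP": ["NE1"], "HIS": ["ND1", "NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"],
}
ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"], "GLN": ["OE1"],
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "HIS": ["ND1", "NE2"], "MET": ["SD"],
}
RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [
        ["CG", "CD1", "CD2", "NE1", "CE2"],
        ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ],
}
CATIONS = {"LYS": ["NZ"], "ARG": ["CZ"]}


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _coords(res, names):
    out = []
    for name in names:
        atom = res.atom(name)
        if atom is None:
            return None
        out.append(tuple(atom.coord))
    return out


def _pairwise_min(res_a, names_a, res_b, names_b, cutoff):
    best = None
    for na in names_a:
        aa = res_a.atom(na)
        if aa is None:
            continue
        for nb in names_b:
            ab = res_b.atom(nb)
            if ab is None:
                continue
            d = _dist(aa.coord, ab.coord)
            if d <= cutoff and (best is None or d < best):
                best = d
    return best


def oracle_salt_bridges(model, cutoff=4.0):
    polymer = model.polymer_residues()
    out = {}
    for rb in polymer:
        if rb.res_name not in BASIC:
            continue
        for ra in polymer:
            if ra.res_name not in ACIDIC:
                continue
            d = _pairwise_min(rb, BASIC[rb.res_name], ra, ACIDIC[ra.res_name], cutoff)
            if d is not None:
                out[frozenset((rb.key, ra.key))] = d
    return out


def oracle_hbonds(model, cutoff=3.5):
    polymer = model.polymer_residues()
    out = {}
    for ri in polymer:
        donors = ["N"] + DONORS.get(ri.res_name, [])
        for rj in polymer:
            if ri.key == rj.key:
                continue
            acceptors = ["O"] + ACCEPTORS.get(rj.res_name, [])
            adjacent = ri.chain_id == rj.chain_id and abs(ri.seq_number - rj.seq_number) < 2
            for nd in donors:
                ad = ri.atom(nd)
                if ad is None:
                    continue
                for na in acceptors:
                    if adjacent and nd in ("N", "CA", "C", "O") and na in ("N", "CA", "C", "O"):
                        continue
                    ab = rj.atom(na)
                    if ab is None:
                        continue
                    d = _dist(ad.coord, ab.coord)
                    if d <= cutoff:
                        key = frozenset((ri.key, rj.key))
                        if key not in out or d < out[key]:
                            out[key] = d
    return out


def _centroids(res):
    cents = []
    for names in RINGS.get(res.res_name, []):
        coords = _coords(res, names)
        if coords is None:
            continue
        n = len(coords)
        cents.append(tuple(sum(c[i] for c in coords) / n for i in range(3)))
    return cents


def oracle_pi_pi(model, cutoff=7.2):
    polymer = [r for r in model.polymer_residues() if r.res_name in RINGS]
    out = {}
    for i, ra in enumerate(polymer):
        for rb in polymer[i + 1 :]:
            if ra.chain_id == rb.chain_id and abs(ra.seq_number - rb.seq_number) == 1:
                continue
            best = None
            for ca in _centroids(ra):
                for cb in _centroids(rb):
                    d = _dist(ca, cb)
                    if d <= cutoff and (best is None or d < best):
                        best = d
            if best is not None:
                out[frozenset((ra.key, rb.key))] = best
    return out


def _plane_normal(coords):
    n = len(coords)
    cx = [sum(c[i] for c in coords) / n for i in range(3)]
    # smallest-eigenvector of the 3x3 scatter via explicit power iteration on
    # the inverse ordering: use numpy here only for the eigendecomposition
    import numpy as np

    centered = np.array(coords) - np.array(cx)
    w, v = np.linalg.eigh(centered.T @ centered)
    normal = v[:, 0]
    return cx, normal / np.linalg.norm(normal)


def oracle_cation_pi(model, dist_cutoff=6.0, angle_cutoff=60.0):
    polymer = model.polymer_residues()
    out = {}
    for rc in polymer:
        if rc.res_name not in CATIONS:
            continue
        for name in CATIONS[rc.res_name]:
            atom = rc.atom(name)
            if atom is None:
                continue
            for rr in polymer:
                if rr.res_name not in RINGS or rr.key == rc.key:
                    continue
                for ring_names in RINGS[rr.res_name]:
                    coords = _coords(rr, ring_names)
                    if coords is None:
                        continue
                    centroid, normal = _plane_normal(coords)
                    v = [atom.coord[i] - centroid[i] for i in range(3)]
                    d = math.sqrt(sum(x * x for x in v))
                    if d == 0 or d > dist_cutoff:
                        continue
                    cosang = abs(sum(vi * ni for vi, ni in zip(v, normal))) / d
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle > angle_cutoff:
                        continue
                    key = frozenset((rc.key, rr.key))
                    if key not in out or d < out[key]:
                        out[key] = d
    return out


def oracle_disulfides(model, cutoff=2.5):
    cys = [r for r in model.polymer_residues() if r.res_name == "CYS"]
    out = {}
    for i, ra in enumerate(cys):
        for rb in cys[i + 1 :]:
            d = _pairwise_min(ra, ["SG"], rb, ["SG"], cutoff)
            if d is not None:
                out[frozenset((ra.key, rb.key))] = d
    return out


ORACLES = {
    "salt_bridge": oracle_salt_bridges,
    "hbond": oracle_hbonds,
    "pi_pi": oracle_pi_pi,
    "cation_pi": oracle_cation_pi,
    "disulfide": oracle_disulfides,
}
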