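"""Rigid-body superposition of congeners onto a template molecule.

Every congener shares the 12-carbon biphenyl skeleton; field comparison
requires all molecules in a common frame, so each is least-squares fitted
(Kabsch, via SVD) onto the template's skeleton carbons.  The skeleton has
two two-fold symmetry axes, so the atom correspondence is ambiguous up to
ring swap and end-over-end flip; all four relabelings are tried and the
minimum-RMSD one kept.

The template is the congener with the largest combined activity Z, ties
broken toward the lower congener number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .congeners import Molecule3D

# Skeleton label order used for correspondence vectors.
_SKEL = ("1", "2", "3", "4", "5", "6", "1'", "2'", "3'", "4'", "5'", "6'")

# Proper rigid symmetries of the twisted biphenyl skeleton (D2): identity,
# C2 about the inter-ring axis (flips both rings: 2<->6, 3<->5), C2
# perpendicular (ring swap), and their product.
def _relabel(flip: bool, swap: bool) -> list[int]:
    def image(lab: str) -> str:
        digit, primed = int(lab[0]), lab.endswith("'")
        if flip:
            digit = {2: 6, 6: 2, 3: 5, 5: 3}.get(digit, digit)
        if swap:
            primed = not primed
        return f"{digit}'" if primed else str(digit)
    return [_SKEL.index(image(lab)) for lab in _SKEL]


_CORRESPONDENCES = [_relabel(f, s) for f in (False, True) for s in (False, True)]


@dataclass
class AlignmentResult:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # applied after rotation, angstrom
    rmsd: float               # skeleton RMSD, angstrom
    template_id: str
    correspondence: int = 0   # index of the winning skeleton relabeling


def _congener_sort_key(cid: str):
    m = re.search(r"(\d+)$", cid)
    return (int(m.group(1)) if m else 10**9, cid)


def select_template(activity_table) -> str:
    """Congener with the largest combined activity Z; ties -> lowest number."""
    if len(activity_table) == 0:
        raise ValueError("empty activity table")
    zmax = activity_table["z"].max()
    at_max = activity_table.loc[activity_table["z"] == zmax, "congener_id"]
    return sorted(at_max, key=_congener_sort_key)[0]


def _kabsch(moving: np.ndarray, target: np.ndarray):
    """Optimal proper rotation + translation mapping moving onto target."""
    mu_m, mu_t = moving.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - mu_t, moving - mu_m)
    R = rot.as_matrix()
    t = mu_t - R @ mu_m
    rmsd = rssd / np.sqrt(len(moving))
    return R, t, rmsd


def superimpose(mol: Molecule3D, template: Molecule3D):
    """Fit ``mol``'s skeleton onto the template's; returns (aligned, result).

    Only the 12 ring carbons enter the fit; substituents ride along.  The
    four symmetry-equivalent correspondences are searched exhaustively.
    """
    if len(mol.ring_labels) != 12 or len(template.ring_labels) != 12:
        raise ValueError("both molecules must carry 12 labeled skeleton carbons")
    skel_m = mol.coords[mol.skeleton_indices()]
    skel_t = template.coords[template.skeleton_indices()]

    # the bare 12-carbon skeleton is symmetric, so correspondences tie at
    # numerical noise whenever dihedrals match; require a real improvement
    # (> 1e-6 A) so the identity relabeling wins ties deterministically
    best = None
    for ci, perm in enumerate(_CORRESPONDENCES):
        R, t, rmsd = _kabsch(skel_m[perm], skel_t)
        if best is None or rmsd < best[0] - 1e-6:
            best = (rmsd, R, t, ci)
    rmsd, R, t, ci = best

    aligned = mol.copy()
    aligned.coords = mol.coords @ R.T + t
    return aligned, AlignmentResult(
        rotation=R, translation=t, rmsd=float(rmsd),
        template_id=template.congener_id, correspondence=ci)


def align_ensemble(molecules, template_id: str):
    """Superimpose every molecule onto the named template, preserving order."""
    by_id = {m.congener_id: m for m in molecules}
    template = by_id[template_id]
    aligned, results = [], []
    for mol in molecules:
        a, res = superimpose(mol, template)
        aligned.append(a)
        results.append(res)
    return aligned, results
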