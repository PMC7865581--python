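"""STDEV*COEFF contour maps and derivative design.

The interpretable output of a CoMFA model is, per grid point, the product
of the descriptor standard deviation and the PLS coefficient: large
positive values mark regions where adding steric bulk (steric block) or
positive potential (electrostatic block) raises the predicted activity,
large negative values regions where it lowers it.  Favored/disfavored
regions are the extreme percentiles of the positive and negative values.

Derivatives are designed by swapping substituents at ring positions of a
parent congener; the modified molecule is rebuilt, recharged, re-aligned
to the training template and scored with the frozen training model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import change_rate
from .align import superimpose
from .congeners import Molecule3D, SubstitutionPattern, assign_charges, \
    build_congener
from .fields import GridSpec
from .pls import PlsModel


@dataclass
class ContourMap:
    """Per-grid-point STDEV*COEFF values for one field block."""

    label: str                    # "steric" | "electrostatic"
    values: np.ndarray            # (n_points,), NaN at masked points
    grid: GridSpec
    favored_pct: float = 80.0
    disfavored_pct: float = 20.0
    favored: np.ndarray | None = None      # grid indices, raise activity
    disfavored: np.ndarray | None = None   # grid indices, lower activity

    def top_points(self, m: int) -> list[int]:
        """Grid indices of the m largest |STDEV*COEFF| values."""
        v = np.abs(np.nan_to_num(self.values))
        return list(np.argsort(v)[::-1][:m])


def stdev_coeff_map(model: PlsModel, scaler, label: str, grid: GridSpec,
                    favored_pct: float = 80.0,
                    disfavored_pct: float = 20.0) -> ContourMap:
    """Contour map of one block from a fitted model and its preprocessing.

    The value at each retained grid point is the scaled-descriptor stdev
    times the PLS coefficient, which is invariant to the block-scaling
    constant.  Favored points are positive values at or above the
    ``favored_pct`` percentile of the positive values; disfavored points
    are negative values at or below the ``disfavored_pct`` percentile of
    the negative values.  Masked points carry NaN.
    """
    blocks = scaler.column_blocks
    gidx = scaler.column_grid_idx
    sd = scaler.column_sd_scaled
    sel = blocks == label
    vals = np.full(grid.n_points, np.nan)
    vals[gidx[sel]] = sd[sel] * model.coef[sel]

    pos = vals[np.nan_to_num(vals) > 0]
    neg = vals[np.nan_to_num(vals) < 0]
    favored = np.array([], dtype=int)
    disfavored = np.array([], dtype=int)
    if pos.size:
        thr = np.percentile(pos, favored_pct)
        favored = np.flatnonzero(np.nan_to_num(vals) >= thr)
    if neg.size:
        thr = np.percentile(neg, disfavored_pct)
        disfavored = np.flatnonzero(np.nan_to_num(vals, nan=np.inf) <= thr)
    return ContourMap(label=label, values=vals, grid=grid,
                      favored_pct=favored_pct, disfavored_pct=disfavored_pct,
                      favored=favored, disfavored=disfavored)


def apply_substitution(parent: Molecule3D, plan: dict[str, str],
                       template: Molecule3D | None = None,
                       dihedral: float | None = None) -> Molecule3D:
    """Swap substituents at named ring positions of a parent congener.

    The molecule is rebuilt from the parent's substitution pattern with the
    plan applied (``H`` removes a substituent), partial charges are
    reassigned, and the result is superimposed onto ``template`` (or onto
    the parent itself when no template is given).
    """
    if parent.pattern is None:
        raise ValueError("parent molecule carries no substitution pattern")
    subs = dict(parent.pattern.substituents)
    for pos, grp in plan.items():
        if grp == "H":
            subs.pop(pos, None)
        else:
            subs[pos] = grp
    new_pattern = SubstitutionPattern(subs)
    if dihedral is None:
        from .congeners import measure_dihedral
        dihedral = measure_dihedral(parent)
    mol = assign_charges(build_congener(new_pattern, dihedral))
    aligned, _ = superimpose(mol, template if template is not None else parent)
    return aligned


@dataclass
class DerivativePrediction:
    derivative_id: str
    parent_id: str
    predicted_log_z: float
    predicted_z: float
    change_rate_pct: float   # signed, relative to the parent prediction


def predict_log_z(model: PlsModel, scaler, raw_row: np.ndarray) -> float:
    """Predicted response for one raw [steric|electrostatic] field row."""
    X = scaler.transform(np.atleast_2d(raw_row))
    return float(model.predict(X)[0])


def predict_derivative(model: PlsModel, scaler, raw_row: np.ndarray,
                       derivative_id: str, parent_id: str,
                       parent_log_z: float) -> DerivativePrediction:
    """Score a derivative's field row against the frozen training model.

    The change rate is signed: negative means the combined activity Z
    dropped relative to the parent (the design goal).
    """
    log_z = predict_log_z(model, scaler, raw_row)
    z = 10.0 ** log_z
    parent_z = 10.0 ** parent_log_z
    return DerivativePrediction(
        derivative_id=derivative_id, parent_id=parent_id,
        predicted_log_z=log_z, predicted_z=z,
        change_rate_pct=change_rate(parent_z, z, mode="signed"))
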