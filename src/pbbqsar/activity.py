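"""Threshold-normalized combined activity for multi-endpoint congener data.

Three endpoints characterize each congener: bioconcentration (BCF),
long-range transport potential (vapor pressure at 25 C, mmHg) and the
highest infrared signal intensity.  Because the endpoints span orders of
magnitude they are log10-transformed, then each is min-max scaled to
0-100 over the working table (the "threshold method"),

    Y_i = 100 * (X_i - X_i_min) / (X_i_max - X_i_min),

and combined with a 5:4:1 weight ratio into a single response

    Z = 0.5*Y1 + 0.4*Y2 - 0.1*Y3,

so that a high Z marks a congener that bioaccumulates, travels far, and is
hard to detect by IR.  PLS modelling downstream uses log10 Z by default.

Change rates between a parent molecule and a derivative are reported as
percentages of the parent value; three sign conventions cover the way
increases, decreases and signed differences are quoted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default endpoint weights (BCF, VP, IR intensity) - the 5:4:1 ratio
DEFAULT_WEIGHTS = (0.5, 0.4, -0.1)

ENDPOINT_COLUMNS = ("bcf", "vp", "ir_intensity")
LOG_COLUMNS = ("log_bcf", "log_vp", "log_ir")


class ActivityError(ValueError):
    pass


def log_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Log10-transform the raw endpoint columns of an activity table.

    Expects columns ``congener_id, bcf, vp, ir_intensity`` with strictly
    positive values; returns a table with ``log_bcf, log_vp, log_ir``.
    """
    out = pd.DataFrame({"congener_id": table["congener_id"]})
    for raw, logged in zip(ENDPOINT_COLUMNS, LOG_COLUMNS):
        vals = np.asarray(table[raw], dtype=float)
        bad = ~(vals > 0)
        if bad.any():
            offender = table["congener_id"].iloc[int(np.flatnonzero(bad)[0])]
            raise ActivityError(
                f"non-positive {raw} for {offender}: cannot log-transform")
        out[logged] = np.log10(vals)
    return out


def threshold_scale(x, lo: float, hi: float, clamp: bool = False):
    """Min-max scale a value (or array) to [0, 100].

    In strict mode (default) values outside [lo, hi] raise; with
    ``clamp=True`` they are clamped, as needed when scoring new derivatives
    against the training table's scaling.
    """
    if not hi > lo:
        raise ActivityError("degenerate scaling range: max must exceed min")
    x = np.asarray(x, dtype=float)
    if clamp:
        x = np.clip(x, lo, hi)
    elif np.any(x < lo) or np.any(x > hi):
        raise ActivityError("value outside scaling range; use clamp mode")
    y = 100.0 * (x - lo) / (hi - lo)
    return float(y) if y.ndim == 0 else y


def combine(y, weights=DEFAULT_WEIGHTS):
    """Weighted combined activity Z from scaled single activities (Y1, Y2, Y3)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ActivityError("weight vector must have length 3")
    z = y @ w
    return float(z[0]) if z.shape == (1,) else z


def scaling_from_table(log_table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-endpoint (min, max) on the log scale, taken from the table itself."""
    return {c: (float(log_table[c].min()), float(log_table[c].max()))
            for c in LOG_COLUMNS}


def combined_activity_table(log_table: pd.DataFrame,
                            weights=DEFAULT_WEIGHTS,
                            scaling: dict | None = None,
                            clamp: bool = False) -> pd.DataFrame:
    """Compute scaled activities Y1..Y3, Z and log10 Z for a log-scale table.

    ``scaling`` defaults to the table's own min/max (training convention);
    pass a stored training scaling with ``clamp=True`` to score externals.
    """
    if scaling is None:
        scaling = scaling_from_table(log_table)
    out = log_table.copy()
    for yi, c in zip(("y1", "y2", "y3"), LOG_COLUMNS):
        lo, hi = scaling[c]
        out[yi] = threshold_scale(log_table[c].to_numpy(), lo, hi, clamp=clamp)
    out["z"] = combine(out[["y1", "y2", "y3"]].to_numpy(), weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_z"] = np.where(out["z"] > 0, np.log10(out["z"]), np.nan)
    return out


def change_rate(reference: float, new: float, mode: str = "signed") -> float:
    """Percent change of ``new`` relative to ``reference``.

    ``signed``   : 100*(new - reference)/|reference| (sign preserved)
    ``increase`` : 100*(new - reference)/reference (positive = increase)
    ``decrease`` : 100*(reference - new)/reference (positive = decrease)

    Rounded to 2 decimals, the reporting convention of the comparison tables.
    """
    if reference == 0:
        raise ActivityError("change rate undefined for zero reference")
    if mode == "signed":
        r = 100.0 * (new - reference) / abs(reference)
    elif mode == "increase":
        r = 100.0 * (new - reference) / reference
    elif mode == "decrease":
        r = 100.0 * (reference - new) / reference
    else:
        raise ActivityError(f"unknown change-rate mode {mode!r}")
    return round(r, 2)
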