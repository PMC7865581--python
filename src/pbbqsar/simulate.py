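"""Synthetic congener studies with a planted structure-activity relationship.

No public per-congener activity table exists for the full 45-congener PBB
set, so end-to-end testing uses simulated studies: a congener subset is
built in 3D, aligned, and its field descriptors computed; the three
log-scale endpoints (BCF, vapor pressure, IR intensity) are then generated
as sparse linear functions of a handful of high-variance field columns
plus Gaussian noise.  The planted columns and coefficients are recorded so
that model recovery (q2, contour localization) can be asserted.

Endpoint anchors place the design parent PBB-153 at the literature
exemplars log10 BCF = 2.22, log10 VP = -7.67 mmHg, log10 IR = 2.84, and
the endpoint spreads across congeners (sd 0.5, 1.5 and 0.3 log units)
reflect the order-of-magnitude ranges such congener series span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import activity
from .align import align_ensemble
from .congeners import (PBB_153, Molecule3D, assign_charges, build_congener,
                        enumerate_congeners, name_congener)
from .fields import ComfaScaler, GridSpec, ProbeConfig, RawFields, compute_fields, \
    make_grid, raw_matrix

#: anchor values for PBB-153 on the log10 scale (BCF, VP mmHg, IR intensity)
PBB153_ANCHORS = (2.22, -7.67, 2.84)

#: across-congener standard deviation of each log10 endpoint
ENDPOINT_SPREADS = (0.5, 1.5, 0.3)

#: minimum combined activity enforced by the generator (log Z must exist)
MIN_COMBINED_ACTIVITY = 5.0


@dataclass
class PlantedSignal:
    """The ground-truth linear map from field columns to log endpoints."""

    columns: list[tuple[str, int]]   # (block label, grid point index)
    coefficients: np.ndarray         # (3 endpoints, n_columns), scaled-X units
    intercepts: np.ndarray           # (3,)
    z_coefficients: np.ndarray       # effective slope of noiseless Z per column
    contributions: np.ndarray        # fractional |slope|*sd share per column

    def material_columns(self, floor: float = 0.5) -> list[tuple[str, int]]:
        """Columns whose share of the combined-activity signal is at least
        ``floor`` times the equal-share level 1/k.  The min-max scaling and
        the 5:4:1 weighting can shrink an endpoint coefficient to near
        nothing in Z; such columns carry no recoverable signal."""
        mask = self.contributions >= floor / len(self.columns)
        return [c for c, m in zip(self.columns, mask) if m]


@dataclass
class SimulatedStudy:
    molecules: list[Molecule3D]      # aligned, charged, simulation frame
    table: pd.DataFrame              # congener_id, bcf, vp, ir_intensity (raw)
    log_table: pd.DataFrame          # congener_id, log_bcf, log_vp, log_ir
    planted: PlantedSignal
    grid: GridSpec
    scaler: ComfaScaler              # fitted on the full simulated ensemble
    raw_fields: RawFields
    noise_sd: float
    seed: int
    template_id: str = "PBB-153"

    @property
    def ids(self) -> list[str]:
        return [m.congener_id for m in self.molecules]

    def descriptor_matrix(self) -> np.ndarray:
        """Raw [steric | electrostatic] matrix in simulation-frame order."""
        return raw_matrix(self.raw_fields)

    def planted_column_indices(self) -> list[int]:
        """Indices of the planted columns within the retained descriptors."""
        blocks = self.scaler.column_blocks
        gidx = self.scaler.column_grid_idx
        return [int(np.flatnonzero((blocks == b) & (gidx == g))[0])
                for b, g in self.planted.columns]

    def planted_endpoints(self) -> np.ndarray:
        """Noiseless log endpoints from the recorded affine map, (n_mol, 3)."""
        Xs = self.scaler.transform(self.descriptor_matrix())
        idx = self.planted_column_indices()
        return (self.planted.intercepts[None, :]
                + Xs[:, idx] @ self.planted.coefficients.T)


def _select_patterns(n_molecules: int, rng: np.random.Generator):
    """PBB-153 plus a seeded random draw from the other 208 congeners."""
    all_patterns = enumerate_congeners(range(1, 11))
    if n_molecules > len(all_patterns):
        raise ValueError(f"only {len(all_patterns)} congeners exist")
    anchor_set = PBB_153.bromine_positions
    others = [p for p in all_patterns if p.bromine_positions != anchor_set]
    picked = rng.choice(len(others), size=n_molecules - 1, replace=False)
    chosen = [PBB_153] + [others[i] for i in sorted(picked)]
    return chosen


def simulate_study(n_molecules: int = 45, seed: int = 0,
                   noise_sd: float = 0.05, dihedral: float = 44.0,
                   spacing: float = 2.0, margin: float = 4.0,
                   probe: ProbeConfig = ProbeConfig(),
                   sigma_min: float = 0.05,
                   n_planted: tuple[int, int] = (5, 10)) -> SimulatedStudy:
    """Generate a fully specified synthetic congener study.

    The same seed reproduces the study byte for byte.  ``noise_sd`` is the
    per-endpoint Gaussian noise on the log10 scale; at zero the endpoints
    are exactly the planted linear map of the field columns.  Coefficient
    draws that would push the combined activity Z of any congener below
    a small positive floor are rejected and redrawn (log Z must exist).
    """
    if n_molecules < 10:
        raise ValueError("need at least 10 molecules for a meaningful study")
    rng = np.random.default_rng(seed)

    patterns = _select_patterns(n_molecules, rng)
    molecules = [assign_charges(build_congener(p, dihedral)) for p in patterns]
    aligned, _ = align_ensemble(molecules, name_congener(PBB_153))

    grid = make_grid(aligned, spacing=spacing, margin=margin)
    raw = compute_fields(aligned, grid, probe)
    scaler = ComfaScaler(grid.n_points, sigma_min).fit(raw_matrix(raw))
    Xs = scaler.transform(raw_matrix(raw))
    Xs_c = Xs - Xs.mean(axis=0)

    # candidate pool: top quartile of columns by descriptor variance that
    # stay clear of the ensemble's dominant factor (the leading principal
    # component, essentially overall bromination) — the planted signal is
    # meant to be a local structure-activity relationship, not a proxy
    # for molecular size
    sd = Xs.std(axis=0, ddof=1)
    pool = np.flatnonzero(sd >= np.quantile(sd, 0.75))
    pc1 = np.linalg.svd(Xs_c, full_matrices=False)[0][:, 0]
    pc1_corr = np.array([abs(np.corrcoef(Xs_c[:, c], pc1)[0, 1])
                         for c in pool])
    pool = pool[pc1_corr < 0.5]
    pool_corr = np.corrcoef(Xs[:, pool].T)
    pool_pos = {int(c): i for i, c in enumerate(pool)}

    anchor_row = 0  # PBB-153 is always first
    anchors = np.asarray(PBB153_ANCHORS)
    spreads = np.asarray(ENDPOINT_SPREADS)

    # Field columns across a congener series are heavily collinear (one
    # bromination factor dominates), so the planted columns are selected
    # greedily to be mutually weakly correlated (|r| < 0.5): a signal
    # planted on near-duplicate columns collapses into a single latent
    # and can never be localized.  Each endpoint then owns a disjoint
    # subset of the columns, with subset sizes proportional to the
    # endpoint's weight in Z and coefficient magnitudes inversely
    # proportional to the column spread, so that every planted column
    # carries a comparable, material share of the combined-activity
    # signal (an immaterial planted column is unrecoverable in
    # principle).  Signs are random; magnitudes vary mildly.  Draws whose
    # noiseless combined activity dips below the positive floor are
    # rejected and redrawn.
    w_abs = np.abs(np.asarray(activity.DEFAULT_WEIGHTS))
    for _ in range(500):
        k = int(rng.integers(n_planted[0], n_planted[1] + 1))
        picked: list[int] = []
        for c in rng.permutation(pool):
            if all(abs(pool_corr[pool_pos[int(c)], pool_pos[p]]) < 0.5
                   for p in picked):
                picked.append(int(c))
            if len(picked) == k:
                break
        if len(picked) < max(3, n_planted[0]):
            continue
        cols = np.sort(picked)
        k = len(cols)
        # ownership counts follow the 5:4:1 weight ratio, min one each
        n_bcf = max(1, round(w_abs[0] / w_abs.sum() * k))
        n_ir = max(1, round(w_abs[2] / w_abs.sum() * k))
        n_vp = k - n_bcf - n_ir
        if n_vp < 1:
            continue
        owner = rng.permutation(np.repeat([0, 1, 2], [n_bcf, n_vp, n_ir]))
        col_sd = Xs_c[:, cols].std(axis=0, ddof=1)
        signs = rng.choice([-1.0, 1.0], size=k)
        mags = rng.uniform(0.7, 1.3, size=k)
        coef = np.zeros((3, k))
        for e in range(3):
            own = owner == e
            coef[e, own] = signs[own] * mags[own] / col_sd[own]
        g = Xs_c[:, cols] @ coef.T
        g_sd = g.std(axis=0, ddof=1)
        if np.any(g_sd == 0):
            continue
        coef *= (spreads / g_sd)[:, None]
        g = Xs_c[:, cols] @ coef.T
        intercepts = anchors - g[anchor_row]
        log_end = intercepts[None, :] + g              # noiseless endpoints
        log_df = pd.DataFrame(log_end, columns=list(activity.LOG_COLUMNS))
        log_df.insert(0, "congener_id", [m.congener_id for m in aligned])
        z = activity.combined_activity_table(log_df)["z"]
        if z.min() >= MIN_COMBINED_ACTIVITY:
            break
    else:
        raise RuntimeError("could not plant a positive combined activity")

    # effective linear map of the noiseless combined activity Z on the
    # planted columns: Eq-style min-max scaling is affine per endpoint, so
    # Z = const + sum_e w_e * 100/range_e * g_e
    ranges = log_end.max(axis=0) - log_end.min(axis=0)
    w = np.asarray(activity.DEFAULT_WEIGHTS)
    z_coef = (coef * (w * 100.0 / ranges)[:, None]).sum(axis=0)
    col_sd = Xs[:, cols].std(axis=0, ddof=1)
    contrib = np.abs(z_coef) * col_sd
    contrib = contrib / contrib.sum()

    noise = rng.normal(scale=noise_sd, size=log_end.shape) if noise_sd > 0 \
        else np.zeros_like(log_end)
    log_end = log_end + noise
    log_table = pd.DataFrame(log_end, columns=list(activity.LOG_COLUMNS))
    log_table.insert(0, "congener_id", [m.congener_id for m in aligned])

    table = pd.DataFrame({
        "congener_id": log_table["congener_id"],
        "bcf": 10.0 ** log_table["log_bcf"],
        "vp": 10.0 ** log_table["log_vp"],
        "ir_intensity": 10.0 ** log_table["log_ir"],
    })

    blocks = scaler.column_blocks
    grid_idx = scaler.column_grid_idx
    # fold the column centering into the intercepts so the recorded map is
    # plainly affine in the scaled descriptor columns
    planted = PlantedSignal(
        columns=[(str(blocks[c]), int(grid_idx[c])) for c in cols],
        coefficients=coef,
        intercepts=intercepts - coef @ Xs.mean(axis=0)[cols],
        z_coefficients=z_coef,
        contributions=contrib,
    )
    return SimulatedStudy(
        molecules=aligned, table=table, log_table=log_table, planted=planted,
        grid=grid, scaler=scaler, raw_fields=raw, noise_sd=noise_sd, seed=seed)
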