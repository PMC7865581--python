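"""CoMFA molecular interaction fields on a rectangular lattice.

For every aligned molecule, a steric (Lennard-Jones, sp3-carbon probe) and
an electrostatic (Coulomb, +1 e probe, distance-dependent dielectric)
energy is evaluated at each grid point.  Values are clamped at a cutoff,
electrostatic values inside a molecule's steric envelope are replaced by
the column mean over the remaining molecules, near-constant columns are
masked, and each field block is scaled to equal overall variance so that
neither field dominates the PLS step (CoMFA-STD scaling).

All energies are in kcal/mol, distances in angstrom, charges in e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Coulomb constant, kcal*angstrom/(mol*e^2)
COULOMB_K = 332.0636

# Tripos-style Lennard-Jones parameters per element: (vdW radius R, epsilon)
VDW_PARAMS = {
    "C": (1.70, 0.107),
    "H": (1.50, 0.042),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "Br": (1.85, 0.434),
}


@dataclass(frozen=True)
class ProbeConfig:
    """CoMFA probe: sp3 carbon with +1 charge by default."""

    radius: float = 1.70        # angstrom
    epsilon: float = 0.107      # kcal/mol
    charge: float = 1.0         # e
    e_cut: float = 30.0         # clamp, kcal/mol


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectangular lattice."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), x fastest-varying last."""
        axes = [np.asarray(self.origin)[d] + self.spacing * np.arange(self.shape[d])
                for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def to_dict(self) -> dict:
        return {"origin": list(self.origin), "spacing": self.spacing,
                "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["origin"]), float(d["spacing"]), tuple(d["shape"]))


def make_grid(ensemble, spacing: float = 2.0, margin: float = 4.0) -> GridSpec:
    """Lattice covering the ensemble bounding box plus ``margin`` on all sides."""
    if not ensemble:
        raise ValueError("empty ensemble")
    coords = np.vstack([m.coords for m in ensemble])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return GridSpec(origin=tuple(lo), spacing=spacing, shape=shape)


def _params(elements):
    out = []
    for e in elements:
        if e not in VDW_PARAMS:
            raise KeyError(f"no Lennard-Jones parameters for element {e!r}")
        out.append(VDW_PARAMS[e])
    arr = np.asarray(out)
    return arr[:, 0], arr[:, 1]


def steric_energy(mol, points, probe: ProbeConfig = ProbeConfig()) -> np.ndarray:
    """Lennard-Jones probe energy at each point, clamped to [0, e_cut].

    Per atom: eps_ij * [(r_m/r)^12 - 2 (r_m/r)^6] with r_m = R_atom + R_probe
    and eps_ij = sqrt(eps_atom * eps_probe); net attractive sums floor at 0.
    """
    radii, eps = _params(mol.elements)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - mol.coords[None, :, :], axis=2)
    r_m = radii + probe.radius
    eps_ij = np.sqrt(eps * probe.epsilon)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        s6 = (r_m / d) ** 6
        e = eps_ij * (s6 * s6 - 2.0 * s6)
    e = np.where(np.isfinite(e), e, probe.e_cut)
    total = e.sum(axis=1)
    return np.clip(total, 0.0, probe.e_cut)


def electrostatic_energy(mol, points, probe: ProbeConfig = ProbeConfig()) -> np.ndarray:
    """Coulomb probe energy with 1/r dielectric: k*q_probe*sum q_i/r_i^2.

    Clamped to [-e_cut, +e_cut]; the steric-envelope substitution is applied
    later at the ensemble level.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - mol.coords[None, :, :], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = COULOMB_K * probe.charge * mol.charges / (d * d)
    e = np.where(np.isinf(e), np.sign(e) * probe.e_cut, e)  # r=0 singularity
    total = np.nan_to_num(e).sum(axis=1)
    return np.clip(total, -probe.e_cut, probe.e_cut)


@dataclass
class RawFields:
    """Unfiltered field values for an ensemble on a shared grid."""

    steric: np.ndarray        # (n_mol, n_points), in [0, e_cut]
    electrostatic: np.ndarray  # (n_mol, n_points), substituted inside envelopes
    excluded: np.ndarray      # bool (n_mol, n_points): steric envelope hits
    grid: GridSpec
    probe: ProbeConfig


def compute_fields(ensemble, grid: GridSpec,
                   probe: ProbeConfig = ProbeConfig(),
                   envelope_mode: str = "column_mean") -> RawFields:
    """Evaluate both field blocks for every molecule of an aligned ensemble.

    ``envelope_mode`` controls electrostatics at sterically excluded points:
    ``column_mean`` (default) replaces them by that column's mean over
    non-excluded molecules; ``keep`` leaves the clamped Coulomb value.
    """
    pts = grid.points()
    steric = np.vstack([steric_energy(m, pts, probe) for m in ensemble])
    electro = np.vstack([electrostatic_energy(m, pts, probe) for m in ensemble])
    excluded = steric >= probe.e_cut - 1e-12

    if envelope_mode == "column_mean":
        ok = ~excluded
        counts = ok.sum(axis=0)
        sums = np.where(ok, electro, 0.0).sum(axis=0)
        col_mean = np.divide(sums, counts, out=np.zeros_like(sums),
                             where=counts > 0)
        electro = np.where(excluded, col_mean[None, :], electro)
    elif envelope_mode != "keep":
        raise ValueError(f"unknown envelope mode {envelope_mode!r}")
    return RawFields(steric=steric, electrostatic=electro, excluded=excluded,
                     grid=grid, probe=probe)


@dataclass
class FieldMatrix:
    """One field block of the descriptor matrix, with filtering metadata."""

    label: str                 # "steric" | "electrostatic"
    values: np.ndarray         # (n_mol, n_points), raw kcal/mol
    grid: GridSpec
    mask: np.ndarray           # bool (n_points,), True = retained column
    column_sd: np.ndarray      # (n_points,), raw per-column stdev
    block_sd: float            # RMS column stdev over retained columns

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def scaled(self) -> np.ndarray:
        """Retained columns divided by the block deviation (CoMFA-STD)."""
        return self.values[:, self.mask] / self.block_sd


class ComfaScaler:
    """Column filter + block scaling, refittable on training subsets.

    Operates on the concatenated raw matrix [steric | electrostatic]; the
    block boundary is given at construction.  sklearn-style fit/transform so
    cross-validation folds can honestly refit the preprocessing.
    """

    def __init__(self, n_points: int, sigma_min: float = 0.05):
        self.n_points = n_points
        self.sigma_min = sigma_min
        self.mask_: np.ndarray | None = None
        self.block_sd_: np.ndarray | None = None  # per retained column

    def fit(self, X_raw: np.ndarray, y=None) -> "ComfaScaler":
        p = self.n_points
        sd = X_raw.std(axis=0, ddof=1)
        mask = sd >= self.sigma_min
        if not mask.any():
            raise ValueError("all field columns filtered out (constant ensemble)")
        scale = np.empty_like(sd)
        for block in (slice(0, p), slice(p, 2 * p)):
            block_mask = mask[block]
            if block_mask.any():
                block_sd = float(np.sqrt(np.mean(sd[block][block_mask] ** 2)))
            else:
                block_sd = 1.0
            scale[block] = block_sd
        self.mask_ = mask
        self.column_sd_raw_ = sd
        self.scale_ = scale
        return self

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        if self.mask_ is None:
            raise RuntimeError("scaler not fitted")
        return (X_raw / self.scale_)[:, self.mask_]

    def fit_transform(self, X_raw: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X_raw).transform(X_raw)

    # -- descriptor metadata for fitted state -------------------------------
    @property
    def column_blocks(self) -> np.ndarray:
        """Block label ('steric'/'electrostatic') of each retained column."""
        labels = np.array(["steric"] * self.n_points +
                          ["electrostatic"] * self.n_points)
        return labels[self.mask_]

    @property
    def column_grid_idx(self) -> np.ndarray:
        """Grid-point index of each retained column."""
        idx = np.concatenate([np.arange(self.n_points), np.arange(self.n_points)])
        return idx[self.mask_]

    @property
    def column_sd_scaled(self) -> np.ndarray:
        """Stdev of each retained column in scaled descriptor units."""
        return (self.column_sd_raw_ / self.scale_)[self.mask_]

    def clone(self) -> "ComfaScaler":
        return ComfaScaler(self.n_points, self.sigma_min)


def raw_matrix(raw: RawFields) -> np.ndarray:
    """Concatenated raw descriptor matrix [steric | electrostatic]."""
    return np.hstack([raw.steric, raw.electrostatic])


def build_matrix(ensemble, grid: GridSpec,
                 probe: ProbeConfig = ProbeConfig(),
                 sigma_min: float = 0.05) -> tuple[FieldMatrix, FieldMatrix]:
    """Compute, filter and scale both field blocks for an aligned ensemble."""
    raw = compute_fields(ensemble, grid, probe)
    scaler = ComfaScaler(grid.n_points, sigma_min).fit(raw_matrix(raw))
    p = grid.n_points
    out = []
    for label, values, block in (
        ("steric", raw.steric, slice(0, p)),
        ("electrostatic", raw.electrostatic, slice(p, 2 * p)),
    ):
        mask = scaler.mask_[block]
        sd = scaler.column_sd_raw_[block]
        block_sd = float(scaler.scale_[block][0])
        out.append(FieldMatrix(label=label, values=values, grid=grid,
                               mask=mask, column_sd=sd, block_sd=block_sd))
    return tuple(out)


def write_cube(grid: GridSpec, values: np.ndarray, path, mol=None,
               comment: str = "field") -> None:
    """Export grid values as a Gaussian cube file (bohr units, as customary)."""
    bohr = 1.0 / 0.529177210903
    vals = np.asarray(values, dtype=float).reshape(grid.shape)
    n_atoms = 0 if mol is None else mol.n_atoms
    with open(path, "w") as fh:
        fh.write(f"{comment}\npbbqsar grid export\n")
        ox, oy, oz = (c * bohr for c in grid.origin)
        fh.write(f"{n_atoms:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
        step = grid.spacing * bohr
        fh.write(f"{grid.shape[0]:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{grid.shape[1]:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}\n")
        fh.write(f"{grid.shape[2]:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}\n")
        if mol is not None:
            from rdkit.Chem import GetPeriodicTable
            pt = GetPeriodicTable()
            for elem, xyz, q in zip(mol.elements, mol.coords, mol.charges):
                z = pt.GetAtomicNumber(elem)
                x, y, zz = (c * bohr for c in xyz)
                fh.write(f"{z:5d}{q:12.6f}{x:12.6f}{y:12.6f}{zz:12.6f}\n")
        flat = vals.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
        for row in flat:
            for k in range(0, len(row), 6):
                fh.write("".join(f"{v:13.5E}" for v in row[k:k + 6]) + "\n")
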