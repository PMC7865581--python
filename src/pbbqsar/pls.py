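"""PLS regression of combined activity on field descriptors, with the full
QSAR validation battery.

The model is fitted by NIPALS partial least squares (scikit-learn backend).
Validation covers: leave-one-out cross-validation (q2, SDEP, optimal
component count), non-cross-validated fit statistics (R2, SEE, regression
F with (n, N-n-1) degrees of freedom), per-field contribution fractions,
progressive scrambling of the response (Q2, cSDEP, dq2/dr2yy following
Clark's protocol with the critical point at r2_yy' = 0.85), and external
test-set prediction (r2_pred, SEP).

Quality gates follow the conventional thresholds for an acceptable CoMFA
model: q2 > 0.5, R2 > 0.9, SEE < 0.95, r2_pred > 0.6, dq2/dr2yy < 1.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

#: critical response-correlation level of the progressive-scrambling fit
SCRAMBLING_CRITICAL_POINT = 0.85

QUALITY_THRESHOLDS = {
    "q2": (">", 0.5),
    "r2": (">", 0.9),
    "see": ("<", 0.95),
    "r2_pred": (">", 0.6),
    "dq2_dr2yy": ("<", 1.2),
}


class PlsError(ValueError):
    pass


@dataclass
class PlsModel:
    """A fitted PLS model on preprocessed descriptors."""

    n_components: int
    coef: np.ndarray        # (n_features,), slope in descriptor units
    x_mean: np.ndarray
    y_mean: float
    x_scores: np.ndarray    # (n_samples, n_components)
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def split_train_test(ids, n_train: int = 35, seed: int = 0):
    """Seeded uniform split without replacement; returns (train, test) ids."""
    ids = list(ids)
    if not 0 < n_train < len(ids):
        raise PlsError("n_train must be positive and smaller than the table")
    rng = np.random.default_rng(seed)
    train_idx = np.sort(rng.choice(len(ids), size=n_train, replace=False))
    train = [ids[i] for i in train_idx]
    test = [x for i, x in enumerate(ids) if i not in set(train_idx.tolist())]
    return train, test


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Fit a NIPALS PLS model of y on X (centering handled internally)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise PlsError("need at least two training rows")
    if np.ptp(y) == 0:
        raise PlsError("constant response")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise PlsError(f"n_components={n_components} exceeds rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return PlsModel(
        n_components=n_components,
        coef=np.asarray(pls.coef_).reshape(-1),
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        x_scores=pls.x_scores_,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
    )


def _loo_press(X: np.ndarray, y: np.ndarray, n_components: int,
               preprocessor=None) -> float:
    """Sum of squared leave-one-out prediction errors.

    When a preprocessor (sklearn-style fit/transform, with .clone()) is
    given, X is the *raw* matrix and filtering/scaling are refit inside
    every fold; otherwise X is used as-is.
    """
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, Xte = X[keep], X[i:i + 1]
        if preprocessor is not None:
            prep = preprocessor.clone()
            Xtr = prep.fit_transform(Xtr)
            Xte = prep.transform(Xte)
        k = min(n_components, np.linalg.matrix_rank(Xtr - Xtr.mean(axis=0)))
        model = fit_pls(Xtr, y[keep], k)
        press += float((model.predict(Xte)[0] - y[i]) ** 2)
    return press


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int,
           preprocessor=None) -> tuple[float, float]:
    """Leave-one-out q2 and SDEP.

    q2 = 1 - PRESS/SS_tot with SS_tot about the full-sample mean;
    SDEP = sqrt(PRESS/N).
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 3:
        raise PlsError("need at least three rows for LOO")
    if np.ptp(y) == 0:
        raise PlsError("constant response")
    press = _loo_press(X, y, n_components, preprocessor)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot, math.sqrt(press / len(y))


def select_components(X: np.ndarray, y: np.ndarray, max_components: int = 10,
                      preprocessor=None) -> tuple[int, float]:
    """Optimal component count by maximum LOO q2; ties favour the smaller n."""
    if max_components < 1:
        raise PlsError("max_components must be >= 1")
    n = len(y)
    if preprocessor is not None:
        Xf = preprocessor.clone().fit_transform(X)
    else:
        Xf = X
    rank = np.linalg.matrix_rank(Xf - Xf.mean(axis=0))
    upper = min(max_components, n - 2, rank)
    best_n, best_q2 = 1, -np.inf
    for k in range(1, upper + 1):
        q2, _ = loo_q2(X, y, k, preprocessor)
        if q2 > best_q2 + 1e-12:
            best_n, best_q2 = k, q2
    return best_n, best_q2


def final_metrics(model: PlsModel, X: np.ndarray, y: np.ndarray
                  ) -> tuple[float, float, float]:
    """Non-cross-validated R2, SEE and regression F.

    SEE = sqrt(RSS/(N-n-1)); F = (R2/n)/((1-R2)/(N-n-1)) with n latent
    components.  A perfect fit reports F = inf.
    """
    y = np.asarray(y, dtype=float).ravel()
    n_comp = model.n_components
    N = len(y)
    if N <= n_comp + 1:
        raise PlsError("too few samples for the fit-statistic denominators")
    resid = y - model.predict(X)
    rss = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot
    see = math.sqrt(rss / (N - n_comp - 1))
    if r2 >= 1.0:
        f = math.inf
    else:
        f = (r2 / n_comp) / ((1.0 - r2) / (N - n_comp - 1))
    return r2, see, f


def regression_f(r2: float, n_samples: int, n_components: int) -> float:
    """Regression F-statistic with (n, N-n-1) degrees of freedom."""
    if r2 >= 1.0:
        return math.inf
    return (r2 / n_components) / ((1.0 - r2) / (n_samples - n_components - 1))


def field_contributions(model: PlsModel, column_blocks: np.ndarray,
                        column_sd: np.ndarray) -> dict[str, float]:
    """Percent contribution of each field block: sum |coef|*sd, normalized."""
    blocks = np.asarray(column_blocks)
    weight = np.abs(model.coef) * np.asarray(column_sd, dtype=float)
    total = weight.sum()
    out = {}
    for label in ("steric", "electrostatic"):
        w = float(weight[blocks == label].sum())
        out[label] = 100.0 * w / total if total > 0 else 0.0
    return out


def external_validation(y_pred: np.ndarray, y_test: np.ndarray,
                        y_train_mean: float) -> tuple[float, float]:
    """External r2_pred and SEP.

    r2_pred = 1 - PRESS/SD with SD = sum (y_test - y_train_mean)^2;
    SEP = sqrt(PRESS/N_test).
    """
    y_test = np.asarray(y_test, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_test) == 0:
        raise PlsError("empty test set")
    press = float(np.sum((y_test - y_pred) ** 2))
    sd = float(np.sum((y_test - y_train_mean) ** 2))
    if sd == 0:
        raise PlsError("test responses all equal the training mean")
    return 1.0 - press / sd, math.sqrt(press / len(y_test))


def scrambling_profile(X: np.ndarray, y: np.ndarray, n_components: int,
                       bins=range(2, 11), replicates: int = 20,
                       seed: int = 0, preprocessor=None):
    """Perturbation profile for progressive scrambling.

    The response is scrambled within similarity bins (contiguous blocks of
    the y-sorted order); coarser binnings perturb more.  Returns arrays
    (r2_yy', q2, SDEP) over all perturbations, with the unscrambled limit
    (r2_yy' = 1 and the plain LOO statistics) as the first entry.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        raise PlsError("need at least 10 rows for progressive scrambling")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")

    q2_full, sdep_full = loo_q2(X, y, n_components, preprocessor)
    r2_pts, q2_pts, sdep_pts = [1.0], [q2_full], [sdep_full]

    for n_bins in bins:
        if n_bins >= n:
            continue
        edges = np.array_split(order, n_bins)
        for _ in range(replicates):
            y_s = y.copy()
            for blk in edges:
                y_s[blk] = y_s[rng.permutation(blk)]
            r = np.corrcoef(y, y_s)[0, 1]
            if np.ptp(y_s) == 0:
                continue
            q2, sdep = loo_q2(X, y_s, n_components, preprocessor)
            r2_pts.append(float(r * r))
            q2_pts.append(q2)
            sdep_pts.append(sdep)
    return np.asarray(r2_pts), np.asarray(q2_pts), np.asarray(sdep_pts)


def progressive_scrambling(X: np.ndarray, y: np.ndarray, n_components: int,
                           bins=range(2, 11), replicates: int = 20,
                           seed: int = 0, preprocessor=None,
                           critical: float = SCRAMBLING_CRITICAL_POINT
                           ) -> tuple[float, float, float]:
    """Progressive scrambling stability statistics (Q2, cSDEP, dq2/dr2yy).

    Quadratics of q2 and SDEP against the scrambled-response correlation
    r2_yy' are evaluated at the critical perturbation level (0.85); the
    slope statistic is the derivative of the q2 quadratic there, rescaled
    by 1/(2 r_yy') per Clark's formulation of progressive scrambling.
    A stable model keeps dq2/dr2yy below about 1.2.
    """
    r2_arr, q2_arr, sdep_arr = scrambling_profile(
        X, y, n_components, bins, replicates, seed, preprocessor)
    q2_fit = np.polynomial.polynomial.polyfit(r2_arr, q2_arr, 2)
    sdep_fit = np.polynomial.polynomial.polyfit(r2_arr, sdep_arr, 2)
    pv = np.polynomial.polynomial.polyval
    q2_crit = float(pv(critical, q2_fit))
    csdep = float(pv(critical, sdep_fit))
    slope = float(q2_fit[1] + 2.0 * q2_fit[2] * critical)
    dq2_dr2yy = slope / (2.0 * math.sqrt(critical))
    return q2_crit, csdep, dq2_dr2yy


@dataclass
class ValidationReport:
    """Every statistic of the model validation battery, in table order."""

    q2: float
    n_components: int
    see: float
    r2: float
    f: float
    r2_pred: float | None = None
    sep: float | None = None
    q2_scrambled: float | None = None
    csdep: float | None = None
    dq2_dr2yy: float | None = None
    steric_pct: float | None = None
    electrostatic_pct: float | None = None
    extras: dict = dc_field(default_factory=dict)

    def quality_flags(self) -> dict[str, bool]:
        """True = the statistic violates its acceptance threshold."""
        values = {"q2": self.q2, "r2": self.r2, "see": self.see,
                  "r2_pred": self.r2_pred, "dq2_dr2yy": self.dq2_dr2yy}
        flags = {}
        for key, (op, thr) in QUALITY_THRESHOLDS.items():
            v = values[key]
            if v is None:
                continue
            ok = v > thr if op == ">" else v < thr
            flags[key] = not ok
        return flags

    def to_dict(self) -> dict:
        d = {"q2": self.q2, "n": self.n_components, "SEE": self.see,
             "R2": self.r2, "F": self.f, "r2_pred": self.r2_pred,
             "SEP": self.sep, "Q2": self.q2_scrambled, "cSDEP": self.csdep,
             "dq2_dr2yy": self.dq2_dr2yy,
             "steric_pct": self.steric_pct,
             "electrostatic_pct": self.electrostatic_pct}
        d.update(self.extras)
        return d
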