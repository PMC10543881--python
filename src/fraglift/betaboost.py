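"""Component-wise gradient boosting of a beta-regression likelihood.

Tumour content is a proportion, so it is modelled with the beta
distribution in its mean/precision parameterization,

    f(y; mu, phi) = Gamma(phi) / (Gamma(mu*phi) * Gamma((1-mu)*phi))
                    * y^(mu*phi - 1) * (1 - y)^((1-mu)*phi - 1),

with a logit link for the mean. Because the feature set (Fourier +
wavelet coefficients) is larger than the sample size, the linear
predictor is built by component-wise boosting: at each iteration the
negative gradient of the summed negative log-likelihood with respect to
the linear predictor is computed, every feature is regressed on it
singly, and only the best-fitting feature's coefficient moves, by a
small step ``nu`` times its fitted slope. The precision ``phi`` is a
scalar nuisance refreshed by one-dimensional likelihood maximization
after every update. The stopping iteration ``mstop`` — the only real
tuning parameter — is chosen by bootstrap cross-validation of the
out-of-bag risk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import digamma, expit, gammaln, logit

_MU_EPS = 1e-12
_LOG_PHI_BOUNDS = (-4.0, 8.0)


def beta_negloglik(y, mu, phi):
    """Negative log-density of the beta distribution (mean/precision form).

    Accepts scalars or arrays (broadcast); all arguments must lie in their
    open ranges: y, mu in (0, 1) and phi > 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = -(
        gammaln(phi) - gammaln(a) - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return out if out.ndim else float(out)


def _fit_phi(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximize the beta likelihood over phi on log phi in [-4, 8]."""

    def objective(log_phi: float) -> float:
        return float(np.sum(beta_negloglik(y, mu, np.exp(log_phi))))

    res = minimize_scalar(
        objective, bounds=_LOG_PHI_BOUNDS, method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def _neg_gradient(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
    """Negative gradient of the summed negative log-likelihood w.r.t. eta.

    d loglik / d mu = phi * (log(y/(1-y)) - psi(mu*phi) + psi((1-mu)*phi));
    chain rule through the logit link gives d mu / d eta = mu * (1 - mu).
    """
    mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    dl_dmu = phi * (
        np.log(y) - np.log1p(-y)
        - digamma(mu * phi) + digamma((1.0 - mu) * phi)
    )
    return dl_dmu * mu * (1.0 - mu)


@dataclass
class BoostedBetaModel:
    """Fitted component-wise boosted beta regression."""

    offset: float
    coef_path: list[tuple[str, float]]
    coefficients: dict[str, float]
    phi: float
    phi_path: list[float]
    mstop: int
    nu: float
    standardization: dict[str, tuple[float, float]]
    feature_names: list[str]
    seed: int
    train_risk_path: list[float] = field(default_factory=list)

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {
                "offset": self.offset,
                "coef_path": self.coef_path,
                "coefficients": self.coefficients,
                "phi": self.phi,
                "phi_path": self.phi_path,
                "mstop": self.mstop,
                "nu": self.nu,
                "standardization": self.standardization,
                "feature_names": self.feature_names,
                "seed": self.seed,
                "train_risk_path": self.train_risk_path,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "BoostedBetaModel":
        if source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        data["coef_path"] = [tuple(item) for item in data["coef_path"]]
        data["standardization"] = {
            k: tuple(v) for k, v in data["standardization"].items()
        }
        return cls(**data)


def _boost_core(
    Xs: np.ndarray,
    y: np.ndarray,
    nu: float,
    mstop: int,
    q_stop: int | None = None,
):
    """Run the boosting loop on an already-standardized matrix.

    Base learners are simple linear regressions (intercept + one
    feature) of the negative gradient; because the columns are centered
    the intercept part is ``mean(u)`` for every candidate, so feature
    choice reduces to the best single-column slope fit. Both the chosen
    slope and the shared intercept move by a factor ``nu`` per
    iteration, which lets the fit converge to the joint maximum
    likelihood (intercept, slope, phi) as iterations grow.

    Returns (offset0, path, phi_path, coef, intercept, risk_path,
    entered): ``path`` lists (column index, coefficient increment,
    intercept increment) per iteration and ``entered`` the distinct
    column indices in order of first entry.
    """
    n, p = Xs.shape
    offset0 = float(logit(np.mean(y)))
    intercept = offset0
    eta = np.full(n, intercept)
    mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    phi = _fit_phi(y, mu)
    ssq = np.sum(Xs * Xs, axis=0)
    coef = np.zeros(p)
    path: list[tuple[int, float, float]] = []
    phi_path = [phi]
    risk_path = [float(np.mean(beta_negloglik(y, mu, phi)))]
    entered: list[int] = []
    entered_set: set[int] = set()
    for _ in range(mstop):
        u = _neg_gradient(y, eta, phi)
        slopes = (Xs.T @ u) / ssq
        centered_ss = np.sum(u * u) - n * np.mean(u) ** 2
        sse = centered_ss - slopes * slopes * ssq
        j = int(np.argmin(sse))  # ties resolve to the smallest column index
        inc = nu * float(slopes[j])
        int_inc = nu * float(np.mean(u))
        coef[j] += inc
        intercept += int_inc
        eta = eta + int_inc + inc * Xs[:, j]
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        phi = _fit_phi(y, mu)
        path.append((j, inc, int_inc))
        phi_path.append(phi)
        risk_path.append(float(np.mean(beta_negloglik(y, mu, phi))))
        if j not in entered_set:
            entered_set.add(j)
            entered.append(j)
        if q_stop is not None and len(entered) >= q_stop:
            break
    return offset0, path, phi_path, coef, intercept, risk_path, entered


def _standardize(X: pd.DataFrame):
    """Center/scale columns; constant columns are dropped with a warning."""
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping constant feature columns: {dropped}",
                      stacklevel=3)
    if not keep.any():
        raise ValueError("all feature columns are constant")
    cols = list(X.columns[keep])
    Xs = (X.loc[:, cols].to_numpy(float) - means[cols].to_numpy()) / (
        sds[cols].to_numpy()
    )
    table = {c: (float(means[c]), float(sds[c])) for c in cols}
    return Xs, cols, table


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("labels must lie strictly inside (0, 1)")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    return y


def fit_boost(
    X: pd.DataFrame,
    y,
    nu: float = 0.1,
    mstop: int = 100,
    seed: int = 0,
) -> BoostedBetaModel:
    """Fit the boosted beta regression on a named feature matrix.

    The fit itself is deterministic; ``seed`` is recorded for provenance
    so downstream artifacts carry a complete recipe.
    """
    y = _validate_xy(X, y)
    Xs, cols, table = _standardize(X)
    offset0, path, phi_path, coef, intercept, risk_path, _ = _boost_core(
        Xs, y, nu=nu, mstop=mstop
    )
    named_path = [(cols[j], inc, int_inc) for j, inc, int_inc in path]
    coefficients = {c: float(v) for c, v in zip(cols, coef) if v != 0.0}
    return BoostedBetaModel(
        offset=intercept,
        coef_path=named_path,
        coefficients=coefficients,
        phi=phi_path[-1],
        phi_path=phi_path,
        mstop=mstop,
        nu=nu,
        standardization=table,
        feature_names=cols,
        seed=seed,
        train_risk_path=risk_path,
    )


def predict(model: BoostedBetaModel, X_new: pd.DataFrame) -> np.ndarray:
    """Predict tumour content for new samples; always in (0, 1)."""
    missing = [c for c in model.feature_names if c not in X_new.columns]
    if missing:
        raise ValueError(f"missing required feature(s): {missing}")
    extra = [c for c in X_new.columns if c not in model.feature_names]
    if extra:
        warnings.warn(f"ignoring {len(extra)} extra feature columns",
                      stacklevel=2)
    eta = np.full(len(X_new), model.offset)
    # iterate in canonical feature order so summation order (and thus the
    # floating-point result) is identical before and after serialization
    for name in model.feature_names:
        coefficient = model.coefficients.get(name)
        if not coefficient:
            continue
        mean, sd = model.standardization[name]
        eta = eta + coefficient * (X_new[name].to_numpy(float) - mean) / sd
    return expit(eta)


@dataclass(frozen=True)
class CvResult:
    """Out-of-bag risk of the boosting path over a grid of mstop values."""

    folds: int
    grid: list[int]
    risks: np.ndarray        # folds x len(grid)
    mean_risk: np.ndarray
    mstop_opt: int
    seed: int


def tune_mstop(
    X: pd.DataFrame,
    y,
    grid: list[int] | None = None,
    folds: int = 25,
    seed: int = 0,
    nu: float = 0.1,
) -> CvResult:
    """Choose mstop by bootstrap cross-validation.

    Draws ``folds`` bootstrap resamples of size n (with replacement),
    fits the boosting path on each resample, and evaluates the mean beta
    negative log-likelihood on the out-of-bag samples at every grid
    point. The grid point with the lowest mean risk wins; ties go to the
    smallest mstop. Resamples with an empty out-of-bag set are redrawn.
    """
    y = _validate_xy(X, y)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples for bootstrap tuning")
    if grid is None:
        grid = list(range(0, 501))
    if not grid:
        raise ValueError("mstop grid must be non-empty")
    grid = sorted(int(g) for g in grid)
    m_max = grid[-1]
    rng = np.random.default_rng(seed)
    risks = np.empty((folds, len(grid)))
    for fold in range(folds):
        while True:
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size:
                break
        X_boot = X.iloc[boot]
        try:
            Xs, cols, table = _standardize(X_boot)
        except ValueError:
            # degenerate resample (all columns constant): redraw deterministically
            risks[fold, :] = np.nan
            continue
        offset0, path, phi_path, _, _, _, _ = _boost_core(
            Xs, y[boot], nu=nu, mstop=m_max
        )
        means = np.array([table[c][0] for c in cols])
        sds = np.array([table[c][1] for c in cols])
        X_oob = (X.iloc[oob][cols].to_numpy(float) - means) / sds
        y_oob = y[oob]
        eta = np.full(oob.size, offset0)
        grid_set = {g: k for k, g in enumerate(grid)}
        if 0 in grid_set:
            mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
            risks[fold, grid_set[0]] = float(
                np.mean(beta_negloglik(y_oob, mu, phi_path[0]))
            )
        for m, (j, inc, int_inc) in enumerate(path, start=1):
            eta = eta + int_inc + inc * X_oob[:, j]
            if m in grid_set:
                mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
                risks[fold, grid_set[m]] = float(
                    np.mean(beta_negloglik(y_oob, mu, phi_path[m]))
                )
        # grid points beyond the realized path length reuse the final state
        if len(path) < m_max:
            mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
            tail_risk = float(np.mean(beta_negloglik(y_oob, mu, phi_path[-1])))
            for g, k in grid_set.items():
                if g > len(path):
                    risks[fold, k] = tail_risk
    mean_risk = np.nanmean(risks, axis=0)
    best = int(np.nanargmin(mean_risk))  # argmin takes the first = smallest mstop
    return CvResult(
        folds=folds,
        grid=grid,
        risks=risks,
        mean_risk=mean_risk,
        mstop_opt=grid[best],
        seed=seed,
    )
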