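"""REML variance-component decomposition of baseline beating variability.

Control-well (media and vehicle) values of each beating parameter are
modelled with a linear mixed model

    y = mu + beta * 1[vehicle] + u_donor + u_plate + eps,

with crossed random intercepts for donor and plate and a fixed
media-vs-vehicle contrast.  Variance components are estimated by
restricted maximum likelihood, profiled over the two variance ratios
(donor and plate variance over residual variance): for a candidate ratio
pair the GLS solution for (mu, beta) and the profiled residual variance
are closed-form via the Woodbury identity, leaving a cheap bounded 2-D
optimisation.  The vehicle contrast is converted to a variance share as
the design-weighted variance p(1-p) beta^2 of the fitted term, so the
decomposition reads donor / plate / vehicle / residual, as fractions of
their sum and as CVs about the grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "fit_varcomp",
    "baseline_observations",
    "cv_table",
    "endpoint_correlation",
    "compare_batches",
    "restricted_loglik",
]

logger = logging.getLogger(__name__)

COMPONENT_ORDER = ("donor", "plate", "vehicle", "other")


@dataclass
class VarianceComponents:
    """Decomposition of one endpoint's baseline variability."""

    endpoint: str
    mu: float
    beta_vehicle: float
    var_donor: float
    var_plate: float
    var_vehicle: float
    var_resid: float
    n_obs: int
    n_donors: int
    n_plates: int
    loglik: float

    @property
    def var_total(self) -> float:
        return self.var_donor + self.var_plate + self.var_vehicle + self.var_resid

    def cv(self, component: str) -> float:
        var = {
            "donor": self.var_donor,
            "plate": self.var_plate,
            "vehicle": self.var_vehicle,
            "other": self.var_resid,
            "total": self.var_total,
        }[component]
        return float(np.sqrt(var) / self.mu)

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.var_total
        return {
            "donor": self.var_donor / tot,
            "plate": self.var_plate / tot,
            "vehicle": self.var_vehicle / tot,
            "other": self.var_resid / tot,
        }

    def as_dict(self) -> dict:
        d = {
            "endpoint": self.endpoint,
            "mu": self.mu,
            "beta_vehicle": self.beta_vehicle,
            "var_donor": self.var_donor,
            "var_plate": self.var_plate,
            "var_vehicle": self.var_vehicle,
            "var_resid": self.var_resid,
            "cv_donor": self.cv("donor"),
            "cv_plate": self.cv("plate"),
            "cv_vehicle": self.cv("vehicle"),
            "cv_other": self.cv("other"),
            "cv_total": self.cv("total"),
            "n_obs": self.n_obs,
        }
        d.update({f"frac_{k}": v for k, v in self.fractions.items()})
        return d


def _design(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    donors = pd.Categorical(obs["donor_id"])
    plates = pd.Categorical(obs["plate_id"])
    n = len(obs)
    z_d = np.zeros((n, len(donors.categories)))
    z_d[np.arange(n), donors.codes] = 1.0
    z_p = np.zeros((n, len(plates.categories)))
    z_p[np.arange(n), plates.codes] = 1.0
    x = np.column_stack([np.ones(n), obs["is_vehicle"].to_numpy(dtype=float)])
    y = obs["value"].to_numpy(dtype=float)
    return y, x, z_d, z_p


def restricted_loglik(
    theta: tuple[float, float],
    y: np.ndarray,
    x: np.ndarray,
    z_d: np.ndarray,
    z_p: np.ndarray,
) -> tuple[float, np.ndarray, float]:
    """Profiled restricted log-likelihood at variance ratios ``theta``.

    ``theta`` holds (var_donor/var_resid, var_plate/var_resid).  Returns
    (loglik, GLS fixed effects, profiled residual variance).  The
    covariance W = I + theta_d Z_d Z_d' + theta_p Z_p Z_p' is handled via
    the Woodbury identity on the low-rank factor U = [Z_d, Z_p] sqrt(theta).
    """
    th_d, th_p = max(theta[0], 0.0), max(theta[1], 0.0)
    n, p = x.shape
    u = np.hstack([z_d * np.sqrt(th_d), z_p * np.sqrt(th_p)])
    m = np.eye(u.shape[1]) + u.T @ u
    cho = np.linalg.cholesky(m)
    logdet_w = 2.0 * float(np.sum(np.log(np.diag(cho))))

    def w_solve(b: np.ndarray) -> np.ndarray:
        ub = u.T @ b
        return b - u @ np.linalg.solve(cho.T, np.linalg.solve(cho, ub))

    wy = w_solve(y)
    wx = w_solve(x)
    xtwx = x.T @ wx
    xtwy = x.T @ wy
    beta = np.linalg.solve(xtwx, xtwy)
    rss = float(y @ wy - beta @ xtwy)
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
        + logdet_w
        + np.linalg.slogdet(xtwx)[1]
    )
    return float(ll), beta, sigma2


def fit_varcomp(obs: pd.DataFrame, endpoint: str = "value") -> VarianceComponents:
    """REML decomposition of one endpoint's control-well variability.

    ``obs`` needs columns donor_id, plate_id, is_vehicle and value; rows
    with undefined values (quiescent wells) are dropped with a logged
    count.  Requires at least two donors, two plates, and both media and
    vehicle wells.  Negative variance estimates are truncated at zero by
    the bounded optimiser.
    """
    obs = obs[["donor_id", "plate_id", "is_vehicle", "value"]].copy()
    n_in = len(obs)
    obs = obs.dropna(subset=["value"])
    if n_in - len(obs):
        logger.warning("%s: dropped %d undefined observations", endpoint, n_in - len(obs))
    n_donors = obs["donor_id"].nunique()
    n_plates = obs["plate_id"].nunique()
    if n_donors < 2:
        raise ValueError(f"{endpoint}: need >=2 donors, got {n_donors}")
    if n_plates < 2:
        raise ValueError(f"{endpoint}: need >=2 plates, got {n_plates}")
    veh = obs["is_vehicle"].astype(bool)
    if veh.all() or (~veh).all():
        raise ValueError(f"{endpoint}: need both media and vehicle control wells")

    y, x, z_d, z_p = _design(obs)

    def neg_ll(log_theta: np.ndarray) -> float:
        theta = np.clip(np.expm1(log_theta), 0.0, 1e7)
        try:
            return -restricted_loglik(tuple(theta), y, x, z_d, z_p)[0]
        except np.linalg.LinAlgError:
            return np.inf

    # moment-based starting values for the variance ratios
    resid_guess = float(obs.groupby(["donor_id", "plate_id"])["value"].var().mean()) or 1.0
    donor_guess = float(obs.groupby("donor_id")["value"].mean().var())
    plate_guess = float(obs.groupby("plate_id")["value"].mean().var())
    starts = [
        (donor_guess / resid_guess, plate_guess / resid_guess),
        (1.0, 1.0),
        (10.0, 0.1),
    ]
    best = None
    for s in starts:
        x0 = np.log1p(np.clip(s, 0.0, 1e6))
        res = optimize.minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # restart from the optimum with a fresh simplex to polish convergence
    best = optimize.minimize(
        neg_ll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
    )
    theta = np.clip(np.expm1(best.x), 0.0, 1e7)
    ll, beta, sigma2 = restricted_loglik(tuple(theta), y, x, z_d, z_p)

    p_veh = float(veh.mean())
    mu = float(beta[0] + p_veh * beta[1])
    return VarianceComponents(
        endpoint=endpoint,
        mu=mu,
        beta_vehicle=float(beta[1]),
        var_donor=float(theta[0] * sigma2),
        var_plate=float(theta[1] * sigma2),
        var_vehicle=float(p_veh * (1 - p_veh) * beta[1] ** 2),
        var_resid=float(sigma2),
        n_obs=len(obs),
        n_donors=n_donors,
        n_plates=n_plates,
        loglik=ll,
    )


def baseline_observations(
    params: pd.DataFrame, wells: pd.DataFrame, endpoint: str
) -> pd.DataFrame:
    """Join beat parameters with the plate map and keep control wells."""
    df = params.merge(wells, on="well_id", validate="one_to_one")
    df = df[df["treatment"].isin(["media", "vehicle"])]
    return pd.DataFrame({
        "donor_id": df["donor_id"],
        "plate_id": df["plate_id"],
        "is_vehicle": df["treatment"].eq("vehicle"),
        "value": df[endpoint],
    })


def cv_table(components: dict[str, VarianceComponents]) -> pd.DataFrame:
    """Tidy per-endpoint summary: CVs plus stacked-bar variance fractions."""
    if not components:
        raise ValueError("no fitted endpoints")
    rows = [vc.as_dict() for vc in components.values()]
    cols = [
        "endpoint", "mu", "cv_donor", "cv_plate", "cv_vehicle", "cv_other",
        "cv_total", "frac_donor", "frac_plate", "frac_vehicle", "frac_other",
        "n_obs",
    ]
    return pd.DataFrame(rows)[cols]


def endpoint_correlation(
    params: pd.DataFrame, endpoint_a: str, endpoint_b: str
) -> float:
    """Pearson correlation of two per-well endpoints across baseline wells."""
    df = params[[endpoint_a, endpoint_b]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired observations")
    return float(stats.pearsonr(df[endpoint_a], df[endpoint_b])[0])


def compare_batches(
    params_batch1: pd.DataFrame,
    params_batch2: pd.DataFrame,
    endpoints: tuple = ("bpm", "amp_mean", "decay_rise_ratio"),
) -> pd.DataFrame:
    """Batch-to-batch concordance of donor-level baseline phenotypes.

    Both inputs need donor_id plus endpoint columns (one row per well).
    Per endpoint: Spearman rank correlation of per-donor means across the
    shared donors — the rank-stability statistic behind the observation
    that slow- and fast-beating donors keep their ordering between
    experiments run months apart — plus the mean per-donor difference.
    """
    shared = sorted(set(params_batch1["donor_id"]) & set(params_batch2["donor_id"]))
    if len(shared) < 3:
        raise ValueError("need >=3 donors shared between batches")
    rows = []
    for ep in endpoints:
        m1 = params_batch1.groupby("donor_id")[ep].mean().loc[shared]
        m2 = params_batch2.groupby("donor_id")[ep].mean().loc[shared]
        ok = m1.notna() & m2.notna()
        if ok.sum() < 3:
            raise ValueError(f"{ep}: fewer than 3 donors with defined values in both batches")
        m1, m2 = m1[ok], m2[ok]
        rho = float(stats.spearmanr(m1, m2)[0])
        rows.append({
            "endpoint": ep,
            "spearman_rho": rho,
            "n_donors": int(ok.sum()),
            "mean_abs_rel_diff": float(np.mean(np.abs(m2 - m1) / m1)),
        })
    return pd.DataFrame(rows)
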