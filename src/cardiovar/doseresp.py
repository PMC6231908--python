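"""Nonlinear mixed-effects concentration-response modelling.

Treated responses are first normalized to each donor's median vehicle
control, anchoring every curve at 1, and then fitted with one of three
model forms (concentration x in uM, natural logarithms):

``PRO2``
    Two-parameter decreasing log-logistic for a negative inotrope's effect
    on beat rate, upper asymptote 1 and lower asymptote 0:
    y = 1 / (1 + exp((ln x - lnEC50) / scale)).  lnEC50 carries the donor
    random effect; the scale (inverse Hill slope) is a shared fixed effect.

``ISO_EMAX``
    Saturated maximal-effect form for a positive inotrope already at full
    effect at the lowest tested concentration; the EC50 is pinned to a
    nominal 0.001 uM and the scale to 1:
    y = 1 + (B - 1) / (1 + exp(ln 0.001 - ln x)).  B carries the donor
    random effect.

``CIS_LOG_EMAX``
    The same saturated form on the natural-log response scale, used for
    the decay/rise ratio under hERG block:
    ln y = (B - 1) / (1 + exp(ln 0.001 - ln x)).

Two estimation routes are provided: ``two_stage`` (per-donor nonlinear
least squares, population mean/SD of the per-donor estimates — for PRO2
the shared scale is estimated jointly across donors) and ``laplace`` (a
marginal-likelihood nonlinear mixed-effects fit with a Gaussian random
effect, Laplace-approximated; exact for the two forms that are linear in
the random effect).  Inter-individual sensitivity is summarized as the
percent change from control at a nominal concentration, conventionally
1 uM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .trace_sim import COMPOUNDS, EC50_SATURATED

__all__ = [
    "ModelSpec",
    "DoseResponseFit",
    "VariabilitySummary",
    "model_for_compound",
    "normalize_to_control",
    "apply_drop_rule",
    "fit_model",
    "predict_change_at",
    "summarize_variability",
]

logger = logging.getLogger(__name__)

#: concentration (uM) whose treated wells are excluded for ISO and PRO:
#: widespread quiescence and cytotoxicity there preclude curve fitting
DROP_CONC = 100.0
DROP_COMPOUNDS = ("ISO", "PRO")
#: nominal concentration (uM) at which inter-donor sensitivity is compared
NOMINAL_CONC = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """One of the three concentration-response model forms."""

    form: str  # PRO2 | ISO_EMAX | CIS_LOG_EMAX
    endpoint: str
    ec50_fixed: float = EC50_SATURATED
    scale_fixed: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("PRO2", "ISO_EMAX", "CIS_LOG_EMAX"):
            raise ValueError(f"unknown model form {self.form!r}")

    @property
    def random_effect(self) -> str:
        return "lnEC50" if self.form == "PRO2" else "B"


def model_for_compound(compound: str) -> ModelSpec:
    """The prototypical endpoint and model form for a reference compound."""
    return {
        "ISO": ModelSpec(form="ISO_EMAX", endpoint="bpm"),
        "PRO": ModelSpec(form="PRO2", endpoint="bpm"),
        "CIS": ModelSpec(form="CIS_LOG_EMAX", endpoint="decay_rise_ratio"),
    }[compound]


def _saturated_gate(x: np.ndarray, ec50: float) -> np.ndarray:
    # 1 / (1 + exp(ln ec50 - ln x)), written without logs for x > 0
    return 1.0 / (1.0 + ec50 / x)


def pro2_mean(x: np.ndarray, lnec50: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((np.log(x) - lnec50) / scale))


def iso_emax_mean(x: np.ndarray, B: float, ec50: float = EC50_SATURATED) -> np.ndarray:
    return 1.0 + (B - 1.0) * _saturated_gate(x, ec50)


def cis_log_emax_mean(x: np.ndarray, B: float, ec50: float = EC50_SATURATED) -> np.ndarray:
    """Mean of ln(normalized decay/rise ratio)."""
    return (B - 1.0) * _saturated_gate(x, ec50)


@dataclass
class DoseResponseFit:
    spec: ModelSpec
    method: str
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    ranef_sd: float
    resid_sd: float
    per_donor: pd.DataFrame  # donor_id, estimate, n_obs
    dropped: dict[str, int] = field(default_factory=dict)

    def donor_params(self) -> pd.Series:
        return self.per_donor.set_index("donor_id")["estimate"]


@dataclass
class VariabilitySummary:
    endpoint: str
    concentration: float
    per_donor_change: pd.Series  # % change per donor
    minimum: float
    maximum: float
    median: float
    interval95: tuple[float, float]


def normalize_to_control(
    params: pd.DataFrame,
    wells: pd.DataFrame,
    endpoint: str,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Divide each well's endpoint by its donor's median vehicle value.

    Returns a tidy response table (donor_id, compound, concentration,
    endpoint_name, normalized_value, quiescent).  The reference is taken
    within each donor's plate where possible, so plate-level technical
    shifts cancel exactly instead of leaving the pooled control median
    straddling two plate modes; a donor-level median is the fallback for
    plates without controls.  Quiescent wells are carried with their flag
    and an undefined value; they are excluded from fitting but reported.
    A donor without a usable vehicle well is an error naming the donor,
    or is dropped with a warning when ``on_missing="drop"`` (the pipeline
    default, since e.g. a fast-beating donor may have no resolvable
    decay/rise ratio in any control well).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    df = params.merge(wells, on="well_id", validate="one_to_one")
    out_rows = []
    for donor, grp in df.groupby("donor_id", sort=True):
        usable = grp[grp["treatment"].eq("vehicle") & ~grp["quiescent"]][endpoint].dropna()
        if usable.empty:
            if on_missing == "drop":
                logger.warning(
                    "donor %s: no usable vehicle control wells for %s; excluded",
                    donor, endpoint,
                )
                continue
            raise ValueError(f"donor {donor}: no usable vehicle control wells for {endpoint}")
        donor_ref = float(usable.median())
        for plate, sub in grp.groupby("plate_id", sort=True):
            veh = sub[sub["treatment"].eq("vehicle") & ~sub["quiescent"]][endpoint].dropna()
            ref = float(veh.median()) if len(veh) else donor_ref
            for _, row in sub.iterrows():
                out_rows.append({
                    "donor_id": donor,
                    "well_id": row["well_id"],
                    "plate_id": plate,
                    "treatment": row["treatment"],
                    "compound": row["compound"] if row["compound"] else None,
                    "concentration": row["conc_uM"],
                    "endpoint_name": endpoint,
                    "normalized_value": row[endpoint] / ref,
                    "quiescent": bool(row["quiescent"]),
                })
    return pd.DataFrame(out_rows)


def apply_drop_rule(table: pd.DataFrame, compound: str) -> pd.DataFrame:
    """Remove the 100 uM group for the inotropes (ISO, PRO).

    At that concentration most wells fall silent and viability drops, so
    the group carries no usable concentration-response information; all
    concentrations are kept for CIS.
    """
    if compound not in COMPOUNDS:
        raise ValueError(f"unknown compound {compound!r}")
    if compound not in DROP_COMPOUNDS:
        return table
    drop = table["compound"].eq(compound) & np.isclose(
        table["concentration"].astype(float).fillna(-1.0), DROP_CONC
    )
    if int(drop.sum()):
        logger.warning("%s: dropped %d wells at %g uM", compound, int(drop.sum()), DROP_CONC)
    out = table[~drop].copy()
    out.attrs["dropped_100uM"] = int(drop.sum())
    return out


def _fit_rows(spec: ModelSpec, table: pd.DataFrame) -> pd.DataFrame:
    rows = table[
        table["compound"].notna()
        & ~table["quiescent"]
        & table["normalized_value"].notna()
        & (table["normalized_value"] > 0)
    ].copy()
    if rows.empty:
        raise ValueError("no usable treated observations")
    return rows


def _two_stage(spec: ModelSpec, rows: pd.DataFrame) -> DoseResponseFit:
    donors = sorted(rows["donor_id"].unique())
    x_all = rows["concentration"].to_numpy(dtype=float)
    y_all = rows["normalized_value"].to_numpy(dtype=float)

    if spec.form in ("ISO_EMAX", "CIS_LOG_EMAX"):
        # linear in (B - 1) given the fixed saturated gate: closed form
        estimates, resid_sq, n_res = [], 0.0, 0
        for donor in donors:
            m = rows["donor_id"].eq(donor).to_numpy()
            g = _saturated_gate(x_all[m], spec.ec50_fixed)
            z = y_all[m] - 1.0 if spec.form == "ISO_EMAX" else np.log(y_all[m])
            b1 = float(g @ z / (g @ g))
            estimates.append(1.0 + b1)
            r = z - b1 * g
            resid_sq += float(r @ r)
            n_res += len(r) - 1
        fixed = {"B": float(np.mean(estimates))}
        fixed_se = {"B": float(np.std(estimates, ddof=1) / np.sqrt(len(estimates))) if len(estimates) > 1 else np.nan}
        ranef_sd = float(np.std(estimates, ddof=1)) if len(estimates) > 1 else 0.0
        shared = {}
    else:  # PRO2: per-donor lnEC50 with one shared scale, fitted jointly
        codes = pd.Categorical(rows["donor_id"], categories=donors).codes

        def residuals(p: np.ndarray) -> np.ndarray:
            scale = np.exp(p[0])
            lnec = p[1:]
            return pro2_mean(x_all, lnec[codes], scale) - y_all

        ln_ec0 = []
        for donor in donors:
            m = rows["donor_id"].eq(donor).to_numpy()
            # crude per-donor start: concentration nearest half-effect
            k = int(np.argmin(np.abs(y_all[m] - 0.5)))
            ln_ec0.append(np.log(x_all[m][k]))
        p0 = np.concatenate([[0.0], ln_ec0])
        sol = optimize.least_squares(residuals, p0, method="lm", xtol=1e-14, ftol=1e-14)
        estimates = list(sol.x[1:])
        scale = float(np.exp(sol.x[0]))
        r = sol.fun
        resid_sq, n_res = float(r @ r), len(r) - len(sol.x)
        fixed = {"lnEC50": float(np.mean(estimates))}
        fixed_se = {"lnEC50": float(np.std(estimates, ddof=1) / np.sqrt(len(estimates))) if len(estimates) > 1 else np.nan}
        ranef_sd = float(np.std(estimates, ddof=1)) if len(estimates) > 1 else 0.0
        shared = {"scale": scale}

    per_donor = pd.DataFrame({
        "donor_id": donors,
        "estimate": estimates,
        "n_obs": [int(rows["donor_id"].eq(d).sum()) for d in donors],
    })
    fixed.update(shared)
    return DoseResponseFit(
        spec=spec,
        method="two_stage",
        fixed_effects=fixed,
        fixed_se=fixed_se,
        ranef_sd=ranef_sd,
        resid_sd=float(np.sqrt(resid_sq / max(n_res, 1))),
        per_donor=per_donor,
    )


def _laplace(spec: ModelSpec, rows: pd.DataFrame) -> DoseResponseFit:
    """Marginal-likelihood NLME fit with a Gaussian random effect.

    The per-donor integral over the random effect is Laplace-approximated
    around the penalized-least-squares mode (exact for ISO_EMAX and
    CIS_LOG_EMAX, which are linear in the random effect).  Starts from the
    two-stage solution.
    """
    start = _two_stage(spec, rows)
    donors = list(start.per_donor["donor_id"])
    groups = [
        (
            rows.loc[rows["donor_id"].eq(d), "concentration"].to_numpy(dtype=float),
            rows.loc[rows["donor_id"].eq(d), "normalized_value"].to_numpy(dtype=float),
        )
        for d in donors
    ]

    def donor_response(x: np.ndarray, y: np.ndarray, b: float, extra: dict) -> np.ndarray:
        if spec.form == "ISO_EMAX":
            return y - iso_emax_mean(x, b, spec.ec50_fixed)
        if spec.form == "CIS_LOG_EMAX":
            return np.log(y) - cis_log_emax_mean(x, b, spec.ec50_fixed)
        return y - pro2_mean(x, b, extra["scale"])

    re_name = spec.random_effect
    mu0 = start.fixed_effects[re_name]
    omega0 = max(start.ranef_sd, 1e-3)
    sigma0 = max(start.resid_sd, 1e-4)
    has_scale = spec.form == "PRO2"
    scale0 = start.fixed_effects.get("scale", 1.0)

    def unpack(p):
        mu, lw, ls = p[0], p[1], p[2]
        extra = {"scale": float(np.exp(p[3]))} if has_scale else {}
        return mu, float(np.exp(lw)), float(np.exp(ls)), extra

    def neg_marginal(p: np.ndarray) -> float:
        mu, omega, sigma, extra = unpack(p)
        total = 0.0
        for x, y in groups:
            def h(b: float) -> float:
                r = donor_response(x, y, b, extra)
                return float(r @ r) / (2 * sigma**2) + (b - mu) ** 2 / (2 * omega**2)

            bhat = optimize.minimize_scalar(
                h, bounds=(mu - 10 * omega - 1.0, mu + 10 * omega + 1.0),
                method="bounded", options={"xatol": 1e-10},
            ).x
            eps = 1e-4 * max(abs(bhat), 1.0)
            hess = (h(bhat + eps) - 2 * h(bhat) + h(bhat - eps)) / eps**2
            hess = max(hess, 1e-12)
            n_i = len(y)
            total += (
                h(bhat)
                + 0.5 * np.log(hess)
                + n_i * np.log(sigma)
                + np.log(omega)
            )
        return total

    p0 = [mu0, np.log(omega0), np.log(sigma0)] + ([np.log(scale0)] if has_scale else [])
    sol = optimize.minimize(
        neg_marginal, np.asarray(p0), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    mu, omega, sigma, extra = unpack(sol.x)

    # empirical Bayes modes at the optimum
    modes = []
    for x, y in groups:
        def h(b: float) -> float:
            r = donor_response(x, y, b, extra)
            return float(r @ r) / (2 * sigma**2) + (b - mu) ** 2 / (2 * omega**2)

        modes.append(float(optimize.minimize_scalar(
            h, bounds=(mu - 10 * omega - 1.0, mu + 10 * omega + 1.0),
            method="bounded", options={"xatol": 1e-10},
        ).x))

    fixed = {re_name: mu}
    fixed.update(extra)
    per_donor = start.per_donor.copy()
    per_donor["estimate"] = modes
    return DoseResponseFit(
        spec=spec,
        method="laplace",
        fixed_effects=fixed,
        fixed_se={re_name: omega / np.sqrt(len(donors))},
        ranef_sd=omega,
        resid_sd=sigma,
        per_donor=per_donor,
        dropped=start.dropped,
    )


def fit_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    method: str = "two_stage",
) -> DoseResponseFit:
    """Fit one concentration-response model to a normalized response table.

    ``table`` is the output of :func:`normalize_to_control` (after
    :func:`apply_drop_rule`); only non-quiescent treated wells enter the
    fit.  ``method`` selects the two-stage or Laplace NLME route.
    """
    rows = _fit_rows(spec, table)
    n_quiescent = int((table["compound"].notna() & table["quiescent"]).sum())
    per_conc = rows.groupby("donor_id")["concentration"].nunique()
    thin = per_conc[per_conc < 2]
    if len(thin):
        raise ValueError(
            f"donors with <2 concentrations after exclusions: {', '.join(thin.index)}"
        )
    if method == "two_stage":
        fit = _two_stage(spec, rows)
    elif method == "laplace":
        fit = _laplace(spec, rows)
    else:
        raise ValueError(f"unknown method {method!r}")
    fit.dropped = {
        "quiescent_wells": n_quiescent,
        "dropped_100uM": int(table.attrs.get("dropped_100uM", 0)),
    }
    if n_quiescent:
        logger.warning("%s: %d quiescent treated wells excluded", spec.form, n_quiescent)
    return fit


def _change_at(spec: ModelSpec, param: float, scale: float, x: float) -> float:
    if spec.form == "ISO_EMAX":
        return 100.0 * (iso_emax_mean(np.asarray(x), param, spec.ec50_fixed) - 1.0)
    if spec.form == "CIS_LOG_EMAX":
        return 100.0 * (np.exp(cis_log_emax_mean(np.asarray(x), param, spec.ec50_fixed)) - 1.0)
    return 100.0 * (pro2_mean(np.asarray(x), param, scale) - 1.0)


def predict_change_at(fit: DoseResponseFit, concentration: float = NOMINAL_CONC) -> pd.Series:
    """Per-donor percent change from control at the given concentration."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    scale = fit.fixed_effects.get("scale", fit.spec.scale_fixed)
    return fit.donor_params().map(
        lambda p: float(_change_at(fit.spec, p, scale, concentration))
    )


def summarize_variability(
    fit: DoseResponseFit, concentration: float = NOMINAL_CONC
) -> VariabilitySummary:
    """Population spread of per-donor percent change at a concentration.

    The 95% interval maps the +-1.96 SD band of the Gaussian random effect
    through the model's prediction at the nominal concentration.
    """
    change = predict_change_at(fit, concentration)
    if len(change) < 2:
        raise ValueError("need >=2 fitted donors")
    scale = fit.fixed_effects.get("scale", fit.spec.scale_fixed)
    mu = fit.fixed_effects[fit.spec.random_effect]
    lo_p, hi_p = mu - 1.96 * fit.ranef_sd, mu + 1.96 * fit.ranef_sd
    band = sorted([
        _change_at(fit.spec, lo_p, scale, concentration),
        _change_at(fit.spec, hi_p, scale, concentration),
    ])
    return VariabilitySummary(
        endpoint=fit.spec.endpoint,
        concentration=concentration,
        per_donor_change=change,
        minimum=float(change.min()),
        maximum=float(change.max()),
        median=float(change.median()),
        interval95=(float(band[0]), float(band[1])),
    )
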