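"""Sequential weighted-least-squares estimation on naively pooled data.

The estimation workflow mirrors how the model was originally fitted:

1. ``fit_pk`` — the one-compartment PK model is fitted simultaneously to the
   pooled drug concentrations of all dose groups (linear kinetics, one shared
   parameter set).
2. ``fit_pd`` — with the PK parameters fixed, the four cytokine pathways are
   fitted jointly (shared mean transit time τ, Imax fixed to 1, baselines R0
   fixed to healthy-animal means, every kin derived from kin = R0·kout).
3. ``fit_disease`` — with PK and PD fixed, the six ALT/AST turnover
   parameters are estimated (α = β = 1.5 stay fixed).

Naïve pooling: every animal-level observation enters one objective — with
destructive sampling each animal contributes a single observation per
analyte, so per-animal effects are not estimable anyway.

The WLS objective is ``Σ wᵢ (yᵢ − ŷᵢ)²`` with prediction-based weights
``wᵢ = 1/max(ŷᵢ, ε)^(2·weight_exponent)``; the default ``weight_exponent=1``
gives relative (1/ŷ²) weighting.  Optimization runs in log-parameter space
(bounded trust-region least squares), which handles the five-orders-of-
magnitude spread of the parameter values and enforces positivity natively.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    DomainError,
    IdentifiabilityError,
    ModelParameters,
    PKParameters,
    SchemaError,
    observable_index,
    pk_concentration,
)
from .simulate import states_at

__all__ = [
    "FitResult",
    "wls_objective",
    "fit_pk",
    "fit_pd",
    "fit_disease",
    "fit_sequential",
    "information_criteria",
    "estimate_cv",
    "baselines_from_table",
    "PD_PARAMETER_NAMES",
    "DISEASE_PARAMETER_NAMES",
]

PK_PARAMETER_NAMES = ("Vd_F", "ka", "ke")
PD_PARAMETER_NAMES = (
    "tau",
    "kout_TNFa", "kout_IFNg", "kout_IL6", "kout_IL10",
    "IC50_TNFa", "IC50_IFNg", "IC50_IL6",
    "S_TNFa", "S_IFNg", "S_IL6", "S_IL10",
    "kin_IL10_dis", "I_IL10_IFNg",
)
DISEASE_PARAMETER_NAMES = (
    "S_ALT_TNFa", "S_ALT_IFNg", "kout_ALT",
    "S_AST_TNFa", "S_AST_IFNg", "kout_AST",
)

_CYTOKINES = ("TNFa", "IFNg", "IL6", "IL10")
_TRANSAMINASES = ("ALT", "AST")
_EPS = 1e-8


@dataclass(frozen=True)
class FitResult:
    """Estimates with precision and goodness-of-fit metrics for one stage."""

    estimates: dict[str, float]
    cv_percent: dict[str, float | None]
    objective: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    fixed: tuple[str, ...] = ()
    unidentifiable: tuple[str, ...] = ()
    residual_fn: Callable | None = field(default=None, repr=False, compare=False)

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": 1,
            "estimates": self.estimates,
            "cv_percent": self.cv_percent,
            "objective": self.objective,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "fixed": list(self.fixed),
            "unidentifiable": list(self.unidentifiable),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            estimates=payload["estimates"], cv_percent=payload["cv_percent"],
            objective=payload["objective"], aic=payload["aic"], bic=payload["bic"],
            n_obs=payload["n_obs"], converged=payload["converged"],
            fixed=tuple(payload.get("fixed", ())),
            unidentifiable=tuple(payload.get("unidentifiable", ())),
        )


# ---------------------------------------------------------------------------
# Predictions and the WLS objective
# ---------------------------------------------------------------------------

def _predictions(params: ModelParameters, data: pd.DataFrame,
                 rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Model predictions aligned with the rows of an observation table.

    Drug rows use the closed-form concentration; biomarker rows come from one
    integration per (dose, ConA) group at that group's sampling times.
    """
    yhat = np.empty(len(data))
    pos = {row: i for i, row in enumerate(data.index)}

    drug = data["analyte"] == "GRMS55"
    if drug.any():
        sub = data[drug]
        c = np.empty(len(sub))
        for dose, dsub in sub.groupby("dose_mg_per_kg"):
            c_vals = pk_concentration(dsub["time_h"].to_numpy(), float(dose), params.pk)
            for row, v in zip(dsub.index, np.atleast_1d(c_vals)):
                yhat[pos[row]] = v

    bio = data[~drug]
    for analyte in bio["analyte"].unique():
        observable_index(analyte)  # schema check: raises on unknown analytes
    for (dose, cona), sub in bio.groupby(["dose_mg_per_kg", "cona"]):
        times = np.unique(sub["time_h"].to_numpy())
        states = states_at(params, float(dose), times, cona=bool(cona),
                           rtol=rtol, atol=atol)
        time_pos = {t: j for j, t in enumerate(times)}
        for row in sub.itertuples():
            idx = observable_index(row.analyte)
            yhat[pos[row.Index]] = states[idx, time_pos[row.time_h]]
    return yhat


def _weighted_residuals(y, yhat, weight_exponent):
    scale = np.maximum(np.abs(yhat), _EPS) ** weight_exponent
    return (y - yhat) / scale


def wls_objective(params: ModelParameters, data: pd.DataFrame,
                  weight_exponent: float = 1.0, *,
                  rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Weighted least-squares objective Σ wᵢ(yᵢ−ŷᵢ)², wᵢ = 1/max(ŷᵢ,ε)^(2·we)."""
    yhat = _predictions(params, data, rtol=rtol, atol=atol)
    r = _weighted_residuals(data["value"].to_numpy(), yhat, weight_exponent)
    return float(np.dot(r, r))


def information_criteria(objective: float, n_obs: int, n_params: int) -> tuple[float, float]:
    """(AIC, BIC) under the least-squares convention.

    ``AIC = n·ln(WSS/n) + 2p`` and ``BIC = n·ln(WSS/n) + p·ln n``, where WSS
    is the weighted sum of squares.  WSS is floored at a tiny positive value
    so that exact-fit (WSS = 0) data yield finite criteria.
    """
    if n_params < 1 or n_obs <= n_params:
        raise DomainError(f"need n_obs > n_params >= 1, got n_obs={n_obs}, n_params={n_params}")
    if objective < 0:
        raise DomainError(f"objective must be >= 0, got {objective!r}")
    wss = max(objective, 1e-300)
    base = n_obs * math.log(wss / n_obs)
    return base + 2 * n_params, base + n_params * math.log(n_obs)


# ---------------------------------------------------------------------------
# Core bounded log-space WLS driver
# ---------------------------------------------------------------------------

def _fit_wls_core(
    residual_fn: Callable[[dict[str, float]], np.ndarray],
    init: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None,
    *,
    n_obs: int,
    fixed: tuple[str, ...] = (),
    unidentifiable: tuple[str, ...] = (),
    n_starts: int = 0,
    seed: int | None = None,
    xtol: float = 1e-10,
    ftol: float = 1e-12,
) -> FitResult:
    names = list(init)
    for name, value in init.items():
        if not (value > 0):
            raise DomainError(f"initial value for {name} must be > 0, got {value!r}")
    x0 = np.log(np.array([init[n] for n in names]))
    lb = np.empty(len(names))
    ub = np.empty(len(names))
    for i, name in enumerate(names):
        lo, hi = (bounds or {}).get(name, (init[name] / 100.0, init[name] * 100.0))
        if not (0 < lo < hi):
            raise DomainError(f"invalid bounds for {name}: ({lo}, {hi})")
        lb[i], ub[i] = math.log(lo), math.log(hi)
    x0 = np.clip(x0, lb, ub)

    def fun(x):
        return residual_fn(dict(zip(names, np.exp(x))))

    def solve(x_start):
        return least_squares(
            fun, x_start, bounds=(lb, ub), method="trf",
            x_scale="jac", diff_step=1e-6, xtol=xtol, ftol=ftol, gtol=1e-12,
        )

    best = solve(x0)
    if n_starts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts):
            perturbed = np.clip(x0 + rng.uniform(np.log(0.5), np.log(1.5), len(names)), lb, ub)
            trial = solve(perturbed)
            if trial.cost < best.cost:
                best = trial

    estimates = dict(zip(names, np.exp(best.x)))
    objective = float(2.0 * best.cost)  # least_squares cost is 0.5 * sum r^2
    p = len(names)
    if n_obs > p:
        aic, bic = information_criteria(objective, n_obs, p)
    else:
        aic = bic = float("nan")
    cv = _cv_from_jacobian(best.jac, objective, n_obs, p, names)
    return FitResult(
        estimates=estimates, cv_percent=cv, objective=objective,
        aic=aic, bic=bic, n_obs=n_obs, converged=bool(best.status > 0),
        fixed=tuple(fixed), unidentifiable=tuple(unidentifiable),
        residual_fn=residual_fn,
    )


def _cv_from_jacobian(jac, objective, n_obs, n_params, names) -> dict[str, float | None]:
    """Asymptotic CV% from the Gauss–Newton curvature in log-parameter space.

    In log space the standard error of ln(p) is the relative standard error of
    p, so CV% = 100·SE(ln p).  Singular curvature yields ``None`` for the
    parameters whose variance is not resolved.
    """
    jac = np.asarray(jac)
    if n_obs <= n_params:
        return {n: None for n in names}
    s2 = objective / (n_obs - n_params)
    jtj = jac.T @ jac
    cv: dict[str, float | None] = {}
    try:
        cov = s2 * np.linalg.pinv(jtj)
        rank = np.linalg.matrix_rank(jtj)
    except np.linalg.LinAlgError:
        return {n: None for n in names}
    diag = np.diag(cov)
    for i, name in enumerate(names):
        var = diag[i]
        if not np.isfinite(var) or var < 0 or (rank < n_params and var > 1e8):
            cv[name] = None
        else:
            cv[name] = float(100.0 * math.sqrt(var))
    return cv


def estimate_cv(fit: FitResult, weight_exponent: float = 1.0) -> dict[str, float | None]:
    """Recompute per-parameter CV% at a fit's optimum by finite differences.

    Uses the Gauss–Newton approximation of the objective curvature (the
    cross-product of the weighted-residual Jacobian in log-parameter space).
    """
    if fit.residual_fn is None:
        raise DomainError("fit carries no residual function (e.g. loaded from JSON)")
    if not fit.converged:
        raise DomainError("CV%% is only meaningful for a converged fit")
    names = list(fit.estimates)
    x = np.log(np.array([fit.estimates[n] for n in names]))

    def fun(xv):
        return fit.residual_fn(dict(zip(names, np.exp(xv))))

    r0 = fun(x)
    jac = np.empty((r0.size, x.size))
    h = 1e-6
    for i in range(x.size):
        xp = x.copy()
        xp[i] += h
        jac[:, i] = (fun(xp) - r0) / h
    return _cv_from_jacobian(jac, float(np.dot(r0, r0)), fit.n_obs, len(names), names)


# ---------------------------------------------------------------------------
# Stage 1: pharmacokinetics
# ---------------------------------------------------------------------------

def fit_pk(
    data: pd.DataFrame,
    init: PKParameters | dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    *,
    weight_exponent: float = 1.0,
    n_starts: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit (Vd_F, ka, ke) to pooled drug concentrations across dose groups.

    The Bateman curve is invariant under swapping ka and ke (with Vd/F
    rescaled), so concentration data alone cannot distinguish the flip-flop
    branch from its mirror; the fit converges to the branch selected by the
    initial guess.
    """
    sub = data[data["analyte"] == "GRMS55"]
    if sub.empty:
        raise SchemaError("no GRMS55 rows in data")
    if sub["time_h"].nunique() < 3:
        raise IdentifiabilityError(
            "PK fit needs >= 3 distinct sampling times, got "
            f"{sub['time_h'].nunique()}"
        )
    if init is None:
        init = {"Vd_F": 1.0, "ka": 1.0, "ke": 3.0}
    elif isinstance(init, PKParameters):
        init = {"Vd_F": init.vd_f, "ka": init.ka, "ke": init.ke}

    y = sub["value"].to_numpy()
    times = sub["time_h"].to_numpy()
    doses = sub["dose_mg_per_kg"].to_numpy()

    def residual_fn(values: dict[str, float]) -> np.ndarray:
        pk = PKParameters(vd_f=values["Vd_F"], ka=values["ka"], ke=values["ke"])
        yhat = (doses / pk.vd_f) * pk.ka / (pk.ka - pk.ke) \
            * (np.exp(-pk.ke * times) - np.exp(-pk.ka * times)) \
            if not math.isclose(pk.ka, pk.ke, rel_tol=1e-12) \
            else (doses / pk.vd_f) * pk.ka * times * np.exp(-pk.ka * times)
        return _weighted_residuals(y, yhat, weight_exponent)

    return _fit_wls_core(residual_fn, init, bounds, n_obs=len(sub),
                         n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# Stage 2: cytokine pharmacodynamics
# ---------------------------------------------------------------------------

def _template_parameters(values: dict[str, float], baselines: dict[str, float],
                         fixed_pk: PKParameters, cona_time: float) -> ModelParameters:
    """Assemble a full parameter vector from stagewise pieces.

    Disease-part slots not under estimation are filled with inert positive
    placeholders (they do not influence PK or cytokine predictions).
    """
    flat = {
        "Vd_F": fixed_pk.vd_f, "ka": fixed_pk.ka, "ke": fixed_pk.ke,
        "cona_time": cona_time,
        "S_ALT_TNFa": 1.0, "S_ALT_IFNg": 1.0, "kout_ALT": 1.0,
        "S_AST_TNFa": 1.0, "S_AST_IFNg": 1.0, "kout_AST": 1.0,
        "R0_ALT": 1.0, "R0_AST": 1.0,
    }
    flat.update(baselines)
    flat.update(values)
    return ModelParameters.from_dict(flat)


_DEFAULT_PD_INIT = {
    "tau": 0.5,
    "kout_TNFa": 0.3, "kout_IFNg": 0.3, "kout_IL6": 0.3, "kout_IL10": 1.0,
    "IC50_TNFa": 10.0, "IC50_IFNg": 10.0, "IC50_IL6": 10.0,
    "S_TNFa": 100.0, "S_IFNg": 1000.0, "S_IL6": 1000.0, "S_IL10": 1.0,
    "kin_IL10_dis": 100.0, "I_IL10_IFNg": 1e-3,
}


def fit_pd(
    data: pd.DataFrame,
    fixed_pk: PKParameters,
    baselines: dict[str, float],
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    *,
    weight_exponent: float = 1.0,
    cona_time: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_starts: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Jointly fit the four cytokine pathways with the PK parameters fixed.

    Estimates τ, the four kout, the three IC50, the four S, kin_IL10_dis and
    I_IL10_IFNg; Imax values are fixed to 1 and every kin derives from the
    baseline constraint.  Without any treated group the IC50s are flagged
    unidentifiable and held at their initial values.
    """
    sub = data[data["analyte"].isin(_CYTOKINES) & data["cona"]]
    if sub.empty:
        raise SchemaError("no post-ConA cytokine rows in data")
    missing = [k for k in ("R0_TNFa", "R0_IFNg", "R0_IL6", "R0_IL10") if k not in baselines]
    if missing:
        raise SchemaError(f"baselines missing {missing}")

    init_all = dict(_DEFAULT_PD_INIT)
    init_all.update(init or {})
    unidentifiable: tuple[str, ...] = ()
    free = list(PD_PARAMETER_NAMES)
    if not (sub["dose_mg_per_kg"] > 0).any():
        unidentifiable = ("IC50_TNFa", "IC50_IFNg", "IC50_IL6")
        free = [n for n in free if n not in unidentifiable]

    held = {n: init_all[n] for n in PD_PARAMETER_NAMES if n not in free}
    y = sub["value"].to_numpy()

    def residual_fn(values: dict[str, float]) -> np.ndarray:
        full = dict(held)
        full.update(values)
        params = _template_parameters(full, baselines, fixed_pk, cona_time)
        yhat = _predictions(params, sub, rtol=rtol, atol=atol)
        return _weighted_residuals(y, yhat, weight_exponent)

    fit = _fit_wls_core(
        residual_fn, {n: init_all[n] for n in free}, bounds, n_obs=len(sub),
        fixed=("Imax_TNFa", "Imax_IFNg", "Imax_IL6") + tuple(baselines),
        unidentifiable=unidentifiable, n_starts=n_starts, seed=seed,
    )
    return fit


# ---------------------------------------------------------------------------
# Stage 3: disease progression
# ---------------------------------------------------------------------------

_DEFAULT_DISEASE_INIT = {
    "S_ALT_TNFa": 0.01, "S_ALT_IFNg": 0.01, "kout_ALT": 0.1,
    "S_AST_TNFa": 0.1, "S_AST_IFNg": 0.01, "kout_AST": 0.1,
}


def fit_disease(
    data: pd.DataFrame,
    fixed_pk_pd: ModelParameters,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    *,
    weight_exponent: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_starts: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit the six ALT/AST turnover parameters with everything upstream fixed.

    ``fixed_pk_pd`` carries the fixed PK and cytokine parameters plus the
    ALT/AST baselines (R0_ALT, R0_AST); α and β stay fixed at their values in
    ``fixed_pk_pd`` (1.5 by default) and are reported under ``fixed``.
    """
    sub = data[data["analyte"].isin(_TRANSAMINASES)]
    if sub.empty:
        raise SchemaError("no ALT/AST rows in data")
    init_all = dict(_DEFAULT_DISEASE_INIT)
    init_all.update(init or {})

    unidentifiable: tuple[str, ...] = ()
    if not sub["cona"].any():
        # without the ConA challenge the cytokines stay at baseline, the
        # transaminases stay constant and no driving force exists
        unidentifiable = ("S_ALT_TNFa", "S_ALT_IFNg", "S_AST_TNFa", "S_AST_IFNg")
    y = sub["value"].to_numpy()

    def residual_fn(values: dict[str, float]) -> np.ndarray:
        params = fixed_pk_pd.with_values(values)
        yhat = _predictions(params, sub, rtol=rtol, atol=atol)
        return _weighted_residuals(y, yhat, weight_exponent)

    return _fit_wls_core(
        residual_fn, {n: init_all[n] for n in DISEASE_PARAMETER_NAMES}, bounds,
        n_obs=len(sub), fixed=("alpha", "beta"),
        unidentifiable=unidentifiable, n_starts=n_starts, seed=seed,
    )


# ---------------------------------------------------------------------------
# Convenience: the full sequential workflow and healthy-animal baselines
# ---------------------------------------------------------------------------

def baselines_from_table(data: pd.DataFrame) -> dict[str, float]:
    """Baseline R0 map from healthy (unchallenged, undosed) animal rows."""
    healthy = data[(~data["cona"]) & (data["dose_mg_per_kg"] == 0)]
    if healthy.empty:
        raise SchemaError("no healthy baseline rows (cona=0, dose=0) in data")
    out = {}
    for analyte, sub in healthy.groupby("analyte"):
        out[f"R0_{analyte}"] = float(sub["value"].mean())
    return out


def fit_sequential(
    data: pd.DataFrame,
    *,
    pk_init: dict[str, float] | None = None,
    pd_init: dict[str, float] | None = None,
    disease_init: dict[str, float] | None = None,
    baselines: dict[str, float] | None = None,
    weight_exponent: float = 1.0,
    cona_time: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_starts: int = 0,
    seed: int | None = None,
) -> tuple[FitResult, FitResult, FitResult, ModelParameters]:
    """Run PK → PD → disease fits and return the assembled parameter vector."""
    if baselines is None:
        baselines = baselines_from_table(data)
    pk_fit = fit_pk(data, init=pk_init, weight_exponent=weight_exponent,
                    n_starts=n_starts, seed=seed)
    pk = PKParameters(vd_f=pk_fit.estimates["Vd_F"], ka=pk_fit.estimates["ka"],
                      ke=pk_fit.estimates["ke"])
    pd_fit = fit_pd(data, pk, baselines, init=pd_init,
                    weight_exponent=weight_exponent, cona_time=cona_time,
                    rtol=rtol, atol=atol, n_starts=n_starts, seed=seed)
    pd_values = dict(pd_fit.estimates)
    for name in pd_fit.unidentifiable:
        pd_values.setdefault(name, _DEFAULT_PD_INIT[name])
    template = _template_parameters(pd_values, baselines, pk, cona_time)
    template = template.with_values({
        "R0_ALT": baselines.get("R0_ALT", 1.0),
        "R0_AST": baselines.get("R0_AST", 1.0),
    })
    dis_fit = fit_disease(data, template, init=disease_init,
                          weight_exponent=weight_exponent, rtol=rtol, atol=atol,
                          n_starts=n_starts, seed=seed)
    final = template.with_values(dis_fit.estimates)
    return pk_fit, pd_fit, dis_fit, final
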