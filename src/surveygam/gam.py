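"""Negative-binomial GAM fitting by penalized IRLS with Laplace REML.

The density model for segment counts is

    count_i ~ NB(mu_i, theta),   log mu_i = x_i' beta + log(area_i)

with variance mu + mu^2/theta, so the linear predictor is log expected
indicated pairs per km².  Smooth terms carry quadratic penalties
``lambda_m * S_m``; the inner loop solves for coefficients by penalized
iteratively reweighted least squares at fixed (lambda, theta), and the
outer loop maximizes a Laplace-approximate restricted marginal likelihood
(REML) over (log lambda, log theta):

    V(rho) = l(beta_hat) - 0.5 beta_hat' S beta_hat
             + 0.5 log|S|_+ - 0.5 log|X'WX + S| + const

Model comparison uses AIC with trace-based effective degrees of freedom
("edf-AIC"): edf = tr[(X'WX + S)^{-1} X'WX], which counts unpenalized
columns fully and penalized ones by their realized complexity.  The
coefficient posterior is N(beta_hat, V_b) with V_b = (X'WX + S)^{-1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .smooths import Standardizer, build_term

__all__ = [
    "TermSpec",
    "ModelSpec",
    "FittedGAM",
    "standard_models",
    "fit_gam",
    "aic",
    "select_model",
    "predict_linear",
    "predict_density",
    "quantile_residuals",
]

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class TermSpec:
    kind: str
    k: object = None


@dataclass(frozen=True)
class ModelSpec:
    """A model formula: an intercept plus the listed terms."""

    name: str
    terms: tuple[TermSpec, ...]


def standard_models(
    *,
    k_space: int = 30,
    k_year: int = 10,
    k_tensor: tuple[int, int, int] = (5, 5, 5),
    observer: bool = False,
    survey_factor: bool = False,
    which: Sequence[str] = ("M0", "M1", "M2", "M3", "M4"),
) -> dict[str, ModelSpec]:
    """The model family M0–M4 (optionally with observer / survey terms).

    M0: s(X,Y);  M1: + s(Year);  M2: + ti(X,Y,Year);
    M3: s(X,Y) + s(Year) + s(fYear);  M4: s(X,Y) + s(fYear).
    """
    space = TermSpec("s_space", k_space)
    year = TermSpec("s_year", k_year)
    ti = TermSpec("ti_space_year", k_tensor)
    fyear = TermSpec("re_year")
    menu = {
        "M0": (space,),
        "M1": (space, year),
        "M2": (space, year, ti),
        "M3": (space, year, fyear),
        "M4": (space, fyear),
    }
    extra = []
    if observer:
        extra.append(TermSpec("re_observer"))
    if survey_factor:
        extra.append(TermSpec("factor_survey"))
    out = {}
    for name in which:
        suffix = ".obs" if observer else ""
        out[name + suffix] = ModelSpec(name + suffix, menu[name] + tuple(extra))
    return out


@dataclass
class FittedGAM:
    spec: ModelSpec
    std: Standardizer
    terms: list
    term_cols: dict[str, slice]
    beta: np.ndarray
    V_b: np.ndarray
    lam: np.ndarray
    theta: float
    edf_total: float
    edf_term: dict[str, float]
    loglik: float
    aic: float
    reml: float
    converged: bool
    basis: str = "ps"
    # fit-time arrays kept for posterior sampling and diagnostics
    X: Optional[np.ndarray] = field(default=None, repr=False)
    y: Optional[np.ndarray] = field(default=None, repr=False)
    offset: Optional[np.ndarray] = field(default=None, repr=False)
    S_total: Optional[np.ndarray] = field(default=None, repr=False)

    def penalized_loglik(self, beta: np.ndarray) -> float:
        """log posterior kernel: NB log-likelihood minus the quadratic penalty."""
        eta = np.clip(self.X @ beta + self.offset, -_ETA_CLIP, _ETA_CLIP)
        return _nb_loglik(self.y, eta, self.theta) - 0.5 * float(beta @ self.S_total @ beta)


def _nb_loglik(y: np.ndarray, eta: np.ndarray, theta: float) -> float:
    mu = np.exp(eta)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * (eta - np.log(theta + mu))
        )
    )


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    std = Standardizer.from_data(data)
    terms = [build_term(t.kind, t.k) for t in spec.terms]
    blocks, term_cols, penalties = [np.ones((len(data), 1))], {"intercept": slice(0, 1)}, []
    col = 1
    for term in terms:
        term.build(data, std)
        M = term.matrix(data, std)
        sl = slice(col, col + term.ncol)
        term_cols[term.name] = sl
        blocks.append(M)
        for S in term.penalties:
            penalties.append((term.name, sl, S))
        col += term.ncol
    X = np.hstack(blocks)
    return std, terms, term_cols, X, penalties


def _penalty_embed(p: int, penalties, lam: np.ndarray) -> np.ndarray:
    S = np.zeros((p, p))
    for lam_m, (_, sl, S_m) in zip(lam, penalties):
        S[sl, sl] += lam_m * S_m
    return S


def _logdet_S_plus(penalties, lam: np.ndarray, block_ranks: dict) -> tuple[float, int]:
    """log pseudo-determinant of the total penalty, blockwise by term."""
    logdet, total_rank = 0.0, 0
    by_term: dict[str, list[tuple[float, np.ndarray]]] = {}
    for lam_m, (name, _, S_m) in zip(lam, penalties):
        by_term.setdefault(name, []).append((lam_m, S_m))
    for name, items in by_term.items():
        r = block_ranks[name]
        total_rank += r
        if len(items) == 1:
            lam_m, S_m = items[0]
            ev = block_ranks[name + "/eigs"]
            logdet += r * np.log(lam_m) + float(np.sum(np.log(ev)))
        else:
            Ssum = sum(lam_m * S_m for lam_m, S_m in items)
            ev = np.linalg.eigvalsh(Ssum)[::-1][:r]
            logdet += float(np.sum(np.log(np.maximum(ev, 1e-300))))
    return logdet, total_rank


def _irls(X, y, offset, S, theta, beta0, tol=1e-8, max_iter=200):
    """Penalized IRLS for NB log-link; returns (beta, converged)."""
    beta = beta0.copy()

    def penalized_nll(b):
        eta = np.clip(X @ b + offset, -_ETA_CLIP, _ETA_CLIP)
        return -(_nb_loglik(y, eta, theta) - 0.5 * b @ S @ b)

    q_old = penalized_nll(beta)
    ridge = 1e-10 * np.eye(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu * theta / (theta + mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + S
        try:
            c, low = linalg.cho_factor(A, check_finite=False)
        except linalg.LinAlgError:
            c, low = linalg.cho_factor(A + ridge * 1e6, check_finite=False)
        beta_new = linalg.cho_solve((c, low), XtW @ z, check_finite=False)
        step = beta_new - beta
        q_new = penalized_nll(beta + step)
        halvings = 0
        while not np.isfinite(q_new) or q_new > q_old + 1e-12:
            step *= 0.5
            halvings += 1
            if halvings > 30:
                break
            q_new = penalized_nll(beta + step)
        beta = beta + step
        if not np.isfinite(q_new):
            return beta, False
        # Fisher scoring converges linearly: require both a stationary
        # objective and a small step, or coefficients stall ~sqrt(tol) short
        small_step = np.max(np.abs(step)) <= 1e-8 * (1.0 + np.max(np.abs(beta)))
        if abs(q_old - q_new) <= tol * (abs(q_new) + 0.1) and small_step:
            return beta, True
        q_old = q_new
    return beta, False


def fit_gam(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    fixed_lambda: Optional[Sequence[float]] = None,
    fixed_theta: Optional[float] = None,
    inner_tol: float = 1e-8,
    outer_tol: float = 1e-4,
    max_inner: int = 200,
    max_outer: int = 100,
) -> FittedGAM:
    """Fit a NB GAM to a segment table (columns x_c, y_c, year, count, area).

    Smoothing parameters and the NB dispersion are selected by maximizing
    the Laplace-approximate REML criterion (Nelder-Mead over their logs),
    unless pinned with ``fixed_lambda`` / ``fixed_theta``.
    """
    y = data["count"].to_numpy(float)
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("counts must be finite and non-negative")
    if y.sum() <= 0:
        raise ValueError("all counts are zero: the likelihood is degenerate")
    area = data["area"].to_numpy(float)
    if np.any(area <= 0) or not np.all(np.isfinite(np.log(area))):
        raise ValueError("segment areas must be positive and finite")
    offset = np.log(area)

    std, terms, term_cols, X, penalties = _build_design(spec, data)
    n, p = X.shape
    m = len(penalties)

    # per-term penalty ranks and eigenvalues (lambda-independent structure)
    block_ranks: dict = {}
    by_term: dict[str, list[np.ndarray]] = {}
    for name, _, S_m in penalties:
        by_term.setdefault(name, []).append(S_m)
    for name, mats in by_term.items():
        ev = np.linalg.eigvalsh(sum(mats))[::-1]
        r = int(np.sum(ev > ev[0] * 1e-9)) if len(ev) else 0
        block_ranks[name] = r
        if len(mats) == 1:
            ev1 = np.linalg.eigvalsh(mats[0])[::-1][:r]
            block_ranks[name + "/eigs"] = ev1

    beta_init = np.zeros(p)
    beta_init[0] = np.log(max(y.sum(), 0.5) / area.sum())
    state = {"beta": beta_init}

    def criterion(rho: np.ndarray) -> float:
        """Negative REML at rho = [log lambda..., log theta]."""
        rho = np.clip(rho, -18.0, 18.0)
        lam = np.exp(rho[:m])
        theta = fixed_theta if fixed_theta is not None else float(np.exp(rho[m]))
        theta = min(max(theta, 1e-4), 1e7)
        S = _penalty_embed(p, penalties, lam)
        beta, ok = _irls(X, y, offset, S, theta, state["beta"],
                         tol=inner_tol, max_iter=max_inner)
        if not ok and not np.all(np.isfinite(beta)):
            return 1e12
        state["beta"] = beta
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu * theta / (theta + mu)
        H = (X.T * w) @ X + S
        sign, logdet_H = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e12
        logdet_S, total_rank = _logdet_S_plus(penalties, lam, block_ranks)
        ll = _nb_loglik(y, eta, theta)
        pen = 0.5 * float(beta @ S @ beta)
        Mp = p - total_rank
        reml = ll - pen + 0.5 * logdet_S - 0.5 * logdet_H + 0.5 * Mp * np.log(2 * np.pi)
        return -reml

    n_free = m + (0 if fixed_theta is not None else 1)
    if fixed_lambda is not None:
        if len(fixed_lambda) != m:
            raise ValueError(f"model has {m} penalties; got {len(fixed_lambda)} lambdas")
        rho_opt = np.concatenate(
            [np.log(np.asarray(fixed_lambda, float))]
            + ([] if fixed_theta is not None else [[0.0]])
        )
        if fixed_theta is None:
            res = optimize.minimize_scalar(
                lambda lt: criterion(np.concatenate([rho_opt[:m], [lt]])),
                bounds=(-7, 14), method="bounded",
                options={"xatol": outer_tol},
            )
            rho_opt[m:] = res.x
        converged_outer = True
    elif n_free > 0 and m > 0:
        x0 = np.zeros(m + (0 if fixed_theta is not None else 1))
        # fatol is absolute: tighter than ~1e-4 chases the inner-IRLS noise
        # floor; 1% precision in log-smoothing parameters is ample.  The
        # initial simplex must span O(1) in log-lambda space, or scipy's
        # default (built from a zero start) collapses before exploring.
        simplex = np.vstack([x0] + [x0 + 2.0 * e for e in np.eye(len(x0))])
        res = optimize.minimize(
            criterion, x0, method="Nelder-Mead",
            options={"fatol": outer_tol, "xatol": 1e-2,
                     "initial_simplex": simplex,
                     "maxfev": max_outer * max(4, 2 * len(x0))},
        )
        rho_opt = np.clip(res.x, -18.0, 18.0)
        converged_outer = bool(res.success)
    else:
        # no penalties: optimize theta only (unless fixed)
        rho_opt = np.zeros(0 if fixed_theta is not None else 1)
        converged_outer = True
        if fixed_theta is None:
            res = optimize.minimize_scalar(
                lambda lt: criterion(np.array([lt])), bounds=(-7, 14),
                method="bounded", options={"xatol": outer_tol},
            )
            rho_opt = np.array([res.x])

    lam = np.exp(rho_opt[:m]) if m else np.zeros(0)
    theta = fixed_theta if fixed_theta is not None else float(np.exp(rho_opt[m]))
    theta = min(max(theta, 1e-4), 1e7)
    S = _penalty_embed(p, penalties, lam)
    beta, inner_ok = _irls(X, y, offset, S, theta, state["beta"],
                           tol=inner_tol, max_iter=max_inner)
    if not inner_ok:
        warnings.warn(f"{spec.name}: penalized IRLS did not fully converge")
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu * theta / (theta + mu)
    XtWX = (X.T * w) @ X
    H = XtWX + S
    V_b = np.linalg.inv(H)
    V_b = 0.5 * (V_b + V_b.T)
    F_diag = np.einsum("ij,ji->i", V_b, XtWX)
    edf_total = float(F_diag.sum())
    edf_term = {
        name: float(F_diag[sl].sum()) for name, sl in term_cols.items()
    }
    ll = _nb_loglik(y, eta, theta)
    fit = FittedGAM(
        spec=spec, std=std, terms=terms, term_cols=term_cols,
        beta=beta, V_b=V_b, lam=lam, theta=theta,
        edf_total=edf_total, edf_term=edf_term,
        loglik=ll, aic=-2.0 * ll + 2.0 * edf_total,
        reml=-criterion(np.concatenate([np.log(lam) if m else np.zeros(0),
                                        [] if fixed_theta is not None else [np.log(theta)]])),
        converged=bool(converged_outer and inner_ok),
        X=X, y=y, offset=offset, S_total=S,
    )
    return fit


def aic(fit: FittedGAM) -> float:
    """edf-AIC: -2 loglik + 2 * trace-based effective degrees of freedom."""
    return fit.aic


def select_model(candidates, data: pd.DataFrame, **fit_kwargs) -> pd.DataFrame:
    """Fit each candidate and rank by AIC (ascending; ties by smaller edf).

    ``candidates`` is a dict name -> ModelSpec or an iterable of ModelSpec.
    Candidates that fail to converge (or error) are reported with NaN AIC
    and excluded from the ranking rather than aborting the comparison.
    """
    if isinstance(candidates, dict):
        specs = list(candidates.values())
    else:
        specs = list(candidates)
    if len(specs) == 0:
        raise ValueError("no candidate models")
    rows, fits = [], {}
    for spec in specs:
        try:
            f = fit_gam(spec, data, **fit_kwargs)
            fits[spec.name] = f
            rows.append({"model": spec.name, "edf": f.edf_total, "aic": f.aic,
                         "converged": f.converged})
        except Exception as exc:  # report, don't abort the comparison
            warnings.warn(f"model {spec.name} failed: {exc}")
            rows.append({"model": spec.name, "edf": np.nan, "aic": np.nan,
                         "converged": False})
    tab = pd.DataFrame(rows)
    ok = tab["aic"].notna()
    tab = pd.concat(
        [tab[ok].sort_values(["aic", "edf"]), tab[~ok]], ignore_index=True
    )
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab.attrs["fits"] = fits
    return tab


def predict_linear(
    fit: FittedGAM,
    newdata: pd.DataFrame,
    exclude: Sequence[str] = (),
    factor_settings: Optional[dict] = None,
):
    """Prediction design matrix and linear predictor on ``newdata``.

    ``exclude`` zeroes the columns of the named terms (e.g. ``["s(Year)"]``
    for a year-averaged spatial surface); ``factor_settings`` fills factor
    covariates absent from ``newdata`` (e.g. ``{"survey_id": "triangle"}``).
    No offset is added: predictions are densities per km².
    """
    unknown = set(exclude) - set(fit.term_cols)
    if unknown:
        raise ValueError(f"exclude names not in model: {sorted(unknown)}; "
                         f"model terms: {sorted(fit.term_cols)}")
    newdata = newdata.copy()
    for var, level in (factor_settings or {}).items():
        if var not in newdata.columns:
            newdata[var] = level
    p = fit.beta.shape[0]
    Xp = np.zeros((len(newdata), p))
    Xp[:, 0] = 1.0
    for term in fit.terms:
        if term.name in exclude:
            continue
        Xp[:, fit.term_cols[term.name]] = term.matrix(newdata, fit.std)
    if "intercept" in exclude:
        Xp[:, 0] = 0.0
    return Xp, Xp @ fit.beta


def predict_density(fit: FittedGAM, newdata: pd.DataFrame, **kw) -> np.ndarray:
    """Expected indicated pairs per km² on the response scale."""
    _, eta = predict_linear(fit, newdata, **kw)
    return np.exp(eta)


def quantile_residuals(
    fit: FittedGAM, n_sim: int = 200, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Randomized-quantile residuals plus dispersion/zero-inflation summaries.

    Residuals use the exact NB CDF with uniform randomization within the
    observed count's probability mass; under a correctly specified model
    they are standard normal.  The summary dict reports the Pearson
    dispersion ratio and the observed/expected zero fraction (with the
    expectation and its spread taken over ``n_sim`` simulated data sets).
    """
    rng = np.random.default_rng(seed)
    eta = np.clip(fit.X @ fit.beta + fit.offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    theta = fit.theta
    pnb = theta / (theta + mu)
    y = fit.y
    lo = stats.nbinom.cdf(y - 1, theta, pnb)
    hi = stats.nbinom.cdf(y, theta, pnb)
    u = np.clip(lo + rng.uniform(size=len(y)) * (hi - lo), 1e-12, 1 - 1e-12)
    resid = stats.norm.ppf(u)
    var = mu + mu**2 / theta
    pearson = float(np.sum((y - mu) ** 2 / var) / max(len(y) - fit.edf_total, 1.0))
    zero_obs = float(np.mean(y == 0))
    sims = rng.negative_binomial(theta, pnb, size=(n_sim, len(y)))
    zero_sim = (sims == 0).mean(axis=1)
    summary = {
        "dispersion_ratio": pearson,
        "zero_fraction_observed": zero_obs,
        "zero_fraction_expected": float(zero_sim.mean()),
        "zero_inflation_ratio": zero_obs / max(float(zero_sim.mean()), 1e-12),
    }
    table = pd.DataFrame({"mu": mu, "count": y, "residual": resid, "uniform": u})
    return table, summary
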