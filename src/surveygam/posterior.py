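"""Posterior simulation of population totals from a fitted density GAM.

A fitted GAM supplies a large-sample coefficient posterior
N(beta_hat, V_b).  Draws b_i from it (directly, or by Metropolis-Hastings
against the penalized likelihood when the Gaussian approximation is poor,
as in sparse surveys with large empty regions) are pushed through a
prediction grid covering the study area:

    y_ik  = a_k * exp(x_k' b_i)          expected pairs in cell k
    Y_ij  = sum_k y_ijk                  expected indicated pairs, year j
    N_ij  = 2 * Y_ij / d_i               indicated breeding birds

with one detection draw d_i per posterior draw from a Beta prior,
constant across years within a draw.  The per-year log trend over a lag
t is T = (log N_{j+t} - log N_j) / t; constant-per-draw detection cancels
out of it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .detection import BetaPrior
from .gam import FittedGAM, predict_linear
from .io import StudyArea

__all__ = [
    "PredictionGrid",
    "PosteriorDraws",
    "make_grid",
    "sample_coefficients_mvn",
    "sample_coefficients_mh",
    "totals_from_draws",
    "detection_correct",
    "trend",
    "summarize",
]


@dataclass(frozen=True)
class PredictionGrid:
    """Square lattice clipped to the study area, replicated per year."""

    cells: pd.DataFrame  # columns x, y, area (km²)
    years: tuple[int, ...]

    @property
    def total_area(self) -> float:
        return float(self.cells["area"].sum())

    def year_table(self, year: int) -> pd.DataFrame:
        tab = self.cells.rename(columns={"x": "x_c", "y": "y_c"}).copy()
        tab["year"] = int(year)
        return tab


@dataclass
class PosteriorDraws:
    """Draws × years matrices of expected totals (index and corrected)."""

    years: tuple[int, ...]
    index_totals: np.ndarray  # draws × years, expected indicated pairs
    corrected_totals: Optional[np.ndarray] = None  # indicated breeding birds
    detection_draws: Optional[np.ndarray] = None
    sampler: str = "mvn"
    seed: Optional[int] = None
    mh_acceptance: Optional[dict] = field(default=None)

    @property
    def n_draws(self) -> int:
        return self.index_totals.shape[0]


def make_grid(
    area: StudyArea, cell_km: float = 1.0, years: Sequence[int] = ()
) -> PredictionGrid:
    """Grid the study area into ``cell_km`` cells clipped at the boundary.

    Boundary cells carry their clipped area and the centroid of the
    clipped part, so cell areas sum to the study area.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    poly = area.union()
    if poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate study-area polygon")
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx + cell_km, cell_km)
    ys = np.arange(miny, maxy + cell_km, cell_km)
    x0, y0 = np.meshgrid(xs[:-1], ys[:-1], indexing="ij")
    boxes = shapely.box(x0.ravel(), y0.ravel(),
                        x0.ravel() + cell_km, y0.ravel() + cell_km)
    clipped = shapely.intersection(boxes, poly)
    areas = shapely.area(clipped)
    keep = areas > 1e-9
    cents = shapely.centroid(clipped[keep])
    cells = pd.DataFrame(
        {
            "x": shapely.get_x(cents),
            "y": shapely.get_y(cents),
            "area": areas[keep],
        }
    )
    return PredictionGrid(cells=cells, years=tuple(int(y) for y in years))


def sample_coefficients_mvn(
    fit: FittedGAM, n_draws: int = 500, seed: int = 0
) -> np.ndarray:
    """Draws from N(beta_hat, V_b) via symmetric eigen-factorization.

    Small negative eigenvalues of V_b (numerical) are clipped to zero.
    """
    rng = np.random.default_rng(seed)
    ev, U = np.linalg.eigh(fit.V_b)
    root = U * np.sqrt(np.clip(ev, 0.0, None))
    z = rng.standard_normal((n_draws, len(fit.beta)))
    return fit.beta + z @ root.T


def sample_coefficients_mh(
    fit: FittedGAM,
    n_draws: int = 500,
    burnin: int = 200,
    thin: int = 1,
    seed: int = 0,
    *,
    t_df: float = 4.0,
    t_scale: float = 1.0,
    rw_scale: float = 0.25,
    return_acceptance: bool = False,
):
    """Metropolis-Hastings sampling of the coefficient posterior.

    Alternates a heavy-tailed independence proposal (multivariate t with
    ``t_df`` degrees of freedom, centred at beta_hat, shape
    ``t_scale² V_b``) with a Gaussian random-walk step (``rw_scale² V_b``),
    targeting the Laplace posterior kernel exp(penalized log-likelihood).
    """
    if fit.X is None:
        raise ValueError("fit does not retain its design matrix; refit with fit_gam")
    rng = np.random.default_rng(seed)
    p = len(fit.beta)
    jitter = 1e-10 * np.trace(fit.V_b) / p * np.eye(p)
    shape_t = t_scale**2 * fit.V_b + jitter
    tdist = stats.multivariate_t(loc=fit.beta, shape=shape_t, df=t_df,
                                 allow_singular=True)
    ev, U = np.linalg.eigh(fit.V_b)
    rw_root = U * np.sqrt(np.clip(ev, 0.0, None)) * rw_scale

    beta = fit.beta.copy()
    lp = fit.penalized_loglik(beta)
    lq = tdist.logpdf(beta)
    acc = {"independence": 0, "random_walk": 0}
    tries = {"independence": 0, "random_walk": 0}
    out = np.empty((n_draws, p))
    kept = 0
    total = burnin + n_draws * thin
    for it in range(total):
        if it % 2 == 0:
            prop = np.asarray(tdist.rvs(random_state=rng))
            lp_prop = fit.penalized_loglik(prop)
            lq_prop = tdist.logpdf(prop)
            log_alpha = (lp_prop - lq_prop) - (lp - lq)
            kind = "independence"
        else:
            prop = beta + rw_root @ rng.standard_normal(p)
            lp_prop = fit.penalized_loglik(prop)
            lq_prop = lq  # symmetric step: proposal density cancels
            log_alpha = lp_prop - lp
            kind = "random_walk"
        tries[kind] += 1
        if np.log(rng.uniform()) < log_alpha:
            beta, lp = prop, lp_prop
            lq = tdist.logpdf(beta) if kind == "random_walk" else lq_prop
            acc[kind] += 1
        if it >= burnin and (it - burnin) % thin == 0 and kept < n_draws:
            out[kept] = beta
            kept += 1
    rates = {k: acc[k] / max(tries[k], 1) for k in acc}
    if max(rates.values()) < 0.01:
        import warnings

        warnings.warn(f"MH acceptance rates very low: {rates}")
    if return_acceptance:
        return out, rates
    return out


def totals_from_draws(
    draws: np.ndarray,
    fit: FittedGAM,
    grid: PredictionGrid,
    factor_settings: Optional[dict] = None,
    exclude: Sequence[str] = (),
    sampler: str = "mvn",
    seed: Optional[int] = None,
) -> PosteriorDraws:
    """Expected indicated-pair totals Y_ij per draw i and year j.

    Evaluated year by year to bound memory: Y_ij = sum_k a_k exp(x_jk' b_i)
    (no offset — cell areas multiply on the response scale).
    """
    n_draws = draws.shape[0]
    Y = np.empty((n_draws, len(grid.years)))
    for j, year in enumerate(grid.years):
        tab = grid.year_table(year)
        Xp, _ = predict_linear(fit, tab, exclude=exclude,
                               factor_settings=factor_settings)
        eta = np.clip(Xp @ draws.T, -50.0, 50.0)  # cells × draws
        Y[:, j] = tab["area"].to_numpy() @ np.exp(eta)
    return PosteriorDraws(years=grid.years, index_totals=Y, sampler=sampler,
                          seed=seed)


def detection_correct(
    post: PosteriorDraws, prior: BetaPrior, seed: int = 0
) -> PosteriorDraws:
    """Apply the detection correction N_ij = 2 Y_ij / d_i.

    One detection draw per posterior draw, constant across years within a
    draw (the decoy study informs an average rate, not year-specific ones),
    sampled independently of the coefficient draws.
    """
    rng = np.random.default_rng(seed)
    d = prior.sample(post.n_draws, rng)
    corrected = 2.0 * post.index_totals / d[:, None]
    return replace(post, corrected_totals=corrected, detection_draws=d)


def trend(
    post: PosteriorDraws, start_year: int, lag: int, *, use_corrected: bool = True
) -> dict:
    """Posterior per-year log growth rate from start_year to start_year+lag.

    T_i = (log N_{i,j+t} - log N_{i,j}) / t per draw; detection cancels,
    so index and corrected trends agree draw-by-draw.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    years = list(post.years)
    for yr in (start_year, start_year + lag):
        if yr not in years:
            raise ValueError(f"year {yr} not among posterior years {years}")
    mat = post.corrected_totals if (use_corrected and post.corrected_totals is not None) \
        else post.index_totals
    j0, j1 = years.index(start_year), years.index(start_year + lag)
    T = (np.log(mat[:, j1]) - np.log(mat[:, j0])) / lag
    return {
        "draws": T,
        "mean": float(T.mean()),
        "median": float(np.median(T)),
        "q025": float(np.quantile(T, 0.025)),
        "q975": float(np.quantile(T, 0.975)),
    }


def summarize(post_or_matrix, years: Optional[Sequence[int]] = None,
              *, corrected: bool = False) -> pd.DataFrame:
    """Per-year posterior mean, median and central 95% interval.

    Quantiles use linear interpolation (type 7).  Accepts a
    :class:`PosteriorDraws` or a raw draws × years matrix plus ``years``.
    """
    if isinstance(post_or_matrix, PosteriorDraws):
        mat = post_or_matrix.corrected_totals if corrected else post_or_matrix.index_totals
        if mat is None:
            raise ValueError("no corrected totals present; run detection_correct")
        years = post_or_matrix.years
    else:
        mat = np.asarray(post_or_matrix, float)
        if years is None:
            raise ValueError("years must be given with a raw draws matrix")
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 draws to summarize")
    return pd.DataFrame(
        {
            "year": list(years),
            "mean": mat.mean(axis=0),
            "median": np.quantile(mat, 0.5, axis=0),
            "q025": np.quantile(mat, 0.025, axis=0),
            "q975": np.quantile(mat, 0.975, axis=0),
        }
    )
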