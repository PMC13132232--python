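"""Penalized spline bases for the density GAM.

All smooth terms are built from tensor-product cubic B-splines with
second-order difference penalties (P-splines).  The contract is the
penalty structure, not the basis family: a quadratic roughness penalty
whose null space holds the polynomial trends the data cannot distinguish
from "perfectly smooth", with sum-to-zero constraints making every smooth
an average-zero deviation from the model intercept.

Terms
-----
* ``s(X,Y)`` — 2D tensor B-spline over standardized coordinates with the
  isotropic penalty ``Sx ⊗ I + I ⊗ Sy`` under a single smoothing
  parameter (X and Y are standardized to a common scale first).
* ``s(Year)`` — 1D P-spline over standardized year.
* ``ti(X,Y,Year)`` — space×time interaction: the row-wise tensor product
  of the *centred* 2D spatial margin and the *centred* 1D year margin,
  with one penalty per margin.  Centring both margins removes everything
  constant in space or in time, so the term is a pure interaction that
  excludes the main effects it sits on top of (functional ANOVA).
* ``s(fYear)``, ``s(Observer)`` — random-effect (ridge) terms: one
  indicator column per level with an identity penalty.
* ``Survey`` — unpenalized treatment-coded fixed factor.

Coordinates are standardized before basis construction: X and Y are
centred and divided by the mean of their standard deviations (keeping the
spatial penalty isotropic), year is centred and scaled by its own SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "Standardizer",
    "build_term",
    "TERM_FACTORIES",
]


@dataclass(frozen=True)
class Standardizer:
    """Covariate standardization fixed at fit time and reused at prediction."""

    x_mean: float
    y_mean: float
    xy_scale: float
    year_mean: float
    year_scale: float

    @classmethod
    def from_data(cls, data: pd.DataFrame) -> "Standardizer":
        x = data["x_c"].to_numpy(float)
        y = data["y_c"].to_numpy(float)
        t = data["year"].to_numpy(float)
        sx, sy = x.std(), y.std()
        xy_scale = 0.5 * (sx + sy)
        if xy_scale <= 0:
            xy_scale = 1.0
        st = t.std()
        return cls(
            x_mean=float(x.mean()),
            y_mean=float(y.mean()),
            xy_scale=float(xy_scale),
            year_mean=float(t.mean()),
            year_scale=float(st if st > 0 else 1.0),
        )

    def xy(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return (
            (data["x_c"].to_numpy(float) - self.x_mean) / self.xy_scale,
            (data["y_c"].to_numpy(float) - self.y_mean) / self.xy_scale,
        )

    def year(self, data: pd.DataFrame) -> np.ndarray:
        return (data["year"].to_numpy(float) - self.year_mean) / self.year_scale


def _pspline_knots(lo: float, hi: float, k: int, degree: int = 3) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0
    span = hi - lo
    lo, hi = lo - 0.001 * span, hi + 0.001 * span
    h = (hi - lo) / (k - degree)
    return lo + h * np.arange(-degree, k + 1)


def _bspline_matrix(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _sumzero_Z(colsums: np.ndarray) -> np.ndarray:
    """Null-space basis of the single constraint colsums @ beta = 0."""
    q, _ = np.linalg.qr(colsums.reshape(-1, 1), mode="complete")
    return q[:, 1:]


def _normalize(S: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(S, 2)
    return S / nrm if nrm > 0 else S


def _row_tensor(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def _effective_k(k: int, n_unique: int, label: str) -> int:
    if k > n_unique:
        warnings.warn(
            f"{label}: basis dimension {k} exceeds unique covariate support "
            f"({n_unique}); reduced", stacklevel=3,
        )
        return max(3, n_unique)
    return k


class Smooth1D:
    """P-spline of standardized year; sum-to-zero constrained."""

    name = "s(Year)"
    is_smooth = True

    def __init__(self, k: int = 10, degree: int = 3, penalty_order: int = 2):
        if k < 3:
            raise ValueError("smooth basis dimension k must be >= 3")
        self.k, self.degree, self.order = k, degree, penalty_order

    def build(self, data: pd.DataFrame, std: Standardizer) -> None:
        t = std.year(data)
        k = _effective_k(self.k, len(np.unique(t)), self.name)
        self.knots = _pspline_knots(t.min(), t.max(), k, self.degree)
        B = _bspline_matrix(t, self.knots, self.degree)
        self.Z = _sumzero_Z(B.sum(axis=0))
        S = self.Z.T @ _diff_penalty(k, self.order) @ self.Z
        self.penalties = [_normalize(S)]
        self.ncol = self.Z.shape[1]

    def matrix(self, data: pd.DataFrame, std: Standardizer) -> np.ndarray:
        return _bspline_matrix(std.year(data), self.knots, self.degree) @ self.Z


class Smooth2D:
    """Isotropic 2D tensor B-spline of standardized (X, Y); one penalty."""

    name = "s(X,Y)"
    is_smooth = True

    def __init__(self, k: int = 30, degree: int = 3, penalty_order: int = 2):
        self.k_margin = max(3, int(np.ceil(np.sqrt(k))))
        self.degree, self.order = degree, penalty_order

    def build(self, data: pd.DataFrame, std: Standardizer) -> None:
        xs, ys = std.xy(data)
        km = self.k_margin
        km_x = _effective_k(km, len(np.unique(xs)), self.name + " [X margin]")
        km_y = _effective_k(km, len(np.unique(ys)), self.name + " [Y margin]")
        self.knots_x = _pspline_knots(xs.min(), xs.max(), km_x, self.degree)
        self.knots_y = _pspline_knots(ys.min(), ys.max(), km_y, self.degree)
        Bx = _bspline_matrix(xs, self.knots_x, self.degree)
        By = _bspline_matrix(ys, self.knots_y, self.degree)
        B = _row_tensor(Bx, By)
        Sx = _diff_penalty(km_x, self.order)
        Sy = _diff_penalty(km_y, self.order)
        # isotropic roughness: one smoothing parameter for both directions
        S = np.kron(Sx, np.eye(km_y)) + np.kron(np.eye(km_x), Sy)
        self.Z = _sumzero_Z(B.sum(axis=0))
        self.penalties = [_normalize(self.Z.T @ S @ self.Z)]
        self.ncol = self.Z.shape[1]

    def matrix(self, data: pd.DataFrame, std: Standardizer) -> np.ndarray:
        xs, ys = std.xy(data)
        Bx = _bspline_matrix(xs, self.knots_x, self.degree)
        By = _bspline_matrix(ys, self.knots_y, self.degree)
        return _row_tensor(Bx, By) @ self.Z


class TensorSpaceTime:
    """Space×time interaction smooth with margin-wise penalties.

    Margins: a 2D B-spline surface over (X, Y) and a 1D B-spline over
    year, each centred over the fitting data before their row-tensor
    product is formed; an overall sum-to-zero constraint is applied last.
    Two smoothing parameters: one for spatial roughness, one for temporal.
    """

    name = "ti(X,Y,Year)"
    is_smooth = True

    def __init__(self, k: tuple[int, int, int] = (5, 5, 5), degree: int = 3,
                 penalty_order: int = 2):
        self.kx, self.ky, self.kt = k
        self.degree, self.order = degree, penalty_order

    def build(self, data: pd.DataFrame, std: Standardizer) -> None:
        xs, ys = std.xy(data)
        t = std.year(data)
        kx = _effective_k(self.kx, len(np.unique(xs)), self.name + " [X]")
        ky = _effective_k(self.ky, len(np.unique(ys)), self.name + " [Y]")
        kt = _effective_k(self.kt, len(np.unique(t)), self.name + " [Year]")
        self.knots_x = _pspline_knots(xs.min(), xs.max(), kx, self.degree)
        self.knots_y = _pspline_knots(ys.min(), ys.max(), ky, self.degree)
        self.knots_t = _pspline_knots(t.min(), t.max(), kt, self.degree)
        Ms = _row_tensor(
            _bspline_matrix(xs, self.knots_x, self.degree),
            _bspline_matrix(ys, self.knots_y, self.degree),
        )
        Mt = _bspline_matrix(t, self.knots_t, self.degree)
        Ss = np.kron(_diff_penalty(kx, self.order), np.eye(ky)) + np.kron(
            np.eye(kx), _diff_penalty(ky, self.order)
        )
        St = _diff_penalty(kt, self.order)
        self.Zs = _sumzero_Z(Ms.sum(axis=0))
        self.Zt = _sumzero_Z(Mt.sum(axis=0))
        Ms_c, Mt_c = Ms @ self.Zs, Mt @ self.Zt
        Ss_c = self.Zs.T @ Ss @ self.Zs
        St_c = self.Zt.T @ St @ self.Zt
        T = _row_tensor(Ms_c, Mt_c)
        S1 = np.kron(Ss_c, np.eye(Mt_c.shape[1]))
        S2 = np.kron(np.eye(Ms_c.shape[1]), St_c)
        self.Zf = _sumzero_Z(T.sum(axis=0))
        self.penalties = [
            _normalize(self.Zf.T @ S1 @ self.Zf),
            _normalize(self.Zf.T @ S2 @ self.Zf),
        ]
        self.ncol = self.Zf.shape[1]

    def matrix(self, data: pd.DataFrame, std: Standardizer) -> np.ndarray:
        xs, ys = std.xy(data)
        t = std.year(data)
        Ms = _row_tensor(
            _bspline_matrix(xs, self.knots_x, self.degree),
            _bspline_matrix(ys, self.knots_y, self.degree),
        ) @ self.Zs
        Mt = _bspline_matrix(t, self.knots_t, self.degree) @ self.Zt
        return _row_tensor(Ms, Mt) @ self.Zf


class RandomEffect:
    """Ridge random effect: indicator columns, identity penalty."""

    is_smooth = True

    def __init__(self, var: str, name: str):
        self.var, self.name = var, name

    def _series(self, data: pd.DataFrame) -> pd.Series:
        # fYear is the year covariate treated as a factor
        if self.var == "fYear":
            return data["year"].astype(int).astype(str)
        return data[self.var].astype(str)

    def build(self, data: pd.DataFrame, std: Standardizer) -> None:
        self.levels = sorted(pd.unique(self._series(data)))
        self.ncol = len(self.levels)
        self.penalties = [np.eye(self.ncol)]

    def matrix(self, data: pd.DataFrame, std: Standardizer) -> np.ndarray:
        vals = self._series(data)
        unknown = set(vals) - set(self.levels)
        if unknown:
            raise ValueError(
                f"{self.name}: level(s) {sorted(unknown)} not seen at fit time; "
                "a pure random-effect term cannot extrapolate to new levels"
            )
        idx = {lv: j for j, lv in enumerate(self.levels)}
        M = np.zeros((len(vals), self.ncol))
        M[np.arange(len(vals)), [idx[v] for v in vals]] = 1.0
        return M


class FixedFactor:
    """Unpenalized treatment-coded factor (first level is baseline)."""

    is_smooth = False

    def __init__(self, var: str, name: str):
        self.var, self.name = var, name
        self.penalties: list[np.ndarray] = []

    def build(self, data: pd.DataFrame, std: Standardizer) -> None:
        self.levels = sorted(map(str, pd.unique(data[self.var].astype(str))))
        self.ncol = len(self.levels) - 1

    def matrix(self, data: pd.DataFrame, std: Standardizer) -> np.ndarray:
        vals = data[self.var].astype(str)
        unknown = set(vals) - set(self.levels)
        if unknown:
            raise ValueError(f"{self.name}: unknown factor level(s) {sorted(unknown)}")
        M = np.zeros((len(vals), self.ncol))
        for j, lv in enumerate(self.levels[1:]):
            M[vals.to_numpy() == lv, j] = 1.0
        return M


TERM_FACTORIES = {
    "s_space": lambda k=30: Smooth2D(k=k),
    "s_year": lambda k=10: Smooth1D(k=k),
    "ti_space_year": lambda k=(5, 5, 5): TensorSpaceTime(k=k),
    "re_year": lambda: RandomEffect("fYear", "s(fYear)"),
    "re_observer": lambda: RandomEffect("observer", "s(Observer)"),
    "factor_survey": lambda: FixedFactor("survey_id", "Survey"),
}


def build_term(kind: str, k=None):
    """Instantiate a term by kind; ``k`` is the basis dimension where it applies."""
    if kind not in TERM_FACTORIES:
        raise ValueError(f"unknown term kind {kind!r}; known: {sorted(TERM_FACTORIES)}")
    factory = TERM_FACTORIES[kind]
    return factory() if k is None else factory(k)
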