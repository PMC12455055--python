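"""Removing mean/variance structure unrelated to coupling (Stage I).

Apparent covariate effects on the *correlation* of two maps can be
manufactured by covariate effects on their *means* or *variances*.  Before
any coupling estimate is formed, each modality is therefore reduced to
standardized residuals by one or both of:

* **between-subject adjustment** — per vertex, a Gaussian location-scale
  fit across subjects: the mean is an additive model with optional cubic
  regression spline terms (optionally stratified by a binary covariate),
  and log(sigma) is linear in named covariates;
  ``eps = (y - mu_hat) / sigma_hat``;
* **within-subject adjustment** — per subject and vertex, centering and
  scaling by the sample mean and SD over the geodesic neighborhood
  ``N_r(v)`` (the vertex included, SD with the n-1 denominator), assuming
  local stationarity of mean and variance.  Default radius: 5 mm.

Both can be composed: between first (observed covariates), then within
(residual local structure from unobserved factors).

Matrix convention: subject-by-vertex arrays span *all* mesh vertices;
masked-out vertices come out as NaN from the within-subject step (they have
no neighborhood) and are excluded from inference downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surface import NeighborhoodIndex

__all__ = [
    "MeanModel",
    "VarianceModel",
    "AdjustmentSettings",
    "ResidualMatrix",
    "natural_spline_basis",
    "between_subject_adjust",
    "within_subject_adjust",
    "compose_adjustments",
]

logger = logging.getLogger(__name__)


@dataclass
class ResidualMatrix:
    """Standardized residuals with a record of how they were produced."""

    values: np.ndarray            # (N, V)
    provenance: dict
    flagged: np.ndarray = None    # (V,) bool: degenerate-variance vertices
    vertex_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values.shape[1]
        if self.flagged is None:
            self.flagged = np.zeros(v, dtype=bool)
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(v)


# ---------------------------------------------------------------------------
# Model specifications and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanModel:
    """Additive mean model: intercept + linear terms + spline terms.

    ``smooth`` columns enter through a natural cubic regression spline with
    ``df`` basis columns (knots at quantiles, no smoothness selection — the
    basis is small and fixed so the fit is deterministic).  If ``by`` names
    a binary column, each spline is stratified: one copy per level.
    """

    linear: tuple[str, ...] = ()
    smooth: tuple[str, ...] = ()
    by: str | None = None
    df: int = 6


@dataclass(frozen=True)
class VarianceModel:
    """log(sigma) = intercept + linear terms in the named covariates."""

    linear: tuple[str, ...] = ()


@dataclass(frozen=True)
class AdjustmentSettings:
    between: bool = True
    mean_model: MeanModel = MeanModel(linear=("x", "z"))
    var_model: VarianceModel = VarianceModel(linear=("x", "z"))
    within: bool = True
    radius: float = 5.0


def natural_spline_basis(x: np.ndarray, df: int = 6,
                         knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form), ``df`` columns.

    Knots default to ``df + 1`` quantiles of ``x`` (so ``df - 1`` interior
    knots).  The basis excludes the intercept; column 0 is ``x`` itself and
    the rest are the usual ``d_k(x) - d_{K-1}(x)`` differences that enforce
    linearity beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if df < 2:
            raise ValueError("spline df must be >= 2")
        knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 distinct knots for a cubic spline")

    def d(j: int) -> np.ndarray:
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[j])

    dk1 = d(k - 2)
    cols = [x] + [d(j) - dk1 for j in range(k - 2)]
    return np.column_stack(cols)


def _mean_design(covs: pd.DataFrame, model: MeanModel) -> tuple[np.ndarray, list[str]]:
    n = len(covs)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for name in model.linear:
        cols.append(covs[name].to_numpy(float))
        names.append(name)
    strata: list[tuple[str, np.ndarray]] = [("", np.ones(n))]
    if model.by is not None:
        levels = np.unique(covs[model.by])
        if len(levels) != 2:
            raise ValueError(
                f"stratifier {model.by!r} must be binary, has {len(levels)} levels"
            )
        strata = [
            (f":{model.by}={lev}", (covs[model.by].to_numpy() == lev).astype(float))
            for lev in levels
        ]
    for name in model.smooth:
        basis = natural_spline_basis(covs[name].to_numpy(float), df=model.df)
        for suffix, ind in strata:
            for j in range(basis.shape[1]):
                cols.append(basis[:, j] * ind)
                names.append(f"s({name}){suffix}[{j}]")
    return np.column_stack(cols), names


def _var_design(covs: pd.DataFrame, model: VarianceModel) -> tuple[np.ndarray, list[str]]:
    n = len(covs)
    cols = [np.ones(n)] + [covs[c].to_numpy(float) for c in model.linear]
    return np.column_stack(cols), ["intercept", *model.linear]


def _check_full_rank(x: np.ndarray, names: list[str], what: str) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the first column that adds no rank
        r = 0
        for j in range(x.shape[1]):
            rj = np.linalg.matrix_rank(x[:, : j + 1])
            if rj == r:
                raise ValueError(
                    f"{what} design is rank-deficient: column {names[j]!r} is "
                    "collinear with earlier columns"
                )
            r = rj
        raise ValueError(f"{what} design is rank-deficient")


# ---------------------------------------------------------------------------
# Between-subject adjustment (vectorized location-scale fit)
# ---------------------------------------------------------------------------

def _fit_log_sd(e: np.ndarray, xv: np.ndarray, max_iter: int = 50,
                tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian ML fit of log(sigma) = Xv @ gamma per vertex, via Newton.

    ``e`` is the (N, V) matrix of mean-model residuals.  Returns
    ``(gamma (q, V), converged (V,))``.  The score is ``Xv' (u - 1)`` with
    ``u = e^2 / sigma^2`` and the Hessian ``2 Xv' diag(u) Xv``; both are
    batched over vertices.
    """
    n, v = e.shape
    q = xv.shape[1]
    e2 = e**2
    gamma = np.zeros((q, v))
    with np.errstate(divide="ignore"):
        gamma[0] = 0.5 * np.log(np.maximum(e2.mean(axis=0), 1e-300))
    converged = np.zeros(v, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(xv @ gamma, -20.0, 20.0)          # (N, V)
        u = e2 * np.exp(-2.0 * eta)
        score = xv.T @ (u - 1.0)                        # (q, V)
        converged = np.abs(score).max(axis=0) < tol * n
        if converged.all():
            break
        hess = 2.0 * np.einsum("nq,nv,np->vqp", xv, u, xv, optimize=True)
        # regularize any near-singular Hessian so the solve stays finite
        hess += 1e-10 * np.eye(q)
        step = np.linalg.solve(hess, score.T[:, :, None])[:, :, 0]  # (V, q)
        # dampen huge steps for stability far from the optimum
        step = np.clip(step, -2.0, 2.0)
        gamma = gamma + step.T * (~converged)
    return gamma, converged


def between_subject_adjust(
    y: np.ndarray,
    covs: pd.DataFrame,
    mean_model: MeanModel = MeanModel(),
    var_model: VarianceModel = VarianceModel(),
    n_iter: int = 2,
) -> ResidualMatrix:
    """Per-vertex location-scale standardization across subjects.

    Iterated two-stage estimation: (1) (weighted) least-squares fit of the
    mean design, (2) Gaussian ML Newton fit of log(sigma) on the variance
    design using the squared mean residuals; the pair is iterated ``n_iter``
    times (two passes suffice for the Gaussian location-scale model).
    Returns residuals ``(y - mu_hat) / sigma_hat``.

    With intercept-only models this reduces to the per-vertex z-score
    (ML/population SD convention, i.e. denominator N).
    """
    y = np.asarray(y, dtype=float)
    n, v = y.shape
    if len(covs) != n:
        raise ValueError(f"covariate table has {len(covs)} rows, data has {n}")
    xm, mean_names = _mean_design(covs, mean_model)
    xv, var_names = _var_design(covs, var_model)
    if n <= xm.shape[1] + 2:
        raise ValueError(
            f"need N > p_mean + 2 subjects (N={n}, p_mean={xm.shape[1]})"
        )
    _check_full_rank(xm, mean_names, "mean")
    _check_full_rank(xv, var_names, "variance")

    beta = np.linalg.solve(xm.T @ xm, xm.T @ y)          # (p, V)
    fallback = np.zeros(v, dtype=bool)
    gamma = np.zeros((xv.shape[1], v))
    for _ in range(n_iter):
        e = y - xm @ beta
        gamma, ok = _fit_log_sd(e, xv)
        if not ok.all():
            bad = ~ok
            fallback |= bad
            gamma[1:, bad] = 0.0
            with np.errstate(divide="ignore"):
                gamma[0, bad] = 0.5 * np.log(
                    np.maximum((e[:, bad] ** 2).mean(axis=0), 1e-300)
                )
        w = np.exp(-2.0 * np.clip(xv @ gamma, -20.0, 20.0))  # (N, V)
        hess = np.einsum("np,nv,nq->vpq", xm, w, xm, optimize=True)
        rhs = np.einsum("np,nv->vp", xm, w * y, optimize=True)
        beta = np.linalg.solve(hess, rhs[:, :, None])[:, :, 0].T
    if fallback.any():
        warnings.warn(
            f"scale fit fell back to constant variance at "
            f"{int(fallback.sum())} vertices",
            stacklevel=2,
        )
    e = y - xm @ beta
    sigma = np.exp(np.clip(xv @ gamma, -20.0, 20.0))
    resid = e / sigma
    return ResidualMatrix(
        values=resid,
        flagged=fallback,
        provenance={
            "between": {
                "mean_model": mean_names,
                "var_model": var_names,
                "n_iter": n_iter,
                "mean_coef": beta,       # (p, V)
                "log_sd_coef": gamma,    # (q, V)
            }
        },
    )


# ---------------------------------------------------------------------------
# Within-subject adjustment
# ---------------------------------------------------------------------------

def within_subject_adjust(
    y: np.ndarray | ResidualMatrix,
    index: NeighborhoodIndex,
    r: float = 5.0,
) -> ResidualMatrix:
    """Standardize each subject's map by local neighborhood mean and SD.

    For every analyzed vertex, ``eps_i(v) = (y_i(v) - mean_{N_r(v)}) /
    sd_{N_r(v)}`` with the neighborhood including ``v`` and the SD using the
    ``|N_r(v)| - 1`` denominator.  Locally constant patches (zero local
    variance) yield residual 0 and flag the vertex.  Masked-out vertices
    become NaN.
    """
    prior_prov: dict = {}
    if isinstance(y, ResidualMatrix):
        prior_prov = dict(y.provenance)
        y = y.values
    y = np.asarray(y, dtype=float)
    a = index.adjacency(r)
    sizes = np.asarray(a.sum(axis=1)).ravel()
    analyzed = index.mesh.analyzed
    small = sizes[analyzed] < 3
    if small.any():
        raise ValueError(
            f"{int(small.sum())} analyzed vertices have |N_r(v)| < 3 at "
            f"r={r} mm; increase the radius or refine the mesh"
        )
    at = a.T.tocsr()
    s1 = y @ at                 # sums over neighborhoods
    s2 = (y**2) @ at
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / sizes
        var = (s2 - sizes * mean**2) / (sizes - 1.0)
    var = np.where(var < 0, 0.0, var)   # numerical guard
    sd = np.sqrt(var)
    degenerate = sd <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (y - mean) / sd
    resid[degenerate] = 0.0
    resid[:, ~index.mesh.mask] = np.nan
    flagged = np.zeros(y.shape[1], dtype=bool)
    flagged[analyzed] = degenerate[:, analyzed].any(axis=0)
    if flagged.any():
        logger.warning(
            "within-subject adjustment: zero local variance at %d vertices "
            "(residuals set to 0)", int(flagged.sum()),
        )
    prov = dict(prior_prov)
    prov["within"] = {"radius": float(r)}
    return ResidualMatrix(values=resid, flagged=flagged, provenance=prov)


def compose_adjustments(
    y: np.ndarray,
    covs: pd.DataFrame,
    index: NeighborhoodIndex,
    settings: AdjustmentSettings = AdjustmentSettings(),
) -> ResidualMatrix:
    """Apply between-subject then within-subject adjustment per ``settings``.

    Disabling both returns the data unchanged apart from masking (masked-out
    vertices set to NaN).
    """
    out: np.ndarray | ResidualMatrix = np.asarray(y, dtype=float)
    prov: dict = {}
    if settings.between:
        out = between_subject_adjust(
            out, covs, settings.mean_model, settings.var_model
        )
        prov.update(out.provenance)
    if settings.within:
        out = within_subject_adjust(out, index, r=settings.radius)
        prov.update(out.provenance)
    if isinstance(out, ResidualMatrix):
        out.provenance = prov
        if not settings.within:
            vals = out.values.copy()
            vals[:, ~index.mesh.mask] = np.nan
            out.values = vals
        return out
    vals = out.copy()
    vals[:, ~index.mesh.mask] = np.nan
    return ResidualMatrix(values=vals, provenance={"identity": True})
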