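"""Testing covariate effects on coupling (Stages III-V).

Given subject-by-vertex coupling estimates ``rho_hat_i(v)`` and covariates
``(x_i, z_i)``, the tanh-linked correlation model is locally approximated
by the linear model ``E[rho_hat_i(v)] = b0(v) + z_i b1(v) + x_i kappa(v)``
(for |t| <= 0.5, |tanh(t) - t| <= 0.042, so the linearization is accurate
at the correlation magnitudes typical of imaging data).  The null
``kappa(v) = 0`` is tested with a score statistic built from the null-model
fit only:

    U(v) = sum_i x~_i * r_i(v)

where ``r_i(v)`` are null-model residuals and ``x~`` is the covariate of
interest residualized on ``[1, Z]``.  Adaptive cluster enhancement then
aggregates U over geodesic discs of growing radius and standardizes by the
exact permutation variance,

    T_r(v) = S(v, r)^2 / Var_H0(S(v, r)),   S(v, r) = sum_{v* in N_r(v)} U(v*)
    T(v)   = max_r T_r(v),

and family-wise error is controlled by permuting ``x~`` across subjects and
comparing T(v) with the permutation distribution of ``max_v T(v)``.

``Var_H0`` is the exact variance of ``S = sum_i a_{pi(i)} b_i`` under a
uniformly random permutation ``pi``: with ``a = x~`` centered,
``Var = (sum_i a_i^2) * (sum_i (b_i - b_bar)^2) / (N - 1)``, where
``b_i = R_i(v, r) = sum_{v* in N_r(v)} r_i(v*)``.  Because the statistic is
standardized by a permutation-invariant constant, the max-T permutation
test is exact regardless of the standardization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import sparse

from .coupling import CouplingMatrix
from .surface import NeighborhoodIndex

__all__ = [
    "NullModelFit",
    "ClusterEnhancement",
    "ClusterTestResult",
    "EffectSizeMap",
    "fit_null_model",
    "score_statistics",
    "cluster_enhance",
    "permutation_test",
    "mass_univariate_test",
    "effect_size_map",
]


# ---------------------------------------------------------------------------
# Stage III: null model
# ---------------------------------------------------------------------------

@dataclass
class NullModelFit:
    """Per-vertex least-squares fit of coupling on the nuisance design [1, Z].

    ``residuals`` are orthogonal to [1, Z] at every vertex; ``x_tilde`` is
    the covariate of interest residualized on the same design (zero mean,
    orthogonal to Z).  ``coupling`` keeps the raw coupling values for the
    joint permutation scheme.
    """

    residuals: np.ndarray        # (N, Va)
    coupling: np.ndarray         # (N, Va)
    x_tilde: np.ndarray          # (N,)
    beta0: np.ndarray            # (Va,)
    beta_nuisance: np.ndarray    # (q, Va)
    vertex_ids: np.ndarray       # (Va,) column ids into the full mesh
    interest: str = "x"
    nuisance: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]


def _coupling_values(rho) -> tuple[np.ndarray, dict]:
    if isinstance(rho, CouplingMatrix):
        return rho.values, rho.settings
    return np.asarray(rho, dtype=float), {}


def fit_null_model(
    rho,
    covs: pd.DataFrame,
    interest: str = "x",
    nuisance: tuple[str, ...] | None = None,
) -> NullModelFit:
    """Fit the null model (no ``x`` term) at every analyzed vertex.

    Vertices with any non-finite coupling value (e.g., outside the mesh
    mask) are dropped from the fit and carry no test statistic.
    """
    values, _ = _coupling_values(rho)
    if nuisance is None:
        nuisance = tuple(c for c in covs.columns if c != interest)
    n = values.shape[0]
    if len(covs) != n:
        raise ValueError(f"covariate table has {len(covs)} rows, coupling has {n}")
    if n <= len(nuisance) + 2:
        raise ValueError("need N > #nuisance + 2 subjects")
    vertex_ids = np.flatnonzero(np.isfinite(values).all(axis=0))
    if vertex_ids.size == 0:
        raise ValueError("no vertex has complete finite coupling values")
    y = values[:, vertex_ids]
    z = np.column_stack([np.ones(n)] + [covs[c].to_numpy(float) for c in nuisance])
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError(f"nuisance design [1, {', '.join(nuisance)}] is collinear")
    ztz = z.T @ z
    beta = np.linalg.solve(ztz, z.T @ y)              # (1+q, Va)
    resid = y - z @ beta
    x = covs[interest].to_numpy(float)
    x_tilde = x - z @ np.linalg.solve(ztz, z.T @ x)
    return NullModelFit(
        residuals=resid,
        coupling=y,
        x_tilde=x_tilde,
        beta0=beta[0],
        beta_nuisance=beta[1:],
        vertex_ids=vertex_ids,
        interest=interest,
        nuisance=tuple(nuisance),
    )


def score_statistics(fit: NullModelFit) -> np.ndarray:
    """Vertex-level score statistics ``U(v) = sum_i x~_i r_i(v)``."""
    return fit.x_tilde @ fit.residuals


# ---------------------------------------------------------------------------
# Stage IV: adaptive cluster enhancement
# ---------------------------------------------------------------------------

@dataclass
class ClusterEnhancement:
    """Cluster sums, their exact permutation variances, and enhanced statistics."""

    radius_grid: tuple[float, ...]
    T_by_radius: np.ndarray      # (n_radii, Va)
    T: np.ndarray                # (Va,)
    signed_T: np.ndarray         # (Va,)
    argmax_radius: np.ndarray    # (Va,) smallest maximizing radius
    zero_variance: np.ndarray    # (Va,) flagged at any radius


class _EnhancementEngine:
    """Precomputed per-radius-group structures shared by observed and permuted passes.

    Radii whose neighborhoods coincide on the mesh are collapsed into
    groups; each group carries the subset adjacency over analyzed vertices
    and the (permutation-invariant) variance of the cluster sum.
    """

    def __init__(self, fit: NullModelFit, index: NeighborhoodIndex | None,
                 radius_grid) -> None:
        if index is None:
            if tuple(float(r) for r in radius_grid) != (0.0,):
                raise ValueError("a NeighborhoodIndex is required unless radius_grid == [0]")
            eye = sparse.identity(fit.residuals.shape[1], format="csr")
            grouped = [(eye, [0.0])]
        else:
            grid = tuple(float(r) for r in radius_grid)
            missing = set(grid) - set(index.radius_grid)
            if missing:
                raise ValueError(
                    f"radii {sorted(missing)} are not in the index's radius grid"
                )
            ids = fit.vertex_ids
            grouped = [
                (a[ids][:, ids].tocsr(), radii)
                for a, radii in index.radius_groups(grid)
            ]
        n = fit.n_subjects
        sum_x2 = float(fit.x_tilde @ fit.x_tilde)
        self.radius_grid = tuple(
            float(r) for _, radii in grouped for r in radii
        )
        self.groups = []
        for a, radii in grouped:
            r_mat = fit.residuals @ a.T             # (N, Va) cluster sums per subject
            centered = r_mat - r_mat.mean(axis=0)
            var = sum_x2 * (centered**2).sum(axis=0) / (n - 1)
            self.groups.append({"adjacency": a, "radii": radii, "var": var})

    def statistics(self, u: np.ndarray) -> ClusterEnhancement:
        """Enhanced statistics for one score field ``u`` of shape (Va,)."""
        t_rows, s_rows, radii = [], [], []
        zero_var = np.zeros(u.shape[-1], dtype=bool)
        for g in self.groups:
            s = g["adjacency"] @ u
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(g["var"] > 0, s**2 / g["var"], 0.0)
            zero_var |= g["var"] <= 0
            for r in g["radii"]:
                t_rows.append(t)
                s_rows.append(s)
                radii.append(r)
        t_by_radius = np.vstack(t_rows)
        s_by_radius = np.vstack(s_rows)
        best = t_by_radius.argmax(axis=0)            # first (smallest) maximizing radius
        cols = np.arange(t_by_radius.shape[1])
        t = t_by_radius[best, cols]
        signed_t = np.sign(s_by_radius[best, cols]) * t
        return ClusterEnhancement(
            radius_grid=tuple(radii),
            T_by_radius=t_by_radius,
            T=t,
            signed_T=signed_t,
            argmax_radius=np.asarray(radii, dtype=float)[best],
            zero_variance=zero_var,
        )

    def max_T(self, u_fields: np.ndarray) -> np.ndarray:
        """max over vertices and radii of T, for a (B, Va) batch of score fields."""
        best = np.zeros(u_fields.shape[0])
        for g in self.groups:
            s = (g["adjacency"] @ u_fields.T).T      # (B, Va)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(g["var"] > 0, s**2 / g["var"], 0.0)
            np.maximum(best, t.max(axis=1), out=best)
        return best


def cluster_enhance(
    fit: NullModelFit,
    index: NeighborhoodIndex | None,
    radius_grid=None,
) -> ClusterEnhancement:
    """Adaptive cluster enhancement of the observed score statistics.

    Ties in ``max_r T_r(v)`` resolve to the smallest maximizing radius, and
    ``signed_T`` carries the sign of the enhancing cluster sum at that
    radius (a display convention; the test uses ``T`` alone).
    """
    if radius_grid is None:
        radius_grid = index.radius_grid if index is not None else (0.0,)
    engine = _EnhancementEngine(fit, index, radius_grid)
    return engine.statistics(score_statistics(fit))


# ---------------------------------------------------------------------------
# Stage V: permutation inference
# ---------------------------------------------------------------------------

@dataclass
class ClusterTestResult:
    """Observed statistics, permutation null maxima, and the FWER decision."""

    U: np.ndarray
    T_by_radius: np.ndarray
    T: np.ndarray
    signed_T: np.ndarray
    threshold: float
    fwer_adjusted_p: np.ndarray
    significant: np.ndarray
    null_maxima: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None
    radius_grid: tuple[float, ...]
    vertex_ids: np.ndarray
    argmax_radius: np.ndarray
    zero_variance: np.ndarray
    scheme: str = "residual"
    settings: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-vertex result table (analyzed vertices only)."""
        return pd.DataFrame(
            {
                "vertex": self.vertex_ids,
                "U": self.U,
                "T": self.T,
                "signed_T": self.signed_T,
                "signed_sqrt_T": np.sign(self.signed_T) * np.sqrt(self.T),
                "enhancing_radius": self.argmax_radius,
                "fwer_adjusted_p": self.fwer_adjusted_p,
                "significant": self.significant,
            }
        )


def _make_permutations(n: int, b: int | None, exhaustive: bool,
                       rng: np.random.Generator) -> np.ndarray:
    if exhaustive:
        total = math.factorial(n)
        if total > 50000:
            raise ValueError(
                f"exhaustive enumeration of {n}! = {total} permutations refused; "
                "use sampled permutations for N > 8"
            )
        perms = np.array(list(_iter_permutations(range(n)))[1:])  # drop identity
    else:
        if b is None or b < 100:
            raise ValueError("need B >= 100 sampled permutations")
        perms = np.stack([rng.permutation(n) for _ in range(b)])
    return perms


def permutation_test(
    fit: NullModelFit,
    index: NeighborhoodIndex | None = None,
    radius_grid=None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = 0,
    exhaustive: bool = False,
    scheme: str = "residual",
) -> ClusterTestResult:
    """Max-statistic permutation test of ``kappa(v) = 0`` with FWER control.

    The residualized covariate ``x~`` is permuted across subjects while the
    residuals (Stages I-II) stay fixed; for each permutation the enhanced
    statistics are recomputed and the map-wide maximum recorded.  The
    threshold is the ``ceil((1 - alpha) (B + 1))``-th smallest null maximum
    and adjusted p-values use the ``(1 + count) / (B + 1)`` convention, so
    the test is valid at finite B.

    ``scheme='joint'`` permutes ``(x, z)`` jointly and refits the null model
    per permutation; by orthogonality of the refitted residuals this
    collapses to scoring the permuted ``x~`` against the raw coupling
    values, which is how it is computed.  ``exhaustive=True`` enumerates all
    ``N! - 1`` non-identity permutations (toy problems only).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if scheme not in ("residual", "joint"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if radius_grid is None:
        radius_grid = index.radius_grid if index is not None else (0.0,)
    engine = _EnhancementEngine(fit, index, radius_grid)
    u_obs = score_statistics(fit)
    enh = engine.statistics(u_obs)

    rng = np.random.default_rng(seed)
    perms = _make_permutations(fit.n_subjects, B, exhaustive, rng)
    b = len(perms)
    target = fit.residuals if scheme == "residual" else fit.coupling
    maxima = np.empty(b)
    batch = max(1, int(2e7) // max(1, target.shape[1] * 8))
    for start in range(0, b, batch):
        p = fit.x_tilde[perms[start : start + batch]]   # (batch, N)
        u_perm = p @ target                              # (batch, Va)
        maxima[start : start + batch] = engine.max_T(u_perm)

    sorted_max = np.sort(maxima)
    k = math.ceil((1.0 - alpha) * (b + 1))
    threshold = sorted_max[k - 1] if k <= b else np.inf
    # p(v) = (1 + #{M_b >= T(v)}) / (B + 1)
    count_ge = b - np.searchsorted(sorted_max, enh.T, side="left")
    p_adj = (1.0 + count_ge) / (b + 1.0)
    significant = enh.T > threshold
    return ClusterTestResult(
        U=u_obs,
        T_by_radius=enh.T_by_radius,
        T=enh.T,
        signed_T=enh.signed_T,
        threshold=float(threshold),
        fwer_adjusted_p=p_adj,
        significant=significant,
        null_maxima=maxima,
        n_permutations=b,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else None,
        radius_grid=tuple(float(r) for r in engine.radius_grid),
        vertex_ids=fit.vertex_ids,
        argmax_radius=enh.argmax_radius,
        zero_variance=enh.zero_variance,
        scheme=scheme,
        settings={"exhaustive": exhaustive},
    )


def mass_univariate_test(
    rho,
    covs: pd.DataFrame,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = 0,
    interest: str = "x",
    nuisance: tuple[str, ...] | None = None,
    **kwargs,
) -> ClusterTestResult:
    """Vertex-wise comparator: the same pipeline with radius grid {0}.

    Identical to ``permutation_test`` with no cluster enhancement.  Meant
    for coupling built *without* within-subject adjustment (a warning is
    issued otherwise, since the combination no longer matches the
    mass-univariate method it is named for).
    """
    if isinstance(rho, CouplingMatrix):
        adj = rho.settings.get("adjustment", {})
        if any("within" in m for m in adj.values() if isinstance(m, dict)):
            warnings.warn(
                "mass-univariate test on within-subject-adjusted coupling; "
                "this is no longer the plain vertex-wise comparator",
                stacklevel=2,
            )
    fit = fit_null_model(rho, covs, interest=interest, nuisance=nuisance)
    return permutation_test(
        fit, index=None, radius_grid=(0.0,), B=B, alpha=alpha, seed=seed, **kwargs
    )


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

@dataclass
class EffectSizeMap:
    """Per-vertex partial correlation of coupling with x given Z."""

    values: np.ndarray
    vertex_ids: np.ndarray
    flagged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vertex": self.vertex_ids, "partial_correlation": self.values}
        )


def effect_size_map(
    rho,
    covs: pd.DataFrame,
    interest: str = "x",
    nuisance: tuple[str, ...] | None = None,
) -> EffectSizeMap:
    """Partial correlation between coupling and the covariate of interest.

    Both coupling and ``x`` are residualized on ``[1, Z]``; the map is the
    Pearson correlation of the two residual vectors at each vertex.
    Zero-variance vertices get value 0 and are flagged.
    """
    fit = fit_null_model(rho, covs, interest=interest, nuisance=nuisance)
    if fit.n_subjects <= len(fit.nuisance) + 3:
        raise ValueError("need N > #nuisance + 3 subjects for a partial correlation")
    num = fit.x_tilde @ fit.residuals
    norm_r = np.sqrt((fit.residuals**2).sum(axis=0))
    norm_x = np.sqrt(fit.x_tilde @ fit.x_tilde)
    flagged = (norm_r <= 1e-14) | (norm_x <= 1e-14)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / (norm_r * norm_x)
    values[flagged] = 0.0
    values = np.clip(values, -1.0, 1.0)
    return EffectSizeMap(values=values, vertex_ids=fit.vertex_ids, flagged=flagged)
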