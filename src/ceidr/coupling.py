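"""Subject-level intermodal coupling estimates (Stage II and the IMCo comparator).

Two estimators of the subject-by-vertex coupling field:

* ``ceidr_coupling`` — the elementwise product of the two modalities'
  standardized residuals, ``rho_hat_i(v) = eps1_i(v) * eps2_i(v)``.  For
  correctly standardized bivariate-normal residuals this is an unbiased
  single-draw estimate of the conditional correlation (unbounded per cell;
  its expectation is rho).
* ``imco_coupling`` — locally *weighted correlation* of the raw maps over a
  kernel neighborhood, per subject and vertex.  This is the symmetric
  variant of intermodal coupling regression (IMCo): correlations replace
  slopes so neither modality is privileged.  Weights are Gaussian in
  geodesic distance, ``w = exp(-d^2 / (2 theta^2))`` with
  ``theta = FWHM / (2 sqrt(2 log 2))``, truncated to zero below 5% of the
  peak weight; a box kernel (equal weights within a radius) is also
  provided, under which IMCo coincides with the product estimator applied
  to within-subject-standardized residuals up to the n vs n-1 SD
  denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .adjust import ResidualMatrix
from .surface import NeighborhoodIndex

__all__ = ["CouplingMatrix", "ceidr_coupling", "imco_coupling", "fwhm_to_theta"]

logger = logging.getLogger(__name__)

#: weights below this fraction of the peak are truncated to zero.
WEIGHT_FLOOR = 0.05


@dataclass
class CouplingMatrix:
    """N-by-V subject-level coupling estimates plus method provenance."""

    values: np.ndarray
    method: str                      # 'ceidr-product' | 'imco-weighted-correlation'
    settings: dict
    flagged: np.ndarray = None       # (V,) degenerate-variance vertices

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.values.shape[1], dtype=bool)


def _values(x) -> tuple[np.ndarray, dict]:
    if isinstance(x, ResidualMatrix):
        return x.values, x.provenance
    return np.asarray(x, dtype=float), {}


def ceidr_coupling(e1, e2) -> CouplingMatrix:
    """Product of the modality-specific residuals, per subject and vertex."""
    v1, p1 = _values(e1)
    v2, p2 = _values(e2)
    if v1.shape != v2.shape:
        raise ValueError(f"residual shapes differ: {v1.shape} vs {v2.shape}")
    return CouplingMatrix(
        values=v1 * v2,
        method="ceidr-product",
        settings={"adjustment": {"modality1": p1, "modality2": p2}},
    )


def fwhm_to_theta(fwhm: float) -> float:
    """Gaussian scale parameter for a kernel of the given full-width at half-maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _kernel_weights(
    index: NeighborhoodIndex, kernel: str, fwhm: float | None, radius: float | None
) -> sparse.csr_matrix:
    d = index.distances.tocoo()
    if kernel == "gaussian":
        if fwhm is None or fwhm <= 0:
            raise ValueError("gaussian kernel requires fwhm > 0")
        theta = fwhm_to_theta(fwhm)
        cutoff = theta * np.sqrt(-2.0 * np.log(WEIGHT_FLOOR))
        if cutoff > index.max_radius + 1e-9:
            raise ValueError(
                f"FWHM={fwhm} mm needs distances to {cutoff:.1f} mm but the "
                f"neighborhood index stops at {index.max_radius} mm; rebuild "
                "the index with a larger maximum radius"
            )
        keep = d.data <= cutoff + 1e-12
        w = np.exp(-(d.data[keep] ** 2) / (2.0 * theta**2))
        rows, cols = d.row[keep], d.col[keep]
    elif kernel == "box":
        if radius is None or radius < 0:
            raise ValueError("box kernel requires a non-negative radius")
        keep = d.data <= radius + 1e-12
        w = np.ones(int(keep.sum()))
        rows, cols = d.row[keep], d.col[keep]
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    wm = sparse.coo_matrix((w, (rows, cols)), shape=d.shape).tocsr()
    wm.sort_indices()
    return wm


def imco_coupling(
    y1: np.ndarray,
    y2: np.ndarray,
    index: NeighborhoodIndex,
    fwhm: float = 5.0,
    kernel: str = "gaussian",
    radius: float | None = None,
) -> CouplingMatrix:
    """Locally weighted Pearson correlation of the two maps, per subject/vertex.

    The weighted correlation uses weighted means and weighted covariance
    normalized by the sum of weights (population convention), so it is
    invariant to rescaling the weights and reduces to the ordinary Pearson
    correlation under equal weights.  Vertices where either modality has
    zero weighted variance get coupling 0 and are flagged.  Symmetric in
    the two modalities by construction.
    """
    y1, _ = _values(y1)
    y2, _ = _values(y2)
    if y1.shape != y2.shape:
        raise ValueError(f"modality shapes differ: {y1.shape} vs {y2.shape}")
    w = _kernel_weights(index, kernel, fwhm, radius)
    wt = w.T.tocsr()
    sw = np.asarray(w.sum(axis=1)).ravel()
    analyzed = index.mesh.mask
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (y1 @ wt) / sw
        m2 = (y2 @ wt) / sw
        c11 = (y1**2 @ wt) / sw - m1**2
        c22 = (y2**2 @ wt) / sw - m2**2
        c12 = ((y1 * y2) @ wt) / sw - m1 * m2
    c11 = np.where(c11 < 0, 0.0, c11)
    c22 = np.where(c22 < 0, 0.0, c22)
    denom = np.sqrt(c11 * c22)
    degenerate = denom <= 1e-14
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = c12 / denom
    corr[degenerate] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr[:, ~analyzed] = np.nan
    flagged = np.zeros(y1.shape[1], dtype=bool)
    flagged[analyzed] = degenerate[:, analyzed].any(axis=0)
    if flagged.any():
        logger.warning(
            "IMCo coupling: zero weighted variance at %d vertices "
            "(coupling set to 0)", int(flagged.sum()),
        )
    return CouplingMatrix(
        values=corr,
        method="imco-weighted-correlation",
        settings={
            "kernel": kernel,
            "fwhm": fwhm if kernel == "gaussian" else None,
            "radius": radius if kernel == "box" else None,
            "weight_floor": WEIGHT_FLOOR,
        },
        flagged=flagged,
    )
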