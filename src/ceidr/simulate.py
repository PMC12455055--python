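"""Synthetic bivariate vertex-level data with covariate-dependent coupling.

Generative model, per subject ``i`` and vertex ``v`` and modality
``m in {1, 2}``::

    y_mi(v) = mu_m(z_i, x_i, v) + sigma_m(z_i, x_i, v) * eps_mi(v)

where ``(eps_1i(v), eps_2i(v))`` is bivariate standard normal with
correlation ``rho(z_i, x_i, v) = tanh(b0(v) + z_i b1(v) + x_i kappa(v))``.
The tanh link keeps correlations strictly inside (-1, 1).  The null
hypothesis of interest is ``kappa(v) = 0`` for all ``v``: the covariate of
interest ``x`` may move means and variances, but not the residual coupling.

The default study design places five disjoint geodesic discs on the mesh:

* region A — modality-1 mean and variance depend on (x, z); modality 2
  homogeneous; coupling tanh(0.3 + 0.1 z) (no x effect);
* region B — both modality means depend on (x, z), variances constant;
  coupling tanh(0.3 + 0.1 z);
* region C (15 mm) — means, variances, and coupling all covariate-dependent;
  coupling tanh(0.3 + 0.1 z + kappa x);
* regions D (7 mm) and E (5 mm) — coupling-only effects, mu = 0, sigma = 1;
* everywhere else — mu = 0, sigma = 1, rho = 0.

With ``kappa = 0`` the whole design satisfies the null, so the any-vertex
rejection rate estimates the family-wise error rate; with ``kappa > 0``
regions C, D, E carry signal of three spatial scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .surface import SurfaceMesh

__all__ = [
    "FieldSpec",
    "SimulationDesign",
    "default_design",
    "simulate_dataset",
    "correlation_field",
    "DEFAULT_KAPPA_GRID",
    "REGION_LABELS",
]

#: kappa sweep used in the power study.
DEFAULT_KAPPA_GRID: tuple[float, ...] = tuple(round(0.01 * k, 2) for k in range(10))

REGION_LABELS = ("A", "B", "C", "D", "E")

#: geodesic radii (mm) of the simulated regions; C/D/E carry the coupling
#: signal at three spatial scales.
DEFAULT_REGION_RADII: Mapping[str, float] = {
    "A": 10.0, "B": 10.0, "C": 15.0, "D": 7.0, "E": 5.0,
}

Fn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _zero(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    return np.zeros_like(np.asarray(x, dtype=float))


def linear_fn(cx: float = 0.0, cz: float = 0.0) -> Fn:
    """Affine covariate map (x, z) -> cx*x + cz*z."""
    def fn(x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return cx * np.asarray(x, float) + cz * np.asarray(z, float)
    return fn


@dataclass(frozen=True)
class FieldSpec:
    """Mean/variance/correlation structure shared by the vertices of a region.

    ``mean_fns`` and ``log_sd_fns`` map per-subject covariates (x, z) to the
    modality mean and log standard deviation; ``corr_params = (b0, b1, kappa)``
    parameterize rho = tanh(b0 + z*b1 + x*kappa).
    """

    mean_fns: tuple[Fn, Fn] = (_zero, _zero)
    log_sd_fns: tuple[Fn, Fn] = (_zero, _zero)
    corr_params: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def correlation(self, x, z) -> np.ndarray:
        b0, b1, kappa = self.corr_params
        x = np.asarray(x, float)
        z = np.asarray(z, float)
        return np.tanh(b0 + z * b1 + x * kappa)


def _default_specs(kappa: float) -> dict[str, FieldSpec]:
    hetero_mean = linear_fn(0.5, 0.5)
    hetero_logsd = linear_fn(0.2, 0.0)
    return {
        "A": FieldSpec(
            mean_fns=(hetero_mean, _zero),
            log_sd_fns=(hetero_logsd, _zero),
            corr_params=(0.3, 0.1, 0.0),
        ),
        "B": FieldSpec(
            mean_fns=(hetero_mean, hetero_mean),
            corr_params=(0.3, 0.1, 0.0),
        ),
        "C": FieldSpec(
            mean_fns=(hetero_mean, hetero_mean),
            log_sd_fns=(hetero_logsd, hetero_logsd),
            corr_params=(0.3, 0.1, kappa),
        ),
        "D": FieldSpec(corr_params=(0.3, 0.1, kappa)),
        "E": FieldSpec(corr_params=(0.3, 0.1, kappa)),
        "null": FieldSpec(),
    }


@dataclass(frozen=True)
class SimulationDesign:
    """Region layout plus per-region field specifications on a mesh."""

    mesh: SurfaceMesh
    region_of: np.ndarray            # (V,) unicode labels, 'null' outside A-E
    specs: Mapping[str, FieldSpec]
    seed_vertices: Mapping[str, int] = field(default_factory=dict)
    region_radii: Mapping[str, float] = field(default_factory=dict)
    kappa: float = 0.0

    def vertices_in(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region_of == label)

    @property
    def signal_vertices(self) -> np.ndarray:
        """Vertices whose coupling depends on x when kappa != 0 (C, D, E)."""
        return np.flatnonzero(np.isin(self.region_of, ("C", "D", "E")))

    @property
    def region_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.region_of != "null")


def _farthest_point_seeds(mesh: SurfaceMesh, k: int) -> np.ndarray:
    """Deterministic maximally-separated seed vertices (greedy farthest-point)."""
    graph = mesh.edge_graph()
    analyzed = mesh.analyzed
    first = analyzed[0]
    seeds = [int(first)]
    mind = csgraph.dijkstra(graph, directed=False, indices=first)
    mind[~mesh.mask] = -np.inf
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        d = csgraph.dijkstra(graph, directed=False, indices=nxt)
        d[~mesh.mask] = -np.inf
        mind = np.minimum(mind, d)
    return np.array(seeds)


def default_design(
    mesh: SurfaceMesh,
    kappa: float,
    region_radii: Mapping[str, float] | None = None,
    specs: Mapping[str, FieldSpec] | None = None,
) -> SimulationDesign:
    """Place the five-region study design on a mesh.

    Seed vertices are chosen deterministically by greedy farthest-point
    sampling (largest regions first), so the layout is reproducible for a
    given mesh.  Raises ``ValueError`` if the discs cannot be placed
    disjointly on the mesh.
    """
    radii = dict(DEFAULT_REGION_RADII if region_radii is None else region_radii)
    if set(radii) != set(REGION_LABELS):
        raise ValueError(f"region_radii must cover exactly {REGION_LABELS}")
    specs = dict(_default_specs(kappa) if specs is None else specs)
    # largest discs claim the most separated seeds
    order = sorted(REGION_LABELS, key=lambda lab: -radii[lab])
    seeds = _farthest_point_seeds(mesh, len(order))
    graph = mesh.edge_graph()
    region_of = np.full(mesh.n_vertices, "null", dtype="<U4")
    seed_of: dict[str, int] = {}
    for lab, seed in zip(order, seeds):
        d = csgraph.dijkstra(graph, directed=False, indices=seed)
        inside = (d <= radii[lab]) & mesh.mask
        if not inside.any():
            raise ValueError(f"region {lab}: geodesic disc contains no vertices")
        clash = inside & (region_of != "null")
        if clash.any():
            raise ValueError(
                f"region {lab} (radius {radii[lab]} mm) overlaps region "
                f"{region_of[np.flatnonzero(clash)[0]]}; the mesh is too small "
                "for disjoint discs of the requested radii"
            )
        region_of[inside] = lab
        seed_of[lab] = int(seed)
    return SimulationDesign(
        mesh=mesh, region_of=region_of, specs=specs,
        seed_vertices=seed_of, region_radii=radii, kappa=float(kappa),
    )


def _per_vertex_fields(design: SimulationDesign, x: np.ndarray, z: np.ndarray):
    """Broadcast region specs to (N, V) mu/sigma/rho arrays."""
    n, v = len(x), design.mesh.n_vertices
    mu1 = np.zeros((n, v)); mu2 = np.zeros((n, v))
    sd1 = np.ones((n, v)); sd2 = np.ones((n, v))
    rho = np.zeros((n, v))
    for lab, spec in design.specs.items():
        idx = design.vertices_in(lab)
        if idx.size == 0:
            continue
        mu1[:, idx] = spec.mean_fns[0](x, z)[:, None]
        mu2[:, idx] = spec.mean_fns[1](x, z)[:, None]
        sd1[:, idx] = np.exp(spec.log_sd_fns[0](x, z))[:, None]
        sd2[:, idx] = np.exp(spec.log_sd_fns[1](x, z))[:, None]
        rho[:, idx] = spec.correlation(x, z)[:, None]
    return mu1, mu2, sd1, sd2, rho


def simulate_dataset(
    design: SimulationDesign, n_subjects: int = 200, seed: int | np.random.SeedSequence = 0
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw one dataset from the generative model.

    Covariates ``x, z`` are iid standard normal; residual pairs are drawn
    from the bivariate normal with the design's correlation via its Cholesky
    factor (``eps2 = rho*eps1 + sqrt(1-rho^2)*u``).  Fully reproducible from
    ``seed``; the draw order (x, z, eps1, u) is part of the contract.

    Returns ``(y1, y2, covariates)`` with ``y`` of shape (N, V) and a
    covariate table with columns ``x`` and ``z``.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    rng = np.random.default_rng(seed)
    n, v = n_subjects, design.mesh.n_vertices
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    eps1 = rng.standard_normal((n, v))
    u = rng.standard_normal((n, v))
    mu1, mu2, sd1, sd2, rho = _per_vertex_fields(design, x, z)
    eps2 = rho * eps1 + np.sqrt(1.0 - rho**2) * u
    y1 = mu1 + sd1 * eps1
    y2 = mu2 + sd2 * eps2
    covs = pd.DataFrame({"x": x, "z": z})
    return y1, y2, covs


def correlation_field(design: SimulationDesign, x: float, z: float) -> np.ndarray:
    """Per-vertex true correlation rho(z, x, v) for scalar covariates."""
    rho = np.zeros(design.mesh.n_vertices)
    xa = np.atleast_1d(float(x))
    za = np.atleast_1d(float(z))
    for lab, spec in design.specs.items():
        idx = design.vertices_in(lab)
        if idx.size:
            rho[idx] = spec.correlation(xa, za)[0]
    return rho
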