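"""Delimited-text matrices, covariate tables, and per-vertex overlays.

Canonical on-disk formats:

* measurement matrix — TSV, one row per subject, header row of vertex ids
  (``v0 .. v{V-1}``), first column ``subject``;
* covariate table — TSV with named columns, one row per subject;
* per-vertex result/overlay tables — TSV keyed by ``vertex``;
* FreeSurfer per-vertex overlays ("curv" format) as an optional interface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_covariates",
    "read_covariates",
    "write_sidecar",
    "read_sidecar",
    "write_overlay",
]


def write_matrix(path, values: np.ndarray) -> None:
    values = np.asarray(values)
    df = pd.DataFrame(
        values, columns=[f"v{j}" for j in range(values.shape[1])]
    )
    df.insert(0, "subject", np.arange(values.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "subject" in df.columns:
        df = df.drop(columns="subject")
    return df.to_numpy(float)


def write_covariates(path, covs: pd.DataFrame) -> None:
    covs.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sidecar(path, metadata: dict) -> None:
    """Reproducibility sidecar (seed, settings, provenance) as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)


def read_sidecar(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_overlay(path, values: np.ndarray, vertex_ids: np.ndarray,
                  n_vertices: int, fill: float = 0.0) -> None:
    """Write a per-vertex map as a FreeSurfer morph-data ("curv") overlay."""
    from nibabel.freesurfer import write_morph_data

    full = np.full(n_vertices, fill, dtype=float)
    full[np.asarray(vertex_ids, dtype=int)] = values
    write_morph_data(str(path), full)
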