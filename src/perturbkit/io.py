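"""Reading and writing datasets: MTX directories, .h5ad, TSV directories.

On-disk MTX follows the common single-cell dialect: ``matrix.mtx`` stores
features x cells (an ``orientation: features_x_cells`` comment is written
into the MatrixMarket header), with ``cells.tsv`` (cell_id plus all
annotation columns) and ``features.tsv`` (feature_id) sidecars. The reader
transposes back to cells x features. ``.h5ad`` round-trips matrix,
annotations, layers and representations through :mod:`anndata`; the TSV
format writes a dense ``matrix.tsv`` with the same sidecars and is meant
for small matrices only.

Writers are deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

import anndata as ad

from .core import PerturbationDataset
from .guides import GuideCountMatrix

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_guide_counts_mtx",
    "write_guide_counts_mtx",
    "write_manifest",
]

FORMATS = ("mtx_dir", "h5ad", "tsv")


def _check_sidecars(path: Path, matrix_rows: int, matrix_cols: int):
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str)
    features = pd.read_csv(path / "features.tsv", sep="\t", dtype=str)
    if len(cells) != matrix_cols:
        raise ValueError(
            f"{path / 'cells.tsv'}: {len(cells)} rows but matrix has "
            f"{matrix_cols} cells (line count mismatch at line {len(cells) + 1})"
        )
    if len(features) != matrix_rows:
        raise ValueError(
            f"{path / 'features.tsv'}: {len(features)} rows but matrix has "
            f"{matrix_rows} features (line count mismatch at line "
            f"{len(features) + 1})"
        )
    return cells, features


def read_dataset(path, fmt: str) -> PerturbationDataset:
    """Read a dataset from ``mtx_dir``, ``h5ad`` or ``tsv``."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format '{fmt}'; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(str(path))

    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
        obs = adata.obs.copy()
        return PerturbationDataset(
            matrix=adata.X,
            obs=obs,
            feature_ids=list(adata.var_names),
            representations={k: np.asarray(v) for k, v in adata.obsm.items()},
            layers={k: np.asarray(v) for k, v in adata.layers.items()},
        )

    if fmt == "mtx_dir":
        try:
            mat = scipy.io.mmread(path / "matrix.mtx")
        except Exception as exc:
            raise ValueError(f"malformed MTX at {path / 'matrix.mtx'}: {exc}")
        mat = sp.csr_matrix(mat)
        cells, features = _check_sidecars(path, mat.shape[0], mat.shape[1])
        obs = cells.set_index("cell_id")
        layers = {}
        for layer_file in sorted(path.glob("layer_*.mtx")):
            name = layer_file.stem[len("layer_"):]
            layers[name] = sp.csr_matrix(scipy.io.mmread(layer_file)).T.toarray()
        reps = {}
        for rep_file in sorted(path.glob("rep_*.tsv")):
            name = rep_file.stem[len("rep_"):]
            reps[name] = pd.read_csv(rep_file, sep="\t", header=None).to_numpy()
        return PerturbationDataset(
            matrix=mat.T.tocsr(),  # stored features x cells
            obs=obs,
            feature_ids=list(features["feature_id"]),
            representations=reps,
            layers=layers,
        )

    # tsv
    mat = pd.read_csv(path / "matrix.tsv", sep="\t", header=None).to_numpy()
    cells, features = _check_sidecars(path, mat.shape[1], mat.shape[0])
    return PerturbationDataset(
        matrix=mat,
        obs=cells.set_index("cell_id"),
        feature_ids=list(features["feature_id"]),
    )


def write_dataset(ds: PerturbationDataset, path, fmt: str) -> None:
    """Write a dataset in the requested format (deterministic output)."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format '{fmt}'; expected one of {FORMATS}")

    if fmt == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        adata = ad.AnnData(
            X=ds.matrix if sp.issparse(ds.matrix)
            else np.asarray(ds.matrix, dtype=float),
            obs=ds.obs.copy(),
            var=pd.DataFrame(index=pd.Index(ds.feature_ids, name="feature_id")),
        )
        for k, v in ds.representations.items():
            adata.obsm[k] = np.asarray(v, dtype=float)
        for k, v in ds.layers.items():
            adata.layers[k] = (
                v if sp.issparse(v) else np.asarray(v, dtype=float)
            )
        adata.write_h5ad(path)
        return

    path.mkdir(parents=True, exist_ok=True)
    cells = ds.obs.copy()
    cells.insert(0, "cell_id", ds.obs.index.astype(str))
    cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    pd.DataFrame({"feature_id": ds.feature_ids}).to_csv(
        path / "features.tsv", sep="\t", index=False
    )
    if fmt == "mtx_dir":
        mat = ds.matrix if sp.issparse(ds.matrix) else sp.csr_matrix(
            np.asarray(ds.matrix, dtype=float)
        )
        scipy.io.mmwrite(
            path / "matrix.mtx", mat.T.tocoo(),
            comment="orientation: features_x_cells",
        )
        for name, layer in ds.layers.items():
            lmat = layer if sp.issparse(layer) else sp.csr_matrix(
                np.asarray(layer, dtype=float)
            )
            scipy.io.mmwrite(
                path / f"layer_{name}.mtx", lmat.T.tocoo(),
                comment="orientation: features_x_cells",
            )
        for name, rep in ds.representations.items():
            pd.DataFrame(np.asarray(rep, dtype=float)).to_csv(
                path / f"rep_{name}.tsv", sep="\t", index=False, header=False
            )
    else:  # tsv (dense, small data only)
        dense = ds.X_dense()
        pd.DataFrame(dense).to_csv(
            path / "matrix.tsv", sep="\t", index=False, header=False
        )


def read_guide_counts_mtx(path) -> GuideCountMatrix:
    """Read guide counts from matrix.mtx (+ cells.tsv / guides.tsv)."""
    path = Path(path)
    mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str)
    guides = pd.read_csv(path / "guides.tsv", sep="\t", dtype=str)
    counts = mat.T  # stored guides x cells
    if counts.shape != (len(cells), len(guides)):
        raise ValueError(
            f"sidecar mismatch: counts {counts.shape} vs "
            f"{len(cells)} cells / {len(guides)} guides"
        )
    return GuideCountMatrix(
        counts=counts.toarray().astype(np.int64),
        cell_ids=list(cells["cell_id"]),
        guide_ids=list(guides["guide_id"]),
    )


def write_guide_counts_mtx(g: GuideCountMatrix, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(g.dense().astype(np.int64))
    scipy.io.mmwrite(
        path / "matrix.mtx", mat.T.tocoo(),
        comment="orientation: guides_x_cells",
    )
    pd.DataFrame({"cell_id": g.cell_ids}).to_csv(
        path / "cells.tsv", sep="\t", index=False
    )
    pd.DataFrame({"guide_id": g.guide_ids}).to_csv(
        path / "guides.tsv", sep="\t", index=False
    )


def write_manifest(path, subcommand: str, params: dict, seed) -> None:
    """JSON run manifest sufficient to reproduce a CLI invocation."""
    import perturbkit

    manifest = {
        "subcommand": subcommand,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "versions": {
            "perturbkit": perturbkit.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    return v
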