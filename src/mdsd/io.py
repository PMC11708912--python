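"""File formats: expression TSV, truth JSON, path edge lists, result tables.

Everything is plain text.  An adjacency path is stored as one edge-list TSV
per model (columns ``node_i``, ``node_j``, 1-based) plus a ``manifest.json``
recording the grid axes, enumeration order, estimator name and tolerances,
so a path can be re-read into an identical degree matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import AdjacencyPath, TuningGrid

__all__ = [
    "write_expression", "read_expression",
    "write_truth", "read_truth",
    "write_path", "read_path",
    "write_mdsd_result",
    "select_top_variance_genes",
]


def write_expression(data: pd.DataFrame, path) -> None:
    """Samples × genes TSV: header of gene ids, first column sample ids."""
    data.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path, transpose=False, impute_missing=False):
    """Read an expression TSV/CSV (first column sample ids, header gene ids).

    ``transpose`` handles genes × samples exports.  Missing values are
    rejected unless ``impute_missing``, which mean-imputes per gene;
    non-numeric cells raise with the offending row and column named.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    data = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        data = data.T
    data.index.name = None
    data.columns.name = None
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna() & data[col].notna()
        if bad.any():
            row = data.index[bad.argmax()]
            raise ValueError(
                f"non-numeric value in column {col!r}, row {row!r}")
        data[col] = coerced
    if data.isna().any().any():
        if not impute_missing:
            raise ValueError(
                "expression matrix contains missing values; pass "
                "impute_missing=True to mean-impute per gene")
        data = data.fillna(data.mean())
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    return data


def write_truth(truth, path, precision_path=None) -> None:
    """Ground-truth network as JSON (1-based node ids); Θ optionally as TSV."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    if precision_path is not None:
        np.savetxt(precision_path, truth.precision, delimiter="\t")


def read_truth(path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("model", "p", "hub_ids", "edges"):
        if key not in d:
            raise ValueError(f"truth file missing key {key!r}")
    return d


def write_path(path_obj: AdjacencyPath, out_dir) -> None:
    """Serialize an adjacency path: model_<k>.tsv edge lists + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, adj in zip(path_obj.kept_indices, path_obj.graphs):
        i, j = np.nonzero(np.triu(adj, k=1))
        pd.DataFrame({"node_i": i + 1, "node_j": j + 1}).to_csv(
            out / f"model_{k:04d}.tsv", sep="\t", index=False)
    manifest = {
        "estimator": path_obj.estimator_name,
        "p": int(path_obj.p),
        "zero_tolerance": path_obj.zero_tolerance,
        "grid": path_obj.grid.to_dict(),
        "kept_indices": [int(k) for k in path_obj.kept_indices],
        "failures": {str(k): v for k, v in path_obj.failures.items()},
        "node_ids": list(path_obj.node_ids),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_path(in_dir) -> AdjacencyPath:
    """Re-read a serialized path; inverse of :func:`write_path`."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    grid = TuningGrid(manifest["grid"]["axes"])
    p = manifest["p"]
    graphs = []
    for k in manifest["kept_indices"]:
        f = src / f"model_{k:04d}.tsv"
        if not f.exists():
            raise ValueError(f"manifest lists model {k} but {f} is missing")
        edges = pd.read_csv(f, sep="\t")
        adj = np.zeros((p, p), dtype=bool)
        if len(edges):
            i = edges["node_i"].to_numpy() - 1
            j = edges["node_j"].to_numpy() - 1
            adj[i, j] = True
            adj[j, i] = True
        graphs.append(adj)
    return AdjacencyPath(
        grid, graphs, manifest["estimator"], manifest["zero_tolerance"],
        kept_indices=list(manifest["kept_indices"]),
        failures={int(k): v for k, v in manifest.get("failures", {}).items()},
        node_ids=manifest.get("node_ids"),
    )


def write_mdsd_result(result, path, manifest_path=None, s_min=None) -> None:
    """Result table (node_id, mdsd, hub_flag) plus a JSON manifest."""
    pd.DataFrame({
        "node_id": result.node_ids,
        "mdsd": result.mdsd,
        "hub_flag": result.hub_flags.astype(int),
    }).to_csv(path, sep="\t", index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump({
                "gamma": result.gamma,
                "cutoff": result.cutoff,
                "mean_mdsd": result.mean_mdsd,
                "s_min": s_min,
                "n_hubs": int(result.hub_flags.sum()),
                "retained_models": result.retained_models.astype(int).tolist(),
            }, fh, indent=1)


def select_top_variance_genes(data: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k genes with the largest sample variance.

    The standard pre-filter before graphical-model construction on genome-
    wide matrices.  Ties break by first occurrence in input order; column
    order of the selected genes follows the input.
    """
    p = data.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds the number of genes p={p}")
    variances = data.var(axis=0, ddof=1)
    order = np.argsort(-variances.to_numpy(), kind="stable")[:k]
    keep = np.sort(order)
    return data.iloc[:, keep]
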