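"""Node tables, manifests, dataset stores and network export.

The canonical node table ships with the package as
``data/nodes_aal92_synthetic.tsv``: 92 rows (90 AAL-style cortical and
subcortical parcels plus the two accumbens nuclei) with 13 seed regions
flagged. The names follow the AAL labelling convention; the centroid
coordinates are approximate synthetic stand-ins on the MNI millimetre
scale (the study's exact centroid table is not deposited) and users can
supply their own table, including their own seed flags.

Time-series and connectivity matrices are stored as flat ``.npy`` arrays
next to a TSV index (one row per array), which keeps every byte of a
results bundle reproducible from the same configuration and seed.
Significant networks are exported in the BrainNet Viewer text convention:
a ``.node`` file (x y z color size label) and a square ``.edge`` matrix.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .paradigm import MANIFEST_COLUMNS

NODE_COLUMNS = ["index", "name", "x", "y", "z", "is_seed"]
CANONICAL_N_NODES = 92
CANONICAL_N_SEEDS = 13

PathLike = Union[str, Path]


def canonical_node_table_path() -> Path:
    return Path(
        importlib.resources.files("megfc").joinpath("data/nodes_aal92_synthetic.tsv")
    )


def load_node_table(path: Optional[PathLike] = None, canonical: Optional[bool] = None) -> pd.DataFrame:
    """Load and validate a node table TSV.

    With no path the packaged canonical table is loaded and the canonical
    invariants (92 rows, 13 seeds) are enforced; pass ``canonical=True`` to
    enforce them on a user table as well.
    """
    if path is None:
        path = canonical_node_table_path()
        if canonical is None:
            canonical = True
    table = pd.read_csv(path, sep="\t")
    missing = set(NODE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    if table["name"].duplicated().any():
        dupes = table["name"][table["name"].duplicated()].tolist()
        raise ValueError(f"duplicate node names: {dupes}")
    if not np.array_equal(table["index"].to_numpy(), np.arange(len(table))):
        raise ValueError("node index column must be 0-based and consecutive")
    table["is_seed"] = table["is_seed"].astype(bool)
    if canonical:
        if len(table) != CANONICAL_N_NODES:
            raise ValueError(
                f"canonical node table must have {CANONICAL_N_NODES} rows, "
                f"got {len(table)}"
            )
        n_seeds = int(table["is_seed"].sum())
        if n_seeds != CANONICAL_N_SEEDS:
            raise ValueError(
                f"canonical node table must flag {CANONICAL_N_SEEDS} seeds, got {n_seeds}"
            )
    return table


def write_node_table(table: pd.DataFrame, path: PathLike) -> None:
    out = table.copy()
    out["is_seed"] = out["is_seed"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def generic_node_table(n_nodes: int, n_seeds: int = 0) -> pd.DataFrame:
    """Placeholder node table (P000...) for non-canonical parcel counts."""
    return pd.DataFrame(
        {
            "index": np.arange(n_nodes),
            "name": [f"P{i:03d}" for i in range(n_nodes)],
            "x": np.zeros(n_nodes),
            "y": np.zeros(n_nodes),
            "z": np.zeros(n_nodes),
            "is_seed": [i < n_seeds for i in range(n_nodes)],
        }
    )


def seed_indices(table: pd.DataFrame) -> list[int]:
    return table.index[table["is_seed"]].tolist()


# ---------------------------------------------------------------------------
# manifests

def write_manifest(manifest: pd.DataFrame, path: PathLike) -> None:
    manifest.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_manifest(path: PathLike) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest["is_rest"] = manifest["is_rest"].astype(bool)
    return manifest


# ---------------------------------------------------------------------------
# array stores (flat binary + TSV sidecar)

def save_array_store(arrays: dict[str, np.ndarray], directory: PathLike,
                     meta: Optional[dict] = None) -> None:
    """Write named arrays as .npy files plus an index.tsv sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for key in sorted(arrays):
        fname = key + ".npy"
        np.save(directory / fname, np.ascontiguousarray(arrays[key]))
        rows.append({"key": key, "file": fname, "shape": "x".join(map(str, arrays[key].shape))})
    pd.DataFrame(rows, columns=["key", "file", "shape"]).to_csv(
        directory / "index.tsv", sep="\t", index=False
    )
    if meta is not None:
        with open(directory / "meta.json", "w") as f:
            json.dump(meta, f, indent=2, sort_keys=True)
            f.write("\n")


def load_array_store(directory: PathLike) -> tuple[dict[str, np.ndarray], dict]:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.tsv", sep="\t")
    arrays = {
        row["key"]: np.load(directory / row["file"]) for _, row in index.iterrows()
    }
    meta_path = directory / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return arrays, meta


# ---------------------------------------------------------------------------
# BrainNet-convention network export

def export_network(
    edges: Sequence[tuple[int, int]],
    node_table: pd.DataFrame,
    prefix: PathLike,
    weights: Optional[np.ndarray] = None,
) -> tuple[Path, Path]:
    """Write a component as BrainNet-style .node and .edge text files.

    Only the component's nodes are written; node size is its degree within
    the component and the color column marks seed membership. The .edge
    file is the square weight matrix over those nodes (1s when no weight
    matrix is given). Returns the two paths.
    """
    prefix = Path(prefix)
    nodes = sorted({i for e in edges for i in e})
    for i in nodes:
        if not 0 <= i < len(node_table):
            raise ValueError(f"unknown node index {i}")
    pos = {n: k for k, n in enumerate(nodes)}
    degree = {n: 0 for n in nodes}
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1

    node_path = prefix.with_suffix(".node")
    edge_path = prefix.with_suffix(".edge")
    with open(node_path, "w") as f:
        f.write("# x\ty\tz\tcolor\tsize\tlabel\n")
        for n in nodes:
            row = node_table.iloc[n]
            color = 2 if bool(row["is_seed"]) else 1
            f.write(
                f"{row['x']:g}\t{row['y']:g}\t{row['z']:g}\t{color}\t"
                f"{degree[n]}\t{row['name']}\n"
            )
    mat = np.zeros((len(nodes), len(nodes)))
    for i, j in edges:
        w = 1.0
        if weights is not None:
            w = float(np.asarray(weights)[i, j])
        mat[pos[i], pos[j]] = w
        mat[pos[j], pos[i]] = w
    with open(edge_path, "w") as f:
        f.write("# edge weight matrix, nodes as in the .node file\n")
        for row in mat:
            f.write("\t".join(f"{v:g}" for v in row) + "\n")
    return node_path, edge_path


def import_network(prefix: PathLike, node_table: pd.DataFrame) -> list[tuple[int, int]]:
    """Re-read an exported .node/.edge pair back into an edge list."""
    prefix = Path(prefix)
    labels = []
    with open(prefix.with_suffix(".node")) as f:
        for line in f:
            if line.startswith("#") or not line.strip():
                continue
            labels.append(line.rstrip("\n").split("\t")[-1])
    name_to_index = {n: i for i, n in enumerate(node_table["name"])}
    nodes = [name_to_index[lab] for lab in labels]
    rows = []
    with open(prefix.with_suffix(".edge")) as f:
        for line in f:
            if line.startswith("#") or not line.strip():
                continue
            rows.append([float(v) for v in line.split()])
    mat = np.asarray(rows) if rows else np.zeros((0, 0))
    edges = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if mat[a, b] != 0:
                edges.append((min(nodes[a], nodes[b]), max(nodes[a], nodes[b])))
    return sorted(edges)


def write_run_log(path: PathLike, entries: dict) -> None:
    """Deterministic JSON run log (sorted keys, no timestamps)."""
    with open(path, "w") as f:
        json.dump(entries, f, indent=2, sort_keys=True, default=str)
        f.write("\n")
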