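"""Readers/writers for expression TSVs, response CSVs and weight archives.

File conventions
----------------
Expression: tab-delimited text, genes in rows, first column header ``gene_id``,
remaining header fields are sample ids, numeric body.

Response: CSV with header ``sample_id,auc[,drug]``.

Weight archive: a single ``.npz`` container of named float arrays plus a JSON
metadata entry carrying gene ids, the network configuration and the creation
seed, so first-layer weights remain gene-addressable after a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (DataError, ExpressionMatrix, InputLayerWeights,
                         ResponseTable, collapse_duplicate_genes)

ARCHIVE_VERSION = 1


class ParseError(DataError):
    """A file could not be parsed; the message names the offending location."""


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Duplicate gene rows collapse to the first occurrence with a warning.
    Non-numeric body cells (including ``NA``) raise :class:`ParseError`
    naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found in header")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            # float() is correctly rounded, so shortest-repr files
            # round-trip bit-exactly (pd.to_numeric is not)
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError
                v = float(cell)
                if not np.isfinite(v):  # rejects 'nan'/'inf' strings too
                    raise ValueError
                values[i, j] = v
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell at gene '{df.index[i]}', "
                    f"sample '{col}'") from None
    gene_ids = [str(g) for g in df.index]
    gene_ids, values = collapse_duplicate_genes(gene_ids, values)
    return ExpressionMatrix(gene_ids, [str(c) for c in df.columns], values,
                            meta={"source_path": str(path)})


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     delimiter: str = "\t") -> None:
    """Write an expression matrix at full float precision (round-trip safe)."""
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter)  # shortest-repr floats: exact round trip


def read_response(path: str | Path) -> ResponseTable:
    """Read a ``sample_id,auc[,drug]`` CSV; drug defaults to ``"unknown"``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    for col in ("sample_id", "auc"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ParseError(f"{path}: duplicate sample ids: {dups}")
    auc = pd.to_numeric(df["auc"], errors="coerce")
    if auc.isna().any():
        bad = df.loc[auc.isna(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: non-numeric auc for sample '{bad}'")
    if "drug" in df.columns:
        drugs = df["drug"].astype(str).unique()
        if len(drugs) > 1:
            raise ParseError(f"{path}: multiple drugs in one response table: {list(drugs)}")
        drug = drugs[0]
    else:
        drug = "unknown"
    return ResponseTable(list(df["sample_id"]), auc.to_numpy(), drug=drug)


def write_response(resp: ResponseTable, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": resp.sample_ids, "auc": resp.auc,
                       "drug": resp.drug})
    df.to_csv(path, index=False)


def save_weights(obj, path: str | Path) -> None:
    """Serialize :class:`InputLayerWeights` or a ``ModelState`` to ``.npz``.

    Numeric payloads round-trip bitwise; metadata (gene ids, network config,
    creation seed) travels as a JSON entry inside the archive.
    """
    from .nn import ModelState  # local import: nn depends on containers only

    path = Path(path)
    if isinstance(obj, InputLayerWeights):
        meta = {"version": ARCHIVE_VERSION, "kind": "input_layer",
                "gene_ids": obj.gene_ids}
        np.savez(path, W=obj.W, b=obj.b,
                 _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
    elif isinstance(obj, ModelState):
        meta = {"version": ARCHIVE_VERSION, "kind": "model_state",
                "gene_ids": obj.gene_ids, "config": obj.config.to_dict()}
        arrays = {name: tensor for name, tensor in obj.parameters.items()}
        arrays["training_log"] = np.asarray(obj.training_log, dtype=np.float64)
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(),
                                           dtype=np.uint8), **arrays)
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def load_weights(path: str | Path):
    """Load an archive written by :func:`save_weights` (type round-trips)."""
    from .nn import ModelState, NetworkConfig

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = np.load(path)
    except Exception as exc:
        raise DataError(f"{path}: truncated or corrupt archive ({exc})") from exc
    with data:
        if "_meta" not in data:
            raise DataError(f"{path}: not a weight archive (no metadata)")
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("version") != ARCHIVE_VERSION:
            raise DataError(
                f"{path}: archive version {meta.get('version')} "
                f"unsupported (expected {ARCHIVE_VERSION})")
        kind = meta.get("kind")
        if kind == "input_layer":
            for name in ("W", "b"):
                if name not in data:
                    raise DataError(f"{path}: missing array '{name}'")
            return InputLayerWeights(meta["gene_ids"], data["W"], data["b"])
        if kind == "model_state":
            config = NetworkConfig.from_dict(meta["config"])
            params = {}
            for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
                if name not in data:
                    raise DataError(f"{path}: missing array '{name}'")
                params[name] = data[name]
            log = list(data["training_log"]) if "training_log" in data else []
            return ModelState(config=config, parameters=params,
                              training_log=log, gene_ids=meta["gene_ids"])
        raise DataError(f"{path}: unknown archive kind '{kind}'")


def archive_manifest(path: str | Path) -> dict:
    """Return the JSON metadata stored in a weight archive."""
    with np.load(Path(path)) as data:
        if "_meta" not in data:
            raise DataError(f"{path}: not a weight archive (no metadata)")
        meta = json.loads(bytes(data["_meta"]).decode())
        meta["arrays"] = {k: list(data[k].shape) for k in data.files if k != "_meta"}
    return meta
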