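"""CSV/TSV readers and writers, model persistence and config snapshots.

Conventions: feature matrices are CSV/TSV with a header row of feature names
and a first column of sample ids; response matrices carry the dose grid (uM)
as their header row.  Predictions are written as long CSV (curve mode:
``sample_id, dose, predicted, sd``) or tidy metric CSV (``sample_id, metric,
value, reached``); metrics whose crossing was not reached in-span are empty
cells flagged ``reached=0``.  Models persist to a versioned JSON archive of
packed tree records plus the estimator config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import DoseGrid, is_reached
from .forest import (
    FunctionalMetricForest,
    FunctionalRandomForest,
    MultivariateRandomForest,
    PerDoseRandomForest,
    ScalarRandomForest,
)

__all__ = ["read_feature_matrix", "read_response_matrix", "align_samples",
           "write_curve_predictions", "read_curve_predictions",
           "write_metric_predictions", "read_metric_predictions",
           "write_predictions", "save_forest", "load_forest",
           "write_config_snapshot", "read_config_snapshot"]

log = logging.getLogger("funcforest")

MODEL_FORMAT_VERSION = 1

_CLASSES = {cls.__name__: cls for cls in
            (ScalarRandomForest, MultivariateRandomForest,
             FunctionalRandomForest, FunctionalMetricForest,
             PerDoseRandomForest)}


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, header=0, dtype=str,
                       keep_default_na=False)


def _numeric_block(df: pd.DataFrame, path) -> np.ndarray:
    values = np.empty(df.shape, dtype=float)
    for c, col in enumerate(df.columns):
        try:
            values[:, c] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            r = int(np.nonzero(bad.isna().to_numpy())[0][0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[r]!r} at row {r + 1},"
                f" column {c + 2}") from None
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite values")
    return values


def read_feature_matrix(path):
    """-> (matrix, sample_ids, feature_names); first column is the id."""
    df = _read_table(path)
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    names = list(df.columns[1:])
    return _numeric_block(df.iloc[:, 1:], path), ids, names


def read_response_matrix(path):
    """-> (matrix, DoseGrid, sample_ids); header row parses as doses in uM."""
    df = _read_table(path)
    try:
        doses = np.array([float(c) for c in df.columns[1:]])
    except ValueError:
        raise ValueError(f"{path}: response header must be numeric doses") from None
    grid = DoseGrid(doses)  # validates increasing/positive
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample id")
    return _numeric_block(df.iloc[:, 1:], path), grid, ids


def align_samples(feature_ids, response_ids):
    """Inner-join positions, in feature-file order; logs dropped samples."""
    pos = {sid: i for i, sid in enumerate(response_ids)}
    fi, ri = [], []
    dropped = 0
    for i, sid in enumerate(feature_ids):
        if sid in pos:
            fi.append(i)
            ri.append(pos[sid])
        else:
            dropped += 1
    extra = len(response_ids) - len(ri)
    if dropped or extra:
        log.warning("sample join: kept %d, dropped %d feature rows / %d "
                    "response rows", len(fi), dropped, extra)
    if not fi:
        raise ValueError("no overlapping sample ids")
    return np.asarray(fi), np.asarray(ri)


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------


def write_curve_predictions(path, sample_ids, doses, predicted, sd=None):
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    sd = (np.zeros_like(predicted) if sd is None
          else np.atleast_2d(np.asarray(sd, dtype=float)))
    rows = []
    for i, sid in enumerate(sample_ids):
        for j, d in enumerate(np.asarray(doses, dtype=float)):
            rows.append((sid, repr(float(d)), repr(float(predicted[i, j])),
                         repr(float(sd[i, j]))))
    pd.DataFrame(rows, columns=["sample_id", "dose", "predicted", "sd"]) \
        .to_csv(path, index=False)


def read_curve_predictions(path):
    df = pd.read_csv(path, dtype={"sample_id": str})
    ids = list(dict.fromkeys(df["sample_id"]))
    doses = np.array(sorted(set(df["dose"])))
    mat = df.pivot(index="sample_id", columns="dose", values="predicted") \
        .loc[ids].to_numpy()
    sd = df.pivot(index="sample_id", columns="dose", values="sd") \
        .loc[ids].to_numpy()
    return ids, doses, mat, sd


def write_metric_predictions(path, sample_ids, metrics: dict):
    """``metrics`` maps metric name -> value vector; NOT_REACHED values are
    written as empty cells with the ``reached`` flag cleared."""
    rows = []
    for name, vec in metrics.items():
        for sid, v in zip(sample_ids, np.asarray(vec, dtype=float)):
            rows.append((sid, name, repr(float(v)) if is_reached(v) else "",
                         int(is_reached(v))))
    pd.DataFrame(rows, columns=["sample_id", "metric", "value", "reached"]) \
        .to_csv(path, index=False)


def read_metric_predictions(path):
    df = pd.read_csv(path, dtype={"sample_id": str})
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        val = float(row["value"]) if row["reached"] == 1 else float("nan")
        out.setdefault(row["metric"], {})[row["sample_id"]] = val
    return out


def write_predictions(path, predictions):
    """Dispatching writer: a ``(sample_ids, doses, matrix[, sd])`` tuple goes
    to the long curve format, a ``(sample_ids, {metric: values})`` pair to
    the tidy metric format."""
    if len(predictions) == 2 and isinstance(predictions[1], dict):
        write_metric_predictions(path, *predictions)
    else:
        write_curve_predictions(path, *predictions)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

_ARRAY_ATTRS = ("_feat", "_thr", "_left", "_right", "_start", "_end",
                "_members", "_node_count", "bootstrap_indices_", "_tree_seeds",
                "vim_picked_", "vim_selected_", "y_train_", "leaf_metric_",
                "omega_")
_SCALAR_ATTRS = ("n_features_in_", "_n_train", "_m")


def _encode(model) -> dict:
    doc = {"class": type(model).__name__, "params": model.get_params()}
    if isinstance(model, PerDoseRandomForest):
        doc["forests"] = [_encode(f) for f in model.forests_]
        doc["n_features_in"] = model.n_features_in_
        doc["doses"] = (model.grid_.doses.tolist()
                        if getattr(model, "grid_", None) is not None else None)
        return doc
    for attr in _ARRAY_ATTRS:
        if hasattr(model, attr):
            arr = getattr(model, attr)
            doc[attr] = {"data": arr.tolist(), "dtype": str(arr.dtype)}
    for attr in _SCALAR_ATTRS:
        if hasattr(model, attr):
            doc[attr] = int(getattr(model, attr))
    grid = getattr(model, "grid_", None)
    doc["doses"] = grid.doses.tolist() if grid is not None else None
    return doc


def _decode(doc: dict):
    cls = _CLASSES[doc["class"]]
    model = cls(**doc["params"])
    if cls is PerDoseRandomForest:
        model.forests_ = [_decode(d) for d in doc["forests"]]
        model.n_features_in_ = doc["n_features_in"]
        model.grid_ = DoseGrid(np.array(doc["doses"])) if doc["doses"] else None
        return model
    for attr in _ARRAY_ATTRS:
        if attr in doc:
            setattr(model, attr,
                    np.array(doc[attr]["data"], dtype=doc[attr]["dtype"]))
    for attr in _SCALAR_ATTRS:
        if attr in doc:
            setattr(model, attr, doc[attr])
    model.grid_ = DoseGrid(np.array(doc["doses"])) if doc.get("doses") else None
    return model


def save_forest(path, model) -> None:
    """Persist a fitted forest as a versioned JSON archive of tree records."""
    doc = {"format": "funcforest-model", "version": MODEL_FORMAT_VERSION}
    doc.update(_encode(model))
    Path(path).write_text(json.dumps(doc))


def load_forest(path):
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "funcforest-model":
        raise ValueError(f"{path}: not a funcforest model archive")
    if doc.get("version", 0) > MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version")
    return _decode(doc)


# ---------------------------------------------------------------------------
# config snapshots
# ---------------------------------------------------------------------------


def write_config_snapshot(path, config: dict) -> None:
    """Plain key=value text snapshot (reproducibility record of a run)."""
    lines = [f"{k}={config[k]!r}" for k in sorted(config)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config_snapshot(path) -> dict:
    import ast

    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = ast.literal_eval(val.strip())
    return out
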