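"""Reading and writing the package's on-disk formats.

Panels travel as plain CSV with an explicit JSON schema sidecar
(``<name>.schema.json``) — no column-type inference. Networks are written
both as weighted edge lists (TSV) and as full-matrix JSON with estimation
metadata; ground truths and analysis results serialize to JSON. Every
stochastic result embeds its seed and replicate count.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GroundTruth
from .errors import ConfigError
from .network import EstimatorConfig, NetworkModel
from .panels import ID_COLUMNS, ItemMeta, ItemPanel, ScorePanel

__all__ = [
    "write_score_panel",
    "read_score_panel",
    "write_item_panel",
    "read_item_panel",
    "write_network",
    "read_network",
    "write_ground_truth",
    "read_ground_truth",
    "write_result_json",
]


def _schema_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".schema.json")


def write_score_panel(panel: ScorePanel, path: str | Path) -> None:
    path = Path(path)
    panel.data[ID_COLUMNS + panel.score_columns].to_csv(path, index=False)
    schema = {
        "kind": "score_panel",
        "score_columns": panel.score_columns,
        "binary_columns": sorted(panel.binary_columns),
    }
    _schema_path(path).write_text(json.dumps(schema, indent=2))


def read_score_panel(path: str | Path) -> ScorePanel:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"score panel not found: {path}")
    sp = _schema_path(path)
    if not sp.exists():
        raise ConfigError(f"schema sidecar not found: {sp}")
    schema = json.loads(sp.read_text())
    if schema.get("kind") != "score_panel":
        raise ConfigError(f"{sp} does not describe a score panel")
    data = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in ID_COLUMNS + schema["score_columns"] if c not in data.columns]
    if missing:
        raise ConfigError(f"{path} is missing columns {missing}")
    return ScorePanel(
        data=data,
        score_columns=list(schema["score_columns"]),
        binary_columns=set(schema.get("binary_columns", [])),
    )


def write_item_panel(panel: ItemPanel, path: str | Path) -> None:
    path = Path(path)
    panel.data[ID_COLUMNS + panel.items].to_csv(path, index=False)
    schema = {
        "kind": "item_panel",
        "items": {
            name: {"scale": m.scale, "n_categories": m.n_categories, "reverse": m.reverse}
            for name, m in panel.item_meta.items()
        },
    }
    _schema_path(path).write_text(json.dumps(schema, indent=2))


def read_item_panel(path: str | Path) -> ItemPanel:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"item panel not found: {path}")
    sp = _schema_path(path)
    if not sp.exists():
        raise ConfigError(f"schema sidecar not found: {sp}")
    schema = json.loads(sp.read_text())
    if schema.get("kind") != "item_panel":
        raise ConfigError(f"{sp} does not describe an item panel")
    data = pd.read_csv(path, dtype={"subject_id": str})
    meta = {
        name: ItemMeta(scale=m["scale"], n_categories=int(m["n_categories"]), reverse=bool(m["reverse"]))
        for name, m in schema["items"].items()
    }
    missing = [c for c in ID_COLUMNS + list(meta) if c not in data.columns]
    if missing:
        raise ConfigError(f"{path} is missing columns {missing}")
    return ItemPanel(data=data, item_meta=meta)


def write_network(net: NetworkModel, path_prefix: str | Path) -> None:
    """Write ``<prefix>.edges.tsv`` (weighted edge list) and
    ``<prefix>.json`` (full matrix plus estimation metadata)."""
    prefix = Path(path_prefix)
    net.edge_list().to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    payload = {
        "node_labels": net.node_labels,
        "weights": net.weights.tolist(),
        "lambda_selected": net.lambda_selected,
        "gamma": net.gamma,
        "n": net.n,
        "correlation_method": net.correlation_method,
        "zero_tol": net.zero_tol,
        "collinear": net.collinear,
        "smoothed": net.smoothed,
    }
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def read_network(path: str | Path) -> NetworkModel:
    payload = json.loads(Path(path).read_text())
    return NetworkModel(
        node_labels=payload["node_labels"],
        weights=np.asarray(payload["weights"], dtype=float),
        lambda_selected=payload["lambda_selected"],
        gamma=payload["gamma"],
        n=payload["n"],
        correlation_method=payload.get("correlation_method", "pearson"),
        zero_tol=payload.get("zero_tol", 1e-8),
        collinear=payload.get("collinear", False),
        smoothed=payload.get("smoothed", False),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "node_labels": truth.node_labels,
        "partial": {f"{g}|{o}": truth.partial[(g, o)].tolist() for g, o in truth.partial},
        "means": {f"{g}|{o}": truth.means[(g, o)].tolist() for g, o in truth.means},
        "cross_occasion_rho": truth.cross_occasion_rho.tolist(),
        "loadings": {k: v.tolist() for k, v in truth.loadings.items()},
        "thresholds": {k: v.tolist() for k, v in truth.thresholds.items()},
        "item_meta": {
            k: {"scale": m.scale, "n_categories": m.n_categories, "reverse": m.reverse}
            for k, m in truth.item_meta.items()
        },
        "binarized_nodes": sorted(truth.binarized_nodes),
        "binarize_cut": truth.binarize_cut,
        "seed": truth.seed,
        "repaired": {f"{g}|{o}": bool(v) for (g, o), v in truth.repaired.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def cells(d):
        out = {}
        for key, val in d.items():
            g, o = key.split("|")
            out[(g, o)] = np.asarray(val, dtype=float)
        return out

    return GroundTruth(
        node_labels=payload["node_labels"],
        partial=cells(payload["partial"]),
        means=cells(payload["means"]),
        cross_occasion_rho=np.asarray(payload["cross_occasion_rho"], dtype=float),
        loadings={k: np.asarray(v, dtype=float) for k, v in payload["loadings"].items()},
        thresholds={k: np.asarray(v, dtype=float) for k, v in payload["thresholds"].items()},
        item_meta={
            k: ItemMeta(scale=m["scale"], n_categories=int(m["n_categories"]), reverse=bool(m["reverse"]))
            for k, m in payload["item_meta"].items()
        },
        binarized_nodes=set(payload["binarized_nodes"]),
        binarize_cut={k: float(v) for k, v in payload["binarize_cut"].items()},
        seed=payload.get("seed"),
        repaired={
            (k.split("|")[0], k.split("|")[1]): v for k, v in payload.get("repaired", {}).items()
        },
    )


class _ResultEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, EstimatorConfig):
            return obj.describe()
        if isinstance(obj, NetworkModel):
            return {
                "node_labels": obj.node_labels,
                "weights": obj.weights.tolist(),
                "lambda_selected": obj.lambda_selected,
                "n": obj.n,
            }
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def write_result_json(result, path: str | Path, drop: tuple[str, ...] = ()) -> None:
    """Serialize a result dataclass (NCT, pathway, bootstrap, ...) to JSON.

    ``drop`` names top-level fields to omit, e.g. bulky permutation arrays.
    """
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        payload = {
            f.name: getattr(result, f.name)
            for f in dataclasses.fields(result)
            if f.name not in drop
        }
    else:
        payload = result
    Path(path).write_text(json.dumps(payload, indent=2, cls=_ResultEncoder))
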