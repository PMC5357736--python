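"""Serialization of models, configs and result tables.

Conventions: TSV for matrices and per-sample/per-variable tables, JSON for
models and structured results, YAML for pipeline configuration.  Every JSON
artefact carries a ``format_version`` field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mccv import MCCVConfig, MCCVEnsemble, ModelRecord, PredictionSummary
from .preprocess import NormalizationRecord

__all__ = [
    "write_json",
    "read_json",
    "ensemble_to_json",
    "ensemble_from_json",
    "write_ensemble",
    "read_ensemble",
    "write_normalization",
    "summaries_to_frame",
    "write_summaries",
    "read_summaries",
]

FORMAT_VERSION = 1


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=1))


def read_json(path):
    return json.loads(Path(path).read_text())


def ensemble_to_json(ensemble: MCCVEnsemble) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "kind": "mccv_plsda_ensemble",
        "rng": "numpy PCG64, named substreams of the config seed",
        "config": dataclasses.asdict(ensemble.config),
        "class_encoding": {str(k): v for k, v in ensemble.class_encoding.items()},
        "ppm": ensemble.ppm.tolist(),
        "sample_ids": list(ensemble.sample_ids),
        "models": [
            {
                "beta": m.beta.tolist(),
                "column_means": m.column_means.tolist(),
                "column_scales": m.column_scales.tolist(),
                "train_units": list(m.train_units),
                "validation_units": list(m.validation_units),
            }
            for m in ensemble.models
        ],
    }


def ensemble_from_json(payload: dict) -> MCCVEnsemble:
    if payload.get("kind") != "mccv_plsda_ensemble":
        raise ValueError("not an MCCV ensemble payload")
    config = MCCVConfig(**payload["config"])
    models = [
        ModelRecord(
            beta=np.array(m["beta"]),
            column_means=np.array(m["column_means"]),
            column_scales=np.array(m["column_scales"]),
            train_units=list(m["train_units"]),
            validation_units=list(m["validation_units"]),
        )
        for m in payload["models"]
    ]

    def _key(k: str):
        try:
            return int(k)
        except ValueError:
            return k

    return MCCVEnsemble(
        config=config,
        models=models,
        class_encoding={_key(k): v for k, v in payload["class_encoding"].items()},
        ppm=np.array(payload["ppm"]),
        sample_ids=list(payload["sample_ids"]),
    )


def write_ensemble(ensemble: MCCVEnsemble, path) -> None:
    write_json(ensemble_to_json(ensemble), path)


def read_ensemble(path) -> MCCVEnsemble:
    return ensemble_from_json(read_json(path))


def write_normalization(record: NormalizationRecord, path) -> None:
    write_json(
        {
            "format_version": FORMAT_VERSION,
            "kind": "pqn_normalization",
            "reference": record.reference.tolist(),
            "quotients": record.quotients,
            "excluded_regions": [list(r) for r in record.excluded_regions],
            "eligible_floor": record.eligible_floor,
        },
        path,
    )


def summaries_to_frame(summaries: list[PredictionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_id=s.sample_id,
                t_pred_mean=s.t_pred_mean,
                t_pred_var=s.t_pred_var,
                n_appearances=s.n_appearances,
            )
            for s in summaries
        ]
    ).set_index("sample_id")


def write_summaries(summaries: list[PredictionSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t")


def read_summaries(path) -> list[PredictionSummary]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return [
        PredictionSummary(
            sample_id=str(sid),
            t_pred_mean=float(r["t_pred_mean"]),
            t_pred_var=float(r["t_pred_var"]),
            n_appearances=int(r["n_appearances"]),
        )
        for sid, r in df.iterrows()
    ]


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
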