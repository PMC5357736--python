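"""End-to-end pipeline orchestration.

Runs the seven analysis stages in order — simulate, normalise, fit,
predict, significance, stats, dash — each stage consuming the previous
stage's files inside the run directory, and writes a manifest recording
inputs, outputs, seeds, wall times and content hashes.  Re-running with the
same configuration and master seed reproduces every numerical output
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .dash import DashConfig, score_cohort, simulate_intakes, stratify_percentiles
from .group_stats import (
    hommel_adjust,
    iqr_outliers,
    skillings_mack,
    wilcoxon_signed_rank,
)
from .mccv import MCCVConfig, group_kde, project, run_mccv
from .preprocess import DEFAULT_EXCLUDED_REGIONS, normalise_cohort
from .significance import (
    attach_qvalues,
    bootstrap_coefficients,
    call_metabolites,
    variable_map,
)
from .spectra import (
    read_annotations,
    read_spectra,
    write_annotations,
    write_spectra,
)
from .synthetic import CohortDesign, default_signature_library, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("metabodiet")

STAGES = (
    "simulate",
    "normalise",
    "fit",
    "predict",
    "significance",
    "stats",
    "dash",
)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full synthetic-cohort run."""

    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    n_nuisance: int = 60
    excluded_regions: list = field(
        default_factory=lambda: [list(r) for r in DEFAULT_EXCLUDED_REGIONS]
    )
    eligible_floor: float = 0.01
    mccv: MCCVConfig = field(default_factory=MCCVConfig)
    classes: tuple = (1, 4)
    model_day: int | None = 3
    n_boot: int = 25
    q_cutoff: float = 0.01
    dash_bands: list = field(
        default_factory=lambda: [[0, 10], [45, 55], [90, 100]]
    )

    def __post_init__(self) -> None:
        # one master seed drives cohort generation and model fitting
        self.design = dataclasses.replace(self.design, seed=self.seed)
        self.mccv = dataclasses.replace(self.mccv, seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d:
            design = dict(d["design"])
            for key in ("diets", "ppm_range"):
                if key in design:
                    design[key] = tuple(design[key])
            d["design"] = CohortDesign(**design)
        if "mccv" in d:
            d["mccv"] = MCCVConfig(**d["mccv"])
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory containing a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.dump_yaml(config.to_dict(), out / "config.yaml")
    manifest: list[dict] = []

    def record(stage: str, inputs: list[Path], outputs: list[Path], t0: float):
        entry = {
            "stage": stage,
            "seed": config.seed,
            "inputs": [p.name for p in inputs],
            "outputs": {p.name: _sha256(p) for p in outputs},
            "wall_time_s": round(time.monotonic() - t0, 3),
        }
        manifest.append(entry)
        log.info(
            "stage=%s seed=%s outputs=%s wall=%.2fs",
            stage, config.seed, list(entry["outputs"]), entry["wall_time_s"],
        )

    try:
        # 1. simulate -------------------------------------------------------
        t0 = time.monotonic()
        signatures = default_signature_library(n_nuisance=config.n_nuisance)
        matrix, annotations, truth = generate_cohort(config.design, signatures)
        write_spectra(matrix, out / "spectra.tsv")
        write_annotations(annotations, out / "annotations.tsv")
        mio.write_json(truth, out / "ground_truth.json")
        intakes = simulate_intakes(
            n_per_template=config.design.n_subjects, seed=config.seed
        )
        intakes.to_csv(out / "intakes.tsv", sep="\t")
        record("simulate", [], [out / "spectra.tsv", out / "annotations.tsv",
                                out / "ground_truth.json", out / "intakes.tsv"], t0)

        # 2. normalise ------------------------------------------------------
        t0 = time.monotonic()
        matrix = read_spectra(out / "spectra.tsv",
                              read_annotations(out / "annotations.tsv"))
        regions = [tuple(r) for r in config.excluded_regions]
        normalised, record_pqn = normalise_cohort(
            matrix,
            reference_diets=config.classes,
            excluded_regions=regions,
            eligible_floor=config.eligible_floor,
        )
        write_spectra(normalised, out / "normalised.tsv")
        mio.write_normalization(record_pqn, out / "normalisation.json")
        record("normalise", [out / "spectra.tsv"],
               [out / "normalised.tsv", out / "normalisation.json"], t0)

        # 3. fit ------------------------------------------------------------
        t0 = time.monotonic()
        normalised = read_spectra(out / "normalised.tsv",
                                  read_annotations(out / "annotations.tsv"))
        model_matrix = normalised
        if config.model_day is not None:
            model_matrix = normalised.select_where(day=config.model_day)
        ensemble, cv_summaries = run_mccv(model_matrix, config.mccv,
                                          classes=config.classes)
        mio.write_ensemble(ensemble, out / "ensemble.json")
        mio.write_summaries(cv_summaries, out / "tpred_train.tsv")
        record("fit", [out / "normalised.tsv"],
               [out / "ensemble.json", out / "tpred_train.tsv"], t0)

        # 4. predict --------------------------------------------------------
        t0 = time.monotonic()
        ensemble = mio.read_ensemble(out / "ensemble.json")
        project_matrix = normalised
        if config.model_day is not None:
            project_matrix = normalised.select_where(day=config.model_day)
        summaries = project(ensemble, project_matrix)
        mio.write_summaries(summaries, out / "tpred.tsv")
        ann = project_matrix.annotation_frame()
        kde_frames = []
        for diet in config.design.diets:
            ids = set(ann.index[ann["diet"] == diet])
            group = [s for s in summaries if s.sample_id in ids]
            kde = group_kde(group, group_label=f"diet{diet}")
            kde_frames.append(pd.DataFrame(
                {"group": kde.group_label, "score": kde.grid,
                 "density": kde.density}
            ))
        pd.concat(kde_frames).to_csv(out / "kde.tsv", sep="\t", index=False)
        record("predict", [out / "ensemble.json", out / "normalised.tsv"],
               [out / "tpred.tsv", out / "kde.tsv"], t0)

        # 5. significance ---------------------------------------------------
        t0 = time.monotonic()
        table = bootstrap_coefficients(ensemble, model_matrix,
                                       n_boot=config.n_boot,
                                       classes=config.classes)
        table = attach_qvalues(table)
        table.to_csv(out / "significance.tsv", sep="\t", index=False)
        truth = mio.read_json(out / "ground_truth.json")
        vmap = variable_map(truth["signatures"], ensemble.ppm)
        calls = call_metabolites(table, vmap, q_cutoff=config.q_cutoff)
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            out / "metabolite_calls.tsv", sep="\t", index=False
        )
        record("significance",
               [out / "ensemble.json", out / "normalised.tsv"],
               [out / "significance.tsv", out / "metabolite_calls.tsv"], t0)

        # 6. stats ----------------------------------------------------------
        t0 = time.monotonic()
        tpred = mio.read_summaries(out / "tpred.tsv")
        scores = {s.sample_id: s.t_pred_mean for s in tpred}
        ann = project_matrix.annotation_frame()
        block = pd.DataFrame(
            {
                "subject": ann["subject_id"],
                "diet": ann["diet"],
                "score": [scores[s] for s in ann.index],
            }
        )
        wide = block.groupby(["subject", "diet"])["score"].mean().unstack()
        omnibus = skillings_mack(wide)
        diets = list(config.design.diets)
        pairs, raw_p = [], []
        for i, d1 in enumerate(diets):
            for d2 in diets[i + 1:]:
                res = wilcoxon_signed_rank(
                    (wide[d1] - wide[d2]).dropna().to_numpy()
                )
                pairs.append(f"diet{d1}_vs_diet{d2}")
                raw_p.append(res.p)
        adj = hommel_adjust(np.array(raw_p))
        outliers = {
            f"diet{d}": [
                sid for sid, flag in zip(
                    block[block["diet"] == d].index,
                    iqr_outliers(block[block["diet"] == d]["score"]),
                ) if flag
            ]
            for d in diets
            if (block["diet"] == d).sum() >= 4
        }
        mio.write_json(
            {
                "format_version": mio.FORMAT_VERSION,
                "omnibus": dataclasses.asdict(omnibus),
                "pairwise": {
                    name: {"p": float(p), "p_adjusted": float(q)}
                    for name, p, q in zip(pairs, raw_p, adj)
                },
                "outlier_sample_rows": outliers,
            },
            out / "stats.json",
        )
        record("stats", [out / "tpred.tsv"], [out / "stats.json"], t0)

        # 7. dash -----------------------------------------------------------
        t0 = time.monotonic()
        intake_table = pd.read_csv(out / "intakes.tsv", sep="\t",
                                   index_col="person_id")
        records = score_cohort(
            intake_table.drop(columns=["template"]), DashConfig()
        )
        totals = [r.total for r in records]
        bands = stratify_percentiles(
            totals, [tuple(b) for b in config.dash_bands]
        )
        dash_df = pd.DataFrame(
            {
                "person_id": [r.person_id for r in records],
                "template": intake_table["template"].to_numpy(),
                "dash_total": totals,
                "percentile_band": bands,
            }
        ).set_index("person_id")
        dash_df.to_csv(out / "dash.tsv", sep="\t")
        record("dash", [out / "intakes.tsv"], [out / "dash.tsv"], t0)
    except Exception as exc:
        stage = STAGES[len(manifest)] if len(manifest) < len(STAGES) else "?"
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    mio.write_json({"format_version": mio.FORMAT_VERSION,
                    "stages": manifest}, out / "manifest.json")
    return out
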