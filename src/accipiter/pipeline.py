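"""End-to-end orchestration: raw table -> validated cohort -> all analyses.

``run_pipeline`` executes the stages in study order and writes one artifact
file per stage plus a run manifest.  A stage failure raises
``StageError`` naming the stage; artifacts from completed stages are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__, reference
from .cohort import assign_population_groups, filter_nominate, reclassify_sex
from .descriptives import dimorphism_table, summarize_all
from .io import read_measurements, validate_records, write_summaries
from .multivariate import pca_element
from .resampling import run_all_elements
from .temporal import ancova_sequential, fit_all_regressions

logger = logging.getLogger("accipiter.pipeline")

ALL_STAGES = (
    "validate",
    "assemble",
    "summarize",
    "dimorphism",
    "pca",
    "regress",
    "ancova",
    "permtest",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, selections and knobs for one pipeline run."""

    input_path: str | Path
    out_dir: str | Path
    dialect: Mapping[str, str] | None = None
    elements: Sequence[str] = reference.ELEMENTS
    code: str = "GL"
    B: int = 10_000
    seed: int = 0
    side_policy: str = "prefer_left"
    pca_codes: Sequence[str] = ("GL", "Bp", "SC")
    ancova_elements: Sequence[str] = ("humerus", "femur")
    stages: Sequence[str] = ALL_STAGES
    group_mapping: Mapping[str, str] | None = None
    region_exclusions: Sequence[tuple[str, str]] | None = field(default=None)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the enabled stages in order; return {artifact name: path}."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stages = list(config.stages)
    t_start = time.perf_counter()

    def _write(name: str, filename: str, writer) -> None:
        path = out_dir / filename
        writer(path)
        artifacts[name] = path
        logger.info("stage artifact %s -> %s", name, path)

    def _run(stage: str, fn) -> None:
        if stage not in stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # keep partial outputs, name the stage
            raise StageError(stage, exc) from exc
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    # -- validate ------------------------------------------------------------
    records, read_issues = read_measurements(config.input_path, dialect=config.dialect)
    report = validate_records(records)

    def _stage_validate():
        payload = {
            "n_input_rows": report.n_records + len(read_issues),
            "n_records": report.n_records,
            "n_rejected": report.n_rejected,
            "read_issues": [[str(i), rule] for i, rule in read_issues],
            "validation_issues": [[str(i), rule] for i, rule in report.issues],
        }
        _write("validation", "validation_report.json",
               lambda p: p.write_text(json.dumps(payload, indent=2)))

    _run("validate", _stage_validate)
    clean = report.valid(records)

    # -- assemble ------------------------------------------------------------
    state: dict[str, object] = {}

    def _stage_assemble():
        filtered = filter_nominate(clean, region_exclusions=config.region_exclusions)
        grouped = assign_population_groups(filtered.records, mapping=config.group_mapping)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, reclass = reclassify_sex(
                grouped, code=config.code, side_policy=config.side_policy
            )
        state["cohort"] = cohort
        state["n_excluded"] = filtered.n_excluded
        _write("cohort", "cohort.csv", lambda p: cohort.to_csv(p, index=False))
        rec_df = pd.DataFrame(
            [
                {
                    "specimen_id": r.specimen_id,
                    "sex_recorded": r.sex_recorded,
                    "sex_assigned": r.sex_assigned,
                    "n_elements_used": r.n_elements_used,
                    "changed": r.changed,
                }
                for r in reclass
            ]
        )
        _write("reclassification", "reclassification.csv",
               lambda p: rec_df.to_csv(p, index=False))

    _run("assemble", _stage_assemble)
    cohort = state.get("cohort", clean)

    # -- summaries -----------------------------------------------------------
    def _stage_summarize():
        summaries = summarize_all(cohort, code=config.code, side_policy=config.side_policy)
        state["summaries"] = summaries
        _write("summaries", "summaries.csv", lambda p: write_summaries(summaries, p))

    _run("summarize", _stage_summarize)

    def _stage_dimorphism():
        summaries = state.get("summaries")
        if summaries is None:
            summaries = summarize_all(cohort, code=config.code, side_policy=config.side_policy)
        dim = dimorphism_table(summaries)
        _write("dimorphism", "dimorphism.csv",
               lambda p: dim.round({"percent": 2}).to_csv(p, index=False))

    _run("dimorphism", _stage_dimorphism)

    # -- PCA -----------------------------------------------------------------
    def _stage_pca():
        rows = []
        for element in config.elements:
            try:
                res = pca_element(
                    cohort, element, config.pca_codes, side_policy=config.side_policy
                )
            except ValueError as exc:
                logger.info("pca skipped for %s: %s", element, exc)
                continue
            for code in res.loadings.index:
                rows.append(
                    {
                        "element": element,
                        "code": code,
                        "pc1_loading": res.loadings.loc[code, "PC1"],
                        "pc1_explained": res.explained_fraction[0],
                        "n_complete": res.n_complete,
                        "dominant": code == res.dominant_loading(),
                    }
                )
        _write("pca", "pca.csv", lambda p: pd.DataFrame(rows).to_csv(p, index=False))

    _run("pca", _stage_pca)

    # -- regressions ---------------------------------------------------------
    def _stage_regress():
        fits = fit_all_regressions(
            cohort, config.elements, code=config.code, side_policy=config.side_policy
        )
        _write("regressions", "regressions.csv", lambda p: fits.to_csv(p, index=False))

    _run("regress", _stage_regress)

    # -- ANCOVA --------------------------------------------------------------
    def _stage_ancova():
        tables = []
        for element in config.ancova_elements:
            try:
                res = ancova_sequential(
                    cohort, element=element, code=config.code, side_policy=config.side_policy
                )
            except ValueError as exc:
                logger.info("ancova skipped for %s: %s", element, exc)
                continue
            t = res.table.reset_index(names="term")
            t.insert(0, "element", element)
            t.insert(1, "n", res.n)
            tables.append(t)
        if not tables:
            raise ValueError("no element had enough complete cases for ANCOVA")
        _write("ancova", "ancova.csv",
               lambda p: pd.concat(tables, ignore_index=True).to_csv(p, index=False))

    _run("ancova", _stage_ancova)

    # -- permutation tests ---------------------------------------------------
    def _stage_permtest():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_all_elements(
                cohort,
                elements=config.elements,
                B=config.B,
                seed=config.seed,
                code=config.code,
                side_policy=config.side_policy,
            )
        _write("permutation", "permutation.csv", lambda p: results.to_csv(p, index=False))

    _run("permtest", _stage_permtest)

    # -- manifest ------------------------------------------------------------
    cfg_repr = repr(config).encode()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "B": config.B,
        "code": config.code,
        "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
        "stages_run": [s for s in ALL_STAGES if s in stages],
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = path
    return artifacts
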