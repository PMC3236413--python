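"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains: cohort generation -> summarization & group tests ->
fee-schedule calibration -> parameter estimation -> decision-tree evaluation
-> one-way OR-time sweeps -> threshold solving -> Monte Carlo PSA, with each
stage consuming the previous stage's outputs.  All artefacts are written to
the output directory together with a manifest recording the package version,
the master seed and SHA-256 hashes of every file; with a fixed seed a rerun
is byte-identical.  The master seed supersedes the per-block seeds of the
cohort and PSA configurations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .cohort import BOOLEAN_FIELDS, generate_cohort, write_cohort_csv
from .config import RunConfig
from .errors import StageError
from .methods import METHOD_ORDER, SurgicalMethod
from .psa import PSAResult, incremental_distribution, run_psa
from .sensitivity import one_way_or_time, threshold_or_time
from .statistics import (
    comparisons_table,
    estimate_model_parameters,
    summarize_cohort,
)
from .tree import ModelParameters, build_tree, rank_methods, tree_to_json

log = logging.getLogger("hystecon")

#: Variables compared across methods in the report.
COMPARISON_VARIABLES = (
    "age",
    "bmi",
    "uterine_weight",
    "or_time",
    "ebl",
    "los",
) + BOOLEAN_FIELDS


@dataclass
class RunReport:
    """Paths and headline results of one pipeline run."""

    output_dir: Path
    files: dict[str, Path]
    ranking: tuple[tuple[SurgicalMethod, float], ...]
    thresholds: list[dict]
    psa: Optional[PSAResult]
    parameters: ModelParameters


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> RunReport:
    """Execute every stage; on failure remove partial outputs and raise a
    :class:`StageError` naming the failed stage."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    created: list[Path] = []
    files: dict[str, Path] = {}

    def write(name: str, fname: str, writer) -> Path:
        path = out / fname
        writer(path)
        created.append(path)
        files[name] = path
        return path

    stage = "setup"
    try:
        stage = "generate"
        log.info("generating synthetic cohort (seed=%d)", config.seed)
        cohort = generate_cohort(config.cohort, seed=config.seed)
        write("cohort", "cohort.csv", lambda p: write_cohort_csv(cohort, p))

        stage = "summarize"
        summary = summarize_cohort(cohort)
        write("summary", "summary.json", lambda p: _dump_json(summary.to_dict(), p))
        comparisons = comparisons_table(cohort, COMPARISON_VARIABLES)
        write(
            "comparisons",
            "comparisons.csv",
            lambda p: comparisons.to_csv(p, index=False, lineterminator="\n"),
        )

        stage = "calibrate"
        schedule, calibration = config.cost.resolve_fee_schedule()
        write(
            "calibration",
            "calibration.json",
            lambda p: _dump_json(
                calibration.to_dict() if calibration else {"fee_schedule": "explicit"},
                p,
            ),
        )

        stage = "estimate-parameters"
        if config.model.source == "config":
            params = config.model_parameters_from_config()
        else:
            params = estimate_model_parameters(
                summary,
                overrides=config.model.overrides,
                fee_schedule=schedule,
                wages=config.cost.wages,
                nonoperative_charges=config.cost.nonoperative_charges,
                added_times=config.model.added_times,
                literature_required=config.model.literature_required,
                cost_to_charge_ratio=config.cost.cost_to_charge_ratio,
            )
        write(
            "parameters",
            "parameters.json",
            lambda p: p.write_text(params.model_dump_json(indent=2) + "\n"),
        )

        stage = "evaluate"
        tree = build_tree(params)
        write("tree", "tree.json", lambda p: p.write_text(tree_to_json(tree) + "\n"))
        ranking = rank_methods(tree)
        write(
            "expected_costs",
            "expected_costs.json",
            lambda p: _dump_json(
                {
                    "expected_costs": {m.value: c for m, c in ranking.order},
                    "ranking": [m.value for m, _ in ranking.order],
                    "tied_pairs": [[a.value, b.value] for a, b in ranking.tied_pairs],
                },
                p,
            ),
        )

        stage = "sweep"
        lo_pct, hi_pct = config.sensitivity.sweep_percentiles
        for method in METHOD_ORDER:
            orstats = summary.methods[method].continuous["or_time"]
            rng_lo = {25.0: orstats.p25, 50.0: orstats.p50, 75.0: orstats.p75}[lo_pct]
            rng_hi = {25.0: orstats.p25, 50.0: orstats.p50, 75.0: orstats.p75}[hi_pct]
            sa = one_way_or_time(
                params, method, (rng_lo, rng_hi), step=config.sensitivity.step
            )
            write(
                f"sa_{method.value}",
                f"sa_{method.value}.csv",
                lambda p, sa=sa: sa.to_frame().to_csv(
                    p, index=False, lineterminator="\n"
                ),
            )

        stage = "threshold"
        thresholds = [
            threshold_or_time(
                params,
                a,
                b,
                search_range=config.sensitivity.threshold_range,
                step=config.sensitivity.step,
            ).to_dict()
            for a, b in config.sensitivity.threshold_pairs
        ]
        write("threshold", "threshold.json", lambda p: _dump_json(thresholds, p))

        stage = "psa"
        psa_config = config.psa.model_copy(update={"seed": config.seed})
        psa_result = run_psa(
            params, psa_config, literature_required=config.model.literature_required
        )
        incremental = incremental_distribution(
            psa_result, SurgicalMethod.TRH, SurgicalMethod.TAH
        )
        write(
            "psa",
            "psa.json",
            lambda p: _dump_json(
                {
                    **psa_result.summary_dict(),
                    "incremental": incremental.to_dict(),
                },
                p,
            ),
        )

        stage = "manifest"
        manifest = {
            "package": "hystecon",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.model_dump_json().encode()
            ).hexdigest(),
            "files": {name: _sha256(path) for name, path in sorted(files.items())},
        }
        write("manifest", "manifest.json", lambda p: _dump_json(manifest, p))
    except Exception as exc:
        for path in created:
            try:
                path.unlink()
            except OSError:  # pragma: no cover - best-effort cleanup
                pass
        raise StageError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return RunReport(
        output_dir=out,
        files=files,
        ranking=ranking.order,
        thresholds=thresholds,
        psa=psa_result,
        parameters=params,
    )
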