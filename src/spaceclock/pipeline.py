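"""End-to-end pipeline: inputs → metrics → inference → summaries → CSV outputs.

Every stage logs one structured line (shapes, seed), derives its random seed
deterministically from the run seed, and any failure propagates wrapped with
the stage name.  A machine-readable manifest records the configuration echo,
seed, package version and which stages completed, so partial output is
detectable.
"""

from __future__ import annotations

import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .age_metrics import (
    AgeMetricTable,
    category_means,
    compute_ead,
    compute_eaa,
    compute_ieaa,
    compute_pace_changes,
    correlation_structure,
)
from .clock_engine import deconvolve_cell_fractions
from .dominance import build_dominance_dataset, dominance_analysis, dominance_table
from .inference import (
    LMMConvergenceError,
    compare_timepoints,
    fit_lmm,
    leave_one_out_sensitivity,
    metric_long_table,
)
from .io_config import (
    RunConfig,
    read_beta_matrix,
    read_cell_table,
    read_clock_table,
    read_metadata,
    read_reference_matrix,
    write_metadata,
    write_table,
)
from .registry import ClockRegistry, default_registry

logger = logging.getLogger("spaceclock")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(master: int, *tags: str) -> int:
    """Deterministic per-task seed from the run seed and a tag path."""
    tag = "|".join(tags)
    return (int(master) ^ zlib.crc32(tag.encode("utf-8"))) & 0x7FFFFFFF


@dataclass
class RunReport:
    output_dir: Path
    manifest: dict
    tables: dict[str, Path] = field(default_factory=dict)


def _ordered_pairs(timepoints: tuple[str, ...]) -> list[tuple[str, str]]:
    return list(itertools.combinations(timepoints, 2))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage the configuration enables and write all outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "spaceclock",
        "version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "stages": [],
        "complete": False,
    }
    tables: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.csv"
        write_table(frame, path, index=index)
        tables[name] = path

    def _stage(name: str):
        logger.info("stage=%s seed=%s", name, config.rng_seed)
        manifest["stages"].append(name)

    try:
        # ---------------- inputs ----------------
        _stage("read_inputs")
        registry = (
            ClockRegistry.from_csv(config.clock_registry)
            if config.clock_registry
            else default_registry()
        )
        meta = read_metadata(config.metadata, config.timepoints)
        if config.clock_table is None:
            raise ValueError("config.clock_table is required")
        clocks = read_clock_table(config.clock_table, registry)
        clocks = clocks.loc[meta.index.intersection(clocks.index)]
        missing = meta.index.difference(clocks.index)
        if len(missing):
            raise ValueError(f"metadata samples missing from clock table: {list(missing)}")
        logger.info("stage=read_inputs clocks=%s meta=%s", clocks.shape, meta.shape)

        cells = None
        if config.cell_table is not None:
            cells = read_cell_table(config.cell_table)
        elif config.beta_matrix is not None and config.reference_matrix is not None:
            _stage("deconvolution")
            beta = read_beta_matrix(config.beta_matrix)
            reference = read_reference_matrix(config.reference_matrix)
            result = deconvolve_cell_fractions(beta, reference)
            cells = result.fractions
            _write("cell_fractions", cells, index=True)
            _write("deconvolution_residuals", result.residual_norm.to_frame(), index=True)
        if cells is not None:
            miss = meta.index.difference(cells.index)
            if len(miss):
                raise ValueError(f"metadata samples missing from cell table: {list(miss)}")
            cells = cells.loc[meta.index]

        # ---------------- metrics ----------------
        _stage("metrics")
        metrics: dict[str, AgeMetricTable] = {}
        year = clocks[[c for c in clocks.columns if registry.units_of(c) == "years"]]
        if "EAD" in config.metrics:
            metrics["EAD"] = compute_ead(year, meta)
        if "EAA" in config.metrics:
            metrics["EAA"] = compute_eaa(year, meta)
        if "IEAA" in config.metrics:
            if cells is None:
                raise ValueError("IEAA requested but no cell-fraction input given")
            metrics["IEAA"] = compute_ieaa(year, meta, cells)
        for tag, table in metrics.items():
            _write(f"metric_{tag}_wide", table.values, index=True)
            _write(f"metric_{tag}_long", table.long())
            if table.audit is not None:
                _write(f"metric_{tag}_audit", table.audit, index=True)

        pace_cols = [c for c in clocks.columns if registry.units_of(c) == "rate"]
        if pace_cols:
            _stage("pace_changes")
            per_subj, means = compute_pace_changes(
                clocks[pace_cols[0]], meta, config.reference_timepoint
            )
            _write("pace_changes", per_subj)
            _write("pace_change_means", means.reset_index())

        pairs = _ordered_pairs(config.timepoints)
        subjects = sorted(meta["subject"].unique())

        # ---------------- per-subject comparisons ----------------
        _stage("comparisons")
        rows = []
        for tag, table in metrics.items():
            for subject in subjects:
                for t1, t2 in pairs:
                    seed = derive_seed(config.rng_seed, "perm", tag, subject, t1, t2)
                    rows.append(
                        compare_timepoints(
                            table, meta, subject, t1, t2,
                            n_permutations=config.n_permutations,
                            seed=seed,
                        ).as_dict()
                    )
        _write("comparisons", pd.DataFrame(rows))

        # ---------------- mixed models ----------------
        _stage("lmm")
        lmm_rows = []
        for tag, table in metrics.items():
            long = metric_long_table(table, meta)
            for t1, t2 in pairs:
                try:
                    fit = fit_lmm(long, t1, t2)
                except LMMConvergenceError as err:
                    lmm_rows.append(
                        {"metric": tag, "t1": t1, "t2": t2, "error": str(err)}
                    )
                    continue
                lmm_rows.append(
                    {
                        "metric": tag,
                        "t1": t1,
                        "t2": t2,
                        "beta1": fit.beta1,
                        "p_value": fit.p_value,
                        "var_subject": fit.var_subject,
                        "var_clock": fit.var_clock,
                        "var_resid": fit.var_resid,
                        "method": fit.method,
                        "n_obs": fit.n_obs,
                    }
                )
        _write("lmm", pd.DataFrame(lmm_rows))

        # ---------------- summaries ----------------
        _stage("summaries")
        cat_frames = [
            category_means(table, registry, meta, pairs) for table in metrics.values()
        ]
        if cat_frames:
            _write("category_means", pd.concat(cat_frames, ignore_index=True))
        strata_frames = []
        for tag, table in metrics.items():
            corr, _, summary = correlation_structure(table, meta)
            _write(f"correlation_{tag}", corr, index=True)
            summary.insert(0, "metric", tag)
            strata_frames.append(summary)
        if strata_frames:
            _write("correlation_strata", pd.concat(strata_frames, ignore_index=True))

        # ---------------- dominance ----------------
        if "EAA" in metrics and "IEAA" in metrics and cells is not None:
            _stage("dominance")
            y, x = build_dominance_dataset(metrics["EAA"], metrics["IEAA"], cells)
            dom = dominance_analysis(y, x)
            _write("dominance", dominance_table(dom))
            _write("dominance_conditional", dom.conditional, index=True)
            _write("dominance_complete", dom.complete, index=True)

        # ---------------- sensitivity ----------------
        if config.sensitivity and metrics:
            _stage("sensitivity")
            ref = config.reference_timepoint
            sens_rows = []
            for tag, table in metrics.items():
                for subject in subjects:
                    for t in config.timepoints:
                        if t == ref:
                            continue
                        seed = derive_seed(config.rng_seed, "loo", tag, subject, ref, t)
                        loo = leave_one_out_sensitivity(
                            table, meta, subject, (ref, t),
                            n_permutations=config.n_permutations, seed=seed,
                        )
                        loo.insert(0, "metric", tag)
                        loo.insert(1, "subject", subject)
                        loo.insert(2, "t1", ref)
                        loo.insert(3, "t2", t)
                        sens_rows.append(loo)
            _write("sensitivity", pd.concat(sens_rows, ignore_index=True))

        manifest["complete"] = True
    except PipelineError:
        raise
    except Exception as err:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["error"] = {"stage": stage, "message": str(err)}
        _write_manifest(out, manifest)
        raise PipelineError(stage, err) from err

    manifest["tables"] = {k: str(v) for k, v in tables.items()}
    _write_manifest(out, manifest)
    return RunReport(output_dir=out, manifest=manifest, tables=tables)


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_simulation(sim, out_dir: str | Path, with_truth: bool = True) -> dict[str, Path]:
    """Write a :class:`~spaceclock.synthetic.SimulatedCohort` as CSV inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clock_table": out / "clock_table.csv",
        "metadata": out / "metadata.csv",
        "cell_fractions": out / "cell_fractions.csv",
    }
    write_table(sim.clock_table, paths["clock_table"], index=True)
    write_metadata(sim.metadata, paths["metadata"])
    write_table(sim.cell_fractions, paths["cell_fractions"], index=True)
    if with_truth:
        truth = sim.truth
        paths["truth_expected"] = out / "truth_expected.csv"
        write_table(truth.expected, paths["truth_expected"], index=True)
        paths["truth_params"] = out / "truth_params.json"
        with open(paths["truth_params"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": truth.seed,
                    "subject_effects": truth.subject_effects,
                    "delta": truth.delta,
                    "gamma": truth.gamma,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        paths["truth_cell_weights"] = out / "truth_cell_weights.csv"
        write_table(sim.truth.cell_weights, paths["truth_cell_weights"], index=True)
    return paths
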