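"""End-to-end orchestration: simulate -> count -> QC -> threshold -> TE -> PCA -> regression.

One root seed drives every stage (the simulator derives per-purpose
substreams), so two runs with the same config produce byte-identical
numeric outputs.  Each stage writes its outputs under the run directory
together with a provenance JSON recording the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, qc, threshold as thr, translation as tr, regression as reg
from .simulate import (
    PanelConfig,
    SimulationConfig,
    simulate_abundances,
    simulate_annotation,
    simulate_mrna_reads,
    simulate_panel,
    simulate_rpf_reads,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "threshold", "te", "pca", "regress")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    outdir: str | Path = "riboshift_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    threshold_rpm: float | str = "auto"  # number or "auto"
    simulation: SimulationConfig | None = None
    panel: PanelConfig | None = None
    write_reads: bool = False
    min_read_length: int = io.DEFAULT_MIN_READ_LENGTH

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = dataclasses.replace(SimulationConfig(), seed=self.seed)
        if self.panel is None:
            self.panel = dataclasses.replace(PanelConfig(), seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        panel = raw.pop("panel", None)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        seed = cfg.seed
        if sim is not None:
            sim.setdefault("seed", seed)
            if "effects" in sim:
                sim["effects"] = {
                    g: tuple(v) for g, v in sim["effects"].items()
                }
            if "cds_length_range" in sim:
                sim["cds_length_range"] = tuple(sim["cds_length_range"])
            cfg.simulation = SimulationConfig(**sim)
        if panel is not None:
            panel.setdefault("seed", seed)
            if "groups" in panel:
                panel["groups"] = tuple(panel["groups"])
            cfg.panel = PanelConfig(**panel)
        return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the aggregated report.

    The report maps each enabled stage to ``{"status": "pass"|"fail", ...}``
    with the stage's headline numbers; a stage failure aborts the run (the
    raised :class:`StageError` names the stage) while earlier outputs are
    retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report: dict[str, dict] = {}

    _write_json(
        {
            "seed": config.seed,
            "stages": list(config.stages),
            "threshold_rpm": config.threshold_rpm,
            "simulation": dataclasses.asdict(sim),
            "panel": dataclasses.asdict(config.panel),
        },
        outdir / "provenance.json",
    )

    # -- simulate + count (the count tables feed every later stage) -------
    annotation = None
    rpf_counts = mrna_counts = None
    reads_store: dict[str, pd.DataFrame] = {}
    try:
        annotation = simulate_annotation(sim)
        annotation.to_tsv(outdir / "annotation.tsv")
        rpf_cols, mrna_cols = [], []
        for condition in ("control", "exercise"):
            ab = simulate_abundances(sim, annotation, condition)
            for rep in ab.loading.columns:
                sid = f"{condition}_{rep}"
                rpf = simulate_rpf_reads(sim, annotation, ab, f"rpf_{sid}", rep)
                rpf = io.filter_by_length(rpf, config.min_read_length)
                mrna = simulate_mrna_reads(sim, annotation, ab, f"mrna_{sid}", rep)
                mrna = io.filter_by_length(mrna, config.min_read_length)
                reads_store[f"rpf_{sid}"] = rpf
                reads_store[f"mrna_{sid}"] = mrna
                if config.write_reads:
                    io.write_reads(rpf, outdir / f"reads_rpf_{sid}.tsv")
                    io.write_reads(mrna, outdir / f"reads_mrna_{sid}.tsv")
                rpf_cols.append(io.count_reads(rpf, annotation, sid))
                mrna_cols.append(io.count_reads(mrna, annotation, sid))
        rpf_counts = io.make_count_table(rpf_cols)
        mrna_counts = io.make_count_table(mrna_cols)
        io.write_counts(rpf_counts, outdir / "rpf_counts.tsv")
        io.write_counts(mrna_counts, outdir / "mrna_counts.tsv")
        if "simulate" in config.stages:
            report["simulate"] = {
                "status": "pass",
                "n_genes": len(annotation),
                "n_top": len(annotation.top_gene_ids),
                "samples": list(rpf_counts.columns),
            }
    except Exception as e:
        report["simulate"] = {"status": "fail", "error": str(e)}
        _write_json(report, outdir / "report.json")
        raise StageError(f"stage 'simulate' failed: {e}") from e

    rpf_rpm = io.rpm_normalize(rpf_counts)
    mrna_rpm = io.rpm_normalize(mrna_counts)

    # -- qc ----------------------------------------------------------------
    if "qc" in config.stages:
        try:
            rpf_reads = reads_store["rpf_exercise_rep1"]
            profile, _ = qc.frame_periodicity(rpf_reads, annotation)
            mg = qc.metagene_profile(rpf_reads, annotation)
            peak = qc.find_start_peak(mg)
            mrna_profile, _ = qc.frame_periodicity(
                reads_store["mrna_exercise_rep1"], annotation
            )
            r = qc.replicate_correlation(
                rpf_rpm["exercise_rep1"], rpf_rpm["exercise_rep2"]
            )
            mg.to_frame().to_csv(outdir / "metagene.tsv", sep="\t", index=False)
            qc_out = {
                "rpf_frame_fractions": profile.as_dict(),
                "mrna_frame_fractions": mrna_profile.as_dict(),
                "replicate_pearson_log2": r,
                "start_peak": dataclasses.asdict(peak) if peak else None,
            }
            _write_json(qc_out, outdir / "qc.json")
            report["qc"] = {
                "status": "pass",
                "periodicity_frame0": profile.frac_frame0,
                "peak_codon": peak.position_codon if peak else None,
                "replicate_pearson": r,
            }
        except Exception as e:
            report["qc"] = {"status": "fail", "error": str(e)}
            _write_json(report, outdir / "report.json")
            raise StageError(f"stage 'qc' failed: {e}") from e

    # -- threshold ----------------------------------------------------------
    threshold_rpm: float | None = None
    if "threshold" in config.stages:
        try:
            res = thr.threshold_analysis(
                rpf_counts["exercise_rep1"], rpf_counts["exercise_rep2"]
            )
            res.bins_frame().to_csv(outdir / "threshold_bins.tsv", sep="\t", index=False)
            threshold_rpm = res.threshold_rpm
            _write_json(
                {"threshold_rpm": res.threshold_rpm, "found": res.found},
                outdir / "threshold.json",
            )
            report["threshold"] = {
                "status": "pass",
                "threshold_rpm": res.threshold_rpm,
            }
        except Exception as e:
            report["threshold"] = {"status": "fail", "error": str(e)}
            _write_json(report, outdir / "report.json")
            raise StageError(f"stage 'threshold' failed: {e}") from e

    if config.threshold_rpm != "auto":
        threshold_rpm = float(config.threshold_rpm)

    def _gene_set() -> pd.Index:
        if threshold_rpm is None:
            return rpf_rpm.index
        all_rpm = pd.concat([rpf_rpm, mrna_rpm], axis=1)
        return thr.apply_threshold(all_rpm, threshold_rpm)

    # -- translational efficiency + TOP shift -------------------------------
    if "te" in config.stages:
        try:
            genes = _gene_set()
            te = tr.te_shift(
                rpf_rpm[["control_rep1", "control_rep2"]],
                rpf_rpm[["exercise_rep1", "exercise_rep2"]],
                mrna_rpm[["control_rep1", "control_rep2"]],
                mrna_rpm[["exercise_rep1", "exercise_rep2"]],
                genes,
            )
            te.rename_axis("gene_id").to_csv(outdir / "te.tsv", sep="\t")
            shift = tr.top_shift_test(te, annotation)
            _write_json(
                {
                    "ks": dataclasses.asdict(shift.ks),
                    "median_top": shift.median_top,
                    "median_nontop": shift.median_nontop,
                    "top_shifted_down": shift.top_shifted_down,
                    "n_genes": int(len(te)),
                    "threshold_rpm": threshold_rpm,
                },
                outdir / "top_shift.json",
            )
            report["te"] = {
                "status": "pass",
                "n_genes": int(len(te)),
                "ks_p": shift.ks.p_value,
                "top_shifted_down": shift.top_shifted_down,
            }
        except Exception as e:
            report["te"] = {"status": "fail", "error": str(e)}
            _write_json(report, outdir / "report.json")
            raise StageError(f"stage 'te' failed: {e}") from e

    # -- pca -----------------------------------------------------------------
    if "pca" in config.stages:
        try:
            genes = _gene_set()
            combined = pd.concat(
                [rpf_rpm.add_prefix("rpf_"), mrna_rpm.add_prefix("mrna_")], axis=1
            )
            scores = tr.pca_profiles(combined, genes)
            scores.to_frame().rename_axis("sample").to_csv(
                outdir / "pca_scores.tsv", sep="\t"
            )
            report["pca"] = {
                "status": "pass",
                "variance_explained": scores.variance_explained.tolist(),
            }
        except Exception as e:
            report["pca"] = {"status": "fail", "error": str(e)}
            _write_json(report, outdir / "report.json")
            raise StageError(f"stage 'pca' failed: {e}") from e

    # -- panel regression -----------------------------------------------------
    if "regress" in config.stages:
        try:
            panel = simulate_panel(config.panel)
            io.write_panel(panel, outdir / "panel.tsv")
            edges = reg.group_correlations(panel)
            edges.to_csv(outdir / "correlation_edges.tsv", sep="\t", index=False)
            trace = reg.panel_regression(panel)
            trace_rows = []
            for step, model in enumerate(trace.models):
                for pred in model.predictors:
                    trace_rows.append(
                        {
                            "step": step,
                            "predictor": pred,
                            "coefficient": model.coefficients[pred],
                            "p_value": model.p_values[pred],
                            "r_squared": model.r_squared,
                        }
                    )
            pd.DataFrame(trace_rows).to_csv(
                outdir / "regression_trace.tsv", sep="\t", index=False
            )
            final = trace.final
            _write_json(
                {
                    "removed": trace.removed,
                    "final_predictors": final.predictors,
                    "coefficients": final.coefficients,
                    "p_values": final.p_values,
                    "r_squared": final.r_squared,
                    "n": final.n,
                },
                outdir / "regression.json",
            )
            report["regress"] = {
                "status": "pass",
                "removed": trace.removed,
                "final_predictors": final.predictors,
            }
        except Exception as e:
            report["regress"] = {"status": "fail", "error": str(e)}
            _write_json(report, outdir / "report.json")
            raise StageError(f"stage 'regress' failed: {e}") from e

    _write_json(report, outdir / "report.json")
    return report
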