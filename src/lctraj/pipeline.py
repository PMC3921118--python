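"""End-to-end analysis pipeline.

Stages, run in order with fail-fast semantics: ingest (raw CSV or synthetic
cohort) -> exclusion filtering and time-zero assignment -> latent class
enumeration and fit on the incident-diabetes population -> modal class
assignment -> class-stratified growth curves for the configured outcome
panel -> pairwise curve contrasts -> report files.  A provenance block
(config hash, seed, package version) accompanies every report; rerunning
with an identical config and seed reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lctraj import __version__
from lctraj.cohort import FlowReport, LongitudinalDataset, apply_exclusions, read_cohort
from lctraj.lclmm import LCLMMFit, LCLMMSpec, select_num_classes
from lctraj.simulate import (
    OutcomeTrack,
    SyntheticConfig,
    generate_cohort,
    generate_outcome_tracks,
)
from lctraj.trajectories import (
    GROUP_FREE,
    GrowthCurveFit,
    curve_contrast_test,
    fit_growth_curve,
    predict_curve,
)

logger = logging.getLogger(__name__)


@dataclass
class OutcomeSpec:
    name: str
    adjustments: tuple[str, ...] = ()
    transform: str | None = None
    max_degree: int = 3


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    seed: int = 0
    input_path: str | None = None  # raw cohort CSV/TSV; None -> synthetic
    synthetic: SyntheticConfig | None = None
    outcome: str = "bmi"
    degree: int = 3
    shared_covariates: tuple[str, ...] = ("age_t0", "sex", "phase")
    g_range: tuple[int, ...] = (1, 2, 3, 4)
    min_share: float = 0.02
    n_starts: int = 4
    tol: float = 1e-6
    max_iter: int = 200
    outcome_panel: list[OutcomeSpec] = field(default_factory=list)
    profile: dict = field(default_factory=lambda: {"age_t0": 60.0, "sex": 1.0})
    t_grid: tuple[float, float, int] = (-18.0, 0.0, 37)
    outdir: str = "results"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.input_path is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if not self.outcome_panel and self.synthetic is not None:
            self.outcome_panel = [
                OutcomeSpec(name=tr.name, transform="log" if tr.log_scale else "identity")
                for tr in self.synthetic.outcomes
            ]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        seed = int(raw.get("seed", 0))
        syn_raw = raw.get("synthetic")
        synthetic = None
        if syn_raw is not None:
            tracks = syn_raw.pop("outcomes", None)
            synthetic = SyntheticConfig(**{**syn_raw, "seed": syn_raw.get("seed", seed)})
            if tracks is not None:
                synthetic.outcomes = [OutcomeTrack(**t) for t in tracks]
        model = raw.get("model", {})
        panel = [
            OutcomeSpec(
                name=o["name"],
                adjustments=tuple(o.get("adjustments", ())),
                transform=o.get("transform"),
                max_degree=int(o.get("max_degree", 3)),
            )
            for o in raw.get("outcomes", [])
        ]
        return cls(
            seed=seed,
            input_path=raw.get("input"),
            synthetic=synthetic,
            outcome=model.get("outcome", "bmi"),
            degree=int(model.get("degree", 3)),
            g_range=tuple(model.get("g_range", (1, 2, 3, 4))),
            min_share=float(model.get("min_share", 0.02)),
            n_starts=int(model.get("n_starts", 4)),
            tol=float(model.get("tol", 1e-6)),
            max_iter=int(model.get("max_iter", 200)),
            outcome_panel=panel,
            profile=raw.get("profile", {"age_t0": 60.0, "sex": 1.0}),
            t_grid=tuple(raw.get("t_grid", (-18.0, 0.0, 37))),
            outdir=raw.get("outdir", "results"),
            verbosity=int(raw.get("verbosity", 1)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, ready for serialization."""

    config: PipelineConfig
    flow: FlowReport | None
    enumeration: pd.DataFrame
    selected_g: int
    fit: LCLMMFit
    avg_posterior: pd.DataFrame
    class_labels: pd.Series
    growth_fits: dict[str, GrowthCurveFit]
    contrasts: pd.DataFrame
    curves: dict[str, dict[str, pd.DataFrame]]
    n_subjects: int
    n_incident: int

    @property
    def incidence_percent(self) -> float:
        return 100.0 * self.n_incident / self.n_subjects

    def provenance(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "version": __version__,
            "selected_g": self.selected_g,
            "n_subjects": self.n_subjects,
            "n_incident": self.n_incident,
        }


def load_dataset(config: PipelineConfig):
    """Ingest stage: raw CSV through the exclusion flow, or synthetic draw."""
    if config.input_path is not None:
        raw = read_cohort(config.input_path)
        dataset, flow = apply_exclusions(raw)
        return dataset, flow
    dataset, truth = generate_cohort(config.synthetic)
    dataset = generate_outcome_tracks(config.synthetic, dataset, truth)
    return dataset, None


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and return the report object."""
    t0 = time.time()
    dataset, flow = load_dataset(config)
    logger.info("ingest: %d subjects, %d records (%.1fs)",
                dataset.n_subjects, dataset.n_records, time.time() - t0)

    incident = dataset.incident_subset()
    spec = LCLMMSpec(
        outcome_name=config.outcome,
        degree=config.degree,
        shared_covariates=config.shared_covariates,
        n_classes=1,
    )
    selected_g, fits, enumeration = select_num_classes(
        incident,
        spec,
        G_range=config.g_range,
        min_share=config.min_share,
        n_starts=config.n_starts,
        tol=config.tol,
        max_iter=config.max_iter,
        seed=config.seed,
    )
    fit = fits[selected_g]
    logger.info("lclmm: selected G=%d (BIC %.1f)", selected_g, fit.bic)

    labels = fit.assignment.map(lambda g: f"class_{g}")
    free_ids = dataset.subjects.index[
        dataset.subjects["diabetes_status"] == "diabetes-free"
    ]
    labels = pd.concat([labels, pd.Series(GROUP_FREE, index=free_ids)])

    growth_fits: dict[str, GrowthCurveFit] = {}
    contrast_rows = []
    curves: dict[str, dict[str, pd.DataFrame]] = {}
    lo, hi, n_grid = config.t_grid
    grid = np.linspace(lo, hi, int(n_grid))
    for ospec in config.outcome_panel:
        gfit = fit_growth_curve(
            ospec.name,
            dataset,
            labels,
            max_degree=ospec.max_degree,
            adjustments=ospec.adjustments,
            transform=ospec.transform,
        )
        growth_fits[ospec.name] = gfit
        profile = dict(config.profile)
        for s in gfit.shared_names:
            profile.setdefault(s, 0.0)
        curves[ospec.name] = {
            g: predict_curve(gfit, profile, g, grid) for g in gfit.groups
        }
        for a, b in combinations(gfit.groups, 2):
            ct = curve_contrast_test(gfit, a, b)
            contrast_rows.append(
                {
                    "outcome": ospec.name,
                    "group_a": a,
                    "group_b": b,
                    "F": ct.F_statistic,
                    "df_num": ct.df_num,
                    "df_den": ct.df_den,
                    "p_value": ct.p_value,
                }
            )
        logger.info("growth curve: %s degrees=%s", ospec.name, gfit.degrees)

    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["outcome", "group_a", "group_b", "F", "df_num", "df_den", "p_value"],
    )
    return AnalysisReport(
        config=config,
        flow=flow,
        enumeration=enumeration,
        selected_g=selected_g,
        fit=fit,
        avg_posterior=fit.average_posterior_table(),
        class_labels=labels,
        growth_fits=growth_fits,
        contrasts=contrasts,
        curves=curves,
        n_subjects=dataset.n_subjects,
        n_incident=incident.n_subjects,
    )


def write_report(report: AnalysisReport, outdir: str | Path) -> Path:
    """Write all report files; on failure, quarantine partial output.

    Files: flow.tsv, bic_table.tsv, fit.json, posteriors.csv,
    avg_posterior.tsv, coefficients.tsv, contrasts.tsv, curves/*.csv,
    provenance.json.  The report is assembled in a temporary directory and
    moved into place, so a crashed run never leaves a half-written report
    at the target path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmp = outdir / ".tmp_report"
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir()
    try:
        if report.flow is not None:
            report.flow.to_tsv(tmp / "flow.tsv")
        report.enumeration.to_csv(tmp / "bic_table.tsv", sep="\t")
        report.fit.to_json(tmp / "fit.json")
        report.fit.posterior.to_csv(tmp / "posteriors.csv")
        report.avg_posterior.to_csv(tmp / "avg_posterior.tsv", sep="\t")

        coef_frames = []
        for name, gfit in report.growth_fits.items():
            tbl = gfit.coefficient_table().reset_index()
            tbl.insert(0, "outcome", name)
            tbl.insert(2, "transform", gfit.transform)
            coef_frames.append(tbl)
        if coef_frames:
            pd.concat(coef_frames, ignore_index=True).to_csv(
                tmp / "coefficients.tsv", sep="\t", index=False
            )
        else:
            pd.DataFrame(columns=["outcome", "group", "transform"]).to_csv(
                tmp / "coefficients.tsv", sep="\t", index=False
            )
        report.contrasts.to_csv(tmp / "contrasts.tsv", sep="\t", index=False)

        curve_dir = tmp / "curves"
        curve_dir.mkdir()
        for name, per_group in report.curves.items():
            for g, frame in per_group.items():
                safe = g.replace("/", "_")
                frame.to_csv(curve_dir / f"{name}__{safe}.csv", index=False)

        (tmp / "provenance.json").write_text(
            json.dumps(report.provenance(), indent=2)
        )
    except Exception:
        failed = outdir / "failed"
        if failed.exists():
            shutil.rmtree(failed)
        tmp.rename(failed)
        raise

    for item in tmp.iterdir():
        target = outdir / item.name
        if target.exists():
            shutil.rmtree(target) if target.is_dir() else target.unlink()
        item.rename(target)
    tmp.rmdir()
    return outdir
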