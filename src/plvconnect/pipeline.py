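"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
ART ANOVA + post-hocs -> ROC, under a single reproducible config."""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .art import ARTResult, PosthocResult, art_anova, posthoc_pairwise
from .bands import DEFAULT_BANDS, BandSpec
from .connectivity import connectivity_table, write_table
from .exceptions import PipelineError
from .preprocess import preprocess_recording
from .recording import GROUPS, Recording
from .roc import LabeledScores, ROCResult, evaluate
from .synthetic import SimConfig, generate_cohort


@dataclass
class PipelineConfig:
    """Everything one run needs; ``sim.master_seed`` drives all randomness."""

    sim: SimConfig = field(default_factory=SimConfig)
    epoch_seconds: float = 180.0
    amplitude_threshold: float = 100.0
    notch_hz: float = 60.0
    bandpass: tuple[float, float] = (1.0, 70.0)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    alpha: float = 0.05
    n_boot: int = 10_000
    positive_class: str = "HC"
    roc_band: str = "delta"
    roc_condition: str = "motor"

    def validate(self) -> None:
        self.sim.validate()
        if self.epoch_seconds > self.sim.duration:
            raise ValueError(
                f"epoch_seconds={self.epoch_seconds} exceeds recording "
                f"duration {self.sim.duration}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.roc_band not in {b.name for b in self.bands}:
            raise ValueError(f"roc_band {self.roc_band!r} not among analysis bands")


@dataclass
class RunReport:
    """Complete, re-runnable record of one pipeline execution."""

    config: PipelineConfig
    table: pd.DataFrame
    art: ARTResult
    posthocs: list[PosthocResult]
    roc: ROCResult
    epoch_log: list[dict]
    seeds: dict[str, int]
    version: str = __version__


def _stage(name: str, ident: str):
    """Context wrapper: re-raise any stage failure with stage and input."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed for {ident}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute every stage in fixed order; deterministic for a given
    ``config.sim.master_seed``. Writes CSV/JSON artifacts when
    ``out_dir`` is given."""
    config.validate()
    seeds = {"master_seed": int(config.sim.master_seed)}

    with _stage("simulate", "cohort"):
        cohort = generate_cohort(config.sim)

    epoched: list[Recording] = []
    epoch_log: list[dict] = []
    for rec in cohort:
        ident = f"{rec.subject_id}/{rec.condition}"
        with _stage("preprocess", ident):
            clean, sel = preprocess_recording(
                rec,
                notch_hz=config.notch_hz,
                band=config.bandpass,
                epoch_seconds=config.epoch_seconds,
                amplitude_threshold=config.amplitude_threshold,
            )
        epoched.append(clean)
        epoch_log.append(
            {
                "recording": ident,
                "duration_s": rec.duration,
                "epoch_start": sel.start,
                "epoch_clean": sel.clean,
                "n_crossings": sel.n_crossings,
            }
        )

    with _stage("connectivity", "cohort"):
        table = connectivity_table(epoched, config.bands)

    with _stage("stats", "connectivity table"):
        art = art_anova(table)
        posthocs = []
        n_bands = len(config.bands)
        for band in config.bands:
            posthocs.append(
                posthoc_pairwise(
                    table,
                    between="group",
                    where={"band": band.name, "condition": config.roc_condition},
                    family=n_bands,
                )
            )
        for group in GROUPS:
            posthocs.append(
                posthoc_pairwise(
                    table,
                    between="condition",
                    where={"band": config.roc_band, "group": group},
                    family=len(GROUPS),
                )
            )

    with _stage("roc", f"{config.roc_band}/{config.roc_condition}"):
        scores = LabeledScores.from_table(
            table,
            band=config.roc_band,
            condition=config.roc_condition,
            positive=config.positive_class,
        )
        boot_seed = int(
            np.random.SeedSequence((config.sim.master_seed, 0xB007)).generate_state(1)[0]
            % (2**31)
        )
        seeds["bootstrap_seed"] = boot_seed
        roc = evaluate(scores, n_boot=config.n_boot, seed=boot_seed)

    report = RunReport(
        config=config,
        table=table,
        art=art,
        posthocs=posthocs,
        roc=roc,
        epoch_log=epoch_log,
        seeds=seeds,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_dict(report: RunReport) -> dict:
    """JSON-serialisable summary of a run."""
    cm = report.roc.confusion
    sim = report.config.sim
    return _jsonable(
        {
            "version": report.version,
            "seeds": report.seeds,
            "config": {
                "n_pd": sim.n_pd,
                "n_hc": sim.n_hc,
                "n_channels": sim.n_channels,
                "fs": sim.fs,
                "duration_s": sim.duration,
                "epoch_seconds": report.config.epoch_seconds,
                "notch_hz": report.config.notch_hz,
                "bandpass_hz": list(report.config.bandpass),
                "bands": {b.name: [b.low, b.high] for b in report.config.bands},
                "alpha": report.config.alpha,
                "n_boot": report.config.n_boot,
                "positive_class": report.config.positive_class,
                "roc_feature": [report.config.roc_band, report.config.roc_condition],
            },
            "n_table_rows": len(report.table),
            "anova": {
                eff: {
                    "F": row["F"],
                    "df_num": int(row["df_num"]),
                    "df_den": int(row["df_den"]),
                    "p": row["p"],
                }
                for eff, row in report.art.anova.iterrows()
            },
            "stripped_max_f": report.art.stripped_max_f,
            "posthocs": [dataclasses.asdict(p) for p in report.posthocs],
            "roc": {
                "auc": report.roc.auc,
                "cutoff": report.roc.cutoff,
                "confusion": dataclasses.asdict(cm) if cm else None,
                "ci": report.roc.ci,
                "n_boot": report.roc.n_boot,
            },
        }
    )


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(report.table, out / "connectivity.csv")
    summary = report_dict(report)
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    (out / "stats.json").write_text(
        json.dumps(
            {
                "anova": summary["anova"],
                "stripped_max_f": summary["stripped_max_f"],
                "posthocs": summary["posthocs"],
            },
            indent=1,
        )
    )
    (out / "roc.json").write_text(json.dumps(summary["roc"], indent=1))
    lines = [
        f"{e['recording']}\tdur={e['duration_s']:.1f}s\tstart={e['epoch_start']}"
        f"\tclean={e['epoch_clean']}\tcrossings={e['n_crossings']}"
        for e in report.epoch_log
    ]
    (out / "log.txt").write_text("\n".join(lines) + "\n")
    (out / "summary.txt").write_text(summarize(report))


def summarize(report: RunReport) -> str:
    """Human-readable headline summary; pure formatting."""
    alpha = report.config.alpha
    lines = [
        f"plvconnect {report.version} — pipeline summary",
        f"cohort: {report.config.sim.n_pd} PD + {report.config.sim.n_hc} HC, "
        f"{report.config.sim.n_channels} channels, "
        f"{report.config.epoch_seconds:.0f} s epochs "
        f"({len(report.table)} connectivity rows)",
        "",
        "ART ANOVA (F, df, p):",
    ]
    for eff, row in report.art.anova.iterrows():
        star = " *" if row["p"] < alpha else ""
        lines.append(
            f"  {eff:<25s} F({int(row['df_num'])},{int(row['df_den'])}) = "
            f"{row['F']:.2f}, p = {row['p']:.4g}{star}"
        )
    lines.append("")
    sig = [p for p in report.posthocs if p.p_adjusted < alpha]
    if sig:
        lines.append("significant post-hoc contrasts (Bonferroni-adjusted):")
        for p in sig:
            lines.append(
                f"  {p.description}: p_adj = {p.p_adjusted:.4g} "
                f"(raw {p.p_raw:.4g}, family {p.family})"
            )
    else:
        lines.append("no significant contrasts")
    lines.append("")
    cm = report.roc.confusion
    band, cond = report.config.roc_band, report.config.roc_condition
    lines.append(
        f"ROC ({band} band, {cond} task, positive={report.roc.data.positive_label}):"
    )
    auc_ci = report.roc.ci.get("auc", (float("nan"), float("nan")))
    lines.append(
        f"  AUC = {report.roc.auc:.3f} (95% CI {auc_ci[0]:.2f}-{auc_ci[1]:.2f}), "
        f"cutoff = {report.roc.cutoff:.4f}"
    )
    if cm is not None:
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lo, hi = report.roc.ci.get(name, (float("nan"), float("nan")))
            lines.append(
                f"  {name:<12s} {getattr(cm, name) * 100:6.1f}% "
                f"(95% CI {lo * 100:.0f}-{hi * 100:.0f}%)"
            )
    return "\n".join(lines) + "\n"
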