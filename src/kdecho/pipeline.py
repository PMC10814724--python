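"""End-to-end pipeline: generate -> derive -> fit-norms -> score -> analyze.

Each stage hands off a plain CSV (or JSON model file) so every
intermediate is independently inspectable, and a run manifest records the
configuration hash, seed and a SHA-256 checksum of every input and output
file; rerunning with the same config and seed reproduces identical
checksums for all stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, GeneratorConfig
from .derive import MEEH_K, derive_table
from .generator import generate_cohort
from .normative import DEFAULT_CUTOFF, NormativeModel, fit_normative, score_table
from .records import read_cohort, write_cohort
from .stats import percent_z_table, pearson_corr, summarize, two_sample_t

log = logging.getLogger("kdecho")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Parameters of the fit/score/analyze stages."""

    mode: str = "regression"  # "regression" | "mean_sd"
    cutoff: float = DEFAULT_CUTOFF
    score_measurements: tuple[str, ...] = ("coronary_inner_d_mm",)
    summary_measurements: tuple[str, ...] = (
        "coronary_inner_d_mm",
        "carotid_outer_d_mm",
        "carotid_wall_mean_mm",
        "aorta_outer_d_mm",
        "ejection_fraction_pct",
    )
    correlation_day: int = 28
    correlation_pairs: tuple[tuple[str, str], ...] = (
        ("carotid_outer_d_mm", "coronary_inner_d_mm"),
        ("carotid_wall_mean_mm", "coronary_inner_d_mm"),
    )
    weight_adjusted_corr: bool = True
    meeh_k: float = MEEH_K

    @classmethod
    def from_dict(cls, data: Mapping[str, Any] | None) -> "AnalysisConfig":
        if not data:
            return cls()
        known = {f.name for f in dataclasses.fields(cls)}
        for key in data:
            if key not in known:
                raise ConfigError(f"analysis.{key}: unknown configuration field")
        kwargs = dict(data)
        for key in ("score_measurements", "summary_measurements"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "correlation_pairs" in kwargs:
            kwargs["correlation_pairs"] = tuple(
                (str(x), str(y)) for x, y in kwargs["correlation_pairs"]
            )
        cfg = cls(**kwargs)
        if cfg.mode not in ("regression", "mean_sd"):
            raise ConfigError("analysis.mode: must be regression or mean_sd")
        return cfg


def load_pipeline_config(path) -> tuple[GeneratorConfig, AnalysisConfig]:
    """Read a YAML file with optional ``generator:`` / ``analysis:`` blocks."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("config file: top level must be a mapping")
    gen_block = data.get("generator", {k: v for k, v in data.items()
                                       if k != "analysis"})
    gen = GeneratorConfig.from_dict(gen_block or {})
    ana = AnalysisConfig.from_dict(data.get("analysis"))
    return gen, ana


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class StageEntry:
    name: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    started: str
    finished: str


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_sha256: str
    seed: int
    version: str
    stages: list[StageEntry] = field(default_factory=list)

    def to_json(self, path) -> None:
        data = {
            "config_sha256": self.config_sha256,
            "seed": self.seed,
            "version": self.version,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        stages = [StageEntry(**s) for s in data.pop("stages")]
        return cls(stages=stages, **data)


def _wadj_column(measurement: str) -> str:
    if measurement.endswith("_wall_mean_mm"):
        return measurement[: -len("_mm")] + "_wadj"
    return f"{measurement}_wadj"


def analyze_tables(
    scored: pd.DataFrame, gen: GeneratorConfig, ana: AnalysisConfig
) -> dict[str, pd.DataFrame]:
    """Summary / t-test / correlation / percent-Z tables from a scored cohort."""
    score_m = ana.score_measurements[0]
    z_col = f"z_{score_m}"

    summaries = []
    for m in ana.summary_measurements:
        if m not in scored.columns:
            continue
        summaries.append(
            summarize(scored, m, z_col=z_col if m == score_m else None,
                      cutoff=ana.cutoff)
        )
    summary_df = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()

    control = gen.control_group
    ttests = []
    treated = [g for g in gen.groups if g != control]
    if (scored["group"] == control).any():
        for m in ana.summary_measurements:
            if m not in scored.columns:
                continue
            for day in sorted(d for d in scored["day"].unique() if d > 0):
                for g in treated:
                    try:
                        res = two_sample_t(scored, g, control, m, int(day))
                    except ValueError:
                        continue
                    ttests.append(res.__dict__)
    ttest_df = pd.DataFrame(ttests)

    corrs = []
    for x, y in ana.correlation_pairs:
        cx = _wadj_column(x) if ana.weight_adjusted_corr else x
        cy = _wadj_column(y) if ana.weight_adjusted_corr else y
        if cx not in scored.columns or cy not in scored.columns:
            continue
        try:
            res = pearson_corr(scored, cx, cy, day=ana.correlation_day)
        except ValueError:
            continue
        corrs.append(res.__dict__)
    corr_df = pd.DataFrame(corrs)

    pct = percent_z_table(
        scored, z_col, ana.cutoff,
        groups=[g for g in gen.groups if (scored["group"] == g).any()],
        days=sorted(scored["day"].unique()),
    )
    return {
        "summaries": summary_df,
        "ttests": ttest_df,
        "correlations": corr_df,
        "percent_z": pct,
    }


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Run all five stages from a config file into ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).  On a stage
    failure, outputs already written by that stage are renamed with a
    ``.partial`` suffix and a :class:`PipelineError` naming the stage is
    raised.
    """
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen, ana = load_pipeline_config(config_path)
    if seed is not None:
        gen = gen.with_seed(seed)
    manifest = RunManifest(
        config_sha256=_sha256(config_path), seed=gen.seed, version=__version__
    )

    def _run_stage(name: str, func, inputs: list[Path], outputs: list[Path]):
        started = _now()
        log.info("stage %s: starting", name)
        try:
            func()
        except Exception as exc:
            for p in outputs:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        entry = StageEntry(
            name=name,
            inputs={p.name: _sha256(p) for p in inputs},
            outputs={p.name: _sha256(p) for p in outputs},
            started=started,
            finished=_now(),
        )
        manifest.stages.append(entry)
        log.info("stage %s: done", name)

    cohort_csv = out / "cohort.csv"
    derived_csv = out / "derived.csv"
    model_files = {
        m: out / f"model_{m}.json" for m in ana.score_measurements
    }
    scored_csv = out / "scored.csv"
    report_dir = out / "report"

    _run_stage(
        "generate",
        lambda: write_cohort(generate_cohort(gen), cohort_csv),
        [config_path], [cohort_csv],
    )
    _run_stage(
        "derive",
        lambda: derive_table(read_cohort(cohort_csv), ana.meeh_k).to_csv(
            derived_csv, index=False
        ),
        [cohort_csv], [derived_csv],
    )

    def _fit():
        derived = pd.read_csv(derived_csv)
        baseline = derived[derived["day"] == 0]
        for m, path in model_files.items():
            fit_normative(baseline, m, mode=ana.mode).to_json(path)

    _run_stage("fit_norms", _fit, [derived_csv], list(model_files.values()))

    def _score():
        derived = pd.read_csv(derived_csv)
        models = {m: NormativeModel.from_json(p) for m, p in model_files.items()}
        score_table(derived, models, ana.cutoff).to_csv(scored_csv, index=False)

    _run_stage("score", _score, [derived_csv, *model_files.values()], [scored_csv])

    def _analyze():
        report_dir.mkdir(exist_ok=True)
        scored = pd.read_csv(scored_csv)
        tables = analyze_tables(scored, gen, ana)
        tables["summaries"].to_csv(report_dir / "summaries.csv", index=False)
        tables["ttests"].to_csv(report_dir / "ttests.csv", index=False)
        tables["correlations"].to_csv(report_dir / "correlations.csv", index=False)
        tables["percent_z"].to_csv(report_dir / "percent_z.csv")
        n_tests = len(tables["ttests"]) + len(tables["correlations"])
        with open(report_dir / "run.log", "w", encoding="utf-8") as fh:
            fh.write(f"kdecho {__version__}\n")
            fh.write(f"seed: {gen.seed}\n")
            fh.write(f"records: {len(scored)}\n")
            fh.write(f"groups: {', '.join(gen.groups)}\n")
            fh.write(f"days: {', '.join(str(d) for d in gen.days)}\n")
            fh.write(f"cutoff: Z > {ana.cutoff} (strict)\n")
            fh.write(f"statistical tests performed (uncorrected): {n_tests}\n")

    _run_stage(
        "analyze", _analyze, [scored_csv],
        [report_dir / "summaries.csv", report_dir / "ttests.csv",
         report_dir / "correlations.csv", report_dir / "percent_z.csv",
         report_dir / "run.log"],
    )

    manifest.to_json(out / "manifest.json")
    return manifest
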