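"""End-to-end pipeline: simulate? -> filter -> classify -> transgen -> homeolog -> report.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives
every stage; all randomness flows from its one seed.  Outputs are
deterministic TSVs plus a run manifest recording the config hash, seed,
library versions and per-output row counts, so two runs with the same
config are byte-identical (the run log aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .categorize import classify_tissue, summarize_categories
from .homeolog import call_partitioning, summarize_dominance, tabulate_comparable
from .iolayer import (
    ExpressionDataset,
    HomeologTable,
    read_expression,
    read_homeolog,
    write_calls,
    write_expression,
    write_homeolog,
)
from .synthetic_data import GroundTruth, HomeologSimConfig, SimConfig, simulate_expression, simulate_homeolog
from .transgen import decompose_sources, find_consistent, summary_frame

logger = logging.getLogger("polyshock.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "build_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _build_nested(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown {context} key(s): {unknown}")
    kwargs = dict(data)
    for f in fields(cls):
        if f.name in kwargs:
            v = kwargs[f.name]
            if f.name == "homeolog" and isinstance(v, dict):
                kwargs[f.name] = _build_nested(HomeologSimConfig, v, "simulate.homeolog")
            elif isinstance(v, list):
                kwargs[f.name] = tuple(v)
            elif f.name == "category_mix" and isinstance(v, dict):
                kwargs[f.name] = {k: float(x) for k, x in v.items()}
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide settings; thresholds follow the analysis conventions
    (FDR < 0.05 for expression contrasts, raw p < 0.05 for partitioning)."""

    out_dir: str = "polyshock_out"
    expression: str | None = None
    manifest: str | None = None
    homeolog: str | None = None
    tissues: tuple[str, ...] | None = None
    generations: tuple[str, ...] | None = None
    alpha_expression: float = 0.05
    alpha_partitioning: float = 0.05
    mpv_mode: str = "measured_mix"
    detection_threshold: float = 5.0
    match_mode: str = "exact_pattern"
    log2_transform: bool = False
    seed: int = 0
    simulate: SimConfig | None = None

    def validate(self) -> None:
        for name in ("alpha_expression", "alpha_partitioning"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.mpv_mode not in ("measured_mix", "computed"):
            raise ValueError(f"unknown mpv_mode {self.mpv_mode!r}")
        if self.match_mode not in ("exact_pattern", "nonadditive_only"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.simulate is None and (self.expression is None or self.manifest is None):
            raise ValueError("either input paths or a simulate: block is required")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("simulate") is not None:
            data["simulate"] = _build_nested(SimConfig, data["simulate"], "simulate")
        cfg = _build_nested(cls, data, "config")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_summary(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def build_report(
    calls: pd.DataFrame,
    transgen_summaries,
    pcalls: pd.DataFrame | None,
    dominance: pd.DataFrame | None,
) -> pd.DataFrame:
    """Aggregate all stage summaries into one (section, key, value) table."""
    rows: list[tuple[str, str, str]] = []

    def put(section, key, value):
        if isinstance(value, float):
            value = f"{value:.6g}"
        rows.append((section, key, str(value)))

    for (tis, gen), grp in calls.groupby(["tissue", "generation"], sort=True):
        nonadd = int((grp["additivity"] == "nonadditive").sum())
        put("classify", f"{tis}:{gen}:n_genes", len(grp))
        put("classify", f"{tis}:{gen}:n_nonadditive", nonadd)
        put("classify", f"{tis}:{gen}:prop_nonadditive", nonadd / len(grp))

    for summ in transgen_summaries:
        put("transgen", f"{summ.tissue}:n_consistent", len(summ.consistent_genes))
        for gen in summ.generations:
            put(
                "transgen",
                f"{summ.tissue}:{gen}:consistent_share",
                summ.consistent_share[gen],
            )
        if summ.tre_vs_eld is not None:
            put("transgen", f"{summ.tissue}:tre_vs_eld_p", summ.tre_vs_eld.p_value)

    if pcalls is not None and len(pcalls):
        for cls_ in ("additive", "nonadditive"):
            x, n, p = tabulate_comparable(pcalls, cls_)
            put("homeolog", f"{cls_}:n_altered", x)
            put("homeolog", f"{cls_}:n_comparable", n)
            put("homeolog", f"{cls_}:prop_altered", p if p is not None else "NA")
        for outcome, cnt in pcalls["outcome"].value_counts().sort_index().items():
            put("homeolog", f"outcome:{outcome}", int(cnt))

    if dominance is not None and len(dominance):
        for r in dominance.itertuples():
            put("dominance", f"{r.genotype}:mean_a_fraction", float(r.mean_a_fraction))
            put("dominance", f"{r.genotype}:n_a_biased", int(r.n_a_biased))
            put("dominance", f"{r.genotype}:n_b_biased", int(r.n_b_biased))

    return pd.DataFrame(rows, columns=["section", "key", "value"])


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("polyshock")
    root.addHandler(handler)
    try:
        truth: GroundTruth | None = None
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)

            @_stage("simulate")
            def _simulate():
                dataset, truth = simulate_expression(sim)
                homeo = simulate_homeolog(sim, truth)
                write_expression(dataset, out / "expression.tsv", out / "manifest.tsv")
                write_homeolog(homeo, out / "homeolog.tsv")
                truth.parental.to_csv(out / "truth_parental.tsv", sep="\t", index=False)
                truth.patterns.to_csv(out / "truth_patterns.tsv", sep="\t", index=False)
                truth.homeolog.to_csv(out / "truth_homeolog.tsv", sep="\t", index=False)
                return dataset, homeo, truth

            dataset, homeo, truth = _simulate()
        else:

            @_stage("ingest")
            def _ingest():
                dataset = read_expression(
                    config.expression, config.manifest, log2_transform=config.log2_transform
                )
                homeo = read_homeolog(config.homeolog) if config.homeolog else None
                return dataset, homeo

            dataset, homeo = _ingest()

        tissues = list(config.tissues) if config.tissues else dataset.tissues()
        if config.generations:
            generations = list(config.generations)
        else:
            gens = dataset.manifest.loc[
                dataset.manifest["role"] == "polyploid", "generation"
            ]
            generations = sorted(gens.unique())

        @_stage("classify")
        def _classify():
            frames = [
                classify_tissue(
                    dataset,
                    tissue,
                    generations,
                    alpha=config.alpha_expression,
                    mpv_mode=config.mpv_mode,
                    detection_threshold=config.detection_threshold,
                )
                for tissue in tissues
            ]
            return pd.concat(frames, ignore_index=True)

        calls = _classify()
        write_calls(calls, out / "calls.tsv")
        row_counts["calls.tsv"] = len(calls)

        @_stage("summarize")
        def _summarize():
            return summarize_categories(calls)

        cat = _summarize()
        _write_summary(cat.pattern_counts, out / "category_counts.tsv")
        _write_summary(cat.propensity, out / "category_propensity.tsv")
        row_counts["category_counts.tsv"] = len(cat.pattern_counts)

        @_stage("transgen")
        def _transgen():
            summaries = []
            for tissue in tissues:
                summ = find_consistent(calls, tissue, generations, config.match_mode)
                if config.match_mode == "exact_pattern":
                    summ = decompose_sources(summ, calls)
                summaries.append(summ)
            return summaries

        summaries = _transgen()
        tg_frames = []
        for summ in summaries:
            f = summary_frame(summ)
            f.insert(0, "tissue", summ.tissue)
            tg_frames.append(f)
        tg = pd.concat(tg_frames, ignore_index=True)
        _write_summary(tg, out / "transgen.tsv")
        row_counts["transgen.tsv"] = len(tg)

        pcalls = None
        dominance = None
        if homeo is not None:
            homeolog_tissue = tissues[0]

            @_stage("homeolog")
            def _homeolog():
                pcalls = call_partitioning(
                    homeo,
                    dataset.manifest,
                    calls,
                    homeolog_tissue,
                    alpha=config.alpha_partitioning,
                )
                dominance = summarize_dominance(homeo, dataset.manifest)
                return pcalls, dominance

            pcalls, dominance = _homeolog()
            write_calls(pcalls, out / "partitioning.tsv")
            _write_summary(dominance, out / "dominance.tsv")
            row_counts["partitioning.tsv"] = len(pcalls)
            row_counts["dominance.tsv"] = len(dominance)

        @_stage("report")
        def _report():
            return build_report(calls, summaries, pcalls, dominance)

        report = _report()
        _write_summary(report, out / "report.tsv")
        row_counts["report.tsv"] = len(report)

        manifest = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "versions": {
                "polyshock": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "row_counts": row_counts,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
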