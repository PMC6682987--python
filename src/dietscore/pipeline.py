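"""End-to-end pipeline: simulate/load -> usual intake -> DQS -> DDS ->
anthropometry -> stratified report, with a run manifest.

Configured by a single YAML file.  Exactly one input source must be present:
either ``inputs`` (paths to subjects.csv and recalls.csv) or ``generator``
(a synthetic-population spec).  One seed governs every stochastic stage
through per-stage derived substreams, so stages re-run independently
reproduce the full run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthro import classify_subjects
from .core import (
    DEFAULT_FACTORS,
    PipelineConfig,
    ValidationError,
    load_recalls,
    load_subjects,
    write_data,
    write_table,
)
from .dds import compute_dds, group_frequencies
from .dqs import assign_all_quintiles, compute_dqs
from .report import (
    country_summary,
    format_p,
    quintile_summary,
    regress_scores,
    score_strata_report,
)
from .synthetic import GeneratorSpec, generate_population
from .usual import UsualIntakeOptions, build_usual_table


class ConfigError(ValueError):
    """The run configuration is ambiguous or incomplete."""


def _substream(seed: int, stage: str) -> int:
    """A stable per-stage seed derived from the run seed (below 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and return the run manifest (also written as JSON).

    ``config`` is a mapping or a path to a YAML file with keys:

    - ``seed``: master seed (default 0)
    - ``out_dir``: output directory
    - ``generator``: GeneratorSpec fields (synthetic input), or
    - ``inputs``: {subjects: path, recalls: path} (real input)
    - ``pipeline``: PipelineConfig fields (scheme, thresholds, estimator flags)
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()

    if ("generator" in config) == ("inputs" in config):
        raise ConfigError(
            "exactly one of 'generator' (synthetic) or 'inputs' (files) required"
        )
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "dietscore_run"))
    out.mkdir(parents=True, exist_ok=True)
    pcfg = PipelineConfig(seed=seed, **config.get("pipeline", {}))
    factors = pcfg.factors
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": seed,
        "stages": [],
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    # --- input stage --------------------------------------------------------
    if "generator" in config:
        gspec = GeneratorSpec(
            seed=_substream(seed, "simulate"), scheme=pcfg.scheme,
            **(config["generator"] or {}),
        )
        subjects, recalls, truth = generate_population(gspec)
        write_data(subjects, out / "subjects.csv")
        write_data(recalls, out / "recalls.csv")
        write_data(truth, out / "truth.csv")
        record("simulate", subjects=len(subjects), recalls=len(recalls))
    else:
        paths = config["inputs"]
        subjects = load_subjects(paths["subjects"])
        recalls = load_recalls(paths["recalls"], factors, pcfg.scheme)
        record("load", subjects=len(subjects), recalls=len(recalls))

    # --- usual intake -------------------------------------------------------
    opts = UsualIntakeOptions(
        transform=pcfg.transform,
        shrink=pcfg.shrink,
        bias_correction=pcfg.bias_correction,
        two_part=pcfg.two_part,
    )
    usual, usual_meta = build_usual_table(subjects, recalls, factors, opts)
    write_data(usual, out / "usual.csv")
    write_data(usual_meta, out / "usual_meta.csv")
    record("usual", rows=len(usual), subgroup_factor_cells=len(usual_meta))

    # --- DQS ---------------------------------------------------------------
    rng = np.random.default_rng(_substream(seed, "dqs"))
    quintiles = assign_all_quintiles(
        usual, subjects, factors,
        min_subgroup_size=pcfg.min_subgroup_size,
        tie_break=pcfg.quintile_tie_break, rng=rng,
    )
    dqs = compute_dqs(quintiles, factors)
    write_data(quintiles.merge(dqs, on="subject_id"), out / "dqs.csv")
    record("dqs", rows=len(dqs))

    # --- DDS ---------------------------------------------------------------
    dds_results = compute_dds(
        recalls, scheme=pcfg.scheme, threshold=pcfg.dds_threshold_g, day=pcfg.dds_day,
        allow_any_day=pcfg.dds_day != 1,
    )
    write_data(dds_results, out / "dds.csv")
    record("dds", rows=len(dds_results))

    # --- anthropometry ------------------------------------------------------
    anthro_classes = classify_subjects(subjects)
    write_data(anthro_classes, out / "anthro.csv")
    record("anthro", rows=len(anthro_classes))

    # --- report -------------------------------------------------------------
    t1 = quintile_summary(usual, quintiles, factors)
    write_table(t1, out / "table1.csv")
    t2 = country_summary(usual, subjects, factors)
    write_table(t2, out / "table2.csv")
    strata, effects, pairwise = score_strata_report(
        dqs, dds_results, subjects, anthro_classes
    )
    write_table(strata, out / "table3.csv")
    if not effects.empty:
        effects = effects.assign(p_display=[format_p(p) for p in effects["p_value"]])
    write_table(effects, out / "anova_effects.csv", precision=4)
    write_table(pairwise, out / "posthoc_pairwise.csv", precision=4)
    freqs = group_frequencies(dds_results, scheme=pcfg.scheme, by_tertile=True)
    freqs_all = group_frequencies(dds_results, scheme=pcfg.scheme, by_tertile=False)
    write_table(pd.concat([freqs_all, freqs], ignore_index=True), out / "fig1_frequencies.csv")

    scores = dqs.merge(dds_results[["subject_id", "dds"]], on="subject_id").merge(
        subjects[["subject_id", "sex", "age_group", "sel", "country"]], on="subject_id"
    )
    reg_rows = []
    for summary in (
        regress_scores(scores, "total_std", ("healthy_std",))
        + regress_scores(scores, "total_std", ("unhealthy_std",))
        + regress_scores(scores, "total_raw", ("healthy_raw", "unhealthy_raw"))
        + regress_scores(scores, "dds", ("healthy_std",), strata="sex")
        + regress_scores(scores, "dds", ("healthy_std",), strata="sel")
        + regress_scores(scores, "dds", ("healthy_std",), strata="country")
    ):
        reg_rows.append(
            {
                "outcome": summary.outcome,
                "predictors": "+".join(summary.predictors),
                "stratum": summary.stratum,
                "n": summary.n,
                "r": summary.r,
                "r_squared": summary.r_squared,
                "collinear": summary.collinear,
            }
        )
    write_table(pd.DataFrame(reg_rows), out / "regressions.csv", precision=4)
    record("report", tables=7)

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
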