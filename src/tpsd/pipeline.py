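"""End-to-end pipeline: simulate -> score -> profiles -> decode -> compare.

Stages are configured by a nestable key-value config (dict or YAML file),
run in a fixed dependency order, and write their CSV outputs plus a JSON run
manifest (seed, parameters, package version, output list) into ``out_dir``.
Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import decode_session, decoding_frame
from .io import write_lick_events
from .performance import best_window_trials, score_session, session_performance_frame, sessions_to_threshold
from .profiles import bin_edges_for_epoch, group_profile, lick_probability_profile, outcome_conditioned_profiles, profile_frame
from .records import SessionRecord
from .simulate import default_config_sequence, ko_expert_like, ko_nonexpert_like, naive_preset, simulate_cohort, wt_like
from .stats import compare_groups, long_format_dprime

__all__ = ["run_pipeline", "default_demo_config", "PipelineError", "PRESET_REGISTRY"]

logger = logging.getLogger("tpsd")

PRESET_REGISTRY = {
    "WT_like": wt_like,
    "KO_expert_like": ko_expert_like,
    "KO_nonexpert_like": ko_nonexpert_like,
    "naive": naive_preset,
}

STAGE_ORDER = ["simulate", "score", "profiles", "decode", "compare"]
STAGE_DEPS = {
    "score": "simulate",
    "profiles": "score",
    "decode": "score",
    "compare": "score",
}


class PipelineError(RuntimeError):
    """Raised when a stage's dependencies are unmet or a stage fails."""


def default_demo_config() -> dict:
    """Desk-scale demo: 8 WT-like + 8 KO-like mice, 6 sessions, 200 bootstrap
    replicates per decoding bin on the learned session."""
    return {
        "stages": ["simulate", "score", "profiles", "decode", "compare"],
        "cohort": {
            "groups": {"WT_like": 8, "KO_expert_like": 5, "KO_nonexpert_like": 3},
            "n_sessions": 6,
            "preferred_fraction": 0.7,
        },
        "profiles": {"sessions": [1, 6], "epoch": [0.0, 3.0], "bin_width": 0.1},
        "decode": {"session": 6, "n_boot": 200, "epoch": [0.5, 2.0], "bin_width": 0.067},
        "compare": {"threshold": 1.0},
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def _by_mouse(sessions: list[SessionRecord], session_number: int) -> list[SessionRecord]:
    return [s for s in sessions if s.session == session_number]


def _profiles_stage(sessions, params, out_dir, outputs):
    frames = []
    epoch = tuple(params.get("epoch", (0.0, 3.0)))
    width = float(params.get("bin_width", 0.1))
    edges = bin_edges_for_epoch(epoch, width)
    for sess_no in params.get("sessions", [1]):
        ensemble = _by_mouse(sessions, sess_no)
        for genotype in sorted({s.genotype for s in ensemble}):
            group = [s for s in ensemble if s.genotype == genotype]
            for stype in ("preferred", "nonpreferred"):
                vectors = []
                for s in group:
                    trials = best_window_trials(s.trials) if len(
                        {t.stimulus_type for t in s.trials}) == 2 else s.trials
                    subset = [t for t in trials if t.stimulus_type == stype]
                    if subset:
                        vectors.append(lick_probability_profile(subset, width, epoch))
                if len(vectors) < 2:
                    continue
                series = group_profile(vectors, edges, stratum=f"{genotype}:{stype}")
                df = profile_frame(series)
                df.insert(0, "session", sess_no)
                frames.append(df)
    out = out_dir / "profiles.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False, float_format="%.6f")
    outputs["profiles"] = [out.name]

    # Outcome-conditioned profiles (FA vs CR) on the last profiled session.
    last = params.get("sessions", [1])[-1]
    frames = []
    for genotype in sorted({s.genotype for s in sessions}):
        ensemble = [s for s in _by_mouse(sessions, last) if s.genotype == genotype]
        if len(ensemble) < 2:
            continue
        per_outcome = outcome_conditioned_profiles(
            ensemble, ("FA", "CR"), bin_width=width, epoch=epoch
        )
        for outcome, series in per_outcome.items():
            df = profile_frame(series)
            df.insert(0, "session", last)
            df["stratum"] = f"{genotype}:{outcome}"
            frames.append(df)
    if frames:
        out = out_dir / "profiles_by_outcome.csv"
        pd.concat(frames, ignore_index=True).to_csv(out, index=False, float_format="%.6f")
        outputs["profiles"].append(out.name)


def _compare_stage(performance: pd.DataFrame, params, out_dir, outputs):
    threshold = float(params.get("threshold", 1.0))
    rows = []
    perf = performance.sort_values(["mouse_id", "session"])
    is_wt = perf["genotype"].str.startswith("WT")
    n_sessions = int(perf["session"].max())

    def to_threshold(group: pd.DataFrame) -> float:
        # Full-session d' for threshold crossing: the best-window maximum has
        # a selection bias (~+0.4 at naive performance) that makes first
        # crossings of d' = 1 noise-dominated.
        s = sessions_to_threshold(list(group["d_prime_full"]), threshold)
        return float(s) if s is not None else float(n_sessions + 1)  # censored

    wt_days = perf[is_wt].groupby("mouse_id").apply(to_threshold, include_groups=False)
    ko_days = perf[~is_wt].groupby("mouse_id").apply(to_threshold, include_groups=False)
    if len(wt_days) >= 3 and len(ko_days) >= 3:
        res = compare_groups(wt_days.to_numpy(), ko_days.to_numpy())
        rows.append(("sessions_to_dprime_gt_1", res.test_name, res.statistic,
                     res.p_value, res.alpha_effective, res.stars,
                     wt_days.mean(), ko_days.mean()))
    final = perf[perf["session"] == n_sessions]
    for metric in ("fa_rate", "hit_rate", "d_prime_best"):
        a = final.loc[is_wt, metric].to_numpy()
        b = final.loc[~is_wt, metric].to_numpy()
        if len(a) >= 3 and len(b) >= 3:
            res = compare_groups(a, b)
            rows.append((f"final_session_{metric}", res.test_name, res.statistic,
                         res.p_value, res.alpha_effective, res.stars, a.mean(), b.mean()))
    out = out_dir / "comparisons.csv"
    pd.DataFrame(
        rows,
        columns=["comparison", "test", "statistic", "p_value", "alpha_effective",
                 "stars", "mean_wt", "mean_ko"],
    ).to_csv(out, index=False, float_format="%.6g")
    outputs["compare"] = [out.name]


def run_pipeline(config, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Raises :class:`PipelineError` if a requested stage's dependency is not
    also requested (e.g. ``decode`` without ``score``).
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        dep = STAGE_DEPS.get(stage)
        if dep is not None and dep not in stages:
            raise PipelineError(f"stage '{stage}' requires stage '{dep}'")
    stages = [s for s in STAGE_ORDER if s in stages]

    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, list[str]] = {}
    t0 = time.time()
    try:
        sessions = None
        performance = None
        if "simulate" in stages:
            logger.info("stage simulate")
            cc = cfg.get("cohort", {})
            groups = cc.get("groups", {"WT_like": 8, "KO_expert_like": 5,
                                       "KO_nonexpert_like": 3})
            presets = {}
            for label, n in groups.items():
                if label not in PRESET_REGISTRY:
                    raise PipelineError(f"unknown preset '{label}'")
                presets[label] = (PRESET_REGISTRY[label](), int(n))
            config_sequence = default_config_sequence(
                int(cc.get("n_sessions", 6)),
                preferred_fraction=float(cc.get("preferred_fraction", 0.7)),
            )
            sessions = simulate_cohort(
                presets, config_sequence=config_sequence, master_seed=seed
            )
            write_lick_events(sessions, out_dir / "events.tsv", out_dir / "trials.tsv")
            sidecar = {
                "master_seed": seed,
                "groups": groups,
                "n_sessions": len(config_sequence),
                "presets": {k: {f: getattr(p, f) for f in (
                    "p_hit_initial", "p_hit_final", "hit_curve_tau",
                    "p_fa_initial", "p_fa_final", "fa_curve_midpoint", "fa_curve_scale",
                    "lick_rate", "lick_isi_shape", "baseline_lick_rate")}
                    for k, (p, _) in presets.items()},
            }
            (out_dir / "simulation.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
            outputs["simulate"] = ["events.tsv", "trials.tsv", "simulation.json"]

        if "score" in stages:
            logger.info("stage score")
            for s in sessions:
                score_session(s)
            performance = session_performance_frame(sessions)
            performance.to_csv(out_dir / "performance.csv", index=False, float_format="%.6f")
            long_format_dprime(performance).to_csv(
                out_dir / "d_prime_long.csv", index=False, float_format="%.6f")
            outputs["score"] = ["performance.csv", "d_prime_long.csv"]

        if "profiles" in stages:
            logger.info("stage profiles")
            _profiles_stage(sessions, cfg.get("profiles", {}), out_dir, outputs)

        if "decode" in stages:
            logger.info("stage decode")
            dc = cfg.get("decode", {})
            ensemble = _by_mouse(sessions, int(dc.get("session", 1)))
            result = decode_session(
                ensemble,
                outcome_variable=dc.get("outcome_variable", "stimulus_type"),
                bin_width=float(dc.get("bin_width", 0.067)),
                epoch=tuple(dc.get("epoch", (0.0, 3.0))),
                n_boot=int(dc.get("n_boot", 200)),
                seed=seed + 1,
            )
            decoding_frame(result).to_csv(
                out_dir / "decoding.csv", index=False, float_format="%.6f")
            outputs["decode"] = ["decoding.csv"]

        if "compare" in stages:
            logger.info("stage compare")
            _compare_stage(performance, cfg.get("compare", {}), out_dir, outputs)

        manifest = {
            "tpsd_version": __version__,
            "seed": seed,
            "config": cfg,
            "stages": stages,
            "outputs": outputs,
            "elapsed_s": round(time.time() - t0, 3),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete in %.1f s", manifest["elapsed_s"])
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # stage failure: log traceback, re-raise wrapped
        logger.exception("stage failure")
        raise PipelineError(str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
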