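"""Config-driven orchestration of the analysis stages.

Stages run in the analysis-plan order: prepare -> descriptives -> screening ->
subgroup search + resampling -> cut-off scan + secondary endpoints -> decision
summary.  Every artifact is written into the run directory with stage
provenance; a single ``run_report.json`` indexes all outputs.  A single master
seed drives every stochastic stage through deterministically derived
sub-seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    BIOMARKERS,
    TrialDataset,
    exclusion_log,
    load_trial,
    prepare_analysis_set,
    save_trial,
    summarize_baseline,
    covariate_associations,
)
from .refine import cutoff_scan, decision_summary, mmrm_endpoint
from .resample import bootstrap_cutoffs, permutation_null
from .screen import forest_frame, interaction_tests, subgroup_forest
from .sides import SidesParams, evaluate_subgroup, sides_run
from .simulate import scenario_library, simulate_trial

log = logging.getLogger("nbsides")

STAGES = ["prepare", "descriptives", "screening", "sides", "resampling",
          "refinement", "decision"]

DEFAULT_CONFIG = {
    "scenario": "feno_threshold",
    "participants": None,  # CSV path; overrides scenario
    "visits": None,
    "seed": 0,
    "outlier_rules": [],
    "sides": {},  # SidesParams overrides
    "bootstrap_B": 50,  # reduced-scale default; production profile uses 500
    "permutation_P": 50,  # reduced-scale default; production profile uses 500
    "scan_halfwidth": 5,  # grid = best cutoff +/- halfwidth, unit steps
    "endpoints": ["fev1_pct_change", "acq6", "aqlq", "symptom_score"],
}


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return cfg


def _subseed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, STAGES.index(stage) if stage in STAGES else 99])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path, artifacts: list, stage: str):
    df.to_csv(path, index=False)
    artifacts.append({"stage": stage, "path": path.name})


def _write_json(obj, path: Path, artifacts: list, stage: str):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
    artifacts.append({"stage": stage, "path": path.name})


def run_pipeline(config: dict | str | Path | None, outdir: str | Path,
                 dry_run: bool = False) -> dict:
    """Execute the full analysis plan; returns the run report dict.

    ``config`` is a YAML path or a dict (see DEFAULT_CONFIG).  With
    ``dry_run`` the config is validated and the stage plan returned without
    executing anything.
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    seed = int(cfg["seed"])
    plan = {
        "stages": STAGES,
        "out_of_scope": {"question_4_safety": "adverse-event tabulations are out of scope"},
        "seed": seed,
        "version": __version__,
        "config": {k: v for k, v in cfg.items() if not isinstance(v, (pd.DataFrame,))},
    }
    if dry_run:
        _validate_config(cfg)
        plan["dry_run"] = True
        return plan

    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[dict] = []
    timings: dict[str, float] = {}
    report = dict(plan)

    def stage_timer(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                timings[name] = round(time.time() - self.t0, 3)
                log.info("stage %s finished in %.1fs", name, timings[name])

        return _T()

    try:
        # ------------------------------------------------- prepare
        with stage_timer("prepare"):
            data, truth = _obtain_data(cfg, seed)
            if truth is not None:
                _write_json(
                    {k: v for k, v in truth.items() if k != "config"}
                    | {"scenario": cfg.get("scenario")},
                    outdir / "truth.json", artifacts, "prepare",
                )
            prepared = prepare_analysis_set(
                data, pool_placebo=True,
                outlier_rules=[tuple(r) for r in cfg["outlier_rules"]],
            )
            save_trial(prepared, outdir / "participants.csv",
                       outdir / "visits.csv" if not prepared.visits.empty else None)
            artifacts.append({"stage": "prepare", "path": "participants.csv"})
            if not prepared.visits.empty:
                artifacts.append({"stage": "prepare", "path": "visits.csv"})
            _write_csv(exclusion_log(prepared), outdir / "exclusions.csv",
                       artifacts, "prepare")

        # ------------------------------------------------- descriptives (Q1)
        with stage_timer("descriptives"):
            _write_csv(summarize_baseline(prepared), outdir / "baseline_summary.csv",
                       artifacts, "descriptives")
            assoc = covariate_associations(
                prepared, ["region", "age_group", "prior_exac_cat"]
            )
            _write_csv(assoc, outdir / "covariate_associations.csv",
                       artifacts, "descriptives")

        # ------------------------------------------------- screening (Q1)
        with stage_timer("screening"):
            tests = interaction_tests(prepared)
            _write_csv(tests, outdir / "interaction_tests.csv", artifacts, "screening")
            forests = []
            for bm in BIOMARKERS:
                for mode in ("quartile", "cumulative"):
                    f = forest_frame(subgroup_forest(prepared, bm, mode))
                    f.insert(0, "mode", mode)
                    f.insert(0, "biomarker", bm)
                    forests.append(f)
            _write_csv(pd.concat(forests, ignore_index=True),
                       outdir / "subgroup_forests.csv", artifacts, "screening")

        # ------------------------------------------------- SIDES (Q2)
        with stage_timer("sides"):
            params = SidesParams(**cfg.get("sides", {}))
            result = sides_run(prepared, params)
            _write_csv(result.trace, outdir / "sides_trace.csv", artifacts, "sides")
            _write_csv(result.summary(), outdir / "sides_subgroups.csv",
                       artifacts, "sides")
            eval_rows = []
            for bm, cand in result.best_per_biomarker.items():
                inside, outside = evaluate_subgroup(prepared, cand.subgroup)
                for eff in (inside, outside):
                    eval_rows.append(
                        {"biomarker": bm, "label": eff.label,
                         "rate_ratio": eff.rate_ratio, "ci_low": eff.ci_low,
                         "ci_high": eff.ci_high, "p_value": eff.p_value,
                         "reduction_pct": eff.reduction_pct,
                         "n_treated": eff.n_treated, "n_control": eff.n_control,
                         "estimable": eff.estimable}
                    )
            _write_csv(pd.DataFrame(eval_rows), outdir / "sides_evaluation.csv",
                       artifacts, "sides")

        # ------------------------------------------------- resampling (Q2)
        with stage_timer("resampling"):
            boot = bootstrap_cutoffs(prepared, params, B=int(cfg["bootstrap_B"]),
                                     seed=_subseed(seed, "resampling"))
            _write_csv(boot.summary(), outdir / "bootstrap_summary.csv",
                       artifacts, "resampling")
            _write_csv(boot.draws_frame(), outdir / "bootstrap_draws.csv",
                       artifacts, "resampling")
            perm = permutation_null(prepared, params, P=int(cfg["permutation_P"]),
                                    seed=_subseed(seed, "refinement"),
                                    observed=result)
            _write_json(perm.summary(), outdir / "permutation_null.json",
                        artifacts, "resampling")
            _write_csv(pd.DataFrame({"draw": np.arange(perm.P),
                                     "best_reduction_pct": perm.null_reductions}),
                       outdir / "permutation_draws.csv", artifacts, "resampling")

        # ------------------------------------------------- refinement (Q3)
        with stage_timer("refinement"):
            best = result.best()
            scan_df = pd.DataFrame()
            secondary: dict[str, list] = {}
            if best is not None:
                c0 = best.subgroup.cutoff
                hw = int(cfg["scan_halfwidth"])
                grid = [round(c0) + d for d in range(-hw, hw + 1)]
                grid = [g for g in grid if g > 0]
                scan_df = cutoff_scan(prepared, best.subgroup.biomarker, grid)
                _write_csv(scan_df, outdir / "cutoff_scan.csv", artifacts, "refinement")
                if not prepared.visits.empty:
                    mm_rows = []
                    for bm, cand in result.best_per_biomarker.items():
                        secondary[bm] = []
                        for ep in cfg["endpoints"]:
                            try:
                                inside, outside = mmrm_endpoint(
                                    prepared, ep, cand.subgroup
                                )
                            except ValueError:
                                continue
                            secondary[bm].append(inside)
                            mm_rows.extend([inside.to_dict(), outside.to_dict()])
                    _write_json(mm_rows, outdir / "secondary_endpoints.json",
                                artifacts, "refinement")

        # ------------------------------------------------- decision summary
        with stage_timer("decision"):
            cands = []
            tests_idx = tests.set_index("biomarker")["q2w_p"]
            for bm, cand in result.best_per_biomarker.items():
                inside, _ = evaluate_subgroup(prepared, cand.subgroup)
                q4w_inside, _ = evaluate_subgroup(prepared, cand.subgroup, arm="q4w")
                denom = int(prepared.participants[bm].notna().sum())
                members = int(cand.subgroup.mask(prepared.participants).sum())
                cands.append(
                    {"subgroup": cand.subgroup, "n": members, "N": denom,
                     "effect": inside,
                     "interaction_p": float(tests_idx.get(bm, np.nan)),
                     "secondary": secondary.get(bm),
                     "q4w_effect": q4w_inside}
                )
            summary = decision_summary(cands) if cands else pd.DataFrame()
            _write_csv(summary, outdir / "decision_summary.csv", artifacts, "decision")
    except Exception as exc:
        report.update({"status": "failed", "failed_stage": _last_stage(timings),
                       "error": repr(exc), "artifacts": artifacts,
                       "timings_s": timings})
        _write_json(report, outdir / "run_report.json", artifacts, "report")
        raise

    report.update({"status": "ok", "artifacts": artifacts, "timings_s": timings})
    _write_json(report, outdir / "run_report.json", artifacts, "report")
    return report


def _last_stage(timings: dict) -> str:
    done = set(timings)
    for s in STAGES:
        if s not in done:
            return s
    return STAGES[-1]


def _validate_config(cfg: dict) -> None:
    if cfg.get("participants") is None:
        name = cfg.get("scenario")
        if name not in scenario_library():
            raise ValueError(f"unknown scenario {name!r} and no data path given")
    SidesParams(**cfg.get("sides", {}))  # raises on bad values


def _obtain_data(cfg: dict, seed: int) -> tuple[TrialDataset, dict | None]:
    if cfg.get("participants"):
        return load_trial(cfg["participants"], cfg.get("visits")), None
    name = cfg.get("scenario")
    lib = scenario_library()
    if name not in lib:
        raise ValueError(f"unknown scenario {name!r}")
    scenario = lib[name]
    data, truth = simulate_trial(scenario, seed=_subseed(seed, "prepare"))
    slim_truth = {
        "true_cutoff": truth["true_cutoff"],
        "n_in_subgroup": int(np.sum(truth["in_subgroup"])),
        "scenario_config": {
            k: v for k, v in dataclasses.asdict(scenario).items()
            if k not in ("endpoints",)
        },
    }
    return data, slim_truth
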