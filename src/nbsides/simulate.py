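"""Synthetic biomarker-stratified exacerbation trials.

The generator emulates a 52-week, four-arm severe-asthma trial: 2:1:2:1
allocation to active/placebo at two dosing intervals, five right-skewed
correlated baseline biomarkers calibrated to published marginal summaries,
negative-binomial exacerbation counts with a log follow-up offset, an optional
threshold-type treatment-by-biomarker interaction (the planted "biomarker-
positive" subgroup), and visit-indexed secondary endpoints with
compound-symmetric within-subject correlation.

Biomarker marginals use a log-normal family moment-matched to a target
(median, mean) pair: ``mu = ln(median)``, ``sigma^2 = 2 ln(mean/median)``.
Cross-biomarker dependence is a Gaussian copula on the log scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset

ARM_ORDER = ["tralo_q2w", "placebo_q2w", "tralo_q4w", "placebo_q4w"]

#: (median, mean) calibration targets on the native scale.
DEFAULT_MARGINALS = {
    "feno_ppb": (20.3, 30.0),
    "periostin_ng_ml": (23.0, 26.0),
    "eos_cells_ul": (200.0, 290.0),
    "dpp4_ng_ml": (250.0, 264.0),
    "ige_iu_ml": (150.0, 430.0),
}

DEFAULT_REGION_PROBS = {
    "north_america": 0.30,
    "europe": 0.35,
    "asia_pacific": 0.20,
    "rest_of_world": 0.15,
}

DEFAULT_VISIT_WEEKS = (4, 12, 24, 36, 52)


@dataclass
class EndpointConfig:
    """Generative model for one visit-indexed secondary endpoint.

    The treatment effect is at steady state from the first post-baseline
    visit: every visit of a treated participant is shifted by
    ``effect_week52`` (plus ``subgroup_bonus`` for members of the planted
    subgroup), so the week-52 value equals the constant effect.  Values are
    subject intercept (between-subject SD) + visit mean + effect + residual
    (within-subject SD), giving a compound-symmetric covariance.
    """

    baseline_mean: float
    baseline_sd: float
    effect_week52: float
    subgroup_bonus: float = 0.0
    visit_means: tuple[float, ...] | None = None  # placebo drift per visit
    between_sd: float = 1.0
    within_sd: float = 1.0


def default_endpoints() -> dict[str, EndpointConfig]:
    # Scales follow the instruments: FEV1 % change spans tens of percent;
    # ACQ-6/AQLQ/symptom scores live on ~0-6 ranges with MCID ~0.5.
    return {
        "fev1_pct_change": EndpointConfig(
            baseline_mean=60.0, baseline_sd=13.0, effect_week52=4.0,
            between_sd=12.0, within_sd=10.0,
        ),
        "acq6": EndpointConfig(
            baseline_mean=2.7, baseline_sd=0.8, effect_week52=-0.10,
            between_sd=0.7, within_sd=0.5,
        ),
        "aqlq": EndpointConfig(
            baseline_mean=4.0, baseline_sd=1.0, effect_week52=0.10,
            between_sd=0.8, within_sd=0.6,
        ),
        "symptom_score": EndpointConfig(
            baseline_mean=2.0, baseline_sd=0.9, effect_week52=-0.05,
            between_sd=0.7, within_sd=0.6,
        ),
    }


@dataclass
class ScenarioConfig:
    """Complete generative truth for one simulated trial."""

    name: str = "custom"
    n_total: int = 1207
    allocation_ratio: tuple[int, int, int, int] = (2, 1, 2, 1)  # ARM_ORDER
    placebo_aaer: float = 0.80  # events / participant-year
    all_comers_rr: float = 1.0  # active Q2W vs placebo rate ratio
    q4w_rr: float | None = None  # defaults to all_comers_rr
    dispersion_k: float = 1.0  # NB2: var = mu + k mu^2; 0 = Poisson
    biomarker_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    biomarker_corr: np.ndarray | None = None  # log-scale; default block 0.3
    prognostic_coefs: dict[str, float] = field(default_factory=dict)
    # (biomarker, cutoff quantile in (0,1), extra rate ratio for treated members)
    interaction: tuple[str, float, float] | None = None
    # (biomarker, slope): treated log-rate gains slope * standardized log-biomarker
    smooth_interaction: tuple[str, float] | None = None
    region_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROBS)
    )
    region_shift: tuple[str, str, float] | None = None  # (biomarker, region, multiplier)
    adolescent_prob: float = 0.05
    prior_exac_probs: tuple[float, float, float] = (0.55, 0.25, 0.20)  # 1 / 2 / >=3
    dropout_by_week52: float = 0.10
    visit_weeks: tuple[int, ...] = DEFAULT_VISIT_WEEKS
    endpoints: dict[str, EndpointConfig] = field(default_factory=default_endpoints)
    endpoint_subgroup_bonus: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 1 for a in self.allocation_ratio):
            raise ValueError("allocation_ratio entries must be >= 1")
        if self.interaction is not None and self.interaction[2] <= 0:
            raise ValueError("subgroup rate ratio must be positive")
        if self.q4w_rr is None:
            self.q4w_rr = self.all_comers_rr
        for bm, (med, mean) in self.biomarker_marginals.items():
            if mean < med * (1 + 1e-9):
                raise ValueError(
                    f"infeasible log-normal moments for {bm}: mean {mean} <= median {med}"
                )

    def corr_matrix(self) -> np.ndarray:
        names = list(self.biomarker_marginals)
        if self.biomarker_corr is not None:
            corr = np.asarray(self.biomarker_corr, dtype=float)
        else:
            corr = np.eye(len(names))
            trio = [n for n in ("feno_ppb", "periostin_ng_ml", "eos_cells_ul") if n in names]
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    if i != j and a in trio and b in trio:
                        corr[i, j] = 0.3
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError("biomarker correlation matrix is not positive semi-definite")
        return corr


def lognormal_params(median: float, mean: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching a (median, mean) pair."""
    mu = np.log(median)
    sigma = float(np.sqrt(2.0 * np.log(mean / median)))
    return mu, sigma


def allocate_arms(n_total: int, ratio: tuple[int, int, int, int]) -> list[int]:
    """Largest-remainder apportionment of n_total over the four arms.

    Ties in the remainders go to the earlier arm in ARM_ORDER.
    """
    w = np.asarray(ratio, dtype=float)
    quota = n_total * w / w.sum()
    sizes = np.floor(quota).astype(int)
    rem = quota - sizes
    short = n_total - sizes.sum()
    for idx in np.argsort(-rem, kind="stable")[:short]:
        sizes[idx] += 1
    return sizes.tolist()


def simulate_trial(config: ScenarioConfig, seed: int | None = None) -> tuple[TrialDataset, dict]:
    """Draw one trial; returns the dataset plus a truth record.

    The truth record stores every generative parameter, the true subgroup
    cut-off (native scale), per-participant true membership and expected event
    rates, sufficient to recompute each participant's expected count exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_total

    sizes = allocate_arms(n, config.allocation_ratio)
    arm = np.repeat(ARM_ORDER, sizes)
    rng.shuffle(arm)

    names = list(config.biomarker_marginals)
    corr = config.corr_matrix()
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ L.T
    logb = np.empty_like(z)
    params = {}
    for j, bm in enumerate(names):
        mu, sigma = lognormal_params(*config.biomarker_marginals[bm])
        params[bm] = (mu, sigma)
        logb[:, j] = mu + sigma * z[:, j]

    regions = list(config.region_probs)
    rp = np.array([config.region_probs[r] for r in regions], dtype=float)
    region = rng.choice(regions, size=n, p=rp / rp.sum())

    if config.region_shift is not None:
        bm, reg, mult = config.region_shift
        j = names.index(bm)
        logb[region == reg, j] += np.log(mult)

    biomarkers = np.exp(logb)

    adolescent = rng.random(n) < config.adolescent_prob
    age = np.where(
        adolescent,
        rng.uniform(12.0, 18.0, size=n),
        rng.uniform(18.0, 75.0, size=n),
    ).round(1)

    pe = np.asarray(config.prior_exac_probs, dtype=float)
    prior = rng.choice([1, 2, 3], size=n, p=pe / pe.sum())
    prior = np.where(prior == 3, 3 + rng.poisson(0.6, size=n), prior)

    # follow-up: exponential dropout truncated at 1 year
    if config.dropout_by_week52 > 0:
        haz = -np.log1p(-config.dropout_by_week52)
        t_drop = rng.exponential(1.0 / haz, size=n)
    else:
        t_drop = np.full(n, np.inf)
    followup = np.minimum(1.0, t_drop)
    followup = np.maximum(followup, 1.0 / 52.0)  # at least one week on study

    treated = np.isin(arm, ["tralo_q2w", "tralo_q4w"])
    log_rate = np.full(n, np.log(config.placebo_aaer))
    # prognostic terms act on standardized log biomarkers (mean-zero by construction)
    for bm, beta in config.prognostic_coefs.items():
        j = names.index(bm)
        mu, sigma = params[bm]
        log_rate += beta * (logb[:, j] - mu) / sigma
    log_rate += np.where(arm == "tralo_q2w", np.log(config.all_comers_rr), 0.0)
    log_rate += np.where(arm == "tralo_q4w", np.log(config.q4w_rr), 0.0)

    if config.smooth_interaction is not None:
        bm, slope = config.smooth_interaction
        j = names.index(bm)
        mu, sigma = params[bm]
        log_rate += np.where(treated, slope * (logb[:, j] - mu) / sigma, 0.0)

    in_subgroup = np.zeros(n, dtype=bool)
    true_cutoff = None
    if config.interaction is not None:
        bm, q, sub_rr = config.interaction
        mu, sigma = params[bm]
        from scipy.stats import norm

        true_cutoff = float(np.exp(mu + sigma * norm.ppf(q)))
        in_subgroup = biomarkers[:, names.index(bm)] > true_cutoff
        log_rate += np.where(treated & in_subgroup, np.log(sub_rr), 0.0)

    mean_count = np.exp(log_rate) * followup
    if config.dispersion_k > 0:
        frailty = rng.gamma(1.0 / config.dispersion_k, config.dispersion_k, size=n)
        counts = rng.poisson(mean_count * frailty)
    else:
        counts = rng.poisson(mean_count)

    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "arm": arm,
            "region": region,
            "age_years": age,
            "prior_exacerbations": prior.astype(int),
            "exacerbation_count": counts.astype(int),
            "followup_years": followup,
        }
    )
    for j, bm in enumerate(names):
        participants[bm] = biomarkers[:, j]

    visits, baselines = _simulate_endpoints(config, rng, participants, treated, in_subgroup)
    for col, vals in baselines.items():
        participants[col] = vals

    data = TrialDataset(
        participants,
        visits,
        {"analysis_set": "simulated", "placebo_pooled": False, "scenario": config.name},
    )
    truth = {
        "config": dataclasses.asdict(config),
        "lognormal_params": {bm: params[bm] for bm in names},
        "true_cutoff": true_cutoff,
        "in_subgroup": in_subgroup,
        "expected_rate": np.exp(log_rate),
        "expected_count": mean_count,
    }
    return data, truth


def _simulate_endpoints(config, rng, participants, treated, in_subgroup):
    n = len(participants)
    weeks = np.asarray(config.visit_weeks)
    frac = weeks / 52.0
    rows = {"participant_id": [], "endpoint": [], "week": [], "value": []}
    baselines = {}
    col_for = {
        "acq6": "baseline_acq6",
        "aqlq": "baseline_aqlq",
        "symptom_score": "baseline_symptom",
        "fev1_pct_change": "baseline_fev1",
    }
    followup = participants["followup_years"].to_numpy()
    ids = participants["participant_id"].to_numpy()
    for ep, cfg in config.endpoints.items():
        base = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(n)
        baselines[col_for[ep]] = base.round(3)
        subj = cfg.between_sd * rng.standard_normal(n)
        bonus = config.endpoint_subgroup_bonus.get(ep, cfg.subgroup_bonus)
        eff = cfg.effect_week52 + np.where(in_subgroup, bonus, 0.0)
        vmeans = cfg.visit_means or tuple(0.0 for _ in weeks)
        for w, f, vm in zip(weeks, frac, vmeans):
            observed = followup * 52.0 >= w - 1e-9
            val = (
                vm
                + subj
                + np.where(treated, eff, 0.0)
                + cfg.within_sd * rng.standard_normal(n)
            )
            rows["participant_id"].extend(ids[observed])
            rows["endpoint"].extend([ep] * int(observed.sum()))
            rows["week"].extend([int(w)] * int(observed.sum()))
            rows["value"].extend(np.round(val[observed], 4))
    visits = pd.DataFrame(rows)
    return visits, baselines


def scenario_library() -> dict[str, ScenarioConfig]:
    """Named scenarios spanning the pre-read-out simulation axes.

    Varies the placebo rate, the all-comers effect and the biomarker-
    exacerbation relationship: global null, prognostic-only, overall-effect-
    only, a FeNO threshold interaction, a smooth (linear-in-log) interaction,
    and a correlated two-biomarker interaction.
    """
    lib: dict[str, ScenarioConfig] = {}
    lib["global_null"] = ScenarioConfig(name="global_null", all_comers_rr=1.0)
    lib["prognostic_only"] = ScenarioConfig(
        name="prognostic_only",
        all_comers_rr=1.0,
        prognostic_coefs={"feno_ppb": 0.25, "eos_cells_ul": 0.15},
    )
    lib["all_comers_effect"] = ScenarioConfig(
        name="all_comers_effect", all_comers_rr=0.80
    )
    lib["feno_threshold"] = ScenarioConfig(
        name="feno_threshold",
        all_comers_rr=0.90,
        prognostic_coefs={"feno_ppb": 0.20},
        interaction=("feno_ppb", 0.60, 0.55),
    )
    lib["smooth_interaction"] = ScenarioConfig(
        name="smooth_interaction",
        all_comers_rr=0.90,
        prognostic_coefs={"feno_ppb": 0.25},
        smooth_interaction=("feno_ppb", -0.20),
    )
    lib["two_biomarker"] = ScenarioConfig(
        name="two_biomarker",
        all_comers_rr=0.90,
        prognostic_coefs={"feno_ppb": 0.15, "periostin_ng_ml": 0.15},
        interaction=("feno_ppb", 0.60, 0.60),
        region_shift=("periostin_ng_ml", "asia_pacific", 1.3),
    )
    return lib
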