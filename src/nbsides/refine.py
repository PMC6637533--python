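"""Decision layer: cut-off grid scan, secondary-endpoint models, summary table.

After the search proposes a cut-off, :func:`cutoff_scan` walks a grid of
nearby thresholds and refits the covariate-adjusted NB interaction model at
each, giving the at-or-above / below effect pair per cut-off (nominal
p-values, no multiplicity adjustment).  :func:`mmrm_endpoint` checks whether
the subgroup's benefit is consistent on the longitudinal secondary endpoints,
and :func:`decision_summary` assembles the side-by-side comparison of
candidate biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy

from .data import BASELINE_COLUMNS, Subgroup, TrialDataset
from .mmrm import RepeatedMeasuresModel
from .nb import EffectEstimate
from .screen import cumulative_pair

SCAN_COVARS = ("C(region)", "C(age_group)", "C(periostin_group)", "C(prior_exac_cat)")


def cutoff_scan(
    data: TrialDataset,
    biomarker: str,
    grid,
    arm: str = "q2w",
    covars=SCAN_COVARS,
) -> pd.DataFrame:
    """Effect pair (at_or_above / below) for every cut-off in the grid.

    Each cut-off gets one NB model with treatment, region, age group,
    periostin group, prior-exacerbation category and the treatment-by-side
    interaction; the at-or-above side is inclusive (``value >= cutoff``).
    Cut-offs outside the observed range yield a single all-comers side with
    the other flagged non-estimable.
    """
    if len(list(grid)) == 0:
        raise ValueError("cut-off grid is empty")
    if biomarker == "periostin_ng_ml":
        covars = tuple(c for c in covars if "periostin" not in c)
    frame = data.comparison(arm)
    rows = []
    for cut in grid:
        above_eff, below_eff = cumulative_pair(
            frame, biomarker, float(cut), covars=list(covars), inclusive_above=True
        )
        for side, eff in (("at_or_above", above_eff), ("below", below_eff)):
            rows.append(
                {
                    "cutoff": float(cut),
                    "side": side,
                    "n_treated": eff.n_treated,
                    "n_control": eff.n_control,
                    "rate_ratio": eff.rate_ratio,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "p_value": eff.p_value,
                    "reduction_pct": eff.reduction_pct,
                    "estimable": eff.estimable,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MMRMResult:
    """Week-52 treatment effect on one endpoint within one subgroup side."""

    endpoint: str
    side: str  # subgroup label or its complement's label
    n_treated: int
    n_control: int
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    covariance_structure: str
    converged: bool = True

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mmrm_endpoint(
    data: TrialDataset,
    endpoint: str,
    subgroup: Subgroup,
    arm: str = "q2w",
) -> tuple[MMRMResult, MMRMResult]:
    """Repeated-measures Week-52 effect inside and outside the subgroup.

    One model over both sides: treatment + region + age group + periostin
    group + prior exacerbations + visit + treatment*visit +
    treatment*subgroup (plus baseline score for the score endpoints, whose
    response is change from baseline).  Covariance is unstructured for FEV1 %
    change and compound-symmetric for the scores.  The reported effect is the
    treatment difference at the final scheduled visit within each side.
    """
    visits = data.visits[data.visits["endpoint"] == endpoint]
    if visits.empty:
        raise ValueError(f"no visit records for endpoint {endpoint!r}")
    part = data.comparison(arm)
    part = part[part[subgroup.biomarker].notna()].copy()
    part["_bmpos"] = subgroup.mask(part).astype(int)

    long = visits.merge(part, on="participant_id", how="inner")
    baseline_col = BASELINE_COLUMNS.get(endpoint)
    if endpoint == "fev1_pct_change":
        long["_resp"] = long["value"]
        baseline_term = []
    else:
        if baseline_col not in long.columns:
            raise ValueError(f"baseline column {baseline_col!r} absent for {endpoint}")
        long = long[long[baseline_col].notna()]
        long["_resp"] = long["value"] - long[baseline_col]
        baseline_term = [baseline_col]
    long = long[long["_resp"].notna()]

    weeks = sorted(long["week"].unique())
    week_idx = {w: i for i, w in enumerate(weeks)}
    long["_vis"] = long["week"].map(week_idx)
    final_week = weeks[-1]

    rhs = " + ".join(
        baseline_term
        + [
            "treated",
            "C(region)",
            "C(age_group)",
            "C(periostin_group)",
            "C(prior_exac_cat)",
            "C(week)",
            "treated:C(week)",
            "treated:_bmpos",
        ]
    )
    if subgroup.biomarker == "periostin_ng_ml":
        rhs = rhs.replace(" + C(periostin_group)", "")
    X = patsy.dmatrix("1 + " + rhs, long, return_type="dataframe")
    structure = "unstructured" if endpoint == "fev1_pct_change" else "compound_symmetric"
    model = RepeatedMeasuresModel(
        long["_resp"], X, long["participant_id"], long["_vis"], len(weeks),
        covariance=structure,
    )
    fit = model.fit()

    out = []
    week_term = f"treated:C(week)[T.{final_week}]"
    for sub in (subgroup, subgroup.complement()):
        inside = sub.direction == subgroup.direction
        terms = ["treated"]
        if week_term in fit.params.index:
            terms.append(week_term)
        if inside:
            terms.append("treated:_bmpos")
        est, ci, p = fit.contrast_effect(terms)
        side_ids = long.loc[long["_bmpos"] == int(inside), :]
        n_t = side_ids.loc[side_ids["treated"] == 1, "participant_id"].nunique()
        n_c = side_ids.loc[side_ids["treated"] == 0, "participant_id"].nunique()
        out.append(
            MMRMResult(
                endpoint=endpoint,
                side=sub.label,
                n_treated=int(n_t),
                n_control=int(n_c),
                effect=est,
                ci_low=ci[0],
                ci_high=ci[1],
                p_value=p,
                covariance_structure=fit.structure,
                converged=fit.converged,
            )
        )
    return out[0], out[1]


#: endpoints where benefit is a negative change
LOWER_IS_BETTER = {"acq6", "symptom_score"}


def _secondary_significant(res: MMRMResult) -> bool:
    if not np.isfinite(res.p_value) or res.p_value >= 0.05:
        return False
    benefit = res.effect < 0 if res.endpoint in LOWER_IS_BETTER else res.effect > 0
    return bool(benefit)


def decision_summary(candidates: list[dict]) -> pd.DataFrame:
    """Side-by-side comparison of candidate predictive biomarkers.

    Each candidate dict supplies: ``subgroup`` (Subgroup), ``n`` and ``N``
    (prevalence numerator/denominator), ``effect`` (EffectEstimate, Q2W vs
    pooled placebo), ``interaction_p`` (continuous interaction Wald p),
    ``secondary`` (list of MMRMResult for the subgroup side) and optionally
    ``q4w_effect`` (EffectEstimate).  A missing input yields a flagged cell,
    never a silent blank.  Interaction p < 0.10 is flagged nominally
    significant.  A pure function of its inputs.
    """
    rows = []
    for cand in candidates:
        sub: Subgroup = cand["subgroup"]
        row: dict = {"subgroup": sub.label, "biomarker": sub.biomarker}
        if "n" in cand and "N" in cand and cand["N"]:
            row["prevalence_pct"] = 100.0 * cand["n"] / cand["N"]
            row["n"] = cand["n"]
            row["N"] = cand["N"]
        else:
            row["prevalence_pct"], row["n"], row["N"] = np.nan, np.nan, np.nan
            row["flag_prevalence"] = "missing"
        eff: EffectEstimate | None = cand.get("effect")
        if eff is not None and eff.estimable:
            row["reduction_pct"] = eff.reduction_pct
            row["reduction_ci_low"], row["reduction_ci_high"] = eff.reduction_ci
        else:
            row["reduction_pct"] = np.nan
            row["reduction_ci_low"] = row["reduction_ci_high"] = np.nan
            row["flag_effect"] = "missing"
        ip = cand.get("interaction_p")
        if ip is not None and np.isfinite(ip):
            row["interaction_p"] = ip
            row["interaction_nominal_sig"] = bool(ip < 0.10)
        else:
            row["interaction_p"] = np.nan
            row["interaction_nominal_sig"] = False
            row["flag_interaction"] = "missing"
        sec = cand.get("secondary")
        if sec is not None:
            n_sig = sum(_secondary_significant(r) for r in sec)
            row["n_secondary_significant"] = n_sig
            row["secondary_endpoints_enhanced"] = ", ".join(
                r.endpoint for r in sec if _secondary_significant(r)
            ) or "none"
        else:
            row["n_secondary_significant"] = np.nan
            row["secondary_endpoints_enhanced"] = "missing"
            row["flag_secondary"] = "missing"
        q4w: EffectEstimate | None = cand.get("q4w_effect")
        if q4w is not None and q4w.estimable:
            row["q4w_reduction_pct"] = q4w.reduction_pct
            row["q4w_consistent"] = bool(q4w.reduction_pct > 0)
        else:
            row["q4w_reduction_pct"] = np.nan
            row["q4w_consistent"] = False
            row["flag_q4w"] = "missing"
        rows.append(row)
    out = pd.DataFrame(rows)
    # rank: interaction significance, then secondary consistency, then effect
    out = out.sort_values(
        by=["interaction_nominal_sig", "n_secondary_significant", "reduction_pct"],
        ascending=[False, False, False],
        kind="stable",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
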