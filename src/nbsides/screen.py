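"""Continuous-biomarker predictive screening.

Three views of "does the biomarker modify the treatment effect?":

* :func:`interaction_tests` -- per-biomarker Wald tests of the
  treatment-by-biomarker interaction in covariate-adjusted NB models, plus a
  joint 5-df likelihood-ratio test across all biomarkers, per comparison arm.
* :func:`effect_curves` -- predicted annualised rate per arm over a biomarker
  grid, either from the linear interaction model or from a per-arm penalized-
  spline smooth whose per-participant link predictions are displayed through a
  tricube local-linear smoother (span 0.67).
* :func:`subgroup_forest` -- rate-ratio forests within biomarker quartiles or
  above/below cumulative quartile cut-offs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._pspline import (
    bspline_basis,
    fit_penalized_nb,
    second_difference_penalty,
    select_lambda,
)
from .data import BIOMARKERS, TrialDataset
from .nb import (
    EffectEstimate,
    ExacerbationRateModel,
    RankDeficiencyError,
    lr_test,
)

#: baseline covariates of the screening models
BASE_TERMS = ["treated", "C(region)", "age_years", "C(prior_exac_cat)"]


def interaction_tests(
    data: TrialDataset,
    biomarkers=BIOMARKERS,
    arms=("q2w", "q4w"),
    scale: str = "raw",
) -> pd.DataFrame:
    """Interaction-test table: one row per biomarker plus a joint LR-test row.

    For each comparison arm (active vs pooled placebo), each biomarker gets a
    separate NB model ``treated + region + age + prior exacerbations +
    biomarker + treated:biomarker`` and the Wald p of the interaction term.
    The "All" row is a likelihood-ratio test comparing the model with all
    five biomarkers and all five interactions against the model with the
    biomarkers but no interactions.  ``scale="log"`` enters log-biomarker.
    """
    rows = {bm: {} for bm in biomarkers}
    joint = {}
    for arm in arms:
        frame = data.comparison(arm).copy()
        cols = {}
        for bm in biomarkers:
            col = bm
            if scale == "log":
                col = f"log_{bm}"
                frame[col] = np.log(frame[bm].where(frame[bm] > 0))
            cols[bm] = col
        for bm in biomarkers:
            col = cols[bm]
            try:
                fit = ExacerbationRateModel(
                    frame, BASE_TERMS + [col, f"treated:{col}"]
                ).fit()
                rows[bm][arm] = fit.wald_p(f"treated:{col}")
            except RankDeficiencyError:
                rows[bm][arm] = np.nan
        all_cols = [cols[bm] for bm in biomarkers]
        try:
            full = ExacerbationRateModel(
                frame, BASE_TERMS + all_cols + [f"treated:{c}" for c in all_cols]
            ).fit()
            reduced = ExacerbationRateModel(frame, BASE_TERMS + all_cols).fit()
            _, p = lr_test(full, reduced, df=len(biomarkers))
            joint[arm] = p
        except RankDeficiencyError:
            joint[arm] = np.nan

    out = [{"biomarker": "All (likelihood ratio test)",
            **{f"{a}_p": joint.get(a, np.nan) for a in arms}}]
    for bm in biomarkers:
        out.append({"biomarker": bm, **{f"{a}_p": rows[bm].get(a, np.nan) for a in arms}})
    return pd.DataFrame(out)


def _reference_row(frame: pd.DataFrame, exclude=("treated",)) -> dict:
    """Prediction covariates: modal category / median continuous value."""
    ref = {}
    for col in frame.columns:
        if col in exclude:
            continue
        s = frame[col].dropna()
        if s.empty:
            continue
        if pd.api.types.is_numeric_dtype(s):
            ref[col] = float(s.median())
        else:
            ref[col] = s.mode().iloc[0]
    return ref


def effect_curves(
    data: TrialDataset,
    biomarker: str,
    mode: str = "linear",
    arm: str = "q2w",
    n_grid: int = 100,
    min_distinct: int = 10,
    span: float = 0.67,
) -> pd.DataFrame:
    """Predicted annualised rate vs biomarker, per arm.

    Linear mode fits the interaction model and predicts at reference covariate
    levels over a grid spanning the 5th-95th sample quantiles.  GAM mode fits
    a per-arm penalized cubic B-spline of the biomarker (second-difference
    penalty, GCV-selected smoothing), then smooths the per-participant link
    predictions with a tricube local-linear smoother (span 0.67) and
    exponentiates.  Output columns: biomarker_value, arm, predicted_aaer;
    the 10th/90th percentiles are attached as frame attrs.
    """
    frame = data.comparison(arm)
    v = frame[biomarker].dropna()
    if v.nunique() < min_distinct:
        raise ValueError(
            f"{biomarker} has fewer than {min_distinct} distinct values"
        )
    q05, q95 = np.quantile(v, [0.05, 0.95])
    p10, p90 = np.quantile(v, [0.10, 0.90])
    arm_labels = {1: arm, 0: "placebo"}

    if mode == "linear":
        model = ExacerbationRateModel(
            frame, BASE_TERMS + [biomarker, f"treated:{biomarker}"]
        )
        fit = model.fit()
        grid = np.linspace(q05, q95, n_grid)
        ref = _reference_row(model.frame, exclude=("treated", biomarker,
                                                   model.outcome, model.exposure))
        rows = []
        import patsy

        for treated in (0, 1):
            pred_df = pd.DataFrame(
                {**{k: [val] * n_grid for k, val in ref.items()},
                 "treated": treated, biomarker: grid}
            )
            Xp = patsy.build_design_matrices(
                [model.X.design_info], pred_df, return_type="dataframe"
            )[0].to_numpy()
            eta = Xp @ fit.params.to_numpy()  # offset log(1 year) = 0
            rows.append(pd.DataFrame({
                "biomarker_value": grid,
                "arm": arm_labels[treated],
                "predicted_aaer": np.exp(eta),
            }))
        out = pd.concat(rows, ignore_index=True)
    elif mode == "gam":
        model = ExacerbationRateModel(frame[frame[biomarker].notna()], BASE_TERMS)
        base_fit = model.fit()
        k = max(base_fit.k, 1e-6)
        used = frame.loc[model.frame.index]  # same rows, all columns
        x = used[biomarker].to_numpy(dtype=float)
        y = used[model.outcome].to_numpy(dtype=float)
        offset = np.log(used[model.exposure].to_numpy(dtype=float))
        treated = used["treated"].to_numpy()

        n_basis = 10
        B, _ = bspline_basis(x, n_basis=n_basis)
        # parametric part: covariates without intercept collinearity issues
        import patsy

        Xpar = patsy.dmatrix(
            "0 + C(region) + age_years + C(prior_exac_cat)", used,
            return_type="dataframe",
        ).to_numpy()
        # per-arm spline blocks (each contains its own level, so no intercept)
        Bp = B * (treated == 0)[:, None]
        Bt = B * (treated == 1)[:, None]
        X = np.hstack([Xpar - Xpar.mean(axis=0), Bp, Bt])
        P = np.zeros((X.shape[1], X.shape[1]))
        D = second_difference_penalty(n_basis)
        off = Xpar.shape[1]
        P[off:off + n_basis, off:off + n_basis] = D
        P[off + n_basis:, off + n_basis:] = D
        lam = select_lambda(y, X, offset, P, k=k)
        beta, _ = fit_penalized_nb(y, X, offset, P, lam, k=k)
        eta_link = X @ beta  # per-participant link prediction, exposure removed

        rows = []
        for t in (0, 1):
            m = treated == t
            sm_xy = lowess(eta_link[m], x[m], frac=span, return_sorted=True)
            gx, gy = sm_xy[:, 0], sm_xy[:, 1]
            inside = (gx >= q05) & (gx <= q95)
            rows.append(pd.DataFrame({
                "biomarker_value": gx[inside],
                "arm": arm_labels[t],
                "predicted_aaer": np.exp(gy[inside]),
            }))
        out = pd.concat(rows, ignore_index=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out.attrs.update({"p10": float(p10), "p90": float(p90),
                      "q05": float(q05), "q95": float(q95)})
    return out


def quartile_groups(values: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Type-7 quartile assignment; ties go to the lower quartile."""
    qs = np.quantile(values.dropna(), [0.25, 0.5, 0.75])
    def assign(x):
        if pd.isna(x):
            return np.nan
        for i, q in enumerate(qs):
            if x <= q:
                return f"Q{i + 1}"
        return "Q4"
    return values.map(assign), qs


def subgroup_forest(
    data: TrialDataset,
    biomarker: str,
    mode: str = "quartile",
    arm: str = "q2w",
    covars=("C(region)", "age_years", "C(prior_exac_cat)"),
    k: float | None = None,
) -> list[EffectEstimate]:
    """Treatment-effect forest over quartile or cumulative-cut subgroups.

    Quartile mode fits one NB model with a saturated treated-by-quartile
    interaction and reads the within-quartile effects off the coefficients;
    cumulative mode fits, for each quartile cut, a treated-by-(above/below)
    interaction model and reports both sides.  ``k`` fixes the dispersion
    (0 = Poisson); by default it is estimated.
    """
    frame = data.comparison(arm).copy()
    groups, qs = quartile_groups(frame[biomarker])
    covars = list(covars)
    effects: list[EffectEstimate] = []

    if mode == "quartile":
        frame["_qgroup"] = groups
        model = ExacerbationRateModel(
            frame, ["treated", "C(_qgroup)", "treated:C(_qgroup)"] + covars
        )
        fit = model.fit(k=k)
        for i, q in enumerate(["Q1", "Q2", "Q3", "Q4"]):
            sub = model.frame[model.frame["_qgroup"] == q]
            n_t = int((sub["treated"] == 1).sum())
            n_c = int((sub["treated"] == 0).sum())
            if n_t == 0 or n_c == 0 or sub["exacerbation_count"].sum() == 0:
                effects.append(EffectEstimate.non_estimable(f"{biomarker} {q}", n_t, n_c))
                continue
            extra = [] if i == 0 else [f"treated:C(_qgroup)[T.{q}]"]
            est, se = fit.contrast(["treated"] + extra)
            effects.append(
                EffectEstimate.from_log_rr(est, se, n_t, n_c, label=f"{biomarker} {q}")
            )
    elif mode == "cumulative":
        for q in qs:
            effects.extend(cumulative_pair(frame, biomarker, float(q), covars, k=k))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return effects


def cumulative_pair(frame: pd.DataFrame, biomarker: str, cut: float,
                    covars=("C(region)", "age_years", "C(prior_exac_cat)"),
                    inclusive_above: bool = False,
                    k: float | None = None) -> list[EffectEstimate]:
    """Above/below effect pair at one cut via a treated-by-side interaction.

    With ``inclusive_above`` the 'above' side is ``value >= cut`` (the scan
    convention); otherwise ``value > cut``.  When one side is empty the other
    side's effect is the all-comers covariate-adjusted effect.
    """
    covars = list(covars)
    f = frame[frame[biomarker].notna()].copy()
    above = f[biomarker] >= cut if inclusive_above else f[biomarker] > cut
    f["_above"] = above.astype(int)
    ops = (">=", "<") if inclusive_above else (">", "<=")
    labels = [f"{biomarker} {ops[0]} {cut:g}", f"{biomarker} {ops[1]} {cut:g}"]
    sides = [f[f["_above"] == 1], f[f["_above"] == 0]]
    ns = [(int((s["treated"] == 1).sum()), int((s["treated"] == 0).sum())) for s in sides]

    if len(sides[0]) == 0 or len(sides[1]) == 0:
        # degenerate cut: single side = all-comers model
        full_idx = 0 if len(sides[0]) else 1
        fit = ExacerbationRateModel(f, ["treated"] + covars).fit(k=k)
        out = [None, None]
        out[full_idx] = fit.effect("treated", label=labels[full_idx])
        other = 1 - full_idx
        out[other] = EffectEstimate.non_estimable(labels[other], *ns[other])
        return out

    fit = ExacerbationRateModel(
        f, ["treated", "_above", "treated:_above"] + covars
    ).fit(k=k)
    est_b, se_b = fit.contrast(["treated"])
    est_a, se_a = fit.contrast(["treated", "treated:_above"])
    out = []
    for label, (est, se), (n_t, n_c), side in zip(
        labels, [(est_a, se_a), (est_b, se_b)], ns, sides
    ):
        if n_t == 0 or n_c == 0 or side["exacerbation_count"].sum() == 0:
            out.append(EffectEstimate.non_estimable(label, n_t, n_c))
        else:
            out.append(EffectEstimate.from_log_rr(est, se, n_t, n_c, label=label))
    return out


def forest_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Forest rows as a table (the CSV export contract)."""
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "n_treated": e.n_treated,
                "n_control": e.n_control,
                "rate_ratio": e.rate_ratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "reduction_pct": e.reduction_pct,
                "p_value": e.p_value,
                "estimable": e.estimable,
            }
            for e in effects
        ]
    )
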