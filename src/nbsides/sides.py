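"""Count-outcome SIDES: recursive subgroup search by differential treatment effect.

The search scans, for each candidate biomarker, cut-offs on a quantile grid
(50 evenly distributed splits by default).  Each cut-off partitions the
participants into two children; a treatment-only negative-binomial rate model
(intercept + treatment + log-follow-up offset) is fitted in each child and the
per-child benefit z statistics feed one of three splitting criteria:

* criterion 1, differential effect: ``p = 2 * (1 - Phi(|z1 - z2| / sqrt(2)))``
* criterion 2, maximum effect: ``p = 2 * min(1 - Phi(z1), 1 - Phi(z2))``
* criterion 3, criterion 1 plus a one-sided benefit requirement on the better
  child (used when a differential effect exists but neither child effect is
  individually significant).

The better child becomes a candidate subgroup if it meets the minimum size
``N_min`` and the minimum prevalence (default 30% of the participants with a
non-missing value of that biomarker).  With search depth ``L > 1`` the top
``M`` candidates recurse, children being pursued only when their treatment-
effect p-value improves on the parent's by the continuation factor ``gamma``.
Identified subgroups are then re-evaluated with the covariate-adjusted model
used for confirmatory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import BIOMARKERS, Subgroup, TrialDataset
from .nb import (
    EffectEstimate,
    ExacerbationRateModel,
    TwoGroupNBFit,
    fit_nb_two_group,
    norm_sf,
)

#: covariate-adjusted evaluation model terms (matches the confirmatory model)
ADJUSTED_TERMS = ["treated", "C(region)", "age_years", "C(prior_exac_cat)"]


@dataclass
class SidesParams:
    """Search configuration.

    L: max covariates defining a subgroup (search depth); M: best candidates
    carried to the next step; n_min: minimum allowed subgroup size N_min;
    min_prevalence: floor on subgroup prevalence among participants non-missing
    for the biomarker; n_splits: candidate cut-offs per biomarker; criterion:
    splitting criterion id; gamma: continuation multiplier (child kept only if
    its effect p <= gamma * parent's); selection_threshold: minimum clinically
    relevant AAER reduction (%).
    """

    L: int = 1
    M: int = 5
    n_min: int = 60
    min_prevalence: float = 0.30
    n_splits: int = 50
    criterion: int = 1
    gamma: float = 1.0
    selection_threshold: float = 0.0
    search_covariates: tuple[str, ...] | None = None  # default: the 5 biomarkers

    def __post_init__(self) -> None:
        if self.L < 1 or self.M < 1 or self.n_min < 1:
            raise ValueError("L, M and n_min must be >= 1")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.criterion not in (1, 2, 3):
            raise ValueError("criterion must be 1, 2 or 3")

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.search_covariates or tuple(BIOMARKERS)


@dataclass
class SplitScore:
    """Statistics of one candidate split."""

    biomarker: str
    cutoff: float
    z_above: float
    z_below: float
    criterion_p: float
    better_child: str  # "above" | "at_or_below"
    n_above: int
    n_below: int
    fit_above: TwoGroupNBFit | None = None
    fit_below: TwoGroupNBFit | None = None

    @property
    def n_s(self) -> int:
        return self.n_above if self.better_child == "above" else self.n_below

    @property
    def better_fit(self) -> TwoGroupNBFit:
        return self.fit_above if self.better_child == "above" else self.fit_below


def candidate_splits(values: np.ndarray, params: SidesParams) -> list[float]:
    """Cut-offs at the quantiles j/(n_splits+1); deduplicated; splits whose
    children could not both seed an admissible subgroup (both below N_min)
    are removed."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        return []
    qs = np.arange(1, params.n_splits + 1) / (params.n_splits + 1)
    cuts = np.unique(np.quantile(v, qs))
    out = []
    for c in cuts:
        n_below = int((v <= c).sum())
        n_above = v.size - n_below
        if n_below == 0 or n_above == 0:
            continue
        if max(n_below, n_above) < params.n_min:
            continue
        out.append(float(c))
    return out


def criterion_p(z1: float, z2: float, criterion: int) -> float:
    """Splitting-criterion p-value from the two child benefit z statistics."""
    if criterion in (1, 3):
        return float(2.0 * norm_sf(abs(z1 - z2) / np.sqrt(2.0)))
    if criterion == 2:
        return float(2.0 * min(norm_sf(z1), norm_sf(z2)))
    raise ValueError(f"unknown criterion {criterion}")


def split_score(
    frame: pd.DataFrame, biomarker: str, cutoff: float, criterion: int = 1
) -> SplitScore | None:
    """Score one split of a comparison frame (must carry a 0/1 ``treated``).

    Returns None when either child's treatment-only NB fit is degenerate
    (empty arm or no events in an arm); callers log the split as discarded.
    """
    v = frame[biomarker].to_numpy(dtype=float)
    return _split_score_arrays(
        frame["exacerbation_count"].to_numpy(dtype=float),
        frame["treated"].to_numpy(),
        frame["followup_years"].to_numpy(dtype=float),
        v, biomarker, cutoff, criterion,
    )


def _split_score_arrays(y, treated, exposure, values, biomarker, cutoff,
                        criterion) -> SplitScore | None:
    return _batch_split_scores(
        y, treated, exposure, values, [cutoff], biomarker, criterion
    )[0]


def _batch_split_scores(y, treated, exposure, values, cuts, biomarker,
                        criterion) -> list[SplitScore | None]:
    """Score every cut-off of one biomarker in a single vectorized pass.

    All child treatment-only NB fits run simultaneously: a batched Newton
    solve of the per-group rate equations inside a synchronized golden-section
    profile over each child's dispersion.  Numerically equivalent to calling
    :func:`split_score` per cut-off (same MLE, same tolerances).
    """
    from scipy.special import gammaln

    cuts = np.asarray(cuts, dtype=float)
    C = len(cuts)
    ok = np.isfinite(values)
    above = ok[None, :] & (values[None, :] > cuts[:, None])
    below = ok[None, :] & (values[None, :] <= cuts[:, None])
    children = np.vstack([above, below])  # 2C x n; row j=above_j, C+j=below_j
    tmask = np.asarray(treated, dtype=bool)
    GT = children & tmask[None, :]
    GC = children & ~tmask[None, :]
    nT, nC = GT.sum(1), GC.sum(1)
    sT, sC = GT @ y, GC @ y
    eT, eC = GT @ exposure, GC @ exposure
    valid = (nT > 0) & (nC > 0) & (sT > 0) & (sC > 0)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return [None] * C

    K = idx.size
    G = np.vstack([GT[idx], GC[idx]])  # 2K x n (treated rows, then control)
    b = np.log(np.concatenate([sT[idx], sC[idx]]) /
               np.concatenate([eT[idx], eC[idx]]))
    yb = y[None, :]
    tb = exposure[None, :]
    gln_y1 = gammaln(y + 1.0)[None, :]

    def newton(b, kchild):
        kg = np.concatenate([kchild, kchild])[:, None]
        for _ in range(40):
            mu = tb * np.exp(b)[:, None]
            den = 1.0 + kg * mu
            score = np.where(G, (yb - mu) / den, 0.0).sum(1)
            info = np.where(G, mu * (1.0 + kg * yb) / den**2, 0.0).sum(1)
            step = np.clip(score / np.maximum(info, 1e-300), -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-9:
                break
        return b, info

    def child_loglik(b, kchild):
        kg = np.concatenate([kchild, kchild])[:, None]
        inv = 1.0 / kg
        mu = tb * np.exp(b)[:, None]
        ll = (gammaln(yb + inv) - gammaln(inv) - gln_y1
              + yb * np.log(kg * mu) - (yb + inv) * np.log1p(kg * mu))
        llg = np.where(G, ll, 0.0).sum(1)
        return llg[:K] + llg[K:]

    # synchronized golden-section maximisation of each child's profile loglik
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    lo, hi, xtol = np.log(1e-4), np.log(30.0), 0.05
    a = np.full(K, lo)
    bb = np.full(K, hi)
    c = bb - phi * (bb - a)
    d = a + phi * (bb - a)
    b, _ = newton(b, np.exp(c))
    fc = child_loglik(b, np.exp(c))
    b, _ = newton(b, np.exp(d))
    fd = child_loglik(b, np.exp(d))
    n_iter = int(np.ceil(np.log((hi - lo) / xtol) / np.log(1.0 / phi)))
    for _ in range(n_iter):
        left = fc >= fd
        bb = np.where(left, d, bb)
        a = np.where(left, a, c)
        c_new = bb - phi * (bb - a)
        d_new = a + phi * (bb - a)
        probe = np.where(left, c_new, d_new)
        b, _ = newton(b, np.exp(probe))
        fp = child_loglik(b, np.exp(probe))
        # left branch: new c is probed, old c becomes d; right branch: mirror
        fc, fd = np.where(left, fp, fd), np.where(left, fc, fp)
        c, d = c_new, d_new
    khat = np.exp((a + bb) / 2.0)
    b, info = newton(b, khat)
    ll = child_loglik(b, khat)

    bad = (info[:K] <= 0) | (info[K:] <= 0)
    beta = b[:K] - b[K:]
    se = np.sqrt(1.0 / np.maximum(info[:K], 1e-300)
                 + 1.0 / np.maximum(info[K:], 1e-300))
    fits: dict[int, TwoGroupNBFit] = {}
    for pos, row in enumerate(idx):
        if bad[pos]:
            continue
        fits[row] = TwoGroupNBFit(
            beta=float(beta[pos]), se=float(se[pos]), k=float(khat[pos]),
            loglik=float(ll[pos]), converged=True,
            n_treated=int(nT[row]), n_control=int(nC[row]),
        )

    out: list[SplitScore | None] = []
    for j in range(C):
        f_above = fits.get(j)
        f_below = fits.get(C + j)
        if f_above is None or f_below is None:
            out.append(None)
            continue
        z1, z2 = f_above.z_benefit, f_below.z_benefit
        better = "above" if z1 >= z2 else "at_or_below"
        out.append(
            SplitScore(
                biomarker=biomarker,
                cutoff=float(cuts[j]),
                z_above=float(z1),
                z_below=float(z2),
                criterion_p=criterion_p(z1, z2, criterion),
                better_child=better,
                n_above=int(above[j].sum()),
                n_below=int(below[j].sum()),
                fit_above=f_above,
                fit_below=f_below,
            )
        )
    return out


@dataclass
class SidesCandidate:
    """One admissible subgroup found by the search."""

    subgroup: Subgroup
    score: SplitScore
    effect: EffectEstimate  # in-search treatment-only effect in the subgroup
    depth: int
    parent: str = ""  # parent subgroup label; "" at the root

    @property
    def sort_key(self):
        return (self.score.criterion_p, self.score.cutoff, self.subgroup.biomarker)


@dataclass
class SidesResult:
    """Outcome of one SIDES run: per-biomarker best subgroups plus the trace."""

    params: SidesParams
    best_per_biomarker: dict[str, SidesCandidate]
    selected: list[SidesCandidate]
    trace: pd.DataFrame

    def best(self) -> SidesCandidate | None:
        return self.selected[0] if self.selected else None

    def summary(self) -> pd.DataFrame:
        rows = []
        for cand in self.selected:
            sc = cand.score
            rows.append(
                {
                    "subgroup": cand.subgroup.label,
                    "biomarker": cand.subgroup.biomarker,
                    "cutoff": cand.subgroup.cutoff,
                    "direction": cand.subgroup.direction,
                    "n_s": sc.n_s,
                    "criterion_p": sc.criterion_p,
                    "z_above": sc.z_above,
                    "z_below": sc.z_below,
                    "rate_ratio": cand.effect.rate_ratio,
                    "reduction_pct": cand.effect.reduction_pct,
                }
            )
        return pd.DataFrame(rows)


class SidesSearch:
    """Model-style wrapper: construct from a prepared dataset, then ``run()``."""

    def __init__(self, data: TrialDataset, params: SidesParams | None = None,
                 arm: str = "q2w"):
        self.params = params or SidesParams()
        self.arm = arm
        self.frame = data.comparison(arm)
        # prevalence denominators: non-missing count per covariate in the
        # full comparison population
        self._denom = {
            c: int(self.frame[c].notna().sum()) for c in self.params.covariates
        }

    def run(self) -> SidesResult:
        params = self.params
        trace_rows: list[dict] = []
        root_mask = pd.Series(True, index=self.frame.index)
        candidates = self._search_node(self.frame, root_mask, depth=1,
                                       parent_label="", parent_p=None,
                                       trace=trace_rows)
        best_per_bm: dict[str, SidesCandidate] = {}
        for cand in candidates:
            bm = cand.subgroup.biomarker
            if bm not in best_per_bm or cand.sort_key < best_per_bm[bm].sort_key:
                best_per_bm[bm] = cand
        selected = sorted(
            (c for c in candidates if c.effect.reduction_pct >= params.selection_threshold),
            key=lambda c: c.sort_key,
        )
        trace = pd.DataFrame(
            trace_rows,
            columns=["node", "biomarker", "cutoff", "z_above", "z_below",
                     "criterion_p", "n_s", "status"],
        )
        return SidesResult(params, best_per_bm, selected, trace)

    # -- internals ----------------------------------------------------------

    def _search_node(self, frame, mask, depth, parent_label, parent_p, trace):
        params = self.params
        node = frame[mask]
        y = node["exacerbation_count"].to_numpy(dtype=float)
        tr = node["treated"].to_numpy()
        ex = node["followup_years"].to_numpy(dtype=float)
        found: list[SidesCandidate] = []
        node_best: list[SidesCandidate] = []
        for bm in params.covariates:
            values = node[bm].to_numpy(dtype=float)
            cuts = candidate_splits(values, params)
            scores = _batch_split_scores(y, tr, ex, values, cuts, bm,
                                         params.criterion) if cuts else []
            # the pre-specified size/prevalence constraints restrict the
            # admissible cut-off set; the best split per covariate (by
            # criterion p) is then chosen over that set
            best_for_bm: SidesCandidate | None = None
            for c, sc in zip(cuts, scores):
                if sc is None:
                    trace.append(_trace_row(parent_label, bm, c, None, "fit_failed"))
                    continue
                status = "admissible"
                cand = self._admissible(sc, depth, parent_label, parent_p)
                if isinstance(cand, str):
                    status = cand
                    cand = None
                trace.append(_trace_row(parent_label, bm, c, sc, status))
                if cand is not None and (
                    best_for_bm is None or cand.sort_key < best_for_bm.sort_key
                ):
                    best_for_bm = cand
            if best_for_bm is not None:
                node_best.append(best_for_bm)
        node_best.sort(key=lambda c: c.sort_key)
        kept = node_best[: params.M] if depth < params.L else node_best
        found.extend(node_best)
        if depth < params.L:
            for cand in kept:
                child_mask = mask & cand.subgroup.mask(frame)
                found.extend(
                    self._search_node(
                        frame, child_mask, depth + 1,
                        parent_label=_compose_label(parent_label, cand.subgroup.label),
                        parent_p=cand.score.better_fit.p_benefit,
                        trace=trace,
                    )
                )
        return found

    def _admissible(self, sc: SplitScore, depth, parent_label, parent_p):
        """Return a SidesCandidate, or a rejection-reason string."""
        params = self.params
        if sc.n_s < params.n_min:
            return "below_n_min"
        # the pre-specified prevalence floor binds the cut-off itself: either
        # child could be the reported subgroup, so both sides must clear it
        denom = self._denom[sc.biomarker]
        if min(sc.n_above, sc.n_below) / denom < params.min_prevalence:
            return "below_prevalence"
        fit = sc.better_fit
        if params.criterion == 3 and fit.p_benefit > 0.05:
            return "criterion3_no_benefit"
        if parent_p is not None and fit.p_benefit > params.gamma * parent_p:
            return "continuation_failed"
        sub = Subgroup(sc.biomarker, sc.better_child, sc.cutoff, inclusive=False)
        eff = EffectEstimate.from_log_rr(
            fit.beta, fit.se, fit.n_treated, fit.n_control, label=sub.label
        )
        return SidesCandidate(sub, sc, eff, depth, parent_label)


def _trace_row(node, bm, cutoff, sc: SplitScore | None, status):
    return {
        "node": node or "<root>",
        "biomarker": bm,
        "cutoff": float(cutoff),
        "z_above": sc.z_above if sc else np.nan,
        "z_below": sc.z_below if sc else np.nan,
        "criterion_p": sc.criterion_p if sc else np.nan,
        "n_s": sc.n_s if sc else np.nan,
        "status": status,
    }


def _compose_label(parent, label):
    return f"{parent} & {label}" if parent else label


def sides_run(data: TrialDataset, params: SidesParams | None = None,
              arm: str = "q2w") -> SidesResult:
    """Functional entry point: one SIDES search on a prepared dataset."""
    return SidesSearch(data, params, arm).run()


def evaluate_subgroup(
    data: TrialDataset,
    subgroup: Subgroup,
    arm: str = "q2w",
    terms=ADJUSTED_TERMS,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Covariate-adjusted effect inside the subgroup and in its complement.

    Separate NB fits on each membership set with the confirmatory covariate
    model (treatment, region, age, prior exacerbations, offset).  A side
    without both arms (or that is empty) is flagged non-estimable.
    """
    frame = data.comparison(arm)
    out = []
    for sub in (subgroup, subgroup.complement()):
        rows = frame[sub.mask(frame)]
        n_t = int((rows["treated"] == 1).sum())
        n_c = int((rows["treated"] == 0).sum())
        if n_t == 0 or n_c == 0:
            out.append(EffectEstimate.non_estimable(sub.label, n_t, n_c))
            continue
        try:
            fit = ExacerbationRateModel(rows, list(terms)).fit()
            eff = fit.effect("treated", label=sub.label)
            if not fit.converged:
                eff = EffectEstimate.non_estimable(sub.label, n_t, n_c)
        except Exception:
            eff = EffectEstimate.non_estimable(sub.label, n_t, n_c)
        out.append(eff)
    return out[0], out[1]


def sensitivity_reruns(
    data: TrialDataset,
    base: SidesParams,
    variants: dict[str, dict] | None = None,
    arm: str = "q2w",
) -> pd.DataFrame:
    """Re-run the search under parameter modifications; summarise stability.

    ``variants`` maps a variant name to SidesParams field overrides (e.g.
    ``{"no_size_restriction": {"n_min": 1, "min_prevalence": 0.0}}``).  The
    base run is always the first row.
    """
    rows = []
    runs = {"base": {}}
    runs.update(variants or {})
    base_best = None
    for name, delta in runs.items():
        params = replace(base, **delta)
        res = sides_run(data, params, arm)
        best = res.best()
        if name == "base":
            base_best = best
        rows.append(
            {
                "variant": name,
                "biomarker": best.subgroup.biomarker if best else None,
                "cutoff": best.subgroup.cutoff if best else np.nan,
                "direction": best.subgroup.direction if best else None,
                "reduction_pct": best.effect.reduction_pct if best else np.nan,
                "same_biomarker_as_base": (
                    best is not None
                    and base_best is not None
                    and best.subgroup.biomarker == base_best.subgroup.biomarker
                ),
                "cutoff_drift": (
                    best.subgroup.cutoff - base_best.subgroup.cutoff
                    if best is not None and base_best is not None
                    and best.subgroup.biomarker == base_best.subgroup.biomarker
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
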