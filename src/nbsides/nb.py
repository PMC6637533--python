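"""Negative-binomial rate modelling with an exposure offset.

Event counts over unequal follow-up are modelled as NB2 (variance
``mu + k*mu^2``) with a log link and ``log(followup_years)`` offset, so
coefficients are log annualised-rate ratios.  The heavy lifting is done by
statsmodels; this module adds the trial-analysis surface: formula-free model
construction from a participant table, rate-ratio/CI/reduction extraction for
treatment contrasts, nested likelihood-ratio tests, and a specialised fast
exact MLE for the intercept+treatment+offset model used inside subgroup
searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats
import statsmodels.api as sm

Z95 = stats.norm.ppf(0.975)


def norm_sf(x):
    """Standard-normal survival function (fast path via the erf core)."""
    return special.ndtr(-np.asarray(x, dtype=float))


class RankDeficiencyError(ValueError):
    """The design matrix is not full rank; names the aliased columns."""


class TermLookupError(KeyError):
    """A requested contrast term is not in the fitted model."""


@dataclass
class EffectEstimate:
    """A treatment contrast on the rate scale.

    ``reduction_pct = (1 - rate_ratio) * 100`` with the CI mapped to
    ``((1 - ci_high) * 100, (1 - ci_low) * 100)``.
    """

    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_treated: int
    n_control: int
    label: str = ""
    estimable: bool = True

    @property
    def reduction_pct(self) -> float:
        return (1.0 - self.rate_ratio) * 100.0

    @property
    def reduction_ci(self) -> tuple[float, float]:
        return ((1.0 - self.ci_high) * 100.0, (1.0 - self.ci_low) * 100.0)

    @classmethod
    def non_estimable(cls, label: str = "", n_treated: int = 0, n_control: int = 0):
        return cls(np.nan, np.nan, np.nan, np.nan, n_treated, n_control, label, False)

    @classmethod
    def from_log_rr(cls, log_rr: float, se: float, n_treated: int, n_control: int,
                    label: str = "") -> "EffectEstimate":
        z = log_rr / se if se > 0 else np.nan
        p = float(2.0 * norm_sf(abs(z))) if np.isfinite(z) else np.nan
        return cls(
            rate_ratio=float(np.exp(log_rr)),
            ci_low=float(np.exp(log_rr - Z95 * se)),
            ci_high=float(np.exp(log_rr + Z95 * se)),
            p_value=float(p),
            n_treated=n_treated,
            n_control=n_control,
            label=label,
        )


class ExacerbationRateModel:
    """NB2 annualised-rate model for a participant table.

    Parameters
    ----------
    frame : DataFrame
        One row per participant; must contain the outcome count, the exposure
        column, and every column named in ``terms``.  Rows with missing values
        in any used column are dropped (complete-case).
    terms : sequence of str
        patsy term strings, e.g. ``["treated", "C(region)", "age_years",
        "C(prior_exac_cat)", "feno_ppb", "treated:feno_ppb"]``.
    """

    def __init__(self, frame: pd.DataFrame, terms, outcome: str = "exacerbation_count",
                 exposure: str = "followup_years"):
        self.terms = list(terms)
        formula = "1 + " + " + ".join(self.terms) if self.terms else "1"
        cols = _columns_used(frame, self.terms) | {outcome, exposure}
        used = frame[sorted(cols)].dropna()
        self.frame = used
        self.outcome = outcome
        self.exposure = exposure
        self.X = patsy.dmatrix(formula, used, return_type="dataframe")
        self.y = used[outcome].to_numpy(dtype=float)
        self.offset = np.log(used[exposure].to_numpy(dtype=float))
        rank = np.linalg.matrix_rank(self.X.to_numpy())
        if rank < self.X.shape[1]:
            raise RankDeficiencyError(
                "design is rank deficient; aliased columns: "
                + ", ".join(_aliased_columns(self.X.to_numpy(), list(self.X.columns)))
            )

    def fit(self, k: float | None = None, maxiter: int = 200) -> "NBRateResults":
        """Maximum-likelihood fit; ``k=0`` forces the Poisson special case,
        ``k=None`` estimates the dispersion jointly."""
        X = self.X.to_numpy()
        names = list(self.X.columns)
        if self.y.sum() == 0:
            # boundary: no events anywhere; rate -> 0 with an infinite-SE guard
            big = 1e12
            return NBRateResults(
                model=self,
                params=pd.Series(0.0, index=names),
                cov=pd.DataFrame(big * np.eye(len(names)), index=names, columns=names),
                k=0.0,
                llf=0.0,
                nobs=len(self.y),
                converged=False,
            )
        if k == 0:
            res = sm.GLM(self.y, X, family=sm.families.Poisson(), offset=self.offset).fit()
            return NBRateResults(
                model=self,
                params=pd.Series(res.params, index=names),
                cov=pd.DataFrame(res.cov_params(), index=names, columns=names),
                k=0.0,
                llf=float(res.llf),
                nobs=int(res.nobs),
                converged=bool(res.converged),
            )
        mod = sm.NegativeBinomial(self.y, X, offset=self.offset, loglike_method="nb2")
        start = None
        pois = None
        try:
            pois = sm.GLM(self.y, X, family=sm.families.Poisson(), offset=self.offset).fit()
            start = np.append(pois.params, 0.3)
        except Exception:
            pass
        res, converged = None, False
        with np.errstate(all="ignore"):
            for method in ("newton", "bfgs"):
                try:
                    cand = mod.fit(start_params=start, method=method,
                                   maxiter=maxiter, disp=0)
                except Exception:
                    continue
                ok = (
                    bool(cand.mle_retvals.get("converged", True))
                    and np.all(np.isfinite(np.asarray(cand.params)))
                    and np.isfinite(cand.llf)
                )
                if ok:
                    res, converged = cand, True
                    break
                if res is None:
                    res = cand
        # the NB2 MLE can sit on the k -> 0 (Poisson) boundary, where the
        # interior optimizer degenerates; take the boundary fit when it wins
        if pois is not None and (
            res is None
            or not np.isfinite(res.llf)
            or float(res.params[-1]) <= 1e-6
            or res.llf < pois.llf - 1e-8
        ):
            return NBRateResults(
                model=self,
                params=pd.Series(np.asarray(pois.params), index=names),
                cov=pd.DataFrame(pois.cov_params(), index=names, columns=names),
                k=0.0,
                llf=float(pois.llf),
                nobs=int(pois.nobs),
                converged=bool(pois.converged),
            )
        alpha = float(res.params[-1])
        if not np.isfinite(res.llf):
            converged = False
        with np.errstate(all="ignore"):
            cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        if not np.all(np.isfinite(cov)):
            # ridge fallback on the information diagonal for near-singular fits
            hess = -mod.hessian(res.params)
            hess[np.diag_indices_from(hess)] += 1e-6
            cov = np.linalg.inv(hess)[: len(names), : len(names)]
        return NBRateResults(
            model=self,
            params=pd.Series(np.asarray(res.params[: len(names)]), index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            k=max(alpha, 0.0),
            llf=float(res.llf),
            nobs=int(res.nobs),
            converged=converged,
        )


@dataclass
class NBRateResults:
    """Fitted NB rate model: coefficients on the log-rate scale plus dispersion."""

    model: ExacerbationRateModel
    params: pd.Series
    cov: pd.DataFrame
    k: float
    llf: float
    nobs: int
    converged: bool

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def contrast(self, coef_names) -> tuple[float, float]:
        """(estimate, SE) of a sum of coefficients."""
        c = pd.Series(0.0, index=self.params.index)
        for name in coef_names:
            if name not in c.index:
                raise TermLookupError(name)
            c[name] = 1.0
        est = float(c @ self.params)
        var = float(c @ self.cov.to_numpy() @ c)
        return est, float(np.sqrt(max(var, 0.0)))

    def wald_p(self, name: str) -> float:
        if name not in self.params.index:
            raise TermLookupError(name)
        z = self.params[name] / self.se(name)
        return float(2.0 * stats.norm.sf(abs(z)))

    def effect(self, term: str = "treated", extra_terms=(), label: str = "") -> EffectEstimate:
        """Rate-ratio estimate for a treatment contrast.

        ``extra_terms`` are interaction coefficients added to the main term,
        giving the effect within the interacting level.
        """
        est, se = self.contrast([term] + list(extra_terms))
        fr = self.model.frame
        if "treated" in fr.columns:
            n_t = int((fr["treated"] == 1).sum())
            n_c = int((fr["treated"] == 0).sum())
        else:  # pragma: no cover - non-comparison frames
            n_t = n_c = self.nobs
        return EffectEstimate.from_log_rr(est, se, n_t, n_c, label=label)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        z = self.params.to_numpy() / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "z": z,
                "p": 2.0 * stats.norm.sf(np.abs(z)),
                "rate_ratio": np.exp(self.params),
            }
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "se": {n: self.se(n) for n in self.params.index},
            "k": self.k,
            "llf": self.llf,
            "nobs": self.nobs,
            "converged": self.converged,
        }


def effect_from_fit(fit: NBRateResults, contrast: str = "treated", **kw) -> EffectEstimate:
    """Module-level convenience mirroring :meth:`NBRateResults.effect`."""
    return fit.effect(term=contrast, **kw)


def lr_test(full: NBRateResults, reduced: NBRateResults, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested NB fits on identical rows."""
    if full.nobs != reduced.nobs:
        raise ValueError(
            f"fits use different rows (n={full.nobs} vs {reduced.nobs}); "
            "align complete cases before testing"
        )
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# fast exact MLE for the intercept + treatment + offset model
# ---------------------------------------------------------------------------

def _nb_loglik_group(b: float, y, t, k: float) -> float:
    mu = t * np.exp(b)
    if k <= 1e-10:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    inv = 1.0 / k
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1)
            + y * np.log(k * mu)
            - (y + inv) * np.log1p(k * mu)
        )
    )


def _newton_group(y, t, k: float, b0: float) -> tuple[float, float]:
    """Solve the per-group rate score equation; returns (b_hat, observed info)."""
    b = b0
    info = 0.0
    for _ in range(40):
        mu = t * np.exp(b)
        denom = 1.0 + k * mu
        score = np.sum((y - mu) / denom)
        info = np.sum(mu * (1.0 + k * y) / denom**2)
        if info <= 0:
            break
        step = score / info
        b += step if -5.0 < step < 5.0 else np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-9:
            break
    return float(b), float(info)


@dataclass
class TwoGroupNBFit:
    """Exact MLE of the treatment-only NB rate model (log RR = beta)."""

    beta: float  # log rate ratio, treated vs control
    se: float
    k: float
    loglik: float
    converged: bool
    n_treated: int
    n_control: int

    @property
    def z_benefit(self) -> float:
        """Positive z indicates treatment benefit (rate reduction)."""
        return -self.beta / self.se

    @property
    def reduction_pct(self) -> float:
        return (1.0 - np.exp(self.beta)) * 100.0

    @property
    def p_benefit(self) -> float:
        """One-sided p for benefit."""
        return float(norm_sf(self.z_benefit))


def fit_nb_two_group(
    counts: np.ndarray, treated: np.ndarray, exposure: np.ndarray, k: float | None = None
) -> TwoGroupNBFit:
    """Treatment-only NB fit via per-group profile likelihood.

    With a saturated two-group mean the likelihood separates by group given k,
    so each group's log-rate is a 1-D Newton solve and k is profiled by a
    bounded scalar search.  Because the beta/k expected cross-information is
    zero under NB2, Wald SEs from the per-group observed information are
    asymptotically exact.
    """
    y = np.asarray(counts, dtype=float)
    tr = np.asarray(treated, dtype=bool)
    ex = np.asarray(exposure, dtype=float)
    y1, t1 = y[tr], ex[tr]
    y0, t0 = y[~tr], ex[~tr]
    n1, n0 = int(tr.sum()), int((~tr).sum())
    if n1 == 0 or n0 == 0 or y1.sum() == 0 or y0.sum() == 0:
        return TwoGroupNBFit(np.nan, np.nan, np.nan, -np.inf, False, n1, n0)
    b1_0 = np.log(y1.sum() / t1.sum())
    b0_0 = np.log(y0.sum() / t0.sum())
    warm = [b1_0, b0_0]

    def profile(kv: float):
        b1, i1 = _newton_group(y1, t1, kv, warm[0])
        b0, i0 = _newton_group(y0, t0, kv, warm[1])
        warm[0], warm[1] = b1, b0
        ll = _nb_loglik_group(b1, y1, t1, kv) + _nb_loglik_group(b0, y0, t0, kv)
        return ll, b1, b0, i1, i0

    if k is not None:
        ll, b1, b0, i1, i0 = profile(k)
        khat = k
    else:
        # golden-section profile over log k; the profile is flat near the
        # optimum, so a 5% tolerance on k leaves the Wald z unchanged to ~1e-4
        khat = _golden_max(lambda lk: profile(np.exp(lk))[0],
                           np.log(1e-4), np.log(30.0), xtol=0.05)
        khat = float(np.exp(khat))
        ll, b1, b0, i1, i0 = profile(khat)
    if i1 <= 0 or i0 <= 0:
        return TwoGroupNBFit(np.nan, np.nan, khat, ll, False, n1, n0)
    beta = b1 - b0
    se = float(np.sqrt(1.0 / i1 + 1.0 / i0))
    return TwoGroupNBFit(float(beta), se, khat, float(ll), True, n1, n0)


_PHI = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, xtol: float = 0.05) -> float:
    """Golden-section maximisation of a unimodal scalar function."""
    a, b = lo, hi
    c = b - _PHI * (b - a)
    d = a + _PHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > xtol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _PHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _PHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _columns_used(frame: pd.DataFrame, terms) -> set[str]:
    cols = set()
    for term in terms:
        for col in frame.columns:
            if _mentions(term, col):
                cols.add(col)
    return cols


def _mentions(term: str, col: str) -> bool:
    import re

    return re.search(rf"(?<![A-Za-z0-9_]){re.escape(col)}(?![A-Za-z0-9_])", term) is not None


def _aliased_columns(X: np.ndarray, names) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-8 if diag.size else 0.0
    return [n for n, d in zip(names, diag) if d < tol]
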