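"""Mixed models for repeated measures (MMRM) by maximum likelihood.

Longitudinal endpoint values are modelled as multivariate normal per subject
with a common fixed-effect design and a shared visit-covariance matrix:

* ``compound_symmetric`` -- between-subject + within-subject variance
  components (equivalently a random subject intercept), fitted by direct ML
  over the two log-variances with the GLS coefficient profile.
* ``unstructured`` -- a free V x V visit covariance, fitted by EM for the
  incomplete multivariate normal (conditional-moment E-step over missing
  visits, GLS coefficient step), which handles monotone dropout under MAR by
  likelihood.

Inference on fixed effects is Wald with the model-based covariance
``(sum_i X_i' V_i^{-1} X_i)^{-1}`` and normal critical values; no small-sample
denominator-df correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

Z95 = stats.norm.ppf(0.975)


@dataclass
class MMRMResults:
    """Fitted repeated-measures model."""

    params: pd.Series
    cov: pd.DataFrame
    sigma: np.ndarray  # V x V visit covariance implied by the fit
    structure: str
    llf: float
    converged: bool
    n_subjects: int
    n_obs: int

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        var = float(c @ self.cov.to_numpy() @ c)
        return est, float(np.sqrt(max(var, 0.0)))

    def contrast_effect(self, coef_names) -> tuple[float, tuple[float, float], float]:
        """(estimate, 95% CI, two-sided p) for a sum of named coefficients."""
        c = pd.Series(0.0, index=self.params.index)
        for name in coef_names:
            c[name] = 1.0
        est, se = self.contrast(c.to_numpy())
        ci = (est - Z95 * se, est + Z95 * se)
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        return est, ci, float(p)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        z = self.params.to_numpy() / se
        return pd.DataFrame(
            {"coef": self.params, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))}
        )


class RepeatedMeasuresModel:
    """GLS repeated-measures model over a long table.

    Parameters
    ----------
    y, X : response vector and fixed-effect design (rows = observations).
    subject : per-row subject codes.
    visit_idx : per-row visit index 0..n_visits-1.
    covariance : "unstructured" or "compound_symmetric".
    """

    def __init__(self, y, X: pd.DataFrame, subject, visit_idx, n_visits: int,
                 covariance: str = "unstructured"):
        order = np.argsort(np.asarray(subject), kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.names = list(X.columns)
        self.X = np.asarray(X, dtype=float)[order]
        self.subject = np.asarray(subject)[order]
        self.visit = np.asarray(visit_idx, dtype=int)[order]
        self.V = int(n_visits)
        if covariance not in ("unstructured", "compound_symmetric"):
            raise ValueError(f"unknown covariance structure {covariance!r}")
        self.covariance = covariance
        # subject boundaries
        _, self._starts = np.unique(self.subject, return_index=True)
        self._starts = np.sort(self._starts)
        self._ends = np.append(self._starts[1:], len(self.y))

    # -- compound symmetry --------------------------------------------------

    def _cs_gls(self, sb2: float, se2: float):
        """GLS estimate and profile loglik under CS covariance.

        Uses the rank-one form V_i^{-1} = (I - rho_i J)/se2 with
        rho_i = sb2/(se2 + n_i sb2), accumulated over subject blocks.
        """
        X, y = self.X, self.y
        ni = (self._ends - self._starts).astype(float)
        rho = sb2 / (se2 + ni * sb2)
        Sx = np.add.reduceat(X, self._starts, axis=0)  # per-subject row sums
        Sy = np.add.reduceat(y, self._starts)
        A = X.T @ X - (Sx.T * rho) @ Sx
        b = X.T @ y - Sx.T @ (rho * Sy)
        beta = np.linalg.solve(A, b)
        quad_corr = float(np.sum(rho * Sy**2))
        quad = (y @ y - quad_corr - 2 * b @ beta + beta @ A @ beta) / se2
        logdet = float(np.sum((ni - 1) * np.log(se2) + np.log(se2 + ni * sb2)))
        cov = np.linalg.inv(A / se2)
        llf = -0.5 * (len(y) * np.log(2 * np.pi) + logdet + quad)
        return beta, cov, llf, logdet

    def _fit_cs(self, maxiter: int = 200) -> MMRMResults:
        resid0 = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        tot = max(resid0.var(), 1e-6)

        def negll(theta):
            sb2, se2 = np.exp(theta)
            return -self._cs_gls(sb2, se2)[2]

        res = optimize.minimize(
            negll,
            x0=np.log([tot / 2, tot / 2]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        sb2, se2 = np.exp(res.x)
        beta, cov, llf, _ = self._cs_gls(sb2, se2)
        sigma = se2 * np.eye(self.V) + sb2
        return MMRMResults(
            params=pd.Series(beta, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            sigma=sigma,
            structure="compound_symmetric",
            llf=float(llf),
            converged=bool(res.success),
            n_subjects=len(self._starts),
            n_obs=len(self.y),
        )

    # -- unstructured -------------------------------------------------------

    def _patterns(self):
        """Group subjects by observed-visit pattern."""
        pats: dict[tuple, list[int]] = {}
        for i, (s, e) in enumerate(zip(self._starts, self._ends)):
            key = tuple(self.visit[s:e])
            pats.setdefault(key, []).append(i)
        return pats

    def _fit_un(self, maxiter: int = 200, tol: float = 1e-8) -> MMRMResults:
        X, y, V = self.X, self.y, self.V
        p = X.shape[1]
        n_subj = len(self._starts)
        pats = self._patterns()

        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        # initial Sigma: available-case residual covariance
        r = y - X @ beta
        Sigma = np.zeros((V, V))
        cnt = np.zeros((V, V))
        for s, e in zip(self._starts, self._ends):
            vi = self.visit[s:e]
            Sigma[np.ix_(vi, vi)] += np.outer(r[s:e], r[s:e])
            cnt[np.ix_(vi, vi)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            Sigma = np.where(cnt > 0, Sigma / np.maximum(cnt, 1), 0.0)
        Sigma = _nearest_pd(Sigma, floor=1e-6 * max(r.var(), 1e-8))

        # stack subjects sharing a pattern for vectorized pattern-wise algebra
        stacked = {}
        for key, subj in pats.items():
            idx = np.concatenate(
                [np.arange(self._starts[i], self._ends[i]) for i in subj]
            )
            m, no = len(subj), len(key)
            stacked[key] = (
                np.array(key),
                X[idx].reshape(m, no, p),
                y[idx].reshape(m, no),
                m,
            )

        def gls_pieces(Sigma):
            A = np.zeros((p, p))
            b = np.zeros(p)
            for key, (vi, Xs, Ys, m) in stacked.items():
                Soo_inv = np.linalg.inv(Sigma[np.ix_(vi, vi)])
                A += np.einsum("avp,vw,awq->pq", Xs, Soo_inv, Xs, optimize=True)
                b += np.einsum("avp,vw,aw->p", Xs, Soo_inv, Ys, optimize=True)
            return A, b

        llf_prev = -np.inf
        converged = False
        for _ in range(maxiter):
            A, b = gls_pieces(Sigma)
            beta = np.linalg.solve(A, b)
            # Sigma EM step with conditional moments over missing visits
            Snew = np.zeros((V, V))
            llf = 0.0
            for key, (vi, Xs, Ys, m) in stacked.items():
                miss = np.setdiff1d(np.arange(V), vi)
                Soo = Sigma[np.ix_(vi, vi)]
                Soo_inv = np.linalg.inv(Soo)
                _, logdet = np.linalg.slogdet(Soo)
                R = Ys - Xs @ beta  # m x n_o residuals
                Snew[np.ix_(vi, vi)] += R.T @ R
                llf += -0.5 * (
                    m * len(vi) * np.log(2 * np.pi)
                    + m * logdet
                    + np.einsum("ai,ij,aj->", R, Soo_inv, R, optimize=True)
                )
                if len(miss):
                    Smo = Sigma[np.ix_(miss, vi)]
                    H = Smo @ Soo_inv
                    Cmm = Sigma[np.ix_(miss, miss)] - H @ Smo.T
                    Rm = R @ H.T  # m x n_miss conditional means
                    Snew[np.ix_(miss, vi)] += Rm.T @ R
                    Snew[np.ix_(vi, miss)] += R.T @ Rm
                    Snew[np.ix_(miss, miss)] += Rm.T @ Rm + m * Cmm
            Sigma = _nearest_pd(Snew / n_subj, floor=1e-10)
            if abs(llf - llf_prev) < tol * (abs(llf) + 1.0):
                converged = True
                llf_prev = llf
                break
            llf_prev = llf

        A, _ = gls_pieces(Sigma)
        cov = np.linalg.inv(A)
        return MMRMResults(
            params=pd.Series(beta, index=self.names),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            sigma=Sigma,
            structure="unstructured",
            llf=float(llf_prev),
            converged=converged,
            n_subjects=n_subj,
            n_obs=len(y),
        )

    def fit(self, maxiter: int = 200) -> MMRMResults:
        if self.covariance == "compound_symmetric":
            return self._fit_cs(maxiter)
        try:
            res = self._fit_un(maxiter)
            if res.converged and np.all(np.linalg.eigvalsh(res.sigma) > 0):
                return res
        except np.linalg.LinAlgError:
            pass
        # documented downgrade: unstructured failed, refit compound symmetry
        res = self._fit_cs(maxiter)
        return MMRMResults(
            params=res.params, cov=res.cov, sigma=res.sigma,
            structure="compound_symmetric_fallback", llf=res.llf,
            converged=res.converged, n_subjects=res.n_subjects, n_obs=res.n_obs,
        )


def _nearest_pd(S: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    S = (S + S.T) / 2.0
    w, Q = np.linalg.eigh(S)
    return (Q * np.maximum(w, floor)) @ Q.T
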