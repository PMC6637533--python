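"""Uncertainty machinery for the subgroup search.

Two complementary procedures quantify how much to trust a chosen cut-off:

* :func:`bootstrap_cutoffs` resamples participants with replacement
  (stratified by arm), re-runs the search on each resample, and histograms the
  chosen cut-off per biomarker over the *original* data's quantile grid, so
  bins are comparable across draws.
* :func:`permutation_null` permutes the biomarker block against the rest of
  the participant record (breaking any biomarker-outcome and biomarker-
  treatment link while preserving the biomarker panel's internal correlation),
  re-runs the search, and records the best subgroup's apparent AAER reduction.
  The resulting null distribution shows how large a "best subgroup" effect
  arises by selection alone; the observed effect is located in it as a
  percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset
from .nb import fit_nb_two_group
from .sides import SidesParams, SidesResult, candidate_splits, sides_run


def _subseeds(seed: int, n: int) -> list[np.random.Generator]:
    """n independent child generators; child k is identical whether the draws
    are run alone or in a batch."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class BootstrapResult:
    """Per-biomarker cut-off stability over B bootstrap draws."""

    B: int
    grid: dict[str, list[float]]  # original-data candidate grid per biomarker
    counts: dict[str, np.ndarray]  # histogram over grid bins
    directions: dict[str, list[str]]  # direction per selecting draw
    n_selected: dict[str, int]  # draws in which the biomarker was selected
    main_run: dict[str, tuple[float, str]]  # comparison row: (cutoff, direction)
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for bm, grid in self.grid.items():
            counts = self.counts[bm]
            modal = int(np.argmax(counts)) if counts.sum() else -1
            main = self.main_run.get(bm)
            rows.append(
                {
                    "biomarker": bm,
                    "n_selected": self.n_selected[bm],
                    "modal_cutoff": grid[modal] if modal >= 0 else np.nan,
                    "modal_count": int(counts[modal]) if modal >= 0 else 0,
                    "main_cutoff": main[0] if main else np.nan,
                    "main_direction": main[1] if main else None,
                }
            )
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        rows = []
        for bm, grid in self.grid.items():
            for b, (bin_idx, direction) in enumerate(
                zip(self._bins.get(bm, []), self.directions[bm])
            ):
                rows.append(
                    {"biomarker": bm, "draw": b, "cutoff": grid[bin_idx],
                     "direction": direction}
                )
        return pd.DataFrame(rows, columns=["biomarker", "draw", "cutoff", "direction"])

    _bins: dict[str, list[int]] = field(default_factory=dict)


def bootstrap_cutoffs(
    data: TrialDataset,
    params: SidesParams | None = None,
    B: int = 500,
    seed: int = 0,
    arm: str = "q2w",
    stratify: bool = True,
    identity: bool = False,
) -> BootstrapResult:
    """Cut-off stability by participant-level bootstrap.

    ``identity=True`` replaces every resample with the original data (a test
    hook: all draws must then reproduce the main run exactly).
    """
    params = params or SidesParams()
    frame = data.comparison(arm)

    grid = {
        bm: candidate_splits(frame[bm].to_numpy(dtype=float), params)
        for bm in params.covariates
    }
    main = sides_run(data, params, arm)
    main_run = {
        bm: (cand.subgroup.cutoff, cand.subgroup.direction)
        for bm, cand in main.best_per_biomarker.items()
    }

    counts = {bm: np.zeros(len(g), dtype=int) for bm, g in grid.items()}
    directions: dict[str, list[str]] = {bm: [] for bm in grid}
    bins: dict[str, list[int]] = {bm: [] for bm in grid}
    n_selected = {bm: 0 for bm in grid}
    n_failed = 0

    rngs = _subseeds(seed, B)
    part = data.participants
    for b in range(B):
        if identity:
            resampled = data
        else:
            rng = rngs[b]
            if stratify:
                idx = np.concatenate(
                    [
                        rng.choice(g.index.to_numpy(), size=len(g), replace=True)
                        for _, g in part.groupby("arm", observed=True)
                    ]
                )
            else:
                idx = rng.choice(part.index.to_numpy(), size=len(part), replace=True)
            boot = part.loc[idx].reset_index(drop=True)
            boot["participant_id"] = [f"B{b}_{i}" for i in range(len(boot))]
            resampled = TrialDataset(boot, metadata=dict(data.metadata))
        try:
            res = sides_run(resampled, params, arm)
        except Exception:
            n_failed += 1
            continue
        for bm, cand in res.best_per_biomarker.items():
            if bm not in grid or not grid[bm]:
                continue
            g = np.asarray(grid[bm])
            j = int(np.argmin(np.abs(g - cand.subgroup.cutoff)))
            counts[bm][j] += 1
            bins[bm].append(j)
            directions[bm].append(cand.subgroup.direction)
            n_selected[bm] += 1

    out = BootstrapResult(
        B=B, grid=grid, counts=counts, directions=directions,
        n_selected=n_selected, main_run=main_run, n_failed=n_failed,
    )
    out._bins = bins
    return out


@dataclass
class PermutationNull:
    """Null distribution of the best-subgroup AAER reduction under permutation."""

    P: int
    null_reductions: np.ndarray  # length P; NaN where a permutation run failed
    observed_best: float
    n_no_subgroup: int  # permutations contributing the all-comers reduction
    n_failed: int

    @property
    def valid(self) -> np.ndarray:
        return self.null_reductions[np.isfinite(self.null_reductions)]

    @property
    def null_median(self) -> float:
        v = self.valid
        return float(np.median(v)) if v.size else np.nan

    @property
    def observed_percentile(self) -> float:
        """Mid-rank percentile of the observed best effect within the null."""
        v = self.valid
        if v.size == 0 or not np.isfinite(self.observed_best):
            return np.nan
        less = np.sum(v < self.observed_best)
        ties = np.sum(v == self.observed_best)
        return float((less + 0.5 * ties) / v.size)

    def summary(self) -> dict:
        return {
            "P": self.P,
            "null_median": self.null_median,
            "observed_best": self.observed_best,
            "observed_percentile": self.observed_percentile,
            "n_no_subgroup": self.n_no_subgroup,
            "n_failed": self.n_failed,
        }


def permutation_null(
    data: TrialDataset,
    params: SidesParams | None = None,
    P: int = 500,
    seed: int = 0,
    arm: str = "q2w",
    joint: bool = True,
    observed: SidesResult | None = None,
) -> PermutationNull:
    """Best-subgroup effect distribution with biomarkers permuted.

    ``joint=True`` permutes the biomarker columns as one block (preserving
    their mutual correlation); ``joint=False`` permutes each independently.
    A permutation whose search selects no admissible subgroup contributes the
    all-comers treatment-only reduction for that permuted dataset.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    params = params or SidesParams()
    bm_cols = [c for c in params.covariates if c in data.participants.columns]

    if observed is None:
        observed = sides_run(data, params, arm)
    obs_best = observed.best()
    observed_best = obs_best.effect.reduction_pct if obs_best else _all_comers_reduction(
        data, arm
    )

    null = np.full(P, np.nan)
    n_no_subgroup = 0
    n_failed = 0
    rngs = _subseeds(seed, P)
    for p in range(P):
        rng = rngs[p]
        perm = data.participants.copy()
        if joint:
            order = rng.permutation(len(perm))
            perm[bm_cols] = perm[bm_cols].to_numpy()[order]
        else:
            for c in bm_cols:
                perm[c] = rng.permutation(perm[c].to_numpy())
        pdata = TrialDataset(perm, metadata=dict(data.metadata))
        try:
            res = sides_run(pdata, params, arm)
        except Exception:
            n_failed += 1
            continue
        best = res.best()
        if best is not None:
            null[p] = best.effect.reduction_pct
        else:
            null[p] = _all_comers_reduction(pdata, arm)
            n_no_subgroup += 1

    return PermutationNull(
        P=P,
        null_reductions=null,
        observed_best=float(observed_best),
        n_no_subgroup=n_no_subgroup,
        n_failed=n_failed,
    )


def _all_comers_reduction(data: TrialDataset, arm: str) -> float:
    rows = data.comparison(arm)
    f = fit_nb_two_group(
        rows["exacerbation_count"].to_numpy(),
        rows["treated"].to_numpy(),
        rows["followup_years"].to_numpy(),
    )
    return f.reduction_pct if f.converged else np.nan
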