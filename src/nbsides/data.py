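"""Trial data model, CSV I/O, validation and analysis-set preparation.

The common currency of every analysis stage is a :class:`TrialDataset`: one row
per participant for baseline and outcome data, plus an optional long table of
per-visit secondary-endpoint measurements.  Biomarker concentrations are kept
on their native scales (ppb, ng/ml, cells/ul, IU/ml) and missing values stay
missing -- a participant with a missing biomarker is excluded only from
analyses of that biomarker.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five candidate biomarkers, in reporting order.
BIOMARKERS = ["feno_ppb", "periostin_ng_ml", "eos_cells_ul", "dpp4_ng_ml", "ige_iu_ml"]

BIOMARKER_LABELS = {
    "feno_ppb": "FeNO",
    "periostin_ng_ml": "Periostin",
    "eos_cells_ul": "Eosinophils",
    "dpp4_ng_ml": "DPP-4",
    "ige_iu_ml": "IgE",
}

BIOMARKER_UNITS = {
    "feno_ppb": "ppb",
    "periostin_ng_ml": "ng/ml",
    "eos_cells_ul": "cells/ul",
    "dpp4_ng_ml": "ng/ml",
    "ige_iu_ml": "IU/ml",
}

ARMS_4 = ["tralo_q2w", "placebo_q2w", "tralo_q4w", "placebo_q4w"]
ARMS_POOLED = ["tralo_q2w", "tralo_q4w", "placebo"]

ENDPOINTS = ["fev1_pct_change", "acq6", "aqlq", "symptom_score"]

#: baseline column used as a covariate for change-from-baseline score endpoints
BASELINE_COLUMNS = {
    "acq6": "baseline_acq6",
    "aqlq": "baseline_aqlq",
    "symptom_score": "baseline_symptom",
    "fev1_pct_change": "baseline_fev1",
}

REQUIRED_PARTICIPANT_COLUMNS = [
    "participant_id",
    "arm",
    "exacerbation_count",
    "followup_years",
]

OPTIONAL_PARTICIPANT_COLUMNS = BIOMARKERS + [
    "region",
    "age_years",
    "prior_exacerbations",
    "baseline_acq6",
    "baseline_aqlq",
    "baseline_symptom",
    "baseline_fev1",
]

VISIT_COLUMNS = ["participant_id", "endpoint", "week", "value"]


class SchemaError(ValueError):
    """A required column is absent or a configuration names an unknown column."""


class ValidationError(ValueError):
    """Field values violate the data contract (negative follow-up, bad arm, ...)."""


@dataclass
class Subgroup:
    """A one-biomarker membership predicate: ``biomarker direction cutoff``.

    ``direction`` is ``"above"`` or ``"at_or_below"``; ``inclusive`` states
    whether the cutoff itself belongs to the *above* side (``FeNO >= 37``) or
    to the lower side (``FeNO > 32.3``).  The predicate partitions the
    participants with a non-missing biomarker value into the subgroup and its
    complementary subgroup.
    """

    biomarker: str
    direction: str  # "above" | "at_or_below"
    cutoff: float
    inclusive: bool = False  # True: "above" means value >= cutoff

    def __post_init__(self) -> None:
        if self.direction not in ("above", "at_or_below"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def mask(self, participants: pd.DataFrame) -> pd.Series:
        """Boolean membership over rows with a non-missing biomarker value.

        Rows with a missing biomarker are False in both this mask and the
        complement's mask.
        """
        v = participants[self.biomarker]
        if self.inclusive:
            above = v >= self.cutoff
        else:
            above = v > self.cutoff
        if self.direction == "above":
            return above & v.notna()
        return (~above) & v.notna()

    def complement(self) -> "Subgroup":
        other = "at_or_below" if self.direction == "above" else "above"
        return dataclasses.replace(self, direction=other)

    @property
    def label(self) -> str:
        name = BIOMARKER_LABELS.get(self.biomarker, self.biomarker)
        unit = BIOMARKER_UNITS.get(self.biomarker, "")
        if self.direction == "above":
            op = ">=" if self.inclusive else ">"
        else:
            op = "<" if self.inclusive else "<="
        return f"{name} {op} {self.cutoff:g} {unit}".rstrip()


@dataclass
class TrialDataset:
    """Per-participant records plus per-visit endpoint records.

    ``metadata`` carries the analysis-set label, whether placebo arms have
    been pooled, and the exclusion log written by
    :func:`prepare_analysis_set`.
    """

    participants: pd.DataFrame
    visits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VISIT_COLUMNS)
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.visits.empty:
            known = set(self.participants["participant_id"])
            orphans = set(self.visits["participant_id"]) - known
            if orphans:
                raise ValidationError(
                    f"visit records reference unknown participants: {sorted(orphans)[:5]}"
                )

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def placebo_pooled(self) -> bool:
        return bool(self.metadata.get("placebo_pooled", False))

    def arm_counts(self) -> pd.Series:
        return self.participants["arm"].value_counts()

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            self.participants.copy(), self.visits.copy(), dict(self.metadata)
        )

    def comparison(self, arm: str = "q2w") -> pd.DataFrame:
        """Rows for an active arm versus (pooled) placebo, with a 0/1 ``treated`` column."""
        active = {"q2w": "tralo_q2w", "q4w": "tralo_q4w"}[arm]
        placebo = ["placebo"] if self.placebo_pooled else ["placebo_q2w", "placebo_q4w"]
        rows = self.participants[self.participants["arm"].isin([active] + placebo)].copy()
        rows["treated"] = (rows["arm"] == active).astype(int)
        return rows


def _validate_participants(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad_arm = sorted(set(df["arm"]) - set(ARMS_4) - set(ARMS_POOLED))
    if bad_arm:
        raise ValidationError(f"unknown arm label(s): {bad_arm}")
    bad_fu = df.loc[~(df["followup_years"] > 0), "participant_id"].tolist()
    if bad_fu:
        raise ValidationError(
            f"followup_years must be positive; offending participants: {bad_fu}"
        )
    counts = df["exacerbation_count"]
    bad_ct = df.loc[(counts < 0) | (counts != np.floor(counts)), "participant_id"].tolist()
    if bad_ct:
        raise ValidationError(
            f"exacerbation_count must be a non-negative integer; offending participants: {bad_ct}"
        )
    for bm in BIOMARKERS:
        if bm in df.columns:
            bad = df.loc[df[bm] < 0, "participant_id"].tolist()
            if bad:
                raise ValidationError(f"negative {bm} values for participants: {bad}")
    if df["participant_id"].duplicated().any():
        dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValidationError(f"duplicate participant ids: {dups}")


def load_trial(
    participants_path: str | Path,
    visits_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Read participant (and optionally visit) CSV files into a TrialDataset.

    ``schema`` maps file column names to canonical names for files using a
    different header convention.  Missing values must be encoded as empty
    fields; they are preserved as missing, never coerced to zero.
    """
    df = pd.read_csv(participants_path)
    if schema:
        df = df.rename(columns=dict(schema))
    _validate_participants(df)
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["exacerbation_count"] = df["exacerbation_count"].astype(int)

    if visits_path is not None:
        vdf = pd.read_csv(visits_path)
        if schema:
            vdf = vdf.rename(columns=dict(schema))
        missing = [c for c in VISIT_COLUMNS if c not in vdf.columns]
        if missing:
            raise SchemaError(f"visit file missing column(s): {', '.join(missing)}")
        vdf = vdf.copy()
        vdf["participant_id"] = vdf["participant_id"].astype(str)
        if vdf.duplicated(["participant_id", "endpoint", "week"]).any():
            raise ValidationError("duplicate (participant, endpoint, week) visit rows")
    else:
        vdf = pd.DataFrame(columns=VISIT_COLUMNS)
    pooled = set(df["arm"]) <= set(ARMS_POOLED) and "placebo" in set(df["arm"])
    return TrialDataset(df, vdf, {"analysis_set": "loaded", "placebo_pooled": pooled})


def save_trial(
    data: TrialDataset,
    participants_path: str | Path,
    visits_path: str | Path | None = None,
) -> None:
    """Write the dataset back to CSV (empty field = missing); lossless roundtrip."""
    data.participants.to_csv(participants_path, index=False)
    if visits_path is not None:
        data.visits.to_csv(visits_path, index=False)


def derive_covariates(
    participants: pd.DataFrame,
    adolescent_age: tuple[float, float] = (12.0, 18.0),
    periostin_cut: float | None = None,
    prior_exac_cap: int = 3,
) -> pd.DataFrame:
    """Attach derived covariate columns used by the regression models.

    age_group: adolescent iff ``12 <= age < 18``; periostin_group: high/low at
    the in-sample median unless a cut is given; prior_exac_cat: ordered
    categories ``1 / 2 / >=3`` (capped).
    """
    df = participants.copy()
    if "age_years" in df.columns:
        lo, hi = adolescent_age
        df["age_group"] = np.where(
            (df["age_years"] >= lo) & (df["age_years"] < hi), "adolescent", "adult"
        )
    if "periostin_ng_ml" in df.columns:
        cut = periostin_cut
        if cut is None:
            cut = float(df["periostin_ng_ml"].median())
        grp = np.where(df["periostin_ng_ml"] >= cut, "high", "low")
        df["periostin_group"] = pd.Series(grp, index=df.index).where(
            df["periostin_ng_ml"].notna()
        )
        df.attrs["periostin_cut"] = cut
    if "prior_exacerbations" in df.columns:
        capped = df["prior_exacerbations"].clip(upper=prior_exac_cap)
        labels = {i: str(i) for i in range(prior_exac_cap)}
        labels[prior_exac_cap] = f">={prior_exac_cap}"
        df["prior_exac_cat"] = capped.map(labels)
    return df


def prepare_analysis_set(
    data: TrialDataset,
    pool_placebo: bool = True,
    outlier_rules: Sequence[tuple[str, float]] = (),
    adolescent_age: tuple[float, float] = (12.0, 18.0),
    periostin_cut: float | None = None,
) -> TrialDataset:
    """Build the full-analysis-set table used by every downstream stage.

    Pools the two placebo arms when flagged, removes participants violating
    explicit ``(biomarker, threshold)`` outlier rules (value strictly greater
    than the threshold), logs every exclusion in the metadata, and attaches the
    derived covariates.  Outcome fields of retained participants are never
    altered.
    """
    df = data.participants.copy()
    for bm, _thr in outlier_rules:
        if bm not in df.columns:
            raise SchemaError(f"outlier rule names unknown biomarker {bm!r}")

    exclusions: list[dict] = []
    keep = pd.Series(True, index=df.index)
    for bm, thr in outlier_rules:
        hit = df[bm] > thr
        for _, row in df[hit & keep].iterrows():
            exclusions.append(
                {
                    "participant_id": row["participant_id"],
                    "rule": f"{bm} > {thr:g}",
                    "value": row[bm],
                }
            )
        keep &= ~hit.fillna(False)
    df = df[keep].copy()

    if pool_placebo:
        df["arm"] = df["arm"].replace({"placebo_q2w": "placebo", "placebo_q4w": "placebo"})

    df = derive_covariates(df, adolescent_age=adolescent_age, periostin_cut=periostin_cut)

    visits = data.visits
    if not visits.empty:
        visits = visits[visits["participant_id"].isin(df["participant_id"])].copy()

    meta = dict(data.metadata)
    meta.update(
        {
            "analysis_set": "full_analysis_set",
            "placebo_pooled": bool(pool_placebo) or data.placebo_pooled,
            "exclusions": exclusions,
        }
    )
    if "periostin_cut" in df.attrs:
        meta["periostin_cut"] = df.attrs["periostin_cut"]
    return TrialDataset(df.reset_index(drop=True), visits.reset_index(drop=True), meta)


def exclusion_log(data: TrialDataset) -> pd.DataFrame:
    """Exclusion log as a table (participant_id, rule, value)."""
    rows = data.metadata.get("exclusions", [])
    return pd.DataFrame(rows, columns=["participant_id", "rule", "value"])


def summarize_baseline(data: TrialDataset, biomarkers: Sequence[str] = BIOMARKERS) -> pd.DataFrame:
    """Per-arm descriptive table: n, mean (SD), median (range) per biomarker.

    Mirrors the standard baseline-distribution table: one row per
    biomarker x arm, with missing values excluded from n.  SD is reported as
    missing when fewer than two values are available.
    """
    rows = []
    arms = [a for a in (ARMS_POOLED if data.placebo_pooled else ARMS_4)
            if a in set(data.participants["arm"])]
    for bm in biomarkers:
        for arm in arms:
            v = data.participants.loc[data.participants["arm"] == arm, bm].dropna()
            n = len(v)
            rows.append(
                {
                    "biomarker": bm,
                    "arm": arm,
                    "n": n,
                    "mean": v.mean() if n else np.nan,
                    "sd": v.std(ddof=1) if n > 1 else np.nan,
                    "median": v.median() if n else np.nan,
                    "min": v.min() if n else np.nan,
                    "max": v.max() if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def covariate_associations(
    data: TrialDataset,
    covariates: Iterable[str],
    biomarkers: Sequence[str] = BIOMARKERS,
) -> pd.DataFrame:
    """Biomarker distribution (median, quartiles) by level of each covariate.

    Long output: (biomarker, covariate, level, n, median, q1, q3).  Covariates
    must already be categorical (use :func:`derive_covariates` for age group
    and prior-exacerbation categories).
    """
    df = data.participants
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            raise SchemaError(f"unknown covariate {cov!r}")
        if pd.api.types.is_float_dtype(df[cov]) and df[cov].nunique() > 10:
            raise SchemaError(
                f"covariate {cov!r} is continuous; bin it before summarising"
            )
        for level, grp in df.groupby(cov, observed=True):
            for bm in biomarkers:
                v = grp[bm].dropna()
                rows.append(
                    {
                        "biomarker": bm,
                        "covariate": cov,
                        "level": level,
                        "n": len(v),
                        "median": v.median() if len(v) else np.nan,
                        "q1": v.quantile(0.25) if len(v) else np.nan,
                        "q3": v.quantile(0.75) if len(v) else np.nan,
                    }
                )
    return pd.DataFrame(rows)
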