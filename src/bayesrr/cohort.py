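"""Cohort data model, CSV I/O, published-aggregate fixture, and descriptive statistics.

The analysis population is critically ill patients aged >= 80 years admitted to
an ICU, split into octogenarians (80-89 years, the reference group) and
nonagenarians (>= 90 years, the exposed group), with 30-day mortality as the
outcome.  One row per ICU admission.

CSV schema (one header row, UTF-8, booleans coded 0/1, missing cells empty):

    age_years, sex, sofa, cfs, niv, mech_vent, vasoactive, rrt,
    withhold, withdraw, admission_dx, elective_surgery, mortality_30d

``age_group`` is derived from ``age_years``: nonagenarian iff age >= 90,
octogenarian iff 80 <= age < 90.  Rows with missing 30-day mortality or
missing age are dropped (complete-case rule on outcome and exposure) and
counted; elective-surgery admissions are optionally dropped and counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CohortValidationError,
    DegenerateCohortError,
    SchemaError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)

OCTOGENARIAN = "octogenarian"
NONAGENARIAN = "nonagenarian"

SCHEMA: tuple[str, ...] = (
    "age_years",
    "sex",
    "sofa",
    "cfs",
    "niv",
    "mech_vent",
    "vasoactive",
    "rrt",
    "withhold",
    "withdraw",
    "admission_dx",
    "elective_surgery",
    "mortality_30d",
)

BOOL_COLUMNS: tuple[str, ...] = (
    "niv",
    "mech_vent",
    "vasoactive",
    "rrt",
    "withhold",
    "withdraw",
    "elective_surgery",
    "mortality_30d",
)

INT_COLUMNS: tuple[str, ...] = ("age_years", "sofa", "cfs")

SEX_LEVELS = ("male", "female")

#: quartile convention used throughout (numpy's default linear interpolation)
QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class PatientRecord:
    """A single ICU admission."""

    age_years: int
    sex: str | None = None
    sofa: int | None = None
    cfs: int | None = None
    niv: bool | None = None
    mech_vent: bool | None = None
    vasoactive: bool | None = None
    rrt: bool | None = None
    withhold: bool | None = None
    withdraw: bool | None = None
    admission_dx: str | None = None
    elective_surgery: bool | None = None
    mortality_30d: bool | None = None

    @property
    def age_group(self) -> str:
        if self.age_years >= 90:
            return NONAGENARIAN
        if 80 <= self.age_years < 90:
            return OCTOGENARIAN
        raise CohortValidationError(f"age_years {self.age_years} outside [80, inf)")


@dataclass
class CohortTable:
    """An ordered collection of patient records backed by a DataFrame.

    Every retained record has non-missing ``mortality_30d`` and ``age_group``.
    """

    df: pd.DataFrame
    provenance: str = ""
    n_dropped_missing: int = 0
    n_dropped_elective: int = 0

    @property
    def n(self) -> int:
        return len(self.df)

    def write_csv(self, path) -> None:
        """Write the schema columns; booleans as 0/1, missing as empty string."""
        out = {}
        for col in SCHEMA:
            s = self.df[col]
            if col in BOOL_COLUMNS:
                out[col] = s.map(lambda v: "" if pd.isna(v) else str(int(bool(v))))
            elif col in INT_COLUMNS:
                out[col] = s.map(lambda v: "" if pd.isna(v) else str(int(v)))
            else:
                out[col] = s.map(lambda v: "" if pd.isna(v) else str(v))
        pd.DataFrame(out).to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Death/total counts for the exposed (nonagenarian) and reference groups."""

    d1: int  # deaths among nonagenarians
    n1: int  # nonagenarians
    d0: int  # deaths among octogenarians
    n0: int  # octogenarians

    def __post_init__(self):
        if not (self.n1 > 0 and self.n0 > 0):
            raise CohortValidationError("group totals must be positive")
        if not (0 <= self.d1 <= self.n1 and 0 <= self.d0 <= self.n0):
            raise CohortValidationError("death counts must lie in [0, total]")

    def as_contingency(self) -> np.ndarray:
        return np.array(
            [[self.d1, self.n1 - self.d1], [self.d0, self.n0 - self.d0]], dtype=float
        )


@dataclass
class DescriptiveSummary:
    """Per-variable group summaries with between-group tests.

    ``continuous`` maps variable -> {group: (median, q1, q3), "p": p-value};
    ``categorical`` maps variable -> {group: {level: (count, percent)}, "p": ...}.
    """

    group_sizes: dict[str, int]
    continuous: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, entry in self.continuous.items():
            row = {"variable": var, "type": "continuous", "p_value": entry.get("p")}
            for g in (OCTOGENARIAN, NONAGENARIAN):
                if g in entry:
                    med, q1, q3 = entry[g]
                    row[g] = f"{med:g} ({q1:g}-{q3:g})"
            rows.append(row)
        for var, entry in self.categorical.items():
            for level in sorted(
                {lv for g in (OCTOGENARIAN, NONAGENARIAN) for lv in entry.get(g, {})}
            ):
                row = {
                    "variable": f"{var}={level}",
                    "type": "categorical",
                    "p_value": entry.get("p"),
                }
                for g in (OCTOGENARIAN, NONAGENARIAN):
                    if level in entry.get(g, {}):
                        cnt, pct = entry[g][level]
                        row[g] = f"{pct:.0f}% ({cnt})"
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# construction and I/O


def _derive_age_group(age: pd.Series) -> pd.Series:
    grp = pd.Series(pd.NA, index=age.index, dtype="object")
    grp[age >= 90] = NONAGENARIAN
    grp[(age >= 80) & (age < 90)] = OCTOGENARIAN
    return grp


def _validate(df: pd.DataFrame) -> None:
    for idx, val in df["age_years"].dropna().items():
        if val < 80:
            raise CohortValidationError(f"row {idx}: age_years {val} < 80")
    for col, lo, hi in (("sofa", 0, 24), ("cfs", 1, 9)):
        s = df[col].dropna()
        bad = s[(s < lo) | (s > hi)]
        if len(bad):
            idx = bad.index[0]
            raise CohortValidationError(
                f"row {idx}: {col}={bad.iloc[0]} outside [{lo}, {hi}]"
            )
    bad_sex = df["sex"].dropna()[~df["sex"].dropna().isin(SEX_LEVELS)]
    if len(bad_sex):
        raise CohortValidationError(
            f"row {bad_sex.index[0]}: sex={bad_sex.iloc[0]!r} not in {SEX_LEVELS}"
        )


def _parse_columns(raw: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(index=raw.index)
    for col in INT_COLUMNS:
        s = raw[col].replace("", pd.NA)
        df[col] = pd.to_numeric(s, errors="raise").astype("Int64")
    df["sex"] = raw["sex"].replace("", pd.NA)
    df["admission_dx"] = raw["admission_dx"].replace("", pd.NA)
    for col in BOOL_COLUMNS:
        s = raw[col].replace("", pd.NA)
        bad = s.dropna()[~s.dropna().isin(("0", "1"))]
        if len(bad):
            raise CohortValidationError(
                f"row {bad.index[0]}: {col}={bad.iloc[0]!r} not 0/1"
            )
        df[col] = s.map({"0": False, "1": True}).astype("boolean")
    return df


def cohort_from_frame(
    df: pd.DataFrame, provenance: str = "", drop_elective: bool = False
) -> CohortTable:
    """Build a validated CohortTable from a typed DataFrame with SCHEMA columns."""
    df = df.copy()
    _validate(df)
    missing = df["mortality_30d"].isna() | df["age_years"].isna()
    n_missing = int(missing.sum())
    df = df[~missing]
    n_elective = 0
    if drop_elective:
        elective = df["elective_surgery"].fillna(False).astype(bool)
        n_elective = int(elective.sum())
        df = df[~elective]
    df = df.reset_index(drop=True)
    df["age_group"] = _derive_age_group(df["age_years"])
    if n_missing or n_elective:
        logger.info(
            "dropped %d rows with missing mortality/age, %d elective admissions",
            n_missing,
            n_elective,
        )
    return CohortTable(
        df=df,
        provenance=provenance,
        n_dropped_missing=n_missing,
        n_dropped_elective=n_elective,
    )


def read_cohort_csv(path, drop_elective: bool = False) -> CohortTable:
    """Read a cohort CSV, applying the complete-case and elective-surgery rules."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_cols = [c for c in SCHEMA if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {', '.join(missing_cols)}")
    df = _parse_columns(raw)
    return cohort_from_frame(df, provenance=str(path), drop_elective=drop_elective)


def cohort_from_records(
    records: Iterable[PatientRecord], provenance: str = ""
) -> CohortTable:
    rows = [
        {col: getattr(r, col) for col in SCHEMA} for r in records
    ]
    raw = pd.DataFrame(rows, columns=list(SCHEMA))
    df = pd.DataFrame(index=raw.index)
    for col in INT_COLUMNS:
        df[col] = pd.array(raw[col], dtype="Int64")
    df["sex"] = raw["sex"]
    df["admission_dx"] = raw["admission_dx"]
    for col in BOOL_COLUMNS:
        df[col] = pd.array(raw[col], dtype="boolean")
    return cohort_from_frame(df, provenance=provenance)


# ---------------------------------------------------------------------------
# published-aggregate fixture


def load_reference_tables() -> dict:
    """Published group-level aggregates and Model-1 posterior summaries."""
    with resources.files("bayesrr.data").joinpath("reference_tables.json").open() as fh:
        return json.load(fh)


def fixture_two_by_two() -> TwoByTwoTable:
    """The published 30-day mortality 2x2 table (365/807 vs 3219/7601)."""
    ref = load_reference_tables()["groups"]
    return TwoByTwoTable(
        d1=ref[NONAGENARIAN]["deaths_30d"],
        n1=ref[NONAGENARIAN]["n"],
        d0=ref[OCTOGENARIAN]["deaths_30d"],
        n0=ref[OCTOGENARIAN]["n"],
    )


def expand_two_by_two(table: TwoByTwoTable, provenance: str = "expanded 2x2") -> CohortTable:
    """Expand aggregate counts into individual records for the unadjusted model.

    Covariates are left missing; ages are set to representative in-group values
    (85 and 91).  The expansion carries exactly the sufficient statistics of the
    unadjusted relative-risk model.
    """
    blocks = [
        (91, True, table.d1),
        (91, False, table.n1 - table.d1),
        (85, True, table.d0),
        (85, False, table.n0 - table.d0),
    ]
    age = np.concatenate([np.full(n, a, dtype=int) for a, _, n in blocks])
    died = np.concatenate([np.full(n, d, dtype=bool) for _, d, n in blocks])
    df = pd.DataFrame({"age_years": pd.array(age, dtype="Int64")})
    for col in ("sofa", "cfs"):
        df[col] = pd.array([pd.NA] * len(age), dtype="Int64")
    df["sex"] = pd.NA
    df["admission_dx"] = pd.NA
    for col in BOOL_COLUMNS:
        df[col] = pd.array([pd.NA] * len(age), dtype="boolean")
    df["mortality_30d"] = pd.array(died, dtype="boolean")
    df["elective_surgery"] = pd.array([False] * len(age), dtype="boolean")
    return cohort_from_frame(df[list(SCHEMA)], provenance=provenance)


# ---------------------------------------------------------------------------
# aggregation and tests


def aggregate_two_by_two(cohort: CohortTable) -> TwoByTwoTable:
    """Tally deaths/totals per age group."""
    df = cohort.df
    groups = set(df["age_group"].dropna())
    if not {OCTOGENARIAN, NONAGENARIAN} <= groups:
        missing = {OCTOGENARIAN, NONAGENARIAN} - groups
        raise DegenerateCohortError(f"age group(s) absent: {sorted(missing)}")
    nona = df["age_group"] == NONAGENARIAN
    octo = df["age_group"] == OCTOGENARIAN
    died = df["mortality_30d"].astype(bool)
    return TwoByTwoTable(
        d1=int((nona & died).sum()),
        n1=int(nona.sum()),
        d0=int((octo & died).sum()),
        n0=int(octo.sum()),
    )


def mortality_percents(
    table: TwoByTwoTable, rounded: bool = False
) -> tuple[float, float]:
    """30-day mortality percentages (exposed, reference).

    ``rounded`` applies half-up rounding to whole percent for report display.
    """
    p1 = 100.0 * table.d1 / table.n1
    p0 = 100.0 * table.d0 / table.n0
    if rounded:
        return float(np.floor(p1 + 0.5)), float(np.floor(p0 + 0.5))
    return p1, p0


def chi_square_2x2(
    table: TwoByTwoTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on the mortality 2x2 table.

    Yates continuity correction is applied iff the flag is set; the default is
    the uncorrected Pearson statistic.
    """
    obs = table.as_contingency()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise UndefinedTestError("chi-square undefined: zero margin")
    res = stats.chi2_contingency(obs, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Convention: U counts pairwise wins of ``sample_a`` over ``sample_b`` plus
    half-ties (scipy's U1); complete separation with a below b gives U = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UndefinedTestError("Mann-Whitney U requires non-empty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


CONTINUOUS_VARS = ("age_years", "sofa", "cfs")
BINARY_VARS = ("niv", "mech_vent", "vasoactive", "rrt", "withhold", "withdraw")


def descriptive_summary(cohort: CohortTable) -> DescriptiveSummary:
    """Group-wise medians/IQRs, counts/percents, and between-group p-values.

    Quartiles use numpy's linear-interpolation convention; the median of an
    odd-length sample is its middle order statistic.
    """
    df = cohort.df
    if len(df) == 0:
        raise DegenerateCohortError("empty cohort")
    masks = {
        OCTOGENARIAN: df["age_group"] == OCTOGENARIAN,
        NONAGENARIAN: df["age_group"] == NONAGENARIAN,
    }
    out = DescriptiveSummary(
        group_sizes={g: int(m.sum()) for g, m in masks.items()}
    )
    for var in CONTINUOUS_VARS:
        vals = {
            g: df.loc[m, var].dropna().astype(float).to_numpy()
            for g, m in masks.items()
        }
        if all(v.size == 0 for v in vals.values()):
            continue
        entry: dict = {}
        for g, v in vals.items():
            if v.size:
                q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
                entry[g] = (float(med), float(q1), float(q3))
        if all(v.size > 0 for v in vals.values()):
            _, p = mann_whitney_u(vals[NONAGENARIAN], vals[OCTOGENARIAN])
            entry["p"] = p
        out.continuous[var] = entry

    cat_vars = [("sex", SEX_LEVELS)] + [(v, (True,)) for v in BINARY_VARS]
    for var, levels in cat_vars:
        entry = {}
        counts = {}
        for g, m in masks.items():
            sub = df.loc[m, var].dropna()
            n_g = len(sub)
            if n_g == 0:
                continue
            if var == "sex":
                cnt = {lv: int((sub == lv).sum()) for lv in levels}
            else:
                cnt = {True: int(sub.astype(bool).sum())}
                cnt[False] = n_g - cnt[True]
            counts[g] = (cnt, n_g)
            entry[g] = {
                lv: (c, 100.0 * c / n_g)
                for lv, c in cnt.items()
                if var == "sex" or lv is True
            }
        if len(counts) == 2:
            tab = np.array(
                [
                    [counts[g][0].get(lv, 0) for lv in (list(SEX_LEVELS) if var == "sex" else [True, False])]
                    for g in (NONAGENARIAN, OCTOGENARIAN)
                ],
                dtype=float,
            )
            if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                entry["p"] = float(stats.chi2_contingency(tab, correction=False).pvalue)
        out.categorical[var] = entry

    if df["admission_dx"].notna().any():
        entry = {}
        tabs = {}
        for g, m in masks.items():
            sub = df.loc[m, "admission_dx"].dropna()
            if len(sub) == 0:
                continue
            vc = sub.value_counts()
            tabs[g] = vc
            entry[g] = {
                lv: (int(c), 100.0 * c / len(sub)) for lv, c in vc.items()
            }
        if len(tabs) == 2:
            levels = sorted(set(tabs[OCTOGENARIAN].index) | set(tabs[NONAGENARIAN].index))
            tab = np.array(
                [[tabs[g].get(lv, 0) for lv in levels] for g in tabs], dtype=float
            )
            keep = tab.sum(axis=0) > 0
            tab = tab[:, keep]
            if tab.shape[1] >= 2 and (tab.sum(axis=1) > 0).all():
                entry["p"] = float(stats.chi2_contingency(tab, correction=False).pvalue)
        out.categorical["admission_dx"] = entry
    return out
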