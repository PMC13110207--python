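"""Reading, validation and export of the site-level CSV schemas.

Three input tables describe a multicenter trial at the site level:

``site_agg.csv``
    One row per site with screening/enrollment counts:
    ``site, n_screen, n_enrolled, y_fail, y_window, y_bii, n_bii, m_shift``.
``labs.csv``
    Long form, one row per *enrolled* participant: ``site, lab_value``.
``times.csv``
    Long form, one row per *screened* participant: ``site, screening_time``
    (positive duration in days).

Shape checks tie the long tables to the aggregate counts (lab rows must
equal ``n_enrolled``; time rows must equal ``n_screen``) so that silent
misalignment between uploads is caught before any modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SITE_AGG_COLUMNS",
    "SiteAggregateTable",
    "LabTable",
    "TimeTable",
    "ValidationReport",
    "SchemaError",
    "read_site_agg",
    "read_long_table",
    "validate_dataset",
    "write_site_agg",
    "write_long_table",
]

SITE_AGG_COLUMNS = (
    "site",
    "n_screen",
    "n_enrolled",
    "y_fail",
    "y_window",
    "y_bii",
    "n_bii",
    "m_shift",
)
_COUNT_COLUMNS = SITE_AGG_COLUMNS[1:]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _check_site_agg_frame(df: pd.DataFrame) -> None:
    missing = [c for c in SITE_AGG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"site_agg is missing required column(s): {', '.join(missing)}")
    if df["site"].duplicated().any():
        dupes = df.loc[df["site"].duplicated(), "site"].tolist()
        raise SchemaError(f"duplicate site identifier(s): {dupes}")
    for col in _COUNT_COLUMNS:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals[~vals.apply(lambda v: float(v).is_integer())]
            if len(bad):
                raise SchemaError(
                    f"non-integer value in count column {col!r} "
                    f"(first at row {bad.index[0]})"
                )
            df[col] = vals.astype(np.int64)
    errs = _count_bound_violations(df)
    if errs:
        site, rule, msg = errs[0]
        raise SchemaError(f"invariant violation at site {site!r}: {msg}")


def _count_bound_violations(df: pd.DataFrame) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    for _, r in df.iterrows():
        s = str(r["site"])
        if any(r[c] < 0 for c in _COUNT_COLUMNS):
            out.append((s, "nonnegative", "all counts must be >= 0"))
        if r["y_fail"] > r["n_screen"]:
            out.append((s, "y_fail<=n_screen", f"y_fail={r['y_fail']} exceeds n_screen={r['n_screen']}"))
        if r["n_enrolled"] > r["n_screen"]:
            out.append((s, "n_enrolled<=n_screen", f"n_enrolled={r['n_enrolled']} exceeds n_screen={r['n_screen']}"))
        if r["y_window"] > r["n_enrolled"]:
            out.append((s, "y_window<=n_enrolled", f"y_window={r['y_window']} exceeds n_enrolled={r['n_enrolled']}"))
        if r["y_bii"] > r["n_bii"]:
            out.append((s, "y_bii<=n_bii", f"y_bii={r['y_bii']} exceeds n_bii={r['n_bii']}"))
        if r["m_shift"] not in (0, 1):
            out.append((s, "m_shift binary", f"m_shift={r['m_shift']} not in {{0,1}}"))
    return out


@dataclass
class SiteAggregateTable:
    """Per-site screening/enrollment counts and the drift flag."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df["site"] = df["site"].astype(str).str.strip()
        _check_site_agg_frame(df)
        self.frame = df.reset_index(drop=True)

    @property
    def sites(self) -> list[str]:
        return list(self.frame["site"])

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, site: str) -> pd.Series:
        sub = self.frame[self.frame["site"] == site]
        if sub.empty:
            raise KeyError(site)
        return sub.iloc[0]


@dataclass
class LabTable:
    """Long-form eligibility lab values, one record per enrolled participant."""

    frame: pd.DataFrame
    value_column: str = "lab_value"

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df["site"] = df["site"].astype(str).str.strip()
        vals = pd.to_numeric(df[self.value_column], errors="raise")
        if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
            raise SchemaError(f"non-finite {self.value_column}")
        df[self.value_column] = vals.astype(float)
        self.frame = df.reset_index(drop=True)

    def values_for(self, site: str) -> np.ndarray:
        return self.frame.loc[self.frame["site"] == site, self.value_column].to_numpy(dtype=float)

    def counts(self) -> pd.Series:
        return self.frame.groupby("site", sort=False)[self.value_column].size()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TimeTable:
    """Long-form screening times (days), one record per screened participant."""

    frame: pd.DataFrame
    value_column: str = "screening_time"

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df["site"] = df["site"].astype(str).str.strip()
        vals = pd.to_numeric(df[self.value_column], errors="raise").astype(float)
        if not np.all(np.isfinite(vals.to_numpy())) or (vals <= 0).any():
            bad = vals.index[(~np.isfinite(vals.to_numpy())) | (vals <= 0)][0]
            raise SchemaError(f"nonpositive or non-finite screening_time at row {bad}")
        df[self.value_column] = vals
        self.frame = df.reset_index(drop=True)

    def values_for(self, site: str) -> np.ndarray:
        return self.frame.loc[self.frame["site"] == site, self.value_column].to_numpy(dtype=float)

    def counts(self) -> pd.Series:
        return self.frame.groupby("site", sort=False)[self.value_column].size()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ValidationReport:
    """Outcome of cross-table shape checks; passes iff no violations."""

    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.passed:
            return "dataset OK"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  site {s!r}: [{rule}] {msg}" for s, rule, msg in self.violations]
        return "\n".join(lines)


def read_site_agg(path: str | Path) -> SiteAggregateTable:
    """Read and validate ``site_agg.csv``.

    Extra columns are preserved on the frame but ignored by all
    computations. Column order in the file is irrelevant.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    return SiteAggregateTable(df)


def read_long_table(path: str | Path, kind: str) -> LabTable | TimeTable:
    """Read ``labs.csv`` (kind='labs') or ``times.csv`` (kind='times')."""
    if kind not in ("labs", "times"):
        raise ValueError(f"unknown long-table kind {kind!r}; expected 'labs' or 'times'")
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    col = "lab_value" if kind == "labs" else "screening_time"
    missing = [c for c in ("site", col) if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing column(s): {', '.join(missing)}")
    if kind == "labs":
        return LabTable(df)
    return TimeTable(df)


def validate_dataset(
    agg: SiteAggregateTable, labs: LabTable, times: TimeTable
) -> ValidationReport:
    """Cross-check the three tables; every inconsistency becomes one violation.

    Rules: lab rows per site must equal ``n_enrolled``; time rows must equal
    ``n_screen``; sites appearing only in a long table are orphans; all
    count bounds from the aggregate schema are re-reported.
    """
    report = ValidationReport()
    report.violations.extend(_count_bound_violations(agg.frame))
    known = set(agg.sites)

    lab_counts = labs.counts()
    time_counts = times.counts()
    for site in sorted(set(lab_counts.index) - known):
        report.violations.append((site, "orphan", "site present in labs.csv but absent from site_agg"))
    for site in sorted(set(time_counts.index) - known):
        report.violations.append((site, "orphan", "site present in times.csv but absent from site_agg"))

    for _, r in agg.frame.iterrows():
        site = r["site"]
        n_lab = int(lab_counts.get(site, 0))
        if n_lab != r["n_enrolled"]:
            report.violations.append(
                (site, "labs==n_enrolled",
                 f"lab rows must equal n_enrolled (got {n_lab}, expected {r['n_enrolled']})")
            )
        n_time = int(time_counts.get(site, 0))
        if n_time != r["n_screen"]:
            report.violations.append(
                (site, "times==n_screen",
                 f"time rows must equal n_screen (got {n_time}, expected {r['n_screen']})")
            )
    return report


def write_site_agg(table: SiteAggregateTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def write_long_table(table: LabTable | TimeTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)
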