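"""The six monitored enrollment-integrity indicators (plus optional CMG).

Every indicator is *risk-aligned*: larger values mean higher site risk.

========================  =============================================
Indicator                 Definition (per site ``s``)
========================  =============================================
``bii``                   Borderline Inclusion Index — fraction of
                          enrolled participants whose eligibility lab
                          value lies in the closed band
                          ``[tau_lab - delta, tau_lab + delta]``.
``fail_rate``             screen failures / screened.
``window``                window violations / enrolled (violations are
                          counted directly, so higher = riskier).
``duration``              median of log screening times.
``edd``                   Eligibility Distribution Divergence — a
                          two-sample distance (Kolmogorov–Smirnov by
                          default, energy distance optionally) between
                          the site's lab distribution and the pooled
                          labs of all *other* sites.
``sfps``                  Screen-Failure Pattern Shift — binary flag
                          from a two-window chi-square test on the
                          composition of screen-failure reasons.
``cmg``                   Consistency with Modernized Guidance —
                          exclusions for modernized criteria versus a
                          benchmark proportion (optional).
========================  =============================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import LabTable, SiteAggregateTable, TimeTable

__all__ = [
    "IndicatorSpec",
    "BIIConfig",
    "DistanceConfig",
    "INDICATOR_REGISTRY",
    "compute_bii",
    "compute_fail_rate",
    "compute_window_risk",
    "compute_duration_stat",
    "compute_edd",
    "ks_statistic",
    "energy_distance",
    "detect_sfps",
    "compute_cmg",
]


@dataclass(frozen=True)
class IndicatorSpec:
    """How one indicator enters the pipeline.

    ``direction`` is +1 when higher raw values mean higher risk and -1
    when they mean lower risk (the draw matrix is negated in that case).
    ``transform`` names the monotone map placing the indicator on an
    approximately additive scale: logit for proportions and Bernoulli
    probabilities, log for positive times and distances.
    """

    name: str
    likelihood: str  # binomial | normal_log | lognormal_distance | bernoulli
    direction: int = +1
    transform: str = "logit"  # logit | log | log1p | identity

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.transform not in ("logit", "log", "log1p", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        proportionlike = self.likelihood in ("binomial", "bernoulli")
        if proportionlike and self.transform != "logit":
            raise ValueError(f"{self.likelihood} indicators use the logit transform")
        if self.likelihood in ("normal_log", "lognormal_distance") and self.transform not in ("log", "identity"):
            raise ValueError("time/distance indicators use a log-scale transform")


#: Default specification of the monitored indicators, risk-aligned.
INDICATOR_REGISTRY: dict[str, IndicatorSpec] = {
    "bii": IndicatorSpec("bii", "binomial", +1, "logit"),
    "fail_rate": IndicatorSpec("fail_rate", "binomial", +1, "logit"),
    "window": IndicatorSpec("window", "binomial", +1, "logit"),
    "duration": IndicatorSpec("duration", "normal_log", +1, "log"),
    "edd": IndicatorSpec("edd", "lognormal_distance", +1, "log"),
    "sfps": IndicatorSpec("sfps", "bernoulli", +1, "logit"),
    "cmg": IndicatorSpec("cmg", "binomial", +1, "logit"),
}


@dataclass(frozen=True)
class BIIConfig:
    """Eligibility threshold and borderline half-width, in lab units.

    When ``delta`` is omitted it defaults to 5% of the threshold — a
    narrow, clinically meaningful band has to be made concrete somehow.
    """

    tau_lab: float
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def half_width(self) -> float:
        return self.delta if self.delta is not None else 0.05 * abs(self.tau_lab)


@dataclass(frozen=True)
class DistanceConfig:
    """Two-sample distance used by EDD and the numerical floor applied
    before the log transform (``log(max(D, floor))``)."""

    method: str = "ks"
    floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("ks", "energy"):
            raise ValueError("method must be 'ks' or 'energy'")
        if not 0 < self.floor < 1:
            raise ValueError("floor must lie in (0, 1)")


def _site_values(labs: "LabTable | Mapping[str, np.ndarray]") -> dict[str, np.ndarray]:
    if isinstance(labs, LabTable):
        return {s: labs.values_for(s) for s in labs.frame["site"].unique()}
    return {s: np.asarray(v, dtype=float) for s, v in labs.items()}


def compute_bii(
    labs: "LabTable | Mapping[str, np.ndarray]", cfg: BIIConfig
) -> pd.DataFrame:
    """Count enrolled participants in the closed borderline band per site.

    Returns a frame with columns ``site, y_bii, n_bii``. Sites with no
    enrolled participants are dropped with a warning.
    """
    d = cfg.half_width
    lo, hi = cfg.tau_lab - d, cfg.tau_lab + d
    rows = []
    for site, vals in _site_values(labs).items():
        if vals.size == 0:
            warnings.warn(f"site {site!r} has no enrolled participants; excluded from BII")
            continue
        y = int(np.count_nonzero((vals >= lo) & (vals <= hi)))
        rows.append((site, y, int(vals.size)))
    return pd.DataFrame(rows, columns=["site", "y_bii", "n_bii"])


def compute_fail_rate(agg: SiteAggregateTable) -> pd.DataFrame:
    """Screen-failure counts ``(y_fail, n_screen)`` per site.

    Counts are passed through untouched — the Stage 1 Beta posterior
    does the division. Sites with ``n_screen == 0`` are dropped.
    """
    df = agg.frame
    keep = df["n_screen"] > 0
    if (~keep).any():
        warnings.warn(f"excluding {int((~keep).sum())} site(s) with n_screen=0 from fail_rate")
    return df.loc[keep, ["site", "y_fail", "n_screen"]].reset_index(drop=True)


def compute_window_risk(agg: SiteAggregateTable) -> pd.DataFrame:
    """Window-violation counts ``(y_window, n_enrolled)`` per site.

    The indicator is risk-aligned by counting violations rather than
    adherence, so no sign flip is needed downstream.
    """
    df = agg.frame
    if (df["y_window"] > df["n_enrolled"]).any():
        raise ValueError("y_window exceeds n_enrolled")
    keep = df["n_enrolled"] > 0
    if (~keep).any():
        warnings.warn(f"excluding {int((~keep).sum())} site(s) with n_enrolled=0 from window risk")
    return df.loc[keep, ["site", "y_window", "n_enrolled"]].reset_index(drop=True)


def compute_duration_stat(
    times: "TimeTable | Mapping[str, np.ndarray]",
) -> pd.DataFrame:
    """Median of log screening times per site (columns ``site, log_median``)."""
    if isinstance(times, TimeTable):
        per_site = {s: times.values_for(s) for s in times.frame["site"].unique()}
    else:
        per_site = {s: np.asarray(v, dtype=float) for s, v in times.items()}
    rows = []
    for site, vals in per_site.items():
        if vals.size == 0:
            warnings.warn(f"site {site!r} has no screening times; excluded from duration")
            continue
        if (vals <= 0).any():
            raise ValueError(f"nonpositive screening time at site {site!r}")
        rows.append((site, float(np.median(np.log(vals)))))
    return pd.DataFrame(rows, columns=["site", "log_median"])


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sample Kolmogorov–Smirnov distance sup|F_x - F_y|."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("KS distance needs two non-empty samples")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def _mean_abs_self(z: np.ndarray) -> float:
    # E|Z - Z'| over all ordered pairs (V-statistic, self-pairs included)
    z = np.sort(z)
    n = z.size
    k = np.arange(n)
    return float(2.0 * np.sum(z * (2 * k - n + 1)) / (n * n))


def _mean_abs_cross(x: np.ndarray, y: np.ndarray) -> float:
    y = np.sort(y)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    total = cs[-1]
    c = np.searchsorted(y, x, side="right")
    sums = x * c - cs[c] + (total - cs[c]) - x * (y.size - c)
    return float(np.sum(sums) / (x.size * y.size))


def energy_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Energy distance ``2 E|X-Y| - E|X-X'| - E|Y-Y'|`` (>= 0).

    Computed as a V-statistic on the empirical distributions; zero iff
    the two empirical distributions coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("energy distance needs two non-empty samples")
    d = 2.0 * _mean_abs_cross(x, np.sort(y)) - _mean_abs_self(x) - _mean_abs_self(y)
    return float(max(d, 0.0))


def compute_edd(
    site_values: np.ndarray,
    pool_values: np.ndarray,
    cfg: DistanceConfig = DistanceConfig(),
) -> float:
    """Distance between one site's lab distribution and the pooled labs
    of the other sites (the focal site must already be excluded from the
    pool — self-comparison would bias the divergence toward zero)."""
    pool_values = np.asarray(pool_values, dtype=float)
    if pool_values.size == 0:
        raise ValueError(
            "EDD is undefined for a single-site trial: the comparison pool is empty"
        )
    if cfg.method == "ks":
        return ks_statistic(site_values, pool_values)
    return energy_distance(site_values, pool_values)


def detect_sfps(
    reason_counts: np.ndarray | pd.DataFrame, alpha: float = 0.05
) -> int:
    """Two-window drift flag on the composition of screen-failure reasons.

    ``reason_counts`` is periods x reasons. Periods are pooled into an
    earlier and a later half; a Pearson chi-square statistic on the
    resulting 2 x R table is compared with the upper-``alpha`` quantile
    of chi-square with R-1 degrees of freedom (R = categories with any
    counts). Returns 1 when a material composition shift is detected.
    """
    counts = np.asarray(reason_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 periods and 2 reason categories")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    split = counts.shape[0] // 2
    half1 = counts[:split].sum(axis=0)
    half2 = counts[split:].sum(axis=0)
    table = np.vstack([half1, half2])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        warnings.warn("fewer than 2 screen-failure reasons with counts; no composition to shift")
        return 0
    if (table.sum(axis=1) == 0).any():
        warnings.warn("one time half has no screen failures; drift undetermined, returning 0")
        return 0
    stat = stats.chi2_contingency(table, correction=False)[0]
    dof = table.shape[1] - 1
    return int(stat > stats.chi2.ppf(1.0 - alpha, dof))


def compute_cmg(
    y_modern_excl: int, n_excl: int, benchmark: float
) -> tuple[int, int, float]:
    """Counts of modernized-criteria exclusions with their benchmark.

    Stage 1 converts these to ``logit(pi) - logit(benchmark)`` so that
    excess exclusion relative to the expected rate is higher risk.
    """
    if not 0 <= y_modern_excl <= n_excl:
        raise ValueError("need 0 <= y_modern_excl <= n_excl")
    if not 0 < benchmark < 1:
        raise ValueError("benchmark proportion must lie in (0, 1)")
    if n_excl == 0:
        warnings.warn("site has no exclusions; excluded from CMG")
    return int(y_modern_excl), int(n_excl), float(benchmark)
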