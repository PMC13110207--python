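"""Dual-key escalation and Bayesian false-discovery-rate control.

A site is escalated only when two keys agree: the composite risk is
probably high (``Pr(S_s > tau | data) > p*``) *and* an operational
corroborator — by default the standardized posterior-mean screen-failure
component — exceeds its cut. Requiring corroboration guards against
single-metric anomalies and keeps escalation proportionate.

The Bayesian FDR of a flag set is the posterior expected proportion of
false discoveries: the mean, over flagged sites, of
``Pr(S_s <= tau | data)``. Because every dual-key flag satisfies key 1,
this estimate is bounded by ``1 - p*`` by construction; the bound is
asserted on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .composite import CompositeResult

__all__ = ["FlagPolicy", "FlagReport", "dual_key_flag", "bayesian_fdr", "calibrate_policy"]


@dataclass(frozen=True)
class FlagPolicy:
    """Dual-key thresholds and the FDR bound.

    ``tau``: composite risk threshold; ``p_star``: required exceedance
    confidence; ``corroborator``: indicator whose standardized
    posterior-mean must exceed ``cut``; ``q``: Bayesian FDR level used
    by :func:`calibrate_policy`.
    """

    tau: float = 1.5
    p_star: float = 0.8
    corroborator: str = "fail_rate"
    cut: float = 0.5
    q: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.p_star < 1:
            raise ValueError("p_star must lie in (0, 1)")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


@dataclass
class FlagReport:
    """Per-site key values and decisions plus the flag-set FDR."""

    table: pd.DataFrame  # site, pr_exceed, corroborator_z, flagged
    policy: FlagPolicy
    fdr: float

    @property
    def flagged_sites(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "site"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["tau"] = self.policy.tau
        out["p_star"] = self.policy.p_star
        out["corroborator"] = self.policy.corroborator
        out["cut"] = self.policy.cut
        out["fdr_estimate"] = self.fdr
        return out


def _non_exceedance(result: CompositeResult, tau: float) -> pd.Series:
    return pd.Series(
        (np.asarray(result.s_draws) <= tau).mean(axis=1),
        index=pd.Index(result.sites, name="site"),
    )


def bayesian_fdr(
    result: CompositeResult, candidate_flags: list[str] | set, tau: float
) -> float:
    """Posterior expected false-discovery proportion of a flag set:
    mean over flagged sites of ``Pr(S_s <= tau | data)``."""
    flags = list(candidate_flags)
    if not flags:
        warnings.warn("empty flag set; Bayesian FDR defined as 0")
        return 0.0
    non_exc = _non_exceedance(result, tau)
    missing = [s for s in flags if s not in non_exc.index]
    if missing:
        raise KeyError(f"flagged site(s) not in result: {missing}")
    return float(non_exc.loc[flags].mean())


def dual_key_flag(
    result: CompositeResult,
    component_means: pd.DataFrame,
    policy: FlagPolicy,
) -> FlagReport:
    """Flag sites where both keys are strictly exceeded.

    ``component_means`` holds per-site standardized posterior-mean
    component scores (sites as rows, indicators as columns).
    """
    if policy.corroborator not in component_means.columns:
        raise KeyError(
            f"unknown corroborator {policy.corroborator!r}; available: "
            f"{sorted(component_means.columns)}"
        )
    pr = pd.Series((np.asarray(result.s_draws) > policy.tau).mean(axis=1),
                   index=pd.Index(result.sites, name="site"))
    corr = component_means[policy.corroborator].reindex(pr.index)
    if corr.isna().any():
        raise KeyError("component means missing for some scored sites")
    flagged = (pr > policy.p_star) & (corr > policy.cut)
    table = pd.DataFrame(
        {
            "site": pr.index,
            "pr_exceed": pr.to_numpy(),
            "corroborator_z": corr.to_numpy(),
            "flagged": flagged.to_numpy(),
        }
    )
    flags = list(table.loc[table["flagged"], "site"])
    if flags:
        fdr = bayesian_fdr(result, flags, policy.tau)
    else:
        fdr = 0.0
    # algebraic bound: every flag satisfies key 1, so non-exceedance < 1 - p*
    assert fdr <= 1.0 - policy.p_star + 1e-12
    return FlagReport(table, policy, fdr)


def calibrate_policy(
    result: CompositeResult,
    q: float,
    grid: list[tuple[float, float]],
    base: FlagPolicy | None = None,
) -> FlagPolicy:
    """Choose ``(tau, p_star)`` on a grid by bounding the Bayesian FDR.

    Among grid points whose exceedance flag set (key 1 alone) has
    estimated FDR <= q, return the one flagging the most sites, breaking
    ties toward larger ``p_star`` (more conservative). When no point
    satisfies the bound, a policy flagging nothing is returned with a
    warning.
    """
    if not grid:
        raise ValueError("calibration grid is empty")
    base = base or FlagPolicy()
    best: tuple[int, float, float, float] | None = None
    s = np.asarray(result.s_draws)
    sites = np.asarray(result.sites)
    for tau, p_star in grid:
        if not 0 < p_star < 1:
            raise ValueError("grid p_star values must lie in (0, 1)")
        pr = (s > tau).mean(axis=1)
        flags = list(sites[pr > p_star])
        if not flags:
            continue
        fdr = float((1.0 - pr[pr > p_star]).mean())
        if fdr <= q:
            key = (len(flags), p_star, tau, fdr)
            if best is None or (key[0], key[1]) > (best[0], best[1]):
                best = key
    if best is None:
        warnings.warn("no grid point satisfies the FDR bound; returning a policy that flags nothing")
        return replace(base, tau=float(np.max(s)) + 1.0, p_star=0.999, q=q)
    _, p_star, tau, _ = best
    return replace(base, tau=tau, p_star=p_star, q=q)
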