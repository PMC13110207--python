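"""Composite site-risk model: the Stage 1-3 pipeline as a fit/results pair.

`CompositeRiskModel` is built from the three site-level tables (or a
simulated `TrialDataset`); `fit()` runs

1. indicator extraction (six risk-aligned indicators),
2. Stage 1 posterior draws per (site, indicator),
3. Stage 2 robust standardization on posterior-mean anchors,
4. Stage 3 weighted composition,

and returns a `CompositeRiskResults` carrying posterior means, credible
intervals, exceedance and Top-K probabilities, per-indicator
contributions, dual-key flags, and the export tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import composite as comp
from .composite import CompositeConfig, CompositeResult, WeightVector
from .flagging import FlagPolicy, FlagReport, dual_key_flag
from .indicators import INDICATOR_REGISTRY, DistanceConfig
from .io import (
    LabTable,
    SiteAggregateTable,
    TimeTable,
    read_long_table,
    read_site_agg,
    validate_dataset,
)
from .stage1 import (
    IndicatorDrawMatrix,
    PriorConfig,
    beta_posterior_draws,
    bernoulli_beta_draws,
    bootstrap_log_distance,
    bootstrap_log_median,
    substream,
)

__all__ = ["CompositeRiskModel", "CompositeRiskResults"]

#: order of the six monitored indicators in draws and exports
INDICATOR_ORDER = ("bii", "fail_rate", "window", "duration", "edd", "sfps")


class CompositeRiskModel:
    """Bayesian composite risk score over the sites of one trial.

    Parameters
    ----------
    site_agg, labs, times
        The validated site-level tables.
    weights
        Fixed simplex weights per indicator; defaults to equal weights.
        Ignored when ``alphas`` is given.
    alphas
        Dirichlet concentrations; when set, weight uncertainty is
        propagated by pairing one weight draw with each score draw.
    composite
        Composite mode (linear / softmax / geomean) and decision
        parameters (tau, Top-K).
    distance
        Two-sample distance used by the EDD indicator.
    prior
        Beta prior shapes for the proportion indicators.
    """

    def __init__(
        self,
        site_agg: SiteAggregateTable,
        labs: LabTable,
        times: TimeTable,
        *,
        weights: WeightVector | None = None,
        alphas: np.ndarray | None = None,
        composite: CompositeConfig = CompositeConfig(),
        distance: DistanceConfig = DistanceConfig(),
        prior: PriorConfig = PriorConfig(),
        validate: bool = True,
    ) -> None:
        if validate:
            report = validate_dataset(site_agg, labs, times)
            if not report.passed:
                raise ValueError(f"input tables failed validation:\n{report}")
        self.site_agg = site_agg
        self.labs = labs
        self.times = times
        self.composite_config = composite
        self.distance_config = distance
        self.prior = prior
        self.alphas = None if alphas is None else np.asarray(alphas, dtype=float)
        self.weights = weights

    @classmethod
    def from_csv(cls, directory: str | Path, **kwargs) -> "CompositeRiskModel":
        """Build the model from ``site_agg.csv``, ``labs.csv`` and
        ``times.csv`` in one directory."""
        d = Path(directory)
        return cls(
            read_site_agg(d / "site_agg.csv"),
            read_long_table(d / "labs.csv", "labs"),
            read_long_table(d / "times.csv", "times"),
            **kwargs,
        )

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "CompositeRiskModel":
        """Build the model from a simulated :class:`TrialDataset`."""
        kwargs.setdefault("validate", False)
        return cls(dataset.site_agg, dataset.labs, dataset.times, **kwargs)

    # ------------------------------------------------------------------
    def _scored_sites(self) -> list[str]:
        """Sites on which all six indicators are defined."""
        df = self.site_agg.frame
        ok = (df["n_screen"] > 0) & (df["n_enrolled"] > 0) & (df["n_bii"] > 0)
        dropped = df.loc[~ok, "site"].tolist()
        if dropped:
            warnings.warn(f"dropping site(s) with empty denominators: {dropped}")
        return df.loc[ok, "site"].tolist()

    def _stage1(self, sites: list[str], draws: int, seed: int) -> dict[str, IndicatorDrawMatrix]:
        prior = PriorConfig(self.prior.beta_a, self.prior.beta_b, draws, seed)
        agg = self.site_agg.frame.set_index("site")
        lab_values = {s: self.labs.values_for(s) for s in sites}
        all_labs = {s: v for s, v in lab_values.items() if v.size}

        k_index = {name: i for i, name in enumerate(INDICATOR_ORDER)}
        out: dict[str, IndicatorDrawMatrix] = {}

        def stream(site_i: int, name: str) -> np.random.Generator:
            return substream(seed, site_i, k_index[name])

        mats = {name: np.empty((len(sites), draws)) for name in INDICATOR_ORDER}
        for i, s in enumerate(sites):
            row = agg.loc[s]
            mats["bii"][i] = beta_posterior_draws(
                int(row["y_bii"]), int(row["n_bii"]), prior, stream(i, "bii")
            )
            mats["fail_rate"][i] = beta_posterior_draws(
                int(row["y_fail"]), int(row["n_screen"]), prior, stream(i, "fail_rate")
            )
            mats["window"][i] = beta_posterior_draws(
                int(row["y_window"]), int(row["n_enrolled"]), prior, stream(i, "window")
            )
            mats["duration"][i] = bootstrap_log_median(
                self.times.values_for(s), draws, stream(i, "duration")
            )
            pool = np.concatenate([v for t, v in all_labs.items() if t != s and v.size])
            mats["edd"][i] = bootstrap_log_distance(
                lab_values[s], pool, self.distance_config, draws, stream(i, "edd")
            )
            mats["sfps"][i] = bernoulli_beta_draws(
                int(row["m_shift"]), draws, stream(i, "sfps")
            )
        for name in INDICATOR_ORDER:
            spec = INDICATOR_REGISTRY[name]
            out[name] = IndicatorDrawMatrix(sites, mats[name], name, spec.transform, spec.direction)
        return out

    def _exact_anchor(self, name: str, sites: list[str], mat) -> pd.Series:
        """Site-level posterior-mean anchors for Stage 2.

        Conjugate (Beta) indicators use the closed-form posterior mean
        of logit(pi), digamma(a) - digamma(b): anchors that coincide in
        exact arithmetic must coincide numerically, or the MAD=0 -> SD
        fallback can never trigger and standardized scores would grow
        with the draw count. Bootstrap indicators have no closed form
        and use empirical draw means.
        """
        from scipy.special import digamma

        if name not in ("bii", "fail_rate", "window", "sfps"):
            return mat.means()
        agg = self.site_agg.frame.set_index("site")
        a0, b0 = self.prior.beta_a, self.prior.beta_b
        vals = []
        for s in sites:
            row = agg.loc[s]
            if name == "bii":
                y, n = row["y_bii"], row["n_bii"]
            elif name == "fail_rate":
                y, n = row["y_fail"], row["n_screen"]
            elif name == "window":
                y, n = row["y_window"], row["n_enrolled"]
            else:  # sfps: Beta(1+m, 2-m)
                y, n = row["m_shift"], 1
                a0 = b0 = 1.0
            vals.append(float(digamma(a0 + y) - digamma(b0 + n - y)))
        return pd.Series(vals, index=sites, name=name)

    def fit(self, draws: int | None = None, seed: int = 0) -> "CompositeRiskResults":
        """Run the full pipeline and return the results object.

        ``draws`` defaults to the prior configuration's draw count.
        Fixing ``(draws, seed)`` makes the fit bit-for-bit reproducible.
        """
        draws = self.prior.n_draws if draws is None else int(draws)
        sites = self._scored_sites()
        if len(sites) < 2:
            raise ValueError("composite scoring needs at least 2 scorable sites")
        stage1 = self._stage1(sites, draws, seed)

        anchors = pd.DataFrame(
            {k: self._exact_anchor(k, sites, stage1[k]) for k in stage1}
        )
        params = comp.fit_standardization(anchors)
        z_std = np.stack(
            [comp.standardize_draws(stage1[k], params).draws for k in INDICATOR_ORDER]
        )

        names = list(INDICATOR_ORDER)
        if self.alphas is not None:
            w_draws = comp.sample_weights(self.alphas, draws, substream(seed, 10**6))
            weights = WeightVector.from_raw(names, self.alphas)  # prior-mean weights
            s_draws = comp.compose(z_std, w_draws, self.composite_config)
            w_mean = w_draws.mean(axis=0)
        else:
            weights = self.weights or WeightVector.equal(names)
            if list(weights.names) != names:
                weights = WeightVector(names, weights.as_series().reindex(names).to_numpy())
            s_draws = comp.compose(z_std, weights.values, self.composite_config)
            w_mean = weights.values

        component_means = pd.DataFrame(
            z_std.mean(axis=2).T, index=pd.Index(sites, name="site"), columns=names
        )
        contributions = component_means * w_mean
        result = comp.summarize(s_draws, sites, self.composite_config, contributions)
        return CompositeRiskResults(
            model=self,
            result=result,
            stage1=stage1,
            anchors=anchors,
            std_params=params,
            z_std=z_std,
            component_means=component_means,
            weights=weights,
            seed=seed,
        )


@dataclass
class CompositeRiskResults:
    """Fitted composite risk scores with uncertainty and diagnostics."""

    model: CompositeRiskModel
    result: CompositeResult
    stage1: dict[str, IndicatorDrawMatrix]
    anchors: pd.DataFrame
    std_params: comp.StandardizationParams
    z_std: np.ndarray  # (K, S, M)
    component_means: pd.DataFrame
    weights: WeightVector
    seed: int

    # -- convenience accessors ----------------------------------------
    @property
    def sites(self) -> list[str]:
        return self.result.sites

    @property
    def mean_score(self) -> pd.Series:
        return self.result.mean

    @property
    def pr_exceed(self) -> pd.Series:
        return self.result.pr_exceed

    def summary(self) -> pd.DataFrame:
        """Site summary table ordered by posterior-mean rank."""
        return self.result.to_frame().sort_values("rank").reset_index(drop=True)

    def flag(self, policy: FlagPolicy | None = None) -> FlagReport:
        """Dual-key flag report at the given policy."""
        return dual_key_flag(self.result, self.component_means, policy or FlagPolicy())

    def classify(self, tau: float | None = None, rule: str = "posterior_mean",
                 p_star: float = 0.8) -> list[str]:
        """Sites classified atypical, either by posterior-mean threshold
        (default) or by exceedance probability."""
        tau = self.result.tau if tau is None else tau
        if rule == "posterior_mean":
            sel = self.result.mean > tau
        elif rule == "exceedance":
            sel = pd.Series(
                (np.asarray(self.result.s_draws) > tau).mean(axis=1) > p_star,
                index=self.result.mean.index,
            )
        else:
            raise ValueError(f"unknown classification rule {rule!r}")
        return list(sel.index[sel])

    # -- exports -------------------------------------------------------
    def posterior_draws_frame(self) -> pd.DataFrame:
        return pd.concat([m.to_long_frame() for m in self.stage1.values()], ignore_index=True)

    def to_csvs(self, outdir: str | Path, policy: FlagPolicy | None = None) -> dict[str, Path]:
        """Write the app's download set: site_summary, flags,
        component_means, posterior_draws."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "site_summary": outdir / "site_summary.csv",
            "flags": outdir / "flags.csv",
            "component_means": outdir / "component_means.csv",
            "posterior_draws": outdir / "posterior_draws.csv",
        }
        self.summary().to_csv(paths["site_summary"], index=False)
        self.flag(policy).to_frame().to_csv(paths["flags"], index=False)
        self.component_means.reset_index().to_csv(paths["component_means"], index=False)
        self.posterior_draws_frame().to_csv(paths["posterior_draws"], index=False)
        return paths

    # -- plots ---------------------------------------------------------
    def plot_forest(self, ax=None):
        """Forest plot of posterior mean composite with 95% CrI."""
        from . import plots

        return plots.forest(self, ax=ax)

    def plot_contributions(self, ax=None):
        """Heatmap of weighted component contributions by site."""
        from . import plots

        return plots.contribution_heatmap(self, ax=ax)
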