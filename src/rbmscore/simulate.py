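"""Synthetic multicenter trials with known atypical sites.

The generator mimics a trial monitored through a single lab-based
eligibility criterion (think creatinine clearance, threshold 60 mL/min):

* 50 sites by default, each screening a DiscreteUniform(20, 100) number
  of candidates;
* candidate lab values are N(80, 15); at atypical sites (10% of sites)
  the site mean is shifted by -12 toward the threshold, inflating
  borderline inclusions and shifting the site's lab distribution;
* screening fails either on eligibility (lab value at or below the
  threshold) or through an independent non-lab channel whose site-level
  probability is Beta-distributed with mean Uniform(0.10, 0.40) and a
  fixed concentration;
* screening durations are log-normal with median 7 days and log-SD 0.4;
  atypical sites run 30% longer (a log-location shift of log 1.3);
* window violations are Binomial(n_enrolled, 1 - theta_s) with
  adherence theta_s ~ Uniform(0.80, 0.95);
* the drift flag is Bernoulli with probability 0.05 at typical and 0.50
  at atypical sites.

Site-level parameters ("profiles") and participant-level data are drawn
from separate substreams, so a fixed site configuration can be re-used
while participant data are redrawn — the setup rank-stability studies
need.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import LabTable, SiteAggregateTable, TimeTable, validate_dataset

__all__ = [
    "TrialConfig",
    "SiteProfiles",
    "TrialDataset",
    "draw_site_profiles",
    "simulate_from_profiles",
    "simulate_trial",
    "simulate_null_trial",
]


@dataclass(frozen=True)
class TrialConfig:
    """Data-generating parameters of the synthetic multicenter trial."""

    n_sites: int = 50
    screen_range: tuple[int, int] = (20, 100)
    lab_mean: float = 80.0
    lab_sd: float = 15.0
    tau_lab: float = 60.0
    atypical_fraction: float = 0.10
    atypical_lab_shift: float = -12.0
    fail_mean_range: tuple[float, float] = (0.10, 0.40)
    fail_concentration: float = 20.0
    duration_median_days: float = 7.0
    duration_log_sd: float = 0.4
    atypical_duration_multiplier: float = 1.30
    adherence_range: tuple[float, float] = (0.80, 0.95)
    drift_prob_typical: float = 0.05
    drift_prob_atypical: float = 0.50
    bii_delta: float = 5.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if not 0 <= self.atypical_fraction < 1:
            raise ValueError("atypical fraction must lie in [0, 1)")
        for name in ("screen_range", "fail_mean_range", "adherence_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be well-ordered")
        if self.lab_sd <= 0 or self.duration_log_sd <= 0:
            raise ValueError("spread parameters must be positive")
        if self.bii_delta <= 0:
            raise ValueError("bii_delta must be positive")


@dataclass
class SiteProfiles:
    """Fixed site-level configuration drawn once per trial: which sites
    are atypical and each site's latent operating parameters."""

    frame: pd.DataFrame  # site, atypical, n_screen, lab_mean, fail_mean, theta, drift_prob, log_dur_median

    @property
    def sites(self) -> list[str]:
        return list(self.frame["site"])


@dataclass
class TrialDataset:
    """A generated trial: the three standard tables plus ground truth."""

    site_agg: SiteAggregateTable
    labs: LabTable
    times: TimeTable
    truth: pd.DataFrame  # site, atypical + generating parameters
    config: TrialConfig

    def truth_labels(self) -> pd.Series:
        return self.truth.set_index("site")["atypical"]

    def write_csvs(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.site_agg.frame.to_csv(outdir / "site_agg.csv", index=False)
        self.labs.frame.to_csv(outdir / "labs.csv", index=False)
        self.times.frame.to_csv(outdir / "times.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _n_atypical(cfg: TrialConfig) -> int:
    raw = cfg.atypical_fraction * cfg.n_sites
    if raw < 1.0:
        if cfg.atypical_fraction > 0:
            warnings.warn(
                f"atypical fraction {cfg.atypical_fraction} x {cfg.n_sites} sites < 1; "
                "no atypical sites generated"
            )
        return 0
    return math.ceil(raw)


def draw_site_profiles(cfg: TrialConfig, seed: int) -> SiteProfiles:
    """Draw the per-site latent configuration (atypical labels, sizes,
    failure means, adherence, drift probabilities)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    s = cfg.n_sites
    width = len(str(s))
    sites = [f"S{i + 1:0{width}d}" for i in range(s)]
    atypical = np.zeros(s, dtype=bool)
    n_at = _n_atypical(cfg)
    if n_at:
        atypical[rng.choice(s, size=n_at, replace=False)] = True
    fail_mean = rng.uniform(*cfg.fail_mean_range, size=s)
    c = cfg.fail_concentration
    drift_prob = np.where(atypical, cfg.drift_prob_atypical, cfg.drift_prob_typical)
    frame = pd.DataFrame(
        {
            "site": sites,
            "atypical": atypical,
            "n_screen": rng.integers(cfg.screen_range[0], cfg.screen_range[1] + 1, size=s),
            "lab_mean": np.where(atypical, cfg.lab_mean + cfg.atypical_lab_shift, cfg.lab_mean),
            "fail_mean": fail_mean,
            # realized site-level failure probability (Beta-Binomial mixing draw)
            "p_fail": rng.beta(fail_mean * c, (1.0 - fail_mean) * c),
            "theta": rng.uniform(*cfg.adherence_range, size=s),
            "drift_prob": drift_prob,
            # realized drift flag: a site-level trait, fixed when the
            # configuration is held fixed and data are redrawn
            "m_shift": (rng.random(s) < drift_prob).astype(int),
            "log_dur_median": np.log(cfg.duration_median_days)
            + np.where(atypical, np.log(cfg.atypical_duration_multiplier), 0.0),
        }
    )
    return SiteProfiles(frame)


def simulate_from_profiles(
    profiles: SiteProfiles, cfg: TrialConfig, seed: int
) -> TrialDataset:
    """Draw participant-level data for a fixed site configuration."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    agg_rows = []
    lab_rows: list[pd.DataFrame] = []
    time_rows: list[pd.DataFrame] = []
    for _, p in profiles.frame.iterrows():
        site = p["site"]
        n_screen = int(p["n_screen"])
        labs = rng.normal(p["lab_mean"], cfg.lab_sd, size=n_screen)
        eligible = labs > cfg.tau_lab
        nonlab_pass = rng.random(n_screen) >= p["p_fail"]
        enrolled = eligible & nonlab_pass
        n_enrolled = int(enrolled.sum())
        enrolled_labs = labs[enrolled]

        lo, hi = cfg.tau_lab - cfg.bii_delta, cfg.tau_lab + cfg.bii_delta
        y_bii = int(np.count_nonzero((enrolled_labs >= lo) & (enrolled_labs <= hi)))

        times = np.exp(rng.normal(p["log_dur_median"], cfg.duration_log_sd, size=n_screen))
        y_window = int(rng.binomial(n_enrolled, 1.0 - p["theta"])) if n_enrolled else 0
        m_shift = int(p["m_shift"])

        agg_rows.append(
            (site, n_screen, n_enrolled, n_screen - n_enrolled, y_window, y_bii, n_enrolled, m_shift)
        )
        lab_rows.append(pd.DataFrame({"site": site, "lab_value": enrolled_labs}))
        time_rows.append(pd.DataFrame({"site": site, "screening_time": times}))

    agg = SiteAggregateTable(
        pd.DataFrame(
            agg_rows,
            columns=["site", "n_screen", "n_enrolled", "y_fail", "y_window", "y_bii", "n_bii", "m_shift"],
        )
    )
    labs_tab = LabTable(pd.concat(lab_rows, ignore_index=True))
    times_tab = TimeTable(pd.concat(time_rows, ignore_index=True))
    truth = profiles.frame.copy()
    report = validate_dataset(agg, labs_tab, times_tab)
    if not report.passed:  # pragma: no cover - generator contract
        raise AssertionError(f"generated dataset failed validation:\n{report}")
    return TrialDataset(agg, labs_tab, times_tab, truth, cfg)


def simulate_trial(cfg: TrialConfig, seed: int) -> TrialDataset:
    """Generate a full trial: site profiles then participant data.

    Identical ``(cfg, seed)`` pairs produce identical datasets.
    """
    profiles = draw_site_profiles(cfg, seed)
    return simulate_from_profiles(profiles, cfg, seed)


def simulate_null_trial(cfg: TrialConfig, seed: int) -> TrialDataset:
    """A trial with no atypical sites (all-null configuration)."""
    return simulate_trial(replace(cfg, atypical_fraction=0.0), seed)
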