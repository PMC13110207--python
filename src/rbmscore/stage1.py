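"""Stage 1: map each indicator observation to posterior draws.

Each (site, indicator) observation becomes ``M`` draws on a transformed,
risk-aligned scale:

* proportions (BII, screen-failure rate, window violations, CMG) get a
  conjugate Beta(1+y, 1+n-y) posterior, reported as ``logit(pi)`` — the
  flat Beta(1,1) prior regularizes away degenerate 0/1 rates;
* screening duration gets a nonparametric bootstrap of the median log
  time;
* the eligibility distribution divergence gets a bootstrap of the
  two-sample distance (both samples resampled), reported as
  ``log(max(D, floor))``;
* the binary drift flag gets a Beta(1+m, 2-m) posterior, reported as
  ``logit(psi)``.

Every (site, indicator) pair draws from its own RNG substream derived
from ``(seed, site_index, indicator_index)``, so adding or removing a
site never perturbs another site's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logit

from .indicators import DistanceConfig, IndicatorSpec, energy_distance

__all__ = [
    "PriorConfig",
    "IndicatorDrawMatrix",
    "substream",
    "beta_posterior_draws",
    "bootstrap_log_median",
    "bootstrap_log_distance",
    "bernoulli_beta_draws",
    "align_direction",
]

_EPS = 1e-12


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, *key)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class PriorConfig:
    """Beta prior shapes, draw count and seed for Stage 1."""

    beta_a: float = 1.0
    beta_b: float = 1.0
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta prior shapes must be positive")
        if self.n_draws < 100:
            raise ValueError("need at least 100 posterior draws")


@dataclass
class IndicatorDrawMatrix:
    """Sites x draws posterior matrix for one indicator on its
    transformed (logit/log) risk-aligned scale."""

    sites: list[str]
    draws: np.ndarray  # (n_sites, M)
    name: str
    transform: str
    direction: int = +1

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[0] != len(self.sites):
            raise ValueError("draws must be (n_sites, M)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError(f"non-finite draw in indicator {self.name!r}")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def means(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=1), index=self.sites, name=self.name)

    def to_long_frame(self) -> pd.DataFrame:
        s, m = self.draws.shape
        return pd.DataFrame(
            {
                "site": np.repeat(self.sites, m),
                "indicator": self.name,
                "draw_index": np.tile(np.arange(m), s),
                "value": self.draws.ravel(),
            }
        )


def beta_posterior_draws(
    y: int, n: int, prior: PriorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draws of ``logit(pi)`` under ``pi ~ Beta(a+y, b+n-y)``."""
    if not 0 <= y <= n:
        raise ValueError(f"need 0 <= y <= n, got y={y}, n={n}")
    rng = substream(prior.seed) if rng is None else rng
    p = rng.beta(prior.beta_a + y, prior.beta_b + n - y, size=prior.n_draws)
    return logit(np.clip(p, _EPS, 1.0 - _EPS))


def bernoulli_beta_draws(
    m: int, n_draws: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draws of ``logit(psi)`` under ``psi ~ Beta(1+m, 2-m)`` for a
    binary drift flag ``m``."""
    if m not in (0, 1):
        raise ValueError(f"drift flag must be 0 or 1, got {m!r}")
    rng = substream(rng) if isinstance(rng, (int, np.integer)) else rng
    p = rng.beta(1.0 + m, 2.0 - m, size=n_draws)
    return logit(np.clip(p, _EPS, 1.0 - _EPS))


def bootstrap_log_median(
    times: np.ndarray, n_draws: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Bootstrap draws of the median log screening time for one site.

    Resamples with replacement at the original sample size.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if (t <= 0).any():
        raise ValueError("screening times must be positive")
    rng = substream(rng) if isinstance(rng, (int, np.integer)) else rng
    logt = np.log(t)
    idx = rng.integers(0, t.size, size=(n_draws, t.size))
    return np.median(logt[idx], axis=1)


def _chain_cum_counts(
    rng: np.random.Generator, n_total: int, cuts: np.ndarray, n_draws: int
) -> np.ndarray:
    """Cumulative counts of a uniform with-replacement resample of
    ``n_total`` ordered items, evaluated at the given cut positions.

    Equivalent in distribution to drawing a multinomial bootstrap and
    taking cumulative sums, but costs O(n_draws * len(cuts)) binomial
    draws via the Markov chain of conditional binomials.
    """
    out = np.empty((n_draws, len(cuts)), dtype=np.int64)
    prev_cut = 0
    prev = np.zeros(n_draws, dtype=np.int64)
    for j, c in enumerate(cuts):
        c = int(c)
        if c > prev_cut:
            p = (c - prev_cut) / (n_total - prev_cut)
            prev = prev + rng.binomial(n_total - prev, p)
            prev_cut = c
        out[:, j] = prev
    return out


def _ks_bootstrap(
    x: np.ndarray, y: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact KS distances between independent bootstrap resamples of x
    and y (both resampled with replacement at their original sizes).

    The supremum of |F_x - F_y| over the real line is attained at a
    support point of x, evaluated from the right, or just left of one;
    both evaluations come from cumulative resample counts sampled
    directly with the chain-binomial device above.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    ys = np.sort(np.asarray(y, dtype=float))
    n, N = xs.size, ys.size

    xu, xcounts = np.unique(xs, return_counts=True)
    cum_x_cuts = np.cumsum(xcounts)  # cumulative x counts at each distinct value
    fx = _chain_cum_counts(rng, n, cum_x_cuts, n_draws) / n
    fx_prev = np.concatenate([np.zeros((n_draws, 1)), fx[:, :-1]], axis=1)

    cy_left = np.searchsorted(ys, xu, side="left")
    cy_right = np.searchsorted(ys, xu, side="right")
    cuts_y = np.unique(np.concatenate([cy_left, cy_right]))
    cum_y = _chain_cum_counts(rng, N, cuts_y, n_draws)
    fy_left = cum_y[:, np.searchsorted(cuts_y, cy_left)] / N
    fy_right = cum_y[:, np.searchsorted(cuts_y, cy_right)] / N

    d = np.maximum(np.abs(fx - fy_right), np.abs(fx_prev - fy_left))
    return d.max(axis=1)


def bootstrap_log_distance(
    site_values: np.ndarray,
    pool_values: np.ndarray,
    cfg: DistanceConfig,
    n_draws: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Bootstrap draws of ``log(max(D, floor))`` where D is the
    two-sample distance between independent resamples of the site and
    pool lab values (both resampled at their original sizes; the floor
    keeps the log finite when a resample pair coincides)."""
    x = np.asarray(site_values, dtype=float)
    y = np.asarray(pool_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = substream(rng) if isinstance(rng, (int, np.integer)) else rng
    if cfg.method == "ks":
        d = _ks_bootstrap(x, y, n_draws, rng)
    else:
        d = np.empty(n_draws)
        for m in range(n_draws):
            xb = x[rng.integers(0, x.size, x.size)]
            yb = y[rng.integers(0, y.size, y.size)]
            d[m] = energy_distance(xb, yb)
    return np.log(np.maximum(d, cfg.floor))


def align_direction(
    draws: IndicatorDrawMatrix, spec: IndicatorSpec
) -> IndicatorDrawMatrix:
    """Negate an indicator whose raw direction is lower-is-risk."""
    if spec.direction == +1:
        return draws
    return replace(draws, draws=-draws.draws, direction=+1)
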