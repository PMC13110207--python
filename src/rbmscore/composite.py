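"""Stage 2 robust standardization and Stage 3 composite risk scoring.

Stage 2 anchors each indicator on its site-level posterior means: the
cross-site median is the center and 1.4826 x MAD the scale (so the scale
matches the SD under normality), with an SD fallback when the MAD is
zero and a unit fallback when both vanish. Every posterior draw is then
standardized with the same affine map, giving unitless robust risk
z-scores comparable across indicators.

Stage 3 combines the standardized draws into a per-site, per-draw
composite:

* ``linear``   — convex combination ``S = sum_k w_k z_k`` (OR/AND
  neutral);
* ``softmax``  — ``(1/lambda) log sum_k exp(lambda w_k z_k)``,
  OR-leaning: one very high-risk indicator dominates;
* ``geomean``  — ``prod_k (c + z_k)^{w_k} - c``, AND-leaning: sites must
  be consistently risky to score high.

Weights live on the simplex; they may be fixed, derived from cross-site
dispersion (``entropy_weights``), or drawn from a Dirichlet prior whose
concentrations encode critical-to-quality priorities, in which case
weight draw ``m`` multiplies score draw ``m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .stage1 import IndicatorDrawMatrix, substream

__all__ = [
    "StandardizationParams",
    "WeightVector",
    "CompositeConfig",
    "CompositeResult",
    "fit_standardization",
    "standardize_draws",
    "compose",
    "sample_weights",
    "entropy_weights",
    "summarize",
]


@dataclass
class StandardizationParams:
    """Per-indicator center (median of site anchors) and scale
    (1.4826 x MAD, SD fallback, then unit fallback)."""

    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            raise ValueError("standardization scales must be positive")


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def fit_standardization(anchor_means: pd.DataFrame) -> StandardizationParams:
    """Fit robust centers/scales from the sites x indicators anchor matrix."""
    if len(anchor_means) < 2:
        raise ValueError("robust standardization needs at least 2 sites")
    centers, scales = {}, {}
    for col in anchor_means.columns:
        x = anchor_means[col].to_numpy(dtype=float)
        centers[col] = float(np.median(x))
        scale = 1.4826 * _mad(x)
        if scale == 0.0:
            scale = float(np.std(x, ddof=1))
        if scale == 0.0:
            warnings.warn(f"indicator {col!r} is constant across sites; unit scale used")
            scale = 1.0
        scales[col] = scale
    return StandardizationParams(pd.Series(centers), pd.Series(scales))


def standardize_draws(
    draws: IndicatorDrawMatrix, params: StandardizationParams
) -> IndicatorDrawMatrix:
    """Apply the per-indicator affine map to every draw."""
    if draws.name not in params.center.index:
        raise KeyError(f"indicator {draws.name!r} missing from standardization params")
    z = (draws.draws - params.center[draws.name]) / params.scale[draws.name]
    return IndicatorDrawMatrix(draws.sites, z, draws.name, draws.transform, draws.direction)


@dataclass
class WeightVector:
    """Simplex weights per indicator, optionally with Dirichlet
    concentrations used when weight uncertainty is sampled."""

    names: list[str]
    values: np.ndarray
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("one weight per indicator")
        if (self.values < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 (use from_raw to auto-normalize)")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)
            if (self.alpha <= 0).any():
                raise ValueError("Dirichlet concentrations must be positive")

    @classmethod
    def from_raw(cls, names: list[str], raw: np.ndarray) -> "WeightVector":
        raw = np.asarray(raw, dtype=float)
        if (raw < 0).any() or raw.sum() <= 0:
            raise ValueError("raw weights must be nonnegative with positive sum")
        return cls(list(names), raw / raw.sum())

    @classmethod
    def equal(cls, names: list[str]) -> "WeightVector":
        k = len(names)
        return cls(list(names), np.full(k, 1.0 / k))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass(frozen=True)
class CompositeConfig:
    """Composite mode and its decision parameters.

    ``tau`` is the standardized risk threshold used for exceedance
    probabilities and ``top_k`` the rank cutoff for Pr(Top-K).
    """

    mode: str = "linear"
    lam: float = 2.0
    shift: float = 3.0
    tau: float = 1.5
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "softmax", "geomean"):
            raise ValueError(f"unknown composite mode {self.mode!r}")
        if self.mode == "softmax" and self.lam <= 0:
            raise ValueError("softmax sharpness lambda must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def compose(
    z_std: np.ndarray, w: np.ndarray, cfg: CompositeConfig
) -> np.ndarray:
    """Per-site, per-draw composite score.

    ``z_std`` is (K, S, M); ``w`` is either a fixed simplex vector (K,)
    or per-draw weights (M, K) paired 1:1 with score draws.
    """
    z = np.asarray(z_std, dtype=float)
    if z.ndim != 3:
        raise ValueError("z_std must be (n_indicators, n_sites, n_draws)")
    k, s, m = z.shape
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        if w.size != k:
            raise ValueError("weight length must equal indicator count")
        wz = w[:, None, None] * z
    elif w.ndim == 2:
        if w.shape != (m, k):
            raise ValueError("per-draw weights must be (n_draws, n_indicators)")
        wz = w.T[:, None, :] * z
    else:
        raise ValueError("weights must be a vector or a draws x indicators matrix")

    if cfg.mode == "linear":
        return wz.sum(axis=0)
    if cfg.mode == "softmax":
        return logsumexp(cfg.lam * wz, axis=0) / cfg.lam
    # geometric mean: prod_k (c + z_k)^{w_k} - c on each draw
    base = cfg.shift + z
    if (base <= 0).any():
        bad = np.argwhere(base <= 0)[0]
        raise ValueError(
            f"geomean shift c={cfg.shift} too small: c + z <= 0 for indicator "
            f"{bad[0]}, site {bad[1]}, draw {bad[2]}"
        )
    if w.ndim == 1:
        logg = (w[:, None, None] * np.log(base)).sum(axis=0)
    else:
        logg = (w.T[:, None, :] * np.log(base)).sum(axis=0)
    return np.exp(logg) - cfg.shift


def sample_weights(
    alpha: np.ndarray, n_draws: int, seed: int | np.random.Generator
) -> np.ndarray:
    """``n_draws`` weight vectors from Dirichlet(alpha), (M, K)."""
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise ValueError("Dirichlet concentrations must be positive")
    rng = substream(seed) if isinstance(seed, (int, np.integer)) else seed
    return rng.dirichlet(alpha, size=n_draws)


def entropy_weights(anchor_means: pd.DataFrame) -> WeightVector:
    """Dispersion-proportional weights: each indicator is weighted by
    the MAD of its site anchors, normalized to the simplex, so
    indicators that actually separate sites carry the score."""
    if len(anchor_means) < 2:
        raise ValueError("dispersion weights need at least 2 sites")
    disp = np.array([_mad(anchor_means[c].to_numpy(dtype=float)) for c in anchor_means.columns])
    if disp.sum() == 0:
        warnings.warn("all indicators constant across sites; falling back to uniform weights")
        return WeightVector.equal(list(anchor_means.columns))
    return WeightVector(list(anchor_means.columns), disp / disp.sum())


@dataclass
class CompositeResult:
    """Posterior summaries of the composite score per site."""

    sites: list[str]
    s_draws: np.ndarray  # (S, M)
    mean: pd.Series = field(init=False)
    cri_lo: pd.Series = field(init=False)
    cri_hi: pd.Series = field(init=False)
    pr_exceed: pd.Series = field(init=False)
    pr_topk: pd.Series = field(init=False)
    rank_draws: np.ndarray = field(init=False)  # (S, M), 1 = highest risk
    rank: pd.Series = field(init=False)
    tau: float = 1.5
    top_k: int = 5
    contributions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.s_draws, dtype=float)
        if s.ndim != 2 or s.shape[0] != len(self.sites):
            raise ValueError("s_draws must be (n_sites, n_draws)")
        idx = pd.Index(self.sites, name="site")
        self.mean = pd.Series(s.mean(axis=1), index=idx, name="mean_S")
        lo, hi = np.percentile(s, [2.5, 97.5], axis=1)
        self.cri_lo = pd.Series(lo, index=idx, name="cri_lo")
        self.cri_hi = pd.Series(hi, index=idx, name="cri_hi")
        self.pr_exceed = pd.Series((s > self.tau).mean(axis=1), index=idx, name="pr_exceed")
        # per-draw descending ranks; ties broken by site order (stable sort)
        order = np.argsort(-s, axis=0, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(1, s.shape[0] + 1)[:, None], axis=0)
        self.rank_draws = ranks
        k = min(self.top_k, s.shape[0])
        self.pr_topk = pd.Series((ranks <= k).mean(axis=1), index=idx, name="pr_topk")
        mean_order = np.lexsort((np.arange(len(idx)), -self.mean.to_numpy()))
        r = np.empty(len(idx), dtype=int)
        r[mean_order] = np.arange(1, len(idx) + 1)
        self.rank = pd.Series(r, index=idx, name="rank")

    @property
    def n_draws(self) -> int:
        return self.s_draws.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.mean, self.cri_lo, self.cri_hi, self.pr_exceed, self.pr_topk, self.rank],
            axis=1,
        ).reset_index()


def summarize(
    s_draws: np.ndarray,
    sites: list[str],
    cfg: CompositeConfig,
    contributions: pd.DataFrame | None = None,
) -> CompositeResult:
    """Posterior mean, equal-tailed 95% CrI, exceedance and Top-K
    probabilities from per-site composite draws."""
    s_draws = np.asarray(s_draws, dtype=float)
    if s_draws.shape[1] < 100:
        raise ValueError("need at least 100 draws to summarize")
    return CompositeResult(
        list(sites), s_draws, tau=cfg.tau, top_k=cfg.top_k, contributions=contributions
    )
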