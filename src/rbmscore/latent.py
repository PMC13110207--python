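"""One-factor Bayesian hierarchical model of latent site risk.

A single latent continuous risk ``R_s ~ N(0, 1)`` per site co-varies
with all indicators through generalized linear layers:

* binomial indicators: ``logit(pi_ks) = b_k0 + b_k R_s + eps_ks`` with
  ``eps_ks ~ N(0, sigma_k_pi^2)`` and ``y_ks ~ Binomial(n_ks, pi_ks)``;
* normal indicators (site-level log-times or log-distances):
  ``x_ks ~ N(mu_ks, sigma_k_obs^2)`` with
  ``mu_ks ~ N(g_k0 + g_k R_s, sigma_k_mu^2)``;
* Bernoulli indicators (drift flags): ``logit(psi_ks) = d_k0 + d_k R_s``
  with no residual term.

Loadings are constrained nonnegative (half-Normal(0,1) priors) so that
higher ``R_s`` always means higher risk — with that constraint there is
no sign-flip ambiguity, and the N(0,1) prior on ``R_s`` pins location
and scale. Intercepts get Normal(0, 5^2) priors and scales
Half-Cauchy(0, 1).

Inference is adaptive Metropolis-within-Gibbs: latent site blocks are
updated by vectorized random-walk MH in parallel across sites (their
full conditionals are independent given the hyperparameters);
normal-layer means, intercepts and loadings are Gibbs-updated from
their conjugate conditionals (the half-Normal loading prior gives a
truncated-normal conditional); scales use the inverse-gamma
auxiliary-variable representation of the Half-Cauchy prior; and two
joint "sweep" moves travel along the soft identifiability ridges
(location: shift all R_s against the intercepts; scale: rescale R_s
against the loadings), without which those directions mix poorly.
Bernoulli-layer coefficients, which lack conjugacy, use adaptive
random-walk proposals — log-scale for the loading, with the half-Normal
prior applied through the change of variables. The sampler interface is
deliberately modular so a gradient-based sampler could be swapped in
without changing any downstream scoring logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composite import CompositeConfig, CompositeResult, WeightVector, compose, summarize

__all__ = [
    "IndicatorData",
    "LatentFactorModel",
    "LatentFactorResults",
    "McmcConfig",
    "fit_one_factor",
    "bayes_composite",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class IndicatorData:
    """Per-site observations for one indicator.

    family 'binomial': ``y`` successes out of ``n`` per site;
    family 'normal': one real observation per site (e.g. median log
    screening time) in ``y``;
    family 'bernoulli': binary flag per site in ``y``.
    """

    name: str
    family: str
    y: np.ndarray
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.family not in ("binomial", "normal", "bernoulli"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial":
            if self.n is None:
                raise ValueError("binomial indicators need denominators")
            object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
            if np.any(self.y < 0) or np.any(self.y > self.n):
                raise ValueError("need 0 <= y <= n")
        if self.family == "bernoulli" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("bernoulli observations must be 0/1")


@dataclass(frozen=True)
class McmcConfig:
    """Chains, iteration counts and seed for the sampler."""

    chains: int = 2
    iterations: int = 3000
    warmup: int = 1500
    seed: int = 0
    initial_step: float = 0.5

    def __post_init__(self) -> None:
        if not self.iterations > self.warmup >= 0:
            raise ValueError("need iterations > warmup >= 0")
        if self.chains < 1:
            raise ValueError("need at least 1 chain")


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _binom_loglik(y, n, eta):
    # up to the binomial coefficient, which cancels in MH ratios
    return y * _log_sigmoid(eta) + (n - y) * _log_sigmoid(-eta)


def _norm_logpdf(x, mu, sd):
    return -_HALF_LOG_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


class _Adapt:
    """Windowed step-size adaptation toward a target acceptance rate."""

    def __init__(self, step: float, target: float):
        self.step = step
        self.target = target
        self.accepted = 0.0
        self.tried = 0

    def update(self) -> None:
        if self.tried >= 50:
            rate = self.accepted / self.tried
            self.step *= float(np.exp(np.clip(rate - self.target, -0.5, 0.5)))
            self.step = float(np.clip(self.step, 1e-3, 10.0))
            self.accepted = 0.0
            self.tried = 0


class LatentFactorModel:
    """One-factor model over a list of :class:`IndicatorData` blocks."""

    def __init__(self, sites: list[str], indicators: list[IndicatorData]):
        if len(indicators) < 2:
            raise ValueError("need at least two indicators with data")
        if len(sites) < 5:
            raise ValueError("need at least 5 sites to identify latent risk")
        s = len(sites)
        for ind in indicators:
            if ind.y.shape[0] != s:
                raise ValueError(f"indicator {ind.name!r} does not cover all sites")
        self.sites = list(sites)
        self.indicators = indicators

    # -- one chain ----------------------------------------------------
    def _run_chain(self, cfg: McmcConfig, chain_seed: np.random.SeedSequence):
        rng = np.random.default_rng(chain_seed)
        s = len(self.sites)
        kept = cfg.iterations - cfg.warmup

        binom = [k for k in self.indicators if k.family == "binomial"]
        norm = [k for k in self.indicators if k.family == "normal"]
        bern = [k for k in self.indicators if k.family == "bernoulli"]

        # state
        R = rng.normal(0, 1, s)
        st = {
            "binom": [
                dict(eta=np.zeros(s) + np.log((k.y + 0.5) / (k.n - k.y + 0.5)),
                     b0=0.0, load=0.5, sig=0.5)
                for k in binom
            ],
            "norm": [
                dict(mu=k.y.copy(), g0=float(np.mean(k.y)), load=0.5, sig_obs=0.5, sig_mu=0.5)
                for k in norm
            ],
            "bern": [dict(d0=0.0, load=0.5) for _ in bern],
        }

        adapts: dict[str, _Adapt] = {}
        aux: dict[str, float] = {}  # Half-Cauchy auxiliary variables

        def adapt(key, target=0.44):
            if key not in adapts:
                adapts[key] = _Adapt(cfg.initial_step, target)
            return adapts[key]

        def bern_loglik_R(Rv):
            total = np.zeros_like(Rv)
            for k, p in zip(bern, st["bern"]):
                eta = p["d0"] + p["load"] * Rv
                total += k.y * _log_sigmoid(eta) + (1 - k.y) * _log_sigmoid(-eta)
            return total

        traces = {
            "R": np.empty((kept, s)),
        }
        for k in binom:
            traces[f"eta::{k.name}"] = np.empty((kept, s))
            for h in ("b0", "load", "sig"):
                traces[f"{h}::{k.name}"] = np.empty(kept)
        for k in norm:
            traces[f"mu::{k.name}"] = np.empty((kept, s))
            for h in ("g0", "load", "sig_obs", "sig_mu"):
                traces[f"{h}::{k.name}"] = np.empty(kept)
        for k in bern:
            for h in ("d0", "load"):
                traces[f"{h}::{k.name}"] = np.empty(kept)

        for it in range(cfg.iterations):
            warm = it < cfg.warmup

            # --- latent risk, all sites in parallel -------------------
            a = adapt("R", 0.30)
            prop = R + rng.normal(0, a.step, s)
            logr = -0.5 * (prop**2 - R**2)
            for k, p in zip(binom, st["binom"]):
                m_new = p["b0"] + p["load"] * prop
                m_old = p["b0"] + p["load"] * R
                logr += _norm_logpdf(p["eta"], m_new, p["sig"]) - _norm_logpdf(p["eta"], m_old, p["sig"])
            for k, p in zip(norm, st["norm"]):
                m_new = p["g0"] + p["load"] * prop
                m_old = p["g0"] + p["load"] * R
                logr += _norm_logpdf(p["mu"], m_new, p["sig_mu"]) - _norm_logpdf(p["mu"], m_old, p["sig_mu"])
            if bern:
                logr += bern_loglik_R(prop) - bern_loglik_R(R)
            acc = np.log(rng.random(s)) < logr
            R = np.where(acc, prop, R)
            if warm:
                a.accepted += float(acc.mean())
                a.tried += 1
                a.update()

            # --- joint sweeps along the soft identifiability ridges ----
            # location: R -> R + delta with compensating intercept shifts
            # leaves every likelihood term unchanged; only priors decide.
            layers = st["binom"] + st["norm"] + st["bern"]
            ikeys = ["b0"] * len(st["binom"]) + ["g0"] * len(st["norm"]) + ["d0"] * len(st["bern"])
            a = adapt("loc_sweep")
            delta = rng.normal(0, a.step)
            logr = -0.5 * (np.sum((R + delta) ** 2) - np.sum(R * R))
            for p, ik in zip(layers, ikeys):
                new_i = p[ik] - p["load"] * delta
                logr += (p[ik] ** 2 - new_i**2) / 50.0
            ok = np.log(rng.random()) < logr
            if ok:
                for p, ik in zip(layers, ikeys):
                    p[ik] = p[ik] - p["load"] * delta
                R = R + delta
            if warm:
                a.accepted += float(ok)
                a.tried += 1
                a.update()

            # scale: R -> c R, loadings -> loadings / c (likelihoods of
            # the linear layers unchanged; priors + Jacobian decide)
            a = adapt("scale_sweep")
            logc = rng.normal(0, a.step)
            c = float(np.exp(logc))
            logr = -0.5 * (c**2 - 1.0) * float(np.sum(R * R))
            for p in layers:
                logr += -0.5 * ((p["load"] / c) ** 2 - p["load"] ** 2)
            logr += (s - len(layers)) * logc
            ok = np.log(rng.random()) < logr
            if ok:
                R = c * R
                for p in layers:
                    p["load"] = p["load"] / c
            if warm:
                a.accepted += float(ok)
                a.tried += 1
                a.update()

            # --- binomial latent logits, sites in parallel ------------
            for k, p in zip(binom, st["binom"]):
                a = adapt(f"eta::{k.name}", 0.30)
                eta, mean = p["eta"], p["b0"] + p["load"] * R
                prop = eta + rng.normal(0, a.step, s)
                logr = (
                    _binom_loglik(k.y, k.n, prop) - _binom_loglik(k.y, k.n, eta)
                    + _norm_logpdf(prop, mean, p["sig"]) - _norm_logpdf(eta, mean, p["sig"])
                )
                acc = np.log(rng.random(s)) < logr
                p["eta"] = np.where(acc, prop, eta)
                if warm:
                    a.accepted += float(acc.mean())
                    a.tried += 1
                    a.update()

            # --- normal latent means: conjugate Gibbs -----------------
            for k, p in zip(norm, st["norm"]):
                prec = 1.0 / p["sig_obs"] ** 2 + 1.0 / p["sig_mu"] ** 2
                mean = (k.y / p["sig_obs"] ** 2 + (p["g0"] + p["load"] * R) / p["sig_mu"] ** 2) / prec
                p["mu"] = rng.normal(mean, np.sqrt(1.0 / prec))

            # --- hyperparameters: scalar random-walk MH ---------------
            def mh_scalar(key, cur, logpost, step_target=0.44):
                a = adapt(key, step_target)
                prop = cur + rng.normal(0, a.step)
                logr = logpost(prop) - logpost(cur)
                ok = np.log(rng.random()) < logr
                if warm:
                    a.accepted += float(ok)
                    a.tried += 1
                    a.update()
                return (prop if ok else cur)

            def gibbs_intercept(resid, sig):
                # Normal(0, 5^2) prior, Gaussian likelihood on the residuals
                prec = resid.size / sig**2 + 1.0 / 25.0
                mean = np.sum(resid) / sig**2 / prec
                return float(rng.normal(mean, np.sqrt(1.0 / prec)))

            def gibbs_loading(target, sig):
                # half-Normal(0,1) prior x Gaussian regression likelihood
                # => truncated-normal conditional on [0, inf)
                prec = np.sum(R * R) / sig**2 + 1.0
                mean = np.sum(R * target) / sig**2 / prec
                sd = np.sqrt(1.0 / prec)
                lo = (0.0 - mean) / sd
                return float(stats.truncnorm.rvs(lo, np.inf, loc=mean, scale=sd, random_state=rng))

            def gibbs_scale(resid, aux_key):
                # Half-Cauchy(0,1) via the inverse-gamma auxiliary trick:
                # sig^2 | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1)
                a = aux.setdefault(aux_key, 1.0)
                shape = 0.5 * (resid.size + 1.0)
                rate = 1.0 / a + 0.5 * float(np.sum(resid * resid))
                sig2 = rate / rng.gamma(shape)
                aux[aux_key] = (1.0 + 1.0 / sig2) / rng.gamma(1.0)
                return float(np.sqrt(sig2))

            for k, p in zip(binom, st["binom"]):
                p["b0"] = gibbs_intercept(p["eta"] - p["load"] * R, p["sig"])
                p["load"] = gibbs_loading(p["eta"] - p["b0"], p["sig"])
                p["sig"] = gibbs_scale(p["eta"] - p["b0"] - p["load"] * R, f"sig::{k.name}")

            for k, p in zip(norm, st["norm"]):
                p["g0"] = gibbs_intercept(p["mu"] - p["load"] * R, p["sig_mu"])
                p["load"] = gibbs_loading(p["mu"] - p["g0"], p["sig_mu"])
                p["sig_mu"] = gibbs_scale(p["mu"] - p["g0"] - p["load"] * R, f"sigmu::{k.name}")
                p["sig_obs"] = gibbs_scale(k.y - p["mu"], f"sigobs::{k.name}")

            for k, p in zip(bern, st["bern"]):
                def bern_ll(d0, load):
                    eta = d0 + load * R
                    return float(np.sum(k.y * _log_sigmoid(eta) + (1 - k.y) * _log_sigmoid(-eta)))

                p["d0"] = mh_scalar(
                    f"d0::{k.name}", p["d0"],
                    lambda v: bern_ll(v, p["load"]) - v**2 / 50.0,
                )
                p["load"] = float(np.exp(mh_scalar(
                    f"loadb::{k.name}", np.log(p["load"]),
                    lambda lv: bern_ll(p["d0"], np.exp(lv)) - 0.5 * np.exp(lv) ** 2 + lv,
                )))

            if not warm:
                j = it - cfg.warmup
                traces["R"][j] = R
                for k, p in zip(binom, st["binom"]):
                    traces[f"eta::{k.name}"][j] = p["eta"]
                    traces[f"b0::{k.name}"][j] = p["b0"]
                    traces[f"load::{k.name}"][j] = p["load"]
                    traces[f"sig::{k.name}"][j] = p["sig"]
                for k, p in zip(norm, st["norm"]):
                    traces[f"mu::{k.name}"][j] = p["mu"]
                    traces[f"g0::{k.name}"][j] = p["g0"]
                    traces[f"load::{k.name}"][j] = p["load"]
                    traces[f"sig_obs::{k.name}"][j] = p["sig_obs"]
                    traces[f"sig_mu::{k.name}"][j] = p["sig_mu"]
                for k, p in zip(bern, st["bern"]):
                    traces[f"d0::{k.name}"][j] = p["d0"]
                    traces[f"load::{k.name}"][j] = p["load"]
        return traces

    def fit(self, mcmc: McmcConfig | None = None) -> "LatentFactorResults":
        """Run the chains and assemble posterior draws with split-R-hat
        and effective-sample-size diagnostics."""
        mcmc = mcmc or McmcConfig()
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
        chains = [self._run_chain(mcmc, sd) for sd in seeds]
        draws = {
            key: np.stack([c[key] for c in chains]) for key in chains[0]
        }  # (chain, draw[, site])
        rhat, ess = _diagnostics(draws)
        converged = bool(np.nanmax(list(rhat.values())) <= 1.1) if mcmc.chains >= 2 else True
        if mcmc.chains < 2:
            warnings.warn("single-chain run: split-R-hat diagnostics unavailable")
        if not converged:
            worst = max(rhat, key=rhat.get)
            warnings.warn(
                f"MCMC did not converge: max split-R-hat {rhat[worst]:.3f} ({worst}); "
                "interpret posteriors with caution"
            )
        return LatentFactorResults(self, mcmc, draws, rhat, ess, converged)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat for one scalar parameter, x is (chain, draw)."""
    c, n = x.shape
    if n < 4:
        return float("nan")
    half = n // 2
    segs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, nn = segs.shape
    means = segs.mean(axis=1)
    b = nn * np.var(means, ddof=1)
    w = np.mean(np.var(segs, axis=1, ddof=1))
    if w == 0:
        return 1.0
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


def _ess(x: np.ndarray) -> float:
    """Crude bulk ESS from pooled autocorrelations (Geyer pairs)."""
    c, n = x.shape
    if n < 8:
        return float(c * n)
    acs = []
    for ch in x:
        ch = ch - ch.mean()
        denom = np.sum(ch * ch)
        if denom == 0:
            return float(c * n)
        ac = np.correlate(ch, ch, "full")[n - 1 :] / denom
        acs.append(ac)
    rho = np.mean(acs, axis=0)
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(c * n / tau)


def _diagnostics(draws: dict[str, np.ndarray]):
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for key, arr in draws.items():
        if arr.ndim == 2:  # scalar param: (chain, draw)
            rhat[key] = _split_rhat(arr)
            ess[key] = _ess(arr)
        else:  # per-site: (chain, draw, site)
            rh = [_split_rhat(arr[:, :, j]) for j in range(arr.shape[2])]
            es = [_ess(arr[:, :, j]) for j in range(arr.shape[2])]
            rhat[key] = float(np.nanmax(rh))
            ess[key] = float(np.nanmin(es))
    return rhat, ess


@dataclass
class LatentFactorResults:
    """Posterior draws of the one-factor model with diagnostics."""

    model: LatentFactorModel
    mcmc: McmcConfig
    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    def posterior_R(self) -> pd.DataFrame:
        arr = self.draws["R"].reshape(-1, len(self.model.sites))
        return pd.DataFrame(
            {
                "site": self.model.sites,
                "mean": arr.mean(axis=0),
                "sd": arr.std(axis=0, ddof=1),
                "cri_lo": np.percentile(arr, 2.5, axis=0),
                "cri_hi": np.percentile(arr, 97.5, axis=0),
            }
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.rhat):
            rows.append((key, self.rhat[key], self.ess[key]))
        return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])

    def z_star_draws(self) -> tuple[list[str], np.ndarray]:
        """Risk-aligned latent contributions per indicator.

        ``logit(pi_ks)`` (= eta) for binomial indicators, ``mu_ks`` for
        normal ones, and ``d_k0 + d_k R_s`` for Bernoulli drift layers.
        Returns (names, array of shape (K, S, M_total)).
        """
        s = len(self.model.sites)
        names, mats = [], []
        for ind in self.model.indicators:
            if ind.family == "binomial":
                arr = self.draws[f"eta::{ind.name}"].reshape(-1, s).T
            elif ind.family == "normal":
                arr = self.draws[f"mu::{ind.name}"].reshape(-1, s).T
            else:
                d0 = self.draws[f"d0::{ind.name}"].reshape(-1)
                load = self.draws[f"load::{ind.name}"].reshape(-1)
                r = self.draws["R"].reshape(-1, s)
                arr = (d0[:, None] + load[:, None] * r).T
            names.append(ind.name)
            mats.append(arr)
        return names, np.stack(mats)

    def bayes_composite(
        self,
        weights: WeightVector | np.ndarray | None = None,
        cfg: CompositeConfig | None = None,
    ) -> CompositeResult:
        """Posterior composite from the latent-factor draws."""
        names, z = self.z_star_draws()
        w = WeightVector.equal(names) if weights is None else weights
        w_arr = w.values if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
        return bayes_composite(z, self.model.sites, w_arr, cfg=cfg)


def bayes_composite(
    z_star: np.ndarray,
    sites: list[str],
    weights: np.ndarray,
    trial_centers: np.ndarray | None = None,
    trial_scales: np.ndarray | None = None,
    cfg: CompositeConfig | None = None,
) -> CompositeResult:
    """Weighted composite of robustly standardized latent contributions.

    Trial-level centers/scales default to the median and 1.4826 x MAD of
    the site-level posterior means of each ``Z*`` — robust trial-level
    posterior anchors mirroring Stage 2.
    """
    z = np.asarray(z_star, dtype=float)
    k, s, m = z.shape
    site_means = z.mean(axis=2)  # (K, S)
    if trial_centers is None:
        trial_centers = np.median(site_means, axis=1)
    if trial_scales is None:
        mad = np.median(np.abs(site_means - trial_centers[:, None]), axis=1)
        trial_scales = 1.4826 * mad
        sd = np.std(site_means, axis=1, ddof=1)
        trial_scales = np.where(trial_scales > 0, trial_scales, np.where(sd > 0, sd, 1.0))
    trial_centers = np.asarray(trial_centers, dtype=float)
    trial_scales = np.asarray(trial_scales, dtype=float)
    if trial_centers.shape != (k,) or trial_scales.shape != (k,):
        raise ValueError("need one trial center and scale per indicator")
    z_std = (z - trial_centers[:, None, None]) / trial_scales[:, None, None]
    cfg = cfg or CompositeConfig()
    s_draws = compose(z_std, np.asarray(weights, dtype=float), cfg)
    return summarize(s_draws, sites, cfg)


def fit_one_factor(
    sites: list[str],
    indicators: list[IndicatorData],
    mcmc: McmcConfig | None = None,
) -> LatentFactorResults:
    """Functional wrapper: build the model and fit it."""
    return LatentFactorModel(sites, indicators).fit(mcmc)
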