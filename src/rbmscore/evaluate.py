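"""Monte-Carlo operating characteristics of the composite score.

Each replicate simulates a trial, runs the full pipeline (indicators ->
Stage 1 posteriors -> robust standardization -> composite), classifies
sites at a standardized risk threshold, and scores the classification
against the known atypical labels. Sensitivity, specificity and FDR are
averaged over replicates with Monte-Carlo standard errors; ranking
stability is the mean pairwise Spearman correlation of posterior-mean
rankings across replicates that share one fixed site configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composite import CompositeConfig, WeightVector
from .model import CompositeRiskModel
from .simulate import TrialConfig, draw_site_profiles, simulate_from_profiles, simulate_trial

__all__ = [
    "EvaluationConfig",
    "EvaluationMetrics",
    "classification_metrics",
    "rank_stability",
    "run_replicates",
]


@dataclass(frozen=True)
class EvaluationConfig:
    """Replication settings for the Monte-Carlo harness.

    ``rule`` selects the classification rule at threshold ``tau``:
    ``posterior_mean`` thresholds E[S_s]; ``exceedance`` thresholds
    Pr(S_s > tau) at confidence ``p_star``. ``fixed_config`` holds one
    drawn site configuration fixed and redraws only participant data,
    which is what ranking-stability runs need.
    """

    n_replicates: int = 500
    n_draws: int = 1000
    tau: float = 1.5
    rule: str = "posterior_mean"
    p_star: float = 0.8
    fixed_config: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.rule not in ("posterior_mean", "exceedance"):
            raise ValueError(f"unknown classification rule {self.rule!r}")


def classification_metrics(
    flagged: set | list, truth: pd.Series | dict
) -> tuple[float, float, float]:
    """(sensitivity, specificity, FDR) of a flag set against truth.

    Sensitivity is NaN when there are no true positives to find; the
    FDR of an empty flag set is 0 by convention.
    """
    truth = pd.Series(truth).astype(bool)
    flagged = set(flagged)
    unknown = flagged - set(truth.index)
    if unknown:
        raise KeyError(f"flagged site(s) absent from truth: {sorted(unknown)}")
    is_flagged = truth.index.isin(flagged)
    tp = int((is_flagged & truth).sum())
    fp = int((is_flagged & ~truth).sum())
    fn = int((~is_flagged & truth).sum())
    tn = int((~is_flagged & ~truth).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    fdr = fp / max(tp + fp, 1)
    return sens, spec, fdr


def rank_stability(score_vectors: list[pd.Series]) -> float:
    """Mean pairwise Spearman rank correlation over replicate score
    vectors sharing one site set (ties get average ranks)."""
    if len(score_vectors) < 2:
        raise ValueError("need at least 2 replicates")
    base = score_vectors[0].index
    for v in score_vectors[1:]:
        if not base.equals(v.index):
            raise ValueError("replicates must cover identical site sets in the same order")
    mat = np.column_stack([v.to_numpy(dtype=float) for v in score_vectors])
    rho = stats.spearmanr(mat).statistic
    if np.isscalar(rho):  # exactly two replicates
        return float(rho)
    iu = np.triu_indices_from(rho, k=1)
    return float(np.mean(rho[iu]))


@dataclass
class EvaluationMetrics:
    """Aggregated operating characteristics with MC standard errors."""

    sensitivity: float
    specificity: float
    fdr: float
    sensitivity_se: float
    specificity_se: float
    fdr_se: float
    spearman: float | None
    top_rank_accuracy: float | None
    n_replicates: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sensitivity", self.sensitivity, self.sensitivity_se),
            ("specificity", self.specificity, self.specificity_se),
            ("fdr", self.fdr, self.fdr_se),
        ]
        if self.spearman is not None:
            rows.append(("spearman", self.spearman, np.nan))
        if self.top_rank_accuracy is not None:
            rows.append(("top_rank_accuracy", self.top_rank_accuracy, np.nan))
        return pd.DataFrame(rows, columns=["metric", "value", "mc_se"])


def _se(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def run_replicates(
    trial_cfg: TrialConfig,
    eval_cfg: EvaluationConfig,
    composite_cfg: CompositeConfig | None = None,
    weights: WeightVector | None = None,
    progress: bool = False,
) -> EvaluationMetrics:
    """Simulate -> score -> classify over Monte-Carlo replicates.

    With ``fixed_config`` the site configuration is drawn once from the
    evaluation seed and only participant-level data are redrawn, and the
    Spearman ranking stability across replicate pairs is reported.
    """
    composite_cfg = composite_cfg or CompositeConfig(tau=eval_cfg.tau)
    root = np.random.SeedSequence(eval_cfg.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(eval_cfg.n_replicates)]
    profiles = draw_site_profiles(trial_cfg, eval_cfg.seed) if eval_cfg.fixed_config else None

    rows = []
    score_vectors: list[pd.Series] = []
    for r, rs in enumerate(rep_seeds):
        try:
            if profiles is not None:
                dataset = simulate_from_profiles(profiles, trial_cfg, rs)
            else:
                dataset = simulate_trial(trial_cfg, rs)
            model = CompositeRiskModel.from_dataset(
                dataset, composite=composite_cfg, weights=weights
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(draws=eval_cfg.n_draws, seed=rs)
            flagged = res.classify(eval_cfg.tau, rule=eval_cfg.rule, p_star=eval_cfg.p_star)
            truth = dataset.truth_labels()
            sens, spec, fdr = classification_metrics(flagged, truth)
            n_true = int(truth.sum())
            if n_true:
                top = res.summary().head(2 * n_true)["site"]
                all_in_top = bool(truth[truth].index.isin(top).all())
            else:
                all_in_top = np.nan
            rows.append((r, rs, sens, spec, fdr, len(flagged), all_in_top))
            score_vectors.append(res.mean_score.sort_index())
        except Exception as exc:
            raise RuntimeError(f"replicate {r} (seed {rs}) failed: {exc}") from exc
        if progress and (r + 1) % 25 == 0:
            print(f"  replicate {r + 1}/{eval_cfg.n_replicates}")

    rep = pd.DataFrame(
        rows,
        columns=["replicate", "seed", "sensitivity", "specificity", "fdr", "n_flagged", "all_atypical_in_top"],
    )
    spearman = None
    if eval_cfg.fixed_config:
        common = score_vectors[0].index
        for v in score_vectors[1:]:
            common = common.intersection(v.index)
        if len(common) < len(score_vectors[0]):
            warnings.warn("some sites unscored in some replicates; stability on common sites")
        spearman = rank_stability([v.loc[common] for v in score_vectors])

    sens = rep["sensitivity"].to_numpy(dtype=float)
    spec = rep["specificity"].to_numpy(dtype=float)
    fdr = rep["fdr"].to_numpy(dtype=float)
    top_acc = rep["all_atypical_in_top"].astype(float)
    return EvaluationMetrics(
        sensitivity=float(np.nanmean(sens)) if not np.all(np.isnan(sens)) else float("nan"),
        specificity=float(np.nanmean(spec)),
        fdr=float(np.nanmean(fdr)),
        sensitivity_se=_se(sens),
        specificity_se=_se(spec),
        fdr_se=_se(fdr),
        spearman=spearman,
        top_rank_accuracy=float(top_acc.mean()) if top_acc.notna().any() else None,
        n_replicates=eval_cfg.n_replicates,
        replicates=rep,
    )
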