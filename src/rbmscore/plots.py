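"""Static decision-support graphics for fitted composite risk scores.

Mirrors the three core monitoring views: a forest plot of posterior
mean composite scores with 95% credible intervals (who is high risk and
how certain the ordering is), a site x component heatmap of weighted
contributions (which indicators drive risk where), and per-site driver
bars (what to act on at one site).
"""

from __future__ import annotations

import numpy as np

__all__ = ["forest", "contribution_heatmap", "driver_bars"]


def _get_ax(ax, figsize):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=figsize)
    return ax


def forest(results, ax=None, max_sites: int = 50):
    """Posterior mean composite with 95% CrI, ordered by rank."""
    summ = results.summary().head(max_sites).iloc[::-1]
    ax = _get_ax(ax, (6, 0.25 * len(summ) + 1))
    y = np.arange(len(summ))
    ax.errorbar(
        summ["mean_S"], y,
        xerr=[summ["mean_S"] - summ["cri_lo"], summ["cri_hi"] - summ["mean_S"]],
        fmt="o", color="tab:blue", ecolor="0.6", capsize=2, markersize=3,
    )
    ax.axvline(results.result.tau, color="tab:red", lw=0.8, ls="--",
               label=f"tau = {results.result.tau:g}")
    ax.set_yticks(y, summ["site"])
    ax.set_xlabel("composite risk score S (posterior mean, 95% CrI)")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def contribution_heatmap(results, ax=None):
    """Weighted component contributions, diverging scale centered at 0."""
    contrib = results.result.contributions
    if contrib is None:
        raise ValueError("results carry no contribution table")
    order = results.result.rank.sort_values().index
    mat = contrib.loc[order]
    ax = _get_ax(ax, (6, 0.18 * len(mat) + 1.5))
    vmax = float(np.abs(mat.to_numpy()).max()) or 1.0
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="weighted contribution w_k z")
    return ax


def driver_bars(results, site: str, ax=None):
    """Component contributions for one site, ordered by absolute impact."""
    contrib = results.result.contributions
    if contrib is None or site not in contrib.index:
        raise KeyError(f"no contributions for site {site!r}")
    row = contrib.loc[site].sort_values(key=np.abs)
    ax = _get_ax(ax, (5, 2.5))
    colors = ["tab:red" if v > 0 else "tab:blue" for v in row]
    ax.barh(row.index, row.to_numpy(), color=colors)
    for i, v in enumerate(row):
        ax.text(v, i, f" {v:.2f}", va="center", fontsize=7)
    ax.axvline(0, color="0.3", lw=0.8)
    ax.set_xlabel(f"contribution to S at {site}")
    return ax
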