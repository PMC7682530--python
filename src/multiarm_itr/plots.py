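"""Optional report figures (headless matplotlib).

Two analogs of the standard application displays: mean ITR effect versus the
utility trade-off parameter b with across-split bands, and posterior densities
of the ITR effect for competing donor-assignment rules.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_effect_vs_b", "plot_posterior_effect_densities"]


def plot_effect_vs_b(table: pd.DataFrame, outcome: str = "utility", path=None):
    """Mean ITR effect vs b per method, with +/- 2 SD across-split bands.

    Expects the tidy application table (rows with target == 'utility').
    """
    ut = table[table["target"] == "utility"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in ut.groupby("method"):
        grp = grp.sort_values("b")
        mean = grp[f"effect_{outcome}_mean"]
        sd = grp[f"effect_{outcome}_sd"]
        ax.plot(grp["b"], mean, marker="o", label=method)
        ax.fill_between(grp["b"], mean - 2 * sd, mean + 2 * sd, alpha=0.15)
    ax.set_xlabel("trade-off parameter b")
    ax.set_ylabel(f"ITR effect on {outcome}")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_posterior_effect_densities(effects_by_rule: dict[str, np.ndarray], path=None):
    """Kernel-free density display (histogram) of per-draw ITR effects per rule."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, eff in effects_by_rule.items():
        ax.hist(np.asarray(eff), bins=40, density=True, histtype="step", label=name)
    ax.set_xlabel("ITR effect")
    ax.set_ylabel("posterior density")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
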