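"""Minimal figures: enrichment running-sum plots and Kaplan–Meier curves."""

from __future__ import annotations

from typing import TYPE_CHECKING, Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import EnrichmentResult
    from .outcomes import SurvivalCurve

__all__ = ["plot_running_sum", "plot_km"]


def plot_running_sum(result: "EnrichmentResult", ax=None):
    """Classic enrichment plot: running sum with the ES marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    n = len(result.running_sum)
    ax.plot(range(1, n + 1), result.running_sum, color="tab:green", lw=1.5)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("gene rank")
    ax.set_ylabel("running enrichment score")
    ax.set_title(
        f"{result.signature_name} in {result.contrast}: "
        f"ES={result.es:.3f}, NES={result.nes:.2f}, p={result.p_perm:.3g}"
    )
    return ax


def plot_km(curves: Mapping[int, "SurvivalCurve"], endpoint: str = "", ax=None):
    """Step-function Kaplan–Meier curves, one line per cluster."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for cluster in sorted(curves):
        curve = curves[cluster]
        times = [0.0, *curve.event_times.tolist()]
        surv = [1.0, *curve.survival.tolist()]
        ax.step(times, surv, where="post", label=f"Cluster {cluster}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if endpoint:
        ax.set_title(endpoint)
    ax.legend()
    return ax
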