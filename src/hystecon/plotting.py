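"""Optional matplotlib figures: PSA cost histograms and one-way SA curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .methods import METHOD_ORDER, SurgicalMethod  # noqa: E402
from .psa import PSAResult, incremental_distribution  # noqa: E402
from .sensitivity import SAResult  # noqa: E402


def plot_psa_histograms(result: PSAResult, path) -> Path:
    """Per-method histograms of sampled total societal costs, plus the
    incremental TRH-vs-TAH cost distribution."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    for ax, method in zip(axes.flat, METHOD_ORDER):
        s = result.methods[method]
        ax.hist(s.costs, bins=60, color="steelblue", edgecolor="none")
        ax.axvline(s.mean, color="crimson", lw=1)
        ax.set_title(f"{method.value} societal cost")
        ax.set_xlabel("USD")
    inc = incremental_distribution(result, SurgicalMethod.TRH, SurgicalMethod.TAH)
    ax = axes.flat[3]
    ax.hist(inc.delta, bins=60, color="darkseagreen", edgecolor="none")
    ax.axvline(0.0, color="black", lw=1)
    ax.set_title(f"TRH - TAH (P(TRH cheaper) = {inc.p_a_cheaper:.2f})")
    ax.set_xlabel("USD")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_sa_curves(results: dict[SurgicalMethod, SAResult], path) -> Path:
    """Step curves of expected cost against OR time with flat reference lines."""
    colors = {SurgicalMethod.TAH: "seagreen", SurgicalMethod.TLH: "royalblue",
              SurgicalMethod.TRH: "firebrick"}
    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4), squeeze=False)
    for ax, (method, sa) in zip(axes.flat, results.items()):
        frame = sa.to_frame()
        ax.step(frame["or_time_min"], frame["expected_cost"], where="post",
                color=colors[method], label=method.value)
        for other, cost in sa.reference_costs.items():
            ax.axhline(cost, ls="--", lw=1, color=colors[other], label=f"{other.value} (default)")
        ax.set_xlabel("OR time (min)")
        ax.set_ylabel("expected societal cost (USD)")
        ax.legend(fontsize=8)
        ax.set_title(f"one-way SA: {method.value}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
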