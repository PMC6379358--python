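"""Optional matplotlib figures: scatter + Bland-Altman panels, weight bars.

Figures are illustrative only; every number lives in the CSV/JSON outputs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .regression import ValidationReport  # noqa: E402
from .weighting import WeightingReport  # noqa: E402


def validation_figure(report: ValidationReport, title: str, path) -> None:
    """Three panels: measured-vs-estimated scatter, Bland-Altman of the
    absolute differences, Bland-Altman of the percent differences."""
    y, yhat = report.measured, report.estimated
    ba = report.bland_altman
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))

    ax = axes[0]
    ax.scatter(y, yhat, s=12)
    lim = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("measured lactate (mmol/L)")
    ax.set_ylabel("estimated lactate (mmol/L)")

    means = (y + yhat) / 2.0
    for ax, diffs, bias, lo, hi, label in (
        (axes[1], ba.differences, ba.bias, ba.lower_loa, ba.upper_loa,
         "difference (mmol/L)"),
        (axes[2], ba.percent_differences, ba.percent_bias,
         ba.percent_lower_loa, ba.percent_upper_loa, "percent difference"),
    ):
        ax.scatter(means, diffs, s=12)
        ax.axhline(bias, color="k")
        ax.axhline(lo, color="k", ls=":")
        ax.axhline(hi, color="k", ls=":")
        ax.set_xlabel("mean of measured and estimated (mmol/L)")
        ax.set_ylabel(label)

    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def weights_figure(report: WeightingReport, path) -> None:
    """Bar chart of signed normalized weights per variable."""
    fig, ax = plt.subplots(figsize=(6, 4))
    vars_ = list(report.variables)
    ax.bar(vars_, [report.normalized[v] for v in vars_])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel(f"normalized weight ({report.rule})")
    ax.set_title(f"stratum: {report.stratum}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
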