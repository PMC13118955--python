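"""Publication-style plots: dose-response, Bland–Altman, pre/post bars."""

from __future__ import annotations

import numpy as np

from .dosestat import AgreementReport, BleachingDelta, DoseResponseFit


def _axes(path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4), dpi=150)
    return plt, fig, ax


def plot_dose_response(fit: DoseResponseFit, path, *, channel: str = "") -> None:
    plt, fig, ax = _axes(path)
    x = np.asarray(fit.concentrations)
    y = np.asarray(fit.mean_signals)
    ax.plot(x, y, "o", color="tab:blue")
    xs = np.linspace(0, x.max() * 1.05, 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, "-", color="tab:red",
            label=f"y = {fit.slope:.1f}x + {fit.intercept:.1f}\nR² = {fit.r_squared:.3f}")
    ax.set_xlabel("administered concentration (μg/mL)")
    ax.set_ylabel("mean segmented signal (A.U.)")
    if channel:
        ax.set_title(channel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bland_altman(report: AgreementReport, a, b, path) -> None:
    """Pairwise means vs differences with bias, LoA and CI bands."""
    plt, fig, ax = _axes(path)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    means = (a + b) / 2.0
    diffs = a - b
    ax.plot(means, diffs, "o", color="tab:blue")
    ax.axhline(report.bias, color="black", label=f"bias = {report.bias:.1f}")
    for loa in (report.loa_lower, report.loa_upper):
        ax.axhline(loa, color="tab:red", linestyle="--")
    ax.axhspan(*report.bias_ci, color="gray", alpha=0.3)
    ax.axhspan(*report.loa_ci_lower, color="tab:red", alpha=0.15)
    ax.axhspan(*report.loa_ci_upper, color="tab:red", alpha=0.15)
    ax.set_xlabel("mean of platforms (A.U.)")
    ax.set_ylabel("difference A − B (A.U.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bleaching(deltas: list[BleachingDelta], path) -> None:
    plt, fig, ax = _axes(path)
    x = np.arange(len(deltas))
    pre = [d.pre_mean for d in deltas]
    post = [d.post_mean for d in deltas]
    width = 0.38
    ax.bar(x - width / 2, pre, width, label="pre-activation", color="tab:blue")
    ax.bar(x + width / 2, post, width, label="post-activation", color="tab:orange")
    ax.set_xticks(x, [f"{d.concentration:g}" for d in deltas])
    ax.set_xlabel("administered concentration (μg/mL)")
    ax.set_ylabel("mean porphyrin signal (A.U.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
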