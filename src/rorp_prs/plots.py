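"""Minimal plotting helpers (Kaplan-Meier, calibration, forest)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def km_plot(km, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in km.curves.items():
        ax.step(curve.index, curve[label], where="post", label=label)
    ax.set_xlabel("Years")
    ax.set_ylabel("Survival probability")
    ax.legend(title=f"log-rank $\\chi^2$={km.chi2:.2f}, p={km.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calibration_plot(calib, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(calib["predicted"], calib["observed_corrected"], "o-", label="bias-corrected")
    ax.plot(calib["predicted"], calib["observed"], "s--", alpha=0.5, label="apparent")
    lims = [
        min(calib["predicted"].min(), calib["observed"].min()) - 0.02,
        1.0,
    ]
    ax.plot(lims, lims, "k:", lw=1)
    ax.set_xlabel("Predicted survival")
    ax.set_ylabel("Observed survival (KM)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest_plot(results, summary, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 0.6 * (len(results) + 2)))
    ys = range(len(results), 0, -1)
    for y, r in zip(ys, results):
        ax.errorbar(
            r.estimate, y,
            xerr=[[r.estimate - r.ci_low], [r.ci_high - r.estimate]],
            fmt="s", color="k",
        )
        ax.text(0.02, y, r.label, transform=ax.get_yaxis_transform())
    ax.errorbar(
        summary.summary, 0,
        xerr=[[summary.summary - summary.ci_low], [summary.ci_high - summary.summary]],
        fmt="D", color="firebrick",
    )
    ax.text(0.02, 0, "summary", transform=ax.get_yaxis_transform())
    ax.axvline(1.0, color="gray", lw=1, ls="--")
    ax.set_xlabel("HR per SD")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
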