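"""Optional matplotlib renderings of the analysis tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_rate_regression(report, ax=None):
    """1/T2n vs 1/T1e-bar with the fitted line and the slope-1/2 reference."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.6))
    table = report.temperature_table
    x = table["inv_T1e_bar_khz"]
    y = table["inv_T2n_khz"]
    ax.plot(x, y, "o", label="fitted rates")
    reg = report.regression
    xs = [0.0, float(x.max()) * 1.05]
    ax.plot(
        xs,
        [reg["slope"] * v + reg["intercept_hz"] * 1e-3 for v in xs],
        "-",
        label=f"fit, slope {reg['slope']:.2f}",
    )
    ax.plot(xs, [0.5 * v for v in xs], "--", color="gray", label="slope 1/2")
    ax.set_xlabel(r"1/$\bar{T}_{1e}$ (kHz)")
    ax.set_ylabel(r"1/$T_{2n}$ (kHz)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_t2n_vs_temperature(report, ax=None):
    """T2n against temperature."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.6))
    table = report.temperature_table
    ax.plot(table["temperature_K"], table["T2n_us"], "s-")
    ax.set_xlabel("temperature (K)")
    ax.set_ylabel(r"$T_{2n}$ ($\mu$s)")
    return ax


def save_report_figures(report, outdir):
    """Write the standard figures next to the report tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in (
        ("rate_regression.png", plot_rate_regression),
        ("t2n_vs_temperature.png", plot_t2n_vs_temperature),
    ):
        ax = fn(report)
        ax.figure.tight_layout()
        ax.figure.savefig(outdir / name, dpi=150)
        plt.close(ax.figure)
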