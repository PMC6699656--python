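"""Best-effort report plots (tabular outputs are the primary deliverable)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def qq_plot(slopes: np.ndarray, theoretical: np.ndarray, significant, path: Path) -> None:
    """Observed per-strain slopes against fitted-normal quantiles."""
    fig, ax = plt.subplots(figsize=(4, 4))
    sig = np.asarray(significant, dtype=bool)
    ax.scatter(theoretical[~sig], slopes[~sig], s=14, c="0.4", label="n.s.")
    if sig.any():
        ax.scatter(theoretical[sig], slopes[sig], s=18, c="crimson", label="p < 0.05")
    lims = [min(theoretical.min(), slopes.min()), max(theoretical.max(), slopes.max())]
    ax.plot(lims, lims, "--", c="steelblue", lw=1)
    ax.axhline(0, ls=":", c="steelblue", lw=1)
    ax.set_xlabel("theoretical normal quantile")
    ax.set_ylabel("observed slope")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def window_fit_plot(series, fit, strain: str, path: Path) -> None:
    """Window mean score vs relative oriC distance with the fitted line."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.scatter(series.midpoint_distance, series.mean_score, s=4, alpha=0.4, c="0.3")
    xs = np.linspace(0, 1, 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, c="crimson", lw=1.5,
            label=f"slope={fit.slope:.2f}, p={fit.p_value:.3g}")
    ax.set_xlabel("relative distance from oriC")
    ax.set_ylabel("mean ortholog score (window)")
    ax.set_title(strain, fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def segment_polar_plot(segment_means: dict[int, float], path: Path) -> None:
    """Polar bar chart of cohort-average ortholog score per chromosome segment."""
    n = len(segment_means)
    theta = [2 * np.pi * (k - 1) / n for k in sorted(segment_means)]
    vals = [segment_means[k] for k in sorted(segment_means)]
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # clockwise, segment 1 at oriC on top
    ax.bar(theta, vals, width=2 * np.pi / n, align="edge", color="steelblue", alpha=0.8)
    ax.set_xticks(theta)
    ax.set_xticklabels([str(k) for k in sorted(segment_means)], fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_report_plots(outdir: Path, frames, fits, config) -> dict:
    """Emit the standard report figures; returns {name: path}."""
    from .positional import slope_population_analysis, segment_analysis, window_series

    plots = {}
    pdir = Path(outdir) / "plots"
    pdir.mkdir(exist_ok=True)
    if len(fits) >= 2:
        qq, _ = slope_population_analysis(fits, alpha=config.alpha)
        p = pdir / "slope_qq.png"
        qq_plot(
            qq["observed_slope"].to_numpy(),
            qq["theoretical_quantile"].to_numpy(),
            qq["significant"].to_numpy(),
            p,
        )
        plots["slope_qq"] = str(p)
    for fr in frames[:4]:
        series = window_series(fr, config.window_size, config.window_step)
        p = pdir / f"window_fit_{fr.strain}.png"
        window_fit_plot(series, fits[fr.strain], fr.strain, p)
        plots[f"window_fit_{fr.strain}"] = str(p)
    if frames:
        table, _, _ = segment_analysis(frames, config.n_segments)
        means = table.groupby("segment")["mean_score"].mean().to_dict()
        p = pdir / "segment_polar.png"
        segment_polar_plot(means, p)
        plots["segment_polar"] = str(p)
    return plots
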