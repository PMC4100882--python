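"""Study figures: volume vs energy with fits, ratio, angle and depth."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["plot_study"]


def plot_study(shots: pd.DataFrame, fits: dict, out_dir) -> list:
    """Write the four standard study figures as PNG files.

    ``shots`` is the per-shot table (as in ``shots.csv``); ``fits`` the
    per-bullet fit section of the study report.  Returns the paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bullets = list(dict.fromkeys(shots["bullet"]))
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for b in bullets:
        sub = shots[shots["bullet"] == b]
        e, v = sub["deposited_energy_j"], sub["volume_ml"]
        pts = ax.plot(e, v, "o", label=b)
        sel = fits.get(b, {}).get("selection", {})
        grid = np.linspace(0, float(e.max()) * 1.05, 100)
        if sel.get("preferred") == "quadratic_origin":
            c = fits[b]["quadratic"]["coefficients"]
            ax.plot(grid, c[0] * grid + c[1] * grid**2, "-",
                    color=pts[0].get_color())
        elif "linear" in fits.get(b, {}):
            c = fits[b]["linear"]["coefficients"]
            ax.plot(grid, c[0] * grid, "-", color=pts[0].get_color())
    ax.set_xlabel("deposited energy (J)")
    ax.set_ylabel("cavity volume (mL)")
    ax.legend()
    fig.tight_layout()
    paths.append(out / "volume_vs_energy.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for b in bullets:
        sub = shots[shots["bullet"] == b]
        ax.plot(sub["deposited_energy_j"], sub["ratio_ml_per_j"], "o", label=b)
    ax.set_xlabel("deposited energy (J)")
    ax.set_ylabel("volume / energy (mL/J)")
    ax.legend()
    fig.tight_layout()
    paths.append(out / "ratio_vs_energy.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)

    for col, fname, ylabel in [
            ("deflection_deg", "deflection_by_bullet.png", "deflection angle (°)"),
            ("max_damage_depth_mm", "depth_by_bullet.png",
             "depth of maximal damage (mm)")]:
        fig, ax = plt.subplots(figsize=(5, 4))
        data = [shots[shots["bullet"] == b][col] for b in bullets]
        ax.boxplot(data, tick_labels=bullets)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        paths.append(out / fname)
        fig.savefig(paths[-1], dpi=120)
        plt.close(fig)
    return [str(p) for p in paths]
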