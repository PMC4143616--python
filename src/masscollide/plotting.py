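"""Diagnostic figures for model predictions and condition summaries.

One panel per occlusion condition: the probability of choosing the motor
object against the motor/projectile mass ratio on a log axis (so 1/3 and
3 sit symmetric about 1), one line per restitution level, with dotted
reference lines at chance (0.5) and at equal masses (r = 1).  A bias
shows up as a curve that does not cross the chance line at r = 1.  These
are verification aids, not reproductions of any published figure.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_predictions"]


def plot_predictions(predictions: pd.DataFrame, out_dir) -> list[Path]:
    """Write one figure per model from a cell-level predictions table.

    ``predictions`` needs columns model, mass_ratio_r, e, occlusion,
    p_motor.  An empty table is a warned no-op.  Returns the figure paths.
    """
    if len(predictions) == 0:
        warnings.warn("no predictions to plot", RuntimeWarning, stacklevel=2)
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for model, sub in predictions.groupby("model"):
        occlusions = sorted(sub["occlusion"].unique())
        fig, axes = plt.subplots(
            1, len(occlusions), figsize=(3.2 * len(occlusions), 3.2), sharey=True
        )
        if len(occlusions) == 1:
            axes = [axes]
        for ax, occ in zip(axes, occlusions):
            panel = sub[sub["occlusion"] == occ]
            for e_level, line in panel.groupby("e"):
                line = line.sort_values("mass_ratio_r")
                ax.plot(
                    line["mass_ratio_r"],
                    line["p_motor"],
                    marker="o",
                    label=f"e = {e_level:g}",
                )
            ax.axhline(0.5, ls=":", c="gray")
            ax.axvline(1.0, ls=":", c="gray")
            ax.set_xscale("log")
            ax.set_ylim(-0.02, 1.02)
            ax.set_title(f"{occ} occluded" if occ != "none" else "unoccluded")
            ax.set_xlabel("mass ratio $m_a/m_b$")
        axes[0].set_ylabel("P(choose motor object)")
        axes[0].legend(frameon=False, fontsize=8)
        fig.suptitle(model)
        fig.tight_layout()
        path = out_dir / f"predictions_{model.replace('/', '_')}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
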