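"""Optional figure output for the study products (headless Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["study_figures"]


def _lines_by_x(df: pd.DataFrame, xcol: str, ycol: str, ax) -> None:
    for x, grp in df.groupby("x"):
        grp = grp.sort_values(xcol)
        ax.plot(grp[xcol], grp[ycol], marker="o", label=f"x = {x:g}")
    ax.legend(fontsize=7)


def study_figures(tables: dict[str, pd.DataFrame], out_dir: Path) -> list[Path]:
    """Render the peak-power and bio-limit curves to PNG; returns paths."""
    out_dir = Path(out_dir)
    paths = []

    psm = tables["psm_vs_x"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for f_kHz, grp in psm.groupby("f_kHz"):
        grp = grp.sort_values("x")
        axes[0].plot(grp["x"], grp["PsM_W_per_g"], marker="o", label=f"{f_kHz:g} kHz")
        axes[1].plot(grp["x"], grp["D_M_nm"], marker="o", label=f"{f_kHz:g} kHz")
    axes[0].set_xlabel("Co$^{2+}$ fraction x")
    axes[0].set_ylabel("peak SLP (W/g)")
    axes[1].set_xlabel("Co$^{2+}$ fraction x")
    axes[1].set_ylabel("peak diameter $D_M$ (nm)")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    p = out_dir / "fig4-5_psm_dm_vs_x.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    bio = tables["biolimit"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    _lines_by_x(bio, "H_kA_per_m", "PsMl_W_per_g", ax)
    ax.set_xlabel("field amplitude H (kA/m)")
    ax.set_ylabel("constrained peak SLP (W/g)")
    fig.tight_layout()
    p = out_dir / "fig8_psml_vs_H.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    return paths
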