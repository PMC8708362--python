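"""End-to-end study reproduction: tables, curves, and printed-value comparison.

``reproduce_study`` runs the whole pipeline from a :class:`RunConfig` —
peak-power tables at each frequency, the bio-limit table, operating windows,
and the curve products behind the study's figures — and writes them as
CSV/JSON together with a summary comparing every replicated cell against the
packaged printed reference values (per-cell relative error).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import biolimit as _biolimit
from . import optimize as _optimize
from .config import RunConfig
from .constants import Environment

__all__ = ["printed_reference", "reproduce_study"]

log = logging.getLogger("ferroheat")


def printed_reference(name: str) -> pd.DataFrame:
    """Packaged printed reference values: 'tables345', 'table6' or 'table7'."""
    with resources.files("ferroheat.data.printed").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def _env(config: RunConfig) -> Environment:
    return Environment(T=config.environment.T_K)


def _round_like_print(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding used by the study's tables: powers to 2 decimals, diameters to 0.1 nm."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("W_per_g") and not col.startswith("d"):
            out[col] = out[col].round(2)
        elif col.endswith("_nm"):
            out[col] = out[col].round(1)
        elif col.endswith("_kHz"):
            out[col] = out[col].round(3)
    return out


def _write(df: pd.DataFrame, out_dir: Path, stem: str, formats: list[str]) -> list[Path]:
    paths = []
    if "csv" in formats:
        p = out_dir / f"{stem}.csv"
        _round_like_print(df).to_csv(p, index=False, lineterminator="\n")
        paths.append(p)
    if "json" in formats:
        p = out_dir / f"{stem}.json"
        p.write_text(df.to_json(orient="records", indent=2) + "\n")
        paths.append(p)
    return paths


def _compare(computed: pd.DataFrame, printed: pd.DataFrame, on: list[str],
             pairs: list[tuple[str, str]], product: str) -> pd.DataFrame:
    computed = computed.astype({k: float for k in on})
    printed = printed.astype({k: float for k in on})
    merged = computed.merge(printed, on=on, how="inner", suffixes=("", "_printed"))
    recs = []
    for _, row in merged.iterrows():
        for comp_col, print_col in pairs:
            printed_val = row.get(print_col)
            if printed_val is None or (isinstance(printed_val, float) and np.isnan(printed_val)):
                continue
            val = row[comp_col]
            recs.append(
                {
                    "product": product,
                    **{k: row[k] for k in on},
                    "quantity": comp_col,
                    "computed": val,
                    "printed": printed_val,
                    "rel_error": abs(val - printed_val) / abs(printed_val),
                    "provenance": row.get("provenance", ""),
                }
            )
    return pd.DataFrame(recs)


def reproduce_study(config: RunConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the full study box and write every table/curve product.

    Returns ``{"tables": {name: DataFrame}, "summary": DataFrame,
    "paths": [Path, ...]}``. ``out_dir`` overrides ``config.output.directory``;
    pass ``out_dir=None`` with a config whose directory is used instead.
    """
    config = config or RunConfig()
    if not config.compositions:
        raise ValueError("composition list must not be empty")
    out = Path(out_dir) if out_dir is not None else Path(config.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    env = _env(config)
    eps, tau0 = config.particle.epsilon, config.particle.tau0_s
    search = (config.search.D_min_m, config.search.D_max_m)
    limit = _biolimit.BioLimit(config.biolimit.limit_product_AHz_per_m)
    log.info(
        "resolved run constants: T=%.1f K, tau0=%.3g s, eps=%.3g, "
        "limit product=%.3g A·Hz/m, D search=[%.1f, %.1f] nm",
        env.T, tau0, eps, limit.C, search[0] * 1e9, search[1] * 1e9,
    )

    tables: dict[str, pd.DataFrame] = {}
    paths: list[Path] = []

    # Peak power and diameter vs composition, one table per frequency
    per_f = []
    for f in config.field.f_Hz:
        t = _optimize.psm_vs_x(
            config.compositions, H=20e3, f=f, search=search,
            env=env, epsilon=eps, tau0=tau0,
        )
        per_f.append(t)
    psm_tables = pd.concat(per_f, ignore_index=True)
    tables["psm_vs_x"] = psm_tables
    paths += _write(psm_tables, out, "tables3-5", config.output.formats)

    # Bio-limit table over the amplitude grid
    bio = _biolimit.psml_vs_field(
        config.compositions, config.biolimit.H_grid_A_per_m, limit,
        env=env, epsilon=eps, tau0=tau0, search=search,
    )
    tables["biolimit"] = bio
    paths += _write(bio, out, "table6", config.output.formats)

    # Operating windows
    windows = []
    for x in config.compositions:
        w = _biolimit.operating_window(
            x, limit, config.biolimit.threshold_W_per_g,
            config.biolimit.H_cap_A_per_m, config.biolimit.saturation_rel_gain,
            config.biolimit.H_grid_A_per_m, env=env, epsilon=eps, tau0=tau0,
            search=search,
        )
        windows.append(
            {
                "x": w.x,
                "feasible": w.feasible,
                "H_lo_kA_per_m": w.H_lo / 1e3,
                "H_hi_kA_per_m": w.H_hi / 1e3,
                "f_hi_kHz": w.f_hi / 1e3,
                "f_lo_kHz": w.f_lo / 1e3,
                "flags": list(w.flags),
            }
        )
    tables["windows"] = pd.DataFrame(windows)
    p = out / "table7.json"
    p.write_text(json.dumps(windows, indent=2) + "\n")
    paths.append(p)

    # Curve products behind the figures
    dm = _optimize.dm_vs_frequency(
        config.compositions, config.field.f_Hz, H=20e3, search=search,
        env=env, epsilon=eps, tau0=tau0,
    )
    tables["dm_vs_frequency"] = dm
    paths += _write(dm, out, "fig5-6_dm", config.output.formats)
    paths += _write(psm_tables, out, "fig4_psm_vs_x", config.output.formats)
    paths += _write(bio, out, "fig8_psml_vs_H", config.output.formats)

    surf_dir = out / "fig3_surfaces"
    surf_dir.mkdir(exist_ok=True)
    D_grid = np.linspace(search[0], search[1], 96)
    f_grid = np.asarray(config.field.f_Hz, dtype=float)
    for x in config.compositions:
        surf = _optimize.ps_surface(x, D_grid, f_grid, H=20e3, env=env,
                                    epsilon=eps, tau0=tau0)
        sp = surf_dir / f"ps_surface_x{x:g}.csv"
        surf.to_csv(sp, index=False, lineterminator="\n")
        paths.append(sp)

    # Comparison against the packaged printed values
    cmp_345 = _compare(
        psm_tables, printed_reference("tables345"), on=["f_kHz", "x"],
        pairs=[("PsM_W_per_g", "PsM_W_per_g_printed"), ("D_M_nm", "D_M_nm_printed")],
        product="psm_vs_x",
    )
    printed6 = printed_reference("table6").drop(columns=["f_l_kHz"])
    cmp_6 = _compare(
        bio, printed6, on=["H_kA_per_m", "x"],
        pairs=[("PsMl_W_per_g", "PsMl_W_per_g_printed"), ("D_Mo_nm", "D_Mo_nm_printed")],
        product="biolimit",
    )
    summary = pd.concat([cmp_345, cmp_6], ignore_index=True)
    tables["summary"] = summary
    sp = out / "summary_vs_printed.csv"
    summary.to_csv(sp, index=False, lineterminator="\n")
    paths.append(sp)

    if config.output.plots:
        from . import plots as _plots

        paths += _plots.study_figures(tables, out)

    return {"tables": tables, "summary": summary, "paths": paths}
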