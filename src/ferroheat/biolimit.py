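"""Operating points under the admissible biological field–frequency limit.

Prolonged exposure of tissue to an alternating magnetic field is considered
safe only while the product of amplitude and frequency stays below a limit
constant, here H·f = 5×10⁹ A·Hz/m. Along that constraint the frequency is
slaved to the amplitude, f_l = C/H, and the only remaining design freedom at
each composition is the amplitude itself plus the particle diameter. This
module evaluates the constrained peak loss power (P_sM)_l and its diameter
D_Mo across compositions and amplitudes, and derives recommended operating
windows from a threshold-plus-saturation heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_ENV, Environment
from .optimize import DEFAULT_SEARCH, find_optimal_diameter
from . import materials as _materials

__all__ = [
    "BioLimit",
    "OperatingWindow",
    "limit_frequency",
    "limit_optimum",
    "psml_vs_field",
    "operating_window",
]

#: Composition grid of the study (the anchor compositions with full properties).
STUDY_COMPOSITIONS = (0.0, 0.05, 0.1, 0.2, 0.4, 0.67, 0.8, 1.0)

#: Amplitude grid of the study, A/m (10–50 kA/m in 10 kA/m steps).
STUDY_H_GRID = tuple(h * 1e3 for h in (10, 20, 30, 40, 50))


@dataclass(frozen=True)
class BioLimit:
    """Field–frequency product limit C = H·f, A·Hz/m (default 5×10⁹)."""

    C: float = 5e9

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ValueError(f"limit product must be positive, got {self.C}")


@dataclass(frozen=True)
class OperatingWindow:
    """Recommended amplitude/frequency window for one composition.

    Bounds are in SI (A/m, Hz); ``flags`` records which rule fixed each
    bound: "threshold-met" / "threshold-unmet-at-grid-min" for the lower
    bound, "saturation-capped" / "hardware-capped" for the upper.
    """

    x: float
    feasible: bool
    H_lo: float = np.nan
    H_hi: float = np.nan
    f_lo: float = np.nan
    f_hi: float = np.nan
    threshold_W_per_g: float = 10.0
    flags: tuple[str, ...] = field(default_factory=tuple)


def limit_frequency(H: float, limit: BioLimit = BioLimit()) -> float:
    """Largest admissible frequency at amplitude H: f_l = C/H (Hz)."""
    if H <= 0:
        raise ValueError(f"field amplitude must be positive, got H={H}")
    return limit.C / H


def limit_optimum(
    x_values=STUDY_COMPOSITIONS,
    H_values=STUDY_H_GRID,
    limit: BioLimit = BioLimit(),
    env: Environment = DEFAULT_ENV,
    epsilon: float = 0.1,
    tau0: float = 1e-9,
    search=DEFAULT_SEARCH,
    model: "_materials.MaterialModel | None" = None,
) -> pd.DataFrame:
    """Constrained optimum (P_sM)_l and D_Mo for every (H, x) pair.

    Long-format DataFrame with columns ``H_kA_per_m``, ``f_l_kHz``, ``x``,
    ``PsMl_W_per_g``, ``D_Mo_nm``; each row is the unconstrained diameter
    optimizer evaluated at (x, H, C/H).
    """
    recs = []
    for H in H_values:
        f_l = limit_frequency(float(H), limit)
        for x in x_values:
            opt = find_optimal_diameter(float(x), float(H), f_l, search, env, epsilon, tau0, model)
            recs.append(
                {
                    "H_kA_per_m": H / 1e3,
                    "f_l_kHz": f_l / 1e3,
                    "x": float(x),
                    "PsMl_W_per_g": opt.PsM_W_per_g,
                    "D_Mo_nm": opt.D_M_nm,
                }
            )
    return pd.DataFrame(recs)


def psml_vs_field(
    x_values=STUDY_COMPOSITIONS,
    H_grid=STUDY_H_GRID,
    limit: BioLimit = BioLimit(),
    env: Environment = DEFAULT_ENV,
    epsilon: float = 0.1,
    tau0: float = 1e-9,
    search=DEFAULT_SEARCH,
    model: "_materials.MaterialModel | None" = None,
) -> pd.DataFrame:
    """(P_sM)_l versus amplitude per composition, with marginal gain.

    Appends ``dPsMl_dH_W_per_g_per_kA_per_m``: the central-difference slope
    of the constrained peak power with respect to H (one-sided at the grid
    ends).
    """
    table = limit_optimum(x_values, H_grid, limit, env, epsilon, tau0, search, model)
    out = []
    for x, grp in table.groupby("x", sort=False):
        grp = grp.sort_values("H_kA_per_m").reset_index(drop=True)
        H = grp["H_kA_per_m"].to_numpy()
        P = grp["PsMl_W_per_g"].to_numpy()
        grp["dPsMl_dH_W_per_g_per_kA_per_m"] = (
            np.gradient(P, H) if len(H) > 1 else np.nan
        )
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def operating_window(
    x: float,
    limit: BioLimit = BioLimit(),
    threshold: float = 10.0,
    H_cap: float = 50e3,
    saturation_rel_gain: float = 0.05,
    H_grid=STUDY_H_GRID,
    env: Environment = DEFAULT_ENV,
    epsilon: float = 0.1,
    tau0: float = 1e-9,
    search=DEFAULT_SEARCH,
    model: "_materials.MaterialModel | None" = None,
) -> OperatingWindow:
    """Recommended (H, f) window at composition ``x`` under the bio-limit.

    Two rules on the amplitude grid (default 10–50 kA/m, 10 kA/m steps):

    * lower bound — smallest H whose constrained peak power meets
      ``threshold`` (W/g). If none does, the result is flagged infeasible.
    * upper bound — H stops paying off once the relative gain of a grid step
      falls below ``saturation_rel_gain``; the bound is the last H before
      that step ("saturation-capped"), else ``H_cap`` ("hardware-capped").

    Frequency bounds follow from f = C/H (larger H ↔ smaller f).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    H_grid = sorted(float(h) for h in H_grid if float(h) <= H_cap)
    if not H_grid:
        raise ValueError("amplitude grid empty after applying H_cap")
    table = limit_optimum([x], H_grid, limit, env, epsilon, tau0, search, model)
    P = table["PsMl_W_per_g"].to_numpy()

    flags: list[str] = []
    meets = np.nonzero(P >= threshold)[0]
    if meets.size == 0:
        return OperatingWindow(
            x=x, feasible=False, threshold_W_per_g=threshold,
            flags=("no-feasible-window",),
        )
    i_lo = int(meets[0])
    flags.append("threshold-met")

    i_hi = len(H_grid) - 1
    capped = "hardware-capped"
    for j in range(1, len(H_grid)):
        rel_gain = (P[j] - P[j - 1]) / P[j - 1] if P[j - 1] > 0 else np.inf
        if rel_gain < saturation_rel_gain:
            i_hi = j - 1
            capped = "saturation-capped"
            break
    flags.append(capped)
    if i_hi < i_lo:
        i_hi = i_lo  # threshold reached only where gains already saturated

    H_lo, H_hi = H_grid[i_lo], H_grid[i_hi]
    return OperatingWindow(
        x=x,
        feasible=True,
        H_lo=H_lo,
        H_hi=H_hi,
        f_lo=limit_frequency(H_hi, limit),
        f_hi=limit_frequency(H_lo, limit),
        threshold_W_per_g=threshold,
        flags=tuple(flags),
    )
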