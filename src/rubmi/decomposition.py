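"""Decomposition of population mean-BMI change into rural, urban and
urbanisation components.

With rural/urban mean BMI at two endpoint years and the urban population
share s, the population mean is m_t = (1 - s_t) r_t + s_t u_t and the
change decomposes exactly (a Kitagawa-style identity) as

    m_2017 - m_1985 = (r_2017 - r_1985)(1 - s_1985)      rural component
                    + (u_2017 - u_1985) s_1985           urban component
                    + (s_2017 - s_1985)(u_2017 - r_2017) urbanisation

Percentage contributions divide each component by the total change and are
suppressed (NR) when the total change is below 0.5 kg m^-2, where the ratio
is unstable.  Both a draw-wise mode (posterior means and credible intervals
of per-draw percentages) and a deterministic point mode (ratios of point
components, used for worked-example tables) are provided.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .postprocess import credible_interval

__all__ = [
    "DecompositionInput",
    "DecompositionResult",
    "decompose_change",
    "percent_contributions",
    "round_half_away",
    "load_reference_contributions",
    "NR_THRESHOLD",
]


def load_reference_contributions() -> pd.DataFrame:
    """Published regional absolute contributions used as worked-example inputs."""
    ref = importlib.resources.files("rubmi.data").joinpath("reference_contributions.csv")
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")

#: Total-change magnitude below which percentage contributions are Not Reported.
NR_THRESHOLD = 0.5


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class DecompositionInput:
    """Endpoint stratum means (kg m^-2) and urban shares; scalars or draw arrays."""

    rural_start: np.ndarray | float
    rural_end: np.ndarray | float
    urban_start: np.ndarray | float
    urban_end: np.ndarray | float
    share_urban_start: np.ndarray | float
    share_urban_end: np.ndarray | float

    def validate(self) -> "DecompositionInput":
        for name in ("share_urban_start", "share_urban_end"):
            s = np.asarray(getattr(self, name), dtype=float)
            if np.any((s < 0) | (s > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("rural_start", "rural_end", "urban_start", "urban_end"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} not finite")
        return self


def decompose_change(inp: DecompositionInput) -> dict[str, np.ndarray]:
    """Absolute rural/urban/urbanisation contributions; exact additivity.

    Works elementwise on draw arrays; also returns the total change in the
    share-weighted population mean, which equals the component sum
    identically.
    """
    inp.validate()
    r0 = np.asarray(inp.rural_start, dtype=float)
    r1 = np.asarray(inp.rural_end, dtype=float)
    u0 = np.asarray(inp.urban_start, dtype=float)
    u1 = np.asarray(inp.urban_end, dtype=float)
    s0 = np.asarray(inp.share_urban_start, dtype=float)
    s1 = np.asarray(inp.share_urban_end, dtype=float)
    rural = (r1 - r0) * (1.0 - s0)
    urban = (u1 - u0) * s0
    urbanization = (s1 - s0) * (u1 - r1)
    total = ((1.0 - s1) * r1 + s1 * u1) - ((1.0 - s0) * r0 + s0 * u0)
    return {"rural": rural, "urban": urban, "urbanization": urbanization, "total": total}


@dataclass
class DecompositionResult:
    """Absolute and percentage contributions with 95% credible intervals."""

    absolute: dict[str, float]
    absolute_ci: dict[str, tuple[float, float]]
    percent: dict[str, float] | None
    percent_ci: dict[str, tuple[float, float]] | None
    total_change: float
    nr: bool

    def rounded_percents(self) -> tuple[int, int, int] | None:
        if self.nr or self.percent is None:
            return None
        return tuple(
            round_half_away(self.percent[k]) for k in ("rural", "urban", "urbanization")
        )


def percent_contributions(
    components: dict[str, np.ndarray | float],
    nr_threshold: float = NR_THRESHOLD,
) -> DecompositionResult:
    """Percentage contributions of decomposition components.

    Draw arrays: percentages are computed per draw and summarised by the
    posterior mean and 2.5th/97.5th percentiles.  Scalars (point mode):
    deterministic ratios of the point components.  In both modes the three
    percentages sum to 100 before rounding, and all three are flagged NR
    when the magnitude of the (posterior-mean) total change is below
    ``nr_threshold`` kg m^-2.
    """
    keys = ("rural", "urban", "urbanization")
    comp = {k: np.asarray(components[k], dtype=float) for k in keys}
    total = np.asarray(
        components.get("total", sum(comp[k] for k in keys)), dtype=float
    )
    draw_mode = total.ndim > 0 and total.size > 1

    absolute = {k: float(comp[k].mean()) for k in keys}
    if draw_mode:
        absolute_ci = {
            k: tuple(map(float, credible_interval(comp[k]))) for k in keys
        }
    else:
        absolute_ci = {k: (absolute[k], absolute[k]) for k in keys}
    total_mean = float(total.mean())
    nr = abs(total_mean) < nr_threshold
    if nr:
        return DecompositionResult(
            absolute=absolute, absolute_ci=absolute_ci, percent=None,
            percent_ci=None, total_change=total_mean, nr=True,
        )
    if draw_mode:
        pct = {k: 100.0 * comp[k] / total for k in keys}
        percent = {k: float(p.mean()) for k, p in pct.items()}
        percent_ci = {k: tuple(map(float, credible_interval(p))) for k, p in pct.items()}
    else:
        percent = {k: float(100.0 * comp[k] / total) for k in keys}
        percent_ci = {k: (percent[k], percent[k]) for k in keys}
    return DecompositionResult(
        absolute=absolute, absolute_ci=absolute_ci, percent=percent,
        percent_ci=percent_ci, total_change=total_mean, nr=False,
    )
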