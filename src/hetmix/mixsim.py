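"""Co-culture growth simulation under drug treatment.

Each cell line grows logistically against a shared carrying capacity (the
subpopulations compete for the same well).  Drug effect enters as a
multiplier on the per-line growth rate through ``g(v) = 2 v - 1``, where
``v`` is the line's viability under the treatment: ``v = 1`` leaves growth
untouched, ``v = 0.5`` produces stasis, and ``v < 0.5`` produces net cell
loss.  This single parameterization covers both cytostatic and cytotoxic
drug phenotypes.

Within-line combination effects are configurable: the ``"ida-min"`` rule
takes the minimum viability across the component drugs (no within-line
interaction, the independent-drug-action assumption), while ``"bliss"``
multiplies viabilities (probabilistic independence of drug hits, which at
the level of growth rates acts super-additively and models a synergistic
combination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HillParams",
    "GrowthParams",
    "hill_viability",
    "hill_ic50_for_viability",
    "seeding_ratio",
    "combined_viability",
    "simulate_mixture",
]

COMBO_MODELS = ("ida-min", "bliss")


class HillParams(NamedTuple):
    """Parameters of a Hill dose-response curve.

    viability(c) = 1 - emax * c**hill / (c**hill + ic50**hill)
    """

    ic50: float
    hill: float
    emax: float


def hill_viability(conc, ic50: float, hill: float, emax: float):
    """Viability in ``[1 - emax, 1]`` under the Hill dose-response law.

    Accepts scalar or array-like concentrations; negative concentrations,
    non-positive IC50/slope, or emax outside [0, 1] are rejected.
    """
    conc = np.asarray(conc, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentration must be non-negative")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if hill <= 0:
        raise ValueError("hill slope must be positive")
    if not 0.0 <= emax <= 1.0:
        raise ValueError("emax must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        ratio = np.power(conc / ic50, hill)
    effect = emax * ratio / (1.0 + ratio)
    out = 1.0 - effect
    return float(out) if out.ndim == 0 else out


def hill_ic50_for_viability(viability: float, conc: float, hill: float, emax: float) -> float:
    """IC50 such that ``hill_viability(conc, ic50, hill, emax) == viability``.

    Used by scenario presets to construct dose-response curves that realize a
    stated per-line viability at a given test dose.
    """
    if conc <= 0:
        raise ValueError("conc must be positive")
    effect = 1.0 - viability
    if not 0.0 < effect < emax:
        raise ValueError(
            f"target viability {viability} not reachable with emax={emax}"
        )
    frac = effect / emax  # fractional occupancy at conc
    return float(conc * ((1.0 - frac) / frac) ** (1.0 / hill))


def seeding_ratio(doubling_times: Sequence[float]) -> np.ndarray:
    """Integer seeding ratio proportional to doubling times.

    Slower-growing lines (longer doubling time) are seeded in proportionally
    larger numbers so every subpopulation contributes comparably to the
    mixture during unperturbed growth: ``ratio_i = round(Td_i / min(Td))``,
    floored at 1.
    """
    td = np.asarray(doubling_times, dtype=float)
    if td.size == 0:
        raise ValueError("doubling_times must be non-empty")
    if (td <= 0).any():
        raise ValueError("doubling times must be positive")
    # half-up rounding (2.5 -> 3), not banker's rounding
    ratio = np.floor(td / td.min() + 0.5).astype(int)
    return np.maximum(ratio, 1)


@dataclass
class GrowthParams:
    """Growth and dose-response parameters of a co-cultured line panel.

    Parameters
    ----------
    doubling_time
        Hours per doubling for each line, > 0.
    cell_area
        Imaging footprint per cell (area units/cell), used to convert counts
        to the per-channel areas a fluorescence reader would report.
    capacity
        Shared carrying capacity of a well, in cells.  Must exceed the total
        seeded count.  Large values give weak coupling between lines.
    combo_model
        Within-line combination rule, ``"ida-min"`` or ``"bliss"``.
    dose_response
        Per line, a mapping drug name -> :class:`HillParams`.
    """

    doubling_time: Mapping[str, float]
    cell_area: Mapping[str, float]
    capacity: float = 2e6
    combo_model: str = "ida-min"
    dose_response: Mapping[str, Mapping[str, HillParams]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.combo_model not in COMBO_MODELS:
            raise ValueError(f"combo_model must be one of {COMBO_MODELS}")
        for line, td in self.doubling_time.items():
            if td <= 0:
                raise ValueError(f"doubling time of {line!r} must be positive")
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(self.doubling_time)


def combined_viability(
    line_dr: Mapping[str, HillParams],
    treatment: Iterable[tuple[str, float]],
    model: str = "ida-min",
) -> float:
    """Within-line viability of a (possibly multi-drug) treatment.

    ``treatment`` is an iterable of (drug, concentration) pairs; an empty
    treatment (vehicle) yields viability 1.
    """
    if model not in COMBO_MODELS:
        raise ValueError(f"model must be one of {COMBO_MODELS}")
    viabilities = []
    for drug, conc in treatment:
        if drug not in line_dr:
            raise KeyError(f"no dose-response parameters for drug {drug!r}")
        p = line_dr[drug]
        viabilities.append(hill_viability(conc, p.ic50, p.hill, p.emax))
    if not viabilities:
        return 1.0
    if model == "ida-min":
        return float(min(viabilities))
    return float(np.prod(viabilities))


def simulate_mixture(
    params: GrowthParams,
    seeding: Mapping[str, float],
    treatment: Iterable[tuple[str, float]] = (),
    duration: float = 120.0,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Simulate per-line cell counts in a treated co-culture.

    The update is a shared-capacity logistic step

        N_i(t + dt) = N_i(t) * exp(r_i * g(v_i) * dt * (1 - sum_j N_j / K))

    with ``r_i = ln 2 / Td_i`` and ``g(v) = 2 v - 1``.  Viabilities ``v_i``
    are computed once from each line's Hill parameters at the (static)
    treatment concentrations; drug exposure is constant over the horizon.

    Returns a DataFrame indexed by time (hours, including 0) with one column
    per line, holding cell counts.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0 or dt > duration:
        raise ValueError("dt must satisfy 0 < dt <= duration")
    lines = params.lines
    if not lines:
        raise ValueError("empty mixture: no lines defined")
    counts = np.array([float(seeding.get(line, 0.0)) for line in lines])
    if (counts < 0).any():
        raise ValueError("seeding counts must be non-negative")
    total0 = counts.sum()
    if total0 <= 0:
        raise ValueError("empty mixture: total seeding must be positive")
    if total0 >= params.capacity:
        raise ValueError("carrying capacity must exceed total seeding")

    treatment = list(treatment)
    rates = np.array([np.log(2.0) / params.doubling_time[line] for line in lines])
    viab = np.array(
        [
            combined_viability(params.dose_response.get(line, {}), treatment, params.combo_model)
            for line in lines
        ]
    )
    growth_mult = 2.0 * viab - 1.0

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    traj = np.empty((n_steps + 1, len(lines)))
    traj[0] = counts
    for step in range(n_steps):
        crowding = 1.0 - traj[step].sum() / params.capacity
        traj[step + 1] = traj[step] * np.exp(rates * growth_mult * dt * crowding)
    return pd.DataFrame(traj, index=pd.Index(times, name="time_h"), columns=list(lines))
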