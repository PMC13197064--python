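"""Production summary metrics (the study's per-condition summary table).

From a simulated trajectory or an observed time course: maximal levan
titre and when it is first reached, the levan production rate (max titre
over time-to-max), maximal biomass, maximal specific growth rate, the
substrate-use efficiency (% w/w of the initial sucrose mass ending up as
levan) and, when a sucrose series is available, the yield on consumed
sucrose.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .calibration import ObservedTimecourse
from .simulator import Trajectory

__all__ = ["ProductionSummary", "summarize_production"]


@dataclass(frozen=True)
class ProductionSummary:
    condition: float                  # initial sucrose, g/L
    max_levan: float                  # g/L
    t_max_levan: float                # h
    levan_production_rate: float      # g/(L h)
    max_biomass: float                # gDW/L
    max_specific_growth_rate: float   # 1/h
    substrate_use_efficiency: float   # % w/w
    yield_on_consumed_sucrose: float | None = None  # g levan / g sucrose consumed
    yield_on_supplied_sucrose: float | None = None  # g levan / g sucrose supplied
    rate_undefined: bool = False

    def to_row(self) -> pd.DataFrame:
        """One CSV row mirroring the summary-table column order."""
        d = asdict(self)
        order = ["condition", "max_levan", "levan_production_rate",
                 "t_max_levan", "max_biomass", "max_specific_growth_rate",
                 "yield_on_consumed_sucrose", "yield_on_supplied_sucrose",
                 "substrate_use_efficiency", "rate_undefined"]
        return pd.DataFrame([{k: d[k] for k in order}])


def _growth_rate_from_series(times: np.ndarray, X: np.ndarray) -> float:
    """Max specific growth rate from a (noisy) biomass series via
    log-linear regression over a sliding 3-point window."""
    lx = np.log(np.clip(X, 1e-9, None))
    best = 0.0
    for i in range(len(times) - 2):
        t = times[i:i + 3]
        y = lx[i:i + 3]
        slope = np.polyfit(t, y, 1)[0]
        best = max(best, float(slope))
    return best


def summarize_production(series, initial_sucrose: float) -> ProductionSummary:
    """Compute the production summary for one condition.

    ``series`` is a ``Trajectory`` (model units; converted internally), an
    ``ObservedTimecourse``, or a plain mapping with 'time' plus measured
    species arrays in g/L.
    """
    if initial_sucrose <= 0:
        raise ValueError("initial_sucrose must be positive")

    if isinstance(series, Trajectory):
        frame = series.to_frame(measurement_units=True)
        times = frame["time"].to_numpy()
        levan = frame["levan"].to_numpy()
        biomass = frame["biomass"].to_numpy()
        sucrose = frame["sucrose"].to_numpy()
        mu_max = float(series.rates["mu"].max())
    else:
        if isinstance(series, ObservedTimecourse):
            times = series.times
            meas = series.measurements
        else:
            meas = dict(series)
            times = np.asarray(meas.pop("time"), dtype=float)
        levan = np.asarray(meas["levan"], dtype=float)
        biomass = np.asarray(meas.get("biomass", np.zeros_like(levan)), dtype=float)
        sucrose = (np.asarray(meas["sucrose"], dtype=float)
                   if "sucrose" in meas else None)
        mu_max = _growth_rate_from_series(times, biomass) if np.any(biomass > 0) else 0.0

    if len(times) == 0:
        raise ValueError("empty series")

    i_max = int(np.argmax(levan))  # first index attaining the maximum
    max_levan = float(levan[i_max])
    t_max = float(times[i_max])
    undefined = max_levan <= 0 or t_max <= 0
    rate = 0.0 if undefined else max_levan / t_max

    yield_consumed = None
    yield_supplied = None
    if max_levan > 0:
        yield_supplied = max_levan / initial_sucrose
        if sucrose is not None:
            consumed = initial_sucrose - float(sucrose[i_max])
            if consumed > 0:
                yield_consumed = max_levan / consumed

    return ProductionSummary(
        condition=initial_sucrose,
        max_levan=max_levan,
        t_max_levan=t_max,
        levan_production_rate=rate,
        max_biomass=float(np.max(biomass)) if len(biomass) else 0.0,
        max_specific_growth_rate=mu_max,
        substrate_use_efficiency=100.0 * max_levan / initial_sucrose,
        yield_on_consumed_sucrose=yield_consumed,
        yield_on_supplied_sucrose=yield_supplied,
        rate_undefined=undefined,
    )
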