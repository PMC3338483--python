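"""Study conditions: per-condition cell-population statistics.

Each condition bundles the descriptive statistics (mean ± SD) of cell
spreading area, ellipse aspect ratio and migration speed for one substrate /
observation-plane combination, plus the fraction of spindle-shaped cells.
The bundled presets are the measured glioblastoma (OSU-2) statistics in 40%
v/v basement-membrane gel at the lowest and highest observation planes, and
on bare glass; they parameterize the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class ConditionParams:
    """Population statistics for one imaging condition.

    Areas in µm², aspect ratio dimensionless (≥ 1), speeds in µm/hr.
    ``spindle_fraction`` is the probability that a cell belongs to the
    spindle-shaped (elongated, well-spread) subpopulation; the remainder are
    rounded cells.
    """

    label: str
    area_mean: float
    area_sd: float
    ar_mean: float
    ar_sd: float
    speed_mean: float
    speed_sd: float
    spindle_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("area_mean", "ar_mean", "speed_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("area_sd", "ar_sd", "speed_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.spindle_fraction <= 1.0:
            raise ValueError("spindle_fraction must lie in [0, 1]")
        if self.ar_mean < 1.0:
            raise ValueError("ar_mean must be >= 1 (major/minor axis ratio)")


#: Measured condition statistics driving the generator defaults.
PRESETS: dict[str, ConditionParams] = {
    # 40% v/v gel, lowest observation plane (interface): two populations
    "40pct_low": ConditionParams(
        label="40pct_low",
        area_mean=1340.0, area_sd=470.0,
        ar_mean=10.4, ar_sd=7.3,
        speed_mean=29.5, speed_sd=11.3,
        spindle_fraction=0.5,
    ),
    # 40% v/v gel, highest observation plane (bulk): rounded cells only
    "40pct_high": ConditionParams(
        label="40pct_high",
        area_mean=400.0, area_sd=270.0,
        ar_mean=1.6, ar_sd=0.8,
        speed_mean=7.6, speed_sd=3.1,
        spindle_fraction=0.0,
    ),
    # cells plated on bare glass (2D control)
    "glass": ConditionParams(
        label="glass",
        area_mean=2309.0, area_sd=1232.0,
        ar_mean=2.2, ar_sd=1.5,
        speed_mean=28.2, speed_sd=9.7,
        spindle_fraction=0.0,
    ),
}


def condition_at_depth(interface: ConditionParams, bulk: ConditionParams,
                       decay_length: float, z: float) -> ConditionParams:
    """Interpolate condition statistics at height z above the interface.

    Every numeric field follows m(z) = m_bulk + (m_0 − m_bulk)·exp(−z/λ),
    the exponential decay of interface-driven spreading with distance from
    the rigid support.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be > 0")
    w = float(np.exp(-z / decay_length))

    def mix(name: str) -> float:
        return getattr(bulk, name) + (getattr(interface, name) - getattr(bulk, name)) * w

    return replace(
        interface,
        label=f"{interface.label}@z={z:g}um",
        area_mean=mix("area_mean"), area_sd=mix("area_sd"),
        ar_mean=mix("ar_mean"), ar_sd=mix("ar_sd"),
        speed_mean=mix("speed_mean"), speed_sd=mix("speed_sd"),
        spindle_fraction=mix("spindle_fraction"),
    )
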