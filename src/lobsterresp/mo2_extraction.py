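"""Per-cycle oxygen-consumption extraction from intermittent-flow traces.

Each sealed measure phase yields one mass-specific rate via the
standard slope method: an ordinary least-squares fit of concentration
against time, scaled by the effective water volume (chamber minus
animal) and corrected for background (microbial) respiration

    MO2 = (-slope * V_eff - background) / body_mass        [mg O2 h^-1 kg^-1]

Cycles failing quality control (low r-squared, fewer than three
samples, oxygen saturation below the floor, negative corrected rate)
are flagged and excluded from downstream trait estimation — never
silently repaired or clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from lobsterresp.trace_io import (
    AnimalRecord,
    BackgroundRecord,
    OxygenTrace,
)

__all__ = [
    "MO2Series",
    "fit_cycle_slope",
    "mo2_from_slope",
    "background_correction",
    "qc_saturation",
    "extract_mo2",
]

FLAG_LOW_R2 = "low_r2"
FLAG_SHORT_CYCLE = "short_cycle"
FLAG_SATURATION = "saturation_floor"
FLAG_NEGATIVE = "negative_mo2"
FLAG_DEGENERATE = "degenerate_slope"


@dataclass
class MO2Series:
    """Per-cycle MO2 estimates with fit quality and QC flags.

    ``data`` columns: cycle_index, cycle_time_h (midpoint of the
    measure phase), slope_mg_l_h, r2, n_samples, min_saturation_pct,
    background_rate_mg_h, mo2 (mg O2 h^-1 kg^-1), flags
    (semicolon-joined), accepted (bool).
    """

    data: pd.DataFrame
    effective_volume_l: float
    body_mass_kg: float
    settings: dict = field(default_factory=dict)

    @property
    def accepted(self) -> pd.DataFrame:
        """Flag-free cycles, ordered by time."""
        out = self.data[self.data["accepted"]]
        return out.sort_values("cycle_time_h").reset_index(drop=True)

    @property
    def n_accepted(self) -> int:
        return int(self.data["accepted"].sum())


def fit_cycle_slope(
    time_s: np.ndarray, o2_mg_l: np.ndarray
) -> tuple[float, float]:
    """OLS slope of concentration vs time for one sealed cycle.

    Returns ``(slope, r2)`` with slope in mg O2 L^-1 h^-1 (negative for
    a respiring animal).  Raises ``ValueError`` below 3 samples; a
    perfectly constant signal returns ``(0.0, nan)`` so the caller can
    flag it as degenerate rather than fake a fit quality.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2_mg_l, dtype=float)
    if len(t) < 3:
        raise ValueError(f"cycle has {len(t)} samples; need >= 3 for a slope")
    if np.ptp(y) == 0.0:
        return 0.0, float("nan")
    res = stats.linregress(t / 3600.0, y)
    return float(res.slope), float(res.rvalue**2)


def mo2_from_slope(
    slope_mg_l_h: float,
    effective_volume_l: float,
    body_mass_kg: float,
    background_rate_mg_h: float = 0.0,
) -> float:
    """Mass-specific oxygen consumption from a concentration slope.

    ``(-slope * V_eff - background) / mass``; the caller supplies
    V_eff = chamber volume minus animal body volume.
    """
    if effective_volume_l <= 0:
        raise ValueError(
            f"effective volume must be > 0 (got {effective_volume_l} L); "
            "animal larger than chamber?"
        )
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    return (-slope_mg_l_h * effective_volume_l - background_rate_mg_h) / body_mass_kg


def background_correction(
    background: BackgroundRecord | None, trial_duration_h: float
) -> Callable[[np.ndarray | float], np.ndarray | float]:
    """Background respiration as a function of trial time (hours).

    Linear interpolation between the pre- and post-trial blank rates;
    with only a pre-trial rate available the rate is held constant (a
    documented fallback, warned about once per call).
    """
    if background is None:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    pre = background.pre_rate_mg_per_h
    post = background.post_rate_mg_per_h
    if post is None:
        warnings.warn(
            "post-trial background rate missing; holding pre-trial rate constant",
            stacklevel=2,
        )
        return lambda t: np.full_like(np.asarray(t, dtype=float), pre)
    if trial_duration_h <= 0:
        raise ValueError("trial_duration_h must be > 0")

    def rate(t):
        frac = np.clip(np.asarray(t, dtype=float) / trial_duration_h, 0.0, 1.0)
        return pre + (post - pre) * frac

    return rate


def qc_saturation(
    trace: OxygenTrace,
    saturation_concentration_mg_l: float,
    floor_percent: float = 77.0,
) -> pd.Series:
    """Per-cycle minimum oxygen saturation (%) flagged against a floor.

    Returns a boolean Series indexed by cycle_index; True = the cycle's
    minimum saturation fell below ``floor_percent`` and should be
    flagged.
    """
    if saturation_concentration_mg_l <= 0:
        raise ValueError("saturation_concentration_mg_l must be > 0")
    min_sat = _cycle_min_saturation(trace, saturation_concentration_mg_l)
    return min_sat < floor_percent


def _cycle_min_saturation(
    trace: OxygenTrace, saturation_concentration_mg_l: float
) -> pd.Series:
    meas = trace.data[trace.data["phase"] == "measure"]
    return (
        meas.groupby("cycle_index")["o2_mg_l"].min()
        / saturation_concentration_mg_l
        * 100.0
    )


def extract_mo2(
    trace: OxygenTrace,
    chamber_volume_l: float,
    animal: AnimalRecord,
    background: BackgroundRecord | None = None,
    saturation_concentration_mg_l: float = 8.0,
    r2_min: float = 0.9,
    saturation_floor_pct: float = 77.0,
    body_density_g_per_ml: float = 1.12,
) -> MO2Series:
    """Convert a whole trace into a QC-flagged per-cycle MO2 series."""
    v_eff = chamber_volume_l - animal.volume_l(body_density_g_per_ml)
    if v_eff <= 0:
        raise ValueError(
            f"{animal.animal_id}: effective volume <= 0 "
            f"({chamber_volume_l} L chamber, {animal.volume_l():.2f} L animal)"
        )
    t_end_h = float(trace.data["time_s"].max()) / 3600.0
    bg_rate = background_correction(background, max(t_end_h, 1e-9))
    min_sat = _cycle_min_saturation(trace, saturation_concentration_mg_l)

    rows = []
    for cycle_index, cyc in trace.measure_cycles():
        t = cyc["time_s"].to_numpy(dtype=float)
        y = cyc["o2_mg_l"].to_numpy(dtype=float)
        mid_h = float((t[0] + t[-1]) / 2.0) / 3600.0
        flags: list[str] = []
        if len(t) < 3:
            rows.append(
                dict(
                    cycle_index=cycle_index,
                    cycle_time_h=mid_h,
                    slope_mg_l_h=np.nan,
                    r2=np.nan,
                    n_samples=len(t),
                    min_saturation_pct=min_sat.get(cycle_index, np.nan),
                    background_rate_mg_h=float(bg_rate(mid_h)),
                    mo2=np.nan,
                    flags=FLAG_SHORT_CYCLE,
                    accepted=False,
                )
            )
            continue
        slope, r2 = fit_cycle_slope(t, y)
        if np.isnan(r2):
            flags.append(FLAG_DEGENERATE)
        elif r2 < r2_min:
            flags.append(FLAG_LOW_R2)
        if min_sat.get(cycle_index, 100.0) < saturation_floor_pct:
            flags.append(FLAG_SATURATION)
        bg = float(bg_rate(mid_h))
        mo2 = mo2_from_slope(slope, v_eff, animal.body_mass_kg, bg)
        if mo2 < 0:
            flags.append(FLAG_NEGATIVE)
        rows.append(
            dict(
                cycle_index=cycle_index,
                cycle_time_h=mid_h,
                slope_mg_l_h=slope,
                r2=r2,
                n_samples=len(t),
                min_saturation_pct=min_sat.get(cycle_index, np.nan),
                background_rate_mg_h=bg,
                mo2=mo2,
                flags=";".join(flags),
                accepted=not flags,
            )
        )
    data = pd.DataFrame(rows)
    return MO2Series(
        data=data,
        effective_volume_l=v_eff,
        body_mass_kg=animal.body_mass_kg,
        settings=dict(
            r2_min=r2_min,
            saturation_floor_pct=saturation_floor_pct,
            saturation_concentration_mg_l=saturation_concentration_mg_l,
            chamber_volume_l=chamber_volume_l,
        ),
    )
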