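"""Whole-trial metabolic traits from a per-cycle MO2 series.

Trait definitions (all rates in mg O2 h^-1 kg^-1):

* **SMR** — mean of the lowest 10% of accepted MO2 values over the
  whole trial (count = ceil(0.1 n), ties broken by cycle order).
* **RMR** — mean (and SD) of accepted MO2 from 16 h post-exercise to
  the end of the trial, the window by which all animals have recovered.
* **MMR** — the single highest accepted MO2 of the trial, elicited by
  the pre-trial exhaustive chase.
* **Aerobic scope** = MMR - SMR; **factorial scope** = MMR / SMR.
* **Recovery time** — the time of the third cycle (counted cumulatively
  from trial start; a consecutive-run variant is provided) whose MO2
  falls below RMR + 1 SD.
* **EPOC** — trapezoidal area under the MO2 curve above a baseline
  (RMR by default; SMR and no-baseline modes available) from the first
  cycle to recovery time, negative excess clipped at zero.
* **Recovery rate** = EPOC / recovery time.

Trials that never yield three sub-threshold cycles are reported as not
recovered; EPOC and recovery rate are then undefined rather than
guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from lobsterresp.mo2_extraction import MO2Series

__all__ = [
    "MetricError",
    "MetabolicSummary",
    "compute_smr",
    "compute_mmr",
    "compute_rmr",
    "compute_recovery_time",
    "compute_epoc",
    "compute_recovery_rate",
    "summarize_metabolism",
]

BASELINE_MODES = ("rmr", "smr", "none")
RECOVERY_RULES = ("cumulative", "consecutive")


class MetricError(ValueError):
    """A trait is undefined for this series (too few cycles, no recovery)."""


@dataclass
class MetabolicSummary:
    """All whole-trial traits for one animal at one temperature."""

    smr: float
    rmr: float
    rmr_sd: float
    mmr: float
    aerobic_scope: float
    factorial_scope: float
    epoc: float | None
    recovery_time_h: float | None
    recovery_rate: float | None
    recovered: bool
    n_cycles_accepted: int
    qc_violations: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "smr": self.smr,
            "rmr": self.rmr,
            "rmr_sd": self.rmr_sd,
            "mmr": self.mmr,
            "aerobic_scope": self.aerobic_scope,
            "factorial_scope": self.factorial_scope,
            "epoc": np.nan if self.epoc is None else self.epoc,
            "recovery_time_h": np.nan
            if self.recovery_time_h is None
            else self.recovery_time_h,
            "recovery_rate": np.nan
            if self.recovery_rate is None
            else self.recovery_rate,
            "recovered": self.recovered,
            "n_cycles_accepted": self.n_cycles_accepted,
            "qc_violations": ";".join(self.qc_violations),
        }
        row.update({f"setting_{k}": v for k, v in self.settings.items()})
        return row


def _accepted_values(series: MO2Series) -> tuple[np.ndarray, np.ndarray]:
    acc = series.accepted
    return (
        acc["cycle_time_h"].to_numpy(dtype=float),
        acc["mo2"].to_numpy(dtype=float),
    )


def compute_smr(series: MO2Series, quantile: float = 0.10) -> float:
    """Mean of the lowest ``quantile`` share of accepted MO2 values.

    Requires at least 10 accepted cycles so the decile is robustly
    defined.  The count is ceil(quantile * n); ties keep cycle order
    (stable sort), so the estimate is deterministic.
    """
    _, mo2 = _accepted_values(series)
    n = len(mo2)
    if n < 10:
        raise MetricError(f"SMR needs >= 10 accepted cycles, got {n}")
    k = math.ceil(quantile * n)
    idx = np.argsort(mo2, kind="stable")[:k]
    return float(np.mean(mo2[idx]))


def compute_mmr(series: MO2Series) -> float:
    """Single highest accepted MO2 over the entire trial."""
    _, mo2 = _accepted_values(series)
    if len(mo2) == 0:
        raise MetricError("MMR needs at least one accepted cycle")
    return float(np.max(mo2))


def compute_rmr(
    series: MO2Series, recovery_window_start_h: float = 16.0
) -> tuple[float, float]:
    """Mean and SD of accepted MO2 from the recovery window to trial end."""
    t, mo2 = _accepted_values(series)
    sel = mo2[t >= recovery_window_start_h]
    if len(sel) == 0:
        raise MetricError(
            f"no accepted cycles at or beyond {recovery_window_start_h} h"
        )
    if len(sel) == 1:
        return float(sel[0]), 0.0
    return float(np.mean(sel)), float(np.std(sel, ddof=1))


def compute_recovery_time(
    series: MO2Series,
    rmr: float,
    rmr_sd: float,
    rule: str = "cumulative",
) -> float | None:
    """Time at which MO2 has fallen three times below RMR + 1 SD.

    ``rule='cumulative'`` (default) takes the third sub-threshold cycle
    counted from trial start; ``'consecutive'`` requires a run of three
    in a row and returns the time of the run's third cycle.  Returns
    ``None`` when fewer than three qualifying cycles exist (animal not
    recovered within the trial).
    """
    if rule not in RECOVERY_RULES:
        raise ValueError(f"rule must be one of {RECOVERY_RULES}")
    t, mo2 = _accepted_values(series)
    below = mo2 < (rmr + rmr_sd)
    if rule == "cumulative":
        idx = np.flatnonzero(below)
        if len(idx) < 3:
            return None
        return float(t[idx[2]])
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run == 3:
            return float(t[i])
    return None


def compute_epoc(
    series: MO2Series,
    recovery_time_h: float,
    baseline_mode: str = "rmr",
    rmr: float | None = None,
    smr: float | None = None,
) -> float:
    """Excess post-exercise oxygen consumption (mg O2 kg^-1).

    Trapezoidal integral of (MO2 - baseline), clipped at zero, from the
    first accepted cycle to ``recovery_time_h``.  Baseline is RMR by
    default; ``smr`` uses the standard rate and ``none`` integrates the
    raw curve (the literal area under the curve).
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
    if recovery_time_h is None:
        raise MetricError("EPOC undefined: recovery time not reached")
    t, mo2 = _accepted_values(series)
    sel = t <= recovery_time_h + 1e-12
    t, mo2 = t[sel], mo2[sel]
    if len(t) < 2:
        raise MetricError("EPOC needs >= 2 accepted cycles before recovery")
    if baseline_mode == "rmr":
        if rmr is None:
            raise ValueError("baseline_mode 'rmr' requires rmr")
        baseline = rmr
    elif baseline_mode == "smr":
        if smr is None:
            raise ValueError("baseline_mode 'smr' requires smr")
        baseline = smr
    else:
        baseline = 0.0
    excess = np.clip(mo2 - baseline, 0.0, None)
    return float(np.trapezoid(excess, t))


def compute_recovery_rate(epoc: float, recovery_time_h: float) -> float:
    """EPOC divided by recovery time (mg O2 h^-1 kg^-1)."""
    if recovery_time_h is None or recovery_time_h <= 0:
        raise MetricError("recovery rate undefined: non-positive recovery time")
    return epoc / recovery_time_h


def summarize_metabolism(
    series: MO2Series,
    recovery_window_start_h: float = 16.0,
    baseline_mode: str = "rmr",
    recovery_rule: str = "cumulative",
    smr_quantile: float = 0.10,
) -> MetabolicSummary:
    """Derive the full trait set for one trial.

    The SMR <= RMR <= MMR ordering is checked and violations surfaced
    in ``qc_violations`` — never silently reordered.  All mode choices
    are echoed in ``settings`` for provenance.
    """
    smr = compute_smr(series, quantile=smr_quantile)
    mmr = compute_mmr(series)
    rmr, rmr_sd = compute_rmr(series, recovery_window_start_h)
    violations = []
    if not smr <= rmr:
        violations.append(f"smr ({smr:.3g}) > rmr ({rmr:.3g})")
    if not rmr <= mmr:
        violations.append(f"rmr ({rmr:.3g}) > mmr ({mmr:.3g})")
    rec_t = compute_recovery_time(series, rmr, rmr_sd, rule=recovery_rule)
    if rec_t is not None:
        epoc = compute_epoc(series, rec_t, baseline_mode, rmr=rmr, smr=smr)
        rate = compute_recovery_rate(epoc, rec_t)
        recovered = True
    else:
        epoc = rate = None
        recovered = False
    return MetabolicSummary(
        smr=smr,
        rmr=rmr,
        rmr_sd=rmr_sd,
        mmr=mmr,
        aerobic_scope=mmr - smr,
        factorial_scope=mmr / smr,
        epoc=epoc,
        recovery_time_h=rec_t,
        recovery_rate=rate,
        recovered=recovered,
        n_cycles_accepted=series.n_accepted,
        qc_violations=violations,
        settings=dict(
            recovery_window_start_h=recovery_window_start_h,
            baseline_mode=baseline_mode,
            recovery_rule=recovery_rule,
            smr_quantile=smr_quantile,
        ),
    )
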