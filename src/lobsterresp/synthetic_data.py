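"""Synthetic respirometry trials and chase tracks with known ground truth.

The generator emulates the study design the package analyses: two spiny
lobster species held at three acclimation temperatures (14.0, 17.5 and
21.5 degC) and each measured acutely at the same three temperatures in a
fully factorial design.  Each simulated trial produces

* a true mass-specific oxygen-consumption trajectory — an exponential
  return from the post-chase maximum (MMR) toward the routine rate
  (RMR), interrupted by quiescent rest bouts that dip to the standard
  rate (SMR) and sparse spontaneous activity bursts;
* a chamber oxygen trace obtained by forward-integrating that
  trajectory through alternating sealed-measure and flush phases, with
  background (microbial) respiration and Gaussian sensor noise;
* a chase click track whose per-event displacement encodes a known
  escape speed.

Every record carries its own :class:`SimulationTruth`, so parameter
recovery (estimate vs truth) can be asserted at any pipeline stage.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from lobsterresp.trace_io import (
    FLUSH,
    MEASURE,
    TRACE_COLUMNS,
    AnimalRecord,
    ChaseTrack,
    OxygenTrace,
)

__all__ = [
    "SimulationTruth",
    "ChamberSpec",
    "CohortDesign",
    "Trajectory",
    "simulate_mo2_trajectory",
    "synthesize_trace",
    "simulate_chase_track",
    "simulate_cohort",
    "substream_seed",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of one simulated trial.

    Rates are mass-specific (mg O2 h^-1 kg^-1).  ``epoc_true`` is the
    analytic excess-oxygen integral above RMR of the exponential
    recovery, (MMR - RMR) * tau.
    """

    smr_true: float = 40.0
    rmr_true: float = 50.0
    mmr_true: float = 110.0
    tau_recovery_h: float = 3.0
    q10_smr: float = 3.3
    background_fraction: float = 0.05
    noise_sd: float = 0.01  # mg O2 L^-1, per-sample sensor noise
    activity_burst_rate: float = 0.1  # spontaneous bursts h^-1
    quiescent_fraction: float = 0.15  # long-run share of time resting at SMR
    quiescent_bout_h: float = 0.7  # mean rest-bout duration
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.smr_true <= self.rmr_true < self.mmr_true):
            raise ValueError(
                "require smr_true <= rmr_true < mmr_true, got "
                f"{self.smr_true}, {self.rmr_true}, {self.mmr_true}"
            )
        if self.tau_recovery_h <= 0:
            raise ValueError("tau_recovery_h must be > 0")
        if self.q10_smr <= 0:
            raise ValueError("q10_smr must be > 0")
        if self.background_fraction < 0:
            raise ValueError("background_fraction must be >= 0")
        if not 0 <= self.quiescent_fraction < 1:
            raise ValueError("quiescent_fraction must be in [0, 1)")

    @property
    def epoc_true(self) -> float:
        """Analytic EPOC above RMR: (MMR - RMR) * tau."""
        return (self.mmr_true - self.rmr_true) * self.tau_recovery_h

    def background_rate(self, body_mass_kg: float) -> float:
        """Whole-chamber background respiration (mg O2 h^-1)."""
        return self.background_fraction * self.smr_true * body_mass_kg


@dataclass(frozen=True)
class ChamberSpec:
    """Respirometer geometry and phase timing.

    Defaults mirror the lobster setup: a 10 L chamber holding a ~1 L
    animal, 6-min sealed measurements, 8-min flushes, 10-s sampling and
    48-h trials.
    """

    chamber_volume_l: float = 10.0
    body_volume_l: float = 1.0
    body_mass_kg: float = 1.12
    body_density_g_per_ml: float = 1.12
    measure_duration_s: float = 360.0
    flush_duration_s: float = 480.0
    sample_interval_s: float = 10.0
    saturation_concentration_mg_l: float = 8.0
    trial_duration_h: float = 48.0

    def __post_init__(self) -> None:
        if self.effective_volume_l <= 0:
            raise ValueError(
                "effective volume (chamber minus body) must be > 0; got "
                f"{self.chamber_volume_l} - {self.body_volume_l} L"
            )
        n = self.measure_duration_s / self.sample_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_interval_s must divide measure_duration_s")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")

    @property
    def effective_volume_l(self) -> float:
        return self.chamber_volume_l - self.body_volume_l

    @property
    def period_s(self) -> float:
        return self.measure_duration_s + self.flush_duration_s


@dataclass(frozen=True)
class CohortDesign:
    """Fully factorial species x acclimation x acute-temperature design."""

    species: tuple[str, ...] = ("J. edwardsii", "S. verreauxi")
    acclimation_temps_c: tuple[float, ...] = (14.0, 17.5, 21.5)
    experimental_temps_c: tuple[float, ...] = (14.0, 17.5, 21.5)
    n_per_cell: int = 6
    reference_temp_c: float = 14.0
    #: multiplicative SMR (and RMR, tau) factor applied per acclimation
    #: step above the coldest group; < 1 reproduces the "plastic floor"
    #: of maintenance metabolism under warm acclimation.
    acclimation_effect_smr: float = 0.85
    #: acute thermal sensitivity per trait (Q10 over experimental temp.)
    q10_map: Mapping[str, float] = field(
        default_factory=lambda: {"smr": 3.3, "mmr": 1.4}
    )
    #: species-level trait multipliers relative to the first species;
    #: the range-shifting species carries a larger aerobic ceiling and
    #: stronger escape performance.
    species_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "S. verreauxi": {"mmr": 1.13, "speed": 1.15, "flips": 1.28}
        }
    )
    #: between-animal lognormal coefficient of variation on trait truths
    individual_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not self.species:
            raise ValueError("design needs at least one species")

    @property
    def n_records(self) -> int:
        return (
            len(self.species)
            * len(self.acclimation_temps_c)
            * len(self.experimental_temps_c)
            * self.n_per_cell
        )


@dataclass
class Trajectory:
    """True MO2 curve sampled on a regular grid (hours, mg O2 h^-1 kg^-1)."""

    time_h: np.ndarray
    mo2: np.ndarray
    truth: SimulationTruth

    def mo2_at(self, t_h: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t_h, self.time_h, self.mo2)


def substream_seed(seed: int, label: str) -> int:
    """Stable per-animal substream seed from a global seed and an ID.

    Hashing keeps substreams reproducible under partial re-runs and
    independent of generation order.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def q10_scale(rate: float, q10: float, t_c: float, t_ref_c: float) -> float:
    """Scale a rate from ``t_ref_c`` to ``t_c`` with thermal coefficient q10."""
    return rate * q10 ** ((t_c - t_ref_c) / 10.0)


def simulate_mo2_trajectory(
    truth: SimulationTruth,
    duration_h: float,
    step_h: float,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> Trajectory:
    """Simulate the true post-exhaustion MO2 curve.

    The deterministic backbone is ``RMR + (MMR - RMR) * exp(-t/tau)``,
    whose excess integral above RMR is exactly ``epoc_true``.  With
    ``stochastic=True`` two behavioural layers are added:

    * quiescent rest bouts during which the baseline drops from RMR to
      SMR — a two-state (rest/active) alternating-renewal process with
      exponential bout lengths.  Bouts are suppressed while the
      recovery excess still exceeds half the RMR-SMR gap, since a
      freshly exhausted animal ventilates heavily rather than resting;
    * sparse activity bursts (Poisson in time, rectangular in shape)
      capped so MO2 never exceeds MMR.

    Raises ``ValueError`` for non-positive ``tau``/``step``.
    """
    if truth.tau_recovery_h <= 0:
        raise ValueError("tau_recovery_h must be > 0")
    if step_h <= 0:
        raise ValueError("step_h must be > 0")
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    if rng is None:
        rng = np.random.default_rng(truth.seed)

    n = int(round(duration_h / step_h)) + 1
    t = np.arange(n) * step_h
    excess = (truth.mmr_true - truth.rmr_true) * np.exp(-t / truth.tau_recovery_h)
    baseline = np.full(n, truth.rmr_true)

    if stochastic and truth.quiescent_fraction > 0:
        gap = truth.rmr_true - truth.smr_true
        quiescent = _rest_bouts(
            t, truth.quiescent_fraction, truth.quiescent_bout_h, rng
        )
        if gap > 0:
            # no resting while recovery excess dominates the dip
            quiescent &= excess < 0.5 * gap
        baseline = np.where(quiescent, truth.smr_true, truth.rmr_true)

    mo2 = baseline + excess

    if stochastic and truth.activity_burst_rate > 0:
        n_bursts = rng.poisson(truth.activity_burst_rate * duration_h)
        scope = truth.mmr_true - truth.rmr_true
        for _ in range(n_bursts):
            t0 = rng.uniform(0.0, duration_h)
            width = rng.exponential(0.1)
            amp = rng.uniform(0.2, 0.5) * scope
            mo2 = np.where((t >= t0) & (t < t0 + width), mo2 + amp, mo2)
        mo2 = np.minimum(mo2, truth.mmr_true)

    return Trajectory(time_h=t, mo2=mo2, truth=truth)


def _rest_bouts(
    t: np.ndarray, fraction: float, mean_bout_h: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean rest mask from an alternating-renewal (active/rest) process."""
    duration = float(t[-1]) if len(t) else 0.0
    mean_active = mean_bout_h * (1.0 - fraction) / fraction
    mask = np.zeros_like(t, dtype=bool)
    pos = 0.0
    resting = False
    while pos < duration:
        bout = rng.exponential(mean_bout_h if resting else mean_active)
        if resting:
            mask |= (t >= pos) & (t < pos + bout)
        pos += bout
        resting = not resting
    return mask


def synthesize_trace(
    trajectory: Trajectory,
    chamber: ChamberSpec,
    truth: SimulationTruth | None = None,
    rng: np.random.Generator | None = None,
    temperature_c: float = 14.0,
    channel_id: str = "ch1",
) -> OxygenTrace:
    """Forward-model the chamber oxygen trace for one trial.

    During each sealed measure phase the concentration falls at
    ``(MO2(t) * mass + background) / V_eff``; during each flush it
    relaxes exponentially back toward saturation, reaching >= 99% of it
    by the end of the flush.  Gaussian sensor noise (sd ``noise_sd``) is
    added to the recorded samples only, never to the chamber state.
    """
    if truth is None:
        truth = trajectory.truth
    if rng is None:
        rng = np.random.default_rng(substream_seed(truth.seed, "trace"))
    if trajectory.time_h[-1] < chamber.trial_duration_h - 1e-9:
        raise ValueError(
            "trajectory shorter than trial duration: "
            f"{trajectory.time_h[-1]:g} h < {chamber.trial_duration_h:g} h"
        )

    dt = chamber.sample_interval_s
    n_meas = int(round(chamber.measure_duration_s / dt))
    n_flush = max(int(round(chamber.flush_duration_s / dt)), 0)
    n_cycles = int(chamber.trial_duration_h * 3600.0 // chamber.period_s)
    if n_cycles < 1:
        raise ValueError("trial too short for a single measure cycle")
    sat = chamber.saturation_concentration_mg_l
    v_eff = chamber.effective_volume_l
    mass = chamber.body_mass_kg
    bg = truth.background_rate(mass)
    k_flush = math.log(100.0) / chamber.flush_duration_s  # 99% recovery

    times: list[np.ndarray] = []
    conc: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    cycles: list[np.ndarray] = []

    c = sat
    for k in range(n_cycles):
        t0 = k * chamber.period_s
        # sealed measure: Euler forward at the sampling resolution
        t_meas = t0 + np.arange(n_meas) * dt
        mo2 = np.asarray(trajectory.mo2_at(t_meas / 3600.0), dtype=float)
        drop = (mo2 * mass + bg) / v_eff * (dt / 3600.0)
        c_meas = c - np.concatenate(([0.0], np.cumsum(drop[:-1])))
        c_end = c - float(np.sum(drop))
        if c_end <= 0 or c_meas.min() <= 0:
            raise ValueError(
                f"oxygen concentration would go non-positive in cycle {k}; "
                "parameters imply implausible depletion"
            )
        times.append(t_meas)
        conc.append(c_meas)
        phases.append(np.full(n_meas, MEASURE, dtype=object))
        cycles.append(np.full(n_meas, k, dtype=int))
        c = c_end
        if n_flush:
            t_fl = t0 + chamber.measure_duration_s + np.arange(n_flush) * dt
            rel = t_fl - (t0 + chamber.measure_duration_s)
            c_fl = sat - (sat - c) * np.exp(-k_flush * rel)
            times.append(t_fl)
            conc.append(c_fl)
            phases.append(np.full(n_flush, FLUSH, dtype=object))
            cycles.append(np.full(n_flush, k, dtype=int))
            c = sat - (sat - c) * math.exp(-k_flush * chamber.flush_duration_s)

    time_s = np.concatenate(times)
    o2 = np.concatenate(conc)
    if truth.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, truth.noise_sd, size=o2.shape)
    df = pd.DataFrame(
        {
            "time_s": time_s,
            "o2_mg_l": o2,
            "temp_c": temperature_c,
            "phase": np.concatenate(phases),
            "cycle_index": np.concatenate(cycles),
        },
        columns=TRACE_COLUMNS,
    )
    return OxygenTrace(df, channel_id=channel_id)


def simulate_chase_track(
    true_speed_cm_s: float,
    n_flips: int,
    fps: float = 24.0,
    px_per_cm: float = 1.0,
    seed: int = 0,
    frame_gap_range: tuple[int, int] = (6, 30),
    inter_event_gap_range: tuple[int, int] = (12, 120),
    arena_px: float = 1000.0,
) -> ChaseTrack:
    """Generate a click track whose calibrated event speeds equal the truth.

    Each tail flip displaces the animal by ``true_speed * gap/fps *
    px_per_cm`` pixels in a uniformly random direction, so the speed
    recovered through the kinematics module equals ``true_speed_cm_s``
    to machine precision.  ``n_flips=0`` yields a valid empty track.
    """
    if true_speed_cm_s < 0:
        raise ValueError("true_speed_cm_s must be >= 0")
    if fps <= 0 or px_per_cm <= 0:
        raise ValueError("fps and px_per_cm must be > 0")
    if n_flips < 0:
        raise ValueError("n_flips must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    frame = 0
    x, y = arena_px / 2.0, arena_px / 2.0
    for _ in range(n_flips):
        gap = int(rng.integers(frame_gap_range[0], frame_gap_range[1] + 1))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        dist_px = true_speed_cm_s * (gap / fps) * px_per_cm
        x1 = x + dist_px * np.cos(theta)
        y1 = y + dist_px * np.sin(theta)
        rows.append((frame, x, y, frame + gap, x1, y1))
        frame += gap + int(
            rng.integers(inter_event_gap_range[0], inter_event_gap_range[1] + 1)
        )
        x, y = x1, y1
    events = pd.DataFrame(rows, columns=ChaseTrack.EVENT_COLUMNS)
    return ChaseTrack(events, fps=fps, px_per_cm=px_per_cm)


def _jitter(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal individual variation with unit median."""
    if cv <= 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, cv)))


@dataclass
class CohortRecord:
    """One simulated trial: metadata, trace, chase track and its truth."""

    animal: AnimalRecord
    trace: OxygenTrace
    track: ChaseTrack
    truth: SimulationTruth
    n_flips_true: int
    true_speed_cm_s: float


def simulate_cohort(
    design: CohortDesign,
    base_truth: SimulationTruth = SimulationTruth(),
    chamber: ChamberSpec = ChamberSpec(),
    seed: int | None = None,
    base_speed_cm_s: float = 60.0,
    base_flips: float = 30.0,
    px_per_cm: float = 8.0,
    fps: float = 24.0,
) -> list[CohortRecord]:
    """Simulate the full factorial cohort.

    Trait truths scale across experimental temperature by the trait Q10
    (``rate * q10 ** ((T - T_ref)/10)``), across acclimation by the
    multiplicative per-step acclimation factor, and across species by
    the configured species effects.  Tail-flip counts are coupled to
    each animal's true EPOC so that escape-vs-EPOC correlations have a
    known positive sign.
    """
    if seed is None:
        seed = base_truth.seed
    records: list[CohortRecord] = []
    rmr_ratio = base_truth.rmr_true / base_truth.smr_true
    q10_smr = design.q10_map.get("smr", base_truth.q10_smr)
    q10_mmr = design.q10_map.get("mmr", 1.4)
    counter = 0
    for species in design.species:
        sp_eff = dict(design.species_effects.get(species, {}))
        for acc_i, t_acc in enumerate(design.acclimation_temps_c):
            acc_factor = design.acclimation_effect_smr**acc_i
            for rep in range(design.n_per_cell):
                counter += 1
                animal_id = f"{species.split('.')[-1].strip().lower()}-a{t_acc:g}-{rep + 1:02d}"
                arng = np.random.default_rng(substream_seed(seed, animal_id))
                mass = float(np.clip(arng.normal(1.10, 0.10), 0.7, 1.6))
                sex = "m" if arng.random() < 0.6 else "f"
                cl = float(np.clip(arng.normal(12.0, 1.0), 9.0, 15.0))
                ind_smr = _jitter(arng, design.individual_cv)
                ind_mmr = _jitter(arng, design.individual_cv)
                ind_tau = _jitter(arng, design.individual_cv)
                for t_exp in design.experimental_temps_c:
                    trial_id = f"{animal_id}-e{t_exp:g}"
                    trial_seed = substream_seed(seed, trial_id)
                    trng = np.random.default_rng(trial_seed)
                    smr = (
                        q10_scale(base_truth.smr_true, q10_smr, t_exp, design.reference_temp_c)
                        * acc_factor
                        * ind_smr
                        * sp_eff.get("smr", 1.0)
                    )
                    rmr = smr * rmr_ratio
                    mmr = (
                        q10_scale(base_truth.mmr_true, q10_mmr, t_exp, design.reference_temp_c)
                        * ind_mmr
                        * sp_eff.get("mmr", 1.0)
                    )
                    if mmr <= rmr:  # guard pathological corners of the grid
                        mmr = rmr * 1.2
                    tau = base_truth.tau_recovery_h * acc_factor * ind_tau
                    truth = replace(
                        base_truth,
                        smr_true=smr,
                        rmr_true=rmr,
                        mmr_true=mmr,
                        tau_recovery_h=tau,
                        seed=trial_seed,
                    )
                    animal = AnimalRecord(
                        animal_id=animal_id,
                        species=species,
                        sex=sex,
                        body_mass_kg=mass,
                        body_volume_l=mass / chamber.body_density_g_per_ml,
                        carapace_length_cm=cl,
                        acclimation_temp_c=t_acc,
                        experimental_temp_c=t_exp,
                    )
                    cham = replace(
                        chamber,
                        body_mass_kg=mass,
                        body_volume_l=mass / chamber.body_density_g_per_ml,
                    )
                    traj = simulate_mo2_trajectory(
                        truth,
                        duration_h=cham.trial_duration_h,
                        step_h=cham.sample_interval_s / 3600.0,
                        rng=np.random.default_rng(substream_seed(seed, trial_id + ":traj")),
                    )
                    trace = synthesize_trace(
                        traj,
                        cham,
                        truth,
                        rng=np.random.default_rng(substream_seed(seed, trial_id + ":noise")),
                        temperature_c=t_exp,
                        channel_id=trial_id,
                    )
                    # escape performance coupled to anaerobic capacity
                    speed = (
                        base_speed_cm_s
                        * sp_eff.get("speed", 1.0)
                        * _jitter(trng, design.individual_cv)
                    )
                    lam = base_flips * sp_eff.get("flips", 1.0) * (
                        truth.epoc_true / base_truth.epoc_true
                    )
                    n_flips = int(trng.poisson(max(lam, 1.0)))
                    track = simulate_chase_track(
                        speed,
                        n_flips,
                        fps=fps,
                        px_per_cm=px_per_cm,
                        seed=substream_seed(seed, trial_id + ":track"),
                    )
                    records.append(
                        CohortRecord(
                            animal=animal,
                            trace=trace,
                            track=track,
                            truth=truth,
                            n_flips_true=n_flips,
                            true_speed_cm_s=speed,
                        )
                    )
    return records
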