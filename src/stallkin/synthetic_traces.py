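"""Stochastic simulator of magnetic-trap transcription experiments.

Generates extension-versus-time traces and dwell-time samples that mimic the
three assay geometries:

* **recycling** — constant low force on supercoiled DNA; the polymerase
  binds, scrunches (~100 nm extension drop), elongates to the stall site
  (~50 nm below baseline), and is eventually removed, returning the trace to
  baseline; the cycle repeats;
* **force-cycling** — alternating low-force windows (binding and stalling
  allowed) and high-force windows (elevated torque, faster removal; high
  positive torque blocks re-initiation);
* direct dwell sampling at a fixed condition, the work-horse for parameter-
  recovery studies.

The single-molecule removal rate composes the Bell torque law with
Michaelis-Menten saturation in [RapA] and [ATP]:

    k(Gamma, c_R, c_A) = k0*exp(theta0*Gamma)
        + kcat * MM(c_R; Km_R) * MM(c_A; Km_A) * exp(theta*(Gamma - Gamma_ref))

with Gamma_ref = +12 pN·nm, the torque at which the concentration series
were measured, so that the torque fit and both saturation fits are
reproduced simultaneously.  Removal never occurs at negative torque
(rate identically zero), matching the observation that neither pathway
dissociates the polymerase from underwound DNA.

Every stochastic operation takes an explicit seed; the same seed gives
byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .mechanics import TWO_XI_KBT, Torque, TrapConditions, torque_from_force
from .survival import DwellSet

#: Torque (pN·nm) of the reference condition for the concentration series.
GAMMA_REF_PN_NM = 12.0

#: Above this extending force the polymerase cannot reliably initiate on
#: positively supercoiled DNA (config threshold, not derived).
INIT_FORCE_CEILING_PN = 0.9

#: Fractional baseline extension in the low-force window of the
#: force-cycling protocol (schematic two-level force-extension mapping).
LOW_FORCE_BASELINE_FACTOR = 0.75


@dataclass(frozen=True)
class TraceConfig:
    """Sampling and geometry of a simulated trace.

    The ~100 nm scrunching drop and ~50 nm elongation/stall drop are the
    trace-level signatures of initiation and stalling; noise is iid Gaussian
    per sample.
    """

    sampling_rate: float = 30.0  # Hz
    noise_sd: float = 10.0  # nm
    baseline_extension: float = 500.0  # nm
    scrunch_drop: float = 100.0  # nm
    elongation_drop: float = 50.0  # nm
    seed: int = 0
    scrunch_exit_rate: float = 0.1  # s^-1, promoter-escape rate out of scrunching

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.scrunch_drop <= 0 or self.elongation_drop <= 0:
            raise ValueError("extension drops must be > 0 nm")

    @property
    def levels(self) -> dict[str, float]:
        """Noise-free extension level of each state, nm."""
        return {
            "baseline": self.baseline_extension,
            "scrunched": self.baseline_extension - self.scrunch_drop,
            "stalled": self.baseline_extension - self.elongation_drop,
        }


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the composed removal model.

    ``theta0_over_kBT`` is the torque sensitivity of the intrinsic
    (enzyme-free) pathway and ``theta_over_kBT`` that of the RapA pathway;
    the two printed fits differ slightly (0.11 vs 0.09 rad/pN·nm) so both
    are carried.  ``greb_rescue_rate`` models GreB anti-backtracking rescue
    as a competing transition that locks the stalled complex in place.
    """

    k0: float = 1.02e-6  # s^-1, intrinsic zero-torque dissociation
    theta0_over_kBT: float = 0.1133  # rad per pN·nm, intrinsic pathway
    theta_over_kBT: float = 0.0953  # rad per pN·nm, RapA pathway
    Km_rapa: float = 7.2  # nM
    kcat: float = 1.1e-3  # s^-1 at saturation, reference torque
    Km_atp: float = 160.0  # uM
    initiation_rate: float = 0.01  # s^-1, lumped binding + promoter escape
    greb_rescue_rate: float = 0.0  # s^-1; 0 = GreB absent

    def __post_init__(self) -> None:
        for name in (
            "k0",
            "theta0_over_kBT",
            "theta_over_kBT",
            "Km_rapa",
            "kcat",
            "Km_atp",
            "initiation_rate",
            "greb_rescue_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class Trace:
    """Sampled extension-versus-time series with protocol annotations."""

    times: np.ndarray  # s, strictly increasing
    extensions: np.ndarray  # nm
    force_schedule: np.ndarray  # pN, piecewise constant, per sample
    turns: int  # signed number of applied turns
    event_log: list[tuple[float, str]] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan


def _gamma(torque: Torque | float) -> float:
    return torque.value if isinstance(torque, Torque) else float(torque)


def effective_rate(
    params: KineticParams,
    torque: Torque | float,
    rapa: float,
    atp: float,
) -> float:
    """Removal rate (s^-1) at a torque and [RapA]/[ATP] combination.

    Intrinsic and RapA-catalysed pathways add; both are identically zero at
    negative torque, where removal is never observed.

    Parameters
    ----------
    rapa : float
        RapA concentration, nM.
    atp : float
        ATP concentration, uM.
    """
    if rapa < 0:
        raise ValueError(f"rapa must be >= 0 nM, got {rapa}")
    if atp < 0:
        raise ValueError(f"atp must be >= 0 uM, got {atp}")
    gamma = _gamma(torque)
    if gamma < 0:
        return 0.0
    rate = params.k0 * np.exp(params.theta0_over_kBT * gamma)
    if rapa > 0 and atp > 0:
        mm = (rapa / (params.Km_rapa + rapa)) * (atp / (params.Km_atp + atp))
        rate += params.kcat * mm * np.exp(
            params.theta_over_kBT * (gamma - GAMMA_REF_PN_NM)
        )
    return float(rate)


def simulate_dwells(
    params: KineticParams,
    torque: Torque | float,
    rapa: float,
    atp: float,
    n: int,
    censor_time: float = np.inf,
    seed: int = 0,
) -> DwellSet:
    """Draw n iid exponential residence times at the effective rate.

    Draws exceeding ``censor_time`` are recorded as right-censored at that
    time.  A zero rate with finite ``censor_time`` returns an all-censored
    set with a warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rate = effective_rate(params, torque, rapa, atp)
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        if not np.isfinite(censor_time):
            raise ValueError("zero removal rate with infinite censor_time")
        warnings.warn("removal rate is zero: returning an all-censored set")
        draws = np.full(n, np.inf)
    else:
        draws = rng.exponential(1.0 / rate, size=n)
    censored = draws > censor_time
    durations = np.where(censored, censor_time, draws)
    return DwellSet.from_durations(
        durations,
        censored,
        condition={
            "torque": _gamma(torque),
            "rapa_nM": rapa,
            "atp_uM": atp,
            "censor_time": censor_time,
            "seed": seed,
        },
    )


def _sample_segments(
    segments: list[tuple[float, float, str]],
    levels: dict[str, float],
    cfg: TraceConfig,
    duration: float,
    rng: np.random.Generator,
    forces: list[tuple[float, float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample piecewise-constant state segments onto a regular time grid."""
    dt = 1.0 / cfg.sampling_rate
    times = np.arange(0.0, duration, dt)
    starts = np.array([s for s, _, _ in segments])
    level_vals = np.array([levels[name] for _, _, name in segments])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segments) - 1)
    ext = level_vals[idx]
    if cfg.noise_sd > 0:
        ext = ext + rng.normal(0.0, cfg.noise_sd, size=ext.shape)
    if forces is None:
        force = np.full_like(times, np.nan)
    else:
        fstarts = np.array([s for s, _, _ in forces])
        fvals = np.array([f for _, _, f in forces])
        fidx = np.clip(
            np.searchsorted(fstarts, times, side="right") - 1, 0, len(forces) - 1
        )
        force = fvals[fidx]
    return times, ext, force


def simulate_recycling_trace(
    params: KineticParams,
    trace_cfg: TraceConfig,
    torque: Torque | float,
    rapa: float,
    atp: float,
    duration: float,
) -> Trace:
    """Iterative bind/scrunch/stall/remove cycles at constant low force.

    Waiting times are exponential: initiation at ``initiation_rate``,
    promoter escape out of scrunching at ``scrunch_exit_rate``, and removal
    at the effective rate for the given torque and concentrations.  With a
    positive ``greb_rescue_rate`` a competing rescue transition can lock the
    stalled complex for the remainder of the trace (right-censored cycle).
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    rng = np.random.default_rng(trace_cfg.seed)
    removal_rate = effective_rate(params, torque, rapa, atp)
    segments: list[tuple[float, float, str]] = []
    events: list[tuple[float, str]] = []
    t = 0.0
    while t < duration:
        # baseline until initiation
        if params.initiation_rate == 0:
            segments.append((t, duration, "baseline"))
            break
        wait = rng.exponential(1.0 / params.initiation_rate)
        t_init = t + wait
        segments.append((t, min(t_init, duration), "baseline"))
        if t_init >= duration:
            break
        events.append((t_init, "initiation"))
        # scrunched intermediate until promoter escape
        t_stall = t_init + rng.exponential(1.0 / trace_cfg.scrunch_exit_rate)
        segments.append((t_init, min(t_stall, duration), "scrunched"))
        if t_stall >= duration:
            break
        events.append((t_stall, "stall"))
        # stalled until removal (or GreB lock, or trace end)
        t_rem = (
            t_stall + rng.exponential(1.0 / removal_rate)
            if removal_rate > 0
            else np.inf
        )
        if params.greb_rescue_rate > 0:
            t_lock = t_stall + rng.exponential(1.0 / params.greb_rescue_rate)
            if t_lock < t_rem:
                events.append((min(t_lock, duration), "lock"))
                t_rem = np.inf
        segments.append((t_stall, min(t_rem, duration), "stalled"))
        if t_rem >= duration:
            break
        events.append((t_rem, "removal"))
        t = t_rem
    times, ext, _ = _sample_segments(
        segments, trace_cfg.levels, trace_cfg, duration, rng
    )
    gamma = _gamma(torque)
    return Trace(
        times=times,
        extensions=ext,
        force_schedule=np.full_like(times, gamma**2 / TWO_XI_KBT if gamma else 0.3),
        turns=int(np.sign(gamma)) * 30,
        event_log=events,
        meta={
            "protocol": "recycling",
            "levels": trace_cfg.levels,
            "torque": gamma,
            "rapa_nM": rapa,
            "atp_uM": atp,
            "sampling_rate": trace_cfg.sampling_rate,
            "noise_sd": trace_cfg.noise_sd,
        },
    )


def simulate_force_cycle_dwells(
    params: KineticParams,
    low_force: float,
    high_force: float,
    hold_low: float,
    n_cycles: int,
    seed: int = 0,
    rapa: float = 0.0,
    atp: float = 1000.0,
    supercoil_sign: int = 1,
) -> DwellSet:
    """Event-level force-cycling protocol: residence times over n cycles.

    Each cycle holds the molecule at ``low_force`` for ``hold_low`` seconds
    (binding and stalling allowed when the force is below the initiation
    ceiling), then raises the force until removal.  The removal clock runs
    at the torque of the current force.  Dwells are recorded the way the
    assay measures them: for a removal in the high-force window, from the
    force step to dissociation; for the (rare) removal at low force, from
    stalling to dissociation.  Cycles without initiation yield no record;
    the simulation continues until ``n_cycles`` dwells are collected.
    """
    if low_force >= high_force:
        raise ValueError(
            f"low_force must be < high_force, got {low_force} >= {high_force}"
        )
    if hold_low <= 0:
        raise ValueError(f"hold_low must be > 0 s, got {hold_low}")
    rng = np.random.default_rng(seed)
    gamma_low = torque_from_force(TrapConditions(low_force), supercoil_sign).value
    gamma_high = torque_from_force(TrapConditions(high_force), supercoil_sign).value
    r_low = effective_rate(params, gamma_low, rapa, atp)
    r_high = effective_rate(params, gamma_high, rapa, atp)
    if r_high == 0.0 and r_low == 0.0:
        raise ValueError("removal rate is zero in both windows; no dwells possible")
    durations: list[float] = []
    windows: list[str] = []
    guard = 0
    while len(durations) < n_cycles and guard < 100 * n_cycles:
        guard += 1
        if low_force > INIT_FORCE_CEILING_PN or params.initiation_rate == 0:
            raise ValueError("initiation impossible at the low-force setting")
        t_init = rng.exponential(1.0 / params.initiation_rate)
        if t_init >= hold_low:
            continue  # no initiation this cycle
        low_left = hold_low - t_init
        t_rem_low = rng.exponential(1.0 / r_low) if r_low > 0 else np.inf
        if t_rem_low < low_left:
            durations.append(t_rem_low)
            windows.append("low")
            continue
        t_rem_high = rng.exponential(1.0 / r_high) if r_high > 0 else np.inf
        durations.append(t_rem_high)
        windows.append("high")
    return DwellSet.from_durations(
        durations,
        condition={
            "protocol": "force-cycling",
            "low_force": low_force,
            "high_force": high_force,
            "torque_low": gamma_low,
            "torque_high": gamma_high,
            "removal_window": windows,
            "rapa_nM": rapa,
            "atp_uM": atp,
            "seed": seed,
        },
    )


def simulate_force_cycle_trace(
    params: KineticParams,
    trace_cfg: TraceConfig,
    low_force: float,
    high_force: float,
    hold_low: float,
    duration: float,
    rapa: float = 0.0,
    atp: float = 1000.0,
    supercoil_sign: int = 1,
) -> Trace:
    """Sampled extension trace of the force-cycling protocol.

    Baseline extension in the low-force window is a fixed fraction of the
    high-force baseline (schematic two-level force-extension mapping); the
    scrunch and stall drops ride on the current baseline.  Re-initiation is
    suppressed in the high-force window (elevated positive torque blocks
    initiation).
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    if low_force >= high_force:
        raise ValueError(
            f"low_force must be < high_force, got {low_force} >= {high_force}"
        )
    if hold_low <= 0:
        raise ValueError(f"hold_low must be > 0 s, got {hold_low}")
    rng = np.random.default_rng(trace_cfg.seed)
    gamma_low = torque_from_force(TrapConditions(low_force), supercoil_sign).value
    gamma_high = torque_from_force(TrapConditions(high_force), supercoil_sign).value
    r_low = effective_rate(params, gamma_low, rapa, atp)
    r_high = effective_rate(params, gamma_high, rapa, atp)
    can_init = low_force <= INIT_FORCE_CEILING_PN and params.initiation_rate > 0

    base = trace_cfg.baseline_extension
    levels = {
        "baseline_low": base * LOW_FORCE_BASELINE_FACTOR,
        "scrunched_low": base * LOW_FORCE_BASELINE_FACTOR - trace_cfg.scrunch_drop,
        "stalled_low": base * LOW_FORCE_BASELINE_FACTOR - trace_cfg.elongation_drop,
        "baseline_high": base,
        "stalled_high": base - trace_cfg.elongation_drop,
    }
    segments: list[tuple[float, float, str]] = []
    forces: list[tuple[float, float, float]] = []
    events: list[tuple[float, str]] = []
    t = 0.0
    stalled = False
    while t < duration:
        # ---- low-force window ----
        w_end = min(t + hold_low, duration)
        forces.append((t, w_end, low_force))
        if t > 0:
            events.append((t, "force_down"))
        cur = t
        while cur < w_end:
            if not stalled:
                if not can_init:
                    segments.append((cur, w_end, "baseline_low"))
                    cur = w_end
                    break
                t_init = cur + rng.exponential(1.0 / params.initiation_rate)
                segments.append((cur, min(t_init, w_end), "baseline_low"))
                if t_init >= w_end:
                    cur = w_end
                    break
                events.append((t_init, "initiation"))
                t_stall = t_init + rng.exponential(1.0 / trace_cfg.scrunch_exit_rate)
                segments.append((t_init, min(t_stall, w_end), "scrunched_low"))
                if t_stall >= w_end:
                    cur = w_end
                    stalled = True  # carries the scrunched->stalled hand-off
                    events.append((min(t_stall, w_end), "stall"))
                    break
                events.append((t_stall, "stall"))
                stalled = True
                cur = t_stall
            else:
                t_rem = (
                    cur + rng.exponential(1.0 / r_low) if r_low > 0 else np.inf
                )
                segments.append((cur, min(t_rem, w_end), "stalled_low"))
                if t_rem >= w_end:
                    cur = w_end
                    break
                events.append((t_rem, "removal"))
                stalled = False
                cur = t_rem
        t = w_end
        if t >= duration:
            break
        # ---- high-force window: lasts until removal (or trace end) ----
        events.append((t, "force_up"))
        if stalled:
            t_rem = t + rng.exponential(1.0 / r_high) if r_high > 0 else np.inf
            segments.append((t, min(t_rem, duration), "stalled_high"))
            if t_rem >= duration:
                forces.append((t, duration, high_force))
                t = duration
                break
            events.append((t_rem, "removal"))
            stalled = False
            w_end = min(t_rem + 1.0 / trace_cfg.sampling_rate, duration)
            segments.append((t_rem, w_end, "baseline_high"))
            forces.append((t, w_end, high_force))
            t = w_end
        else:
            w_end = min(t + hold_low, duration)
            segments.append((t, w_end, "baseline_high"))
            forces.append((t, w_end, high_force))
            t = w_end
    times, ext, force = _sample_segments(
        segments, levels, trace_cfg, duration, rng, forces
    )
    return Trace(
        times=times,
        extensions=ext,
        force_schedule=force,
        turns=supercoil_sign * 30,
        event_log=events,
        meta={
            "protocol": "force-cycling",
            "levels": levels,
            "low_force": low_force,
            "high_force": high_force,
            "torque_low": gamma_low,
            "torque_high": gamma_high,
            "rapa_nM": rapa,
            "atp_uM": atp,
            "sampling_rate": trace_cfg.sampling_rate,
            "noise_sd": trace_cfg.noise_sd,
        },
    )


def event_log_dwells(trace: Trace) -> list[tuple[float, float, bool]]:
    """(start, duration, censored) of each stall from the simulator's log."""
    out = []
    start = None
    for t, ev in trace.event_log:
        if ev == "stall":
            start = t
        elif ev in ("removal", "lock") and start is not None:
            out.append((start, t - start, ev == "lock"))
            start = None
    if start is not None:
        out.append((start, trace.duration - start, True))
    return out


def write_trace(trace: Trace, path: str) -> None:
    """Write a trace as tab-separated text plus a YAML event-log sidecar."""
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "extension_nm": trace.extensions,
            "force_pN": trace.force_schedule,
            "turns": trace.turns,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "events": [[float(t), str(ev)] for t, ev in trace.event_log],
        "meta": {
            k: (dict(v) if isinstance(v, dict) else v) for k, v in trace.meta.items()
        },
        "turns": trace.turns,
    }
    with open(str(path) + ".events.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_trace(path: str) -> Trace:
    """Read a trace written by :func:`write_trace`."""
    df = pd.read_csv(path, sep="\t")
    events: list[tuple[float, str]] = []
    meta: dict[str, Any] = {}
    turns = int(df["turns"].iloc[0]) if len(df) else 0
    try:
        with open(str(path) + ".events.yaml") as fh:
            sidecar = yaml.safe_load(fh)
        events = [(float(t), str(ev)) for t, ev in sidecar.get("events", [])]
        meta = sidecar.get("meta", {})
        turns = int(sidecar.get("turns", turns))
    except FileNotFoundError:
        pass
    return Trace(
        times=df["time_s"].to_numpy(float),
        extensions=df["extension_nm"].to_numpy(float),
        force_schedule=df["force_pN"].to_numpy(float),
        turns=turns,
        event_log=events,
        meta=meta,
    )
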