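"""Single-cell pacing protocols, APD measurement and steady-state checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import maleckar
from .regions import CellParameterSet


class SimulationBlowupError(RuntimeError):
    """Raised when the integrator produces non-finite state."""

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"non-finite state at t = {time_ms:.3f} ms")


@dataclass(frozen=True)
class PacingProtocol:
    """Constant-BCL stimulus train.

    Defaults follow the stabilization protocol used throughout the package:
    1 ms, 52 pA/pF depolarizing pulses at a basic cycle length of 1000 ms,
    integrated at dt = 0.02 ms.
    """

    n_beats: int = 3600
    bcl: float = 1000.0          # ms
    stim_amplitude: float = 52.0  # pA/pF, depolarizing
    stim_duration: float = 1.0    # ms
    dt: float = 0.02              # ms
    output_dt: float = 1.0        # ms, recording interval

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.stim_duration < self.bcl:
            raise ValueError("stim_duration must be shorter than bcl")


@dataclass
class ActionPotentialTrace:
    """Vm (and intracellular concentration) samples from a pacing run."""

    time: np.ndarray                 # ms, monotone
    vm: np.ndarray                   # mV
    concentrations: np.ndarray | None  # (n_samples, 3): Na_i, K_i, Ca_i (mM)
    prestim_concentrations: np.ndarray | None  # (n_beats, 3), pre-stimulus
    protocol: PacingProtocol | None = None
    beat_starts: np.ndarray | None = None      # ms, stimulus onset per beat
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.time) != len(self.vm):
            raise ValueError("time and vm must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def final_beat(self) -> "ActionPotentialTrace":
        """Slice out the last complete beat window."""
        if self.beat_starts is None or len(self.beat_starts) == 0:
            return self
        t0 = self.beat_starts[-1]
        i0 = np.searchsorted(self.time, t0)
        return ActionPotentialTrace(
            time=self.time[i0:],
            vm=self.vm[i0:],
            concentrations=None if self.concentrations is None
            else self.concentrations[i0:],
            prestim_concentrations=self.prestim_concentrations,
            protocol=self.protocol,
            beat_starts=self.beat_starts[-1:],
            metadata=dict(self.metadata),
        )


@njit(cache=False)
def _pace_kernel(y, n_beats, steps_per_beat, dt_s, amp, dur_s,
                 sc_gto, sc_gcal, sc_gkr, rec_stride, vm_out, conc_out,
                 prestim_out):
    k = 0
    for b in range(n_beats):
        prestim_out[b, 0] = y[16]
        prestim_out[b, 1] = y[17]
        prestim_out[b, 2] = y[18]
        for i in range(steps_per_beat):
            if i % rec_stride == 0:
                vm_out[k] = y[0]
                conc_out[k, 0] = y[16]
                conc_out[k, 1] = y[17]
                conc_out[k, 2] = y[18]
                k += 1
            stim = amp if i * dt_s < dur_s else 0.0
            maleckar._step(y, dt_s, sc_gto, sc_gcal, sc_gkr, stim)
        if not np.isfinite(y[0]):
            return b + 1
    return n_beats


def pace_single_cell(
    params: CellParameterSet,
    protocol: PacingProtocol,
    state: np.ndarray | None = None,
    t0: float = 0.0,
) -> ActionPotentialTrace:
    """Integrate the full ionic model under a constant-BCL stimulus train.

    Returns Vm and intracellular Na+/K+/Ca2+ sampled every
    ``protocol.output_dt`` ms, plus the pre-stimulus concentrations of every
    beat. The final-beat window is recoverable from ``beat_starts``.

    ``state`` lets a caller continue from a previously stabilized state
    vector (modified in place is avoided: a copy is taken).
    """
    y = maleckar.initial_state_vector() if state is None else state.copy()
    dt_s = protocol.dt * 1e-3
    steps_per_beat = int(round(protocol.bcl / protocol.dt))
    rec_stride = max(1, int(round(protocol.output_dt / protocol.dt)))
    n_rec_per_beat = (steps_per_beat + rec_stride - 1) // rec_stride
    n_rec = n_rec_per_beat * protocol.n_beats
    vm_out = np.empty(n_rec)
    conc_out = np.empty((n_rec, 3))
    prestim = np.empty((protocol.n_beats, 3))

    beats_done = _pace_kernel(
        y, protocol.n_beats, steps_per_beat, dt_s,
        protocol.stim_amplitude, protocol.stim_duration * 1e-3,
        params.scale_gto, params.scale_gCaL, params.scale_gKr,
        rec_stride, vm_out, conc_out, prestim,
    )
    if beats_done < protocol.n_beats or not np.all(np.isfinite(y)):
        raise SimulationBlowupError(t0 + beats_done * protocol.bcl)

    time = t0 + np.arange(n_rec) // n_rec_per_beat * protocol.bcl \
        + (np.arange(n_rec) % n_rec_per_beat) * (protocol.dt * rec_stride)
    beat_starts = t0 + np.arange(protocol.n_beats) * protocol.bcl
    return ActionPotentialTrace(
        time=time,
        vm=vm_out,
        concentrations=conc_out,
        prestim_concentrations=prestim,
        protocol=protocol,
        beat_starts=beat_starts,
        metadata={
            "region_id": params.region_id,
            "final_state": y,
            "scalings": params.scalings,
        },
    )


def measure_apd(
    trace: ActionPotentialTrace,
    repolarization_fraction: float = 0.9,
    beat: int = -1,
) -> float:
    """Action-potential duration (ms) at the given repolarization fraction.

    Onset is the time of maximum dVm/dt within the beat; the duration runs
    until Vm first falls below peak - fraction * (peak - diastolic), with
    linear interpolation between samples. ``beat`` selects which stimulated
    beat of the trace to measure (default: last).
    """
    if not 0.0 < repolarization_fraction < 1.0:
        raise ValueError("repolarization_fraction must be in (0, 1)")
    t, v = _beat_window(trace, beat)
    v_rest = v[0]
    i_peak = int(np.argmax(v))
    v_peak = v[i_peak]
    if v_peak < -40.0 or v_peak - v_rest < 20.0:
        raise ValueError("no beat detected")
    dv = np.diff(v) / np.diff(t)
    i_on = int(np.argmax(dv[: max(i_peak, 1) + 1]))
    t_on = t[i_on]
    v_thresh = v_peak - repolarization_fraction * (v_peak - v_rest)
    below = np.nonzero(v[i_peak:] <= v_thresh)[0]
    if len(below) == 0:
        raise ValueError("trace never repolarizes past the APD threshold")
    j = i_peak + below[0]
    # linear interpolation between samples j-1 and j
    t_cross = t[j - 1] + (v_thresh - v[j - 1]) * (t[j] - t[j - 1]) / (v[j] - v[j - 1])
    return float(t_cross - t_on)


def _beat_window(trace: ActionPotentialTrace, beat: int):
    if trace.beat_starts is not None and len(trace.beat_starts) > 0:
        starts = np.asarray(trace.beat_starts, dtype=float)
        n = len(starts)
        b = beat % n
        t0 = starts[b]
        t1 = starts[b + 1] if b + 1 < n else trace.time[-1] + 1.0
        sel = (trace.time >= t0) & (trace.time < t1)
        return trace.time[sel], trace.vm[sel]
    return trace.time, trace.vm


def check_steady_state(
    trace: ActionPotentialTrace,
    window_beats: int = 60,
    per_species: bool = False,
):
    """Relative pre-stimulus concentration change over the final beats (%).

    For each of intracellular Na+, K+ and Ca2+, compare the value sampled
    immediately before the stimulus of the first and the last beat of the
    final ``window_beats`` beats. Returns the maximum over species of
    |last - first| / |first| * 100, or the per-species dict when
    ``per_species`` is set.
    """
    pre = trace.prestim_concentrations
    if pre is None:
        raise ValueError("trace lacks concentration samples")
    if len(pre) < window_beats:
        raise ValueError(
            f"trace has {len(pre)} beats, fewer than window_beats={window_beats}"
        )
    first = pre[-window_beats]
    last = pre[-1]
    rel = np.abs(last - first) / np.abs(first) * 100.0
    if per_species:
        return {"Na_i": float(rel[0]), "K_i": float(rel[1]), "Ca_i": float(rel[2])}
    return float(np.max(rel))


def pace_to_steady_state(
    params: CellParameterSet,
    bcl: float = 1000.0,
    stim_amplitude: float = 52.0,
    stim_duration: float = 1.0,
    dt: float = 0.02,
    max_beats: int = 3600,
    check_every: int = 20,
    apd_tol: float = 0.2,
    min_beats: int = 200,
    output_dt: float = 0.5,
) -> tuple[ActionPotentialTrace, np.ndarray]:
    """Pace at constant BCL until APD90 stops drifting, then return the run.

    The reference stabilization protocol is 3600 beats; per-beat APD90 is
    monitored every ``check_every`` beats and the run stops early once the
    drift per ``check_every`` beats falls below ``apd_tol`` ms (and at least
    ``min_beats`` beats have been run). Returns the trace of the final
    ``check_every`` beats (with the full pre-stimulus concentration history
    of all beats attached) and the APD90 history.
    """
    y = params.initial_state()
    proto = PacingProtocol(
        n_beats=check_every, bcl=bcl, stim_amplitude=stim_amplitude,
        stim_duration=stim_duration, dt=dt, output_dt=output_dt,
    )
    apds: list[float] = []
    all_prestim: list[np.ndarray] = []
    beats = 0
    trace = None
    while beats < max_beats:
        n = min(check_every, max_beats - beats)
        if n != proto.n_beats:
            proto = PacingProtocol(
                n_beats=n, bcl=bcl, stim_amplitude=stim_amplitude,
                stim_duration=stim_duration, dt=dt, output_dt=output_dt,
            )
        trace = pace_single_cell(params, proto, state=y, t0=beats * bcl)
        y = trace.metadata["final_state"]
        all_prestim.append(trace.prestim_concentrations)
        beats += n
        apds.append(measure_apd(trace))
        if beats >= min_beats and len(apds) >= 2 and \
                abs(apds[-1] - apds[-2]) < apd_tol:
            break
    assert trace is not None
    trace.prestim_concentrations = np.vstack(all_prestim)
    trace.metadata["beats_run"] = beats
    trace.metadata["apd_history"] = np.asarray(apds)
    return trace, np.asarray(apds)
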