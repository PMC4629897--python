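"""Derived maps and signal features.

Local activation time (LAT) maps, per-node APD maps with per-region
statistics, body-surface RMS (B-RMS) maps, P-wave feature extraction and
the per-region contribution decomposition of the forward-computed ECG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import interpolate_lat
from .forward import LeadTraces, ObservationPoints, compute_pseudo_ecg
from .geometry import RegionLabelField
from .monodomain import VmSeries, node_regions

#: default upward-crossing threshold for activation detection (mV)
ACTIVATION_THRESHOLD = -40.0

#: fraction of peak |V| that delimits the P-wave duration window
DURATION_GATE = 0.05
#: fraction of the dominant peak a secondary lobe/notch must reach
LOBE_GATE = 0.25


@dataclass
class LATField:
    """Per-node activation time (ms); NaN marks never-activated nodes."""

    times: np.ndarray

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times)


def compute_lat_map(vm: VmSeries,
                    threshold: float = ACTIVATION_THRESHOLD) -> LATField:
    """First upward threshold crossing per node, linearly interpolated."""
    n = vm.vm.shape[1]
    out = np.full(n, np.nan)
    above = vm.vm >= threshold
    ever = above.any(axis=0)
    for i in np.nonzero(ever)[0]:
        out[i] = interpolate_lat(vm.times, vm.vm[:, i], threshold)
    return LATField(times=out)


@dataclass
class APDMap:
    """Per-node APD (ms) plus the per-region mean/SD table."""

    apd: np.ndarray                  # (n_nodes,), NaN where not activated
    region_table: pd.DataFrame       # region, n_nodes, mean_ms, sd_ms
    n_excluded: int


def compute_apd_map(
    vm: VmSeries,
    labels: RegionLabelField | None = None,
    fraction: float = 0.9,
    threshold: float = ACTIVATION_THRESHOLD,
) -> APDMap:
    """Per-node APD at the given repolarization fraction.

    Onset per node is the sample of maximum dV/dt; the AP amplitude is
    peak minus the pre-activation baseline (the node's first sample).
    Nodes that never depolarize past the threshold are excluded (NaN) and
    counted.
    """
    t = vm.times
    V = vm.vm
    n = V.shape[1]
    apd = np.full(n, np.nan)
    for i in range(n):
        v = V[:, i]
        if v.max() < threshold:
            continue
        rest = v[0]
        ipk = int(np.argmax(v))
        vpk = v[ipk]
        dv = np.diff(v) / np.diff(t)
        ion = int(np.argmax(dv[: max(ipk, 1) + 1]))
        vth = vpk - fraction * (vpk - rest)
        below = np.nonzero(v[ipk:] <= vth)[0]
        if len(below) == 0:
            continue
        j = ipk + below[0]
        tc = t[j - 1] + (vth - v[j - 1]) * (t[j] - t[j - 1]) / (v[j] - v[j - 1])
        apd[i] = tc - t[ion]

    rows = []
    if labels is not None:
        nreg = node_regions(vm.mesh, labels)
        for i, name in enumerate(labels.names):
            vals = apd[(nreg == i) & np.isfinite(apd)]
            if len(vals):
                rows.append({"region": name, "n_nodes": len(vals),
                             "mean_ms": float(vals.mean()),
                             "sd_ms": float(vals.std())})
    table = pd.DataFrame(rows, columns=["region", "n_nodes", "mean_ms", "sd_ms"])
    return APDMap(apd=apd, region_table=table,
                  n_excluded=int(np.sum(~np.isfinite(apd))))


@dataclass
class BRMSMap:
    """Per-surface-point RMS of the potential trace over a window (mV_RMS)."""

    values: np.ndarray

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("RMS values must be non-negative")


def compute_brms_map(
    traces: np.ndarray,
    times: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> BRMSMap:
    """RMS over the window per point; no baseline subtraction.

    ``traces`` has shape (n_times, n_points); ``window`` is (t0, t1) in ms
    over ``times`` (default: the full trace).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if window is not None:
        if times is None:
            raise ValueError("window requires times")
        sel = (times >= window[0]) & (times <= window[1])
        if not sel.any():
            raise ValueError("empty RMS window")
        traces = traces[sel]
    if traces.shape[0] == 0:
        raise ValueError("empty RMS window")
    return BRMSMap(values=np.sqrt(np.mean(traces ** 2, axis=0)))


@dataclass
class PWaveFeatures:
    duration: float    # ms
    amplitude: float   # mVpp
    morphology: str    # monophasic+ | monophasic- | biphasic | M-shaped | indeterminate


def extract_pwave_features(times: np.ndarray, v: np.ndarray,
                           duration_gate: float = DURATION_GATE,
                           lobe_gate: float = LOBE_GATE) -> PWaveFeatures:
    """Duration, peak-to-peak amplitude and morphology class of one P-wave.

    Duration spans where |V| exceeds ``duration_gate`` of max |V|; the
    morphology classes are monophasic (one dominant signed lobe), biphasic
    (two opposite-sign lobes each above ``lobe_gate`` of the peak) and
    M-shaped (two same-sign peaks separated by a notch deeper than
    ``lobe_gate``). A flat trace is indeterminate with zero amplitude.
    """
    v = np.asarray(v, dtype=float)
    peak = np.max(np.abs(v))
    if peak == 0.0 or not np.isfinite(peak):
        return PWaveFeatures(duration=0.0, amplitude=0.0,
                             morphology="indeterminate")
    active = np.nonzero(np.abs(v) > duration_gate * peak)[0]
    duration = float(times[active[-1]] - times[active[0]])
    amplitude = float(v.max() - v.min())

    vmax, vmin = v.max(), v.min()
    pos_dominant = vmax >= -vmin
    major = vmax if pos_dominant else -vmin
    minor = -vmin if pos_dominant else vmax
    if minor > lobe_gate * major:
        morphology = "biphasic"
    else:
        sign = 1.0 if pos_dominant else -1.0
        w = sign * v
        peaks = _local_maxima(w)
        big = [p for p in peaks if w[p] > lobe_gate * major]
        m_shaped = False
        for a, b in zip(big[:-1], big[1:]):
            notch = w[a:b + 1].min()
            if (min(w[a], w[b]) - notch) > lobe_gate * major:
                m_shaped = True
        if m_shaped:
            morphology = "M-shaped"
        else:
            morphology = "monophasic+" if pos_dominant else "monophasic-"
    return PWaveFeatures(duration=duration, amplitude=amplitude,
                         morphology=morphology)


def _local_maxima(w: np.ndarray) -> list[int]:
    idx = []
    for i in range(1, len(w) - 1):
        if w[i] >= w[i - 1] and w[i] > w[i + 1]:
            idx.append(i)
    return idx


@dataclass
class RegionContributionSet:
    """Per-region forward traces, B-RMS maps and contribution shares."""

    total: LeadTraces
    per_region: dict[str, LeadTraces]
    shares: pd.Series = field(default=None)  # % of summed RMS, sums to 100
    brms_per_region: dict[str, BRMSMap] = field(default_factory=dict)


def decompose_region_contributions(
    vm: VmSeries,
    labels: RegionLabelField,
    points: ObservationPoints,
    gamma: float = 1.0,
    sigma_ratio: float = 1.0,
) -> RegionContributionSet:
    """Per-region pseudo-ECG by masking the source integral to each region.

    Linearity of the infinite-medium integral makes the per-region traces
    sum exactly to the whole-atria trace. Shares are each region's summed
    RMS normalized to 100%.
    """
    if labels.indices.shape[0] != vm.mesh.n_elements:
        raise ValueError("label field does not match the source mesh")
    total = compute_pseudo_ecg(vm, points, gamma, sigma_ratio)
    per_region: dict[str, LeadTraces] = {}
    brms: dict[str, BRMSMap] = {}
    rms_sum: dict[str, float] = {}
    for name in sorted(labels.present()):
        mask = labels.mask(name)
        tr = compute_pseudo_ecg(vm, points, gamma, sigma_ratio,
                                element_mask=mask)
        per_region[name] = tr
        m = compute_brms_map(tr.values)
        brms[name] = m
        rms_sum[name] = float(m.values.sum())
    shares = pd.Series(rms_sum)
    shares = shares / shares.sum() * 100.0
    return RegionContributionSet(total=total, per_region=per_region,
                                 shares=shares, brms_per_region=brms)
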