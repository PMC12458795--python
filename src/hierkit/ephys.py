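"""Slice-electrophysiology metrics.

Covers the whole-cell measurements used to characterize thalamic relay
neurons and their synaptic inputs across social ranks:

- FI curves and peak firing rate from current-clamp step protocols
  (:func:`fi_curve`), input resistance from a small hyperpolarizing
  voltage-clamp pulse (:func:`input_resistance`);
- two-cluster excitability typing on (peak rate, input resistance) features
  with K-means (:func:`cluster_neurons`) and Hartigan's dip test for
  bimodality (:func:`dip_bimodality`);
- template-match detection of spontaneous postsynaptic currents with
  difference-of-exponential kinetics (:func:`detect_psc_events`) and
  per-minute cumulative charge transfer (:func:`charge_transfer`);
- paired-pulse short-term plasticity ratios over five-pulse trains
  (:func:`paired_pulse`);
- the antagonist-sensitive fraction of the barium current carried by TRPM3
  (:func:`trpm3_fraction`) and peak extraction from IV step protocols
  (:func:`iv_peak`);
- the white-noise current stimulus generator used to evoke stable firing
  (:func:`white_noise_stimuli`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from hierkit._dip import dip_statistic, dip_test

logger = logging.getLogger(__name__)

__all__ = [
    "PSCEvent",
    "PairedPulseSeries",
    "IVCurve",
    "WhiteNoiseStimuli",
    "PSC_PARAMS",
    "fi_curve",
    "count_spikes",
    "input_resistance",
    "cluster_neurons",
    "dip_bimodality",
    "detect_psc_events",
    "charge_transfer",
    "paired_pulse",
    "trpm3_fraction",
    "iv_peak",
    "white_noise_stimuli",
    "dip_statistic",
]

#: Template-match detection parameters per event polarity (ms).
PSC_PARAMS = {
    "excitatory": {"rise_ms": 0.5, "decay_ms": 2.0, "baseline_ms": 3.0, "template_ms": 7.0},
    "inhibitory": {"rise_ms": 1.0, "decay_ms": 3.0, "baseline_ms": 5.0, "template_ms": 10.0},
}


# ---------------------------------------------------------------------------
# intrinsic excitability
# ---------------------------------------------------------------------------


def count_spikes(
    v_mV: np.ndarray, fs: float, threshold_mV: float = 0.0, refractory_ms: float = 2.0
) -> int:
    """Count action potentials as upward threshold crossings with a refractory guard."""
    v = np.asarray(v_mV, dtype=float)
    above = v >= threshold_mV
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(crossings) == 0:
        return 0
    guard = refractory_ms / 1000.0 * fs
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= guard:
            kept.append(c)
    return len(kept)


def fi_curve(
    step_currents_pA: np.ndarray,
    responses_mV: list[np.ndarray],
    fs: float,
    spike_threshold_mV: float = 0.0,
    refractory_ms: float = 2.0,
) -> pd.DataFrame:
    """Firing rate vs. injected current from a current-clamp step protocol.

    Each response sweep covers one current step; the rate is the spike count
    divided by the step duration, so it is invariant to step length at fixed
    spike density.  Returns a tidy frame (``current_pA``, ``n_spikes``,
    ``rate_hz``); the peak firing rate is ``df["rate_hz"].max()``.
    """
    currents = np.asarray(step_currents_pA, dtype=float)
    if len(currents) == 0 or len(currents) != len(responses_mV):
        raise ValueError("need one response sweep per current step")
    rows = []
    for i_pA, v in zip(currents, responses_mV):
        n = count_spikes(v, fs, spike_threshold_mV, refractory_ms)
        dur = len(v) / fs
        rows.append({"current_pA": i_pA, "n_spikes": n, "rate_hz": n / dur})
    return pd.DataFrame(rows)


def input_resistance(
    current_pA: np.ndarray,
    fs: float,
    step_window_s: tuple[float, float],
    baseline_window_s: tuple[float, float],
    delta_v_mV: float = -10.0,
    plateau_frac: float = 0.5,
) -> float:
    """Input resistance (MΩ) from a small hyperpolarizing voltage-clamp pulse.

    The steady-state (plateau) current is averaged over the trailing
    ``plateau_frac`` of the step window to avoid the capacitive transient;
    ``R = ΔV / ΔI`` with ΔV in mV and ΔI in pA gives MΩ after a factor 1000.
    """
    i = np.asarray(current_pA, dtype=float)
    b0, b1 = (int(round(t * fs)) for t in baseline_window_s)
    s0, s1 = (int(round(t * fs)) for t in step_window_s)
    p0 = s1 - max(int(round((s1 - s0) * plateau_frac)), 1)
    baseline = float(np.mean(i[b0:b1]))
    plateau = float(np.mean(i[p0:s1]))
    delta_i = plateau - baseline
    if abs(delta_i) < 1e-9:
        raise ValueError("no measurable current deflection (open circuit?)")
    return 1000.0 * delta_v_mV / delta_i


def cluster_neurons(
    peak_rates_hz: np.ndarray, input_resistances_mohm: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Two-cluster K-means typing of neurons on (peak rate, input resistance).

    Features are z-scored before clustering (10 seeded restarts).  Cluster
    identity is defined by centroid order, not initialization: cluster 1 is
    the lower-input-resistance centroid.  Returns integer labels (1 or 2) per
    neuron and the cluster-2/cluster-1 count ratio.
    """
    from sklearn.cluster import KMeans

    rates = np.asarray(peak_rates_hz, dtype=float)
    rins = np.asarray(input_resistances_mohm, dtype=float)
    if len(rates) != len(rins) or len(rates) < 2:
        raise ValueError("need >= 2 neurons with both features")
    if not (np.isfinite(rates).all() and np.isfinite(rins).all()):
        raise ValueError("features must be finite")
    X = np.column_stack([rates, rins])
    sd = X.std(axis=0)
    if np.all(sd == 0):
        logger.warning("identical feature vectors: clustering degenerate, all labeled 1")
        return np.ones(len(rates), dtype=int), 0.0
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    # order clusters by raw-scale centroid input resistance
    rin_means = [rins[km.labels_ == c].mean() for c in (0, 1)]
    low_rin = int(np.argmin(rin_means))
    labels = np.where(km.labels_ == low_rin, 1, 2)
    n1, n2 = int((labels == 1).sum()), int((labels == 2).sum())
    ratio = n2 / n1 if n1 else float("inf")
    return labels, ratio


def dip_bimodality(values: np.ndarray, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Hartigan's dip statistic and bootstrap p-value (uniform reference null).

    The dip is rank-based (invariant to monotone rescaling of the values);
    ``n_boot`` uniform samples of the same size calibrate the p-value.
    """
    return dip_test(values, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# synaptic events
# ---------------------------------------------------------------------------


@dataclass
class PSCEvent:
    """One detected postsynaptic current event (amplitude rectified positive)."""

    time_s: float
    amplitude_pA: float
    charge_pC: float
    polarity: str


def _condition_trace(trace: np.ndarray, fs: float, lowpass_hz: float, notch_hz: tuple) -> np.ndarray:
    """2 kHz low-pass plus 60 Hz (and harmonics) notch filtering."""
    y = np.asarray(trace, dtype=float)
    nyq = fs / 2.0
    if lowpass_hz and lowpass_hz < nyq:
        sos = signal.butter(4, lowpass_hz / nyq, btype="low", output="sos")
        y = signal.sosfiltfilt(sos, y)
    for f0 in notch_hz:
        if f0 < nyq:
            b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
            y = signal.filtfilt(b, a, y)
    return y


def detect_psc_events(
    trace: np.ndarray,
    fs: float,
    polarity: str = "excitatory",
    rise_ms: float | None = None,
    decay_ms: float | None = None,
    baseline_ms: float | None = None,
    template_ms: float | None = None,
    threshold_mult: float = 3.0,
    apply_filters: bool = True,
    lowpass_hz: float = 2000.0,
    notch_hz: tuple = (60.0, 120.0, 180.0),
    refractory_ms: float | None = None,
) -> list[PSCEvent]:
    """Template-match detection of spontaneous postsynaptic currents.

    The trace is low-pass filtered at 2 kHz and notch filtered at 60 Hz and
    harmonics, rectified by polarity (excitatory events are negative-going,
    inhibitory positive-going), and scanned with a sliding scaled-template
    fit: a difference-of-exponentials template (default kinetics per
    :data:`PSC_PARAMS`, preceded by a flat baseline segment) is least-squares
    fitted for amplitude and offset at every position.  Positions where the
    fitted amplitude exceeds ``threshold_mult`` times the baseline noise SD
    (robustly estimated from the median absolute deviation of the conditioned
    trace) are kept, reduced to local maxima, and merged within a refractory
    window (default: one decay time constant plus rise time).

    Event time is the template onset; charge is the fitted amplitude times
    the template time-integral (pA·s = pC).
    """
    if polarity not in PSC_PARAMS:
        raise ValueError("polarity must be 'excitatory' or 'inhibitory'")
    p = PSC_PARAMS[polarity]
    rise_ms = rise_ms if rise_ms is not None else p["rise_ms"]
    decay_ms = decay_ms if decay_ms is not None else p["decay_ms"]
    baseline_ms = baseline_ms if baseline_ms is not None else p["baseline_ms"]
    template_ms = template_ms if template_ms is not None else p["template_ms"]
    if fs < 10.0 / (rise_ms / 1000.0):
        logger.warning("sampling rate %.0f Hz is marginal for a %.2g ms rise time", fs, rise_ms)

    n_base = int(round(baseline_ms / 1000.0 * fs))
    n_total = int(round(template_ms / 1000.0 * fs))
    n_event = max(n_total - n_base, 2)
    if n_total > len(trace):
        raise ValueError("template longer than trace")

    y = _condition_trace(trace, fs, lowpass_hz, notch_hz) if apply_filters else np.asarray(trace, float)
    sign = -1.0 if polarity == "excitatory" else 1.0
    s = sign * y  # events now positive-going
    from hierkit.synthio import psc_kernel

    kern = psc_kernel(fs, rise_ms, decay_ms, length_ms=n_event / fs * 1000.0)[:n_event]
    w = np.concatenate([np.zeros(n_base), kern])
    N = len(w)

    # sliding least-squares fit of s ~ a*w + c (Clements–Bekkers scaled template)
    ones = np.ones(N)
    sum_s = np.convolve(s, ones[::-1], mode="valid")
    sum_ws = np.convolve(s, w[::-1], mode="valid")
    sum_w, sum_w2 = w.sum(), (w**2).sum()
    denom = sum_w2 - sum_w**2 / N
    amp = (sum_ws - sum_w * sum_s / N) / denom

    noise_sd = float(np.median(np.abs(s - np.median(s))) * 1.4826)
    thr = threshold_mult * max(noise_sd, 1e-12)
    cand = amp > thr
    if not cand.any():
        return []

    refractory = (refractory_ms if refractory_ms is not None else rise_ms + decay_ms) / 1000.0 * fs
    # charge uses the full transient, not the (shorter) fitting template
    kern_integral = psc_kernel(fs, rise_ms, decay_ms).sum() / fs  # s (unit amplitude)
    events: list[PSCEvent] = []
    # local maxima of the fitted-amplitude series within qualifying stretches
    peaks, _ = signal.find_peaks(np.where(cand, amp, 0.0), distance=max(int(refractory), 1))
    for pk in peaks:
        if not cand[pk]:
            continue
        a = float(amp[pk])
        t0 = (pk + n_base) / fs
        events.append(PSCEvent(time_s=t0, amplitude_pA=a, charge_pC=a * kern_integral, polarity=polarity))
    return events


def charge_transfer(
    events: list[PSCEvent], duration_s: float
) -> pd.DataFrame:
    """Per-minute and cumulative charge transfer from detected events.

    Rectified event charges are binned into 60 s intervals spanning
    ``duration_s``; the cumulative column is the running total (pC).
    """
    n_bins = max(int(np.ceil(duration_s / 60.0)), 1)
    per_min = np.zeros(n_bins)
    for ev in events:
        b = min(int(ev.time_s // 60.0), n_bins - 1)
        per_min[b] += abs(ev.charge_pC)
    return pd.DataFrame(
        {"minute": np.arange(n_bins), "charge_pC": per_min, "cumulative_pC": np.cumsum(per_min)}
    )


def trace_charge(trace: np.ndarray, fs: float) -> float:
    """Time-integral of the rectified current (pA -> pC), for cross-checks."""
    return float(np.sum(np.abs(trace)) / fs)


# ---------------------------------------------------------------------------
# paired pulse, TRPM3, IV
# ---------------------------------------------------------------------------


@dataclass
class PairedPulseSeries:
    """Five evoked amplitudes normalized to the first response."""

    amplitudes: np.ndarray
    ratios: np.ndarray
    regime: str


def paired_pulse(amplitudes_pA: np.ndarray) -> PairedPulseSeries:
    """Short-term plasticity ratios from a five-pulse evoked train.

    ``ratios[i] = a_i / a_1`` (so ``ratios[0]`` is exactly 1); the regime is
    facilitation when the mean of ratios 2..5 exceeds 1, depression when it
    is below 1, and "mixed" on the exact boundary (flagged).
    """
    a = np.asarray(amplitudes_pA, dtype=float)
    if len(a) != 5:
        raise ValueError("paired-pulse train must have exactly 5 amplitudes")
    if np.any(a <= 0):
        raise ValueError("amplitudes must be positive (rectified)")
    ratios = a / a[0]
    ratios[0] = 1.0
    m = float(ratios[1:].mean())
    if m > 1:
        regime = "facilitation"
    elif m < 1:
        regime = "depression"
    else:
        logger.warning("paired-pulse ratios on the facilitation/depression boundary")
        regime = "mixed"
    return PairedPulseSeries(amplitudes=a, ratios=ratios, regime=regime)


def trpm3_fraction(peak_control_pA: float, peak_antagonist_pA: float) -> float:
    """Antagonist-sensitive fraction of the (barium) current.

    ``(peak_control - peak_antagonist) / peak_control`` on rectified peak
    amplitudes; 0 for identical peaks, 1 for complete block.  Values can be
    negative if the antagonist potentiates the current.
    """
    if peak_control_pA <= 0:
        raise ValueError("peak control current must be positive (rectified)")
    return (peak_control_pA - peak_antagonist_pA) / peak_control_pA


@dataclass
class IVCurve:
    """Peak currents over a voltage-step grid for one condition."""

    voltages_mV: np.ndarray
    peaks_pA: np.ndarray
    condition: str = "control"
    missing_steps: list[float] = field(default_factory=list)


def iv_peak(
    voltages_mV: np.ndarray,
    current_traces: list[np.ndarray],
    fs: float,
    step_onset_s: float = 0.0,
    blank_ms: float = 1.0,
    condition: str = "control",
    expected_grid: np.ndarray | None = None,
) -> IVCurve:
    """Per-step peak (maximum-magnitude, signed) current from an IV protocol.

    The first ``blank_ms`` after the step onset are blanked to skip the
    capacitive transient.  The conventional grid steps from -110 mV to
    +30 mV in 5 mV increments (holding -70 mV); pass ``expected_grid`` to
    flag missing steps.
    """
    v = np.asarray(voltages_mV, dtype=float)
    if len(v) != len(current_traces):
        raise ValueError("need one current trace per voltage step")
    if np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be strictly increasing")
    blank = int(round((step_onset_s + blank_ms / 1000.0) * fs))
    peaks = np.empty(len(v))
    for i, tr in enumerate(current_traces):
        seg = np.asarray(tr, dtype=float)[blank:]
        if seg.size == 0:
            raise ValueError("trace shorter than blanking window")
        peaks[i] = seg[np.argmax(np.abs(seg))]
    missing = []
    if expected_grid is not None:
        missing = [float(g) for g in expected_grid if not np.any(np.isclose(v, g))]
        if missing:
            logger.warning("IV grid has missing steps: %s", missing)
    return IVCurve(voltages_mV=v, peaks_pA=peaks, condition=condition, missing_steps=missing)


# ---------------------------------------------------------------------------
# white-noise stimuli
# ---------------------------------------------------------------------------


@dataclass
class WhiteNoiseStimuli:
    """Alpha-filtered noise current patterns and the selected subset."""

    raw: np.ndarray
    filtered: np.ndarray
    selected: np.ndarray

    @property
    def stimuli(self) -> np.ndarray:
        return self.filtered[self.selected]


def white_noise_stimuli(
    n_patterns: int = 400,
    sigma_pA: float = 50.0,
    alpha_ms: float = 2.0,
    n_select: int = 200,
    fs: float = 10_000.0,
    duration_s: float = 1.0,
    seed: int = 0,
) -> WhiteNoiseStimuli:
    """Generate frozen-noise current stimuli for stable-firing experiments.

    ``n_patterns`` Gaussian noise patterns (SD ``sigma_pA``) are low-pass
    filtered by convolution with a peak-normalized alpha kernel
    ``(t/α)·exp(1 − t/α)``, which imposes an autocorrelation time of order α;
    ``n_select`` of them are chosen uniformly at random (seeded).
    """
    if n_select > n_patterns:
        raise ValueError("n_select must not exceed n_patterns")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration_s * fs))
    raw = rng.normal(0.0, sigma_pA, size=(n_patterns, n_samp))
    alpha = alpha_ms / 1000.0
    t = np.arange(0, 8 * alpha, 1.0 / fs)
    kern = (t / alpha) * np.exp(1.0 - t / alpha)  # peak value 1 at t = alpha
    filtered = np.apply_along_axis(lambda r: np.convolve(r, kern, mode="same"), 1, raw)
    selected = rng.choice(n_patterns, size=n_select, replace=False)
    return WhiteNoiseStimuli(raw=raw, filtered=filtered, selected=selected)
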