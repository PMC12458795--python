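"""Fiber-photometry and miniscope analysis for tube-test trials.

Photometry traces are block-averaged to 20 Hz, Gaussian-smoothed, and
referenced to the 30 s of baseline preceding tube entry.  A trial is
partitioned into approach/interact/retreat epochs by tube thirds, and the
onset of the first sustained deviation from baseline is detected with a
run-length rule: the first sample starting a run of at least five successive
points moving in the same direction while the baseline-subtracted signal
exceeds three baseline standard deviations.  Onsets are reported relative to
the meeting in the middle of the tube and optionally averaged over blocks of
four successive trials.

Miniscope ROI responses are summarized as the post-minus-pre mean activity
around the first encounter (20 s windows) and three-way classified against
two standard deviations of the session's difference distribution
(activated / inhibited / persistent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from hierkit.synthio import TraceSet

logger = logging.getLogger(__name__)

__all__ = [
    "EpochPartition",
    "DeviationOnset",
    "ROIClassification",
    "preprocess_photometry",
    "partition_epochs",
    "detect_deviation_onset",
    "average_onsets",
    "epoch_activity",
    "classify_rois",
    "fraction_summary",
]

DEFAULT_TARGET_FS = 20.0
DEFAULT_KERNEL_WIDTH_S = 0.25  # Gaussian FWHM-scale width: 5 samples at 20 Hz
BASELINE_WINDOW_S = 30.0
PRE_POST_WINDOW_S = 20.0
RUN_LENGTH = 5
SD_MULTIPLE = 3.0


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess_photometry(
    trace: TraceSet,
    target_fs: float = DEFAULT_TARGET_FS,
    kernel_width_s: float = DEFAULT_KERNEL_WIDTH_S,
) -> TraceSet:
    """Downsample, smooth, and compute baseline statistics.

    The trace is block-average downsampled to ``target_fs`` (the decimation
    factor is ``round(fs / target_fs)``; a trailing partial block is averaged
    as-is, so the output length is ``ceil(n / factor)``), then smoothed with a
    Gaussian kernel of standard deviation ``kernel_width_s``.  The baseline
    mean and SD are computed from the ``baseline_window_s`` seconds preceding
    the ``tube_entry`` event of the *downsampled, unsmoothed* signal and
    stored on the returned trace: the SD describes baseline activity, and
    measuring it after smoothing would shrink it by the kernel's
    noise-reduction factor, making the downstream 3-SD deviation criterion
    fire on smoothed noise.  A zero baseline SD is flagged as degenerate
    (logged) and handled downstream.
    """
    if target_fs > trace.fs:
        raise ValueError("target_fs must not exceed the recording rate")
    if "tube_entry" not in trace.events:
        raise ValueError("trace must carry a tube_entry event")
    entry = trace.events["tube_entry"]
    if entry - trace.baseline_window_s < -1e-9:
        raise ValueError("baseline window extends before recording start")

    factor = max(int(round(trace.fs / target_fs)), 1)
    n = len(trace.values)
    n_out = -(-n // factor)  # ceil division
    padded = np.full(n_out * factor, np.nan)
    padded[:n] = trace.values
    down = np.nanmean(padded.reshape(n_out, factor), axis=1)
    fs_out = trace.fs / factor

    sigma_samples = kernel_width_s * fs_out
    smooth = gaussian_filter1d(down, sigma_samples, mode="nearest") if sigma_samples > 0 else down

    b0 = int(round((entry - trace.baseline_window_s) * fs_out))
    b1 = int(round(entry * fs_out))
    baseline = down[b0:b1]
    mean, sd = float(np.mean(baseline)), float(np.std(baseline))
    if sd == 0:
        logger.warning("degenerate baseline: SD = 0")
    return replace(trace, values=smooth, fs=fs_out, baseline_mean=mean, baseline_sd=sd)


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------


@dataclass
class EpochPartition:
    """Approach/interact/retreat intervals (s), half-open ``[start, end)``."""

    approach: tuple[float, float]
    interact: tuple[float, float]
    retreat: tuple[float, float]
    excluded: bool = False
    reason: str = ""


def partition_epochs(
    times: np.ndarray,
    positions: np.ndarray,
    tube_length: float,
    first_interaction_time: float | None = None,
) -> EpochPartition:
    """Partition a trial by tube thirds from a position time series.

    ``positions`` is the animal's distance along the tube in ``[0, L]``.  The
    approach epoch runs until the first sample at or beyond ``L/3``, the
    interact epoch until the first sample at or beyond ``2L/3``, and the
    retreat epoch to the end (boundary samples belong to the later epoch:
    half-open convention, so position exactly ``L/3`` is "interact").

    A trial is marked excluded when the first interaction falls outside the
    middle third of the tube, or when the annotation is missing.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < -1e-9 or positions.max() > tube_length + 1e-9):
        raise ValueError("positions must lie in [0, tube_length]")
    third, two_thirds = tube_length / 3.0, 2.0 * tube_length / 3.0
    t0, t_end = float(times[0]), float(times[-1])
    cross1 = np.flatnonzero(positions >= third)
    cross2 = np.flatnonzero(positions >= two_thirds)
    t1 = float(times[cross1[0]]) if len(cross1) else t_end
    t2 = float(times[cross2[0]]) if len(cross2) else t_end

    excluded, reason = False, ""
    if first_interaction_time is None:
        excluded, reason = True, "missing first-interaction annotation"
        logger.warning(reason)
    else:
        pos_at = float(np.interp(first_interaction_time, times, positions))
        if not (third <= pos_at < two_thirds):
            excluded, reason = True, "first interaction outside middle third of tube"
    return EpochPartition(approach=(t0, t1), interact=(t1, t2), retreat=(t2, t_end), excluded=excluded, reason=reason)


# ---------------------------------------------------------------------------
# deviation onset
# ---------------------------------------------------------------------------


@dataclass
class DeviationOnset:
    """First sustained deviation from baseline.

    ``time`` is seconds relative to the middle-meeting event (negative =
    before meeting); ``direction`` is +1/-1 for the run's sign.
    """

    time: float
    direction: int
    absolute_time: float


def detect_deviation_onset(
    trace: TraceSet,
    run_length: int = RUN_LENGTH,
    sd_multiple: float = SD_MULTIPLE,
    criterion_on: str = "signal",
) -> DeviationOnset | None:
    """Detect the first sustained baseline deviation in a preprocessed trace.

    The baseline mean is subtracted and the first difference of the signal
    taken.  The onset is the first sample (after tube entry) starting a run of
    at least ``run_length`` successive points whose first differences share
    one sign while the criterion values exceed ``sd_multiple`` times the
    baseline SD in that direction.  By default the magnitude criterion is
    applied to the baseline-subtracted *signal* values (the first difference
    only supplies the run direction); pass ``criterion_on="derivative"`` to
    threshold the differentiated values instead.

    Returns ``None`` when nothing qualifies or the baseline is degenerate.
    """
    if trace.baseline_mean is None or trace.baseline_sd is None:
        raise ValueError("trace has no baseline statistics; run preprocess_photometry first")
    if trace.baseline_sd == 0:
        logger.warning("degenerate baseline SD = 0: no onset reported")
        return None
    if criterion_on not in {"signal", "derivative"}:
        raise ValueError("criterion_on must be 'signal' or 'derivative'")

    centered = trace.values - trace.baseline_mean
    diff = np.diff(centered)
    threshold = sd_multiple * trace.baseline_sd
    entry_idx = int(round(trace.events.get("tube_entry", 0.0) * trace.fs))
    meeting = trace.events.get("middle_meeting", 0.0)

    sign = np.sign(diff)
    crit = centered[1:] if criterion_on == "signal" else diff
    # qualifying[i]: sample i+1 continues a run in the direction of diff[i]
    # while exceeding the threshold in that direction.
    qual_pos = (sign > 0) & (crit > threshold)
    qual_neg = (sign < 0) & (crit < -threshold)

    best: DeviationOnset | None = None
    for qual, direction in ((qual_pos, 1), (qual_neg, -1)):
        run = 0
        for i in range(len(qual)):
            run = run + 1 if qual[i] else 0
            if run >= run_length:
                start = i - run_length + 1  # first diff index of the run
                if start + 1 < entry_idx:  # onsets are sought after tube entry
                    continue
                t_abs = (start + 1) / trace.fs
                cand = DeviationOnset(time=t_abs - meeting, direction=direction, absolute_time=t_abs)
                if best is None or cand.absolute_time < best.absolute_time:
                    best = cand
                break
    return best


def average_onsets(onsets: list[DeviationOnset | None], block: int = 4) -> list[float]:
    """Mean onset time (relative to meeting) over successive blocks of trials.

    Trials without a detected onset are dropped from their block; a block with
    no detections yields NaN.  The default block of four matches the
    four-successive-trials averaging used for rank-dependent interactions.
    """
    out = []
    for i in range(0, len(onsets), block):
        vals = [o.time for o in onsets[i : i + block] if o is not None]
        out.append(float(np.mean(vals)) if vals else float("nan"))
    return out


def epoch_activity(trace: TraceSet, partition: EpochPartition) -> pd.Series:
    """Per-epoch mean of the baseline-subtracted signal.

    Intended for export (one row per trial) to downstream rank-sum testing.
    Empty epochs yield NaN (flagged).  Excluded trials raise ``ValueError``.
    """
    if partition.excluded:
        raise ValueError(f"trial excluded: {partition.reason}")
    if trace.baseline_mean is None:
        raise ValueError("trace has no baseline statistics; run preprocess_photometry first")
    centered = trace.values - trace.baseline_mean
    t = trace.time
    out = {}
    for name in ("approach", "interact", "retreat"):
        lo, hi = getattr(partition, name)
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            logger.warning("empty epoch %s", name)
            out[name] = float("nan")
        else:
            out[name] = float(centered[mask].mean())
    return pd.Series(out, name="epoch_mean")


# ---------------------------------------------------------------------------
# ROI classification
# ---------------------------------------------------------------------------


@dataclass
class ROIClassification:
    """Three-way ROI response classes with the diff distribution they came from."""

    diff: np.ndarray
    labels: list[str]
    threshold: float
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n:
            self.fractions = {
                lab: self.labels.count(lab) / n for lab in ("activated", "inhibited", "persistent")
            }


def classify_rois(
    pre_means: np.ndarray,
    post_means: np.ndarray,
    sd_method: str = "robust",
    null_sd: float | None = None,
) -> ROIClassification:
    """Classify ROIs by post-minus-pre mean activity around the first encounter.

    The threshold is two standard deviations of the session's distribution of
    differences (computed across ROIs): differences above +2 SD are
    "activated", below -2 SD "inhibited", and the remaining cells "persistent"
    (unchanged).

    By default the SD is estimated robustly (1.4826 x median absolute
    deviation), i.e. from the unchanged bulk of the distribution.  The naive
    across-ROI standard deviation (``sd_method="global"``) is self-defeating
    when many ROIs respond: by Chebyshev's inequality at most 25% of values
    can lie beyond two global SDs, so sessions where most cells respond could
    never be classified as such.  The robust estimate reduces to the plain SD
    on a pure-null session but still breaks down when half or more of the
    ROIs respond; for such sessions pass ``null_sd`` measured from a baseline
    recording, which then takes precedence over ``sd_method``.

    Requires at least 3 ROIs for a usable SD; a zero SD labels everything
    persistent (flagged).
    """
    pre = np.asarray(pre_means, dtype=float)
    post = np.asarray(post_means, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post vectors must have equal length")
    if len(pre) < 3:
        raise ValueError("need at least 3 ROIs for a reliable SD")
    if sd_method not in {"robust", "global"}:
        raise ValueError("sd_method must be 'robust' or 'global'")
    diff = post - pre
    if null_sd is not None:
        sd = float(null_sd)
    elif sd_method == "robust":
        sd = float(np.median(np.abs(diff - np.median(diff))) * 1.4826)
    else:
        sd = float(np.std(diff))
    if sd == 0:
        logger.warning("zero dispersion in diffs: all ROIs classified persistent")
        labels = ["persistent"] * len(diff)
        return ROIClassification(diff=diff, labels=labels, threshold=0.0)
    thr = 2.0 * sd
    labels = ["activated" if d > thr else "inhibited" if d < -thr else "persistent" for d in diff]
    return ROIClassification(diff=diff, labels=labels, threshold=thr)


def fraction_summary(
    sessions: list[tuple[ROIClassification, str]],
) -> pd.DataFrame:
    """Pool ROI class fractions across sessions by outcome.

    ``sessions`` is a list of ``(classification, outcome)`` with outcome
    ``"win"`` or ``"lose"``.  Fractions are pooled over all ROIs of all
    sessions sharing an outcome and sum to 1 per outcome.
    """
    counts: dict[str, dict[str, int]] = {}
    for cls, outcome in sessions:
        bucket = counts.setdefault(outcome, {"activated": 0, "inhibited": 0, "persistent": 0})
        for lab in cls.labels:
            bucket[lab] += 1
    rows = {}
    for outcome, bucket in counts.items():
        total = sum(bucket.values())
        rows[outcome] = {lab: (n / total if total else float("nan")) for lab, n in bucket.items()}
    return pd.DataFrame.from_dict(rows, orient="index")
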