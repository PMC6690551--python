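"""Pulse detection, baseline/peak measurement and cycle classification.

A song pulse's *peak height* is the distance from its local baseline to the
largest positive-or-negative deflection.  The *slice level* is a fixed
fraction of that height (50% standard, 60% stringent); every local deflection
exceeding the slice level is a counted peak, and a pulse with any counted
peak besides the primary one is *polycyclic*, otherwise *monocyclic*.

Detection works on the band-passed trace.  The absolute event threshold is
``detection_noise_multiplier`` times the robust noise scale (normal-consistent
median absolute deviation) of the whole filtered recording, floored at 10% of
the recording's maximal deflection so that noise-free recordings are still
segmented.  Candidate events whose peak falls below 1.5x the threshold are
discarded as sub-threshold fluctuations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_io import AnalysisConfig, SongRecording

logger = logging.getLogger("pulsesong")

MONOCYCLIC = "monocyclic"
POLYCYCLIC = "polycyclic"

#: below-threshold gap (s) tolerated inside one event before it is closed
_CLUSTER_GAP_S = 0.005
#: padding (s) added to each side of a detected event window
_WINDOW_PAD_S = 0.002
#: floor on the detection threshold, as a fraction of the maximal deflection
_THRESHOLD_FLOOR_FRACTION = 0.10
#: events must reach this multiple of the detection threshold to be kept
_EVENT_VALIDATION_FACTOR = 1.5
#: longest above-threshold span accepted as one pulse; anything longer is
#: sustained oscillation (sine song), not a wing-beat pulse
_MAX_EVENT_S = 0.050
#: minimum usable baseline history before falling back to the global median
_MIN_BASELINE_S = 0.050


@dataclass
class PulseEvent:
    """One detected song pulse and its slice-level classification."""

    primary_peak_s: float
    baseline: float
    peak_height: float
    window: tuple[float, float]  # [start_s, end_s)
    peak_times_s: list[float]
    cycle_count: int
    pulse_class: str
    slice_level: float

    def __post_init__(self) -> None:
        if self.cycle_count != len(self.peak_times_s) or self.cycle_count < 1:
            raise ValueError("cycle_count must equal len(peak_times_s) >= 1")
        expected = MONOCYCLIC if self.cycle_count == 1 else POLYCYCLIC
        if self.pulse_class != expected:
            raise ValueError(
                f"pulse_class {self.pulse_class!r} inconsistent with "
                f"cycle_count {self.cycle_count}"
            )


@dataclass
class ClassificationSummary:
    n_pulses: int
    n_polycyclic: int
    percent_polycyclic: float | None
    cycle_histogram: dict[int, int]


def detection_threshold(recording: SongRecording, config: AnalysisConfig) -> float:
    """Absolute event threshold for a band-passed recording."""
    x = recording.samples
    noise_scale = sps.median_abs_deviation(x, scale="normal")
    floor = _THRESHOLD_FLOOR_FRACTION * float(np.max(np.abs(x)))
    return max(config.detection_noise_multiplier * noise_scale, floor)


def detect_pulses(
    recording: SongRecording, config: AnalysisConfig
) -> list[tuple[float, float]]:
    """Segment a band-passed recording into provisional pulse windows.

    Returns time-ordered, non-overlapping half-open windows ``[start_s,
    end_s)``.  The caller is expected to pass the output of
    :func:`pulsesong.spectral_analysis.bandpass_filter`.  Sustained sine-song
    oscillation does not yield events: any above-threshold stretch longer
    than ~50 ms is rejected as sustained oscillation rather than a wing-beat
    pulse, and a recording dominated by sine song additionally has a noise
    scale comparable to its own amplitude, keeping the threshold high.
    """
    x = recording.samples
    sr = recording.sample_rate_hz
    thr = detection_threshold(recording, config)
    if thr <= 0:
        return []
    above = np.flatnonzero(np.abs(x) > thr)
    if above.size == 0:
        return []
    gap = max(1, int(round(_CLUSTER_GAP_S * sr)))
    pad = int(round(_WINDOW_PAD_S * sr))
    breaks = np.flatnonzero(np.diff(above) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [above.size - 1]))
    windows: list[tuple[int, int]] = []
    max_span = int(round(_MAX_EVENT_S * sr))
    for s, e in zip(starts, ends):
        if above[e] - above[s] > max_span:
            continue  # sustained oscillation (sine song), not a pulse
        i0 = max(0, int(above[s]) - pad)
        i1 = min(x.size, int(above[e]) + pad + 1)
        peak = float(np.max(np.abs(x[i0:i1])))
        if peak < _EVENT_VALIDATION_FACTOR * thr:
            continue  # sub-threshold fluctuation, not a song pulse
        if windows and i0 <= windows[-1][1]:
            windows[-1] = (windows[-1][0], i1)
        else:
            windows.append((i0, i1))
    return [(i0 / sr, i1 / sr) for i0, i1 in windows]


def estimate_baseline(
    recording: SongRecording,
    onset_s: float,
    window_s: float = 3.0,
    exclude_windows: list[tuple[float, float]] | None = None,
) -> float:
    """Mean voltage of the period immediately preceding a pulse's rising phase.

    Samples inside ``exclude_windows`` (detected pulse windows) are omitted.
    If fewer than 50 ms of usable history remain, falls back to the
    recording-wide median of non-pulse samples (logged as a fallback).
    """
    sr = recording.sample_rate_hz
    x = recording.samples
    onset_i = int(round(onset_s * sr))
    if not 0 <= onset_i <= x.size:
        raise ValueError(f"onset_s={onset_s} outside recording")
    start_i = max(0, onset_i - int(round(window_s * sr)))
    mask = np.ones(onset_i - start_i, dtype=bool)
    for w0, w1 in exclude_windows or ():
        j0 = max(start_i, int(round(w0 * sr))) - start_i
        j1 = min(onset_i, int(round(w1 * sr))) - start_i
        if j1 > j0 >= 0:
            mask[j0:j1] = False
    usable = int(mask.sum())
    if usable >= int(_MIN_BASELINE_S * sr):
        return float(np.mean(x[start_i:onset_i][mask]))
    logger.debug(
        "baseline fallback to recording-wide median at onset %.3f s "
        "(only %.1f ms of history)", onset_s, usable / sr * 1000.0,
    )
    full_mask = np.ones(x.size, dtype=bool)
    for w0, w1 in exclude_windows or ():
        full_mask[int(round(w0 * sr)):int(round(w1 * sr))] = False
    pool = x[full_mask] if full_mask.any() else x
    return float(np.median(pool))


def measure_peak_height(
    recording: SongRecording, window: tuple[float, float], baseline: float
) -> tuple[float, float]:
    """Peak height (baseline to largest |deflection|) and the primary peak time.

    Ties go to the earliest sample.
    """
    sr = recording.sample_rate_hz
    i0, i1 = (int(round(window[0] * sr)), int(round(window[1] * sr)))
    seg = np.abs(recording.samples[i0:i1] - baseline)
    if seg.size == 0:
        raise ValueError("empty pulse window")
    k = int(np.argmax(seg))  # argmax returns the first maximum
    return float(seg[k]), (i0 + k) / sr


def count_cycles(
    recording: SongRecording,
    window: tuple[float, float],
    baseline: float,
    peak_height: float,
    slice_fraction: float,
    min_separation_ms: float = 1.0,
) -> tuple[int, str, list[float]]:
    """Count a pulse's cycles by the slice-level criterion.

    Candidate peaks are local extrema of ``|signal - baseline|`` inside the
    window; those exceeding ``slice_fraction * peak_height`` are counted,
    subject to a separation rule that suppresses ripple: two counted peaks
    must be >= ``min_separation_ms`` apart and either have a zero-crossing of
    the baseline-subtracted signal between them or dip below 50% of the
    smaller peak.  The primary peak is always counted.
    """
    if not peak_height > 0:
        raise ValueError("peak_height must be positive")
    sr = recording.sample_rate_hz
    i0, i1 = (int(round(window[0] * sr)), int(round(window[1] * sr)))
    d = recording.samples[i0:i1] - baseline
    a = np.abs(d)
    slice_level = slice_fraction * peak_height

    cand = _local_maxima(a)
    primary = int(np.argmax(a))
    if primary not in cand:
        cand.append(primary)
    cand = [c for c in cand if a[c] > slice_level or c == primary]

    # greedy by amplitude (earliest on ties); keep a candidate only if it is
    # separated from every already-counted peak
    order = sorted(cand, key=lambda c: (-a[c], c))
    min_sep = int(round(min_separation_ms / 1000.0 * sr))
    accepted: list[int] = []
    for c in order:
        ok = True
        for p in accepted:
            lo, hi = (c, p) if c < p else (p, c)
            if hi - lo < min_sep:
                ok = False
                break
            between = d[lo:hi + 1]
            has_zero_crossing = np.any(np.signbit(between[:-1]) != np.signbit(between[1:])) or np.any(between == 0)
            dips = np.min(a[lo:hi + 1]) < 0.5 * min(a[lo], a[hi])
            if not (has_zero_crossing or dips):
                ok = False
                break
        if ok:
            accepted.append(c)
    accepted.sort()
    times = [(i0 + c) / sr for c in accepted]
    n = len(accepted)
    return n, (MONOCYCLIC if n == 1 else POLYCYCLIC), times


def _local_maxima(a: np.ndarray) -> list[int]:
    """Indices of strict-left / weak-right local maxima (first sample of plateaus)."""
    if a.size < 3:
        return []
    rising = a[1:-1] > a[:-2]
    falling = a[1:-1] >= a[2:]
    idx = np.flatnonzero(rising & falling) + 1
    # collapse plateaus: keep an index only if it is the first of its run
    out = []
    last_val = None
    last_i = -10
    for i in idx:
        if a[i] == last_val and np.all(a[last_i:i] == a[i]):
            continue
        out.append(int(i))
        last_val = a[i]
        last_i = i
    return out


def summarize_classification(events: list[PulseEvent]) -> ClassificationSummary:
    """Aggregate counts and the polycyclic percentage (absent when no pulses)."""
    n = len(events)
    n_poly = sum(1 for e in events if e.pulse_class == POLYCYCLIC)
    hist: dict[int, int] = {}
    for e in events:
        hist[e.cycle_count] = hist.get(e.cycle_count, 0) + 1
    percent = 100.0 * n_poly / n if n > 0 else None
    return ClassificationSummary(
        n_pulses=n, n_polycyclic=n_poly, percent_polycyclic=percent,
        cycle_histogram=dict(sorted(hist.items())),
    )


def extract_events(
    filtered: SongRecording, config: AnalysisConfig
) -> list[PulseEvent]:
    """Detect, measure and classify every pulse in a band-passed recording."""
    windows = detect_pulses(filtered, config)
    events: list[PulseEvent] = []
    for window in windows:
        baseline = estimate_baseline(
            filtered, window[0], config.baseline_window_s, exclude_windows=windows
        )
        height, peak_s = measure_peak_height(filtered, window, baseline)
        if height <= 0:
            continue  # degenerate zero-height event
        cycles, klass, times = count_cycles(
            filtered, window, baseline, height, config.slice_fraction
        )
        events.append(
            PulseEvent(
                primary_peak_s=peak_s, baseline=baseline, peak_height=height,
                window=window, peak_times_s=times, cycle_count=cycles,
                pulse_class=klass, slice_level=config.slice_fraction * height,
            )
        )
    return events
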