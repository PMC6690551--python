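"""Synthetic courtship-song generator with per-pulse ground truth.

Emulates the statistical structure of *Drosophila melanogaster* pulse song:
bouts of brief wing-beat pulses with Gaussian interpulse intervals (~35 ms in
wild type), a per-pulse carrier frequency, a monocyclic/polycyclic cycle-count
mixture, optional sine-song segments (120-180 Hz), additive white recording
noise and a DC baseline offset.  Two presets bracket the phenotypes of
interest: ``wildtype`` (monocyclic pulses, ~232 Hz carrier, 35 ms IPI) and
``cro`` (a *croaker*-like song: 35% polycyclic pulses at a higher carrier and
a prolonged IPI).

Every generated recording comes with a :class:`GroundTruth` table recording
each drawn pulse time, class, cycle count and carrier, so detection and
classification can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .core_io import SongRecording

#: relative crest heights of the sub-threshold flank lobes on each side of the
#: counted lobes.  They stay below the 50% slice level even after the ~500 Hz
#: low-pass of the analysis band (which smooths the primary crest more than
#: the flanks and so inflates flank ratios), while keeping the waveform
#: oscillatory enough that its spectral peak sits at the carrier frequency.
FLANK_PROFILE = (0.18, 0.13, 0.09, 0.05, 0.02)

#: geometric decay of successive counted-lobe crests after the primary peak;
#: 0.85**3 = 0.614 keeps even the 4th counted lobe well above the 50% slice.
LOBE_DECAY = 0.85

#: IPI draws are clipped below at this floor so consecutive pulses never
#: overlap (pulse waveforms are at most ~15 ms wide).
IPI_FLOOR_MS = 15.0


@dataclass
class SineSongParams:
    """Optional sustained sine-song segments inserted into interbout gaps."""

    carrier_hz: float = 150.0
    amplitude: float = 0.25
    duration_s: float = 0.5

    def __post_init__(self) -> None:
        if not 120.0 <= self.carrier_hz <= 180.0:
            raise ValueError("sine-song carrier must lie in [120, 180] Hz")


@dataclass
class GenotypeSongParams:
    """Generator parameterization for one genotype.

    ``cycle_mixture`` maps cycle count (>= 2) to probability, conditional on a
    pulse being polycyclic.  Monocyclic pulses use ``pulse_carrier_hz``;
    polycyclic pulses use ``polycyclic_carrier_hz``.
    """

    ipi_mean_ms: float
    ipi_sd_ms: float
    pulse_carrier_hz: float
    polycyclic_carrier_hz: float
    polycyclic_fraction: float
    cycle_mixture: dict[int, float] = field(
        default_factory=lambda: {2: 0.65, 3: 0.345, 4: 0.005}
    )
    pulse_amplitude: float = 1.0
    noise_sd: float = 0.0
    bout_length_pulses: float = 50.0
    interbout_gap_s: float = 1.0
    sine_song: Optional[SineSongParams] = None
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.ipi_mean_ms > 0:
            raise ValueError("ipi_mean_ms must be positive")
        if not 0.0 <= self.polycyclic_fraction <= 1.0:
            raise ValueError("polycyclic_fraction must lie in [0, 1]")
        total = sum(self.cycle_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cycle_mixture probabilities sum to {total}, not 1")
        if any(c < 2 for c in self.cycle_mixture):
            raise ValueError("cycle_mixture entries must have cycle count >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator actually drew: per-pulse and per-bout records."""

    pulses: pd.DataFrame  # onset_s, primary_peak_s, cycle_count, class, carrier_hz, bout_id
    bouts: pd.DataFrame   # bout_id, start_s, end_s

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def polycyclic_fraction(self) -> float:
        if self.n_pulses == 0:
            return float("nan")
        return float((self.pulses["class"] == "polycyclic").mean())

    def ipis_ms(self) -> np.ndarray:
        """Ground-truth IPIs (peak to peak, within bouts), in ms."""
        out = []
        for _, grp in self.pulses.groupby("bout_id"):
            t = grp["primary_peak_s"].to_numpy()
            out.append(np.diff(t) * 1000.0)
        return np.concatenate(out) if out else np.empty(0)


_PRESETS = {
    "wildtype": dict(
        ipi_mean_ms=35.0, ipi_sd_ms=3.0,
        pulse_carrier_hz=232.0, polycyclic_carrier_hz=350.0,
        polycyclic_fraction=0.0,
        noise_sd=0.1,  # amplitude SNR 10 against unit pulses
    ),
    "cro": dict(
        ipi_mean_ms=40.0, ipi_sd_ms=4.0,
        pulse_carrier_hz=313.0, polycyclic_carrier_hz=350.0,
        polycyclic_fraction=0.35,
        noise_sd=0.1,
    ),
}


def genotype_preset(name: str) -> GenotypeSongParams:
    """Return generator parameters for a named genotype preset.

    ``wildtype``: monocyclic pulses only, 232 Hz carrier, 35 +/- 3 ms IPI.
    ``cro``: 35% polycyclic pulses (cycle mixture 65% two-cycle, 34.5%
    three-cycle, 0.5% four-cycle), 313 Hz monocyclic / 350 Hz polycyclic
    carriers, 40 +/- 4 ms IPI.
    """
    try:
        kwargs = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return GenotypeSongParams(**kwargs)


def _lobe_profile(cycle_count: int) -> np.ndarray:
    flank = list(FLANK_PROFILE)
    counted = [LOBE_DECAY**k for k in range(cycle_count)]
    return np.array(flank[::-1] + counted + flank, dtype=float)


def primary_peak_offset_s(cycle_count: int, carrier_hz: float) -> float:
    """Time of the primary crest relative to the start of the pulse waveform."""
    half = 1.0 / (2.0 * carrier_hz)
    return (len(FLANK_PROFILE) + 0.5) * half


def make_pulse(
    cycle_count: int, carrier_hz: float, amplitude: float, sample_rate_hz: float
) -> np.ndarray:
    """Synthesize one damped-oscillation song pulse.

    The waveform is a carrier sinusoid under a smooth (monotone-cubic)
    envelope passing through prescribed crest heights: ``cycle_count`` counted
    lobes (primary at 100%, then decaying by ``LOBE_DECAY`` per lobe, all
    above the 50% slice level) framed by sub-threshold flank lobes.  In the
    noise-free case the number of half-period lobes exceeding 50% of the
    maximal lobe therefore equals ``cycle_count`` exactly, and the peak
    absolute value equals ``amplitude``.
    """
    if cycle_count < 1:
        raise ValueError("cycle_count must be >= 1")
    if not carrier_hz < sample_rate_hz / 2:
        raise ValueError("carrier_hz must be below the Nyquist frequency")
    prof = _lobe_profile(cycle_count)
    half = 1.0 / (2.0 * carrier_hz)
    n = int(np.floor(len(prof) * half * sample_rate_hz))
    if amplitude == 0:
        return np.zeros(n)
    crest_t = (np.arange(len(prof)) + 0.5) * half
    knots = np.concatenate(([0.0], crest_t, [len(prof) * half]))
    vals = np.concatenate(([0.0], prof, [0.0]))
    envelope = PchipInterpolator(knots, vals)
    t = np.arange(n) / sample_rate_hz
    s = envelope(t) * np.sin(2.0 * np.pi * carrier_hz * t)
    return s * (amplitude / np.max(np.abs(s)))


def generate_song(
    params: GenotypeSongParams, duration_s: float, seed: int
) -> tuple[SongRecording, GroundTruth]:
    """Generate a song recording plus exact ground truth.

    One pseudo-random stream is seeded per call; the draw order is fixed:
    bout sizes, then IPIs, then pulse classes, then cycle counts, then
    recording noise.  Identical ``(params, duration_s, seed)`` give identical
    output.  Pulses whose waveform would extend past ``duration_s`` are
    dropped.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    sr = 10_000.0

    # 1) bout structure: sizes drawn until the expected timeline over-covers
    #    the requested duration (surplus bouts are simply never placed).
    mean_ipi_s = params.ipi_mean_ms / 1000.0
    bout_sizes: list[int] = []
    covered = 0.0
    while covered < duration_s * 1.5 + 5.0:
        size = max(1, int(rng.poisson(params.bout_length_pulses)))
        bout_sizes.append(size)
        covered += size * mean_ipi_s + params.interbout_gap_s
    n_total = int(sum(bout_sizes))

    # 2) IPIs for every within-bout step, clipped at the non-overlap floor
    n_ipis = n_total - len(bout_sizes)
    ipis_ms = rng.normal(params.ipi_mean_ms, params.ipi_sd_ms, size=n_ipis)
    ipis_ms = np.maximum(ipis_ms, IPI_FLOOR_MS)

    # 3) classes, 4) cycle counts (conditional on polycyclic)
    is_poly = rng.random(n_total) < params.polycyclic_fraction
    cycle_values = np.array(sorted(params.cycle_mixture), dtype=int)
    cycle_probs = np.array([params.cycle_mixture[c] for c in cycle_values])
    cycle_probs = cycle_probs / cycle_probs.sum()
    poly_cycles = rng.choice(cycle_values, size=n_total, p=cycle_probs)

    n_samples = int(round(duration_s * sr))
    samples = np.zeros(n_samples)
    # pulses are kept clear of the recording edges (lead-in silence, end
    # margin) so no pulse is ever truncated by the recording boundary
    end_margin = int(round(0.1 * sr))

    start_pad_s = 0.5  # lead-in silence before the first bout
    pulse_rows = []
    bout_rows = []
    t_peak = start_pad_s + primary_peak_offset_s(1, params.pulse_carrier_hz)
    ipi_cursor = 0
    pulse_index = 0
    done = False
    for bout_id, size in enumerate(bout_sizes):
        if done:
            break
        bout_start = None
        placed_in_bout = 0
        for j in range(size):
            if j > 0:
                t_peak += ipis_ms[ipi_cursor] / 1000.0
                ipi_cursor += 1
            poly = bool(is_poly[pulse_index])
            cycles = int(poly_cycles[pulse_index]) if poly else 1
            carrier = params.polycyclic_carrier_hz if poly else params.pulse_carrier_hz
            pulse_index += 1
            wave = make_pulse(cycles, carrier, params.pulse_amplitude, sr)
            offset = primary_peak_offset_s(cycles, carrier)
            start_s = t_peak - offset
            i0 = int(round(start_s * sr))
            if i0 < 0 or i0 + wave.size > n_samples - end_margin:
                done = True
                break
            samples[i0:i0 + wave.size] += wave
            if bout_start is None:
                bout_start = start_s
            pulse_rows.append(
                dict(onset_s=start_s, primary_peak_s=t_peak, cycle_count=cycles,
                     **{"class": "polycyclic" if poly else "monocyclic"},
                     carrier_hz=carrier, bout_id=bout_id)
            )
            placed_in_bout += 1
        if placed_in_bout:
            last = pulse_rows[-1]
            bout_rows.append(dict(bout_id=bout_id, start_s=bout_start,
                                  end_s=last["onset_s"] + _pulse_span_s(
                                      last["cycle_count"], last["carrier_hz"])))
        # advance to the next bout's first peak
        t_peak += params.interbout_gap_s + params.ipi_mean_ms / 1000.0

    # optional sine-song segments in interbout gaps
    if params.sine_song is not None:
        _insert_sine_song(samples, sr, bout_rows, params.sine_song, duration_s)

    # 5) additive white recording noise and the DC baseline
    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd, size=n_samples)
    samples += params.baseline_offset

    pulses = pd.DataFrame(
        pulse_rows,
        columns=["onset_s", "primary_peak_s", "cycle_count", "class",
                 "carrier_hz", "bout_id"],
    )
    bouts = pd.DataFrame(bout_rows, columns=["bout_id", "start_s", "end_s"])
    recording = SongRecording(
        samples=samples, sample_rate_hz=sr, genotype="",
        source=f"generate_song(seed={seed})",
    )
    return recording, GroundTruth(pulses=pulses, bouts=bouts)


def _pulse_span_s(cycle_count: int, carrier_hz: float) -> float:
    return len(_lobe_profile(cycle_count)) / (2.0 * carrier_hz)


def _insert_sine_song(
    samples: np.ndarray, sr: float, bout_rows: list[dict],
    sine: SineSongParams, duration_s: float,
) -> None:
    """Place a sine segment at the start of each interbout gap (and the lead-in)."""
    # lead-in segment is capped so it ends before the first bout (~0.45 s in)
    gap_starts = [(0.05, 0.45)] + [(row["end_s"] + 0.05, duration_s) for row in bout_rows]
    for g0, cap in gap_starts:
        g1 = min(g0 + sine.duration_s, cap, duration_s)
        i0, i1 = int(round(g0 * sr)), int(round(g1 * sr))
        if i1 <= i0 or i1 > samples.size:
            continue
        t = np.arange(i1 - i0) / sr
        ramp = np.minimum(1.0, np.minimum(t, t[::-1]) / 0.02)  # 20 ms on/off ramp
        samples[i0:i1] += sine.amplitude * ramp * np.sin(2 * np.pi * sine.carrier_hz * t)


def ground_truth_to_csv(truth: GroundTruth, path) -> None:
    """Write the per-pulse ground truth as CSV (onset_s, peak_s, cycle_count, class, carrier_hz)."""
    df = truth.pulses.rename(columns={"primary_peak_s": "peak_s"})
    df.to_csv(path, index=False)
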