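"""End-to-end song analysis: recording -> ResultBundle.

Order of operations: band-pass filter (DC removal, ~1-500 Hz), event
detection on the filtered trace, per-pulse baseline / peak height / cycle
classification, interpulse intervals with a Gaussian fit, and averaged
per-pulse power spectra (overall and stratified by pulse class,
noise-subtracted when the recording contains enough song-free signal).
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd

from . import __version__
from .core_io import AnalysisConfig, ResultBundle, SongRecording
from .ipi_analysis import compute_ipis, fit_gaussian
from .pulse_analysis import extract_events, summarize_classification
from .spectral_analysis import bandpass_filter, pulse_spectrum, stratified_spectra

logger = logging.getLogger("pulsesong")


def analyze_song(recording: SongRecording, config: AnalysisConfig | None = None) -> ResultBundle:
    """Run the full pipeline on one recording and return all result tables."""
    config = config or AnalysisConfig()
    config.validate_for_rate(recording.sample_rate_hz)
    logger.info(
        "pulsesong %s | numpy %s | python %s | source=%s | slice=%.2f seed=%d",
        __version__, np.__version__, sys.version.split()[0],
        recording.source, config.slice_fraction, config.rng_seed,
    )

    filtered = bandpass_filter(recording, config.band_low_hz, config.band_high_hz)
    events = extract_events(filtered, config)
    summary_cls = summarize_classification(events)

    pulse_table = pd.DataFrame(
        [
            dict(
                primary_peak_s=e.primary_peak_s, baseline=e.baseline,
                peak_height=e.peak_height, cycle_count=e.cycle_count,
                **{"class": e.pulse_class}, slice_level=e.slice_level,
                window_start_s=e.window[0], window_end_s=e.window[1],
            )
            for e in events
        ]
    )

    ipis = compute_ipis(events, config.bout_break_ms, genotype=recording.genotype)
    ipi_table = pd.DataFrame(
        [dict(bout_id=s.bout_id, ipi_ms=s.ipi_ms) for s in ipis]
    )
    gauss = None
    try:
        if len(ipis) >= 30:
            gauss = fit_gaussian(ipis, config.ipi_bin_width_ms)
    except (ValueError, RuntimeError) as exc:
        logger.warning("IPI Gaussian fit unavailable: %s", exc)

    spectrum_rows = []
    peaks: dict[str, float] = {}
    if events:
        overall = pulse_spectrum(filtered, events, config)
        peaks["all"] = overall.peak_hz
        spectrum_rows.extend(_spectrum_rows("all", overall))
        for klass, spec in stratified_spectra(filtered, events, config).items():
            peaks[klass] = spec.peak_hz
            spectrum_rows.extend(_spectrum_rows(klass, spec))
    spectrum_table = pd.DataFrame(spectrum_rows)

    summary = {
        "genotype": recording.genotype,
        "source": recording.source,
        "slice_fraction": config.slice_fraction,
        "n_pulses": summary_cls.n_pulses,
        "n_polycyclic": summary_cls.n_polycyclic,
        "percent_polycyclic": summary_cls.percent_polycyclic,
        "cycle_histogram": {str(k): v for k, v in summary_cls.cycle_histogram.items()},
        "n_ipis": len(ipis),
        "ipi_fit": None if gauss is None else {
            "mu_ms": gauss.mu_ms, "sigma_ms": gauss.sigma_ms,
            "amplitude": gauss.amplitude, "r_squared": gauss.r_squared,
            "n": gauss.n, "bin_width_ms": gauss.bin_width_ms,
        },
        "peak_hz": peaks,
    }
    bundle = ResultBundle(
        pulse_table=pulse_table, ipi_table=ipi_table,
        spectrum_table=spectrum_table, summary=summary,
    )
    bundle.validate()
    return bundle


def _spectrum_rows(klass: str, spec) -> list[dict]:
    return [
        {"class": klass, "freq_hz": f, "power": p,
         "noise_subtracted": bool(spec.noise_subtracted)}
        for f, p in zip(spec.freq_hz, spec.power)
    ]
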