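"""Domain types and I/O for courtship-song analysis.

The universal input is a :class:`SongRecording`: a mono voltage trace with a
sampling rate (nominally 10 kHz) and a genotype label.  Analysis results are
collected in a :class:`ResultBundle` of flat tables (pulses, interpulse
intervals, spectra) plus a JSON-serializable summary.  Voltage units are
arbitrary throughout -- every downstream threshold is relative.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

logger = logging.getLogger("pulsesong")

NOMINAL_RATE_HZ = 10_000.0

#: fixed column orders for the result tables (deterministic CSV output)
PULSE_COLUMNS = [
    "primary_peak_s", "baseline", "peak_height", "cycle_count", "class",
    "slice_level", "window_start_s", "window_end_s",
]
IPI_COLUMNS = ["bout_id", "ipi_ms"]
SPECTRUM_COLUMNS = ["class", "freq_hz", "power", "noise_subtracted"]


@dataclass
class SongRecording:
    """A mono acoustic recording of courtship song.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, arbitrary units, possibly signed.
    sample_rate_hz : float
        Sampling rate; the analysis grid assumes a nominal 10 kHz.
    genotype : str
        Free-text genotype label carried through to results.
    source : str
        Provenance: a file path or a generator seed descriptor.
    """

    samples: np.ndarray
    sample_rate_hz: float
    genotype: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class AnalysisConfig:
    """Tunable parameters of the song-analysis pipeline.

    ``slice_fraction`` is the per-pulse cycle-counting threshold as a fraction
    of peak height (0.50 standard, 0.60 stringent variant).  The detection
    threshold is ``detection_noise_multiplier`` times the robust (normal-
    consistent MAD) noise scale of the band-passed trace.
    """

    slice_fraction: float = 0.50
    detection_noise_multiplier: float = 5.0
    baseline_window_s: float = 3.0
    bout_break_ms: float = 100.0
    band_low_hz: float = 1.0
    band_high_hz: float = 500.0
    fft_window_samples: int = 1024
    ipi_bin_width_ms: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.slice_fraction < 1.0:
            raise ValueError("slice_fraction must lie in (0, 1)")
        if not self.detection_noise_multiplier > 0:
            raise ValueError("detection_noise_multiplier must be positive")
        n = self.fft_window_samples
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError("fft_window_samples must be a power of two")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("require 0 < band_low_hz < band_high_hz")

    def validate_for_rate(self, sample_rate_hz: float) -> None:
        if not self.band_high_hz < sample_rate_hz / 2:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} must be below the Nyquist "
                f"frequency {sample_rate_hz / 2}"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat key/value YAML/JSON config; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ResultBundle:
    """All tabular output of one analysis run."""

    pulse_table: pd.DataFrame
    ipi_table: pd.DataFrame
    spectrum_table: pd.DataFrame
    summary: dict

    def __post_init__(self) -> None:
        self.pulse_table = _with_columns(self.pulse_table, PULSE_COLUMNS)
        self.ipi_table = _with_columns(self.ipi_table, IPI_COLUMNS)
        self.spectrum_table = _with_columns(self.spectrum_table, SPECTRUM_COLUMNS)

    def validate(self) -> None:
        n = self.summary.get("n_pulses")
        if n is not None and n != len(self.pulse_table):
            raise ValueError(
                f"summary n_pulses={n} != pulse table rows {len(self.pulse_table)}"
            )
        n_ipi = self.summary.get("n_ipis")
        if n_ipi is not None and n_ipi != len(self.ipi_table):
            raise ValueError(
                f"summary n_ipis={n_ipi} != ipi table rows {len(self.ipi_table)}"
            )

    def equals(self, other: "ResultBundle") -> bool:
        for a, b in (
            (self.pulse_table, other.pulse_table),
            (self.ipi_table, other.ipi_table),
            (self.spectrum_table, other.spectrum_table),
        ):
            if len(a) != len(b) or list(a.columns) != list(b.columns):
                return False
            for col in a.columns:
                xa, xb = a[col].to_numpy(), b[col].to_numpy()
                if xa.dtype.kind in "fc":
                    if not np.allclose(xa, xb, rtol=1e-10, atol=1e-12, equal_nan=True):
                        return False
                elif not (xa == xb).all():
                    return False
        return _json_round_trip(self.summary) == _json_round_trip(other.summary)


def _with_columns(df: pd.DataFrame | None, columns: list[str]) -> pd.DataFrame:
    if df is None or len(df) == 0:
        return pd.DataFrame({c: [] for c in columns})
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    return df[columns].reset_index(drop=True)


def _json_round_trip(obj):
    return json.loads(json.dumps(obj, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_wav(path: str | Path) -> SongRecording:
    """Read a mono WAV file into a :class:`SongRecording`.

    Integer PCM is rescaled to [-1, 1]; 32/64-bit float data is taken as-is.
    A sampling rate other than the nominal 10 kHz is accepted with a warning.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unreadable WAV header in {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"expected mono recording, got {data.shape[1]} channels in {path}"
        )
    if data.dtype.kind == "i":
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned with midpoint 128
        info = np.iinfo(data.dtype)
        half = (info.max + 1) / 2
        samples = (data.astype(np.float64) - half) / half
    else:
        samples = data.astype(np.float64)
    if rate != NOMINAL_RATE_HZ:
        logger.warning("WAV %s sampled at %d Hz (nominal is 10000 Hz)", path, rate)
    return SongRecording(samples=samples, sample_rate_hz=float(rate), source=str(path))


def write_wav(recording: SongRecording, path: str | Path, dtype: str = "float32") -> Path:
    """Write a recording as mono WAV (``float32`` or ``int16`` PCM)."""
    path = Path(path)
    if dtype == "float32":
        wavfile.write(path, int(round(recording.sample_rate_hz)),
                      recording.samples.astype(np.float32))
    elif dtype == "int16":
        peak = float(np.max(np.abs(recording.samples)))
        scale = 32767.0 / peak if peak > 0 else 1.0
        wavfile.write(path, int(round(recording.sample_rate_hz)),
                      np.round(recording.samples * scale).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    return path


def write_results(bundle: ResultBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle to ``out_dir`` as three CSVs plus ``summary.json``.

    Column order is fixed; the files round-trip through
    :func:`read_results` into an equal bundle.
    """
    bundle.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pulse_table": out_dir / "pulses.csv",
        "ipi_table": out_dir / "ipis.csv",
        "spectrum_table": out_dir / "spectra.csv",
        "summary": out_dir / "summary.json",
    }
    bundle.pulse_table.to_csv(paths["pulse_table"], index=False)
    bundle.ipi_table.to_csv(paths["ipi_table"], index=False)
    bundle.spectrum_table.to_csv(paths["spectrum_table"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(bundle.summary, fh, indent=2, default=_json_default)
        fh.write("\n")
    return paths


def read_results(out_dir: str | Path) -> ResultBundle:
    """Read back a bundle previously written by :func:`write_results`."""
    out_dir = Path(out_dir)
    with open(out_dir / "summary.json") as fh:
        summary = json.load(fh)
    return ResultBundle(
        pulse_table=pd.read_csv(out_dir / "pulses.csv"),
        ipi_table=pd.read_csv(out_dir / "ipis.csv"),
        spectrum_table=pd.read_csv(out_dir / "spectra.csv"),
        summary=summary,
    )
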