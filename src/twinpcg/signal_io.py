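"""Reading, windowing and synthesis of heart-sound records.

A phonocardiogram (PCG) is the acoustic waveform of the beating heart. Each
cardiac cycle produces two dominant transients, S1 (closure of the
atrioventricular valves, low-pitched) and S2 (closure of the semilunar
valves, slightly higher-pitched). Many pathologies add a *murmur*: broadband
turbulent-flow noise, most often in the systolic interval between S1 and S2.

The synthetic generator in this module emulates exactly that structure so
the full feature-extraction and classification pipeline can be exercised
without any external recordings: Gaussian-enveloped tone bursts for S1/S2 at
a configurable heart rate, an optional band-limited systolic murmur that
defines the "abnormal" class, and additive white sensor noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfilt

NORMAL = "normal"
ABNORMAL = "abnormal"

#: Fixed analysis window used throughout: 10,000 samples at 2 kHz (5 s).
DEFAULT_WINDOW = 10_000
DEFAULT_RATE = 2000


@dataclass(frozen=True)
class HeartSoundRecord:
    """A sampled heart-sound waveform with optional class label."""

    record_id: str
    samples: np.ndarray
    sampling_rate: int
    label: str | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.label is not None and self.label not in (NORMAL, ABNORMAL):
            raise ValueError(f"label must be {NORMAL!r} or {ABNORMAL!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of the synthetic PCG generator.

    Defaults give a 5 s record at 2 kHz (10,000 samples) with plausible PCG
    physiology: S1 around 50 Hz, S2 around 80 Hz, murmur band 100-400 Hz.
    """

    duration_s: float = 5.0
    sampling_rate: int = DEFAULT_RATE
    heart_rate_bpm: float = 72.0
    s1_freq_hz: float = 50.0
    s2_freq_hz: float = 80.0
    s1_width_s: float = 0.02    # Gaussian envelope sd; burst lasts ~6 sd
    s2_width_s: float = 0.015
    systole_s: float = 0.32     # S1 -> S2 interval (near-constant physiologically)
    murmur_amplitude: float = 0.0
    murmur_band_hz: tuple[float, float] = (100.0, 400.0)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not (20 <= self.heart_rate_bpm <= 220):
            raise ValueError("heart_rate_bpm must lie in [20, 220]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.murmur_amplitude < 0:
            raise ValueError("murmur_amplitude must be >= 0")
        lo, hi = self.murmur_band_hz
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("murmur_band_hz must satisfy 0 < lo < hi < Nyquist")


def read_wav(path: str | Path) -> HeartSoundRecord:
    """Read a mono PCM WAV file into a :class:`HeartSoundRecord`.

    Integer PCM is scaled to [-1, 1] by the full scale of its dtype so that
    scale-dependent features (coefficient two-norms) are computed on a fixed
    amplitude convention. The label is left unset.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"{path}: mono required, file has {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned 8-bit PCM is offset-binary
            offset = (info.max + 1) / 2.0
            scale = offset
        samples = (data.astype(float) - offset) / scale
    else:
        samples = data.astype(float)
    return HeartSoundRecord(record_id=path.stem, samples=samples,
                            sampling_rate=int(rate))


def write_wav(path: str | Path, record: HeartSoundRecord) -> None:
    """Write a record as 16-bit PCM WAV, clipping amplitudes to [-1, 1]."""
    clipped = np.clip(record.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(Path(path), record.sampling_rate, data)


def window_record(record: HeartSoundRecord, n: int = DEFAULT_WINDOW) -> HeartSoundRecord:
    """Take the first ``n`` samples, zero-padding records that are shorter.

    Idempotent for fixed ``n``; the label and rate are preserved.
    """
    if n <= 0:
        raise ValueError("window length n must be positive")
    m = record.samples.size
    if m >= n:
        samples = record.samples[:n]
    else:
        samples = np.concatenate([record.samples, np.zeros(n - m)])
    return replace(record, samples=samples)


def _gauss_burst(t: np.ndarray, center: float, width: float, freq: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / width) ** 2)
    return env * np.sin(2 * np.pi * freq * (t - center))


def synthesize_pcg(config: SynthesisConfig, label: str = NORMAL) -> HeartSoundRecord:
    """Generate one synthetic phonocardiogram.

    The waveform is a sum of per-beat S1 and S2 Gaussian-enveloped tone
    bursts at ``heart_rate_bpm``, plus (for the abnormal class) band-limited
    murmur noise confined to the systolic S1->S2 interval, plus white noise.

    Deterministic for a fixed config: the sensor-noise and murmur random
    streams are spawned independently from ``config.seed``, so the normal
    and abnormal variants of the same seed share identical background noise
    and differ only by the murmur.
    """
    if label not in (NORMAL, ABNORMAL):
        raise ValueError(f"label must be {NORMAL!r} or {ABNORMAL!r}")
    n = int(round(config.duration_s * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    period = 60.0 / config.heart_rate_bpm

    x = np.zeros(n)
    beat_starts = np.arange(0.0, config.duration_s, period)
    # S1 centered shortly after beat onset so the burst is fully inside.
    s1_offset = 3 * config.s1_width_s
    for t0 in beat_starts:
        x += _gauss_burst(t, t0 + s1_offset, config.s1_width_s, config.s1_freq_hz)
        # S2 softer than S1, as at the apex
        x += 0.45 * _gauss_burst(t, t0 + s1_offset + config.systole_s,
                                 config.s2_width_s, config.s2_freq_hz)

    noise_ss, murmur_ss = np.random.SeedSequence(config.seed).spawn(2)
    if label == ABNORMAL and config.murmur_amplitude > 0:
        rng = np.random.default_rng(murmur_ss)
        raw = rng.standard_normal(n)
        nyq = config.sampling_rate / 2
        lo, hi = config.murmur_band_hz
        sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
        band = sosfilt(sos, raw)
        band /= max(np.std(band), 1e-12)
        # smooth systolic window between the tails of S1 and S2
        gate = np.zeros(n)
        for t0 in beat_starts:
            a = t0 + s1_offset + 2 * config.s1_width_s
            b = t0 + s1_offset + config.systole_s - 2 * config.s2_width_s
            if b <= a:
                continue
            inside = (t >= a) & (t <= b)
            gate[inside] = np.maximum(
                gate[inside], np.sin(np.pi * (t[inside] - a) / (b - a)) ** 2
            )
        x += config.murmur_amplitude * gate * band

    if config.noise_sd > 0:
        rng = np.random.default_rng(noise_ss)
        x += config.noise_sd * rng.standard_normal(n)

    rid = f"syn-{label}-{config.seed}"
    return HeartSoundRecord(record_id=rid, samples=x,
                            sampling_rate=config.sampling_rate, label=label)


def synthesize_dataset(
    n_normal: int,
    n_abnormal: int,
    seed: int = 0,
    base_config: SynthesisConfig | None = None,
) -> list[HeartSoundRecord]:
    """Generate a labeled two-class synthetic PCG dataset.

    Per-record variation emulates the heterogeneity of a multi-site clinical
    archive: heart rate U(55, 100) bpm, S1/S2 center frequencies jittered
    ~10%, sensor noise sd U(0.01, 0.04), and an overall record gain
    LogNormal(0, 1.6) — uncalibrated recording chains put record amplitudes
    on wildly different scales, so absolute level carries no class
    information. Abnormal records get a systolic murmur of amplitude
    U(0.2, 0.5) in a band that varies per record (center U(150, 600) Hz,
    ~±40% width): different pathologies murmur in different bands, which
    spreads the murmur's energy signature across different wavelet-packet
    nodes from record to record. Deterministic in ``seed``.
    """
    base = base_config or SynthesisConfig()
    rng = np.random.default_rng(seed)
    records: list[HeartSoundRecord] = []
    labels = [NORMAL] * n_normal + [ABNORMAL] * n_abnormal
    for i, label in enumerate(labels):
        center = rng.uniform(150.0, 600.0)
        cfg = replace(
            base,
            heart_rate_bpm=rng.uniform(55, 100),
            s1_freq_hz=base.s1_freq_hz * rng.uniform(0.9, 1.1),
            s2_freq_hz=base.s2_freq_hz * rng.uniform(0.9, 1.1),
            noise_sd=rng.uniform(0.01, 0.04),
            murmur_amplitude=rng.uniform(0.2, 0.5) if label == ABNORMAL else 0.0,
            murmur_band_hz=(0.6 * center, min(1.4 * center, 950.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = synthesize_pcg(cfg, label)
        gain = float(rng.lognormal(0.0, 1.6))
        records.append(
            HeartSoundRecord(
                record_id=f"{label}-{i:04d}",
                samples=gain * rec.samples,
                sampling_rate=rec.sampling_rate,
                label=label,
            )
        )
    return records


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``record_id,label`` CSV into a dict.

    Accepts the textual labels {normal, abnormal} or the -1/1 integer
    convention (abnormal maps to the positive class, +1).
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("record_id", "id"):
                continue
            rid, raw = row[0].strip(), row[1].strip().lower()
            if raw in (NORMAL, "-1"):
                mapping[rid] = NORMAL
            elif raw in (ABNORMAL, "1", "+1"):
                mapping[rid] = ABNORMAL
            else:
                raise ValueError(f"unrecognized label {raw!r} for record {rid!r}")
    return mapping


def write_labels(path: str | Path, records: list[HeartSoundRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "label"])
        for rec in records:
            writer.writerow([rec.record_id, rec.label])
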