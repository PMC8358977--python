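"""Synthetic EEG cohort generator.

Emulates the study conditions the decoding analysis assumes: per subject, two
long sessions (one per stimulus class) in which a class-specific evoked
response repeats at a constant 2 Hz on top of spatially correlated 1/f
background noise, with optional bad channels and high-amplitude transient
artifacts. The acoustic stimuli themselves are never modelled - only the two
distinguishable stimulus-locked neural signatures the classifiers need.

Randomness is organised as one master seed fanned out with
``numpy.random.SeedSequence`` spawn keys, so any subject or session can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import CLASSES, Recording


@dataclass
class GeneratorConfig:
    """Conditions for one synthetic subject/cohort.

    snr is the ratio of evoked-response RMS (over the template's support) to
    background RMS; ``subject_snr_spread`` is the log-normal sigma of the
    cohort-level SNR distribution. Artifact transients default to brief
    (150 ms) localized pulses at 12x the background RMS, at a rate chosen so
    that roughly a quarter of 2-s epochs contain one.
    """

    n_channels: int = 64
    n_usable: int = 60
    native_rate: float = 1000.0
    stim_rate: float = 2.0
    n_repetitions: int = 2000
    snr: float = 0.6
    subject_snr_spread: float = 0.3
    background_rms: float = 20.0  # microvolts
    noise_slope: float = 1.0  # spectral exponent alpha, power ~ 1/f^alpha
    spatial_mixing_scale: float = 0.5  # kernel length on the unit sphere
    artifact_channel_count: int = 2
    artifact_transient_rate: float = 8.0  # transients per minute
    transient_amplitude: float = 12.0  # peak, in units of background RMS
    transient_duration: float = 0.15  # seconds
    site: str = "A"
    site_noise_scale: float = 1.0  # >1 adds a stationary site-specific noise floor
    rng_seed: int = 0

    def __post_init__(self):
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.native_rate <= 0 or self.stim_rate <= 0:
            raise ValueError("rates must be positive")
        if self.n_usable > self.n_channels:
            raise ValueError("n_usable cannot exceed n_channels")
        if self.artifact_channel_count >= self.n_channels:
            raise ValueError("artifact_channel_count must be < n_channels")

    @property
    def session_duration(self) -> float:
        """Seconds: n_repetitions / stim_rate."""
        return self.n_repetitions / self.stim_rate

    @property
    def onset_spacing(self) -> int:
        spacing = self.native_rate / self.stim_rate
        if abs(spacing - round(spacing)) > 1e-9:
            raise ValueError("native_rate must be an integer multiple of stim_rate")
        return int(round(spacing))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StimulusTemplate:
    """Stimulus-locked evoked waveform for one class, with a spatial profile."""

    class_label: str
    waveform: np.ndarray  # unit-RMS amplitude series at `rate`
    rate: float
    spatial_profile: np.ndarray  # per-channel gain

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.rate


def spiral_positions(n_channels: int) -> np.ndarray:
    """Deterministic sensor layout: Fibonacci spiral on the upper unit sphere."""
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    # z spans the upper hemisphere (scalp), azimuth follows the golden angle
    z = 0.05 + 0.95 * (i + 0.5) / n_channels
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_template(
    class_label: str,
    rng: np.random.Generator | int,
    rate: float = 1000.0,
    n_channels: int = 64,
    n_usable: int = 60,
) -> StimulusTemplate:
    """Build the evoked-response template for one stimulus class.

    The drum response is a fast damped oscillation (alpha-range energy,
    ~80 ms); the syllable response is a slower windowed low-frequency burst
    (delta/theta energy, ~300 ms). Both fit well inside the 0.5 s
    inter-onset interval and are normalised to unit RMS over their support.
    A small seeded jitter individualises the waveform and spatial profile
    per subject without moving the spectral signature across bands.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class_label {class_label!r}; expected one of {CLASSES}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    jitter = rng.normal(0.0, 1.0, size=4)
    positions = spiral_positions(n_channels)
    if class_label == "drum":
        dur = 0.08
        f0 = 11.0 * (1 + 0.04 * jitter[0])  # alpha-range carrier
        tau = 0.022 * (1 + 0.05 * jitter[1])
        t = np.arange(int(round(dur * rate))) / rate
        wave = np.exp(-t / tau) * np.sin(2 * np.pi * f0 * t)
        center = np.array([0.0, 0.15, 1.0])
    else:
        dur = 0.30
        f0 = 3.2 * (1 + 0.04 * jitter[0])  # delta/low-theta envelope
        t = np.arange(int(round(dur * rate))) / rate
        env = np.hanning(len(t))
        wave = env * np.sin(2 * np.pi * f0 * t + 0.3 * jitter[1])
        center = np.array([0.75, 0.0, 0.66])
    wave = wave / np.sqrt(np.mean(wave**2))
    center = center / np.linalg.norm(center)
    d2 = np.sum((positions - center) ** 2, axis=1)
    profile = np.exp(-d2 / (2 * 0.55**2))
    profile = profile * (1 + 0.05 * rng.normal(size=n_channels))
    profile[n_usable:] = 0.0  # unused channels carry no evoked response
    profile = profile / np.max(np.abs(profile))
    return StimulusTemplate(class_label, wave.astype(np.float64), rate, profile)


def generate_background(
    n_channels: int,
    duration: float,
    rate: float,
    rng: np.random.Generator | int,
    rms: float = 20.0,
    slope: float = 1.0,
    mixing_scale: float = 0.5,
    positions: np.ndarray | None = None,
) -> Recording:
    """Spatially correlated 1/f background noise, no events.

    Each channel's spectrum has power proportional to f^-slope; channels are
    mixed through a distance kernel exp(-d/mixing_scale) on the sensor
    positions, then rescaled so every channel has the requested RMS.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(round(duration * rate))
    if positions is None:
        positions = spiral_positions(n_channels)
    white = rng.standard_normal((n_channels, n)).astype(np.float32)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-slope / 2.0)
    # flatten below 0.3 Hz so very slow drift does not dominate long sessions
    low = (f > 0) & (f < 0.3)
    shape[low] = 0.3 ** (-slope / 2.0)
    spec *= shape[None, :]
    pink = np.fft.irfft(spec, n=n, axis=1).astype(np.float32)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    mix = np.exp(-d / mixing_scale).astype(np.float32)
    mix /= np.sqrt((mix**2).sum(axis=1, keepdims=True))
    data = mix @ pink
    data *= (rms / data.std(axis=1, keepdims=True)).astype(np.float32)
    return Recording(data=data, rate=rate, channel_positions=positions)


def generate_session(
    config: GeneratorConfig,
    class_label: str,
    rng: np.random.Generator | int | None = None,
    snr: float | None = None,
) -> Recording:
    """One continuous session: background + the class template at every onset.

    Onsets are exactly ``native_rate / stim_rate`` samples apart and number
    ``n_repetitions``; the template is scaled so that (template RMS x gain) /
    background RMS equals the subject SNR at the best-coupled channel.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    snr = config.snr if snr is None else snr
    template = make_template(
        class_label, rng, config.native_rate, config.n_channels, config.n_usable
    )
    spacing = config.onset_spacing
    if len(template.waveform) > spacing:
        raise ValueError("template longer than the inter-onset interval")
    rec = generate_background(
        config.n_channels,
        config.session_duration,
        config.native_rate,
        rng,
        rms=config.background_rms,
        slope=config.noise_slope,
        mixing_scale=config.spatial_mixing_scale,
    )
    onsets = np.arange(config.n_repetitions, dtype=np.int64) * spacing
    scale = snr * config.background_rms  # template has unit RMS
    if scale > 0:
        burst = (scale * np.outer(template.spatial_profile, template.waveform)).astype(
            np.float32
        )
        w = burst.shape[1]
        for onset in onsets:
            rec.data[:, onset : onset + w] += burst
    if config.site_noise_scale > 1.0:
        extra = (config.site_noise_scale - 1.0) * config.background_rms
        rec.data += (extra * rng.standard_normal(rec.data.shape)).astype(np.float32)
    rec.event_onsets = onsets
    rec.event_labels = np.array([class_label] * len(onsets), dtype=object)
    rec.site = config.site
    return rec


def inject_artifacts(
    recording: Recording,
    config: GeneratorConfig,
    rng: np.random.Generator | int,
    bad_channels: np.ndarray | None = None,
) -> tuple[Recording, dict]:
    """Contaminate a recording with bad channels and transient artifacts.

    Bad channels (``artifact_channel_count`` of the usable set) alternate
    between near-flat traces and high-variance traces. Transients are
    Poisson-placed (rate per minute) localized pulses: a Hann window of
    ``transient_duration`` at ``transient_amplitude`` x background RMS on a
    spatial neighbourhood of channels. Returns the contaminated recording and
    a ground-truth manifest {bad_channels, transients}.

    ``bad_channels`` fixes which channels go bad (a subject's two sessions
    come from a single net application, so their bad electrodes coincide);
    when None, the set is drawn from ``rng``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rec = recording.copy()
    manifest: dict = {"bad_channels": [], "transients": []}
    rms = float(np.median(rec.data.std(axis=1)))
    n_usable = min(recording.n_channels, 60)
    if config.artifact_channel_count > 0:
        if bad_channels is None:
            bad = rng.choice(n_usable, size=config.artifact_channel_count, replace=False)
        else:
            bad = np.asarray(bad_channels)
        for j, ch in enumerate(np.sort(bad)):
            if j % 2 == 0:
                rec.data[ch] = 0.01 * rec.data[ch]
                kind = "flat"
            else:
                rec.data[ch] = rec.data[ch] + (5.0 * rms) * rng.standard_normal(
                    rec.n_samples
                ).astype(np.float32)
                kind = "high_variance"
            manifest["bad_channels"].append({"channel": int(ch), "kind": kind})
    if config.artifact_transient_rate > 0:
        n_t = rng.poisson(config.artifact_transient_rate * recording.duration / 60.0)
        w = int(round(config.transient_duration * recording.rate))
        pulse = np.hanning(w).astype(np.float32)
        positions = (
            recording.channel_positions
            if recording.channel_positions is not None
            else spiral_positions(recording.n_channels)
        )
        for _ in range(n_t):
            start = int(rng.integers(0, max(1, rec.n_samples - w)))
            center = int(rng.integers(0, n_usable))
            d = np.linalg.norm(positions[:n_usable] - positions[center], axis=1)
            chans = np.argsort(d)[:12]  # localized neighbourhood
            gain = np.exp(-(np.sort(d)[:12] ** 2) / (2 * 0.4**2))
            amp = config.transient_amplitude * rms * rng.choice([-1.0, 1.0])
            rec.data[chans, start : start + w] += (
                amp * gain[:, None] * pulse[None, : rec.n_samples - start]
            ).astype(np.float32)
            manifest["transients"].append(
                {"start": start, "stop": start + w, "channels": chans.tolist()}
            )
    return rec, manifest


@dataclass
class SubjectData:
    """Both sessions of one synthetic subject plus ground truth."""

    subject_id: str
    recordings: dict  # class label -> Recording (contaminated)
    manifests: dict  # class label -> artifact manifest
    snr: float
    site: str
    config: GeneratorConfig = field(repr=False, default=None)


def generate_subject(
    config: GeneratorConfig, seed_seq: np.random.SeedSequence, subject_id: str = "S001"
) -> SubjectData:
    """One subject: SNR drawn from the cohort spread, two sessions, artifacts."""
    kids = seed_seq.spawn(1 + 2 * len(CLASSES))
    rng_subject = np.random.default_rng(kids[0])
    spread = config.subject_snr_spread
    if spread > 0:
        # log-normal with unit mean multiplier
        snr = config.snr * float(
            np.exp(spread * rng_subject.standard_normal() - spread**2 / 2)
        )
    else:
        snr = config.snr
    bad_set = None
    if config.artifact_channel_count > 0:
        bad_set = rng_subject.choice(
            min(config.n_channels, 60),
            size=config.artifact_channel_count,
            replace=False,
        )
    recordings, manifests = {}, {}
    for i, label in enumerate(CLASSES):
        rec = generate_session(
            config, label, rng=np.random.default_rng(kids[1 + 2 * i]), snr=snr
        )
        rec, manifest = inject_artifacts(
            rec, config, rng=np.random.default_rng(kids[2 + 2 * i]), bad_channels=bad_set
        )
        recordings[label] = rec
        manifests[label] = manifest
    return SubjectData(subject_id, recordings, manifests, snr, config.site, config)


def generate_cohort(
    n_subjects: int,
    config: GeneratorConfig | None = None,
    n_site_b: int = 0,
    site_b_noise_scale: float = 1.0,
) -> list[SubjectData]:
    """Generate a cohort of paired sessions (default conditions, seeded).

    The last ``n_site_b`` subjects are assigned to recording site B with an
    optionally distinct stationary noise floor, mirroring a two-site study.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or GeneratorConfig()
    master = np.random.SeedSequence(config.rng_seed)
    children = master.spawn(n_subjects)
    out = []
    for i in range(n_subjects):
        cfg = config
        if i >= n_subjects - n_site_b:
            from dataclasses import replace as _replace

            cfg = _replace(config, site="B", site_noise_scale=site_b_noise_scale)
        out.append(generate_subject(cfg, children[i], subject_id=f"S{i + 1:03d}"))
    return out


def iter_cohort(
    n_subjects: int,
    config: GeneratorConfig | None = None,
    n_site_b: int = 0,
    site_b_noise_scale: float = 1.0,
):
    """Lazily yield the same cohort as :func:`generate_cohort` (memory-friendly)."""
    config = config or GeneratorConfig()
    master = np.random.SeedSequence(config.rng_seed)
    children = master.spawn(n_subjects)
    for i in range(n_subjects):
        cfg = config
        if i >= n_subjects - n_site_b:
            from dataclasses import replace as _replace

            cfg = _replace(config, site="B", site_noise_scale=site_b_noise_scale)
        yield generate_subject(cfg, children[i], subject_id=f"S{i + 1:03d}")
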