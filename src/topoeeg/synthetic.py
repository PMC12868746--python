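"""Synthetic multi-channel EEG cohorts with controllable band structure.

Generates labelled patient/control recordings as sums of amplitude-modulated
band-centre oscillations plus band-limited and broadband noise, together with
PANSS-like clinical scores planted as a linear function of each subject's
Theta amplitude.  Every downstream stage of the package (band decomposition,
delay embedding, persistence images, forecasting, clinical correlation) is
testable end-to-end on these cohorts without any external data.

The generator is not a biophysical EEG model: there is no volume conduction,
no dipole forward model and no artifact simulation.  What it does guarantee
is (i) band-localized spectral power at configurable amplitudes, (ii) a class
contrast expressed as per-band amplitude shifts, and (iii) a clinical score
whose linear dependence on a signal property is known exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "BAND_NAMES",
    "BAND_EDGES",
    "BAND_CENTRES",
    "EEGRecording",
    "ClinicalScores",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "generate_cohort",
    "plant_clinical_relation",
    "substream_rng",
]

#: Canonical five-band decomposition used throughout the package (Hz).
BAND_NAMES = ("Delta", "Theta", "Alpha", "Beta", "Gamma")
BAND_EDGES = {
    "Delta": (1.0, 3.0),
    "Theta": (4.0, 7.0),
    "Alpha": (8.0, 12.0),
    "Beta": (13.0, 30.0),
    "Gamma": (31.0, 49.0),
}
#: Carrier frequency for each band's oscillatory component (band midpoint).
BAND_CENTRES = {name: 0.5 * (lo + hi) for name, (lo, hi) in BAND_EDGES.items()}


def substream_rng(seed: int, *labels: str | int) -> np.random.Generator:
    """Derive an independent, reproducible RNG substream from a global seed.

    Labels are hashed (CRC-32) so that every named stage of a run draws from
    its own stream; the same (seed, labels) always yields the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            entropy.append(zlib.crc32(lab.encode()) & 0x7FFFFFFF)
        else:
            entropy.append(int(lab) & 0x7FFFFFFF)
    return np.random.default_rng(entropy)


@dataclass
class EEGRecording:
    """A multi-channel EEG recording.

    data is a float array of shape (n_channels, n_samples) in microvolt-scale
    arbitrary units; fs is the sampling rate in Hz; label is one of
    "patient", "control" or "unknown".
    """

    subject_id: str
    data: np.ndarray
    fs: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ClinicalScores:
    """PANSS-like severity scores for one patient-class subject."""

    subject_id: str
    panss_total: float
    panss_positive: float
    panss_negative: float


@dataclass
class SyntheticCohortConfig:
    """Conditions under which a synthetic cohort is generated.

    band_amp_means are per-band oscillation amplitudes (arbitrary microvolt
    scale) with a roughly 1/f profile; band_effect_sizes are relative
    patient-class amplitude shifts (0.4 means patients' band amplitude mean is
    40% above controls').  The default contrast lives in Theta and Gamma, the
    bands that carry the clinical signal in this model family.
    clinical_slope maps a subject's Theta amplitude onto the PANSS total
    score; clinical_noise_sd is the score noise around that line.
    """

    n_subjects_per_class: int = 10
    duration_s: float = 160.0
    fs: float = 250.0
    n_channels: int = 8
    band_amp_means: dict[str, float] = field(
        default_factory=lambda: {
            "Delta": 20.0, "Theta": 10.0, "Alpha": 15.0, "Beta": 5.0, "Gamma": 3.0,
        }
    )
    band_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "Delta": 0.0, "Theta": 0.4, "Alpha": 0.0, "Beta": 0.0, "Gamma": 0.4,
        }
    )
    amp_jitter_sd: float = 0.2
    noise_sd: float = 2.0
    clinical_intercept: float = 60.0
    clinical_slope: float = 1.5
    clinical_noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for name in BAND_NAMES:
            if name not in self.band_amp_means or name not in self.band_effect_sizes:
                raise ValueError(f"missing band entry: {name}")
            if not np.isfinite(self.band_effect_sizes[name]):
                raise ValueError("effect sizes must be finite")
        if self.noise_sd < 0 or self.amp_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SyntheticSubject:
    """One generated subject: recording, drawn band amplitudes, scores."""

    recording: EEGRecording
    band_amplitudes: dict[str, float]
    scores: ClinicalScores | None = None


def _band_component(rng: np.random.Generator, amp: float, band: str,
                    n_channels: int, t: np.ndarray, fs: float) -> np.ndarray:
    """Amplitude-modulated carrier at the band centre plus band-passed noise."""
    lo, hi = BAND_EDGES[band]
    fc = BAND_CENTRES[band]
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    am_phase = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    am_freq = rng.uniform(0.1, 0.4)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * am_freq * t + am_phase)
    carrier = amp * envelope * np.sin(2 * np.pi * fc * t + phases)
    # Band-limited stochastic component at half the carrier RMS.
    white = rng.standard_normal((n_channels, t.shape[-1]))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    coloured = sps.sosfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(coloured**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    coloured = coloured / rms * (0.5 * amp / np.sqrt(2.0))
    return carrier + coloured


def _synthesize_subject(cfg: SyntheticCohortConfig, subject_id: str,
                        label: str, rng: np.random.Generator) -> SyntheticSubject:
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    data = np.zeros((cfg.n_channels, n))
    amps: dict[str, float] = {}
    is_patient = label == "patient"
    for band in BAND_NAMES:
        mean_amp = cfg.band_amp_means[band]
        if is_patient:
            mean_amp *= 1.0 + cfg.band_effect_sizes[band]
        # Log-normal between-subject amplitude variation keeps amplitudes
        # positive and gives the clinical regression a non-degenerate
        # predictor even at zero effect size.
        amp = mean_amp * np.exp(rng.normal(0.0, cfg.amp_jitter_sd))
        amps[band] = float(amp)
        if amp > 0:
            data += _band_component(rng, amp, band, cfg.n_channels, t, cfg.fs)
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape)
    rec = EEGRecording(subject_id=subject_id, data=data, fs=cfg.fs, label=label)
    return SyntheticSubject(recording=rec, band_amplitudes=amps)


def generate_cohort(cfg: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """Generate a two-class cohort; patients carry planted clinical scores.

    The output is fully determined by ``cfg`` (including ``cfg.seed``):
    each subject draws from a named RNG substream, so cohorts are
    bit-identical across runs and insensitive to generation order.
    """
    cfg.validate()
    subjects: list[SyntheticSubject] = []
    for cls, label in (("pat", "patient"), ("ctl", "control")):
        for i in range(cfg.n_subjects_per_class):
            sid = f"{cls}{i:03d}"
            rng = substream_rng(cfg.seed, "subject", sid)
            subjects.append(_synthesize_subject(cfg, sid, label, rng))
    patients = [s for s in subjects if s.recording.label == "patient"]
    scores = plant_clinical_relation(
        patients,
        slope=cfg.clinical_slope,
        noise_sd=cfg.clinical_noise_sd,
        seed=cfg.seed,
        intercept=cfg.clinical_intercept,
    )
    by_id = {sc.subject_id: sc for sc in scores}
    for s in patients:
        s.scores = by_id[s.recording.subject_id]
    return subjects


def plant_clinical_relation(cohort: list[SyntheticSubject], slope: float,
                            noise_sd: float, seed: int,
                            intercept: float = 60.0) -> list[ClinicalScores]:
    """Plant PANSS-like scores linearly related to Theta amplitude.

    For every patient-class subject: total = intercept + slope * Theta
    amplitude + N(0, noise_sd).  Positive/negative subscale scores are fixed
    fractions of the total with their own noise.  With noise_sd = 0 and
    nonzero slope the total score is an exact affine function of the planted
    Theta amplitude; with slope = 0 it is independent of the signal.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    out: list[ClinicalScores] = []
    for s in cohort:
        if s.recording.label != "patient":
            continue
        rng = substream_rng(seed, "clinical", s.recording.subject_id)
        theta = s.band_amplitudes["Theta"]
        total = intercept + slope * theta + rng.normal(0.0, noise_sd)
        positive = 0.28 * total + rng.normal(0.0, 0.3 * noise_sd)
        negative = 0.23 * total + rng.normal(0.0, 0.3 * noise_sd)
        out.append(ClinicalScores(s.recording.subject_id, float(total),
                                  float(positive), float(negative)))
    return out


def null_cohort_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """A cohort with identical class distributions (all effect sizes zero)."""
    cfg = SyntheticCohortConfig(seed=seed, **overrides)
    return replace(cfg, band_effect_sizes={b: 0.0 for b in BAND_NAMES})


def drifting_blob_sequences(n_sequences: int, n_frames: int, resolution: int,
                            noise_sd: float = 0.35, n_positions: int = 4,
                            width: float = 2.5,
                            seed: int = 0) -> dict[tuple[str, str], np.ndarray]:
    """Image sequences with planted spatial and temporal structure.

    Each frame is a Gaussian blob at one of ``n_positions`` equispaced
    horizontal stations on an R x R grid, buried under heavy independent
    pixel noise and clipped to [0, 1]; the blob advances one station per
    frame (wrapping around).  The clean next frame is thus a deterministic
    nonlinear function of a single global, noise-buried property of the
    current frame — which station the blob occupies.  Recovering that
    station rewards local spatial aggregation (the per-pixel signal-to-noise
    ratio is low, but the blob is smooth, so neighbourhood averaging helps)
    followed by a global nonlinear readout (render the *next* station);
    purely pointwise models cannot express the re-rendering, and purely
    sequential models must integrate raw noisy pixels.  Returned in
    ``make_pairs`` sequence format: {(sequence_id, "synthetic"): (T, R, R)}.
    """
    rng = substream_rng(seed, "blob")
    yy, xx = np.mgrid[0:resolution, 0:resolution]
    row = resolution / 2.0
    step = resolution // n_positions
    out: dict[tuple[str, str], np.ndarray] = {}
    for s in range(n_sequences):
        k0 = int(rng.integers(n_positions))
        frames = np.empty((n_frames, resolution, resolution))
        for t in range(n_frames):
            c = ((k0 + t) % n_positions) * step
            # Wrap-aware horizontal distance keeps the blob continuous.
            dx = np.minimum(np.abs(xx - c), resolution - np.abs(xx - c))
            clean = np.exp(-(dx**2 + (yy - row) ** 2) / (2 * width**2))
            noisy = clean + noise_sd * rng.standard_normal(clean.shape)
            frames[t] = np.clip(noisy, 0.0, 1.0)
        out[(f"seq{s:03d}", "synthetic")] = frames
    return out
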