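"""Stage-labelled synthetic polysomnography.

The generator emulates the features an epoch classifier relies on —
stage-conditioned EEG spectral content (alpha in wake, theta in N1/REM,
spindle-band bursts in N2, high-amplitude delta in N3), chin-EMG tone that
collapses in REM, and EOG deflection events — plus the between-database
variability sources the multi-site validation needs: per-site gain,
additive noise level, small spectral shifts, mains interference, and
optional ECG contamination mirrored into a clean reference channel.

It makes no claim of physiological realism (no K-complexes, arousals or
microstructure); it exists so the full pipeline is testable without
clinical recordings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sig

from .model import RecordingPatterns
from .preprocess import FilterSettings, patterns_to_arrays, preprocess_recording
from .psg_io import (
    AASM_STAGES,
    Channel,
    Hypnogram,
    Recording,
    ValidationError,
    write_edf,
    write_hypnogram_text,
)

EPOCH_SECONDS = 30


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Band:
    """Band-limited noise component: [lo, hi] Hz at a target RMS (uV).

    ``burst`` components are amplitude-modulated into ~1 s events (sleep
    spindles) instead of being continuously present.
    """

    lo: float
    hi: float
    rms: float
    burst: bool = False


@dataclasses.dataclass
class StageRecipe:
    """Spectral recipe of one sleep stage."""

    eeg_bands: list[Band]
    emg_rms: float  # chin tone, uV
    eog_rate: float  # deflection events per minute
    eog_amp: float  # deflection amplitude, uV


#: Default per-stage recipes.  Amplitudes are in the uV range of scalp
#: signals; the stage contrasts (alpha/theta/delta balance, EMG atonia in
#: REM, eye-movement density) are deliberately strong so that the stages
#: are well separable by a spectral classifier.
DEFAULT_RECIPES: dict[str, StageRecipe] = {
    "W": StageRecipe(
        eeg_bands=[Band(8, 12, 30.0), Band(1, 30, 6.0)],
        emg_rms=30.0, eog_rate=12.0, eog_amp=80.0,
    ),
    "N1": StageRecipe(
        eeg_bands=[Band(4, 7, 25.0), Band(1, 30, 6.0)],
        emg_rms=15.0, eog_rate=4.0, eog_amp=50.0,
    ),
    "N2": StageRecipe(
        eeg_bands=[Band(4, 7, 18.0), Band(12, 14, 22.0, burst=True), Band(1, 30, 6.0)],
        emg_rms=10.0, eog_rate=0.5, eog_amp=40.0,
    ),
    "N3": StageRecipe(
        eeg_bands=[Band(0.5, 2, 90.0), Band(1, 30, 6.0)],
        emg_rms=8.0, eog_rate=0.0, eog_amp=0.0,
    ),
    "R": StageRecipe(
        eeg_bands=[Band(4, 7, 25.0), Band(1, 30, 7.0)],
        emg_rms=2.0, eog_rate=18.0, eog_amp=90.0,
    ),
}

#: First-order Markov stage dynamics with sticky bouts (self-transition
#: 0.85, mean bout ~3.3 min) cycling through the physiological order
#: W -> N1 -> N2 -> {N3 -> N2, R}, wake-ups from N3/R.  Row order
#: W, N1, N2, N3, R; stationary distribution roughly (.07,.14,.42,.19,.18).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.85, 0.14, 0.01, 0.00, 0.00],
        [0.01, 0.85, 0.13, 0.00, 0.01],
        [0.01, 0.01, 0.85, 0.07, 0.06],
        [0.01, 0.00, 0.14, 0.85, 0.00],
        [0.02, 0.04, 0.09, 0.00, 0.85],
    ]
)

#: Transition matrix used by the short multi-site benchmark recordings:
#: dwell times scaled down (self-transition 0.70, ~18 bouts per 60-epoch
#: recording) and doubly stochastic (uniform stationary distribution), so
#: every recording covers all five stages with ~12 epochs each -- the
#: stage coverage an overnight recording has, compressed to desk scale.
#: Bouts cycle through the physiological order W->N1->N2->N3->R->W.
BENCHMARK_TRANSITIONS = 0.70 * np.eye(5) + 0.30 * np.roll(np.eye(5), 1, axis=1)


@dataclasses.dataclass
class SiteConfig:
    """Site-specific acquisition characteristics ("one database")."""

    name: str = "site"
    fs: int = 128  # acquisition rate, Hz (>= 100)
    gain: float = 1.0  # amplification multiplier
    noise_sd: float = 2.0  # additive broadband noise, uV
    mains_hz: int = 50
    mains_amplitude: float = 0.0  # uV; 0 disables interference
    ecg_contamination: bool = False
    band_shift_hz: float = 0.0  # shifts every EEG band edge
    emg_scale: float = 1.0  # scales chin tone across all stages

    def __post_init__(self):
        if self.fs < 100:
            raise ValidationError("site fs must be >= 100 Hz")
        if self.mains_hz not in (50, 60):
            raise ValidationError("mains_hz must be 50 or 60")


@dataclasses.dataclass
class SimConfig:
    n_recordings: int = 3
    epochs_per_recording: int = 60
    site: SiteConfig = dataclasses.field(default_factory=SiteConfig)
    transition_matrix: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    recipes: dict[str, StageRecipe] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RECIPES)
    )
    seed: int = 0


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

def _check_transitions(tm: np.ndarray) -> np.ndarray:
    tm = np.asarray(tm, dtype=np.float64)
    if tm.shape != (5, 5) or (tm < 0).any():
        raise ValidationError("transition matrix must be 5x5 non-negative")
    if np.abs(tm.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValidationError("transition matrix rows must sum to 1")
    return tm


def simulate_hypnogram(
    n_epochs: int, transition_matrix: Optional[np.ndarray] = None, seed: int = 0
) -> Hypnogram:
    """First-order Markov chain over (W, N1, N2, N3, R), starting in W."""
    tm = _check_transitions(
        DEFAULT_TRANSITIONS if transition_matrix is None else transition_matrix
    )
    rng = np.random.default_rng(seed)
    state = 0
    stages = []
    for _ in range(n_epochs):
        stages.append(AASM_STAGES[state])
        state = int(rng.choice(5, p=tm[state]))
    return Hypnogram(stages=stages)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _band_noise(rng, n, fs, lo, hi, rms):
    """Butterworth-filtered white noise scaled to a target RMS."""
    hi = min(hi, 0.49 * fs)
    lo = max(lo, 0.01)
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfilt(sos, rng.standard_normal(n))
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def _burst_envelope(rng, n, fs, n_bursts=4, width_s=1.0):
    env = np.zeros(n)
    w = int(width_s * fs)
    win = np.hanning(w)
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n - w))
        env[start : start + w] += win[: n - start]
    return np.clip(env, 0, 1)


def _eog_events(rng, n, fs, rate_per_min, amp):
    """Slow biphasic deflections (derivative-of-Gaussian waveform)."""
    x = np.zeros(n)
    n_events = rng.poisson(rate_per_min * (n / fs) / 60.0)
    w = int(0.8 * fs)
    t = np.linspace(-2.5, 2.5, w)
    shape = -t * np.exp(-(t**2) / 2)
    shape /= np.abs(shape).max()
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n - w)))
        x[start : start + w] += rng.choice([-1.0, 1.0]) * amp * shape[: n - start]
    return x


def _ecg_train(rng, n, fs, bpm=60.0, amp=400.0, tau=0.02):
    """Periodic two-sided exponential spikes at ~bpm with timing jitter."""
    x = np.zeros(n)
    w = int(0.12 * fs)
    t = (np.arange(2 * w + 1) - w) / fs
    spike = amp * np.exp(-np.abs(t) / tau)
    period = 60.0 / bpm
    tt = 0.5 * period
    while tt < n / fs:
        c = int(tt * fs)
        lo, hi = max(0, c - w), min(n, c + w + 1)
        x[lo:hi] += spike[lo - (c - w) : lo - (c - w) + (hi - lo)]
        tt += period * (1.0 + 0.05 * rng.standard_normal())
    return x


def simulate_epoch(
    stage: str,
    site: SiteConfig,
    rng: np.random.Generator,
    recipes: Optional[dict[str, StageRecipe]] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """One 30 s epoch: rows (EEG1, EEG2, EMG, EOG) at ``site.fs``.

    Returns (signals, clean_ecg_reference or None).  Site gain, broadband
    noise, mains interference and ECG contamination are already applied to
    the signal rows; the reference row is the uncontaminated ECG.
    """
    recipes = recipes or DEFAULT_RECIPES
    if stage not in recipes:
        raise ValidationError(f"unknown stage {stage!r}")
    rec = recipes[stage]
    fs, n = site.fs, site.fs * EPOCH_SECONDS

    def eeg_row():
        row = np.zeros(n)
        for band in rec.eeg_bands:
            lo = band.lo + site.band_shift_hz
            hi = band.hi + site.band_shift_hz
            comp = _band_noise(rng, n, fs, lo, hi, band.rms)
            if band.burst:
                comp = comp * _burst_envelope(rng, n, fs)
                cur = np.sqrt(np.mean(comp**2))
                if cur > 0:
                    comp *= band.rms / cur
            row += comp
        return row

    eeg1, eeg2 = eeg_row(), eeg_row()
    emg = _band_noise(rng, n, fs, 20.0, 0.45 * fs, rec.emg_rms * site.emg_scale)
    eog = _band_noise(rng, n, fs, 0.3, 1.5, 8.0) + _eog_events(
        rng, n, fs, rec.eog_rate, rec.eog_amp
    )
    sig = np.stack([eeg1, eeg2, emg, eog])

    ecg = None
    if site.ecg_contamination:
        ecg = _ecg_train(rng, n, fs)
        sig += np.outer([0.15, 0.15, 0.10, 0.12], ecg)
    if site.mains_amplitude > 0:
        t = np.arange(n) / fs
        mains = site.mains_amplitude * np.sin(2 * np.pi * site.mains_hz * t)
        sig += mains[None, :]
    sig += site.noise_sd * rng.standard_normal(sig.shape)
    sig *= site.gain
    return sig, ecg


def simulate_recording(
    cfg: SimConfig, index: int = 0
) -> tuple[Recording, Hypnogram]:
    """One full synthetic recording (5 channels when ECG is simulated)."""
    ss = np.random.SeedSequence([cfg.seed, index])
    hyp_seed, sig_seed = ss.spawn(2)
    hyp = simulate_hypnogram(
        cfg.epochs_per_recording,
        cfg.transition_matrix,
        seed=int(hyp_seed.generate_state(1)[0]) % (2**31),
    )
    rng = np.random.default_rng(sig_seed)
    site = cfg.site
    chunks, ecg_chunks = [], []
    for stage in hyp.stages:
        sig, ecg = simulate_epoch(stage, site, rng, cfg.recipes)
        chunks.append(sig)
        if ecg is not None:
            ecg_chunks.append(ecg)
    full = np.concatenate(chunks, axis=1)
    labels = ["EEG C4-M1", "EEG C3-M2", "EMG Chin", "EOG E1-M2"]
    channels = [
        Channel(lab, site.fs, "uV", full[i]) for i, lab in enumerate(labels)
    ]
    if ecg_chunks:
        channels.append(Channel("ECG", site.fs, "uV", np.concatenate(ecg_chunks)))
    rec_id = f"{site.name}-{index:02d}"
    return Recording(id=rec_id, channels=channels), hyp


def simulate_site_dataset(cfg: SimConfig, out_dir) -> list[tuple[Path, Path]]:
    """Write ``n_recordings`` EDF+ files plus stage-per-line text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(cfg.n_recordings):
        rec, hyp = simulate_recording(cfg, i)
        edf_path = out / f"{rec.id}.edf"
        txt_path = out / f"{rec.id}_stages.txt"
        write_edf(rec, hyp, edf_path)
        write_hypnogram_text(hyp, txt_path)
        paths.append((edf_path, txt_path))
    return paths


# ---------------------------------------------------------------------------
# In-memory multi-site benchmark
# ---------------------------------------------------------------------------

#: Site perturbations used by the multi-site generalization benchmark:
#: different acquisition rates, gains, noise floors, small spectral shifts
#: and EMG tone scalings, emulating three independent sleep labs.
BENCHMARK_SITES = (
    SiteConfig(name="siteA", fs=128, gain=1.0, noise_sd=2.0, band_shift_hz=0.0,
               emg_scale=1.0),
    SiteConfig(name="siteB", fs=100, gain=0.6, noise_sd=5.0, band_shift_hz=1.0,
               emg_scale=0.7),
    SiteConfig(name="siteC", fs=120, gain=1.6, noise_sd=3.5, band_shift_hz=-0.8,
               emg_scale=1.3),
)


def site_patterns(
    cfg: SimConfig, filters: Optional[FilterSettings] = None
) -> list[RecordingPatterns]:
    """Simulate a site and run every recording through preprocessing."""
    out = []
    for i in range(cfg.n_recordings):
        rec, hyp = simulate_recording(cfg, i)
        patterns = preprocess_recording(rec, hyp, filters=filters)
        values, stage_labels = patterns_to_arrays(patterns)
        out.append(RecordingPatterns(rec.id, values, stage_labels))
    return out


def make_benchmark_sites(
    n_recordings: int = 3,
    epochs_per_recording: int = 60,
    seed: int = 0,
    sites: Sequence[SiteConfig] = BENCHMARK_SITES,
    filters: Optional[FilterSettings] = None,
) -> dict[str, list[RecordingPatterns]]:
    """Preprocessed multi-site benchmark data, keyed by site name."""
    out = {}
    for si, site in enumerate(sites):
        cfg = SimConfig(
            n_recordings=n_recordings,
            epochs_per_recording=epochs_per_recording,
            site=site,
            transition_matrix=BENCHMARK_TRANSITIONS.copy(),
            seed=(seed * 1000003 + si) % (2**31),
        )
        out[site.name] = site_patterns(cfg, filters=filters)
    return out
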