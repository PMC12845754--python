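"""Synthetic multi-subject EEG with planted discriminative channels.

The generator emulates the structure of a motor-imagery protocol: each
subject contributes ``runs_per_subject`` continuous runs (the first two
resting, the rest alternating motor execution / motor imagery).  Every
channel carries 1/f-plus-white background noise; a small per-subject set of
*planted* channels additionally carries a narrow-band (alpha-range)
sinusoid whose frequency and amplitude are subject-specific and whose
amplitude is modulated by the task.  Because the planted set and
frequencies differ across subjects, the planted channels are the ground
truth that any electrode-selection method should recover, and a simple
band-power contrast (:func:`bandpower_ranking`) serves as the reference
oracle for that recovery.

The whole dataset is a pure function of :class:`SyntheticConfig` (every run
is seeded from ``(config.seed, subject_id, run_index)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .data import Run, TASKS, task_for_run_index

__all__ = [
    "SubjectSignature",
    "SyntheticConfig",
    "make_signature",
    "synthesize_run",
    "generate_dataset",
    "bandpower_ranking",
    "save_runs",
    "load_runs",
]

#: Default amplitude factor applied to the planted sinusoid per task.
DEFAULT_TASK_MODULATION = {
    "rest": 0.3,
    "motor_execution": 1.0,
    "motor_imagery": 0.7,
}


@dataclass(frozen=True)
class SubjectSignature:
    """The planted, subject-specific spectral identity of one subject."""

    subject_id: int
    planted_channels: tuple  # 0-based channel indices, sorted
    peak_freq_hz: tuple  # one alpha-band frequency per planted channel
    peak_amp: float  # unitless multiplier on the planted amplitude
    task_modulation: dict  # task -> amplitude factor


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects: int = 8
    n_channels: int = 64
    fs: float = 160.0
    runs_per_subject: int = 14
    run_duration_s: float = 30.0
    n_planted: int = 4
    snr: float = 5.0  # linear signal-to-noise power ratio at modulation 1.0
    seed: int = 0
    task_modulation: dict = field(default_factory=lambda: dict(DEFAULT_TASK_MODULATION))

    def __post_init__(self):
        if min(self.n_subjects, self.n_channels, self.runs_per_subject) < 1:
            raise ValueError("all counts must be positive")
        if self.n_planted > self.n_channels:
            raise ValueError(
                f"n_planted={self.n_planted} exceeds n_channels={self.n_channels}"
            )
        n = self.fs * self.run_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * run_duration_s must be an integer sample count")

    @property
    def samples_per_run(self) -> int:
        return int(round(self.fs * self.run_duration_s))


def make_signature(
    subject_id: int, config: SyntheticConfig, seed: int | None = None
) -> SubjectSignature:
    """Draw a subject's planted channels and alpha-band peak frequencies.

    The RNG is seeded by ``(seed or config.seed, subject_id)``, so the same
    call always yields the same signature and distinct subjects draw from
    distinct streams.  Planted channels are sampled without replacement;
    peak frequencies are uniform in the 7-13 Hz alpha band, well below the
    Nyquist frequency at 160 Hz.
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base, subject_id]))
    channels = tuple(
        sorted(rng.choice(config.n_channels, size=config.n_planted, replace=False).tolist())
    )
    freqs = tuple(rng.uniform(7.0, 13.0, size=config.n_planted).tolist())
    amp = float(rng.uniform(0.8, 1.25))
    return SubjectSignature(
        subject_id=subject_id,
        planted_channels=channels,
        peak_freq_hz=freqs,
        peak_amp=amp,
        task_modulation=dict(config.task_modulation),
    )


def _pink_plus_white(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """Unit-power noise: pink (1/f spectral shaping) + white, mixed 1:1."""
    white = rng.standard_normal((n_channels, n))
    base = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(base, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])  # amplitude ~ f^-1/2 => power ~ 1/f
    scale[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    mixed = (pink + white) / np.sqrt(2.0)
    return mixed


def synthesize_run(
    signature: SubjectSignature,
    task: str,
    run_index: int,
    config: SyntheticConfig,
) -> Run:
    """Generate one run: background noise everywhere, planted sinusoids.

    Planted channel ``c`` receives a sinusoid at its signature frequency
    with a random phase per run, scaled so that at task modulation 1.0 and
    ``peak_amp`` 1.0 the sinusoid-to-noise power ratio equals
    ``config.snr``.  Non-planted channels are noise only.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task label {task!r}; expected one of {TASKS}")
    n = config.samples_per_run
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, signature.subject_id, run_index])
    )
    data = _pink_plus_white(rng, config.n_channels, n)
    t = np.arange(n) / config.fs
    mod = signature.task_modulation[task]
    amp = np.sqrt(2.0 * config.snr) * signature.peak_amp * mod
    for ch, f in zip(signature.planted_channels, signature.peak_freq_hz):
        phase = rng.uniform(0, 2 * np.pi)
        data[ch] += amp * np.sin(2 * np.pi * f * t + phase)
    return Run(
        subject_id=signature.subject_id,
        run_index=run_index,
        task=task,
        data=data,
        fs=config.fs,
    )


def generate_dataset(config: SyntheticConfig) -> list[Run]:
    """All runs for all subjects: runs 1-2 rest, then execution/imagery."""
    runs = []
    for s in range(config.n_subjects):
        sig = make_signature(s, config)
        for r in range(1, config.runs_per_subject + 1):
            runs.append(synthesize_run(sig, task_for_run_index(r), r, config))
    return runs


# --------------------------------------------------------------------- oracle
def bandpower_ranking(
    runs: list[Run],
    subject_id: int,
    band: tuple[float, float] = (7.0, 13.0),
) -> np.ndarray:
    """Reference channel ranking from a subject-vs-rest band-power contrast.

    For every channel, the mean Welch power in ``band`` is computed per
    subject; channels are ranked by how far the target subject's power
    exceeds the across-subject mean, in units of the across-subject
    standard deviation.  This exploits exactly the between-subject
    variability the planted signatures create, and is the oracle that
    learned electrode selection is compared against.

    Returns channel indices sorted by descending score.
    """
    subjects = sorted({r.subject_id for r in runs})
    if subject_id not in subjects:
        raise ValueError(f"subject {subject_id} not present")
    if len(subjects) < 2:
        raise ValueError("contrast needs >= 2 subjects")
    power = {}
    for s in subjects:
        mats = [r for r in runs if r.subject_id == s]
        per_run = []
        for r in mats:
            f, pxx = sps.welch(r.data, fs=r.fs, nperseg=min(512, r.n_samples), axis=1)
            sel = (f >= band[0]) & (f <= band[1])
            per_run.append(pxx[:, sel].mean(axis=1))
        power[s] = np.mean(per_run, axis=0)
    mat = np.stack([power[s] for s in subjects])  # subjects x channels
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0) + 1e-12
    score = (power[subject_id] - mu) / sd
    return np.argsort(-score, kind="stable")


# ---------------------------------------------------------------- persistence
def save_runs(runs: list[Run], out_dir) -> Path:
    """Persist runs as one .npy matrix each plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for r in runs:
        name = f"S{r.subject_id:03d}R{r.run_index:02d}.npy"
        np.save(out / name, r.data)
        manifest.append(
            {
                "file": name,
                "subject_id": r.subject_id,
                "run_index": r.run_index,
                "task": r.task,
                "fs": r.fs,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_runs(in_dir) -> list[Run]:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    return [
        Run(
            subject_id=m["subject_id"],
            run_index=m["run_index"],
            task=m["task"],
            data=np.load(src / m["file"]),
            fs=m["fs"],
        )
        for m in manifest
    ]
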