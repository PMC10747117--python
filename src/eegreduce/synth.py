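"""Synthetic multichannel EEG with planted focal seizure activity.

The generator emulates the statistical structure the pipeline assumes:
19-channel 10-20 scalp EEG at 500 Hz, split into interictal and ictal
segments.  Interictal background is 1/f-coloured Gaussian noise per channel.
Ictal segments add a high-amplitude rhythmic spike-wave component — a
low-frequency oscillation (default 3 Hz) with decaying harmonics giving
sharp periodic deflections — on a configurable subset of "focal" channels
only.  Non-focal channels are drawn from exactly the same distribution in
both classes, so any information the classifier finds on them is spurious
by construction.

Two sources of realistic variability keep the task from being trivially
separable on a single electrode: the discharge amplitude on each focal
channel is re-drawn every second and occasionally drops to near-quiescence
(seizure involvement of any one electrode waxes and wanes), and background
on every channel carries sporadic high-amplitude artifact transients at the
same rate in both classes (blink/movement-like bumps).  A classifier
therefore has to combine evidence across the focal channels, which is what
lets the recurrence selection recover the full planted set.

Every random draw comes from a dedicated substream spawned from the config
seed (per split, class, segment and channel), so output is bit-identical
under a fixed seed and the focal effect is exactly local.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .types import ICTAL, INTERICTAL, MONTAGE_19, DatasetSplit, Recording

log = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG generator.

    Defaults describe the reference study condition used throughout the test
    suite: 19 channels at 500 Hz, three planted focal channels, a 3 Hz
    spike-wave rhythm at five times the background amplitude.
    """

    channel_names: tuple[str, ...] = MONTAGE_19
    fs: float = 500.0
    train_seconds_per_class: float = 300.0
    test_seconds_per_class: float = 60.0
    record_seconds: float = 60.0  # one Recording per contiguous segment
    focal_channels: tuple[str, ...] = ("Fz", "C4", "T5")
    ictal_freq: float = 3.0  # Hz, spike-wave repetition rate
    amplitude_gain: float = 5.0  # ictal component std = (gain-1) x background std
    spike_sharpness: int = 4  # number of harmonics shaping the spike
    quiet_prob: float = 0.3  # chance a focal channel is near-quiescent in a 1-s block
    background_exponent: float = 1.0  # 1/f^beta power spectrum
    noise_scale: float = 20.0  # background std, microvolts
    artifact_prob: float = 0.05  # artifact transients per channel per second
    artifact_amp: float = 4.0  # artifact peak, multiples of background std
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.focal_channels = tuple(self.focal_channels)
        unknown = set(self.focal_channels) - set(self.channel_names)
        if unknown:
            raise ValueError(f"focal channels not in montage: {sorted(unknown)}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.focal_channels and self.amplitude_gain != 1.0:
            log.warning(
                "amplitude_gain=%.3g with an empty focal set: the ictal class "
                "will be indistinguishable from background",
                self.amplitude_gain,
            )


def ground_truth(config: SynthConfig) -> frozenset[str]:
    """The planted focal channel set, for recovery tests."""
    return frozenset(config.focal_channels)


def _colored_noise(rng: np.random.Generator, n: int, beta: float, scale: float) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum and std ``scale``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-beta / 2.0)
    gain[0] = 0.0  # remove DC so segments are mean-free
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _spike_wave(
    rng: np.random.Generator, n: int, fs: float, freq: float, harmonics: int
) -> np.ndarray:
    """Unit-std rhythmic spike-wave: harmonic stack with 1/h decay and a
    random phase, sharpening the oscillation into periodic spikes."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    w = np.zeros(n)
    for h in range(1, max(1, harmonics) + 1):
        w += np.sin(2 * np.pi * h * freq * t + h * phase) / h
    sd = w.std()
    return w / sd if sd > 0 else w


def _artifacts(
    rng: np.random.Generator, n: int, fs: float, prob: float, amp_sd: float
) -> np.ndarray:
    """Sporadic blink/movement-like transients: raised-cosine bumps of
    ~0.2-0.4 s with random sign and peak amplitude, at ``prob`` per second."""
    out = np.zeros(n)
    block = int(round(fs))
    for start in range(0, n, block):
        if rng.uniform() >= prob:
            continue
        width = int(rng.uniform(0.2, 0.4) * fs)
        pos = start + rng.integers(0, max(1, block - width))
        if pos + width > n:
            continue
        bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        sign = rng.choice((-1.0, 1.0))
        out[pos : pos + width] += sign * rng.uniform(0.6, 1.0) * amp_sd * bump
    return out


def _block_envelope(
    rng: np.random.Generator, n: int, fs: float, quiet_prob: float
) -> np.ndarray:
    """Per-second discharge amplitude on one focal channel: usually
    U(0.5, 1.5), but near-quiescent (U(0, 0.2)) with probability
    ``quiet_prob`` — electrode involvement waxes and wanes."""
    block = int(round(fs))
    n_blocks = math.ceil(n / block)
    env = rng.uniform(0.5, 1.5, size=n_blocks)
    quiet = rng.uniform(size=n_blocks) < quiet_prob
    env[quiet] = rng.uniform(0.0, 0.2, size=int(quiet.sum()))
    return np.repeat(env, block)[:n]


def _make_recording(
    config: SynthConfig,
    seconds: float,
    label: str,
    seed_seq: np.random.SeedSequence,
    source_id: str,
) -> Recording:
    n = int(round(seconds * config.fs))
    n_chan = len(config.channel_names)
    # one substream per channel plus one for the ictal component
    children = seed_seq.spawn(n_chan + 1)
    data = np.empty((n_chan, n))
    for ci, child in enumerate(children[:n_chan]):
        rng = np.random.default_rng(child)
        data[ci] = _colored_noise(rng, n, config.background_exponent, config.noise_scale)
        if config.artifact_prob > 0:
            data[ci] += _artifacts(
                rng, n, config.fs, config.artifact_prob,
                config.artifact_amp * config.noise_scale,
            )
    if label != INTERICTAL and config.focal_channels and config.amplitude_gain != 1.0:
        ictal_rng = np.random.default_rng(children[-1])
        effect_sd = (config.amplitude_gain - 1.0) * config.noise_scale
        for chan in config.focal_channels:
            ci = config.channel_names.index(chan)
            wave = _spike_wave(
                ictal_rng, n, config.fs, config.ictal_freq, config.spike_sharpness
            )
            env = _block_envelope(ictal_rng, n, config.fs, config.quiet_prob)
            data[ci] += effect_sd * wave * env
    return Recording(
        channel_names=config.channel_names,
        fs=config.fs,
        data=data,
        label=label,
        source_id=source_id,
    )


def generate(config: SynthConfig) -> DatasetSplit:
    """Generate a labelled train/test split under the config.

    Each class contributes ``*_seconds_per_class`` of signal, cut into
    contiguous segments of ``record_seconds`` (one :class:`Recording` each;
    a shorter final remainder segment is kept).  Train and test use disjoint
    random substreams.
    """
    root = np.random.SeedSequence(config.seed)
    split_seqs = dict(zip(("train", "test"), root.spawn(2)))
    split = DatasetSplit()
    for split_name, seconds in (
        ("train", config.train_seconds_per_class),
        ("test", config.test_seconds_per_class),
    ):
        class_seqs = dict(
            zip((INTERICTAL, ICTAL), split_seqs[split_name].spawn(2))
        )
        for label in (INTERICTAL, ICTAL):
            n_rec = max(1, math.ceil(seconds / config.record_seconds))
            rec_seqs = class_seqs[label].spawn(n_rec)
            remaining = seconds
            for i in range(n_rec):
                sec = min(config.record_seconds, remaining)
                if sec * config.fs < 2:
                    break
                rec = _make_recording(
                    config,
                    sec,
                    label,
                    rec_seqs[i],
                    source_id=f"synth:{split_name}:{label}:{i:02d}",
                )
                remaining -= sec
                getattr(split, split_name).append(rec)
    log.info(
        "synthetic split: %d train / %d test recordings, focal=%s gain=%.2g",
        len(split.train), len(split.test),
        list(config.focal_channels), config.amplitude_gain,
    )
    return split


def write_fixture_dataset(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a generated split in both supported on-disk formats.

    Writes the MAT layout (``dataset.mat``) and one CSV per recording, so
    both loaders can be exercised against the same ground truth.
    """
    from . import io as eio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    split = generate(config)
    paths: dict[str, Path] = {}
    paths["mat"] = eio.save_ubmc_dataset(split, out_dir / "dataset.mat")
    for split_name, recs in (("train", split.train), ("test", split.test)):
        for i, rec in enumerate(recs):
            key = f"csv_{split_name}_{rec.label}_{i:02d}"
            paths[key] = eio.save_delimited(
                rec, out_dir / f"{split_name}_{rec.label}_{i:02d}.csv"
            )
    return paths


def null_config(config: SynthConfig) -> SynthConfig:
    """The same condition with the ictal effect removed (gain 1)."""
    return replace(config, amplitude_gain=1.0)
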