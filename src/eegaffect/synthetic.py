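"""Synthetic DEAP-geometry EEG with class-conditional band structure.

The generator emulates the preprocessed DEAP release geometry — 32
participants x 40 trials x 32 channels x 8064 samples at 128 Hz (63 s) with
continuous ratings in [1, 9] on four affect scales — so that segmentation,
training and evaluation can be exercised without the licensed recordings.

Each trial's signal is a sum of band-limited oscillations (random-phase
sinusoid mixtures in the canonical delta/theta/alpha/beta/gamma bands), a
1/f "pink" background, and white sensor noise.  Affect classes are injected
as band-limited amplitude modulation: each rating label owns one band, and
trials whose rating binarizes positive carry a larger amplitude in that
band.  The labels are independent Bernoulli draws, and each signature band
is concentrated on its own group of channels (a coarse spatial topography),
so four per-label classifiers can each recover "their" effect.

The ``separability`` dial scales the between-class amplitude gap: 0 removes
all class structure (a null dataset), 1 is the default gap, larger values
widen it.  Per-band base amplitudes sit at the same order of magnitude
(tens of microvolts, configurable) so every label's signature has a
comparable signal-to-background ratio; gamma is kept at its realistically
small sub-microvolt scale and is deliberately not a default signature band.

What this generator does NOT emulate: volume conduction and electrode
geometry, non-stationarity and artifacts (blinks, EMG), inter-participant
variability, or any genuine neural correlate of affect.  Passing tests
show the pipeline recovers planted spectral structure — not that it would
reach any particular accuracy on real recordings.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import welch

from .dataio import (
    DEAP_RATING_ORDER,
    BinaryLabeling,
    Dataset,
    Trial,
    dataset_to_arrays,
    save_deap_participant,
)
from .errors import ValidationError

#: Canonical EEG band edges in Hz (gamma capped below the 64 Hz Nyquist).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Default label -> signature band.  Low-frequency bands carry the labels so
#: the class structure survives moderate temporal decimation.
DEFAULT_BAND_ASSIGNMENT: dict[str, str] = {
    "valence": "alpha",
    "arousal": "beta",
    "dominance": "theta",
    "liking": "delta",
}

#: Positive-class fractions after threshold-5 binarization (the published
#: DEAP class ratios: arousal 40-60, valence 47-53, dominance 35-65,
#: liking 7-93).
DEFAULT_LABEL_RATIOS: dict[str, float] = {
    "arousal": 0.60,
    "valence": 0.53,
    "dominance": 0.65,
    "liking": 0.93,
}

#: Per-band carrier amplitudes (microvolts RMS), equalized to the same order
#: of magnitude so each label's signature is comparably detectable.
DEFAULT_BASE_AMPLITUDES: dict[str, float] = {
    "delta": 30.0,
    "theta": 22.0,
    "alpha": 30.0,
    "beta": 80.0,
    "gamma": 1.5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset; the seed makes it a pure function."""

    n_participants: int = 32
    n_trials_per_participant: int = 40
    n_channels: int = 32
    sampling_rate: float = 128.0
    duration: float = 63.0
    label_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_RATIOS))
    band_assignment: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BAND_ASSIGNMENT))
    base_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_AMPLITUDES))
    signature_gain: float = 3.0  # positive-class amplitude multiplier at separability 1
    separability: float = 1.0
    topo_background: float = 0.1  # signature-band amplitude off its channel group
    pink_sigma: float = 8.0  # 1/f background RMS, microvolts
    white_sigma: float = 6.0  # sensor noise RMS, microvolts
    carrier: str = "noise"  # "noise" (dense random-phase spectrum) | "sinusoid"
    sinusoids_per_band: int = 6  # mixture size for the "sinusoid" carrier
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_trials_per_participant, self.n_channels) < 1:
            raise ValidationError("all counts must be positive")
        for name, r in self.label_ratios.items():
            if not (0.0 < r < 1.0):
                raise ValidationError(f"label ratio {name}={r} outside (0, 1)")
        n_samples = self.sampling_rate * self.duration
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValidationError(
                f"duration x sampling_rate = {n_samples} is not an integral sample count"
            )
        if self.separability < 0:
            raise ValidationError("separability must be >= 0")
        if self.carrier not in ("noise", "sinusoid"):
            raise ValidationError(f"carrier must be 'noise' or 'sinusoid', got {self.carrier!r}")
        for label, band in self.band_assignment.items():
            if band not in BANDS:
                raise ValidationError(f"unknown band {band!r} assigned to {label!r}")
            if label not in self.label_ratios:
                raise ValidationError(f"band assigned to unknown label {label!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def channel_group(self, band: str) -> np.ndarray:
        """The channel indices on which ``band``'s signature is concentrated."""
        sig_bands = sorted(set(self.band_assignment.values()),
                           key=lambda b: BANDS[b][0])
        if band not in sig_bands:
            return np.arange(self.n_channels)
        groups = np.array_split(np.arange(self.n_channels), len(sig_bands))
        return groups[sig_bands.index(band)]


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sigma: float) -> np.ndarray:
    """1/f-spectrum background, normalized to the requested per-channel RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]  # avoid the DC singularity
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= sigma / x.std(axis=1, keepdims=True)
    return x


def _sinusoid_carrier(rng: np.random.Generator, band: tuple[float, float], k: int,
                      n_channels: int, t: np.ndarray) -> np.ndarray:
    """Unit-RMS mixture of ``k`` random-phase sinusoids per channel in ``band``."""
    freqs = rng.uniform(band[0], band[1], size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, k))
    arg = 2.0 * np.pi * freqs[:, None] * t[None, :]  # (k, S)
    # cos(arg + phi) = cos(phi) cos(arg) - sin(phi) sin(arg): two small GEMMs
    carrier = np.cos(phases) @ np.cos(arg) - np.sin(phases) @ np.sin(arg)
    return carrier / np.sqrt(k / 2.0)


def _noise_carrier(rng: np.random.Generator, band: tuple[float, float],
                   n_channels: int, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS band-limited noise: a dense mixture of random-phase sinusoids.

    White noise is band-passed in the frequency domain, so every FFT bin in
    the band carries an independent random phase.  Unlike a small sinusoid
    mixture, consecutive windows of the same trial are statistically fresh:
    the only stable class cue is the band's amplitude, which is the contract
    the classifier is supposed to discover.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[:, ~((f >= band[0]) & (f < band[1]))] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate(spec: SyntheticSpec) -> Dataset:
    """Generate the dataset described by ``spec`` (bit-identical per seed)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.n_samples
    t = np.arange(s) / spec.sampling_rate
    band_of_label = dict(spec.band_assignment)
    label_of_band = {b: l for l, b in band_of_label.items()}
    labeling = BinaryLabeling()

    # per-band channel amplitude profile (before class modulation)
    topo = {}
    for band in BANDS:
        w = np.full(spec.n_channels, spec.topo_background
                    if band in label_of_band else 1.0)
        w[spec.channel_group(band)] = 1.0
        topo[band] = w

    trials = []
    label_names = list(spec.label_ratios)
    for p in range(spec.n_participants):
        pid = f"s{p + 1:02d}"
        for k in range(spec.n_trials_per_participant):
            # ratings: class first, then a rating on the matching side of 5
            ratings: dict[str, float] = {}
            for name in label_names:
                positive = rng.random() < spec.label_ratios[name]
                ratings[name] = (rng.uniform(5.0, 9.0) if positive
                                 else rng.uniform(1.0, 5.0))
            classes = {name: labeling(r) for name, r in ratings.items()}

            signal = np.zeros((spec.n_channels, s))
            for band, edges in BANDS.items():
                if spec.carrier == "noise":
                    carrier = _noise_carrier(rng, edges, spec.n_channels, s,
                                             spec.sampling_rate)
                else:
                    carrier = _sinusoid_carrier(rng, edges, spec.sinusoids_per_band,
                                                spec.n_channels, t)
                amp = spec.base_amplitudes.get(band, 0.0) * topo[band]
                label = label_of_band.get(band)
                if label is not None and classes[label] == 1:
                    gain = 1.0 + spec.separability * (spec.signature_gain - 1.0)
                    amp = amp * gain
                signal += amp[:, None] * carrier
            if spec.pink_sigma > 0:
                signal += _pink_noise(rng, spec.n_channels, s, spec.pink_sigma)
            if spec.white_sigma > 0:
                signal += spec.white_sigma * rng.standard_normal((spec.n_channels, s))

            trials.append(Trial(
                participant_id=pid,
                trial_id=f"{pid}/t{k:02d}",
                signal=signal.astype(np.float32),
                sampling_rate=spec.sampling_rate,
                ratings=ratings,
            ))
    return Dataset(trials=tuple(trials), label_schema="deap")


def band_power_check(dataset: Dataset, band: str, label: str | None = None,
                     channels: np.ndarray | None = None) -> dict[int, float]:
    """Mean in-band spectral power per binarized class of ``label``.

    Validates the generator's spectral contract: with separability > 0 the
    positive class of the label that owns ``band`` shows the larger power.
    ``label`` defaults to the band's owner under the default assignment;
    ``channels`` restricts the estimate (default: all channels).  Power is a
    Welch estimate integrated over the band, averaged over trials/channels.
    """
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}; valid: {sorted(BANDS)}")
    if label is None:
        owners = [l for l, b in DEFAULT_BAND_ASSIGNMENT.items() if b == band]
        if not owners or owners[0] not in (dataset.label_names or ()):
            raise ValidationError(
                f"no label owns band {band!r} by default; pass label= explicitly"
            )
        label = owners[0]
    lo, hi = BANDS[band]
    labeling = BinaryLabeling()
    acc: dict[int, list[float]] = {0: [], 1: []}
    for trial in dataset:
        sig = trial.signal if channels is None else trial.signal[channels]
        f, pxx = welch(sig, fs=trial.sampling_rate, nperseg=min(512, trial.n_samples),
                       axis=1)
        mask = (f >= lo) & (f < hi)
        power = float(np.trapezoid(pxx[:, mask], f[mask], axis=1).mean())
        acc[labeling(trial.ratings[label])].append(power)
    return {cls: float(np.mean(vals)) if vals else float("nan")
            for cls, vals in acc.items()}


def write_deap_layout(dataset: Dataset, out_dir, spec: SyntheticSpec | None = None,
                      container: str = "h5") -> list[Path]:
    """Write one DEAP-layout file per participant, plus a sidecar spec record.

    ``container`` picks the on-disk form: "h5", "npz", or "csv" (a long-format
    dump directory per participant).  Returns the written participant paths.
    """
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_participant: dict[str, list[Trial]] = {}
    for trial in dataset:
        by_participant.setdefault(trial.participant_id, []).append(trial)
    paths = []
    for pid, trials in by_participant.items():
        sub = Dataset(trials=tuple(trials), label_schema=dataset.label_schema)
        data, labels = dataset_to_arrays(sub, rating_order=DEAP_RATING_ORDER)
        path = out_dir / (pid if container == "csv" else f"{pid}.{container}")
        save_deap_participant(path, data, labels)
        paths.append(path)
    if spec is not None:
        record = {k: (dict(v) if isinstance(v, Mapping) else v)
                  for k, v in vars(spec).items()}
        (out_dir / "generator_spec.yaml").write_text(yaml.safe_dump(record))
    return paths
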