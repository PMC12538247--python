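"""Domain types and I/O for affect-labelled EEG recordings.

The central objects are :class:`Trial` (one participant-stimulus recording:
a channels x samples matrix plus the participant's self-assessment ratings)
and :class:`Dataset` (an ordered collection of trials sharing a channel
layout and sampling rate).  Two labelling schemas are supported:

* ``"deap"`` — four continuous ratings in [1, 9] (arousal, valence,
  dominance, liking), binarized at a threshold (default 5) into
  negative/positive classes;
* ``"seed"`` — a single categorical label in {-1, 0, 1}
  (negative / neutral / positive film-clip affect).

On-disk layouts follow the public DEAP release geometry: one file per
participant holding a ``data`` array of shape (40, C, 8064) and a
``labels`` array of shape (40, 4).  Both an HDF5/npz binary container and a
long-format CSV dump are read and written, so synthetic datasets can
exercise the loaders without any licensed download.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: DEAP rating names in the public release's column order.
DEAP_RATING_ORDER: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")

#: Samples covered by the 3-second pre-trial baseline at 128 Hz.
BASELINE_SAMPLES = 384


@dataclass(frozen=True)
class Trial:
    """One participant-stimulus EEG recording with its affect ratings.

    ``signal`` is a real matrix of shape (channels, samples) in
    microvolt-scale arbitrary units.  ``ratings`` maps label name to a
    rating: continuous in [1, 9] for the DEAP schema, or categorical in
    {-1, 0, 1} for the SEED schema.
    """

    participant_id: str
    trial_id: str
    signal: np.ndarray
    sampling_rate: float = 128.0
    ratings: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal)
        if sig.ndim != 2 or sig.shape[0] < 1 or sig.shape[1] < 1:
            raise ValidationError(
                f"trial signal must be a 2-D channels x samples matrix with at "
                f"least one channel and one sample; got shape {sig.shape}"
            )
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def drop_baseline(self, n_samples: int = BASELINE_SAMPLES) -> "Trial":
        """Return a copy with the first ``n_samples`` (pre-trial baseline) removed."""
        if n_samples >= self.n_samples:
            raise ValidationError(
                f"cannot drop {n_samples} baseline samples from a trial of "
                f"{self.n_samples} samples"
            )
        return Trial(
            participant_id=self.participant_id,
            trial_id=self.trial_id,
            signal=self.signal[:, n_samples:],
            sampling_rate=self.sampling_rate,
            ratings=dict(self.ratings),
        )


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of trials sharing channel count and sampling rate."""

    trials: tuple[Trial, ...]
    label_schema: str = "deap"  # "deap" (4 binary labels) or "seed" (1 ternary label)

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        if self.label_schema not in ("deap", "seed"):
            raise ValidationError(f"unknown label_schema {self.label_schema!r}")
        if trials:
            n_ch = trials[0].n_channels
            rate = trials[0].sampling_rate
            names = set(trials[0].ratings)
            for t in trials:
                if t.n_channels != n_ch:
                    raise ValidationError(
                        "all trials in a dataset must share the channel count"
                    )
                if t.sampling_rate != rate:
                    raise ValidationError(
                        "all trials in a dataset must share the sampling rate"
                    )
                if set(t.ratings) != names:
                    raise ValidationError(
                        "every trial must carry every label in the schema"
                    )
                if self.label_schema == "deap":
                    for name, r in t.ratings.items():
                        if not np.isfinite(r) or not (1.0 <= r <= 9.0):
                            raise ValidationError(
                                f"DEAP-mode rating {name}={r} outside [1, 9] "
                                f"in trial {t.trial_id}"
                            )
        object.__setattr__(self, "trials", trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    @property
    def label_names(self) -> tuple[str, ...]:
        return tuple(self.trials[0].ratings) if self.trials else ()

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate


@dataclass(frozen=True)
class BinaryLabeling:
    """Threshold rule mapping a continuous rating to a binary class.

    A rating strictly below ``threshold`` is the negative class (0);
    a rating at or above it is the positive class (1).  The boundary is
    positive: self-assessments use the scale midpoint as "at least moderate".
    """

    threshold: float = 5.0

    def __call__(self, rating: float):
        arr = np.asarray(rating, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"rating must be finite, got {rating!r}")
        out = (arr >= self.threshold).astype(int)
        return out if arr.ndim else int(out)


def binarize(
    ratings: Mapping[str, float], labeling: BinaryLabeling | None = None
) -> dict[str, int]:
    """Binarize a per-label ratings mapping: 0 = negative, 1 = positive."""
    labeling = labeling or BinaryLabeling()
    return {name: labeling(r) for name, r in ratings.items()}


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition specification.

    ``unit`` controls the partitioned unit: ``"trial"`` keeps all segments of
    a trial on one side (no overlap leakage across the partition), while
    ``"segment"`` shuffles individual segments and is only appropriate when
    windows do not overlap — it is allowed behind this explicit flag and
    logged as a leakage risk.
    """

    train_fraction: float = 0.8
    unit: str = "trial"  # "trial" | "segment"
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.unit not in ("trial", "segment"):
            raise ValidationError(f"split unit must be 'trial' or 'segment', got {self.unit!r}")


def _trial_key(item) -> tuple:
    """Grouping key: the owning trial of either a Trial or a Segment."""
    ref = getattr(item, "trial_ref", None)
    if ref is not None:
        return tuple(ref)
    return (item.participant_id, item.trial_id)


def _shuffled_split(keys: list, frac: float, rng: np.random.Generator,
                    labels: dict | None) -> tuple[set, set]:
    """Partition ``keys`` into train/test key sets, floor(frac*n) in train."""
    keys = list(keys)
    if labels is None:
        order = rng.permutation(len(keys))
        n_train = math.floor(frac * len(keys))
        train = {keys[i] for i in order[:n_train]}
    else:
        # stratified: floor split within each class, remainder to test
        train = set()
        by_class: dict = {}
        for k in keys:
            by_class.setdefault(labels[k], []).append(k)
        for cls in sorted(by_class):
            members = by_class[cls]
            order = rng.permutation(len(members))
            n_train = math.floor(frac * len(members))
            train.update(members[i] for i in order[:n_train])
    test = set(keys) - train
    return train, test


def split(items, spec: SplitSpec, labels: Sequence | None = None):
    """Partition trials or segments into (train, test) per ``spec``.

    ``items`` is a Dataset, a sequence of Trials, or a sequence of Segments.
    With ``unit="trial"`` the shuffle happens over distinct parent trials and
    every item follows its trial, so no two segments of one trial cross the
    partition.  ``labels`` (optional, one hashable class per item) enables
    stratification; with trial-level splitting all items of a trial must
    agree on the class.

    Sizes follow a floor rule: ``floor(train_fraction * n_units)`` units go
    to train, the remainder to test.  Same seed, same partition.
    """
    items = list(items)
    if len(items) < 2:
        raise ValidationError("need at least 2 items to split")
    rng = np.random.default_rng(spec.seed)

    label_of = None
    if spec.stratify:
        if labels is None:
            raise ValidationError("stratify=True requires per-item labels")
        if len(labels) != len(items):
            raise ValidationError("labels must align one-to-one with items")

    if spec.unit == "segment":
        logger.warning(
            "segment-level split requested: overlapping windows from one trial "
            "may appear in both partitions (leakage risk)"
        )
        keys = list(range(len(items)))
        if spec.stratify:
            label_of = dict(zip(keys, labels))
        train_keys, _ = _shuffled_split(keys, spec.train_fraction, rng, label_of)
        train = [items[i] for i in keys if i in train_keys]
        test = [items[i] for i in keys if i not in train_keys]
        return train, test

    # trial-level: group by owning trial, preserving first-seen order
    keys: list = []
    seen = set()
    for it in items:
        k = _trial_key(it)
        if k not in seen:
            seen.add(k)
            keys.append(k)
    if len(keys) < 2:
        raise ValidationError("trial-level split needs at least 2 distinct trials")
    if spec.stratify:
        label_of = {}
        for it, lab in zip(items, labels):
            k = _trial_key(it)
            if k in label_of and label_of[k] != lab:
                raise ValidationError(
                    f"trial {k} has inconsistent labels; cannot stratify at trial level"
                )
            label_of[k] = lab
    train_keys, _ = _shuffled_split(keys, spec.train_fraction, rng, label_of)
    train = [it for it in items if _trial_key(it) in train_keys]
    test = [it for it in items if _trial_key(it) not in train_keys]
    return train, test


# ---------------------------------------------------------------------------
# DEAP-layout readers / writers
# ---------------------------------------------------------------------------

_DEAP_N_TRIALS = 40
_DEAP_N_SAMPLES = 8064
_DEAP_N_RATINGS = 4


def _read_arrays(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (data, labels) arrays from an HDF5 file, an npz file, or a CSV dump."""
    if path.is_dir():
        return _read_csv_dump(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if "data" not in f or "labels" not in f:
                raise FormatError(
                    f"{path}: expected datasets 'data' and 'labels', "
                    f"found {sorted(f.keys())}"
                )
            return f["data"][...], f["labels"][...]
    if suffix == ".npz":
        with np.load(path) as f:
            if "data" not in f or "labels" not in f:
                raise FormatError(
                    f"{path}: expected arrays 'data' and 'labels', "
                    f"found {sorted(f.files)}"
                )
            return f["data"], f["labels"]
    raise FormatError(
        f"{path}: unsupported container (expected .h5/.hdf5, .npz, or a CSV dump directory)"
    )


def _read_csv_dump(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the long-format CSV dump: data.csv (trial,channel,sample,value) + labels.csv."""
    import pandas as pd

    data_f, labels_f = path / "data.csv", path / "labels.csv"
    if not data_f.exists() or not labels_f.exists():
        raise FormatError(f"{path}: CSV dump needs data.csv and labels.csv")
    df = pd.read_csv(data_f, float_precision="round_trip")
    need = {"trial", "channel", "sample", "value"}
    if not need.issubset(df.columns):
        raise FormatError(f"{data_f}: expected columns {sorted(need)}, got {list(df.columns)}")
    n_t = int(df["trial"].max()) + 1
    n_c = int(df["channel"].max()) + 1
    n_s = int(df["sample"].max()) + 1
    if len(df) != n_t * n_c * n_s:
        raise FormatError(
            f"{data_f}: ragged dump ({len(df)} rows, expected {n_t * n_c * n_s})"
        )
    df = df.sort_values(["trial", "channel", "sample"])
    data = df["value"].to_numpy().reshape(n_t, n_c, n_s)
    lab = pd.read_csv(labels_f, float_precision="round_trip")
    rating_cols = [c for c in lab.columns if c != "trial"]
    labels = lab.sort_values("trial")[rating_cols].to_numpy()
    return data, labels


def load_deap_participant(
    path,
    channel_limit: int = 32,
    rating_order: Sequence[str] = DEAP_RATING_ORDER,
    participant_id: str | None = None,
    drop_baseline: bool = False,
) -> Dataset:
    """Load one participant's DEAP-layout file into a Dataset of 40 trials.

    The file must hold a ``data`` array of shape (40, C, 8064) with C >= the
    32 EEG channels (peripheral channels, if present, come after) and a
    ``labels`` array of shape (40, 4).  ``rating_order`` names the rating
    columns; the default is the public release order
    (valence, arousal, dominance, liking).  ``drop_baseline`` trims the
    3-second pre-trial baseline (384 samples) from every trial.
    """
    path = Path(path)
    data, labels = _read_arrays(path)
    data = np.asarray(data)
    labels = np.asarray(labels, dtype=float)
    if data.ndim != 3 or data.shape[0] != _DEAP_N_TRIALS or data.shape[2] != _DEAP_N_SAMPLES:
        raise FormatError(
            f"{path}: expected data of shape ({_DEAP_N_TRIALS}, C, {_DEAP_N_SAMPLES}), "
            f"found {data.shape}"
        )
    if data.shape[1] < channel_limit:
        raise FormatError(
            f"{path}: file has {data.shape[1]} channels, fewer than "
            f"channel_limit={channel_limit}"
        )
    if labels.shape != (_DEAP_N_TRIALS, _DEAP_N_RATINGS):
        raise FormatError(
            f"{path}: expected labels of shape ({_DEAP_N_TRIALS}, {_DEAP_N_RATINGS}), "
            f"found {labels.shape}"
        )
    if len(rating_order) != _DEAP_N_RATINGS:
        raise ValidationError(f"rating_order must name 4 columns, got {rating_order!r}")
    if not np.all(np.isfinite(labels)) or labels.min() < 1.0 or labels.max() > 9.0:
        raise ValidationError(
            f"{path}: ratings outside [1, 9] (range {labels.min()}..{labels.max()})"
        )
    pid = participant_id if participant_id is not None else path.stem
    trials = []
    for i in range(_DEAP_N_TRIALS):
        t = Trial(
            participant_id=pid,
            trial_id=f"{pid}/t{i:02d}",
            signal=data[i, :channel_limit, :],
            sampling_rate=128.0,
            ratings=dict(zip(rating_order, labels[i])),
        )
        if drop_baseline:
            t = t.drop_baseline()
        trials.append(t)
    return Dataset(trials=tuple(trials), label_schema="deap")


def save_deap_participant(
    path,
    data: np.ndarray,
    labels: np.ndarray,
    rating_order: Sequence[str] = DEAP_RATING_ORDER,
) -> None:
    """Write (data, labels) arrays in the DEAP participant layout.

    The container is chosen from the path: ``.h5``/``.hdf5`` (HDF5),
    ``.npz`` (NumPy), or a directory (long-format CSV dump).
    """
    path = Path(path)
    data = np.asarray(data)
    labels = np.asarray(labels)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=data)
            f.create_dataset("labels", data=labels)
        return
    if suffix == ".npz":
        np.savez(path, data=data, labels=labels)
        return
    if suffix == "":
        import pandas as pd

        path.mkdir(parents=True, exist_ok=True)
        n_t, n_c, n_s = data.shape
        idx = np.indices((n_t, n_c, n_s)).reshape(3, -1)
        # float64 text repr round-trips exactly; narrower dtypes would not
        pd.DataFrame(
            {"trial": idx[0], "channel": idx[1], "sample": idx[2],
             "value": data.ravel().astype(np.float64)}
        ).to_csv(path / "data.csv", index=False, float_format="%.17g")
        lab = pd.DataFrame(labels, columns=list(rating_order))
        lab.insert(0, "trial", np.arange(n_t))
        lab.to_csv(path / "labels.csv", index=False, float_format="%.17g")
        return
    raise FormatError(f"{path}: unsupported container suffix {suffix!r}")


def dataset_to_arrays(
    dataset: Dataset, rating_order: Sequence[str] = DEAP_RATING_ORDER
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a (single-participant) Dataset back into (data, labels) arrays."""
    data = np.stack([t.signal for t in dataset.trials])
    labels = np.array([[t.ratings[name] for name in rating_order] for t in dataset.trials])
    return data, labels


# ---------------------------------------------------------------------------
# SEED-style loading
# ---------------------------------------------------------------------------


def load_seed_session(path, participant_id: str | None = None,
                      sampling_rate: float = 200.0) -> Dataset:
    """Load a SEED-style session: per-clip channel x sample arrays + ternary labels.

    The npz file holds ``labels`` (n_clips,) with values in {-1, 0, 1}
    (negative / neutral / positive) and arrays ``clip_0`` .. ``clip_{n-1}``,
    each channels x samples.  Clip lengths may differ; channel counts must not.
    """
    path = Path(path)
    with np.load(path) as f:
        if "labels" not in f:
            raise FormatError(f"{path}: expected a 'labels' array")
        labels = np.asarray(f["labels"])
        if not np.isin(labels, (-1, 0, 1)).all():
            raise ValidationError(f"{path}: SEED labels must lie in {{-1, 0, 1}}")
        pid = participant_id if participant_id is not None else path.stem
        trials = []
        for i, lab in enumerate(labels):
            key = f"clip_{i}"
            if key not in f:
                raise FormatError(f"{path}: missing array {key!r} for clip {i}")
            trials.append(
                Trial(
                    participant_id=pid,
                    trial_id=f"{pid}/c{i:02d}",
                    signal=np.asarray(f[key]),
                    sampling_rate=sampling_rate,
                    ratings={"emotion": int(lab)},
                )
            )
    return Dataset(trials=tuple(trials), label_schema="seed")
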