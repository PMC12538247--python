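"""Overlapping sliding-window segmentation and the two-phase parameter search.

A trial of ``L`` samples is cut into fixed-length windows of ``N`` samples.
Consecutive windows advance by the overlap parameter ``O`` — the number of
samples NOT shared between them — so each consecutive pair shares exactly
``N - O`` samples.  ``O = N`` tiles the trial with disjoint windows; small
``O`` (the regime favoured here, optimum 6) produces near-duplicate windows
differing by a few trailing samples.

Two modes:

* ``tile`` — windows start at 0, O, 2O, ... while they fit
  (``start + N <= L``); trailing samples that do not fill a window are
  dropped;
* ``capped(K)`` — exactly K windows with the same shift; it is an error if
  the K-th would overrun the trial.

The module also hosts the two-phase grid search: phase 1 sweeps candidate
window sizes at a fixed overlap, phase 2 sweeps overlaps at the winning
window size.  Both drivers delegate the actual train/evaluate work to a
caller-supplied ``eval_fn`` so they can be unit-tested with stubs and run
for real by the pipeline.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .dataio import Dataset, Trial
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Metric columns of a search table row, in report order.
METRIC_COLUMNS = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class SegmentationSpec:
    """Window length ``N``, overlap parameter ``O`` (= shift), and mode."""

    window_size: int
    overlap_param: int
    mode: str = "tile"  # "tile" | "capped"
    cap: int | None = None

    def __post_init__(self) -> None:
        n, o = self.window_size, self.overlap_param
        if not (isinstance(n, (int, np.integer)) and isinstance(o, (int, np.integer))):
            raise ValidationError("window_size and overlap_param must be integers")
        if not (1 <= o <= n):
            raise ValidationError(
                f"need 1 <= overlap_param <= window_size, got O={o}, N={n}"
            )
        if self.mode not in ("tile", "capped"):
            raise ValidationError(f"mode must be 'tile' or 'capped', got {self.mode!r}")
        if self.mode == "capped":
            if self.cap is None or self.cap < 1:
                raise ValidationError("capped mode requires cap >= 1")
        elif self.cap is not None:
            raise ValidationError("cap is only meaningful in capped mode")

    @property
    def shared_samples(self) -> int:
        """Samples shared by consecutive windows: N - O."""
        return self.window_size - self.overlap_param


@dataclass(frozen=True)
class Segment:
    """A windowed slice of a trial, carrying provenance and inherited ratings."""

    signal: np.ndarray  # channels x window_size, a verbatim slice of the parent
    trial_ref: tuple[str, str]  # (participant_id, trial_id)
    start_index: int  # 0-based sample offset, half-open [start, start+N)
    ratings: Mapping[str, float] = field(default_factory=dict)

    @property
    def window_size(self) -> int:
        return self.signal.shape[1]


def count_segments(length: int, spec: SegmentationSpec) -> int:
    """Number of windows ``segment_trial`` emits for a trial of ``length`` samples.

    Tile mode: ``floor((length - N) / O) + 1``.  Capped mode: the cap K,
    after checking the K-th window fits.
    """
    n, o = spec.window_size, spec.overlap_param
    if n > length:
        raise ValidationError(
            f"window_size {n} exceeds trial length {length}"
        )
    if spec.mode == "capped":
        k = spec.cap
        last_start = (k - 1) * o
        if last_start + n > length:
            raise ValidationError(
                f"capped({k}) overruns the trial: window {k} would span "
                f"[{last_start}, {last_start + n}) in a trial of {length} samples"
            )
        return k
    return (length - n) // o + 1


def segment_trial(trial: Trial, spec: SegmentationSpec) -> list[Segment]:
    """Cut one trial into ordered windows per ``spec``.

    Windows start at 0, O, 2O, ...; each signal is a verbatim slice
    ``trial.signal[:, start:start+N]`` and inherits the trial's ratings.
    """
    n_out = count_segments(trial.n_samples, spec)
    n, o = spec.window_size, spec.overlap_param
    ref = (trial.participant_id, trial.trial_id)
    return [
        Segment(
            signal=trial.signal[:, i * o : i * o + n],
            trial_ref=ref,
            start_index=i * o,
            ratings=trial.ratings,
        )
        for i in range(n_out)
    ]


def segment_dataset(dataset: Dataset | Sequence[Trial], spec: SegmentationSpec) -> list[Segment]:
    """Segment every trial, concatenating in trial order."""
    out: list[Segment] = []
    for trial in dataset:
        out.extend(segment_trial(trial, spec))
    return out


def reconstruct_prefix(segments: Sequence[Segment]) -> np.ndarray:
    """Stitch tile-mode segments of one trial back into the covered prefix.

    Consecutive windows at shift O share N - O samples; de-duplicating the
    shared block and concatenating the O new samples of each later window
    reproduces ``trial.signal[:, :last_start + N]`` exactly.
    """
    segs = sorted(segments, key=lambda s: s.start_index)
    if not segs:
        raise ValidationError("cannot reconstruct from zero segments")
    out = segs[0].signal
    for prev, cur in zip(segs, segs[1:]):
        shift = cur.start_index - prev.start_index
        out = np.concatenate([out, cur.signal[:, -shift:]], axis=1)
    return out


# ---------------------------------------------------------------------------
# Two-phase grid search
# ---------------------------------------------------------------------------

#: eval_fn contract: (dataset, SegmentationSpec) -> {label: {metric: value}}
EvalFn = Callable[[Dataset, SegmentationSpec], Mapping[str, Mapping[str, float]]]


@dataclass(frozen=True)
class SearchResult:
    """Grid-search output: a metrics table plus the per-label optimum."""

    table: pd.DataFrame  # columns: label, <swept param>, accuracy, precision, recall, f1
    best: dict[str, int]  # label -> optimal parameter value
    param: str  # "window_size" or "overlap_param"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _run_search(
    dataset: Dataset,
    candidates: Sequence[int],
    make_spec: Callable[[int], SegmentationSpec],
    eval_fn: EvalFn,
    param: str,
    prefer_larger: bool,
) -> SearchResult:
    if len(candidates) == 0:
        raise ValidationError("candidate list must be non-empty")
    max_len = min(t.n_samples for t in dataset)
    rows = []
    per_label_scores: dict[str, list[tuple[float, int]]] = {}
    for value in candidates:
        spec = make_spec(value)
        if spec.window_size > max_len:
            raise ValidationError(
                f"candidate {param}={value}: window_size {spec.window_size} exceeds "
                f"the shortest trial ({max_len} samples)"
            )
        metrics = eval_fn(dataset, spec)
        for label, m in metrics.items():
            rows.append({"label": label, param: value, **{k: m[k] for k in METRIC_COLUMNS}})
            per_label_scores.setdefault(label, []).append((m["accuracy"], value))
    best: dict[str, int] = {}
    for label, scored in per_label_scores.items():
        top = max(a for a, _ in scored)
        tied = [v for a, v in scored if a == top]
        choice = max(tied) if prefer_larger else min(tied)
        if len(tied) > 1:
            logger.info(
                "%s search, label %s: accuracy tie at %.4f among %s; choosing %s (%s)",
                param, label, top, sorted(tied), choice,
                "larger window keeps more context" if prefer_larger
                else "smaller overlap keeps windows most similar",
            )
        best[label] = choice
    table = pd.DataFrame(rows, columns=["label", param, *METRIC_COLUMNS])
    return SearchResult(table=table, best=best, param=param)


def phase1_window_search(
    dataset: Dataset,
    candidate_ns: Sequence[int],
    fixed_o: int,
    eval_fn: EvalFn,
    mode: str = "tile",
    cap: int | None = None,
) -> SearchResult:
    """Phase 1: sweep window sizes at a fixed overlap parameter.

    Each candidate N is evaluated by ``eval_fn`` on the dataset segmented
    with (N, fixed_o); the optimum per label is the argmax of accuracy, ties
    broken toward the larger window (longer temporal context), logged.
    """
    def make_spec(n: int) -> SegmentationSpec:
        return SegmentationSpec(window_size=n, overlap_param=min(fixed_o, n),
                                mode=mode, cap=cap)

    return _run_search(dataset, candidate_ns, make_spec, eval_fn,
                       param="window_size", prefer_larger=True)


def phase2_overlap_search(
    dataset: Dataset,
    fixed_n: int,
    candidate_os: Sequence[int],
    eval_fn: EvalFn,
    mode: str = "tile",
    cap: int | None = None,
) -> SearchResult:
    """Phase 2: sweep overlap parameters at the winning window size.

    Ties break toward the smaller O: a smaller shift keeps consecutive
    windows most similar, which is the regime the method favours.
    """
    def make_spec(o: int) -> SegmentationSpec:
        return SegmentationSpec(window_size=fixed_n, overlap_param=o, mode=mode, cap=cap)

    return _run_search(dataset, candidate_os, make_spec, eval_fn,
                       param="overlap_param", prefer_larger=False)
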