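"""%MVC normalisation, cycle windowing, fatigue labels, dataset splits.

Raw sEMG amplitudes differ widely between subjects, so every signal is
expressed as a percentage of the muscle's maximum voluntary contraction
(MVC) benchmark before any analysis: ``semg_pct = semg / semg_mvc * 100``.

One network input window is cut per action cycle (1 s at 60°/s, 250 ms at
180°/s, start-aligned), polyphase-resampled to the model's fixed sample
counts (120 or 160 per channel), and labelled with one of four fatigue
classes from the cycle's Borg RPE rating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.signal import resample_poly

if TYPE_CHECKING:  # avoid an import cycle with the simulator
    from .synthetic_semg import Recording

__all__ = [
    "FATIGUE_CLASSES",
    "LabelScheme",
    "Window",
    "SplitSpec",
    "DatasetSplit",
    "normalize_mvc",
    "moving_rms",
    "compute_mvc_reference",
    "extract_windows",
    "split_dataset",
    "window_length_for_speed",
    "target_samples_for_speed",
]

FATIGUE_CLASSES = ("relaxed", "a_little_tired", "very_tired", "extremely_tired")

#: model input length per channel, by speed condition
_TARGET_SAMPLES = {60: 120, 180: 160}
#: analysis window duration in seconds, by speed condition
_WINDOW_SECONDS = {60: 1.0, 180: 0.25}


def window_length_for_speed(speed: int, sampling_rate: float) -> int:
    return int(round(_WINDOW_SECONDS[speed] * sampling_rate))


def target_samples_for_speed(speed: int) -> int:
    return _TARGET_SAMPLES[speed]


@dataclass(frozen=True)
class LabelScheme:
    """Partition of the Borg 6–20 RPE range into the four fatigue classes.

    ``upper_edges`` are the inclusive upper RPE bounds of classes 0..2;
    everything above the last edge (up to 20) is class 3.
    """

    upper_edges: tuple[int, int, int] = (12, 16, 18)

    @classmethod
    def table2(cls) -> "LabelScheme":
        """Default binning: 6–12 / 13–16 / 17–18 / 19–20."""
        return cls((12, 16, 18))

    @classmethod
    def o5_variant(cls) -> "LabelScheme":
        """Alternative binning 6–12 / 13–16 / 17–19 / 20."""
        return cls((12, 16, 19))

    def validate(self) -> None:
        e = self.upper_edges
        if not (6 <= e[0] < e[1] < e[2] < 20):
            raise ValueError("upper_edges must be strictly increasing within 6..19")

    def label_for_rpe(self, rpe: int) -> int:
        if not 6 <= rpe <= 20:
            raise ValueError(f"RPE {rpe} outside the Borg 6-20 scale")
        for cls_idx, edge in enumerate(self.upper_edges):
            if rpe <= edge:
                return cls_idx
        return 3


@dataclass
class Window:
    """One normalised model input sample with its fatigue label."""

    matrix: np.ndarray  # (6, T) in %MVC
    label: int  # 0..3
    subject_id: str
    cycle_index: int  # 0-based
    speed: int

    def validate(self) -> None:
        if self.matrix.shape[0] != 6:
            raise ValueError("window must have 6 channels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("window entries must be finite")
        if self.label not in (0, 1, 2, 3):
            raise ValueError("label must be one of 0..3")


def normalize_mvc(signal: np.ndarray, mvc_reference: np.ndarray) -> np.ndarray:
    """Express each channel as a percentage of its MVC benchmark."""
    signal = np.asarray(signal, dtype=float)
    mvc = np.asarray(mvc_reference, dtype=float)
    if mvc.shape != (signal.shape[0],):
        raise ValueError("one MVC reference per channel required")
    if np.any(mvc <= 0):
        raise ValueError("MVC reference values must be strictly positive")
    return signal / mvc[:, None] * 100.0


def moving_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Moving RMS along the last axis (boxcar of ``window_samples``)."""
    window_samples = max(int(window_samples), 1)
    kernel = np.ones(window_samples) / window_samples
    x = np.asarray(x, dtype=float)
    power = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), -1, x ** 2
    )
    return np.sqrt(power)


def compute_mvc_reference(
    mvc_segments: Sequence[np.ndarray],
    sampling_rate: float = 1000.0,
    rms_window_s: float = 0.1,
) -> np.ndarray:
    """Mean dynamic MVC benchmark per channel.

    For each segment the per-channel summary is the peak of the 100 ms
    moving RMS (robust to single-sample spikes); the reference is the mean
    of that summary over the provided segments.
    """
    segments = list(mvc_segments)
    if not segments:
        raise ValueError("at least one MVC segment is required")
    peaks = []
    for seg in segments:
        seg = np.atleast_2d(np.asarray(seg, dtype=float))
        win = int(round(rms_window_s * sampling_rate))
        peaks.append(moving_rms(seg, win).max(axis=1))
    return np.mean(peaks, axis=0)


def extract_windows(
    rec: "Recording",
    scheme: LabelScheme | None = None,
    window_len: int | None = None,
    resample_to: int | None = None,
    stride: int | None = None,
    envelope_ms: float | None = 25.0,
) -> list[Window]:
    """Cut one labelled %MVC window per action cycle.

    By default each window is the *whole* action cycle, time-normalised:
    the %MVC moving-RMS envelope (``envelope_ms``, 25 ms) of the cycle is
    polyphase-resampled to exactly ``resample_to`` samples per channel
    (120 at 60°/s, 160 at 180°/s), so cycles of any native duration map
    onto the model's fixed input shape. At the resulting 40-160 samples
    per second only envelope content is representable anyway (raw sEMG
    needs >= 500 Hz); the envelope keeps amplitude and slow spectral
    information in the sample values. Pass ``envelope_ms=None`` to
    resample the raw oscillatory signal instead, and a fixed
    ``window_len`` (native samples) to cut start-aligned fixed-duration
    windows rather than whole cycles.

    Cycles shorter than ``window_len`` (or, in whole-cycle mode, shorter
    than 2 samples) are skipped with a warning; ``stride`` (native
    samples) optionally cuts additional overlapping windows per cycle
    for augmentation.
    """
    scheme = scheme or LabelScheme.table2()
    scheme.validate()
    if resample_to is None:
        resample_to = target_samples_for_speed(rec.speed)

    pct = normalize_mvc(rec.signal, rec.mvc_reference)
    if envelope_ms is not None:
        pct = moving_rms(pct, int(round(envelope_ms * rec.sampling_rate / 1000.0)))

    windows: list[Window] = []
    for idx, ((start, end), rpe) in enumerate(
        zip(rec.cycle_bounds, rec.rpe_per_cycle)
    ):
        wlen = window_len if window_len is not None else end - start
        starts = [start]
        if stride and window_len is not None:
            starts = list(range(start, end - window_len + 1, stride)) or [start]
        for s0 in starts:
            if s0 + wlen > end or wlen < 2:
                warnings.warn(
                    f"cycle {idx} of {rec.subject_id} shorter than the "
                    f"{wlen}-sample window; skipped"
                )
                continue
            seg = pct[:, s0 : s0 + wlen]
            g = math.gcd(resample_to, wlen)
            mat = resample_poly(seg, resample_to // g, wlen // g, axis=1)
            # guard against off-by-one from non-integer ratios
            mat = mat[:, :resample_to]
            w = Window(
                matrix=np.ascontiguousarray(mat),
                label=scheme.label_for_rpe(rpe),
                subject_id=rec.subject_id,
                cycle_index=idx,
                speed=rec.speed,
            )
            w.validate()
            windows.append(w)
    if not windows:
        raise ValueError("no cycle was long enough to cut a window from")
    return windows


@dataclass(frozen=True)
class SplitSpec:
    """3:1:1 train/validation/test split plus held-out subjects.

    ``pooled_segments`` pools every remaining window, shuffles the pool
    once with ``seed`` and cuts five contiguous equal segments assigned
    3:1:1 — so the test segment shares subjects (but never windows) with
    training, and subject-level generalisation is measured on the
    ``holdout_subjects`` kept out of the pool entirely. ``by_subject``
    applies the 3:1:1 ratio at whole-subject granularity instead, for a
    fully cross-subject evaluation.
    """

    mode: str = "pooled_segments"  # or "by_subject"
    ratios: tuple[int, int, int] = (3, 1, 1)
    holdout_subjects: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("pooled_segments", "by_subject"):
            raise ValueError("mode must be pooled_segments or by_subject")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if self.holdout_subjects < 0:
            raise ValueError("holdout_subjects must be >= 0")


@dataclass
class DatasetSplit:
    train: list[Window]
    val: list[Window]
    test: list[Window]
    holdout: list[Window]
    holdout_subject_ids: list[str]

    def all_windows(self) -> list[Window]:
        return self.train + self.val + self.test + self.holdout


def split_dataset(windows: Iterable[Window], spec: SplitSpec) -> DatasetSplit:
    """Partition windows into train/val/test/holdout, disjointly."""
    spec.validate()
    windows = list(windows)
    if not windows:
        raise ValueError("cannot split an empty window set")

    subjects = sorted({w.subject_id for w in windows})
    if spec.holdout_subjects >= len(subjects):
        raise ValueError(
            f"holdout_subjects={spec.holdout_subjects} leaves no subjects "
            f"to split (cohort has {len(subjects)})"
        )
    rng = np.random.default_rng(spec.seed)
    holdout_ids = sorted(
        rng.choice(subjects, size=spec.holdout_subjects, replace=False).tolist()
    )
    holdout = [w for w in windows if w.subject_id in holdout_ids]
    rest = [w for w in windows if w.subject_id not in holdout_ids]
    rest.sort(key=lambda w: (w.subject_id, w.cycle_index))

    r_train, r_val, r_test = spec.ratios
    total_parts = r_train + r_val + r_test

    if spec.mode == "pooled_segments":
        n = len(rest)
        order = rng.permutation(n)
        pooled = [rest[i] for i in order]
        cut1 = n * r_train // total_parts
        cut2 = n * (r_train + r_val) // total_parts
        train, val, test = pooled[:cut1], pooled[cut1:cut2], pooled[cut2:]
    else:  # by_subject
        ids = [s for s in subjects if s not in holdout_ids]
        m = len(ids)
        cut1 = m * r_train // total_parts
        cut2 = m * (r_train + r_val) // total_parts
        id_train, id_val, id_test = (
            set(ids[:cut1]),
            set(ids[cut1:cut2]),
            set(ids[cut2:]),
        )
        train = [w for w in rest if w.subject_id in id_train]
        val = [w for w in rest if w.subject_id in id_val]
        test = [w for w in rest if w.subject_id in id_test]

    return DatasetSplit(
        train=train,
        val=val,
        test=test,
        holdout=holdout,
        holdout_subject_ids=holdout_ids,
    )
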