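"""ECG preprocessing, beat segmentation and six-class evaluation.

R peaks are found with a Pan-Tompkins-style detector (5-15 Hz band-pass,
squared derivative, moving-window integration, adaptive threshold, 200 ms
refractory period).  Beats are cut into fixed 250-sample windows (100
samples before the R peak, 150 after) and min-max normalized into [0,1],
the logistic range the autoencoder stack expects; a constant window maps to
all-0.5.  Evaluation builds the six-class confusion matrix (rows =
predicted class, columns = true class), per-class sensitivity and overall
plus macro-averaged accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .sae import StackedSAE, classify_batch
from .synthgen import BEAT_CLASSES, BEAT_WINDOW, R_OFFSET, ECGRecord

__all__ = [
    "ConfusionMatrix",
    "WFDB_CODE_MAP",
    "detect_r_peaks",
    "segment_beats",
    "beats_with_labels",
    "evaluate",
]

#: standard single-character annotation codes mapped onto the six classes
WFDB_CODE_MAP = {"N": "N", "A": "AP", "V": "PVC", "R": "RBBB", "L": "LBBB", "/": "PACE"}


@dataclass
class ConfusionMatrix:
    """Class-count matrix; rows are predicted classes, columns true classes."""

    counts: np.ndarray
    class_names: tuple[str, ...] = BEAT_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a square class-count matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, predicted, truth, class_names=BEAT_CLASSES) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(class_names)}
        k = len(class_names)
        counts = np.zeros((k, k), dtype=int)
        for p, t in zip(predicted, truth):
            counts[idx[p], idx[t]] += 1
        return cls(counts, tuple(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0

    def sensitivity(self) -> dict[str, float]:
        """Per-class sensitivity diagonal/column-sum; 0 (with a warning) for
        classes absent from the truth."""
        out = {}
        col = self.counts.sum(axis=0)
        for i, c in enumerate(self.class_names):
            if col[i] == 0:
                warnings.warn(f"no true samples of class {c}; sensitivity set to 0", stacklevel=2)
                out[c] = 0.0
            else:
                out[c] = float(self.counts[i, i]) / float(col[i])
        return out

    def pair_error_counts(self) -> dict[tuple[str, str], int]:
        """Unordered off-diagonal confusion counts per class pair."""
        out = {}
        k = len(self.class_names)
        for i in range(k):
            for j in range(i + 1, k):
                out[(self.class_names[i], self.class_names[j])] = int(
                    self.counts[i, j] + self.counts[j, i]
                )
        return out


def detect_r_peaks(record: ECGRecord) -> list[int]:
    """R-peak sample indices via band-pass + squared derivative + adaptive
    threshold with a 200 ms refractory period.  A flat record yields []."""
    x = np.asarray(record.samples, dtype=float)
    fs = record.fs
    if len(x) < 10 or np.ptp(x) == 0:
        return []
    nyq = fs / 2.0
    b, a = signal.butter(2, [5.0 / nyq, min(15.0, 0.95 * nyq) / nyq], btype="band")
    filt = signal.filtfilt(b, a, x)
    deriv = np.gradient(filt)
    sq = deriv**2
    win = max(1, int(0.15 * fs))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    cand, props = signal.find_peaks(integ, height=1e-12, distance=max(1, int(0.2 * fs)))
    if cand.size == 0:
        return []
    # adaptive threshold: candidate heights are bimodal (QRS complexes vs
    # T waves / noise); the geometric mean of the median and the maximum
    # sits in the gap, halved for margin toward inclusion
    h = props["peak_heights"]
    height = 0.5 * np.sqrt(np.median(h) * h.max())
    locs = cand[h >= height]
    # refine each detection to the nearby maximum of the median-filtered raw
    # signal: the 9-sample median suppresses narrow pacing spikes (a few
    # samples wide) while leaving the broader QRS apex in place
    half = int(0.08 * fs)
    energy = signal.medfilt(x, kernel_size=9)
    peaks = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(x), loc + half + 1)
        peaks.append(lo + int(np.argmax(energy[lo:hi])))
    peaks = sorted(set(peaks))
    # enforce refractory on the refined indices
    out: list[int] = []
    for p in peaks:
        if out and (p - out[-1]) < int(0.2 * fs):
            if energy[p] > energy[out[-1]]:
                out[-1] = p
            continue
        out.append(p)
    return out


def segment_beats(record: ECGRecord, peaks) -> tuple[np.ndarray, list[int]]:
    """Fixed 250-sample windows (100 pre-R, 150 post-R), min-max normalized.

    Peaks without full context (edge beats) are dropped.  Constant windows
    map to all-0.5.  Returns (beat matrix, kept peak indices).
    """
    x = np.asarray(record.samples, dtype=float)
    beats, kept = [], []
    for p in peaks:
        p = int(p)
        lo, hi = p - R_OFFSET, p - R_OFFSET + BEAT_WINDOW
        if lo < 0 or hi > len(x):
            continue
        w = x[lo:hi]
        rng = np.ptp(w)
        if rng == 0:
            beats.append(np.full(BEAT_WINDOW, 0.5))
        else:
            beats.append((w - w.min()) / rng)
        kept.append(p)
    if not beats:
        return np.zeros((0, BEAT_WINDOW)), []
    return np.vstack(beats), kept


def beats_with_labels(record: ECGRecord) -> tuple[np.ndarray, list[str]]:
    """Segment a record at its annotated R samples; returns (X, labels)."""
    peaks = [i for i, _ in record.annotations]
    X, kept = segment_beats(record, peaks)
    lab = dict(record.annotations)
    return X, [lab[p] for p in kept]


def evaluate(
    stack: StackedSAE, beats: np.ndarray, truth, class_names=BEAT_CLASSES
) -> tuple[ConfusionMatrix, dict[str, float], float]:
    """Classify beats and tabulate the confusion matrix.

    Returns (confusion matrix, per-class sensitivity, overall accuracy =
    trace / total).
    """
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    truth = list(truth)
    if len(beats) != len(truth) or len(truth) == 0:
        raise ValueError("beats and truth must have the same nonzero length")
    pred, _ = classify_batch(stack, beats)
    cm = ConfusionMatrix.from_labels(pred, truth, class_names)
    return cm, cm.sensitivity(), cm.accuracy
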