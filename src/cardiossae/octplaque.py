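"""Intravascular-OCT A-line analysis: plaque characterization and TCFA flagging.

The polar OCT image (rows = depth, columns = angles, row 0 on the lumen
side) is unfolded along the per-column lumen border: for each column the 100
pixels immediately below the border form an A-line.  A-lines are classified
into fibrous (F), fibro-calcified (F-C), fibro-lipid (F-L) and guidewire
shadow (GS) tissue: GS by a near-zero pre-filter, the rest by a sparse
stacked autoencoder with a SoftMax head trained on labelled A-lines.
Per-column labels are smoothed and grouped into circular plaque regions; for
fibro-lipid regions the fibrous-cap thickness is measured per column (first
depth at which the A-line falls below 50% of its cap plateau) and regions
whose minimum cap is thinner than the thin-cap threshold (default 65 um) are
flagged vulnerable (TCFA).  Binary-mask segmentation quality is summarized
by Dice, Jaccard, Hausdorff distance, precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from . import sae as sae_mod

__all__ = [
    "ALINE_LEN",
    "PolarOCTImage",
    "ALine",
    "PlaqueRegion",
    "SegMetrics",
    "OCTAnalysisConfig",
    "OCTReport",
    "unfold",
    "classify_aline",
    "classify_alines",
    "generate_regions",
    "cap_thickness",
    "seg_metrics",
    "analyze_image",
]

ALINE_LEN = 100  # pixels taken below the lumen border per column

TISSUE_CLASSES = ("F", "F-C", "F-L", "GS")


@dataclass
class PolarOCTImage:
    """Polar OCT frame: depth x angle intensities in [0,1] plus lumen border.

    border[c] is the lumen-border row of column c; pixel_pitch_um is the
    axial sampling pitch.
    """

    intensity: np.ndarray
    border: np.ndarray
    pixel_pitch_um: float = 10.0

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.border = np.asarray(self.border, dtype=int)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D depth x angle matrix")
        if self.border.shape != (self.intensity.shape[1],):
            raise ValueError("border must hold one row index per column")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_angle(self) -> int:
        return self.intensity.shape[1]


@dataclass
class ALine:
    """One axial depth profile of the unfolded image."""

    values: np.ndarray
    column: int
    pad_count: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (ALINE_LEN,):
            raise ValueError(f"A-line must have exactly {ALINE_LEN} values")
        if not (0 <= self.pad_count <= ALINE_LEN):
            raise ValueError("pad_count out of range")


@dataclass
class PlaqueRegion:
    """Circular plaque arc [start_col, end_col); end_col may exceed n_angle
    when the region wraps across the 0 seam (columns are taken modulo
    n_angle)."""

    start_col: int
    end_col: int
    tissue_class: str
    min_cap_thickness_um: float | None = None
    vulnerable: bool = False

    def __post_init__(self):
        if self.end_col <= self.start_col:
            raise ValueError("end_col must exceed start_col")
        if self.vulnerable and self.tissue_class != "F-L":
            raise ValueError("only fibro-lipid regions can be vulnerable")

    def columns(self, n_angle: int) -> np.ndarray:
        return np.arange(self.start_col, self.end_col) % n_angle

    @property
    def width(self) -> int:
        return self.end_col - self.start_col


@dataclass
class SegMetrics:
    """Dice / Jaccard / Hausdorff / precision / recall bundle."""

    dice: float
    jaccard: float
    hausdorff_px: float
    precision: float
    recall: float

    def __post_init__(self):
        for name in ("dice", "jaccard", "precision", "recall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        if self.hausdorff_px < 0:
            raise ValueError("hausdorff must be >= 0")
        if self.jaccard > self.dice + 1e-12:
            raise ValueError("jaccard cannot exceed dice")


# ---------------------------------------------------------------------------


def unfold(image: PolarOCTImage) -> tuple[np.ndarray, np.ndarray]:
    """Unfold the image along the lumen border.

    Column c of the result holds intensity rows border[c]+1 .. border[c]+100;
    rows past the image bottom are zero-padded.  Returns (aline_matrix of
    shape (100, n_angle), per-column pad counts).  A border at the last row
    yields a fully padded A-line (flagged by pad_count=100, not an error).
    """
    nd, na = image.n_depth, image.n_angle
    out = np.zeros((ALINE_LEN, na))
    pads = np.zeros(na, dtype=int)
    for c in range(na):
        start = int(image.border[c]) + 1
        avail = max(0, min(ALINE_LEN, nd - start))
        if avail > 0:
            out[:avail, c] = image.intensity[start : start + avail, c]
        pads[c] = ALINE_LEN - avail
    return out, pads


def aline(image: PolarOCTImage, column: int) -> ALine:
    """The A-line of one column."""
    mat, pads = unfold(image)
    return ALine(mat[:, column], column, int(pads[column]))


#: A-lines whose maximum lies below this are guidewire shadow ("close to the
#: zero line") and bypass the network.
GS_THRESHOLD = 0.08


def classify_aline(values, stack: sae_mod.StackedSAE, gs_threshold: float = GS_THRESHOLD) -> str:
    """Tissue label of one A-line: GS pre-filter, then SoftMax argmax."""
    values = np.asarray(values, dtype=float)
    if float(values.max(initial=0.0)) < gs_threshold:
        return "GS"
    if stack is None or not stack.has_head:
        raise sae_mod.SAEError("A-line classifier stack is untrained (no head)")
    label, _ = sae_mod.classify(stack, values)
    return str(label)


def classify_alines(
    aline_matrix: np.ndarray, stack: sae_mod.StackedSAE, gs_threshold: float = GS_THRESHOLD
) -> np.ndarray:
    """Per-column tissue labels for an unfolded (100, n_angle) matrix."""
    na = aline_matrix.shape[1]
    labels = np.full(na, "GS", dtype="<U3")
    maxes = aline_matrix.max(axis=0)
    net_cols = np.where(maxes >= gs_threshold)[0]
    if net_cols.size:
        if stack is None or not stack.has_head:
            raise sae_mod.SAEError("A-line classifier stack is untrained (no head)")
        pred, _ = sae_mod.classify_batch(stack, aline_matrix[:, net_cols].T)
        labels[net_cols] = pred
    return labels


# ---------------------------------------------------------------------------
# region generation


def _circular_majority(labels: np.ndarray, width: int = 5) -> np.ndarray:
    """Majority filter over a circular window; ties keep the center label."""
    n = len(labels)
    half = width // 2
    out = labels.copy()
    for i in range(n):
        window = [labels[(i + d) % n] for d in range(-half, half + 1)]
        vals, counts = np.unique(window, return_counts=True)
        best = counts.max()
        winners = set(vals[counts == best])
        if labels[i] in winners:
            out[i] = labels[i]
        else:
            out[i] = sorted(winners)[0]
    return out


def _circular_runs(labels: np.ndarray) -> list[list]:
    """Maximal circular runs as [start, length, label]; a run crossing the
    seam is reported once with start near the end of the axis."""
    n = len(labels)
    if n == 0:
        return []
    if all(l == labels[0] for l in labels):
        return [[0, n, labels[0]]]
    # rotate so position 0 starts a run
    start0 = 0
    while labels[start0 - 1] == labels[start0]:
        start0 -= 1  # negative indexing walks back across the seam
    start0 %= n
    runs = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[(start0 + j) % n] == labels[(start0 + i) % n]:
            j += 1
        runs.append([(start0 + i) % n, j - i, labels[(start0 + i) % n]])
        i = j
    return runs


def generate_regions(
    labels, n_angle: int | None = None, min_run: int = 8, majority_width: int = 5
) -> list[PlaqueRegion]:
    """Group per-column tissue labels into circular plaque regions.

    A circular majority filter (width 5) smooths the labels, then runs
    shorter than min_run columns are merged into their larger neighbor
    (ties go to the following neighbor).  GS runs are excluded from the
    returned regions; wrap-around runs are joined across the 0 seam.
    """
    labels = np.asarray(labels, dtype="<U3")
    n = len(labels) if n_angle is None else n_angle
    if len(labels) != n:
        raise ValueError("one label per column required")
    if n == 0:
        return []
    smoothed = _circular_majority(labels, majority_width)
    runs = _circular_runs(smoothed)
    # absorb short runs into the larger neighbor, repeatedly
    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[1] for r in runs]
        order = int(np.argmin(lengths))
        if lengths[order] < min_run:
            prev = runs[(order - 1) % len(runs)]
            nxt = runs[(order + 1) % len(runs)]
            target = nxt if nxt[1] >= prev[1] else prev
            target_label = target[2]
            runs[order][2] = target_label
            # merge adjacent equal-label runs
            merged: list[list] = []
            for r in runs:
                if merged and merged[-1][2] == r[2] and (merged[-1][0] + merged[-1][1]) % n == r[0]:
                    merged[-1][1] += r[1]
                else:
                    merged.append(r)
            if len(merged) > 1 and merged[0][2] == merged[-1][2] and (
                (merged[-1][0] + merged[-1][1]) % n == merged[0][0]
            ):
                merged[-1][1] += merged[0][1]
                merged.pop(0)
            runs = merged
            changed = True
    regions = []
    for start, length, lab in runs:
        if lab == "GS":
            continue
        regions.append(PlaqueRegion(start_col=start, end_col=start + length, tissue_class=str(lab)))
    regions.sort(key=lambda r: r.start_col)
    return regions


# ---------------------------------------------------------------------------
# cap thickness


def cap_thickness(
    image: PolarOCTImage, region: PlaqueRegion, thin_cap_um: float = 65.0
) -> tuple[np.ndarray, PlaqueRegion]:
    """Fibrous-cap thickness per column of a fibro-lipid region.

    Per column the thickness is pixel_pitch_um times the first depth index at
    which the A-line drops below 50% of its cap plateau (the A-line maximum).
    Columns with no drop point get 100 * pixel_pitch_um (cap exceeds the
    unfolded window).  Returns (per-column thickness in um, region updated
    with min_cap_thickness_um and the vulnerable flag).
    """
    if region.tissue_class != "F-L":
        raise ValueError("cap thickness is defined for fibro-lipid (F-L) regions")
    mat, _ = unfold(image)
    cols = region.columns(image.n_angle)
    thick = np.empty(len(cols))
    for i, c in enumerate(cols):
        prof = mat[:, c]
        plateau = prof.max()
        if plateau <= 0:
            thick[i] = ALINE_LEN * image.pixel_pitch_um
            continue
        below = np.where(prof < 0.5 * plateau)[0]
        if below.size == 0:
            thick[i] = ALINE_LEN * image.pixel_pitch_um
        else:
            thick[i] = float(below[0]) * image.pixel_pitch_um
    min_cap = float(thick.min()) if len(cols) else float("nan")
    updated = replace(
        region,
        min_cap_thickness_um=min_cap,
        vulnerable=bool(min_cap < thin_cap_um),
    )
    return thick, updated


# ---------------------------------------------------------------------------
# segmentation metrics


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded).astype(float)


def seg_metrics(pred_mask, gold_mask) -> SegMetrics:
    """Dice, Jaccard, Hausdorff (boundary, pixels), precision and recall.

    Conventions for empty masks: both empty -> dice=jaccard=precision=
    recall=1, hausdorff=0; exactly one empty -> all overlap metrics 0 and
    hausdorff equal to the image diagonal.
    """
    A = np.asarray(pred_mask, dtype=bool)
    B = np.asarray(gold_mask, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    a, b = int(A.sum()), int(B.sum())
    if a == 0 and b == 0:
        return SegMetrics(1.0, 1.0, 0.0, 1.0, 1.0)
    diag = float(np.sqrt(sum((s - 1) ** 2 for s in A.shape))) if A.ndim else 0.0
    if a == 0 or b == 0:
        return SegMetrics(0.0, 0.0, diag, 0.0, 0.0)
    inter = int(np.sum(A & B))
    union = int(np.sum(A | B))
    dice = 2.0 * inter / (a + b)
    jac = inter / union
    prec = inter / a
    rec = inter / b
    pa, pb = _boundary_points(A), _boundary_points(B)
    h = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return SegMetrics(dice, jac, float(h), prec, rec)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class OCTAnalysisConfig:
    gs_threshold: float = GS_THRESHOLD
    thin_cap_um: float = 65.0
    min_run: int = 8
    majority_width: int = 5


@dataclass
class OCTReport:
    labels: np.ndarray  # per-column predicted tissue labels (post-smoothing labels of the regions are in `regions`)
    regions: list[PlaqueRegion]
    vulnerable_mask: np.ndarray  # bool per column
    cap_thickness_um: dict[int, float] = field(default_factory=dict)  # column -> um (F-L columns)
    metrics: SegMetrics | None = None

    def per_column_rows(self):
        """(column, label, cap_um or '', vulnerable) rows for CSV export."""
        na = len(self.labels)
        region_label = np.array(self.labels, dtype="<U3")
        for r in self.regions:
            region_label[r.columns(na)] = r.tissue_class
        for c in range(na):
            yield (
                c,
                str(region_label[c]),
                self.cap_thickness_um.get(c, ""),
                bool(self.vulnerable_mask[c]),
            )


def analyze_image(
    image: PolarOCTImage,
    stack: sae_mod.StackedSAE,
    config: OCTAnalysisConfig | None = None,
    gold_vulnerable_mask=None,
) -> OCTReport:
    """Unfold -> classify A-lines -> group regions -> cap thickness -> TCFA.

    Deterministic for fixed inputs.  When a ground-truth vulnerable-column
    mask is given, Dice/Jaccard/Hausdorff/precision/recall of the predicted
    vulnerable columns are attached.
    """
    config = config or OCTAnalysisConfig()
    mat, _ = unfold(image)
    labels = classify_alines(mat, stack, config.gs_threshold)
    regions = generate_regions(labels, image.n_angle, config.min_run, config.majority_width)
    vulnerable = np.zeros(image.n_angle, dtype=bool)
    caps: dict[int, float] = {}
    out_regions = []
    for reg in regions:
        if reg.tissue_class == "F-L":
            thick, reg = cap_thickness(image, reg, config.thin_cap_um)
            for c, t in zip(reg.columns(image.n_angle), thick):
                caps[int(c)] = float(t)
            if reg.vulnerable:
                vulnerable[reg.columns(image.n_angle)] = True
        out_regions.append(reg)
    metrics = None
    if gold_vulnerable_mask is not None:
        metrics = seg_metrics(vulnerable, gold_vulnerable_mask)
    return OCTReport(labels, out_regions, vulnerable, caps, metrics)
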