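"""Seeded synthetic generators: ECG beats/records, pre-SCD windows, OCT phantoms.

Every generator is a pure function of its arguments and a seed, so all
downstream stages are testable without any external recording.

Beats are modelled as sums of Gaussian bumps (ECGSYN-style morphology), one
per P/Q/R/S/T component, with per-class parameter tables.  Six beat classes
are covered: normal (N), atrial premature (AP), premature ventricular
contraction (PVC), right/left bundle branch block (RBBB/LBBB), and paced
(PACE).  The classes are designed so that N and AP differ mainly in the
P wave (a small-amplitude component, hence the hardest distinction), the
wide-QRS classes (PVC/RBBB/LBBB) share a QRS at least 1.5x the normal width
but differ in notch/T-wave polarity, and PACE carries a narrow pacing spike.

Pre-sudden-cardiac-death windows emulate a morphology drift that grows as
onset approaches: QRS widening, R-amplitude decay and an added 4-7 Hz
oscillation, each proportional to drift_severity * (6-k)/5 for a window
taken k minutes before onset.  This mimics a qualitative statistical
structure, not clinical reality.

Polar OCT phantoms carry per-column depth profiles below a lumen border with
four signatures: fibrous (bright plateau, slow decay), fibro-calcified
(bright cap, sharp drop to a low sharply-bordered pool), fibro-lipid
(moderate flat cap, then rapid diffuse attenuation) and guidewire shadow
(essentially zero).  Ground-truth column labels and a thin-cap vulnerable
mask are returned alongside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .octplaque import PolarOCTImage

__all__ = [
    "BEAT_CLASSES",
    "BEAT_WINDOW",
    "R_OFFSET",
    "DEFAULT_FS",
    "BeatTemplate",
    "ECGRecord",
    "OCTPhantomSpec",
    "UnknownBeatClassError",
    "beat_template",
    "gen_beat",
    "gen_record",
    "gen_scd_windows",
    "gen_oct_phantom",
]

BEAT_CLASSES = ("N", "AP", "PVC", "RBBB", "LBBB", "PACE")
BEAT_WINDOW = 250  # samples per beat vector
R_OFFSET = 100  # samples before the R peak inside the window
DEFAULT_FS = 360.0  # Hz


class UnknownBeatClassError(ValueError):
    """Raised for a beat class outside the six supported ones."""


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians beat morphology.

    wave_params: tuple of (center_s, width_s, amplitude_mV) Gaussian bumps
    rr_scale   : prematurity factor applied to the preceding RR interval
    spike      : optional (amplitude_mV, width_s) pacing artifact
    spike_offset_s : spike center relative to the R peak
    """

    beat_class: str
    wave_params: tuple[tuple[float, float, float], ...]
    rr_scale: float = 1.0
    spike: tuple[float, float] | None = None
    spike_offset_s: float = -0.055


# Per-class morphology table (centers s relative to R, widths s, amplitudes mV).
# N and AP share everything except the P wave; PVC/RBBB/LBBB have QRS >= 1.5x
# the normal width under a 10%-of-R threshold scan; PACE carries a spike.
_TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate(
        "N",
        (
            (-0.22, 0.028, 0.15),  # P
            (-0.035, 0.010, -0.12),  # Q
            (0.0, 0.012, 1.00),  # R
            (0.035, 0.010, -0.25),  # S
            (0.22, 0.055, 0.35),  # T
        ),
    ),
    "AP": BeatTemplate(
        "AP",
        (
            (-0.16, 0.020, 0.06),  # altered, low-amplitude early P
            (-0.035, 0.010, -0.12),
            (0.0, 0.012, 1.00),
            (0.035, 0.010, -0.25),
            (0.22, 0.055, 0.35),
        ),
        rr_scale=0.72,
    ),
    "PVC": BeatTemplate(
        "PVC",
        (
            (-0.06, 0.018, -0.15),
            (0.0, 0.038, 1.15),  # wide ectopic R
            (0.07, 0.022, -0.35),
            (0.30, 0.070, -0.45),  # discordant T
        ),
        rr_scale=0.85,
    ),
    "RBBB": BeatTemplate(
        "RBBB",
        (
            (-0.22, 0.028, 0.15),
            (-0.035, 0.010, -0.10),
            (0.0, 0.012, 0.90),
            (0.055, 0.024, 0.55),  # R' notch
            (0.24, 0.060, 0.25),
        ),
    ),
    "LBBB": BeatTemplate(
        "LBBB",
        (
            (-0.22, 0.028, 0.12),
            (0.0, 0.030, 0.95),  # broad slurred R
            (0.045, 0.030, 0.45),
            (0.25, 0.060, -0.30),  # discordant T
        ),
    ),
    "PACE": BeatTemplate(
        "PACE",
        (
            (0.0, 0.034, 0.85),  # broad paced QRS
            (0.26, 0.060, -0.35),
        ),
        spike=(1.40, 0.0035),
        spike_offset_s=-0.055,
    ),
}


def beat_template(beat_class: str) -> BeatTemplate:
    """The library template for one of the six beat classes."""
    try:
        return _TEMPLATES[beat_class]
    except KeyError:
        raise UnknownBeatClassError(
            f"unknown beat class {beat_class!r}; expected one of {BEAT_CLASSES}"
        ) from None


@dataclass
class ECGRecord:
    """Single-lead ECG record: samples (mV), sampling rate and annotations."""

    samples: np.ndarray
    fs: float
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation index outside record")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _eval_template(template: BeatTemplate, t: np.ndarray, rng, jitter: float) -> np.ndarray:
    """Evaluate a (possibly jittered) template on time axis t (s, 0 = R)."""
    y = np.zeros_like(t)
    for center, width, amp in template.wave_params:
        if jitter > 0:
            amp = amp * (1.0 + jitter * rng.standard_normal())
            center = center + jitter * width * rng.standard_normal()
            width = width * max(1.0 + jitter * rng.standard_normal(), 0.2)
        y += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    if template.spike is not None:
        amp, width = template.spike
        center = template.spike_offset_s
        if jitter > 0:
            amp = amp * (1.0 + jitter * rng.standard_normal())
            center = center + jitter * width * rng.standard_normal()
        y += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    return y


def gen_beat(
    template: BeatTemplate | str,
    fs: float = DEFAULT_FS,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """One fixed-length beat vector (250 samples, R at offset 100).

    With jitter=0 the result is exactly the noiseless sum-of-Gaussians
    template waveform; otherwise each Gaussian's amplitude, center and width
    are perturbed by the fractional jitter, deterministically per seed.
    """
    if isinstance(template, str):
        template = beat_template(template)
    elif template.beat_class not in BEAT_CLASSES:
        raise UnknownBeatClassError(
            f"unknown beat class {template.beat_class!r}; expected one of {BEAT_CLASSES}"
        )
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    t = (np.arange(BEAT_WINDOW) - R_OFFSET) / fs
    return _eval_template(template, t, rng, jitter)


def gen_record(
    n_beats: int,
    class_mix,
    fs: float = DEFAULT_FS,
    noise_sd: float = 0.0,
    seed: int = 0,
    jitter: float = 0.0,
    rr_base_s: float = 0.75,
    rr_sd_s: float = 0.03,
) -> ECGRecord:
    """Annotated ECG record with beats drawn from a six-class mixture.

    RR intervals are Gaussian around rr_base_s, scaled by each beat's
    prematurity factor; baseline wander (amplitude 3 * noise_sd, ~0.25 Hz)
    and white noise of sd noise_sd are added, so noise_sd=0 gives an exactly
    clean record.
    """
    class_mix = np.asarray(class_mix, dtype=float)
    if class_mix.shape != (len(BEAT_CLASSES),):
        raise ValueError(f"class_mix must have {len(BEAT_CLASSES)} entries")
    if abs(class_mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    if n_beats == 0:
        return ECGRecord(np.zeros(0), fs, [])

    classes = rng.choice(len(BEAT_CLASSES), size=n_beats, p=class_mix)
    labels = [BEAT_CLASSES[c] for c in classes]

    # R-peak times: cumulative RR intervals, scaled by prematurity
    r_times = []
    t = 0.45  # lead-in before the first beat
    for lab in labels:
        r_times.append(t)
        rr = max(0.40, rng.normal(rr_base_s * beat_template(lab).rr_scale, rr_sd_s))
        t += rr
    total_s = r_times[-1] + 0.6
    n = int(np.ceil(total_s * fs))
    tt = np.arange(n) / fs
    sig = np.zeros(n)
    support = 0.45  # beat waveform support half-width (s)
    for rt, lab in zip(r_times, labels):
        lo = max(0, int((rt - support) * fs))
        hi = min(n, int((rt + support) * fs) + 1)
        sig[lo:hi] += _eval_template(beat_template(lab), tt[lo:hi] - rt, rng, jitter)
    if noise_sd > 0:
        phase = rng.uniform(0, 2 * np.pi)
        f_w = rng.uniform(0.2, 0.35)
        sig += 3.0 * noise_sd * np.sin(2 * np.pi * f_w * tt + phase)
        sig += noise_sd * rng.standard_normal(n)
    ann = [(int(round(rt * fs)), lab) for rt, lab in zip(r_times, labels)]
    return ECGRecord(sig, fs, ann)


# ---------------------------------------------------------------------------
# pre-SCD windows


def _drifted_template(base: BeatTemplate, m: float, rng) -> BeatTemplate:
    """Widen QRS components and decay amplitudes by drift magnitude m in [0,1]."""
    wf = 1.0 + 0.8 * m * (1.0 + 0.15 * rng.standard_normal())
    af = 1.0 - 0.35 * m * (1.0 + 0.15 * rng.standard_normal())
    waves = []
    for center, width, amp in base.wave_params:
        if abs(center) < 0.09:  # QRS-region components
            waves.append((center * wf, width * wf, amp * af))
        else:
            waves.append((center, width, amp * af))
    return replace(base, wave_params=tuple(waves))


def gen_scd_windows(
    n_pairs: int,
    window_s: float = 60.0,
    fs: float = DEFAULT_FS,
    drift_severity: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> list[tuple[ECGRecord, ECGRecord, int]]:
    """Paired (non-SCD, pre-SCD, minutes_before_onset) ECG windows.

    The pre-SCD window at k minutes before onset carries a drift of magnitude
    drift_severity * (6-k)/5: QRS widening, R-amplitude decay and an added
    4-7 Hz oscillation.  Non-SCD windows are stationary normal rhythm.
    With drift_severity=0 both windows come from the same distribution.
    """
    if window_s * fs < BEAT_WINDOW:
        raise ValueError("window shorter than one beat")
    if not (0.0 <= drift_severity <= 1.0):
        raise ValueError("drift_severity must lie in [0,1]")
    rng = np.random.default_rng(seed)
    base = beat_template("N")
    out = []
    n_beats = int(np.ceil(window_s / 0.6)) + 2
    for i in range(n_pairs):
        k = (i % 5) + 1
        m = drift_severity * (6 - k) / 5.0

        def _window(drift_m, sub):
            r = np.random.default_rng([seed, i, sub])
            n_samp = int(window_s * fs)
            tt = np.arange(n_samp) / fs
            sig = np.zeros(n_samp)
            t = 0.3
            anns = []
            while t < window_s - 0.4:
                tpl = _drifted_template(base, drift_m, r) if drift_m > 0 else base
                lo = max(0, int((t - 0.45) * fs))
                hi = min(n_samp, int((t + 0.45) * fs) + 1)
                sig[lo:hi] += _eval_template(tpl, tt[lo:hi] - t, r, 0.03)
                anns.append((int(round(t * fs)), "N"))
                t += max(0.4, r.normal(0.8, 0.04))
            if drift_m > 0:
                f_osc = r.uniform(4.0, 7.0)
                sig += 0.18 * drift_m * np.sin(2 * np.pi * f_osc * tt + r.uniform(0, 2 * np.pi))
            if noise_sd > 0:
                sig += 3.0 * noise_sd * np.sin(
                    2 * np.pi * r.uniform(0.2, 0.35) * tt + r.uniform(0, 2 * np.pi)
                )
                sig += noise_sd * r.standard_normal(n_samp)
            anns = [(a, c) for a, c in anns if a < n_samp]
            return ECGRecord(sig, fs, anns)

        out.append((_window(0.0, 0), _window(m, 1), k))
    return out


# ---------------------------------------------------------------------------
# OCT phantoms


@dataclass
class OCTPhantomSpec:
    """Geometry and tissue layout of a polar OCT phantom.

    arcs: list of (start_col, end_col, tissue_class in {F, F-C, F-L},
    cap_thickness_um); half-open column spans, non-overlapping.  Columns not
    covered by an arc or the guidewire default to fibrous (F) wall tissue.
    """

    n_depth: int = 200
    n_angle: int = 360
    pixel_pitch_um: float = 10.0
    arcs: list[tuple[int, int, str, float]] = field(default_factory=list)
    guidewire: tuple[int, int] | None = None
    border_profile: np.ndarray | None = None
    noise_sd: float = 0.0
    thin_cap_um: float = 65.0

    def validate(self) -> None:
        spans = [(s, e) for s, e, _, _ in self.arcs]
        if self.guidewire is not None:
            spans.append(self.guidewire)
        for s, e in spans:
            if not (0 <= s < e <= self.n_angle):
                raise ValueError(f"invalid arc span ({s}, {e})")
        for i, (s1, e1) in enumerate(spans):
            for s2, e2 in spans[i + 1 :]:
                if s1 < e2 and s2 < e1:
                    raise ValueError("arcs overlap")
        for _, _, cls, _ in self.arcs:
            if cls not in ("F", "F-C", "F-L"):
                raise ValueError(f"unknown tissue class {cls!r}")
        if self.border_profile is not None:
            b = np.asarray(self.border_profile)
            if b.shape != (self.n_angle,):
                raise ValueError("border_profile must have one row index per column")
            if b.min() < 0 or b.max() >= self.n_depth - 1:
                raise ValueError("border rows must satisfy 0 <= row < n_depth - 1")


def _class_profile(cls: str, depth: np.ndarray, cap_px: int) -> np.ndarray:
    """Noiseless depth-intensity signature below the border (depth index 0 =
    first pixel under the lumen border)."""
    if cls == "F":
        # bright plateau then slow exponential decay
        return np.where(depth < 25, 0.75, 0.75 * np.exp(-(depth - 25) / 50.0))
    if cls == "F-C":
        # bright cap, sharp drop into a low, sharply bordered calcium pool
        out = np.full_like(depth, 0.03, dtype=float)
        out[depth < cap_px + 30] = 0.12
        out[depth < cap_px] = 0.85
        return out
    if cls == "F-L":
        # moderate flat cap, then rapid diffuse attenuation (drops below half
        # the cap level immediately, so the 50%-rule recovers cap_px exactly)
        out = 0.22 * np.exp(-(depth - cap_px) / 12.0)
        out[depth < cap_px] = 0.55
        return out
    if cls == "GS":
        return np.zeros_like(depth, dtype=float)
    raise ValueError(f"unknown tissue class {cls!r}")


def gen_oct_phantom(
    spec: OCTPhantomSpec, seed: int = 0
) -> tuple[PolarOCTImage, np.ndarray, np.ndarray]:
    """Polar OCT phantom with ground truth.

    Returns (image, per-column tissue labels in {F, F-C, F-L, GS},
    boolean per-column vulnerable mask).  The vulnerable mask covers the
    columns of F-L arcs whose cap_thickness_um < spec.thin_cap_um.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    nd, na = spec.n_depth, spec.n_angle
    if spec.border_profile is None:
        border = np.round(30 + 8 * np.sin(2 * np.pi * np.arange(na) / na)).astype(int)
    else:
        border = np.asarray(spec.border_profile, dtype=int).copy()

    labels = np.full(na, "F", dtype="<U3")
    caps = np.full(na, 200.0)  # background fibrous tissue: cap irrelevant
    for s, e, cls, cap in spec.arcs:
        labels[s:e] = cls
        caps[s:e] = cap
    if spec.guidewire is not None:
        s, e = spec.guidewire
        labels[s:e] = "GS"

    img = np.zeros((nd, na))
    for c in range(na):
        b = border[c]
        depth = np.arange(nd - b - 1)
        cap_px = int(round(caps[c] / spec.pixel_pitch_um))
        img[b + 1 :, c] = _class_profile(str(labels[c]), depth, cap_px)
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0)

    vulnerable = np.zeros(na, dtype=bool)
    for s, e, cls, cap in spec.arcs:
        if cls == "F-L" and cap < spec.thin_cap_um:
            vulnerable[s:e] = True

    image = PolarOCTImage(intensity=img, border=border, pixel_pitch_um=spec.pixel_pitch_um)
    return image, labels, vulnerable
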