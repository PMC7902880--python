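"""Shared I/O, configuration, seed fan-out and run manifests.

Records travel as two UTF-8 CSV files with '.' decimals:

    <name>.csv      # fs: <Hz>
                    sample_index,mV
                    0,0.0123...
    <name>.ann.csv  sample_index,beat_class

Float samples are written with repr (shortest round-trip), so
write -> read is the identity on values and annotations.

Phantoms are written as 16-bit grayscale PNG plus a per-column sidecar CSV
(border row, tissue label, vulnerable flag); re-reading quantizes
intensities to 16 bits.

Seeds: one master seed deterministically derives every module seed via
SHA-256 of "<master>:<stage>" reduced modulo 2^31 (documented fan-out), and
a RunManifest snapshots config, seeds, input digests and per-stage metrics
so every reported number is reproducible.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .esn import ESNConfig
from .octplaque import OCTAnalysisConfig, PolarOCTImage
from .sae import SAEHyper
from .synthgen import BEAT_CLASSES, ECGRecord

__all__ = [
    "TOOLKIT_VERSION",
    "RecordFormatError",
    "ConfigError",
    "Config",
    "SynthConfig",
    "RunManifest",
    "read_record",
    "write_record",
    "read_phantom",
    "write_phantom",
    "load_config",
    "stage_seed",
    "file_digest",
    "metrics_report",
]

TOOLKIT_VERSION = "0.1.0"


class RecordFormatError(ValueError):
    """Malformed record file; the message cites the offending line."""


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


# ---------------------------------------------------------------------------
# ECG record CSV I/O


def write_record(record: ECGRecord, path) -> None:
    """Write `<path>.csv` and `<path>.ann.csv` (path may omit the suffix)."""
    base = Path(str(path)[:-4] if str(path).endswith(".csv") else str(path))
    with open(base.with_suffix(".csv"), "w", encoding="utf-8", newline="") as f:
        f.write(f"# fs: {record.fs!r}\n")
        f.write("sample_index,mV\n")
        for i, v in enumerate(record.samples):
            f.write(f"{i},{float(v)!r}\n")
    with open(str(base) + ".ann.csv", "w", encoding="utf-8", newline="") as f:
        f.write("sample_index,beat_class\n")
        for i, c in record.annotations:
            f.write(f"{i},{c}\n")


def read_record(path) -> ECGRecord:
    """Read a record written by write_record.  A missing or empty annotation
    file yields a record with no annotations."""
    base = Path(str(path)[:-4] if str(path).endswith(".csv") else str(path))
    csv_path = base.with_suffix(".csv")
    fs = None
    samples = []
    with open(csv_path, encoding="utf-8") as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs:" in line:
                    try:
                        fs = float(line.split("fs:")[1].strip())
                    except ValueError:
                        raise RecordFormatError(
                            f"{csv_path}: line {lineno}: malformed fs header"
                        ) from None
                continue
            if line.lower().startswith("sample_index"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise RecordFormatError(f"{csv_path}: line {lineno}: expected 2 fields")
            try:
                idx = int(parts[0])
                val = float(parts[1])
            except ValueError:
                raise RecordFormatError(
                    f"{csv_path}: line {lineno}: non-numeric sample"
                ) from None
            if idx != len(samples):
                raise RecordFormatError(
                    f"{csv_path}: line {lineno}: non-consecutive sample_index"
                )
            samples.append(val)
    if fs is None:
        raise RecordFormatError(f"{csv_path}: missing '# fs:' header line")
    ann_path = Path(str(base) + ".ann.csv")
    annotations: list[tuple[int, str]] = []
    if ann_path.exists():
        with open(ann_path, encoding="utf-8") as f:
            for lineno, line in enumerate(f, start=1):
                line = line.strip()
                if not line or line.lower().startswith("sample_index"):
                    continue
                parts = line.split(",")
                if len(parts) != 2:
                    raise RecordFormatError(f"{ann_path}: line {lineno}: expected 2 fields")
                try:
                    idx = int(parts[0])
                except ValueError:
                    raise RecordFormatError(
                        f"{ann_path}: line {lineno}: non-integer sample_index"
                    ) from None
                annotations.append((idx, parts[1]))
    return ECGRecord(np.asarray(samples), fs, annotations)


# ---------------------------------------------------------------------------
# phantom I/O (16-bit grayscale PNG + sidecar CSV)


def write_phantom(
    image: PolarOCTImage, labels, vulnerable, base_path
) -> tuple[Path, Path]:
    import imageio.v3 as iio

    base = Path(base_path)
    png = base.with_suffix(".png")
    sidecar = Path(str(base) + ".columns.csv")
    data = np.clip(np.round(image.intensity * 65535.0), 0, 65535).astype(np.uint16)
    iio.imwrite(png, data)
    with open(sidecar, "w", encoding="utf-8", newline="") as f:
        w = csv.writer(f)
        w.writerow(["column", "border_row", "tissue_label", "vulnerable", "pixel_pitch_um"])
        for c in range(image.n_angle):
            w.writerow(
                [c, int(image.border[c]), str(labels[c]), int(bool(vulnerable[c])), image.pixel_pitch_um]
            )
    return png, sidecar


def read_phantom(base_path) -> tuple[PolarOCTImage, np.ndarray, np.ndarray]:
    import imageio.v3 as iio

    base = Path(base_path)
    data = iio.imread(base.with_suffix(".png"))
    intensity = data.astype(float) / 65535.0
    rows = []
    with open(str(base) + ".columns.csv", encoding="utf-8") as f:
        for row in csv.DictReader(f):
            rows.append(row)
    border = np.array([int(r["border_row"]) for r in rows])
    labels = np.array([r["tissue_label"] for r in rows], dtype="<U3")
    vulnerable = np.array([bool(int(r["vulnerable"])) for r in rows])
    pitch = float(rows[0]["pixel_pitch_um"]) if rows else 10.0
    return PolarOCTImage(intensity, border, pitch), labels, vulnerable


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SynthConfig:
    n_beats: int = 100
    class_mix: tuple[float, ...] = tuple([1.0 / 6] * 6)
    fs: float = 360.0
    noise_sd: float = 0.02
    jitter: float = 0.05
    n_pairs: int = 20
    window_s: float = 60.0
    drift_severity: float = 1.0
    n_phantoms: int = 5
    phantom_noise_sd: float = 0.0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ConfigError("class_mix must sum to 1")
        if self.noise_sd < 0 or self.jitter < 0:
            raise ConfigError("noise_sd and jitter must be >= 0")


@dataclass(frozen=True)
class Config:
    sae: SAEHyper = field(default_factory=SAEHyper)
    sae_hidden_dims: tuple[int, ...] = (120, 60, 30, 15)
    oct_hidden_dims: tuple[int, ...] = (60, 30, 15)
    esn: ESNConfig = field(default_factory=ESNConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    oct: OCTAnalysisConfig = field(default_factory=OCTAnalysisConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sae_hidden_dims"] = list(self.sae_hidden_dims)
        d["oct_hidden_dims"] = list(self.oct_hidden_dims)
        d["synth"] = asdict(self.synth)
        d["synth"]["class_mix"] = list(self.synth.class_mix)
        return d


_SECTION_TYPES = {
    "sae": SAEHyper,
    "esn": ESNConfig,
    "synth": SynthConfig,
    "oct": OCTAnalysisConfig,
}

_TOP_SCALARS = {"sae_hidden_dims": tuple, "oct_hidden_dims": tuple}


def load_config(path=None) -> Config:
    """Load and validate a YAML config; an empty/missing file gives the full
    defaults.  Unknown keys are rejected with the offending key named, and
    dataclass range checks (e.g. rho_target in (0,1)) are applied."""
    raw = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(cls)}
            for sub in value:
                if sub not in valid:
                    raise ConfigError(f"unknown config key {key}.{sub}")
            if cls is SynthConfig and "class_mix" in value:
                value = dict(value, class_mix=tuple(value["class_mix"]))
            try:
                kwargs[key] = cls(**value)
            except (ValueError, TypeError) as e:
                raise ConfigError(f"invalid value in section {key!r}: {e}") from e
        elif key in _TOP_SCALARS:
            kwargs[key] = tuple(value)
        else:
            raise ConfigError(f"unknown config key {key}")
    return Config(**kwargs)


# ---------------------------------------------------------------------------
# seeds, digests, manifests, reports


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of '<master>:<stage>' mod 2^31."""
    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**31)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Snapshot that makes a run's numbers reproducible."""

    master_seed: int
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    toolkit_version: str = TOOLKIT_VERSION
    stage_metrics: dict = field(default_factory=dict)

    def derive_seed(self, stage: str) -> int:
        s = stage_seed(self.master_seed, stage)
        self.seeds[stage] = s
        return s

    def record_input(self, name: str, path) -> None:
        self.input_digests[name] = file_digest(path)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _round_floats(obj, sig=6):
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (int, str)) or obj is None:
        return obj
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def metrics_report(metrics: dict, manifest: RunManifest | None = None) -> str:
    """Serialize stage metrics as a stable JSON document: sorted keys,
    floats at 6 significant digits, manifest digest included."""
    doc = {"metrics": _round_floats(metrics)}
    if manifest is not None:
        doc["manifest_digest"] = manifest.digest
        doc["toolkit_version"] = manifest.toolkit_version
    else:
        doc["toolkit_version"] = TOOLKIT_VERSION
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"
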