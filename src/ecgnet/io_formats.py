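"""ECG record and dataset I/O.

Readers return records in a fixed canonical lead order (I, II, III, aVR,
aVL, aVF, V1..V6) because the model and every attribution output index leads
positionally.  WFDB support covers the header + 16-bit signal layout used by
the PhysioNet PTB diagnostic database; delimited-text matrices and an
internal binary-bundle dataset format round out the surface.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CANONICAL_LEADS",
    "LOCALIZATION_CLASSES",
    "DETECTION_CLASSES",
    "FormatError",
    "EcgRecord",
    "LabelTaxonomy",
    "BeatDataset",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_matrix_record",
    "write_matrix_record",
    "save_dataset",
    "load_dataset",
]

#: Standard 12-lead montage, the positional convention for all model inputs.
CANONICAL_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                   "V1", "V2", "V3", "V4", "V5", "V6")

#: Healthy controls plus the ten infarct localizations.
LOCALIZATION_CLASSES = ("H", "A", "AL", "AS", "I", "IL", "IP", "IPL", "L", "P", "PL")

#: Binary detection taxonomy: healthy controls vs any infarct.
DETECTION_CLASSES = ("HC", "MI")

_LEAD_LOOKUP = {name.upper(): name for name in CANONICAL_LEADS}

DATASET_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


def normalize_lead_name(name: str) -> str | None:
    """Map e.g. ``'AVL'`` or ``'avl'`` to ``'aVL'``; None if not a 12-lead name."""
    return _LEAD_LOOKUP.get(name.strip().upper())


@dataclass
class EcgRecord:
    """A continuous multi-lead ECG signal.

    ``signal`` is (T samples, L leads) in millivolts; ``fs`` in Hz.
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple
    label: str | None = None
    record_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (samples x leads)")
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != self.signal.shape[1]:
            raise ValueError("lead_names length must match signal columns")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("duplicate lead names")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def is_model_ready(self) -> bool:
        """True when the record can feed the 651 x 12 model input."""
        return self.n_leads == 12 and self.n_samples >= 651

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signal[:, self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"lead {name!r} not present in record {self.record_id!r}")

    def resampled(self, fs: float) -> "EcgRecord":
        """Polyphase-resample to a new rate (window constants assume 1 kHz)."""
        if fs == self.fs:
            return self
        from fractions import Fraction

        from scipy.signal import resample_poly

        frac = Fraction(fs / self.fs).limit_denominator(1000)
        sig = resample_poly(self.signal, frac.numerator, frac.denominator, axis=0)
        return EcgRecord(sig, fs, self.lead_names, self.label, self.record_id,
                         dict(self.meta, resampled_from=self.fs))


class LabelTaxonomy:
    """Ordered class vocabulary with a name <-> index bijection."""

    def __init__(self, classes=LOCALIZATION_CLASSES):
        self.classes = tuple(classes)
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        self._index = {c: i for i, c in enumerate(self.classes)}

    @classmethod
    def localization(cls) -> "LabelTaxonomy":
        return cls(LOCALIZATION_CLASSES)

    @classmethod
    def detection(cls) -> "LabelTaxonomy":
        return cls(DETECTION_CLASSES)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"label {name!r} not in taxonomy {self.classes}")

    def decode(self, index: int) -> str:
        return self.classes[index]

    def __eq__(self, other):
        return isinstance(other, LabelTaxonomy) and self.classes == other.classes

    def __contains__(self, name):
        return name in self._index

    def __repr__(self):
        return f"LabelTaxonomy({list(self.classes)})"

    def collapse_to_detection(self, labels: np.ndarray, healthy: str = "H"):
        """Map localization indices to the binary HC/MI taxonomy."""
        healthy_idx = self.encode(healthy)
        det = LabelTaxonomy.detection()
        mapped = np.where(np.asarray(labels) == healthy_idx,
                          det.encode("HC"), det.encode("MI"))
        return mapped.astype(np.int64), det


@dataclass
class BeatDataset:
    """Fixed-geometry beat windows with integer labels.

    ``X`` is (N, T, L) float32 in mV, baseline-corrected, with the R-peak at
    a fixed row; ``y`` holds taxonomy indices.
    """

    X: np.ndarray
    y: np.ndarray
    taxonomy: LabelTaxonomy
    fs: float = 1000.0
    r_row: int = 250
    record_ids: list = field(default_factory=list)
    r_indices: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3:
            raise ValueError("X must be (beats, samples, leads)")
        if len(self.y) != len(self.X):
            raise ValueError("labels must match beat count")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def window_length(self) -> int:
        return self.X.shape[1]

    @property
    def n_leads(self) -> int:
        return self.X.shape[2]

    def subset(self, idx) -> "BeatDataset":
        idx = np.asarray(idx)
        return BeatDataset(
            self.X[idx], self.y[idx], self.taxonomy, self.fs, self.r_row,
            [self.record_ids[i] for i in idx] if self.record_ids else [],
            self.r_indices[idx] if self.r_indices is not None else None,
            dict(self.meta),
        )

    def class_counts(self) -> dict:
        counts = np.bincount(self.y, minlength=self.taxonomy.n_classes)
        return {c: int(n) for c, n in zip(self.taxonomy.classes, counts)}

    def as_detection(self, healthy: str = "H") -> "BeatDataset":
        y2, det = self.taxonomy.collapse_to_detection(self.y, healthy)
        return BeatDataset(self.X, y2, det, self.fs, self.r_row,
                           list(self.record_ids),
                           self.r_indices, dict(self.meta, collapsed="detection"))


# ---------------------------------------------------------------------------
# WFDB header + 16-bit signal files
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"^([0-9.eE+-]+)(?:\(([-0-9]+)\))?(?:/(\S+))?$")


def write_wfdb_record(record: EcgRecord, directory, name: str | None = None,
                      gain: float = 2000.0) -> Path:
    """Write a record as a WFDB header (.hea) + format-16 signal (.dat) pair.

    Samples are quantized to ``round(mV * gain)`` 16-bit integers, so the
    round-trip error is at most half a quantization step (1 / (2*gain) mV).
    Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or record.record_id or "record"
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    lines = [f"{name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    checksums = (adc.astype(np.int64).sum(axis=0) % 65536).astype(np.int64)
    checksums = np.where(checksums >= 32768, checksums - 65536, checksums)
    for j, lead in enumerate(record.lead_names):
        first = int(adc[0, j]) if record.n_samples else 0
        lines.append(
            f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} {int(checksums[j])} 0 {lead}"
        )
    if record.label is not None:
        lines.append(f"# label: {record.label}")
    header = directory / f"{name}.hea"
    header.write_text("\n".join(lines) + "\n")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())  # sample-major interleave
    return header


def read_wfdb_record(path, label_table: dict | None = None) -> EcgRecord:
    """Read a WFDB record (format-16 signals) given its .hea path or stem.

    Values are returned in millivolts in canonical lead order when all 12
    leads are present; otherwise the record keeps its native order and is
    flagged not model-ready.  A ``# label:`` header comment, when present,
    populates the record label; an entry in ``label_table`` (record name ->
    class name) takes precedence — header metadata is not a reliable class
    source in clinical archives, so an external table is authoritative.
    """
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FormatError(f"missing WFDB header file: {path}")
    lines = [ln.rstrip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty WFDB header: {path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line in {path}: {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if n_sig < 1:
        raise FormatError(f"{path}: record declares no signals")

    label = None
    sig_lines = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            m = re.search(r"#\s*label:\s*(\S+)", ln)
            if m:
                label = m.group(1)
            continue
        sig_lines.append(ln)
    if len(sig_lines) < n_sig:
        raise FormatError(f"{path}: header declares {n_sig} signals, found {len(sig_lines)}")

    gains, baselines, leads, dat_files = [], [], [], []
    for j, ln in enumerate(sig_lines[:n_sig]):
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"{path}: malformed signal line {j + 1}: {ln!r}")
        dat_files.append(parts[0])
        fmt = parts[1]
        if fmt.split("x")[0] != "16":
            raise FormatError(f"{path}: unsupported WFDB signal format {fmt!r} (only 16)")
        gain, baseline = 200.0, 0  # WFDB defaults
        if len(parts) > 2:
            m = _GAIN_RE.match(parts[2])
            if not m:
                raise FormatError(f"{path}: cannot parse gain field {parts[2]!r}")
            gain = float(m.group(1)) or 200.0
            baseline = int(m.group(2) or 0)
        gains.append(gain)
        baselines.append(baseline)
        leads.append(parts[-1] if len(parts) >= 9 else f"ch{j}")
    if len(set(dat_files)) != 1:
        raise FormatError(f"{path}: multi-file signal groups are not supported")

    dat_path = path.parent / dat_files[0]
    if not dat_path.exists():
        raise FormatError(f"missing WFDB signal file: {dat_path}")
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise FormatError(
            f"{dat_path}: expected {n_samples * n_sig} samples, file holds {raw.size}"
        )
    adc = raw[: n_samples * n_sig].reshape(n_samples, n_sig).astype(np.float64)
    signal = (adc - np.asarray(baselines)) / np.asarray(gains)

    if label_table and name in label_table:
        label = label_table[name]
    norm = [normalize_lead_name(l) or l for l in leads]
    record = EcgRecord(signal, fs, norm, label, name, {"source": str(path)})
    if set(norm) == set(CANONICAL_LEADS):
        perm = [norm.index(l) for l in CANONICAL_LEADS]
        record = EcgRecord(signal[:, perm], fs, CANONICAL_LEADS, label, name,
                           {"source": str(path), "lead_permutation": perm})
    else:
        warnings.warn(
            f"record {name!r} has {n_sig} lead(s) {norm}; not usable as 12-lead model input",
            stacklevel=2,
        )
    return record


# ---------------------------------------------------------------------------
# Delimited-text matrices
# ---------------------------------------------------------------------------

def read_matrix_record(path, fs: float = 1000.0, lead_names=CANONICAL_LEADS,
                       delimiter: str | None = None, label: str | None = None) -> EcgRecord:
    """Read a delimited text matrix: one column per lead, one row per sample."""
    path = Path(path)
    rows = []
    n_cols = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.replace(",", " ").split()
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise FormatError(
                    f"{path}: row {i} has {len(parts)} columns, expected {n_cols}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(f"{path}: non-numeric value at row {i}")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    signal = np.asarray(rows, dtype=np.float64)
    if len(lead_names) != signal.shape[1]:
        raise FormatError(
            f"{path}: {signal.shape[1]} columns but {len(lead_names)} lead names supplied"
        )
    return EcgRecord(signal, fs, lead_names, label, path.stem, {"source": str(path)})


def write_matrix_record(record: EcgRecord, path, fmt: str = "%.9g") -> Path:
    path = Path(path)
    header = "\t".join(record.lead_names)
    np.savetxt(path, record.signal, fmt=fmt, delimiter="\t",
               header=header, comments="# ")
    return path


# ---------------------------------------------------------------------------
# Internal dataset bundle: .npz arrays + .json sidecar
# ---------------------------------------------------------------------------

def save_dataset(ds: BeatDataset, path) -> Path:
    """Save a dataset as ``<path>.npz`` plus a ``<path>.json`` sidecar."""
    if len(ds) == 0:
        raise ValueError("refusing to save an empty dataset")
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"X": ds.X, "y": ds.y}
    if ds.r_indices is not None:
        arrays["r_indices"] = ds.r_indices
    np.savez(base.with_suffix(".npz"), **arrays)
    sidecar = {
        "format_version": DATASET_FORMAT_VERSION,
        "classes": list(ds.taxonomy.classes),
        "fs": ds.fs,
        "r_row": ds.r_row,
        "n_beats": len(ds),
        "window_length": ds.window_length,
        "n_leads": ds.n_leads,
        "record_ids": list(ds.record_ids),
        "meta": _jsonable(ds.meta),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return base.with_suffix(".npz")


def load_dataset(path) -> BeatDataset:
    base = Path(path)
    if base.suffix in {".npz", ".json"}:
        base = base.with_suffix("")
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing dataset sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    version = sidecar.get("format_version")
    if version != DATASET_FORMAT_VERSION:
        raise FormatError(
            f"dataset format version {version} is incompatible "
            f"(this build reads version {DATASET_FORMAT_VERSION})"
        )
    try:
        with np.load(base.with_suffix(".npz")) as npz:
            X = npz["X"]
            y = npz["y"]
            r_indices = npz["r_indices"] if "r_indices" in npz else None
    except Exception as exc:  # truncated/corrupt archive must not pass silently
        raise FormatError(f"cannot read dataset arrays {base.with_suffix('.npz')}: {exc}")
    if len(X) != sidecar["n_beats"]:
        raise FormatError(
            f"{base}: sidecar declares {sidecar['n_beats']} beats, arrays hold {len(X)}"
        )
    return BeatDataset(
        X, y, LabelTaxonomy(sidecar["classes"]), sidecar["fs"], sidecar["r_row"],
        sidecar.get("record_ids", []),
        r_indices, sidecar.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
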