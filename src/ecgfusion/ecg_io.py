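"""Reading, writing and preprocessing of single-lead ECG records.

Supports two on-disk layouts:

* a PhysioNet-2017-style WFDB directory — one ``<record>.hea`` / ``<record>.dat``
  pair per record (format 16, little-endian int16 with gain/baseline) plus an
  optional ``REFERENCE.csv`` mapping record names to rhythm labels;
* a MAT v5 container holding a cell array of signal vectors and a parallel
  label array.

The preprocessing chain mirrors the standard single-lead pipeline: length
standardization to a fixed sample count, zero-phase high-pass Butterworth
baseline removal, and min-max normalization to [-1, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.signal

#: The four-symbol rhythm alphabet: normal sinus rhythm, atrial fibrillation,
#: other rhythm, noisy/uninterpretable.
LABELS = ("N", "A", "O", "~")

#: Default sampling rate in Hz (single-lead ambulatory recordings).
DEFAULT_FS = 300.0

#: Default standardized record length in samples.
TARGET_LEN = 8527


class ValidationError(ValueError):
    """Raised when a record or argument violates a documented contract."""


class FormatError(IOError):
    """Raised when an on-disk record cannot be parsed."""


@dataclass
class EcgRecord:
    """One single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray
        Real-valued trace, arbitrary amplitude units.
    fs : float
        Sampling rate in Hz; must be positive.
    label : str or None
        Rhythm label in ``LABELS``, or None when unlabeled.
    record_id, subject_id : str
        Record and subject identifiers (subject ids drive LOSO folds).
    meta : dict
        Free-form provenance (e.g. the generator's emitted RR series).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: str | None = None
    record_id: str = ""
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"record {self.record_id!r} contains non-finite samples")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"record {self.record_id!r} has unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )
        if not self.subject_id:
            self.subject_id = self.record_id

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class RecordSet:
    """Ordered collection of :class:`EcgRecord` with consistent class counts."""

    records: list[EcgRecord]

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValidationError(f"duplicate record_ids: {sorted(dupes)}")

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.records:
            if r.label is not None:
                counts[r.label] += 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=object)

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([r.subject_id for r in self.records], dtype=object)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> EcgRecord:
        return self.records[i]

    def metadata(self) -> pd.DataFrame:
        """Per-record metadata table (record_id, subject_id, label, length, fs)."""
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.records],
                "subject_id": [r.subject_id for r in self.records],
                "label": [r.label for r in self.records],
                "length": [len(r) for r in self.records],
                "fs": [r.fs for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.metadata().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# WFDB-style (.hea/.dat, format 16) reader/writer
# ---------------------------------------------------------------------------

def _read_wfdb_record(hea_path: Path) -> tuple[np.ndarray, float]:
    try:
        lines = [
            ln.strip()
            for ln in hea_path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        head = lines[0].split()
        name, n_sig = head[0], int(head[1])
        fs = float(head[2]) if len(head) > 2 else DEFAULT_FS
        n_samp = int(head[3]) if len(head) > 3 else 0
        if n_sig != 1:
            raise FormatError(f"record {name!r}: expected 1 signal, header says {n_sig}")
        sig = lines[1].split()
        dat_file, fmt = sig[0], sig[1]
        if fmt != "16":
            raise FormatError(f"record {name!r}: unsupported sample format {fmt!r}")
        # gain field may look like "1000", "1000(0)" or "1000(0)/mV"
        gain_field = sig[2] if len(sig) > 2 else "200"
        m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?(?:/(\S+))?", gain_field)
        gain = float(m.group(1)) if m else 200.0
        baseline = int(m.group(2)) if m and m.group(2) else 0
        raw = np.fromfile(hea_path.parent / dat_file, dtype="<i2")
        if n_samp and raw.size != n_samp:
            raise FormatError(
                f"record {name!r}: header declares {n_samp} samples, file has {raw.size}"
            )
        return (raw.astype(np.float64) - baseline) / (gain or 1.0), fs
    except (OSError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot read WFDB record {hea_path.stem!r}: {exc}") from exc


def write_wfdb(record: EcgRecord, directory: str | Path, gain: float = 1000.0) -> None:
    """Write one record as a format-16 ``.hea``/``.dat`` pair.

    Samples are quantized to int16 ADC units with the given gain; amplitudes
    must stay within +-32767/gain.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(np.asarray(record.samples) * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValidationError(
            f"record {record.record_id!r}: amplitude exceeds int16 range at gain {gain}"
        )
    adc = adc.astype("<i2")
    name = record.record_id or "record"
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    hea = (
        f"{name} 1 {record.fs:g} {adc.size}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if adc.size else 0} 0 0 ECG\n"
    )
    (directory / f"{name}.hea").write_text(hea)


def write_wfdb_dataset(records: RecordSet, directory: str | Path, gain: float = 1000.0) -> None:
    """Write a RecordSet as a WFDB directory with a REFERENCE.csv label file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_wfdb(rec, directory, gain=gain)
        if rec.label is not None:
            rows.append(f"{rec.record_id},{rec.label}")
    if rows:
        (directory / "REFERENCE.csv").write_text("\n".join(rows) + "\n")


def _load_wfdb_dir(directory: Path) -> RecordSet:
    labels: dict[str, str] = {}
    ref = directory / "REFERENCE.csv"
    if ref.exists():
        for ln in ref.read_text().splitlines():
            if ln.strip():
                rid, lab = ln.split(",")[:2]
                labels[rid.strip()] = lab.strip()
    records = []
    for hea in sorted(directory.glob("*.hea")):
        samples, fs = _read_wfdb_record(hea)
        records.append(
            EcgRecord(samples, fs=fs, label=labels.get(hea.stem), record_id=hea.stem)
        )
    if not records:
        raise FormatError(f"no WFDB records found under {directory}")
    return RecordSet(records)


# ---------------------------------------------------------------------------
# MAT dialect: cell array of signals + parallel label array
# ---------------------------------------------------------------------------

def write_mat(
    records: RecordSet,
    path: str | Path,
    signals_key: str = "signals",
    labels_key: str = "labels",
) -> None:
    """Write a RecordSet as a MAT v5 cell array plus parallel labels."""
    cell = np.empty(len(records), dtype=object)
    for i, rec in enumerate(records):
        cell[i] = np.asarray(rec.samples, dtype=np.float64)
    labels = np.array([r.label if r.label is not None else "" for r in records], dtype=object)
    ids = np.array([r.record_id for r in records], dtype=object)
    scipy.io.savemat(str(path), {signals_key: cell, labels_key: labels, "record_ids": ids})


def _load_mat(
    path: Path,
    fs: float,
    signals_key: str = "signals",
    labels_key: str = "labels",
) -> RecordSet:
    try:
        contents = scipy.io.loadmat(str(path), squeeze_me=True)
    except (OSError, ValueError, NotImplementedError) as exc:
        raise FormatError(f"cannot read MAT container {path.name!r}: {exc}") from exc
    if signals_key not in contents:
        raise FormatError(f"MAT container {path.name!r} has no {signals_key!r} array")
    cell = np.atleast_1d(contents[signals_key])
    n = cell.size
    raw_labels = contents.get(labels_key)
    labels = [None] * n
    if raw_labels is not None:
        flat = np.atleast_1d(raw_labels)
        labels = [str(v).strip() or None for v in flat]
        if len(labels) != n:
            raise FormatError(
                f"MAT container {path.name!r}: {n} signals but {len(labels)} labels"
            )
    ids = contents.get("record_ids")
    ids = [str(v) for v in np.atleast_1d(ids)] if ids is not None else [
        f"rec{i:05d}" for i in range(n)
    ]
    records = [
        EcgRecord(np.asarray(cell[i], dtype=np.float64).ravel(), fs=fs,
                  label=labels[i], record_id=ids[i])
        for i in range(n)
    ]
    return RecordSet(records)


def load_records(
    path: str | Path,
    format: str = "wfdb",
    fs: float = DEFAULT_FS,
    signals_key: str = "signals",
    labels_key: str = "labels",
) -> RecordSet:
    """Load a dataset of single-lead ECG records.

    Parameters
    ----------
    path : path
        WFDB directory (``format="wfdb"``) or MAT file (``format="mat"``).
    format : {"wfdb", "mat"}
    fs : float
        Sampling rate used for the MAT dialect (WFDB reads it from headers).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format == "wfdb":
        return _load_wfdb_dir(path)
    if format == "mat":
        return _load_mat(path, fs=fs, signals_key=signals_key, labels_key=labels_key)
    raise ValidationError(f"unknown format {format!r}; expected 'wfdb' or 'mat'")


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def standardize_length(record: EcgRecord, target_len: int = TARGET_LEN) -> EcgRecord:
    """Pad (zeros at the tail) or truncate (keep the head) to ``target_len``."""
    if target_len < 1:
        raise ValidationError(f"target_len must be >= 1, got {target_len}")
    x = record.samples
    if x.size == 0:
        raise ValidationError(f"record {record.record_id!r} is empty")
    if x.size >= target_len:
        out = x[:target_len].copy()
    else:
        out = np.concatenate([x, np.zeros(target_len - x.size)])
    return replace(record, samples=out)


def remove_baseline(record: EcgRecord, cutoff_hz: float = 0.5, order: int = 4) -> EcgRecord:
    """Remove baseline drift with a zero-phase high-pass Butterworth filter.

    The filter is applied forward-backward (``filtfilt``) so ECG morphology is
    not phase-shifted; the effective magnitude response is |H|^2.
    """
    nyquist = record.fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) for fs={record.fs}"
        )
    sos = scipy.signal.butter(order, cutoff_hz, btype="highpass", fs=record.fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, record.samples)
    return replace(record, samples=out)


def minmax_normalize(record: EcgRecord) -> EcgRecord:
    """Scale to [-1, 1]; a constant trace maps to all zeros by convention."""
    x = record.samples
    lo, hi = x.min(), x.max()
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = 2.0 * (x - lo) / (hi - lo) - 1.0
    return replace(record, samples=out)


def resample_record(record: EcgRecord, fs_new: float) -> EcgRecord:
    """Optional polyphase resampling (off by default in the pipeline)."""
    if fs_new <= 0:
        raise ValidationError(f"fs_new must be positive, got {fs_new}")
    from fractions import Fraction

    frac = Fraction(fs_new / record.fs).limit_denominator(1000)
    out = scipy.signal.resample_poly(record.samples, frac.numerator, frac.denominator)
    return replace(record, samples=out, fs=fs_new)


def preprocess(
    record: EcgRecord,
    target_len: int = TARGET_LEN,
    cutoff_hz: float = 0.5,
    order: int = 4,
    resample_to: float | None = None,
) -> EcgRecord:
    """Full chain: (optional resample) -> fixed length -> high-pass -> min-max."""
    if resample_to is not None and resample_to != record.fs:
        record = resample_record(record, resample_to)
    record = standardize_length(record, target_len)
    record = remove_baseline(record, cutoff_hz=cutoff_hz, order=order)
    return minmax_normalize(record)
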