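"""Reading and writing EEG recordings, metadata, and feature tables.

Recordings are held in memory as a channels x time matrix in microvolts.
Scalp montage handling is restricted to the 19 electrodes of the
international 10-20 system; modern temporal-chain names (T7/T8/P7/P8) are
normalized to the legacy names (T3/T4/T5/T6) used throughout the package.

Two recording formats are supported:

* EDF (European Data Format), read through :mod:`mne` and written with a
  minimal 16-bit encoder;
* delimited text (TSV) with a header row of channel labels, one column per
  channel — the sampling rate must then be supplied by the caller.

Feature tables and subject metadata travel as TSV with ``NA`` for missing
values; floats are serialized at 17 significant digits so that a
write/read round trip is value-exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 19 scalp electrodes of the 10-20 system, in conventional montage order.
MONTAGE_1020 = (
    "Fp1", "Fp2", "F7", "F8", "F3", "F4", "C3", "C4", "T3", "T4",
    "P3", "P4", "T5", "T6", "O1", "O2", "Fz", "Cz", "Pz",
)

#: Modern 10-10 temporal-chain names mapped onto the legacy labels.
_LABEL_SYNONYMS = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}

_CANONICAL = {lab.lower(): lab for lab in MONTAGE_1020}


def canonical_label(label: str) -> str:
    """Normalize an electrode label to canonical 10-20 spelling.

    Case-insensitive; T7/T8/P7/P8 are treated as synonyms of T3/T4/T5/T6.
    Labels outside the 19-electrode set are returned stripped but otherwise
    unchanged (they will be reported by :func:`check_montage`).
    """
    key = label.strip().lower()
    if key in _LABEL_SYNONYMS:
        return _LABEL_SYNONYMS[key]
    return _CANONICAL.get(key, label.strip())


@dataclass
class Recording:
    """A multi-channel EEG recording (channels x samples, microvolts)."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    reference_state: str = "original"  # "original" | "common_average"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match samples rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains NaN or infinite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(canonical_label(label))
        except ValueError as err:
            raise KeyError(f"channel not present: {label}") from err
        return self.samples[idx]


@dataclass
class SubjectMeta:
    """Per-subject metadata driving the group statistics."""

    subject_id: str
    group: str  # "WS" | "control"
    structural_flag: int
    genetic_flag: int

    def __post_init__(self) -> None:
        if self.group not in ("WS", "control"):
            raise ValueError(f"group must be 'WS' or 'control', got {self.group!r}")
        if self.structural_flag not in (0, 1) or self.genetic_flag not in (0, 1):
            raise ValueError("etiology flags must be 0 or 1")


@dataclass
class FeatureTable:
    """Subject x feature matrix with feature names and provenance.

    Feature names follow the ``<family>.<band-or-measure>.<scope>``
    convention (e.g. ``rp.theta.O1``, ``coh.alpha.F4-F8``,
    ``ent.peen.global``). Missing values are NaN in memory, ``NA`` on disk.
    """

    subjects: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.subjects), len(self.feature_names)):
            raise ValueError("values shape must be (n_subjects, n_features)")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subjects, name="subject_id"),
            columns=self.feature_names,
        )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


def read_recording(path, format: str | None = None, fs: float | None = None,
                   subject_id: str | None = None) -> Recording:
    """Read an EEG recording from EDF or delimited text.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"edf", "delimited_text"}, optional
        Inferred from the extension when omitted (``.edf`` -> EDF).
    fs : float, optional
        Sampling rate in Hz; required for text input, ignored for EDF
        (taken from the file header).
    subject_id : str, optional
        Defaults to the file stem.
    """
    path = str(path)
    if format is None:
        format = "edf" if path.lower().endswith(".edf") else "delimited_text"
    if subject_id is None:
        import os
        subject_id = os.path.splitext(os.path.basename(path))[0]

    if format == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data(units="uV")
        labels = [canonical_label(_strip_edf_decorations(ch))
                  for ch in raw.ch_names]
        _check_unique(labels)
        return Recording(data, float(raw.info["sfreq"]), labels,
                         subject_id=subject_id)
    if format == "delimited_text":
        if fs is None:
            raise ValueError("sampling rate required for delimited text input")
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        labels = [canonical_label(c) for c in df.columns]
        _check_unique(labels)
        return Recording(df.to_numpy(dtype=np.float64).T, float(fs), labels,
                         subject_id=subject_id)
    raise ValueError(f"unknown format: {format!r}")


def _strip_edf_decorations(label: str) -> str:
    """Drop the 'EEG ' type prefix and '-REF' style suffixes of EDF labels."""
    lab = label.strip()
    if lab.lower().startswith("eeg"):
        lab = lab[3:].lstrip(" -_")
    for suffix in ("-ref", "-le", "-avg"):
        if lab.lower().endswith(suffix):
            lab = lab[: -len(suffix)]
    return lab


def _check_unique(labels: list[str]) -> None:
    if len(set(labels)) != len(labels):
        dups = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValueError(f"duplicate channel labels after normalization: {dups}")


def check_montage(rec: Recording) -> list[str]:
    """Report deviations from the 19-electrode 10-20 montage.

    Returns an empty list iff the channel set equals the montage set
    (order-insensitive); otherwise a list of ``"missing: X"`` /
    ``"extra: Y"`` strings, montage order first.
    """
    have = set(rec.channel_labels)
    want = set(MONTAGE_1020)
    report = [f"missing: {lab}" for lab in MONTAGE_1020 if lab not in have]
    report += [f"extra: {lab}" for lab in rec.channel_labels if lab not in want]
    return report


def write_recording_text(rec: Recording, path) -> None:
    """Write a recording as TSV (header = channel labels, one column each)."""
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt="%.17g", delimiter="\t")


def write_recording_edf(rec: Recording, path) -> None:
    """Write a recording as a minimal EDF file (16-bit, microvolt units).

    One data record per second (the trailing partial second is padded with
    the physical minimum and truncated on read by duration bookkeeping not
    being needed here: recordings produced by this package are whole
    seconds). Values are quantized to the 16-bit digital grid, so a read
    back is equal only to within the quantization step.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / spr))
    nch = rec.n_channels

    phys_min = np.minimum(rec.samples.min(axis=1), -1.0)
    phys_max = np.maximum(rec.samples.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    hdr = io.BytesIO()

    def f(text, width):
        hdr.write(f"{text:<{width}.{width}}".encode("ascii"))

    f("0", 8)                               # version
    f(rec.subject_id or "X", 80)            # patient id
    f("wsqeeg", 80)                         # recording id
    f("01.01.00", 8)                        # start date
    f("00.00.00", 8)                        # start time
    f(str(256 * (nch + 1)), 8)              # header bytes
    f("", 44)                               # reserved
    f(str(n_rec), 8)
    f("1", 8)                               # record duration, seconds
    f(str(nch), 4)
    for lab in rec.channel_labels:
        f(f"EEG {lab}", 16)
    for _ in range(nch):
        f("AgAgCl electrode", 80)
    for _ in range(nch):
        f("uV", 8)
    for v in phys_min:
        f(f"{v:.8g}"[:8], 8)
    for v in phys_max:
        f(f"{v:.8g}"[:8], 8)
    for _ in range(nch):
        f(str(dig_min), 8)
    for _ in range(nch):
        f(str(dig_max), 8)
    for _ in range(nch):
        f("", 80)                           # prefiltering
    for _ in range(nch):
        f(str(spr), 8)
    for _ in range(nch):
        f("", 32)                           # reserved

    # headers store physical ranges at 8 ascii chars; quantize against the
    # values the reader will parse back, not the full-precision ones
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)

    padded = np.full((nch, n_rec * spr), pmin[:, None], dtype=np.float64)
    padded[:, : rec.n_samples] = rec.samples
    digital = np.clip(
        np.rint((padded - pmin[:, None]) / gain[:, None] + dig_min),
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def write_feature_table(table: FeatureTable, path) -> None:
    """Serialize a feature table as TSV (subject_id + one column per feature).

    NaN is written as ``NA``; floats use 17 significant digits so the
    round trip is exact. Provenance entries go into ``# key=value`` header
    comment lines.
    """
    with open(path, "w") as fh:
        for key in sorted(table.provenance):
            fh.write(f"# {key}={table.provenance[key]}\n")
        fh.write("subject_id\t" + "\t".join(table.feature_names) + "\n")
        for sid, row in zip(table.subjects, table.values):
            cells = ["NA" if np.isnan(v) else f"{v:.17g}" for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_feature_table(path) -> FeatureTable:
    provenance = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            provenance[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False,
                         dtype={"subject_id": str}, float_precision="round_trip")
    subjects = df["subject_id"].tolist()
    names = [c for c in df.columns if c != "subject_id"]
    values = df[names].to_numpy(dtype=np.float64) if names else np.empty((len(subjects), 0))
    return FeatureTable(subjects, names, values, provenance)


def write_metadata(meta: list[SubjectMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tgroup\tstructural_flag\tgenetic_flag\n")
        for m in meta:
            fh.write(f"{m.subject_id}\t{m.group}\t{m.structural_flag}\t{m.genetic_flag}\n")


def read_metadata(path) -> list[SubjectMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "structural_flag", "genetic_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    if df[list(required)].isna().any().any():
        raise ValueError("metadata contains missing values")
    return [
        SubjectMeta(str(r.subject_id), str(r.group), int(r.structural_flag),
                    int(r.genetic_flag))
        for r in df.itertuples()
    ]
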