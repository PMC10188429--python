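"""Reading and writing recordings: per-recording CSV, EDF, cohort manifests.

The CSV dialect is text-only and lossless: three comment lines carrying
subject id, label and sampling interval, then a header row ``ch1..ch8``
and one row per time point.  EDF output uses the plain European Data
Format (ASCII header, 16-bit little-endian samples), which no installed
library writes; reading EDF goes through :mod:`mne`.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import N_CHANNELS, Recording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_recording_edf",
    "read_recording_edf",
    "read_recording",
    "write_cohort",
    "read_cohort",
]


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# label: {rec.label}\n")
        fh.write(f"# sampling_interval: {rec.sampling_interval!r}\n")
        fh.write(",".join(f"ch{i + 1}" for i in range(N_CHANNELS)) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.17g")
    return path


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    meta: dict[str, str] = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    for key in ("subject_id", "label", "sampling_interval"):
        if key not in meta:
            raise ValueError(f"{path}: CSV header is missing '# {key}: ...'")
    frame = pd.read_csv(body, float_precision="round_trip")
    if frame.shape[1] != N_CHANNELS:
        raise ValueError(f"{path}: expected {N_CHANNELS} channel columns, found {frame.shape[1]}")
    return Recording(
        subject_id=meta["subject_id"],
        label=int(meta["label"]),
        data=frame.to_numpy(dtype=np.float64).T,
        sampling_interval=float(meta["sampling_interval"]),
    )


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write an EDF file (one data record per second, int16 samples).

    Physical min/max are set per channel from the data range, so samples are
    quantised to the 16-bit grid of that range — the usual EDF precision.
    """
    path = Path(path)
    sfreq = rec.sfreq
    samples_per_record = int(round(sfreq))
    if not math.isclose(samples_per_record, sfreq, rel_tol=1e-9):
        raise ValueError(f"EDF writer requires an integer sampling rate, got {sfreq} Hz")
    n_records = rec.n_samples // samples_per_record
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * samples_per_record]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    def pad(value: object, width: int) -> bytes:
        text = f"{value}"[:width]
        return text.ljust(width).encode("ascii")

    header = b"".join([
        pad(0, 8),                       # version
        pad(f"{rec.subject_id}-L{rec.label}", 80),  # patient code carries the label
        pad("eegvit synthetic", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 + 256 * N_CHANNELS, 8),  # header bytes
        pad("", 44),
        pad(n_records, 8),
        pad(1, 8),                       # record duration, seconds
        pad(N_CHANNELS, 4),
    ])
    fields = [
        [pad(f"ch{i + 1}", 16) for i in range(N_CHANNELS)],
        [pad("AgAgCl electrode", 80)] * N_CHANNELS,
        [pad("uV", 8)] * N_CHANNELS,
        [pad(f"{phys_min[i]:.6g}", 8) for i in range(N_CHANNELS)],
        [pad(f"{phys_max[i]:.6g}", 8) for i in range(N_CHANNELS)],
        [pad(dig_min, 8)] * N_CHANNELS,
        [pad(dig_max, 8)] * N_CHANNELS,
        [pad("", 80)] * N_CHANNELS,
        [pad(samples_per_record, 8)] * N_CHANNELS,
        [pad("", 32)] * N_CHANNELS,
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        # EDF interleaves by record: all of ch1's samples for record r, then ch2's, ...
        records = digital.reshape(N_CHANNELS, n_records, samples_per_record)
        fh.write(np.ascontiguousarray(records.transpose(1, 0, 2)).tobytes())
    return path


def read_recording_edf(path: str | Path, subject_id: str | None = None, label: int | None = None) -> Recording:
    """Read an 8-channel EDF file via mne.

    ``subject_id``/``label`` override what the EDF patient field carries
    (external files will not use this writer's convention); if neither the
    file nor the arguments provide them, a clear error is raised.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    if data.shape[0] != N_CHANNELS:
        raise ValueError(f"{path}: expected {N_CHANNELS} channels, found {data.shape[0]}")
    # mne rescales microvolt-dimensioned channels to volts; undo when it did
    if raw._orig_units and all(u in ("uV", "µV") for u in raw._orig_units.values()):
        data = data * 1e6
    patient = (raw.info["subject_info"] or {}).get("his_id", "") or ""
    if "-L" in patient:  # this writer's convention: <subject_id>-L<label>
        code, _, tag = patient.rpartition("-L")
        if subject_id is None:
            subject_id = code
        if label is None and tag.isdigit():
            label = int(tag)
    elif subject_id is None and patient:
        subject_id = patient
    if subject_id is None or label is None:
        raise ValueError(
            f"{path}: subject id / label not recoverable from the EDF header; "
            "pass them explicitly or use a cohort manifest"
        )
    return Recording(subject_id, label, data, 1.0 / raw.info["sfreq"])


def read_recording(path: str | Path, fmt: str | None = None, **kwargs) -> Recording:
    """Dispatch on format ('csv' or 'edf'; inferred from the suffix if None)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_recording_csv(path)
    if fmt == "edf":
        return read_recording_edf(path, **kwargs)
    raise ValueError(f"unsupported recording format {fmt!r} for {path}")


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def write_cohort(cohort: list[Recording], outdir: str | Path, fmt: str = "csv") -> Path:
    """Write every recording plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        fname = f"{rec.subject_id}.{fmt}"
        if fmt == "csv":
            write_recording_csv(rec, outdir / fname)
        elif fmt == "edf":
            write_recording_edf(rec, outdir / fname)
        else:
            raise ValueError(f"unsupported cohort format {fmt!r}")
        rows.append({"subject_id": rec.subject_id, "label": rec.label, "path": fname})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load a cohort from its manifest; labels come from the manifest."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    for col in ("subject_id", "label", "path"):
        if col not in table.columns:
            raise ValueError(f"{manifest_path}: manifest lacks required column {col!r}")
    if table["subject_id"].isna().any() or table["label"].isna().any():
        raise ValueError(f"{manifest_path}: manifest has missing subject ids or labels")
    cohort = []
    for row in table.itertuples():
        path = manifest_path.parent / str(row.path)
        rec = read_recording(path, subject_id=str(row.subject_id), label=int(row.label)) \
            if path.suffix.lower() == ".edf" else read_recording(path)
        if rec.subject_id != str(row.subject_id):
            raise ValueError(
                f"{path}: file subject id {rec.subject_id!r} disagrees with manifest {row.subject_id!r}"
            )
        if rec.label != int(row.label):
            raise ValueError(f"{path}: file label {rec.label} disagrees with manifest {row.label}")
        cohort.append(rec)
    return cohort
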