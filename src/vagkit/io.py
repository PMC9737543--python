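"""File formats: recordings (WAV/CSV), cohort manifests, feature tables.

Conventions: frequencies in Hz, times in seconds, 0-based sample indexing.
WAV files store float32 samples with the sampling rate in the header; the
CSV dialect for signals is two comma-separated columns ``time_s,amplitude``
with '.' decimals. Manifests are CSV with the header
``subject_id,group,side,session,path``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from vagkit.simulate import MANIFEST_COLUMNS, VagRecording


class FormatError(ValueError):
    """A file failed to parse as the expected format."""


def write_recording(recording: VagRecording, path, fmt: str | None = None) -> None:
    """Write a recording as WAV (float32) or CSV (time_s,amplitude)."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "wav")
    if fmt == "wav":
        wavfile.write(path, int(round(recording.sampling_rate)),
                      recording.samples.astype(np.float32))
    elif fmt == "csv":
        t = np.arange(len(recording.samples)) / recording.sampling_rate
        pd.DataFrame({"time_s": t, "amplitude": recording.samples}).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_recording(path, fmt: str | None = None, **meta) -> VagRecording:
    """Read a WAV or CSV recording; the file's sampling rate wins over defaults.

    Extra keyword arguments (subject_id, group, side, session) populate the
    recording's metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "wav")
    if fmt == "wav":
        rate, samples = wavfile.read(path)
        return VagRecording(samples=np.asarray(samples, dtype=float),
                            sampling_rate=float(rate), **meta)
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"{path}: {exc}") from exc
        if list(df.columns) != ["time_s", "amplitude"]:
            raise FormatError(f"{path}: expected header 'time_s,amplitude', "
                              f"got {list(df.columns)}")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise FormatError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        bad = np.nonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12))[0]
        if len(bad):
            # file line number: header is line 1, data row j is line j+2, and
            # the offender is the second row of the bad pair (j = bad[0]+1)
            raise FormatError(f"{path}: non-uniform time step at data row {bad[0] + 3}")
        return VagRecording(samples=df["amplitude"].to_numpy(dtype=float),
                            sampling_rate=1.0 / dt[0], **meta)
    raise ValueError(f"unknown format {fmt!r}")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "path": str},
                     keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    df["session"] = df["session"].astype(int)
    return df


def load_cohort(manifest_path) -> tuple[pd.DataFrame, list[VagRecording]]:
    """Read a manifest CSV and every recording it references."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    recordings = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        recordings.append(read_recording(
            p, subject_id=row["subject_id"], group=row["group"],
            side=row["side"], session=int(row["session"])))
    return manifest, recordings


def write_recordings(manifest: pd.DataFrame, recordings, out_dir,
                     fmt: str = "wav", path_prefix: str = "") -> pd.DataFrame:
    """Write every recording under `out_dir`; returns a manifest with paths filled.

    `path_prefix` is prepended to the stored (relative) paths so the manifest
    can live in a parent directory of the recordings.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = manifest.copy()
    for i, rec in enumerate(recordings):
        name = f"{rec.subject_id}_{rec.side}_s{rec.session}.{fmt}"
        write_recording(rec, out_dir / name, fmt)
        manifest.loc[manifest.index[i], "path"] = path_prefix + name
    return manifest
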