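"""Reading and writing EEG recordings and cohort tables.

EDF/EDF+ is the clinical interchange format read here (via :mod:`mne`); plain
numeric CSV matrices are the lossless working format used between pipeline
stages. All amplitudes are microvolts internally; EDF physical dimensions are
converted on read. Anesthesia-state labels travel either in the file name
convention ``<subject>_<state>.edf`` or in a manifest CSV; the manifest wins
on conflict.

A minimal EDF *writer* is included so that the simulator can emit
standard-format fixtures; it writes plain EDF (16-bit, one-second records).
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .montage import normalize_label
from .recording import STATES, EEGRecording

logger = logging.getLogger("doc_eeg.io")

_STATE_PATTERN = re.compile(r"^(?P<subject>.+)_(?P<state>" + "|".join(STATES) + r")$")

COHORT_COLUMNS = (
    "subject_id", "group", "timepoint",
    "auditory", "visual", "motor", "oromotor", "communication", "arousal",
)


def _subject_state_from_name(stem: str) -> tuple[str | None, str | None]:
    m = _STATE_PATTERN.match(stem)
    if m:
        return m.group("subject"), m.group("state")
    return None, None


def read_edf(path: str | Path, subject_id: str | None = None,
             group: str | None = None, state: str | None = None) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` in microvolts.

    Channel labels are case-normalized and mapped through the modern->legacy
    alias table (T7 -> T3 etc.); channels that do not map onto the 19-label
    10-20 set are dropped with a warning. Subject id and anesthesia state are
    taken from the ``<subject>_<state>.edf`` file-name convention unless given
    explicitly.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of IOError/ValueError
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    keep_idx: list[int] = []
    labels: list[str] = []
    for i, name in enumerate(raw.ch_names):
        canon = normalize_label(name)
        if canon is None:
            logger.warning("dropping unmapped channel %r in %s", name, path.name)
        elif canon in labels:
            logger.warning("dropping duplicate channel %r in %s", name, path.name)
        else:
            keep_idx.append(i)
            labels.append(canon)
    if not labels:
        raise FormatError(f"{path}: no channels map onto the 10-20 montage")

    data_uv = raw.get_data(picks=keep_idx) * 1e6  # mne returns Volts
    name_subject, name_state = _subject_state_from_name(path.stem)
    return EEGRecording(
        subject_id=subject_id or name_subject or path.stem,
        group=group,
        state=state or name_state,
        fs=float(raw.info["sfreq"]),
        channels=labels,
        data=data_uv,
    )


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as plain EDF (16-bit, one-second data records).

    The sampling rate must be a positive integer. The last record is
    zero-padded when the duration is not a whole number of seconds. Amplitude
    resolution is limited by the 16-bit digitization (range / 65535), which is
    far below EEG noise floors; use the CSV round-trip where losslessness
    matters.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {rec.fs}")
    n_ch, n_samp = rec.data.shape
    n_records = int(np.ceil(n_samp / fs)) if n_samp else 0

    phys_max = float(max(1.0, np.max(np.abs(rec.data)) if rec.data.size else 1.0))
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    header = b"".join([
        pad("0", 8),
        pad(rec.subject_id or "X", 80),
        pad(f"Startdate 01-JAN-2000 {rec.state or 'X'}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        (16, rec.channels),
        (80, ["AgAgCl electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{phys_min:.6g}"] * n_ch),
        (8, [f"{phys_max:.6g}"] * n_ch),
        (8, [str(dig_min)] * n_ch),
        (8, [str(dig_max)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(fs)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(pad(str(v), width) for v in values) for width, values in fields
    )

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = rec.data
    digital = np.clip(
        np.round((padded - phys_min) * scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_matrix_csv(path: str | Path, fs: float,
                    channels: list[str] | None = None, *,
                    subject_id: str | None = None, group: str | None = None,
                    state: str | None = None) -> EEGRecording:
    """Read a samples x channels numeric CSV into a recording.

    The header row carries the channel labels unless ``channels`` is given.
    A non-numeric cell raises a parse error naming its row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if channels is None:
        channels = [str(c) for c in df.columns]
    elif len(channels) != df.shape[1]:
        raise FormatError(
            f"{path}: {df.shape[1]} columns but {len(channels)} labels given"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r = int(np.argmax(bad.any(axis=1).to_numpy()))
        c = str(bad.columns[int(np.argmax(bad.iloc[r].to_numpy()))])
        raise FormatError(f"{path}: non-numeric cell at row {r}, column {c!r}")
    if numeric.isna().any().any():
        raise FormatError(f"{path}: missing values in matrix")
    name_subject, name_state = _subject_state_from_name(path.stem)
    return EEGRecording(
        subject_id=subject_id or name_subject or path.stem,
        group=group,
        state=state or name_state,
        fs=fs,
        channels=list(channels),
        data=numeric.to_numpy().T,
    )


def write_matrix_csv(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a samples x channels CSV, lossless to >= 9 digits."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channels)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CRS-R table.

    Expected columns: ``subject_id, group, timepoint, auditory, visual, motor,
    oromotor, communication, arousal`` with one row per subject per timepoint
    (``pre_op`` or ``month3``). Subscale values are validated against their
    defined ranges.
    """
    from . import crsr

    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty cohort table", path)
        return df[list(COHORT_COLUMNS)]
    for col in crsr.SUBSCALES:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, vals.round()):
            raise SchemaError(f"{path}: column {col!r} must be integer")
        df[col] = vals.astype(int)
    for _, row in df.iterrows():
        crsr.CRSRAssessment(
            auditory=row["auditory"], visual=row["visual"], motor=row["motor"],
            oromotor=row["oromotor"], communication=row["communication"],
            arousal=row["arousal"], timepoint=str(row["timepoint"]),
        )
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a recording manifest (subject_id, group, state, path)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group", "state", "path") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_states = set(df["state"]) - set(STATES)
    if bad_states:
        raise SchemaError(f"{path}: unknown state label(s) {sorted(bad_states)}")
    return df
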