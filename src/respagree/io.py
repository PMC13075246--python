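"""Epoch-level data model and long-format CSV input/output.

Both devices report one breaths-per-minute (bpm) value per 1-minute epoch.
An epoch is minute-aligned and covers the half-open interval [t, t + 60 s);
timestamps carrying a nonzero seconds component are truncated to the minute
before any join. The analysis is defined only on *paired* epochs, so stream
alignment is an inner join and unpaired epochs are logged, never imputed.

CSV schema (UTF-8, comma-separated, header required)::

    subject_id, epoch_start, bpm_ref, bpm_test, ref_artifact,
    test_usable_seconds, age_months, nap_duration_min

``epoch_start`` is ISO-8601 at minute resolution. ``bpm_ref`` comes from the
reference device (a wearable cardiorespiratory sensor), ``bpm_test`` from the
camera-based test device; either may be empty (missing). ``ref_artifact`` is
0/1 — the reference device's accelerometer-coincident movement flag.
``test_usable_seconds`` (0-60) is the number of seconds of usable signal the
test device saw within the epoch. The two subject covariates repeat per row.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("respagree")

#: column order of the epoch table inside :class:`PairedDataset`
EPOCH_COLUMNS = [
    "subject_id",
    "epoch_start",
    "bpm_ref",
    "bpm_test",
    "ref_artifact",
    "test_usable_seconds",
]
#: subject covariates carried alongside the epoch table
SUBJECT_COLUMNS = ["subject_id", "age_months", "nap_duration_min"]
#: on-disk column order
CSV_COLUMNS = EPOCH_COLUMNS + SUBJECT_COLUMNS[1:]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


class SchemaError(ValueError):
    """The CSV header is missing required columns."""


class RowValidationError(ValueError):
    """A row violates an epoch-level invariant (strict mode)."""


class DuplicateEpochError(ValueError):
    """Two rows share the same (subject_id, epoch_start) key."""


@dataclass(frozen=True)
class EpochRecord:
    """One paired (subject, minute) observation.

    ``bpm_ref``/``bpm_test`` are nonnegative breaths per minute or ``None``
    when the device produced nothing for the epoch. ``epoch_start`` must have
    a zero seconds component.
    """

    subject_id: str
    epoch_start: datetime
    bpm_ref: float | None
    bpm_test: float | None
    ref_artifact: bool = False
    test_usable_seconds: int = 60

    def validate(self) -> "EpochRecord":
        if self.epoch_start.second != 0 or self.epoch_start.microsecond != 0:
            raise RowValidationError(
                f"epoch_start {self.epoch_start!r} has a nonzero seconds component"
            )
        for name in ("bpm_ref", "bpm_test"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise RowValidationError(f"{name}={v!r} is not a nonnegative finite value")
        if not 0 <= int(self.test_usable_seconds) <= 60:
            raise RowValidationError(
                f"test_usable_seconds={self.test_usable_seconds!r} outside [0, 60]"
            )
        return self


@dataclass(frozen=True)
class SubjectInfo:
    """Per-subject covariates used by the moderator analysis."""

    subject_id: str
    age_months: float
    nap_duration_min: float

    def validate(self) -> "SubjectInfo":
        for name in ("age_months", "nap_duration_min"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v <= 0:
                raise RowValidationError(f"{name}={v!r} must be positive")
        return self


@dataclass
class PairedDataset:
    """A validated collection of paired epochs plus subject covariates.

    ``epochs`` holds one row per (subject, minute) with the
    :data:`EPOCH_COLUMNS` layout, sorted by (subject_id, epoch_start);
    ``subjects`` holds one row per subject with the :data:`SUBJECT_COLUMNS`
    layout. ``log`` carries bookkeeping from the reader/aligner (rows
    dropped, epochs unpaired) and is ignored by equality.
    """

    epochs: pd.DataFrame
    subjects: pd.DataFrame
    log: dict = field(default_factory=dict, compare=False)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[EpochRecord],
        subjects: Iterable[SubjectInfo] | None = None,
    ) -> "PairedDataset":
        recs = [r.validate() for r in records]
        epochs = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in recs],
                "epoch_start": pd.to_datetime([r.epoch_start for r in recs]),
                "bpm_ref": [np.nan if r.bpm_ref is None else float(r.bpm_ref) for r in recs],
                "bpm_test": [np.nan if r.bpm_test is None else float(r.bpm_test) for r in recs],
                "ref_artifact": [bool(r.ref_artifact) for r in recs],
                "test_usable_seconds": [int(r.test_usable_seconds) for r in recs],
            },
            columns=EPOCH_COLUMNS,
        )
        if subjects is None:
            ids = sorted({r.subject_id for r in recs})
            subj = pd.DataFrame(
                {"subject_id": ids, "age_months": np.nan, "nap_duration_min": np.nan},
                columns=SUBJECT_COLUMNS,
            )
        else:
            infos = [s.validate() for s in subjects]
            subj = pd.DataFrame(
                {
                    "subject_id": [s.subject_id for s in infos],
                    "age_months": [s.age_months for s in infos],
                    "nap_duration_min": [s.nap_duration_min for s in infos],
                },
                columns=SUBJECT_COLUMNS,
            )
        return cls(epochs, subj).sort().validate()

    @classmethod
    def empty(cls) -> "PairedDataset":
        epochs = pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=object),
                "epoch_start": pd.Series(dtype="datetime64[ns]"),
                "bpm_ref": pd.Series(dtype=float),
                "bpm_test": pd.Series(dtype=float),
                "ref_artifact": pd.Series(dtype=bool),
                "test_usable_seconds": pd.Series(dtype="int64"),
            },
            columns=EPOCH_COLUMNS,
        )
        subjects = pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=object),
                "age_months": pd.Series(dtype=float),
                "nap_duration_min": pd.Series(dtype=float),
            },
            columns=SUBJECT_COLUMNS,
        )
        return cls(epochs, subjects)

    # -- views ------------------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def epochs_per_subject(self) -> pd.Series:
        """m_i, indexed by subject_id (subjects with no epochs count 0)."""
        counts = self.epochs.groupby("subject_id").size()
        return counts.reindex(self.subjects["subject_id"], fill_value=0)

    @property
    def records(self) -> list[EpochRecord]:
        out = []
        for row in self.epochs.itertuples(index=False):
            out.append(
                EpochRecord(
                    subject_id=row.subject_id,
                    epoch_start=row.epoch_start.to_pydatetime(),
                    bpm_ref=None if pd.isna(row.bpm_ref) else float(row.bpm_ref),
                    bpm_test=None if pd.isna(row.bpm_test) else float(row.bpm_test),
                    ref_artifact=bool(row.ref_artifact),
                    test_usable_seconds=int(row.test_usable_seconds),
                )
            )
        return out

    @property
    def subject_info(self) -> list[SubjectInfo]:
        return [
            SubjectInfo(r.subject_id, float(r.age_months), float(r.nap_duration_min))
            for r in self.subjects.itertuples(index=False)
        ]

    # -- maintenance ------------------------------------------------------
    def sort(self) -> "PairedDataset":
        self.epochs = (
            self.epochs.sort_values(["subject_id", "epoch_start"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.subjects = (
            self.subjects.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
        )
        return self

    def validate(self) -> "PairedDataset":
        ep, subj = self.epochs, self.subjects
        missing_cols = [c for c in EPOCH_COLUMNS if c not in ep.columns]
        if missing_cols:
            raise SchemaError(f"epoch table missing columns: {missing_cols}")
        unknown = set(ep["subject_id"]) - set(subj["subject_id"])
        if unknown:
            raise RowValidationError(f"epochs reference unknown subjects: {sorted(unknown)}")
        if len(ep):
            ts = pd.to_datetime(ep["epoch_start"])
            if (ts.dt.second != 0).any() or (ts.dt.microsecond != 0).any():
                raise RowValidationError("epoch_start values must be minute-aligned")
            dup = ep.duplicated(subset=["subject_id", "epoch_start"])
            if dup.any():
                key = ep.loc[dup.idxmax(), ["subject_id", "epoch_start"]].tolist()
                raise DuplicateEpochError(f"duplicate epoch key {tuple(key)}")
            for col in ("bpm_ref", "bpm_test"):
                vals = ep[col].to_numpy(dtype=float)
                bad = np.isfinite(vals) & (vals < 0) | np.isinf(vals)
                if bad.any():
                    raise RowValidationError(f"{col} contains negative or non-finite values")
            usable = ep["test_usable_seconds"].to_numpy()
            if ((usable < 0) | (usable > 60)).any():
                raise RowValidationError("test_usable_seconds outside [0, 60]")
        if subj.duplicated(subset=["subject_id"]).any():
            raise DuplicateEpochError("duplicate subject_id in subject table")
        return self

    def subset(self, mask: np.ndarray) -> "PairedDataset":
        """Row subset preserving order; subject table is kept as-is."""
        return PairedDataset(
            self.epochs.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            self.subjects.copy(),
            dict(self.log),
        )

    def equals(self, other: "PairedDataset") -> bool:
        return self.epochs.equals(other.epochs) and self.subjects.equals(other.subjects)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_epochs(path: str | Path, strict: bool = True) -> PairedDataset:
    """Read the long-format epoch CSV into a validated :class:`PairedDataset`.

    In strict mode any invariant violation raises; otherwise offending rows
    are dropped, counted in ``dataset.log`` and reported through the module
    logger. Rows are returned sorted by (subject_id, epoch_start).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    if raw.empty:
        return PairedDataset.empty()

    bad = pd.Series(False, index=raw.index)
    reasons: dict[int, str] = {}

    ts = pd.to_datetime(raw["epoch_start"], errors="coerce")
    mask = ts.isna()
    for i in raw.index[mask]:
        reasons.setdefault(i, f"unparseable timestamp {raw.at[i, 'epoch_start']!r}")
    bad |= mask
    mask = ~ts.isna() & ((ts.dt.second != 0) | (ts.dt.microsecond != 0))
    for i in raw.index[mask]:
        reasons.setdefault(i, f"epoch_start {raw.at[i, 'epoch_start']!r} not minute-aligned")
    bad |= mask

    numeric: dict[str, pd.Series] = {}
    for col, lo, hi in (
        ("bpm_ref", 0.0, np.inf),
        ("bpm_test", 0.0, np.inf),
        ("test_usable_seconds", 0, 60),
    ):
        vals = pd.to_numeric(raw[col], errors="coerce")
        mask = vals.isna() & raw[col].notna()
        for i in raw.index[mask]:
            reasons.setdefault(i, f"unparseable {col} {raw.at[i, col]!r}")
        bad |= mask
        mask = vals.notna() & ((vals < lo) | (vals > hi) | np.isinf(vals))
        for i in raw.index[mask]:
            reasons.setdefault(i, f"{col}={raw.at[i, col]!r} outside [{lo}, {hi}]")
        bad |= mask
        numeric[col] = vals
    mask = numeric["test_usable_seconds"].isna()
    for i in raw.index[mask]:
        reasons.setdefault(i, "missing test_usable_seconds")
    bad |= mask

    art = pd.to_numeric(
        raw["ref_artifact"].replace(
            {"True": 1, "true": 1, "False": 0, "false": 0}
        ),
        errors="coerce",
    )
    mask = art.isna() | ~art.isin([0, 1])
    for i in raw.index[mask]:
        reasons.setdefault(i, f"ref_artifact {raw.at[i, 'ref_artifact']!r} not 0/1")
    bad |= mask

    if strict and bad.any():
        first = min(reasons)
        raise RowValidationError(
            f"{path.name}: {int(bad.sum())} invalid rows; first at line "
            f"{first + 2}: {reasons[first]}"
        )
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("read_epochs(%s): dropped %d invalid rows", path.name, n_dropped)
    keep = ~bad

    epochs = pd.DataFrame(
        {
            "subject_id": raw.loc[keep, "subject_id"],
            "epoch_start": ts[keep],
            "bpm_ref": numeric["bpm_ref"][keep].astype(float),
            "bpm_test": numeric["bpm_test"][keep].astype(float),
            "ref_artifact": art[keep].astype(bool),
            "test_usable_seconds": numeric["test_usable_seconds"][keep].astype("int64"),
        },
        columns=EPOCH_COLUMNS,
    )

    dup = epochs.duplicated(subset=["subject_id", "epoch_start"])
    n_dup = int(dup.sum())
    if n_dup:
        key = epochs.loc[dup.idxmax(), ["subject_id", "epoch_start"]].tolist()
        if strict:
            raise DuplicateEpochError(f"{path.name}: duplicate epoch key {tuple(key)}")
        logger.info("read_epochs(%s): dropped %d duplicate rows", path.name, n_dup)
        epochs = epochs.loc[~dup]

    covs = raw.loc[keep, SUBJECT_COLUMNS].copy()
    covs["age_months"] = pd.to_numeric(covs["age_months"], errors="coerce")
    covs["nap_duration_min"] = pd.to_numeric(covs["nap_duration_min"], errors="coerce")
    subjects = covs.groupby("subject_id", as_index=False).first()[SUBJECT_COLUMNS]
    conflicts = covs.groupby("subject_id").nunique(dropna=True)
    if (conflicts[["age_months", "nap_duration_min"]] > 1).any().any():
        warnings.warn("conflicting subject covariates; first value per subject kept")
    if strict:
        nonpos = (subjects[["age_months", "nap_duration_min"]] <= 0).any(axis=1)
        if nonpos.any():
            raise RowValidationError(
                f"{path.name}: nonpositive covariates for subjects "
                f"{subjects.loc[nonpos, 'subject_id'].tolist()}"
            )

    data = PairedDataset(epochs, subjects, {"n_dropped_rows": n_dropped, "n_dropped_duplicates": n_dup})
    return data.sort().validate()


def write_epochs(data: PairedDataset, path: str | Path) -> Path:
    """Write the dataset to CSV with deterministic column and row order.

    Re-reading the file reproduces the dataset exactly; a second write is
    byte-identical.
    """
    path = Path(path)
    data.validate()
    df = data.epochs.copy()
    df = df.sort_values(["subject_id", "epoch_start"], kind="mergesort")
    df = df.merge(data.subjects, on="subject_id", how="left")
    df["epoch_start"] = pd.to_datetime(df["epoch_start"]).dt.strftime(TIMESTAMP_FORMAT)
    df["ref_artifact"] = df["ref_artifact"].astype(int)
    df["test_usable_seconds"] = df["test_usable_seconds"].astype("int64")
    df.to_csv(path, index=False, columns=CSV_COLUMNS)
    return path


# ---------------------------------------------------------------------------
# stream alignment
# ---------------------------------------------------------------------------

def align_streams(
    ref_rows: pd.DataFrame,
    test_rows: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
) -> PairedDataset:
    """Inner-join two per-device epoch streams on (subject_id, minute).

    Each input carries one device's rows with columns ``subject_id``,
    ``epoch_start``, ``bpm`` plus that device's artifact metadata
    (``ref_artifact`` for the reference stream, ``test_usable_seconds`` for
    the test stream; both optional with clean defaults). Timestamps are
    truncated to the minute before joining. Epochs present in only one
    stream are excluded and counted in the result's ``log``.
    """
    def _prep(rows: pd.DataFrame, label: str) -> pd.DataFrame:
        for col in ("subject_id", "epoch_start", "bpm"):
            if col not in rows.columns:
                raise SchemaError(f"{label} stream missing column {col!r}")
        out = rows.copy()
        out["subject_id"] = out["subject_id"].astype(str)
        out["epoch_start"] = pd.to_datetime(out["epoch_start"]).dt.floor("min")
        dup = out.duplicated(subset=["subject_id", "epoch_start"])
        if dup.any():
            key = out.loc[dup.idxmax(), ["subject_id", "epoch_start"]].tolist()
            raise DuplicateEpochError(f"{label} stream: duplicate epoch key {tuple(key)}")
        return out

    ref = _prep(ref_rows, "reference")
    test = _prep(test_rows, "test")
    if "ref_artifact" not in ref.columns:
        ref["ref_artifact"] = False
    if "test_usable_seconds" not in test.columns:
        test["test_usable_seconds"] = 60

    merged = ref.merge(
        test,
        on=["subject_id", "epoch_start"],
        how="inner",
        suffixes=("_ref", "_test"),
    )
    log = {
        "n_unpaired_ref": len(ref) - len(merged),
        "n_unpaired_test": len(test) - len(merged),
    }
    if merged.empty:
        warnings.warn("align_streams: no overlapping epochs between the two streams")
        out = PairedDataset.empty()
        out.log = log
        return out

    epochs = pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "epoch_start": merged["epoch_start"],
            "bpm_ref": merged["bpm_ref"].astype(float),
            "bpm_test": merged["bpm_test"].astype(float),
            "ref_artifact": merged["ref_artifact"].astype(bool),
            "test_usable_seconds": merged["test_usable_seconds"].astype("int64"),
        },
        columns=EPOCH_COLUMNS,
    )
    if subjects is None:
        ids = sorted(epochs["subject_id"].unique())
        subjects = pd.DataFrame(
            {"subject_id": ids, "age_months": np.nan, "nap_duration_min": np.nan},
            columns=SUBJECT_COLUMNS,
        )
    else:
        subjects = subjects[SUBJECT_COLUMNS].copy()
        subjects["subject_id"] = subjects["subject_id"].astype(str)
    return PairedDataset(epochs, subjects, log).sort().validate()
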