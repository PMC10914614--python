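"""Canonical on-disk dialects and validated in-memory containers.

All tables are UTF-8, tab-separated, ``.`` decimal, with a mandatory header
row — the dialect of common proteomics exports. Three table types are
defined here:

* intensity matrices — one row per protein, columns ``protein_id``,
  ``F01`` .. ``F20``, ``P`` (pellet), ``organism``; one designated spike-in
  row (the known-amount foreign protein added per fraction);
* annotation tables — ``protein_id``, ``organism``, ``reference_complex``;
* transcript count time courses — ``transcript_id``, ``genome``, then one
  column per time point labelled in minutes (``t0``, ``t2``, ...).

Empty or ``NA`` intensity cells are parsed as 0 (MaxQuant-style absence
means "not detected"); the number of such cells is counted and logged so
silent imputation never goes unnoticed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

N_FRACTIONS = 20
FRACTION_COLUMNS: list[str] = [f"F{i:02d}" for i in range(1, N_FRACTIONS + 1)]
PELLET_COLUMN = "P"
VALUE_COLUMNS: list[str] = FRACTION_COLUMNS + [PELLET_COLUMN]

ORGANISMS = ("host", "phage", "spike_in")
GENOMES = ("host", "phage")
REFERENCE_COMPLEXES = ("30S", "50S", "RNAP", "other", "none")

_MISSING_TOKENS = {"", "na", "nan", "n/a"}
_TIME_LABEL_RE = re.compile(r"^t(\d+(?:\.\d+)?)$")


# ---------------------------------------------------------------------------
# containers


@dataclass
class IntensityMatrix:
    """Raw protein × (fraction 1..20 + pellet) intensities.

    ``values`` has shape (n_proteins, 21): columns F01..F20 then P.
    ``spike_in_id`` names exactly one row whose 21 values are all > 0.
    """

    protein_ids: list[str]
    values: np.ndarray
    organism: list[str]
    spike_in_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.protein_ids)
        if self.values.shape != (n, len(VALUE_COLUMNS)):
            raise IntegrityError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n} proteins x {len(VALUE_COLUMNS)} columns"
            )
        if len(self.organism) != n:
            raise IntegrityError("organism labels do not match protein rows")
        if len(set(self.protein_ids)) != n:
            dupes = sorted(
                {p for p in self.protein_ids if self.protein_ids.count(p) > 1}
            )
            raise IntegrityError(f"duplicate protein_id(s): {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("non-finite intensity values")
        if np.any(self.values < 0):
            raise IntegrityError("negative intensity values")
        bad = sorted(set(self.organism) - set(ORGANISMS))
        if bad:
            raise FormatError(
                f"unknown organism label(s) {bad}; allowed: {list(ORGANISMS)}"
            )
        if self.protein_ids.count(self.spike_in_id) != 1:
            raise IntegrityError(
                f"spike_in_id {self.spike_in_id!r} must name exactly one row"
            )
        if np.any(self.values[self.spike_index] <= 0):
            raise IntegrityError(
                f"spike-in row {self.spike_in_id!r} must be > 0 in all "
                f"{len(VALUE_COLUMNS)} columns"
            )

    @property
    def spike_index(self) -> int:
        return self.protein_ids.index(self.spike_in_id)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=VALUE_COLUMNS)
        df.insert(0, "protein_id", self.protein_ids)
        df["organism"] = self.organism
        return df

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            protein_ids=list(self.protein_ids),
            values=self.values.copy(),
            organism=list(self.organism),
            spike_in_id=self.spike_in_id,
        )


@dataclass
class AnnotationTable:
    """Per-protein organism and reference-complex membership."""

    protein_ids: list[str]
    organism: list[str]
    reference_complex: list[str]

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if len(self.organism) != n or len(self.reference_complex) != n:
            raise IntegrityError("annotation columns have unequal lengths")
        if len(set(self.protein_ids)) != n:
            raise IntegrityError("duplicate protein_id in annotation table")
        bad = sorted(set(self.organism) - set(GENOMES))
        if bad:
            raise FormatError(
                f"unknown organism label(s) {bad}; allowed: {list(GENOMES)}"
            )
        bad = sorted(set(self.reference_complex) - set(REFERENCE_COMPLEXES))
        if bad:
            raise FormatError(
                f"unknown reference_complex term(s) {bad}; allowed: "
                f"{list(REFERENCE_COMPLEXES)}"
            )

    def complex_of(self, protein_id: str) -> str:
        return self.reference_complex[self.protein_ids.index(protein_id)]

    def members(self, label: str) -> list[str]:
        return [
            p
            for p, c in zip(self.protein_ids, self.reference_complex)
            if c == label
        ]

    def labels(self) -> list[str]:
        """Reference labels present (excluding 'none'), in first-seen order."""
        seen: list[str] = []
        for c in self.reference_complex:
            if c != "none" and c not in seen:
                seen.append(c)
        return seen


@dataclass
class CountsTimecourse:
    """Transcript × time-point raw counts with genome-of-origin labels."""

    transcript_ids: list[str]
    genome: list[str]
    timepoints: np.ndarray  # minutes, strictly increasing
    counts: np.ndarray  # (n_transcripts, n_timepoints) non-negative ints

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts)
        n = len(self.transcript_ids)
        if len(set(self.transcript_ids)) != n:
            raise IntegrityError("duplicate transcript_id")
        if len(self.genome) != n:
            raise IntegrityError("genome labels do not match transcript rows")
        bad = sorted(set(self.genome) - set(GENOMES))
        if bad:
            raise FormatError(
                f"unknown genome label(s) {bad}; allowed: {list(GENOMES)}"
            )
        if self.timepoints.ndim != 1 or np.any(np.diff(self.timepoints) <= 0):
            raise FormatError("time points must be strictly increasing")
        if self.counts.shape != (n, len(self.timepoints)):
            raise IntegrityError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{n} transcripts x {len(self.timepoints)} time points"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_int)) or np.any(
                as_int != np.round(as_int)
            ):
                raise FormatError("counts must be finite integers")
            self.counts = as_int.astype(np.int64)
        if np.any(self.counts < 0):
            raise IntegrityError("negative counts")

    @property
    def phage_mask(self) -> np.ndarray:
        return np.array([g == "phage" for g in self.genome], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=[_format_time_label(t) for t in self.timepoints]
        )
        df.insert(0, "transcript_id", self.transcript_ids)
        df.insert(1, "genome", self.genome)
        return df


# ---------------------------------------------------------------------------
# helpers


def _format_time_label(t: float) -> str:
    return f"t{t:g}"


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, no header row") from exc


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _parse_intensity_cell(text: str) -> tuple[float, bool]:
    """Return (value, was_missing). Missing tokens map to 0."""
    if text.strip().lower() in _MISSING_TOKENS:
        return 0.0, True
    try:
        v = float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable intensity value {text!r}") from exc
    if not math.isfinite(v):
        raise FormatError(f"non-finite intensity value {text!r}")
    return v, False


# ---------------------------------------------------------------------------
# readers / writers


def read_intensity_table(path, spike_in_id: str) -> IntensityMatrix:
    """Read a protein × fraction intensity TSV.

    Header must contain ``protein_id``, ``F01`` .. ``F20``, ``P`` and
    ``organism``. Empty/NA cells parse as 0 (logged). Row order preserved;
    no rows are dropped.
    """
    df = _read_tsv(path)
    _require_columns(df, ["protein_id"] + VALUE_COLUMNS + ["organism"], path)
    n_missing = 0
    values = np.empty((len(df), len(VALUE_COLUMNS)), dtype=float)
    for j, col in enumerate(VALUE_COLUMNS):
        for i, text in enumerate(df[col].tolist()):
            try:
                v, miss = _parse_intensity_cell(text)
            except FormatError as exc:
                raise FormatError(
                    f"{path}: row {i + 1}, column {col}: {exc}"
                ) from exc
            values[i, j] = v
            n_missing += miss
    if n_missing:
        logger.warning(
            "%s: %d empty/NA intensity cells imputed as 0 (not detected)",
            path,
            n_missing,
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise IntegrityError(
            f"{path}: negative intensity at row {i + 1}, "
            f"column {VALUE_COLUMNS[j]}"
        )
    ids = df["protein_id"].tolist()
    if spike_in_id not in ids:
        raise IntegrityError(
            f"{path}: spike-in row {spike_in_id!r} not found"
        )
    return IntensityMatrix(
        protein_ids=ids,
        values=values,
        organism=df["organism"].tolist(),
        spike_in_id=spike_in_id,
    )


def write_intensity_table(m: IntensityMatrix, path) -> None:
    df = m.to_frame()
    for col in VALUE_COLUMNS:
        df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_annotations(path) -> AnnotationTable:
    """Read a protein annotation TSV (protein_id, organism, reference_complex).

    An empty ``reference_complex`` field is stored as ``none``; any term
    outside the controlled vocabulary is rejected.
    """
    df = _read_tsv(path)
    _require_columns(df, ["protein_id", "organism", "reference_complex"], path)
    ref = [
        c.strip() if c.strip() else "none"
        for c in df["reference_complex"].tolist()
    ]
    return AnnotationTable(
        protein_ids=df["protein_id"].tolist(),
        organism=[o.strip() for o in df["organism"].tolist()],
        reference_complex=ref,
    )


def write_annotations(ann: AnnotationTable, path) -> None:
    pd.DataFrame(
        {
            "protein_id": ann.protein_ids,
            "organism": ann.organism,
            "reference_complex": ann.reference_complex,
        }
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_counts_table(path) -> CountsTimecourse:
    """Read a transcript × time-point count TSV.

    Header: ``transcript_id``, ``genome``, then time columns labelled in
    minutes (``t0``, ``t2``, ...), strictly increasing left to right.
    Counts must be non-negative integers.
    """
    df = _read_tsv(path)
    _require_columns(df, ["transcript_id", "genome"], path)
    time_cols = [c for c in df.columns if c not in ("transcript_id", "genome")]
    if not time_cols:
        raise FormatError(f"{path}: no time-point columns found")
    times = []
    for c in time_cols:
        match = _TIME_LABEL_RE.match(c)
        if not match:
            raise FormatError(
                f"{path}: column {c!r} is not a time label (expected e.g. t0, t2)"
            )
        times.append(float(match.group(1)))
    if any(b <= a for a, b in zip(times, times[1:])):
        raise FormatError(
            f"{path}: time columns must be strictly increasing; got {time_cols}"
        )
    counts = np.empty((len(df), len(time_cols)), dtype=np.int64)
    for j, col in enumerate(time_cols):
        for i, text in enumerate(df[col].tolist()):
            try:
                v = float(text)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {i + 1}, column {col}: "
                    f"unparseable count {text!r}"
                ) from exc
            if not math.isfinite(v) or v != round(v):
                raise FormatError(
                    f"{path}: row {i + 1}, column {col}: "
                    f"count {text!r} is not an integer"
                )
            if v < 0:
                raise FormatError(
                    f"{path}: row {i + 1}, column {col}: negative count {text!r}"
                )
            counts[i, j] = int(round(v))
    return CountsTimecourse(
        transcript_ids=df["transcript_id"].tolist(),
        genome=[g.strip() for g in df["genome"].tolist()],
        timepoints=np.array(times, dtype=float),
        counts=counts,
    )


def write_counts_table(tc: CountsTimecourse, path) -> None:
    tc.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gene_map(path) -> dict[str, str]:
    """Read a protein → transcript mapping TSV (protein_id, transcript_id)."""
    df = _read_tsv(path)
    _require_columns(df, ["protein_id", "transcript_id"], path)
    ids = df["protein_id"].tolist()
    if len(set(ids)) != len(ids):
        raise IntegrityError(f"{path}: duplicate protein_id in gene map")
    return dict(zip(ids, df["transcript_id"].tolist()))


def write_gene_map(gene_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {
            "protein_id": list(gene_map.keys()),
            "transcript_id": list(gene_map.values()),
        }
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
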