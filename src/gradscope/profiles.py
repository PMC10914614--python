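"""Sedimentation-profile construction from raw gradient intensities.

A lysate separated on a glycerol gradient is collected as 20 fractions plus
the pellet, and each protein's intensity across those compartments is its
sedimentation signature. Three steps turn raw intensities into comparable
profiles:

1. **Spike-in correction** — every fraction received the same amount of a
   foreign standard protein (human albumin in the original protocol), so
   per-fraction technical scale differences are removed by dividing each
   column by the spike-in's value in that column (rescaled to the median
   spike-in level so overall magnitudes stay interpretable).
2. **Per-protein normalization** — fractions 1–20 are divided by their own
   maximum (peak set to 1), while the pellet is expressed as a *share* of
   the protein's total abundance across the whole gradient. The two scales
   are deliberately different: the fraction vector encodes shape, the
   pellet share encodes how much of the protein sank to the tube bottom.
3. **Abundance filter** — only proteins whose summed, spike-corrected
   intensity exceeds 10^8 (log10 > 8.0 by default) are retained; below
   that, iBAQ-style quantification is too noisy to interpret as a profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSpikeInError, EmptyProfileError, FormatError
from .io import (
    FRACTION_COLUMNS,
    N_FRACTIONS,
    IntensityMatrix,
    _read_tsv,
    _require_columns,
)

logger = logging.getLogger(__name__)

PELLET_DENOMINATORS = ("total", "gradient_only")


@dataclass
class SedimentationProfile:
    """Normalized 20-fraction vector plus pellet share for one protein.

    ``fractions`` is max-normalized (peak = 1); ``pellet_share`` is the
    pellet's share of total protein; ``total_intensity`` is the sum of all
    21 raw (spike-corrected) values; ``peak_fraction`` is 1-based, ties
    broken to the lowest index.
    """

    protein_id: str
    fractions: np.ndarray
    pellet_share: float
    total_intensity: float
    peak_fraction: int
    organism: str = "host"

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (N_FRACTIONS,):
            raise ValueError("fractions must be a 20-vector")


def spike_in_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Correct per-fraction technical scale using the spike-in row.

    Column *j* of every row is multiplied by ``s_ref / s_j`` where ``s_j``
    is the spike-in's value in column *j* and ``s_ref`` is the median of
    the 21 spike-in values. The spike-in row itself becomes constant at
    ``s_ref``. Idempotent: applying twice equals applying once.
    """
    s = m.values[m.spike_index].copy()
    if np.any(s <= 0):
        raise DegenerateSpikeInError(
            f"spike-in row {m.spike_in_id!r} has non-positive values; "
            "per-fraction correction factors are undefined"
        )
    s_ref = float(np.median(s))
    corrected = m.values * (s_ref / s)[np.newaxis, :]
    out = m.copy()
    out.values = corrected
    out.validate()
    return out


def normalize_profile(
    raw: np.ndarray,
    protein_id: str = "",
    organism: str = "host",
    pellet_denominator: str = "total",
) -> SedimentationProfile:
    """Build a sedimentation profile from one row of 21 raw values.

    ``fractions_i = raw_i / max(raw_1..raw_20)``;
    ``pellet_share = raw_P / (sum(raw_1..20) + raw_P)`` (default) or
    ``raw_P / sum(raw_1..20)`` with ``pellet_denominator='gradient_only'``.
    Scale-invariant: multiplying the row by any c > 0 leaves the profile
    unchanged.
    """
    if pellet_denominator not in PELLET_DENOMINATORS:
        raise ValueError(
            f"pellet_denominator must be one of {PELLET_DENOMINATORS}"
        )
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (N_FRACTIONS + 1,):
        raise ValueError("expected 21 values (F01..F20 then P)")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise ValueError("raw values must be finite and non-negative")
    if not np.any(raw > 0):
        raise EmptyProfileError(
            f"protein {protein_id!r}: all 21 values are zero"
        )
    grad = raw[:N_FRACTIONS]
    pellet = float(raw[N_FRACTIONS])
    fmax = float(grad.max())
    if fmax > 0:
        fractions = grad / fmax
        peak = int(np.argmax(grad)) + 1  # argmax takes the lowest tied index
    else:
        # pellet-only protein: flat zero fraction vector, peak defaults to 1
        fractions = grad.copy()
        peak = 1
    if pellet_denominator == "total":
        share = pellet / (float(grad.sum()) + pellet)
    else:
        share = pellet / float(grad.sum()) if grad.sum() > 0 else math.inf
    return SedimentationProfile(
        protein_id=protein_id,
        fractions=fractions,
        pellet_share=float(share),
        total_intensity=float(raw.sum()),
        peak_fraction=peak,
        organism=organism,
    )


def normalize_matrix(
    m: IntensityMatrix,
    pellet_denominator: str = "total",
    skip_empty: bool = True,
) -> list[SedimentationProfile]:
    """Normalize every row of a (spike-corrected) intensity matrix.

    All-zero rows are skipped with a logged count when ``skip_empty`` is
    true, otherwise they raise :class:`EmptyProfileError`.
    """
    profiles: list[SedimentationProfile] = []
    n_empty = 0
    for pid, row, org in zip(m.protein_ids, m.values, m.organism):
        try:
            profiles.append(
                normalize_profile(
                    row, pid, org, pellet_denominator=pellet_denominator
                )
            )
        except EmptyProfileError:
            if not skip_empty:
                raise
            n_empty += 1
    if n_empty:
        logger.warning("%d all-zero protein rows excluded", n_empty)
    return profiles


def filter_by_abundance(
    profiles: list[SedimentationProfile],
    threshold_log10: float = 8.0,
    spike_in_id: str | None = None,
) -> list[SedimentationProfile]:
    """Retain proteins with log10(total spike-corrected intensity) strictly
    above ``threshold_log10``. The spike-in row is always excluded.

    An empty result is permitted (and logged).
    """
    kept = [
        p
        for p in profiles
        if p.protein_id != spike_in_id
        and p.organism != "spike_in"
        and p.total_intensity > 0
        and math.log10(p.total_intensity) > threshold_log10
    ]
    if not kept:
        logger.warning(
            "abundance filter at log10 > %s retained no proteins",
            threshold_log10,
        )
    return kept


# ---------------------------------------------------------------------------
# profile table IO (the pipeline's intermediate format)

_PROFILE_COLUMNS = (
    ["protein_id"]
    + FRACTION_COLUMNS
    + ["pellet_share", "total_intensity", "peak_fraction", "organism"]
)


def write_profiles_table(profiles: list[SedimentationProfile], path) -> None:
    rows = []
    for p in profiles:
        row: dict[str, object] = {"protein_id": p.protein_id}
        for col, v in zip(FRACTION_COLUMNS, p.fractions):
            row[col] = repr(float(v))
        row["pellet_share"] = repr(float(p.pellet_share))
        row["total_intensity"] = repr(float(p.total_intensity))
        row["peak_fraction"] = p.peak_fraction
        row["organism"] = p.organism
        rows.append(row)
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_profiles_table(path) -> list[SedimentationProfile]:
    df = _read_tsv(path)
    _require_columns(df, _PROFILE_COLUMNS, path)
    profiles = []
    for _, rec in df.iterrows():
        try:
            fractions = np.array(
                [float(rec[c]) for c in FRACTION_COLUMNS], dtype=float
            )
            profiles.append(
                SedimentationProfile(
                    protein_id=rec["protein_id"],
                    fractions=fractions,
                    pellet_share=float(rec["pellet_share"]),
                    total_intensity=float(rec["total_intensity"]),
                    peak_fraction=int(rec["peak_fraction"]),
                    organism=rec["organism"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad profile row: {exc}") from exc
    return profiles
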