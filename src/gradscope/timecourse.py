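"""Infection time-course analysis: genome shares and transcript ranking.

After phage addition, phage mRNAs accumulate until they account for a
large share of all coding transcripts. Two quantities drive candidate
prioritization:

* the per-time-point **genome read fraction** — phage counts divided by
  total counts at each time point;
* a **cumulative abundance ranking** of phage transcripts over the early
  window: transcripts are sorted by summed raw counts and the minimal
  prefix whose cumulative share strictly exceeds a cutoff (default 85% of
  total phage reads) forms the "top set" of early, abundant transcripts.

Candidates that co-sediment with ribosomes are then ordered by whether
their transcript is in the top set, its rank, and the co-sedimentation
score — early, abundant expression first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .candidates import CandidateCall
from .errors import ParameterError, UndefinedFractionError
from .io import CountsTimecourse


@dataclass
class TranscriptRank:
    """One phage transcript's abundance share and rank over the window."""

    transcript_id: str
    genome: str
    share: float
    rank: int
    in_top_set: bool


@dataclass
class PrioritizedCandidate:
    """A candidate joined to its transcript's expression rank."""

    protein_id: str
    transcript_id: str | None
    rank: int | None
    in_top_set: bool
    score: float
    mapped: bool


def genome_read_fraction(tc: CountsTimecourse) -> np.ndarray:
    """Phage share of total counts at each time point, in [0, 1]."""
    totals = tc.counts.sum(axis=0)
    if np.any(totals == 0):
        t = tc.timepoints[int(np.flatnonzero(totals == 0)[0])]
        raise UndefinedFractionError(
            f"zero total counts at time point t={t:g}; fraction undefined"
        )
    phage = tc.counts[tc.phage_mask].sum(axis=0)
    return phage / totals


def rank_transcripts_cumulative(
    tc: CountsTimecourse,
    window: tuple[float, float] = (0.0, 10.0),
    cutoff: float = 0.85,
) -> list[TranscriptRank]:
    """Rank phage transcripts by summed counts with a cumulative cutoff.

    Counts are summed over time points inside ``window`` (inclusive),
    transcripts sorted descending (ties by id, lexicographic), and
    ``in_top_set`` marks the minimal prefix whose cumulative share
    *strictly exceeds* ``cutoff``. Shares are of total phage reads in the
    window and sum to 1.
    """
    if not 0.0 < cutoff < 1.0:
        raise ParameterError(f"cutoff must be in (0, 1); got {cutoff}")
    lo, hi = window
    if hi < lo:
        raise ParameterError(f"empty window {window}")
    tmask = (tc.timepoints >= lo) & (tc.timepoints <= hi)
    if not tmask.any():
        raise ParameterError(f"window {window} contains no time points")
    pmask = tc.phage_mask
    sums = tc.counts[:, tmask].sum(axis=1)
    entries = [
        (tc.transcript_ids[i], int(sums[i]))
        for i in range(len(tc.transcript_ids))
        if pmask[i]
    ]
    total = sum(s for _, s in entries)
    if total == 0:
        raise ParameterError(
            "no phage transcript has nonzero counts in the window"
        )
    entries.sort(key=lambda e: (-e[1], e[0]))
    ranks: list[TranscriptRank] = []
    cumulative = 0.0
    top_open = True
    for rank, (tid, s) in enumerate(entries, start=1):
        share = s / total
        in_top = top_open
        cumulative += share
        if cumulative > cutoff:
            top_open = False
        ranks.append(
            TranscriptRank(
                transcript_id=tid,
                genome="phage",
                share=share,
                rank=rank,
                in_top_set=in_top,
            )
        )
    return ranks


def top_set_size(ranks: list[TranscriptRank]) -> int:
    return sum(r.in_top_set for r in ranks)


def prioritize_candidates(
    candidates: list[CandidateCall],
    ranks: list[TranscriptRank],
    gene_map: dict[str, str] | None = None,
) -> list[PrioritizedCandidate]:
    """Order candidates by early transcript abundance.

    Sort key: in_top_set (top-set members first), transcript rank
    ascending, co-sedimentation score descending. A candidate whose
    protein maps to no ranked transcript sorts last and is flagged
    ``mapped=False``. ``gene_map`` maps protein id → transcript id;
    omitted, the identity mapping is used.
    """
    rank_by_id = {r.transcript_id: r for r in ranks}
    out: list[PrioritizedCandidate] = []
    for c in candidates:
        tid = (gene_map or {}).get(c.protein_id, c.protein_id)
        r = rank_by_id.get(tid)
        if r is None:
            out.append(
                PrioritizedCandidate(
                    protein_id=c.protein_id,
                    transcript_id=None,
                    rank=None,
                    in_top_set=False,
                    score=c.score,
                    mapped=False,
                )
            )
        else:
            out.append(
                PrioritizedCandidate(
                    protein_id=c.protein_id,
                    transcript_id=tid,
                    rank=r.rank,
                    in_top_set=r.in_top_set,
                    score=c.score,
                    mapped=True,
                )
            )
    out.sort(
        key=lambda p: (
            not p.in_top_set,
            p.rank if p.rank is not None else math.inf,
            -p.score,
            p.protein_id,
        )
    )
    return out
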