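"""Selection rules for phage ribosome-association candidates.

During jumbo-phage infection most phage proteins stay in the first few
low-molecular-weight gradient fractions (monomers and small complexes),
structural virion proteins accumulate in the pellet (virion assembly
intermediates), and a small set of phage proteins co-sediments with
ribosomal subunits without pelleting. That last set — HMW peak, ribosomal
co-sedimentation, low pellet share — is the candidate class this module
nominates, together with a 30S-vs-50S subunit call.

Rules, each a declared parameter:

* **HMW**: peak fraction ≥ ``hmw_min_fraction`` (default 4; fractions 1–3
  are the low-molecular-weight end).
* **ribosomal**: assigned to a 30S or 50S reference centroid at
  correlation ≥ ``r_min``.
* **soluble**: pellet share ≤ ``pellet_max`` (default 0.2) — a pellet-heavy
  protein is virion-like, not a soluble ribosome binder.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import ComplexAssignment, ReferenceCentroid, _pearson
from .errors import AmbiguousSubunitError, ParameterError
from .profiles import SedimentationProfile

RIBOSOMAL_LABELS = ("30S", "50S")


@dataclass
class CandidateCall:
    """One phage protein's pass/fail against the candidate rules."""

    protein_id: str
    is_hmw: bool
    pellet_share: float
    assigned_label: str
    subunit_class: str  # 30S, 50S or none
    score: float
    passes: bool


def flag_hmw(
    profile: SedimentationProfile, hmw_min_fraction: int = 4
) -> bool:
    """True iff the profile peaks at or beyond the HMW boundary fraction."""
    return profile.peak_fraction >= hmw_min_fraction


def call_ribosome_candidates(
    profiles: list[SedimentationProfile],
    assignments: list[ComplexAssignment],
    organism: str = "phage",
    pellet_max: float = 0.2,
    hmw_min_fraction: int = 4,
) -> list[CandidateCall]:
    """Nominate ribosome-association candidates among one organism's proteins.

    A protein passes iff it is HMW, assigned to a ribosomal (30S/50S)
    centroid, and its pellet share is at most ``pellet_max``. Only passing
    calls are returned, sorted by correlation score descending (ties by
    protein id for determinism). Assignments must have been computed with
    the intended ``r_min``; the correlation threshold lives there.
    """
    if not 0 <= pellet_max <= 1:
        raise ParameterError("pellet_max must be in [0, 1]")
    assign_by_id = {a.protein_id: a for a in assignments}
    calls: list[CandidateCall] = []
    for p in profiles:
        if p.organism != organism:
            continue
        a = assign_by_id.get(p.protein_id)
        if a is None:
            continue
        hmw = flag_hmw(p, hmw_min_fraction)
        ribosomal = a.label in RIBOSOMAL_LABELS
        passes = hmw and ribosomal and p.pellet_share <= pellet_max
        if passes:
            calls.append(
                CandidateCall(
                    protein_id=p.protein_id,
                    is_hmw=hmw,
                    pellet_share=p.pellet_share,
                    assigned_label=a.label,
                    subunit_class=a.label if ribosomal else "none",
                    score=a.score,
                    passes=True,
                )
            )
    calls.sort(key=lambda c: (-c.score, c.protein_id))
    return calls


def classify_subunit(
    profile: SedimentationProfile,
    centroid_30s: ReferenceCentroid,
    centroid_50s: ReferenceCentroid,
    tie_tolerance: float = 1e-9,
) -> str:
    """30S-vs-50S call by the higher centroid correlation.

    A tie within ``tie_tolerance`` raises :class:`AmbiguousSubunitError`
    — an ambiguous class is flagged for manual review, never silently
    resolved.
    """
    r30 = _pearson(profile.fractions, centroid_30s.centroid)
    r50 = _pearson(profile.fractions, centroid_50s.centroid)
    if abs(r30 - r50) < tie_tolerance:
        raise AmbiguousSubunitError(
            f"protein {profile.protein_id!r}: 30S vs 50S correlations tie "
            f"(r30={r30:.6f}, r50={r50:.6f}); manual review required"
        )
    return "30S" if r30 > r50 else "50S"
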