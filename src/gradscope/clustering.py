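"""Co-sedimentation clustering and machinery assignment.

Proteins that are part of the same macromolecular complex sediment
together, so their normalized fraction vectors are highly correlated. This
module provides:

* a correlation distance (1 − Pearson r over the 20 fractions; the pellet
  is excluded because it lives on a share-of-total scale, not the
  max-normalized shape scale);
* agglomerative hierarchical clustering of profiles (average or complete
  linkage) for the global heat-map view;
* a 2-D t-SNE embedding as a diagnostic view of profile neighbourhoods;
* reference centroids — the mean normalized profile of annotated members
  of each machinery (30S, 50S, RNAP, ...) — and a correlation-based
  assignment rule: a protein is assigned to the centroid it correlates
  with best, provided that correlation reaches ``r_min`` (default 0.8).

Machinery assignment deliberately uses the centroid-correlation rule, not
the embedding: the embedding is for eyes, the correlation is the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from sklearn.manifold import TSNE

from .errors import (
    InsufficientReferenceError,
    ParameterError,
    UndefinedCorrelationError,
)
from .io import N_FRACTIONS, AnnotationTable
from .profiles import SedimentationProfile

ASSIGNABLE_LABELS = ("30S", "50S", "RNAP", "other")
UNASSIGNED = "unassigned"
LINKAGE_METHODS = ("average", "complete")


@dataclass
class ReferenceCentroid:
    """Mean normalized fraction vector of a machinery's annotated members."""

    label: str
    centroid: np.ndarray
    n_members: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (N_FRACTIONS,):
            raise ValueError("centroid must be a 20-vector")


@dataclass
class ComplexAssignment:
    """A protein's best-correlated machinery label and the correlation."""

    protein_id: str
    label: str
    score: float


# ---------------------------------------------------------------------------
# distance


def _fraction_vector(p: SedimentationProfile | np.ndarray) -> np.ndarray:
    if isinstance(p, SedimentationProfile):
        return p.fractions
    v = np.asarray(p, dtype=float)
    if v.shape != (N_FRACTIONS,):
        raise ValueError("expected a 20-fraction vector")
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt((xc**2).sum()))
    ny = float(np.sqrt((yc**2).sum()))
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for a zero-variance profile"
        )
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def profile_distance(
    p: SedimentationProfile | np.ndarray, q: SedimentationProfile | np.ndarray
) -> float:
    """1 − Pearson r over the 20 fraction values (pellet excluded).

    Ranges over [0, 2]: 0 for identical shapes, 2 for perfect
    anti-correlation. Symmetric; raises on zero-variance input.
    """
    return 1.0 - _pearson(_fraction_vector(p), _fraction_vector(q))


def distance_matrix(profiles: list[SedimentationProfile]) -> np.ndarray:
    """Full symmetric matrix of pairwise profile distances."""
    X = np.vstack([p.fractions for p in profiles])
    sd = X.std(axis=1)
    if np.any(sd == 0):
        flat = [p.protein_id for p, s in zip(profiles, sd) if s == 0]
        raise UndefinedCorrelationError(
            f"zero-variance profile(s): {flat[:5]}"
        )
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


# ---------------------------------------------------------------------------
# hierarchical clustering


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(D, k=1)
    return D[iu]


def hierarchical_cluster(
    profiles: list[SedimentationProfile],
    linkage: str = "average",
    k: int = 2,
) -> np.ndarray:
    """Agglomerative clustering on correlation distance; k flat clusters.

    Returns integer labels 0..k−1, renumbered in order of first appearance
    so the labelling is deterministic for a given input order.
    """
    if linkage not in LINKAGE_METHODS:
        raise ParameterError(f"linkage must be one of {LINKAGE_METHODS}")
    n = len(profiles)
    if n < 2:
        raise ParameterError("need at least 2 profiles to cluster")
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside 1..n={n}")
    Z = linkage_matrix(profiles, linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels


def linkage_matrix(
    profiles: list[SedimentationProfile], linkage: str = "average"
) -> np.ndarray:
    """scipy-format linkage matrix on the profile correlation distance."""
    if linkage not in LINKAGE_METHODS:
        raise ParameterError(f"linkage must be one of {LINKAGE_METHODS}")
    D = distance_matrix(profiles)
    return hierarchy.linkage(_condensed(D), method=linkage)


def merge_sequence(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf-index sets created at each agglomeration step of a linkage
    matrix — a representation of merge order that is independent of the
    clustering library's internal node numbering."""
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        new = clusters[int(a)] | clusters[int(b)]
        clusters[n + step] = new
        merges.append(new)
    return merges


# ---------------------------------------------------------------------------
# embedding


def embed_2d(
    profiles: list[SedimentationProfile],
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """t-SNE embedding of the 20-dim normalized fraction vectors.

    Reproducible for a fixed seed. Requires n ≥ 3 × perplexity so the
    neighbourhood size is meaningful.
    """
    n = len(profiles)
    if perplexity <= 0:
        raise ParameterError("perplexity must be > 0")
    if n < 3 * perplexity:
        raise ParameterError(
            f"perplexity {perplexity} too large for n={n} profiles "
            f"(need n >= 3*perplexity)"
        )
    X = np.vstack([p.fractions for p in profiles])
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed),
        init="pca",
        learning_rate="auto",
    )
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# reference centroids and assignment


def build_reference_centroids(
    profiles: list[SedimentationProfile],
    annotations: AnnotationTable,
    min_members: int = 3,
) -> list[ReferenceCentroid]:
    """Mean fraction vector per annotated reference complex.

    Every reference label present in the annotation table must have at
    least ``min_members`` members among the supplied (filter-passing)
    profiles, otherwise the centroid would not be trustworthy and an
    :class:`InsufficientReferenceError` is raised naming the label.
    """
    by_id = {p.protein_id: p for p in profiles}
    centroids = []
    for label in annotations.labels():
        members = [
            by_id[pid] for pid in annotations.members(label) if pid in by_id
        ]
        if len(members) < min_members:
            raise InsufficientReferenceError(
                f"reference complex {label!r} has {len(members)} member "
                f"profile(s); at least {min_members} required"
            )
        centroid = np.mean([m.fractions for m in members], axis=0)
        centroids.append(
            ReferenceCentroid(
                label=label, centroid=centroid, n_members=len(members)
            )
        )
    return centroids


def assign_to_reference(
    profile: SedimentationProfile,
    centroids: list[ReferenceCentroid],
    r_min: float = 0.8,
) -> ComplexAssignment:
    """Assign a profile to its best-correlated reference centroid.

    The label is the centroid with the maximal Pearson r against the
    profile's fraction vector; if that maximum is below ``r_min`` the
    protein is ``unassigned``. The score is always the maximal r.
    """
    if not centroids:
        raise ParameterError("no reference centroids supplied")
    best_label, best_r = None, -np.inf
    for c in centroids:
        r = _pearson(profile.fractions, c.centroid)
        if r > best_r:
            best_label, best_r = c.label, r
    label = best_label if best_r >= r_min else UNASSIGNED
    return ComplexAssignment(
        protein_id=profile.protein_id, label=label, score=float(best_r)
    )


def assign_all(
    profiles: list[SedimentationProfile],
    centroids: list[ReferenceCentroid],
    r_min: float = 0.8,
) -> list[ComplexAssignment]:
    return [assign_to_reference(p, centroids, r_min=r_min) for p in profiles]
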