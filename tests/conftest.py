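"""Shared fixtures: the default simulated study, normalized once per session."""

from __future__ import annotations

import numpy as np
import pytest

from gradscope.clustering import assign_all, build_reference_centroids
from gradscope.profiles import (
    filter_by_abundance,
    normalize_matrix,
    spike_in_normalize,
)
from gradscope.simulate import (
    default_gradient_config,
    default_timecourse_config,
    simulate_gradient,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def gradient_sim():
    """Default simulated gradient (seed 42): raw matrix plus ground truth."""
    return simulate_gradient(default_gradient_config(seed=42))


@pytest.fixture(scope="session")
def normalized_study(gradient_sim):
    """The default study after spike-in correction, profile normalization,
    abundance filtering, centroid building and machinery assignment."""
    matrix, truth = gradient_sim
    corrected = spike_in_normalize(matrix)
    profiles = normalize_matrix(corrected)
    retained = filter_by_abundance(
        profiles, threshold_log10=8.0, spike_in_id=matrix.spike_in_id
    )
    annotations = truth.annotation_table()
    centroids = build_reference_centroids(retained, annotations)
    assignments = assign_all(retained, centroids, r_min=0.8)
    return {
        "matrix": matrix,
        "corrected": corrected,
        "truth": truth,
        "profiles": profiles,
        "retained": retained,
        "annotations": annotations,
        "centroids": centroids,
        "assignments": assignments,
    }


@pytest.fixture(scope="session")
def timecourse_sim():
    """Default simulated infection time course (seed 42)."""
    return simulate_timecourse(default_timecourse_config(seed=42))


# ---------------------------------------------------------------------------
# independent oracles


def bruteforce_agglomeration(
    D: np.ndarray, method: str = "average"
) -> list[frozenset[int]]:
    """Exhaustive agglomerative clustering, recomputing every pairwise
    cluster-to-cluster linkage value at each step from the original
    distance matrix. Ties break to the lexicographically lowest cluster
    index pair. Returns the merged leaf-index set at each step."""
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(D))]
    merges: list[frozenset[int]] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pair_ds = [D[a, b] for a in clusters[i] for b in clusters[j]]
                d = max(pair_ds) if method == "complete" else float(
                    np.mean(pair_ds)
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [
            c for k, c in enumerate(clusters) if k not in (i, j)
        ] + [merged]
    return merges


def pearson_textbook(x, y) -> float:
    """Straight-from-the-definition Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.sum() / n, y.sum() / n
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum()) * np.sqrt(((y - my) ** 2).sum())
    return float(num / den)


def topset_bruteforce(counts: np.ndarray, cutoff: float) -> int:
    """Prefix-sum oracle for the cumulative top-set size: sort descending,
    count how many items are needed for the running share to exceed the
    cutoff."""
    total = counts.sum()
    shares = np.sort(counts)[::-1] / total
    running = 0.0
    for k, s in enumerate(shares, start=1):
        running += s
        if running > cutoff:
            return k
    return len(shares)
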