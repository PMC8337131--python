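"""Descriptor matching by nearest / next-nearest Euclidean distance.

Search is brute force (the descriptor sets here are small, and exactness
beats speed); a match survives iff the ratio of the first to the second
nearest-neighbour distance does not exceed the threshold.  Distance ties
are broken by the lower train index, so matching is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class Match:
    query_index: int
    train_index: int
    distance: float
    ratio: float


def descriptor_distance(a, b) -> float:
    """Euclidean distance between two descriptor vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"descriptor dimensionality mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def match_descriptors(query, train, ratio_threshold: float = 0.7) -> list[Match]:
    """One best train match per query descriptor, ratio-test filtered.

    With a single train descriptor the match is kept unconditionally
    (ratio recorded as 0).  ``ratio_threshold=1.0`` disables the filter,
    reproducing raw first-nearest-neighbour matching.
    """
    if not 0.0 < ratio_threshold <= 1.0:
        raise ValueError(f"ratio threshold must be in (0, 1], got {ratio_threshold}")
    if len(query) == 0 or len(train) == 0:
        return []
    q = np.asarray(query, dtype=np.float64)
    t = np.asarray(train, dtype=np.float64)
    if q.shape[1] != t.shape[1]:
        raise ValueError(f"descriptor dimensionality mismatch: {q.shape[1]} vs {t.shape[1]}")
    d = cdist(q, t)
    matches: list[Match] = []
    for i in range(d.shape[0]):
        order = np.argsort(d[i], kind="stable")  # stable: ties -> lower train index
        j = int(order[0])
        d1 = float(d[i, j])
        if d.shape[1] == 1:
            matches.append(Match(i, j, d1, 0.0))
            continue
        d2 = float(d[i, int(order[1])])
        ratio = d1 / d2 if d2 > 0 else (0.0 if d1 == 0 else 1.0)
        if ratio <= ratio_threshold:
            matches.append(Match(i, j, d1, ratio))
    return matches


def matches_to_points(matches, query_kps, train_kps):
    """Matches -> ((x_query, y_query), (x_train, y_train)) coordinate pairs.

    Query keypoints come from the floating image and train keypoints from
    the registration target, so the pairs feed affine estimation in the
    floating-to-reference direction.
    """
    pairs = []
    for m in matches:
        if not (0 <= m.query_index < len(query_kps)) or not (
            0 <= m.train_index < len(train_kps)
        ):
            raise ValueError(f"match index out of range: {m}")
        qk = query_kps[m.query_index]
        tk = train_kps[m.train_index]
        pairs.append(((qk.x, qk.y), (tk.x, tk.y)))
    return pairs
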