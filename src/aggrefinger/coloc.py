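"""Two-channel spot colocalization with a chance-match estimate.

Spots detected independently in two channels are matched by Euclidean
distance within a fixed radius (default 4 px), taking the closest candidate
and enforcing one-to-one pairing greedily by ascending distance. The
expected rate of spurious matches is estimated by mirroring the second
channel's x-coordinates about the image midline — destroying true
correspondence while preserving density and y-structure — and re-running
the same matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class ColocResult:
    pairs: list[tuple[int, int]]  # (index in A, index in B)
    n_a: int
    n_b: int
    radius_px: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def proportion(self) -> float:
        """Proportion of reference-channel (A) spots colabelled."""
        return coloc_proportion(self)


def match_spots(centroids_a: np.ndarray, centroids_b: np.ndarray,
                radius_px: float = 4.0) -> ColocResult:
    """One-to-one nearest matching of A-spots to B-spots within ``radius_px``.

    Candidate pairs within the radius are sorted by (distance, A index,
    B index) and accepted greedily, so each spot joins at most one pair and
    ties at identical distance resolve deterministically to the lower index.
    """
    if radius_px < 0:
        raise ValueError("radius must be non-negative")
    a = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    b = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return ColocResult([], len(a) if a.size else 0, len(b) if b.size else 0,
                           radius_px)

    tree = cKDTree(b)
    candidates = []
    for i, neighbours in enumerate(tree.query_ball_point(a, radius_px)):
        for j in neighbours:
            d = float(np.hypot(*(a[i] - b[j])))
            candidates.append((d, i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return ColocResult(pairs, len(a), len(b), radius_px)


def coloc_proportion(result: ColocResult) -> float:
    """Matched pairs over the reference channel's total spot count."""
    if result.n_a == 0:
        raise ValueError("reference channel has no spots; proportion undefined")
    return result.n_matched / result.n_a


def chance_coloc_proportion(centroids_a: np.ndarray, centroids_b: np.ndarray,
                            image_width_px: float, radius_px: float = 4.0,
                            mode: str = "mirror_x") -> float:
    """Chance colocalization proportion after scrambling channel B.

    ``mirror_x`` (default) maps x -> (width - 1) - x; ``swap_xy`` exchanges
    the coordinate axes. Either transform preserves point density while
    destroying real correspondence.
    """
    if image_width_px <= 0:
        raise ValueError("image width must be positive")
    b = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    if b.size == 0:
        return 0.0
    if np.any(b[:, 0] < 0) or np.any(b[:, 0] >= image_width_px):
        raise ValueError("B x-coordinates outside [0, width)")
    if mode == "mirror_x":
        b = np.column_stack([(image_width_px - 1) - b[:, 0], b[:, 1]])
    elif mode == "swap_xy":
        b = b[:, ::-1]
    else:
        raise ValueError(f"unknown chance mode {mode!r}")
    return coloc_proportion(match_spots(centroids_a, b, radius_px))
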