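"""k-nearest-neighbour entropy estimators with periodic K-D tree searches.

Three estimators are exposed:

* :func:`generic_entropy` — the generic p-dimensional estimator.  For M
  samples with k-th neighbour distances d (self excluded) it computes

      H = < ln( c_p (M-1) d^p / V_ref ) > - psi(k),      c_p = pi^(p/2) / Gamma(p/2+1),

  which with V_ref = 1 is the Kozachenko-Leonenko / Singh differential
  entropy estimator.

* :func:`h1_estimate` — the one-particle estimator over a trajectory of N
  atoms and F frames.  Neighbour candidates for an atom in frame j are the
  atoms of the other F-1 frames (never the same frame), giving

      H1 = < ln( 4 pi N (F-1) d^3 / (3 V) ) > - psi(k).

  H1 estimates  -(1/V) \\int g(r) ln g(r) dr  for the one-particle density
  rho g(r) around a fixed solute; it is 0 for an unstructured fluid and
  negative for a structured one.

* :func:`h2_estimate` — the two-particle (pair-space, 6-D) estimator

      H2 = < ln( N (N-1) (F-1) pi^3 d^6 / (6 V^2) ) > - psi(k)

  over unordered atom pairs, with the exchange-symmetric pair metric
  (distance between pairs is minimised over the two particle matchings;
  implemented by inserting both orderings of every candidate pair into the
  K-D tree, which is also why the candidate count is the ordered-pair count
  N (N-1) (F-1)).  Same-frame candidates are excluded; candidates sharing an
  atom with the query pair but living in another frame are kept.

All searches use scipy's cKDTree; periodic boxes use its toroidal metric,
which applies the minimum image per coordinate (hence per 3-D block in pair
space).  Coincident points produce zero distances; the affected terms are
dropped with a warning (they are measure-zero for continuous systems).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .trajectory import Trajectory

__all__ = [
    "NeighborQuery",
    "EntropyEstimate",
    "knn_distance",
    "generic_entropy",
    "h1_estimate",
    "h2_estimate",
]


@dataclass(frozen=True)
class NeighborQuery:
    """Neighbour-search settings: rank k, optional box period, optional exclusions."""

    k: int = 1
    period: Optional[float] = None
    exclude: Optional[np.ndarray] = None  # indices into the candidate set to skip

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


@dataclass(frozen=True)
class EntropyEstimate:
    """Output of one estimator evaluation (dimensionless, per Eq.-42-style sums)."""

    value: float
    frames_used: int
    n_objects: int
    k: int
    n_dropped: int = 0  # zero-distance terms dropped


def _wrap(x: np.ndarray, period: Optional[float]) -> np.ndarray:
    if period is None:
        return x
    return x - period * np.floor(x / period)


def knn_distance(
    points: np.ndarray, query: np.ndarray, q: NeighborQuery
) -> float:
    """k-th smallest (minimum-image, if periodic) distance from ``query`` to ``points``.

    ``q.exclude`` lists candidate indices to skip (e.g. the query itself when
    it is a member of ``points``).
    """
    points = np.asarray(points, dtype=float)
    query = np.asarray(query, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array (M, p)")
    mask = np.ones(len(points), dtype=bool)
    if q.exclude is not None:
        mask[np.asarray(q.exclude, dtype=int)] = False
    candidates = points[mask]
    if len(candidates) < q.k:
        raise ValueError(
            f"need at least k={q.k} candidates after exclusions, have {len(candidates)}"
        )
    tree = cKDTree(_wrap(candidates, q.period), boxsize=q.period)
    d, _ = tree.query(_wrap(query[None, :], q.period), k=q.k)
    d = np.atleast_2d(d)
    return float(d[0, -1])


def _log_unit_ball(p: int) -> float:
    """ln of the p-dimensional unit-ball volume pi^(p/2)/Gamma(p/2+1)."""
    return 0.5 * p * math.log(math.pi) - gammaln(0.5 * p + 1.0)


def _drop_zero(logd_args: np.ndarray, what: str) -> tuple[np.ndarray, int]:
    nz = logd_args > 0.0
    n_dropped = int((~nz).sum())
    if n_dropped:
        warnings.warn(
            f"{what}: dropped {n_dropped} zero-distance (duplicate point) terms",
            stacklevel=3,
        )
    return logd_args[nz], n_dropped


def generic_entropy(
    samples: np.ndarray,
    q: NeighborQuery = NeighborQuery(),
    reference_volume: float = 1.0,
) -> EntropyEstimate:
    """Generic p-dimensional KNN entropy of a sample cloud (self excluded)."""
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    m, p = x.shape
    if m < q.k + 1:
        raise ValueError(f"need at least k+1={q.k + 1} samples, got {m}")
    tree = cKDTree(_wrap(x, q.period), boxsize=q.period)
    d, _ = tree.query(_wrap(x, q.period), k=q.k + 1)  # column 0 is self (d=0)
    dk = np.atleast_2d(d)[:, -1]
    dk, n_dropped = _drop_zero(dk, "generic_entropy")
    value = (
        p * np.mean(np.log(dk))
        + _log_unit_ball(p)
        + math.log(m - 1)
        - math.log(reference_volume)
        - digamma(q.k)
    )
    return EntropyEstimate(
        value=float(value), frames_used=m, n_objects=1, k=q.k, n_dropped=n_dropped
    )


def _cross_frame_kth(
    tree: cKDTree,
    points: np.ndarray,
    frame_of: np.ndarray,
    k: int,
    n_same_frame: int,
    pair_id: Optional[np.ndarray] = None,
) -> np.ndarray:
    """k-th neighbour distance for every point, skipping same-frame candidates.

    Queries a buffered number of neighbours and escalates per-point until k
    cross-frame neighbours are found.  When ``pair_id`` is given, candidates
    mapping to the same unordered pair are deduplicated (the pair metric is
    the min over the two orderings, so only the closest ordering counts).
    """
    n_pts = len(points)
    out = np.full(n_pts, np.nan)

    if pair_id is None:
        # vectorized fast path: query a buffered neighbour count, pick the
        # k-th cross-frame hit per row, fall back to the loop for stragglers
        m0 = min(k + 8, n_pts)
        d, idx = tree.query(points, k=m0)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        valid = frame_of[np.clip(idx, 0, n_pts - 1)] != frame_of[:, None]
        valid &= idx < n_pts
        cum = np.cumsum(valid, axis=1)
        enough = cum[:, -1] >= k
        pos = np.argmax(cum == k, axis=1)
        rows = np.flatnonzero(enough)
        out[rows] = d[rows, pos[rows]]
        todo = np.flatnonzero(~enough)
        if todo.size == 0:
            return out
        m = 2 * m0 + n_same_frame
    else:
        todo = np.arange(n_pts)
        m = k + 8
    while todo.size:
        m = min(m, n_pts)
        d, idx = tree.query(points[todo], k=m)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        unresolved = []
        for row, i in enumerate(todo):
            good_d = []
            seen: set = set()
            for col in range(d.shape[1]):
                j = idx[row, col]
                if j >= n_pts or frame_of[j] == frame_of[i]:
                    continue
                if pair_id is not None:
                    pid = pair_id[j]
                    if pid in seen:
                        continue
                    seen.add(pid)
                good_d.append(d[row, col])
                if len(good_d) == k:
                    break
            if len(good_d) == k:
                out[i] = good_d[-1]
            else:
                unresolved.append(i)
        if not unresolved:
            break
        if m == n_pts:
            raise ValueError("insufficient cross-frame neighbour candidates")
        todo = np.array(unresolved)
        m = 2 * m + n_same_frame
    return out


def h1_estimate(traj: Trajectory, k: int = 1) -> EntropyEstimate:
    """One-particle KNN entropy over a trajectory (neighbours from other frames)."""
    if traj.n_frames < 2:
        raise ValueError("h1_estimate needs at least 2 frames (the F-1 factor)")
    f, n = traj.n_frames, traj.n_atoms
    box = traj.box_edge
    pts = traj.coordinates.reshape(f * n, 3)
    pts = pts - box * np.floor(pts / box)
    frame_of = np.repeat(np.arange(f), n)
    tree = cKDTree(pts, boxsize=box)
    dk = _cross_frame_kth(tree, pts, frame_of, k, n_same_frame=n)
    dk, n_dropped = _drop_zero(dk, "h1_estimate")
    v = box**3
    value = (
        3.0 * np.mean(np.log(dk))
        + math.log(4.0 * math.pi * n * (f - 1) / (3.0 * v))
        - digamma(k)
    )
    return EntropyEstimate(
        value=float(value), frames_used=f, n_objects=n, k=k, n_dropped=n_dropped
    )


def h2_estimate(
    traj: Trajectory, k: int = 1, pair_cutoff: Optional[float] = None
) -> EntropyEstimate:
    """Two-particle (6-D pair-space) KNN entropy over a trajectory.

    ``pair_cutoff`` optionally restricts the pair list to pairs within a
    stated minimum-image separation, bounding the O(N^2 F) cost.  This is an
    approximation: the candidate count in the logarithm is then the actual
    ordered-candidate count in the other frames rather than N(N-1)(F-1).
    """
    if traj.n_frames < 2:
        raise ValueError("h2_estimate needs at least 2 frames (the F-1 factor)")
    f, n = traj.n_frames, traj.n_atoms
    if n < 2:
        raise ValueError("h2_estimate needs at least 2 atoms")
    box = traj.box_edge
    coords = traj.coordinates - box * np.floor(traj.coordinates / box)

    iu1, iu2 = np.triu_indices(n, 1)
    if pair_cutoff is not None:
        pair_rows = []
        for j in range(f):
            dvec = coords[j, iu1] - coords[j, iu2]
            dvec -= box * np.rint(dvec / box)
            sel = np.einsum("ij,ij->i", dvec, dvec) <= pair_cutoff**2
            pair_rows.append((j, iu1[sel], iu2[sel]))
    else:
        pair_rows = [(j, iu1, iu2) for j in range(f)]

    blocks, frames_list, pid_list = [], [], []
    per_frame_pairs = np.zeros(f, dtype=np.int64)
    for j, a, b in pair_rows:
        per_frame_pairs[j] = len(a)
        ab = np.concatenate([coords[j, a], coords[j, b]], axis=1)
        ba = np.concatenate([coords[j, b], coords[j, a]], axis=1)
        blocks.append(ab)
        blocks.append(ba)
        pid = j * (n * n) + a * n + b  # unordered pair id, same for both orderings
        pid_list.extend([pid, pid])
        frames_list.extend([np.full(len(a), j), np.full(len(a), j)])
    pts6 = np.concatenate(blocks, axis=0)
    frame_of = np.concatenate(frames_list)
    pair_id = np.concatenate(pid_list)
    if pts6.shape[0] == 0:
        raise ValueError("no pairs selected (pair_cutoff too small?)")

    tree = cKDTree(pts6, boxsize=box)
    # query one ordering of each pair only; the metric is exchange symmetric
    is_query = np.concatenate(
        [np.repeat([True, False], len(a)) for j, a, b in pair_rows]
    )
    q_idx = np.flatnonzero(is_query)
    dk_q = _cross_frame_kth(
        tree,
        pts6,
        frame_of,
        k,
        n_same_frame=2 * int(per_frame_pairs.max()),
        pair_id=pair_id,
    )[q_idx]
    dk, n_dropped = _drop_zero(dk_q, "h2_estimate")

    v = box**3
    if pair_cutoff is None:
        log_candidates = math.log(n * (n - 1) * (f - 1))
        cand_term = np.full(len(q_idx), log_candidates)[dk_q > 0]
    else:
        total_ordered = 2 * per_frame_pairs.sum()
        cand = total_ordered - 2 * per_frame_pairs[frame_of[q_idx]]
        cand_term = np.log(cand.astype(float))[dk_q > 0]
    value = (
        np.mean(6.0 * np.log(dk) + cand_term)
        + 3.0 * math.log(math.pi)
        - math.log(6.0)
        - 2.0 * math.log(v)
        - digamma(k)
    )
    n_pairs = int(per_frame_pairs.sum())
    return EntropyEstimate(
        value=float(value), frames_used=f, n_objects=n_pairs, k=k, n_dropped=n_dropped
    )
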