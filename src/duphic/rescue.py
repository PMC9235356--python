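"""Probabilistic rescue of multi-mapping Hi-C read pairs.

Standard Hi-C pipelines discard reads that align equally well to several
positions, which blanks out segmental duplications.  This module instead
allocates each multi-mapping read across its candidate bin pairs:

1. a genomic **distance-decay prior** is fitted by a univariate spline to
   the mean contact count per bin pair as a function of separation,
   using uniquely mapping reads only;
2. per-read **posteriors** over the candidates are computed iteratively,
   each candidate weighted by the prior at its distance times the local
   contact count (unique reads plus the current fractional allocation of
   all multireads) in a square neighbourhood around the candidate;
3. converged posteriors are either accumulated as **fractional counts**
   (every multiread contributes total mass 1 spread over candidates) or
   subjected to a **stringent filter** that keeps a read only when its
   best candidate reaches a posterior of at least 0.99.

The update is synchronous (Jacobi-style): all posteriors of a sweep are
computed from the previous sweep's matrix, so the result does not depend
on read order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .matrix import ContactMatrix
from .region import ReadPair

__all__ = [
    "DistanceDecayPrior",
    "PosteriorTable",
    "StringentResult",
    "bin_uni_reads",
    "fit_distance_prior",
    "allocate_multireads",
    "accumulate_fractional",
    "apply_stringent_filter",
    "accumulate_stringent",
]

PRIOR_FLOOR = 1e-12


@dataclass(frozen=True)
class DistanceDecayPrior:
    """Normalised contact probability as a function of distance (bins).

    ``probabilities`` sum to 1 over ``distances`` (the grid
    ``min_d .. max``).  Distances below ``min_d`` — self/adjacent-bin
    artefacts excluded from fitting — evaluate to the floor value, so
    short-range candidates are vanishingly down-weighted but never make
    a read's support empty.
    """

    distances: np.ndarray
    probabilities: np.ndarray
    min_d: int
    floor: float
    knots: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("distance grid must be strictly increasing")
        if np.any(self.probabilities <= 0):
            raise ValueError("prior probabilities must be positive")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("prior must be normalised")

    def evaluate(self, d) -> np.ndarray:
        """P(d) for any integer distance(s); floor outside the grid."""
        d = np.asarray(d, dtype=int)
        out = np.full(d.shape, self.floor, dtype=float)
        lo, hi = int(self.distances[0]), int(self.distances[-1])
        ok = (d >= lo) & (d <= hi)
        out[ok] = self.probabilities[d[ok] - lo]
        return out if out.shape else float(out)

    def loglog_slope(self) -> float:
        """OLS slope of log P(d) against log d over the fitted grid."""
        x = np.log(self.distances.astype(float))
        y = np.log(self.probabilities)
        return float(np.polyfit(x, y, 1)[0])


@dataclass
class PosteriorTable:
    """Per-read candidate posteriors after allocation.

    Every read appears; single-candidate reads carry posterior exactly 1.
    """

    posteriors: dict[str, list[tuple[tuple[int, int], float]]]
    iterations: int
    converged: bool

    def multi_ids(self) -> list[str]:
        return [rid for rid, ps in self.posteriors.items() if len(ps) > 1]


@dataclass(frozen=True)
class StringentResult:
    assignments: dict[str, tuple[int, int]]  # multireads kept, whole count 1
    n_kept: int
    n_dropped: int
    threshold: float


def bin_uni_reads(reads: list[ReadPair], bin_size: int,
                  n_bins: int) -> ContactMatrix:
    """Contact matrix of uniquely mapping reads only (mass = #uni)."""
    m = ContactMatrix(bin_size, n_bins)
    for r in reads:
        if not r.is_multi:
            i, j = r.candidates[0]
            m.add(i, j, 1.0)
    return m


def _distance_means(matrix: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean count per admissible bin pair at every distance 0..n-1."""
    n = matrix.n_bins
    totals = np.zeros(n)
    for (i, j), c in matrix.entries.items():
        totals[j - i] += c
    npairs = n - np.arange(n)
    return totals / npairs, totals


def fit_distance_prior(matrix: ContactMatrix, min_d: int = 2,
                       spline_df: int = 8,
                       floor: float = PRIOR_FLOOR) -> DistanceDecayPrior:
    """Fit the distance-decay prior with a univariate spline.

    The mean count per bin pair at each distance ``d >= min_d`` is
    smoothed by a cubic least-squares spline in log(d)-log(mean) space
    (``spline_df`` degrees of freedom, interior knots at quantiles of
    log d), exponentiated back, floored at ``floor`` and normalised over
    the grid.  Distances with zero observed mean contribute no fitting
    points but still receive a (spline-interpolated, floored) value.
    """
    if min_d < 1:
        raise ValueError("min_d must be >= 1")
    means, _ = _distance_means(matrix)
    n = matrix.n_bins
    grid = np.arange(min_d, n)
    if grid.size == 0:
        raise ValueError("matrix too small for the requested min_d")
    obs = grid[means[grid] > 0]
    if obs.size < spline_df:
        raise ValueError(
            f"need counts at >= {spline_df} distinct distances >= {min_d}, "
            f"got {obs.size}")

    x = np.log(obs.astype(float))
    y = np.log(means[obs])
    n_interior = max(int(spline_df) - 4, 0)
    # interior knots at quantiles; drop duplicates/ends for Schoenberg-Whitney
    if n_interior > 0:
        q = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.unique(np.quantile(x, q))
        knots = knots[(knots > x[0]) & (knots < x[-1])]
    else:
        knots = np.array([])
    spline = LSQUnivariateSpline(x, y, t=knots, k=min(3, obs.size - 1))

    g = np.exp(spline(np.log(grid.astype(float))))
    g = np.maximum(g, floor)
    probs = g / g.sum()
    return DistanceDecayPrior(
        distances=grid, probabilities=probs, min_d=min_d,
        floor=floor / g.sum(),
        knots=np.asarray(spline.get_knots()),
        coefficients=np.asarray(spline.get_coeffs()),
    )


def _prefix2d(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    s[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    return s


def _neighborhood_sums(total: np.ndarray, ci: np.ndarray, cj: np.ndarray,
                       w: int) -> np.ndarray:
    """Sum of ``total`` over the (2w+1)^2 square centred on each (ci, cj),
    clipped to the matrix."""
    n = total.shape[0]
    s = _prefix2d(total)
    r1 = np.clip(ci - w, 0, n)
    r2 = np.clip(ci + w + 1, 0, n)
    c1 = np.clip(cj - w, 0, n)
    c2 = np.clip(cj + w + 1, 0, n)
    return s[r2, c2] - s[r1, c2] - s[r2, c1] + s[r1, c1]


def allocate_multireads(
    reads: list[ReadPair],
    matrix: ContactMatrix,
    prior: DistanceDecayPrior,
    w: int = 2,
    pseudocount: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> PosteriorTable:
    """Iterative posterior allocation of multireads over their candidates.

    Per sweep, candidate k of a read at distance d_k gets weight
    ``P(d_k) * (L_k + pseudocount)`` where ``L_k`` is the summed current
    count (unique + fractional multi from the previous sweep) in the
    ``(2w+1)``-bin square around candidate k; weights are normalised per
    read.  The first sweep sees unique-read counts only.  Iteration stops
    when the largest per-read posterior change drops below ``tol``.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    n = matrix.n_bins
    U = matrix.to_dense()

    multis = [r for r in reads if r.is_multi]
    # flatten candidates
    starts, ci, cj = [], [], []
    for r in multis:
        starts.append(len(ci))
        for (i, j) in r.candidates:
            ci.append(i)
            cj.append(j)
    starts = np.asarray(starts, dtype=int)
    ci = np.asarray(ci, dtype=int)
    cj = np.asarray(cj, dtype=int)
    read_of = np.repeat(np.arange(len(multis)),
                        [len(r.candidates) for r in multis]) \
        if multis else np.zeros(0, dtype=int)

    table: dict[str, list[tuple[tuple[int, int], float]]] = {}
    for r in reads:
        if not r.is_multi:
            table[r.read_id] = [(r.candidates[0], 1.0)]

    if not multis:
        return PosteriorTable(table, iterations=0, converged=True)

    pw = prior.evaluate(cj - ci)
    post = np.zeros(len(ci))
    M = np.zeros((n, n))
    iterations = 0
    converged = False

    for iterations in range(1, max_iter + 1):
        L = _neighborhood_sums(U + M, ci, cj, w)
        weight = pw * (L + pseudocount)
        sums = np.add.reduceat(weight, starts)
        # degenerate rows (all-zero weight): fall back to the prior alone
        bad = sums[read_of] <= 0
        if bad.any():
            weight = np.where(bad, pw, weight)
            sums = np.add.reduceat(weight, starts)
        new_post = weight / sums[read_of]
        delta = np.abs(new_post - post).max()
        post = new_post
        # synchronous refresh of the fractional layer
        M[:] = 0.0
        np.add.at(M, (ci, cj), post)
        off = ci != cj
        np.add.at(M, (cj[off], ci[off]), post[off])
        if delta < tol:
            converged = True
            break

    for k, r in enumerate(multis):
        lo = starts[k]
        hi = starts[k + 1] if k + 1 < len(starts) else len(ci)
        table[r.read_id] = [(r.candidates[t - lo], float(post[t]))
                            for t in range(lo, hi)]
    # preserve input read order in the table
    ordered = {r.read_id: table[r.read_id] for r in reads}
    return PosteriorTable(ordered, iterations=iterations, converged=converged)


def accumulate_fractional(matrix: ContactMatrix,
                          posteriors: PosteriorTable) -> ContactMatrix:
    """Add each multiread's posterior mass to the matrix.

    Output mass = input mass + number of multireads (each multiread's
    posteriors sum to 1).
    """
    out = matrix.copy()
    for rid, ps in posteriors.posteriors.items():
        if len(ps) <= 1:
            continue
        for (i, j), p in ps:
            out.add(i, j, p)
    return out


def apply_stringent_filter(posteriors: PosteriorTable,
                           threshold: float = 0.99) -> StringentResult:
    """Whole-read allocation of multireads at a posterior threshold.

    A multiread is assigned in full (count 1) to its maximum-posterior
    candidate iff that posterior is **greater than or equal to** the
    threshold; otherwise it is discarded.  Exact ties with the threshold
    are kept.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    assignments: dict[str, tuple[int, int]] = {}
    dropped = 0
    for rid, ps in posteriors.posteriors.items():
        if len(ps) <= 1:
            continue
        best_pair, best_p = max(ps, key=lambda t: t[1])
        if best_p >= threshold:
            assignments[rid] = best_pair
        else:
            dropped += 1
    return StringentResult(assignments=assignments, n_kept=len(assignments),
                           n_dropped=dropped, threshold=threshold)


def accumulate_stringent(matrix: ContactMatrix,
                         result: StringentResult) -> ContactMatrix:
    """Unique-read matrix plus whole counts at stringent assignments."""
    out = matrix.copy()
    for (i, j) in result.assignments.values():
        out.add(i, j, 1.0)
    return out
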