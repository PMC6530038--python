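"""Triplet enumeration and liquid-association scoring.

For normal-score-transformed rows x, y, z the LA score is the sample mean
of the triple product, lambda = (1/m) * sum_i x_i y_i z_i.  The statistic is
symmetric in its three arguments, so the scan is organized per "scouting"
gene z: for each scout, lambda is computed against every eligible pair
(x, y), where eligibility requires all three pairwise correlations of the
triplet to sit inside the screen band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .expression import ExpressionMatrix, PairEligibility

logger = logging.getLogger(__name__)

__all__ = ["TripletRecord", "ScanResult", "la_score", "enumerate_scout_pairs", "scan_scout", "scan_all"]


@dataclass(frozen=True)
class TripletRecord:
    """A canonical gene triplet (i < j < k) with its LA score and scout."""

    i: int
    j: int
    k: int
    scout: int
    lam: float

    def __post_init__(self) -> None:
        if not self.i < self.j < self.k:
            raise ValueError("triplet indices must be canonical: i < j < k")
        if self.scout not in (self.i, self.j, self.k):
            raise ValueError("scout must be one of the triplet genes")

    @property
    def genes(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


@dataclass
class ScanResult:
    """All eligible pairs for one scout with their LA scores.

    ``pairs[t] = (i, j)`` with ``i < j`` and ``lams[t]`` the LA score of the
    triplet ``{i, j, scout}``.  The ``lams`` array is the scout's observed
    empirical lambda distribution.
    """

    scout: int
    pairs: np.ndarray  # (k, 2) int
    lams: np.ndarray  # (k,) float

    @property
    def n_triplets(self) -> int:
        return int(self.lams.size)

    def records(self) -> list[TripletRecord]:
        out = []
        for (i, j), lam in zip(self.pairs, self.lams):
            a, b, c = sorted((int(i), int(j), self.scout))
            out.append(TripletRecord(a, b, c, scout=self.scout, lam=float(lam)))
        return out


def la_score(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """LA score of a triplet: the sample mean of the elementwise product."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1 or x.size < 1:
        raise ValueError("x, y, z must be 1-D arrays of equal positive length")
    return float(np.mean(x * y * z))


def enumerate_scout_pairs(scout: int, eligibility: PairEligibility) -> Iterator[tuple[int, int]]:
    """Yield pairs (i, j), i < j, forming an eligible triplet with the scout.

    A pair qualifies when all three pairwise masks (i,j), (i,scout),
    (j,scout) are true.  Order is lexicographic, hence deterministic.
    """
    mask = eligibility.mask
    n = mask.shape[0]
    if not 0 <= scout < n:
        raise IndexError(f"scout index {scout} out of range for {n} genes")
    with_scout = mask[scout]
    for i in range(n):
        if i == scout or not with_scout[i]:
            continue
        row = mask[i]
        for j in range(i + 1, n):
            if j == scout:
                continue
            if row[j] and with_scout[j]:
                yield (i, j)


def _scout_pair_arrays(scout: int, eligibility: PairEligibility) -> np.ndarray:
    """Vectorized equivalent of :func:`enumerate_scout_pairs` as a (k, 2) array."""
    mask = eligibility.mask
    n = mask.shape[0]
    if not 0 <= scout < n:
        raise IndexError(f"scout index {scout} out of range for {n} genes")
    cand = np.flatnonzero(mask[scout])
    cand = cand[cand != scout]
    if cand.size < 2:
        return np.empty((0, 2), dtype=int)
    sub = mask[np.ix_(cand, cand)]
    ii, jj = np.nonzero(np.triu(sub, k=1))
    return np.column_stack([cand[ii], cand[jj]])


def scan_scout(
    matrix: ExpressionMatrix,
    scout: int,
    eligibility: PairEligibility,
    scout_row: np.ndarray | None = None,
) -> ScanResult:
    """Compute LA scores of the scout against every eligible pair.

    ``scout_row`` optionally replaces the scout's expression row (used by the
    permutation null, which shuffles the scout's sample labels while keeping
    the pair universe fixed).
    """
    pairs = _scout_pair_arrays(scout, eligibility)
    z = matrix.values[scout] if scout_row is None else np.asarray(scout_row, float)
    if z.size != matrix.n_samples:
        raise ValueError("scout row length does not match the sample count")
    if pairs.shape[0] == 0:
        logger.warning("scout %d has no eligible pairs; skipped", scout)
        return ScanResult(scout=scout, pairs=pairs, lams=np.empty(0))
    weighted = matrix.values[pairs[:, 0]] * z  # (k, m)
    lams = np.einsum("km,km->k", weighted, matrix.values[pairs[:, 1]]) / matrix.n_samples
    return ScanResult(scout=scout, pairs=pairs, lams=lams)


def scan_all(
    matrix: ExpressionMatrix,
    eligibility: PairEligibility,
    scouts: list[int] | None = None,
) -> dict[int, ScanResult]:
    """Scan every gene (or a subset) as scout; returns per-scout results.

    Each qualifying triplet {i, j, k} appears in exactly three scans (once
    per member as scout) with the same LA score; deduplication happens after
    selection, so per-scout provenance is retained here.
    """
    if scouts is None:
        scouts = list(range(matrix.n_genes))
    return {s: scan_scout(matrix, s, eligibility) for s in scouts}
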