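"""Permutation null models and local-fdr selection of significant triplets.

For each scouting gene the observed LA scores over its eligible pairs form
an empirical distribution f.  Shuffling the scout row's sample labels and
recomputing the scores over the same pair set yields a null distribution f0
in which the ternary relationship is destroyed but the pair structure is
kept.  The local false discovery rate at a score value is the density ratio

    fdr(lambda) = f0_hat(lambda) / f_hat(lambda),

interpreted as the posterior probability that a triplet scoring lambda is
null.  Thresholds at a target fdr are read off the (tail-monotone
regularized) curve in both tails, and triplets whose score falls outside
the two thresholds are selected.

Null-density estimation supports two estimators:

* ``"normal"`` (default): a normal density with mean and standard deviation
  estimated from the pooled permutation scores.  Null LA scores of
  unrelated triplets are approximately normal, and the parametric tail is
  far more stable than a kernel tail, whose behaviour beyond the most
  extreme permutation draw is dominated by the randomness of that single
  order statistic.
* ``"kde"``: a Gaussian kernel density with Silverman bandwidth, the same
  estimator used for the observed density.

See ``docs/methods.md`` for the trade-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .expression import ExpressionMatrix, PairEligibility
from .scan import ScanResult, TripletRecord, scan_scout

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "FdrCurve",
    "permuted_scan",
    "kde_density",
    "fdr_curve",
    "select_triplets",
]

_DENSITY_FLOOR = 1e-10
_GRID_SIZE = 512


@dataclass
class NullModel:
    """Pooled null LA scores for one scout from permuted-scout scans."""

    scout: int
    null_lams: np.ndarray
    n_permutations: int
    seed: int


@dataclass
class FdrCurve:
    """Observed/null density estimates and the resulting local-fdr function.

    ``fdr`` is the capped, tail-monotone regularized curve used for
    thresholding; ``raw_fdr`` is the plain capped density ratio.
    ``lower_threshold``/``upper_threshold`` are the outermost grid values at
    which the regularized curve first meets the target in each tail, or
    ``None`` if the target is never reached on that side.
    """

    grid: np.ndarray
    f_obs: np.ndarray
    f_null: np.ndarray
    fdr: np.ndarray
    raw_fdr: np.ndarray
    mode: float
    fdr_target: float
    lower_threshold: float | None
    upper_threshold: float | None

    def selects(self, lam: float | np.ndarray) -> np.ndarray:
        """Boolean mask: does a score fall in a selected (significant) tail?"""
        lam = np.asarray(lam, dtype=float)
        out = np.zeros(lam.shape, dtype=bool)
        if self.lower_threshold is not None:
            out |= lam <= self.lower_threshold
        if self.upper_threshold is not None:
            out |= lam >= self.upper_threshold
        return out


def _scout_rng(seed: int, scout: int) -> np.random.Generator:
    # per-scout stream derived deterministically from the run seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(scout,)))


def permuted_scan(
    matrix: ExpressionMatrix,
    scout: int,
    eligibility: PairEligibility,
    n_permutations: int = 1,
    seed: int = 0,
) -> NullModel:
    """Build the scout's permutation null by shuffling its sample labels.

    Eligibility is *not* recomputed after permutation: the null scores are
    evaluated over exactly the observed pair set, so the two distributions
    are directly comparable.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = _scout_rng(seed, scout)
    z = matrix.values[scout]
    chunks = []
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        res = scan_scout(matrix, scout, eligibility, scout_row=zp)
        chunks.append(res.lams)
    null_lams = np.concatenate(chunks) if chunks else np.empty(0)
    if null_lams.size == 0:
        logger.warning("scout %d: empty pair set, empty null", scout)
    return NullModel(scout=scout, null_lams=null_lams, n_permutations=n_permutations, seed=seed)


def kde_density(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density with Silverman bandwidth evaluated on a grid.

    Requires at least 10 values with positive spread; on a grid spanning the
    data plus/minus three bandwidths the trapezoidal integral is ~1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("kde_density needs at least 10 values")
    if np.std(values) == 0:
        raise ValueError("kde_density undefined for identical values (zero bandwidth)")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    return kde(np.asarray(grid, dtype=float))


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    return float(np.std(values, ddof=1) * (4.0 / (3.0 * n)) ** 0.2)


def fdr_curve(
    observed: np.ndarray,
    null: NullModel | np.ndarray,
    fdr_target: float,
    null_density: str = "normal",
    conservatism: float = 2.0,
) -> FdrCurve:
    """Form the local-fdr curve f0/f and locate the two tail thresholds.

    Parameters
    ----------
    observed
        LA scores of the scout's observed scan.
    null
        Permutation null scores (a :class:`NullModel` or a plain array).
    fdr_target
        Target local fdr in (0, 1); e.g. 0.1.
    null_density
        ``"normal"`` for a permutation-calibrated normal null density,
        ``"kde"`` for a kernel estimate (same estimator as the observed
        density).
    conservatism
        The denominator uses a lower confidence bound on the observed
        density, ``f - conservatism * se(f)``, with the usual pointwise
        kernel-estimate standard error ``se = sqrt(f R(K) / (n h))``.
        Where the observed density rests on a handful of stray points the
        bound collapses to the floor, so a score is only called
        significant there when the null density itself is negligible;
        where the density is well supported the bound is indistinguishable
        from the plain estimate.  Set to 0 for the unadjusted ratio.
    """
    if not 0 < fdr_target < 1:
        raise ValueError("fdr_target must be in (0, 1)")
    obs = np.asarray(observed, dtype=float)
    nul = null.null_lams if isinstance(null, NullModel) else np.asarray(null, dtype=float)
    if obs.size == 0 or nul.size == 0:
        raise ValueError("observed and null samples must be non-empty")
    if null_density not in ("normal", "kde"):
        raise ValueError("null_density must be 'normal' or 'kde'")
    if conservatism < 0:
        raise ValueError("conservatism must be >= 0")

    bw = max(_silverman_bandwidth(obs), _silverman_bandwidth(nul))
    lo = min(obs.min(), nul.min()) - 3 * bw
    hi = max(obs.max(), nul.max()) + 3 * bw
    grid = np.linspace(lo, hi, _GRID_SIZE)

    f_obs = np.maximum(kde_density(obs, grid), _DENSITY_FLOOR)
    if null_density == "kde":
        f_null = kde_density(nul, grid)
    else:
        f_null = stats.norm.pdf(grid, loc=np.mean(nul), scale=np.std(nul, ddof=1))

    # roughness R(K) of the Gaussian kernel = 1 / (2 sqrt(pi))
    h_obs = _silverman_bandwidth(obs)
    se_obs = np.sqrt(f_obs * 0.28209479177387814 / (obs.size * h_obs))
    denom = np.maximum(f_obs - conservatism * se_obs, _DENSITY_FLOOR)
    raw = np.clip(f_null / denom, 0.0, 1.0)
    mode_idx = int(np.argmax(f_null))
    mode = float(grid[mode_idx])

    # regularize: fdr non-increasing moving outward from the null mode
    fdr = raw.copy()
    right = slice(mode_idx, None)
    left = slice(0, mode_idx + 1)
    if grid[right].size > 1:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        fdr[right] = iso.fit_transform(grid[right], raw[right])
    if grid[left].size > 1:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        fdr[left] = iso.fit_transform(grid[left], raw[left])
    fdr = np.clip(fdr, 0.0, 1.0)

    upper = None
    above = np.flatnonzero((grid > mode) & (fdr <= fdr_target))
    if above.size:
        upper = float(grid[above[0]])
    lower = None
    below = np.flatnonzero((grid < mode) & (fdr <= fdr_target))
    if below.size:
        lower = float(grid[below[-1]])

    return FdrCurve(
        grid=grid,
        f_obs=f_obs,
        f_null=f_null,
        fdr=fdr,
        raw_fdr=raw,
        mode=mode,
        fdr_target=fdr_target,
        lower_threshold=lower,
        upper_threshold=upper,
    )


def select_triplets(
    scans: dict[int, ScanResult],
    curves: dict[int, FdrCurve],
) -> list[TripletRecord]:
    """Select triplets whose score falls outside a scout's fdr thresholds.

    The union over all scouts is canonicalized (i < j < k) and
    deduplicated; the first selecting scout provides the retained record
    (LA scores are identical across scouts up to floating-point rounding).
    Returned records are sorted by gene indices for reproducibility.
    """
    chosen: dict[tuple[int, int, int], TripletRecord] = {}
    for scout in sorted(scans):
        res = scans[scout]
        if res.n_triplets == 0 or scout not in curves:
            continue
        hits = curves[scout].selects(res.lams)
        for t in np.flatnonzero(hits):
            i, j = int(res.pairs[t, 0]), int(res.pairs[t, 1])
            key = tuple(sorted((i, j, scout)))
            if key not in chosen:
                a, b, c = key
                chosen[key] = TripletRecord(a, b, c, scout=scout, lam=float(res.lams[t]))
    return [chosen[k] for k in sorted(chosen)]
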