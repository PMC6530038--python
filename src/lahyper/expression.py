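"""Expression-matrix handling and the pairwise-correlation eligibility screen.

The liquid-association (LA) statistic for a gene triplet, the sample mean of
the elementwise product of three expression rows, is a valid measure of
dynamic correlation only when the three genes are close to pairwise
uncorrelated and each row is marginally standard normal.  This module
provides the two ingredients that establish those conditions on real data:

* a rank-based *normal score transform* applied to every gene row, which
  forces each row to an (approximately) standard-normal marginal, and
* a *correlation screen* that marks a gene pair as eligible only when its
  Pearson correlation (after transformation) falls inside the narrow band
  ``(mu - c*sigma, mu + c*sigma)`` around the empirical mean ``mu`` of all
  pairwise correlations, with ``sigma`` their standard deviation and ``c``
  a small user constant.

Utilities based on the Fisher transformation of the correlation coefficient
are included to help choose ``c``: for two truly uncorrelated genes observed
over ``m`` samples the sampling standard deviation of their correlation is
approximately ``1/sqrt(m)``, so a band whose half-width is near
``1.96/sqrt(m)`` keeps pairs whose correlation is indistinguishable from
zero at the 95% level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ScreenSummary",
    "PairEligibility",
    "load_expression",
    "normal_score_transform",
    "normal_scores",
    "screen_summary",
    "eligible_pairs",
    "correlation_sampling_sd",
    "correlation_ci_halfwidth",
    "suggest_c",
]


@dataclass
class ExpressionMatrix:
    """A genes-by-samples abundance matrix with row/column identifiers.

    Attributes
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Real-valued abundances; no missing values allowed.
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if len(set(self.gene_ids)) != n:
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != m:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, indices: np.ndarray | list[int]) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene rows (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class ScreenSummary:
    """Summary of the off-diagonal pairwise-correlation distribution.

    ``lower``/``upper`` bound the open eligibility interval
    ``(mu - c*sigma, mu + c*sigma)``.
    """

    mu: float
    sigma: float
    c: float
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", self.mu - self.c * self.sigma)
        object.__setattr__(self, "upper", self.mu + self.c * self.sigma)


@dataclass
class PairEligibility:
    """Symmetric boolean mask of gene pairs passing the correlation screen."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.mask.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if self.mask.diagonal().any():
            raise ValueError("mask diagonal must be false")

    @property
    def n_genes(self) -> int:
        return self.mask.shape[0]

    @property
    def n_eligible_pairs(self) -> int:
        return int(np.triu(self.mask, 1).sum())


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


def load_expression(
    path: str | Path,
    max_zero_fraction: float = 0.10,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Load a TSV/CSV expression matrix and drop genes with too many zeros.

    The file must have a header row of sample identifiers and gene
    identifiers in the first column.  The delimiter is inferred from the
    extension (``.csv`` -> comma, anything else -> tab) unless given.

    Parameters
    ----------
    path
        Input file.
    max_zero_fraction
        Keep only genes whose fraction of exactly-zero entries is at most
        this value (default 0.10, i.e. the "more than ten percent zeros"
        exclusion rule).
    delimiter
        Explicit field separator, overriding extension-based inference.

    Returns
    -------
    ExpressionMatrix
        Filtered matrix; the original gene order is preserved.

    Raises
    ------
    ValueError
        On duplicate gene identifiers (naming them) or non-numeric cells
        (naming the row/column location).
    """
    path = Path(path)
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be within [0, 1]")
    sep = delimiter if delimiter is not None else ("," if path.suffix.lower() == ".csv" else "\t")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"duplicate gene ids in {path.name}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {gene_ids[r]!r}, sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at gene {gene_ids[r]!r}, sample {df.columns[c]!r}")
    values = numeric.to_numpy(dtype=float)
    zero_frac = (values == 0.0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    n_kept, n_dropped = int(keep.sum()), int((~keep).sum())
    logger.info(
        "loaded %s: %d genes, %d samples; kept %d, dropped %d with zero fraction > %.3g",
        path.name, len(gene_ids), values.shape[1], n_kept, n_dropped, max_zero_fraction,
    )
    return ExpressionMatrix(
        values[keep],
        [g for g, k in zip(gene_ids, keep) if k],
        [str(s) for s in df.columns],
    )


def normal_score_transform(row: np.ndarray) -> np.ndarray:
    """Map a row to van der Waerden normal scores ``Phi^-1(rank/(m+1))``.

    Ties receive average ranks and therefore identical scores.  The output
    preserves the rank order of the input and, for tie-free rows, is exactly
    symmetric around zero because the plotting positions ``i/(m+1)`` are
    symmetric about one half.

    Raises
    ------
    ValueError
        If the row has fewer than 2 entries or is constant (ranks carry no
        information, so the transform is undefined for LA purposes).
    """
    row = np.asarray(row, dtype=float)
    m = row.size
    if m < 2:
        raise ValueError("normal score transform needs at least 2 samples")
    if np.all(row == row[0]):
        raise ValueError("constant row: normal score transform undefined")
    ranks = stats.rankdata(row, method="average")
    return stats.norm.ppf(ranks / (m + 1))


def normal_scores(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the normal score transform to every gene row."""
    transformed = np.vstack([normal_score_transform(r) for r in matrix.values])
    return ExpressionMatrix(transformed, list(matrix.gene_ids), list(matrix.sample_ids))


def _offdiag_correlations(values: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return corr[iu]


def screen_summary(matrix: ExpressionMatrix, c: float) -> ScreenSummary:
    """Summarize the distribution of distinct off-diagonal pairwise correlations.

    ``mu`` and ``sigma`` are the mean and (sample) standard deviation over
    the ``n(n-1)/2`` distinct gene pairs of the transformed matrix; the
    eligibility interval is the open band ``(mu - c*sigma, mu + c*sigma)``.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes to summarize pairwise correlations")
    r = _offdiag_correlations(matrix.values)
    mu = float(np.mean(r))
    sigma = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    return ScreenSummary(mu=mu, sigma=sigma, c=float(c))


def eligible_pairs(matrix: ExpressionMatrix, summary: ScreenSummary) -> PairEligibility:
    """Mark gene pairs whose correlation lies strictly inside the screen band."""
    corr = np.corrcoef(matrix.values)
    mask = (corr > summary.lower) & (corr < summary.upper)
    np.fill_diagonal(mask, False)
    mask &= mask.T  # guard against asymmetric float artifacts
    return PairEligibility(mask=mask)


def correlation_sampling_sd(m: int) -> float:
    """Sampling sd of the Pearson correlation of two uncorrelated genes.

    Large-sample (Fisher-transformation) approximation ``1/sqrt(m)`` for
    sample size ``m``; satisfies ``correlation_sampling_sd(m) * sqrt(m) == 1``.
    """
    if m < 4:
        raise ValueError("need m >= 4 samples for the Fisher approximation")
    return 1.0 / float(np.sqrt(m))


def correlation_ci_halfwidth(m: int) -> float:
    """Half-width of the 95% null CI for a sample correlation, ``1.96/sqrt(m)``."""
    return 1.96 * correlation_sampling_sd(m)


def suggest_c(sigma: float, m: int) -> float:
    """Suggest the screen constant ``c`` so the band matches the null 95% CI.

    Solves ``c * sigma = 1.96 / sqrt(m)`` for ``c`` given the empirical
    pairwise-correlation standard deviation ``sigma``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return correlation_ci_halfwidth(m) / sigma
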