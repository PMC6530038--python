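"""Synthetic expression data with planted dynamic-correlation triplets.

The generator emulates the data mechanism that liquid association is built
to detect: a gene pair (x, y) whose correlation flips with the level of a
third gene z.  For a planted triplet, z ~ N(0,1) and, given z, (x, y) are
bivariate normal with unit variances and conditional correlation
rho(z) = delta * sign(z) (or delta * tanh(z) for a smooth alternative).
All marginal pairwise correlations of the planted triple are zero in
expectation, so the triple passes the low-correlation screen, while its
population LA score is E[z * rho(z)]:

    sign link:  delta * E|z|      = delta * sqrt(2/pi)
    tanh link:  delta * E[z tanh z]  (evaluated numerically)

All remaining genes are i.i.d. standard normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .expression import ExpressionMatrix

__all__ = [
    "PlantedTriplet",
    "population_lambda",
    "generate_null_matrix",
    "generate_planted_dataset",
    "planted_recovery_report",
]


@dataclass(frozen=True)
class PlantedTriplet:
    """Specification of one planted dynamic-correlation triplet."""

    x: int
    y: int
    z: int
    delta: float = 0.8
    link: str = "sign"

    def __post_init__(self) -> None:
        if len({self.x, self.y, self.z}) != 3:
            raise ValueError("planted triplet genes must be distinct")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.link not in ("sign", "tanh"):
            raise ValueError("link must be 'sign' or 'tanh'")

    @property
    def genes(self) -> tuple[int, int, int]:
        return tuple(sorted((self.x, self.y, self.z)))


def population_lambda(delta: float, link: str = "sign") -> float:
    """Population LA score of a planted triplet, E[z * rho(z)]."""
    if link == "sign":
        return delta * float(np.sqrt(2.0 / np.pi))
    if link == "tanh":
        val, _ = integrate.quad(lambda z: z * np.tanh(z) * stats.norm.pdf(z), -np.inf, np.inf)
        return delta * float(val)
    raise ValueError("link must be 'sign' or 'tanh'")


def generate_null_matrix(n: int, m: int, seed: int) -> ExpressionMatrix:
    """An n x m matrix of i.i.d. standard-normal entries, reproducible by seed."""
    if n < 3 or m < 4:
        raise ValueError("need n >= 3 genes and m >= 4 samples")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n, m))
    width = max(4, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    sample_ids = [f"s{j:04d}" for j in range(m)]
    return ExpressionMatrix(values, gene_ids, sample_ids)


def generate_planted_dataset(
    n: int,
    m: int,
    specs: list[PlantedTriplet],
    seed: int,
) -> tuple[ExpressionMatrix, list[dict]]:
    """Null matrix with planted triplets substituted at the specified rows.

    Planted gene indices must be disjoint across specs.  Returns the matrix
    and a truth table: one record per planted triplet with the canonical
    gene index triple, the gene identifiers, delta, link and the population
    LA score.
    """
    used: set[int] = set()
    for s in specs:
        overlap = used & {s.x, s.y, s.z}
        if overlap:
            raise ValueError(f"planted gene indices overlap across specs: {sorted(overlap)}")
        used.update((s.x, s.y, s.z))
        if max(s.x, s.y, s.z) >= n:
            raise ValueError(f"planted index out of range for n={n}")
    matrix = generate_null_matrix(n, m, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    truth = []
    for s in specs:
        z = rng.standard_normal(m)
        rho = s.delta * (np.sign(z) if s.link == "sign" else np.tanh(z))
        a = rng.standard_normal(m)
        b = rng.standard_normal(m)
        x = a
        y = rho * a + np.sqrt(1.0 - rho**2) * b
        matrix.values[s.x] = x
        matrix.values[s.y] = y
        matrix.values[s.z] = z
        truth.append(
            {
                "genes": s.genes,
                "gene_ids": tuple(matrix.gene_ids[g] for g in s.genes),
                "delta": s.delta,
                "link": s.link,
                "population_lambda": population_lambda(s.delta, s.link),
            }
        )
    return matrix, truth


def write_fixture(
    matrix: ExpressionMatrix,
    truth: list[dict],
    out_dir,
) -> tuple[str, str]:
    """Write a fixture as ``expression.tsv`` plus ``truth.tsv`` in a directory.

    The expression file is the standard genes-in-rows TSV the pipeline
    loads; the truth table lists one planted triplet per row with gene
    identifiers and the population LA score.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene_i\tgene_j\tgene_k\tdelta\tlink\tpopulation_lambda\n")
        for rec in truth:
            a, b, c = rec["gene_ids"]
            fh.write(
                f"{a}\t{b}\t{c}\t{rec['delta']:.10g}\t{rec['link']}\t"
                f"{rec['population_lambda']:.10g}\n"
            )
    return str(expr_path), str(truth_path)


def planted_recovery_report(
    selected: set[tuple[int, int, int]] | list[tuple[int, int, int]],
    truth: list[dict],
) -> dict[str, float]:
    """Recall and empirical FDR of a selection against the planted truth.

    recall = planted triplets selected / planted;
    empirical_fdr = selected non-planted / selected (0 when nothing is
    selected).
    """
    sel = {tuple(sorted(t)) for t in selected}
    planted = {tuple(rec["genes"]) for rec in truth}
    tp = len(sel & planted)
    recall = tp / len(planted) if planted else 0.0
    fdr = (len(sel) - tp) / len(sel) if sel else 0.0
    return {
        "n_selected": float(len(sel)),
        "n_planted": float(len(planted)),
        "recall": recall,
        "empirical_fdr": fdr,
    }
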