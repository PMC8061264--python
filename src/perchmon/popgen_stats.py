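"""Per-individual, per-pair and per-locus population-genetic statistics.

* ``pht`` — individual genetic diversity as the proportion of heterozygous
  calls (PHt).
* ``pair_dissimilarity`` — the fraction of allelic differences between two
  genotypes (mate dissimilarity of a broodstock pair).
* ``per_locus_fst`` — Weir & Cockerham's two-population theta per locus.

Missing-data policy throughout: statistics use pairwise-complete loci and
record the denominator actually compared.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmatrix import MISSING, GenotypeMatrix


@dataclass
class PairDissimilarity:
    pair_id: str
    dissimilarity: float
    loci_compared: int


def pht(genotype_row: np.ndarray) -> float:
    """Proportion of heterozygous loci among called loci.

    Raises ``ValueError`` when every call is missing (undefined statistic).
    """
    g = np.asarray(genotype_row)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("PHt undefined: all calls missing")
    return float((g[called] == 1).sum() / n)


def pair_dissimilarity(
    row_a: np.ndarray, row_b: np.ndarray, pair_id: str = ""
) -> PairDissimilarity:
    """Fraction of allelic differences between two genotypes.

    Per shared called locus the dosage difference |gA - gB| counts the
    differing allele copies (0, 1 or 2); the sum is divided by the 2L
    allele comparisons made, so a homozygote-heterozygote mismatch scores
    0.5 at that locus.
    """
    a = np.asarray(row_a)
    b = np.asarray(row_b)
    if a.shape != b.shape:
        raise ValueError("genotype rows differ in length")
    shared = (a != MISSING) & (b != MISSING)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("dissimilarity undefined: no shared called loci")
    diff = np.abs(a[shared].astype(int) - b[shared].astype(int)).sum()
    return PairDissimilarity(pair_id=pair_id, dissimilarity=float(diff / (2 * n)),
                             loci_compared=n)


def _wc_components(ga: np.ndarray, gb: np.ndarray):
    """Weir-Cockerham (1984) variance components a, b, c per locus.

    ``ga``/``gb`` are dosage matrices (individuals x loci) for the two
    populations; missing calls are excluded locus-wise.  Returns arrays
    ``(a, b, c, n_a, n_b)``; loci without >=2 called genotypes in each
    population come back as NaN components.
    """
    r = 2.0
    comp = []
    for g in (ga, gb):
        called = g != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0).sum(axis=0) / (2 * n)
            h = np.where(called, g == 1, False).sum(axis=0) / n
        comp.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comp
    valid = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0)
            * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c, n1, n2


def per_locus_fst(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix) -> pd.DataFrame:
    """Weir-Cockerham theta per locus between two population samples.

    Monomorphic loci (zero total variance) are reported as F_ST = 0; loci
    with fewer than two called genotypes in either population are NaN.
    Columns: ``locus``, ``fst``, ``n_a``, ``n_b``.
    """
    if not np.array_equal(pop_a.loci, pop_b.loci):
        raise ValueError("population matrices must share a locus panel")
    a, b, c, n1, n2 = _wc_components(pop_a.dosage, pop_b.dosage)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom == 0.0, 0.0, a / denom)
    return pd.DataFrame(
        {"locus": pop_a.loci, "fst": theta,
         "n_a": n1.astype(int), "n_b": n2.astype(int)}
    )


def mean_fst(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix) -> float:
    """Multi-locus Weir-Cockerham estimate: ratio of summed components."""
    a, b, c, _, _ = _wc_components(pop_a.dosage, pop_b.dosage)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0:
        return 0.0
    return float(num / den)


def pht_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """PHt for every individual; all-missing rows get NaN with a note."""
    rows = []
    for i, iid in enumerate(matrix.ids):
        try:
            v = pht(matrix.dosage[i])
            rows.append(dict(id=iid, pht=v, status="ok"))
        except ValueError:
            rows.append(dict(id=iid, pht=np.nan, status="all_missing"))
    return pd.DataFrame(rows)


def pair_dissimilarity_table(
    matrix: GenotypeMatrix, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Dissimilarity for each (pair_id, dam_id, sire_id) row with genotypes.

    Pairs whose dam or sire is not in the matrix, or with no shared called
    loci, are reported with NaN and a status note.
    """
    have = set(matrix.ids)
    rows = []
    for row in pairs.itertuples():
        if row.dam_id not in have or row.sire_id not in have:
            rows.append(dict(pair_id=row.pair_id, dissimilarity=np.nan,
                             loci_compared=0, status="parent_ungenotyped"))
            continue
        try:
            d = pair_dissimilarity(matrix.row(row.dam_id), matrix.row(row.sire_id),
                                   pair_id=row.pair_id)
            rows.append(dict(pair_id=d.pair_id, dissimilarity=d.dissimilarity,
                             loci_compared=d.loci_compared, status="ok"))
        except ValueError:
            rows.append(dict(pair_id=row.pair_id, dissimilarity=np.nan,
                             loci_compared=0, status="no_shared_loci"))
    return pd.DataFrame(rows)
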