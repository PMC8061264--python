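"""Diploid SNP genotype container and its plain-text dialect.

Genotypes are biallelic dosage calls: 0 (homozygous reference), 1
(heterozygous), 2 (homozygous alternate), with ``-1`` encoding a missing
call.  Rows are individuals (or samples — one fish may yield several
samples across recaptures), columns are loci.  Per-locus metadata such as
DArT-style reproducibility scores ride along in a DataFrame indexed by
locus id.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with optional per-locus metadata.

    Parameters
    ----------
    ids
        Unique individual/sample identifiers, one per row.
    loci
        Unique locus identifiers, one per column.
    dosage
        ``int8`` array of shape ``(len(ids), len(loci))`` with values in
        ``{0, 1, 2, -1}``.
    locus_meta
        Optional DataFrame indexed by locus id (e.g. columns
        ``reproducibility``, ``tag``).
    """

    ids: np.ndarray
    loci: np.ndarray
    dosage: np.ndarray
    locus_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.loci = np.asarray(self.loci, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids are not unique")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus ids are not unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, -1}")
        if self.locus_meta is not None:
            missing_meta = set(self.loci) - set(self.locus_meta.index)
            if missing_meta:
                raise ValueError(f"locus_meta lacks {len(missing_meta)} loci")
            self.locus_meta = self.locus_meta.loc[list(self.loci)]

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def locus_call_rate(self) -> np.ndarray:
        n = max(self.n_individuals, 1)
        return self.called().sum(axis=0) / n

    def individual_call_rate(self) -> np.ndarray:
        n = max(self.n_loci, 1)
        return self.called().sum(axis=1) / n

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over called genotypes.

        Loci with no calls get ``nan``.
        """
        called = self.called()
        alt = np.where(called, self.dosage, 0).sum(axis=0).astype(float)
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2 * n), np.nan)

    # -- selection ---------------------------------------------------------
    def _index_of(self, wanted: Sequence, pool: np.ndarray, what: str) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(pool)}
        try:
            return np.array([lookup[w] for w in wanted], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown {what} id: {exc.args[0]!r}") from None

    def subset(
        self,
        individuals: Iterable | None = None,
        loci: Iterable | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given ids (boolean masks allowed)."""
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_loci)
        if individuals is not None:
            individuals = np.asarray(list(individuals), dtype=object)
            if individuals.dtype == object and len(individuals) and isinstance(
                individuals[0], (bool, np.bool_)
            ):
                individuals = individuals.astype(bool)
            if individuals.dtype == bool:
                rows = rows[individuals]
            else:
                rows = self._index_of(individuals, self.ids, "individual")
        if loci is not None:
            loci = np.asarray(list(loci), dtype=object)
            if loci.dtype == object and len(loci) and isinstance(
                loci[0], (bool, np.bool_)
            ):
                loci = loci.astype(bool)
            if loci.dtype == bool:
                cols = cols[loci]
            else:
                cols = self._index_of(loci, self.loci, "locus")
        meta = None
        if self.locus_meta is not None:
            meta = self.locus_meta.iloc[cols].copy()
        return GenotypeMatrix(
            ids=self.ids[rows],
            loci=self.loci[cols],
            dosage=self.dosage[np.ix_(rows, cols)].copy(),
            locus_meta=meta,
        )

    def row(self, individual_id) -> np.ndarray:
        idx = self._index_of([individual_id], self.ids, "individual")[0]
        return self.dosage[idx]

    # -- text I/O ----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the genotype dialect: rows=individuals, columns=loci, NA missing."""
        df = pd.DataFrame(self.dosage, index=self.ids, columns=self.loci)
        df = df.astype(object).where(df != MISSING, "NA")
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, locus_meta: pd.DataFrame | None = None
    ) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        dosage = df.to_numpy(dtype=float)
        dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
        return cls(
            ids=df.index.to_numpy(dtype=object),
            loci=df.columns.to_numpy(dtype=object),
            dosage=dosage,
            locus_meta=locus_meta,
        )

    @classmethod
    def vstack(cls, matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack matrices sharing an identical locus panel."""
        first = matrices[0]
        for m in matrices[1:]:
            if not np.array_equal(m.loci, first.loci):
                raise ValueError("cannot stack matrices with different loci")
        return cls(
            ids=np.concatenate([m.ids for m in matrices]),
            loci=first.loci.copy(),
            dosage=np.vstack([m.dosage for m in matrices]),
            locus_meta=first.locus_meta.copy() if first.locus_meta is not None else None,
        )
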