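"""SNP panel quality control.

Filters a raw DArT-style genotype matrix down to an analysis-ready panel:
one SNP per sequencing tag, perfect-reproducibility loci, call-rate filters
on loci then individuals, and removal of loci monomorphic within a chosen
subset of individuals.  Also screens for sex-linked loci, which would break
analyses that assume codominant autosomal markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmatrix import MISSING, GenotypeMatrix


class EmptyPanelError(RuntimeError):
    """Raised when a filtering stage empties the panel; names the stage."""

    def __init__(self, stage: str):
        super().__init__(f"QC stage '{stage}' removed everything")
        self.stage = stage


@dataclass
class QCReport:
    """Per-stage removal counts, serialisable to JSON."""

    stages: list = field(default_factory=list)

    def record(self, stage: str, loci_removed: int = 0, individuals_removed: int = 0,
               loci_left: int = 0, individuals_left: int = 0) -> None:
        self.stages.append(
            dict(stage=stage, loci_removed=int(loci_removed),
                 individuals_removed=int(individuals_removed),
                 loci_left=int(loci_left), individuals_left=int(individuals_left))
        )

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def filter_panel(
    matrix: GenotypeMatrix,
    min_reproducibility: float = 1.0,
    max_locus_missing: float = 0.10,
    max_individual_missing: float = 0.25,
    drop_monomorphic_for=None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Cull the panel in a fixed order and report counts per stage.

    Order: one SNP per tag -> reproducibility -> locus missingness ->
    individual missingness -> monomorphic loci within
    ``drop_monomorphic_for`` (an id subset; defaults to all retained
    individuals).  Because removing a called individual can raise another
    locus's missing fraction, the two missingness stages are swept to a
    fixed point, which makes the whole filter idempotent.
    """
    for name, v in (("min_reproducibility", min_reproducibility),
                    ("max_locus_missing", max_locus_missing),
                    ("max_individual_missing", max_individual_missing)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} must be in [0, 1]")

    report = QCReport()
    m = matrix

    # one SNP per sequencing tag: keep the first listed SNP
    if m.locus_meta is not None and "tag" in m.locus_meta.columns:
        tags = m.locus_meta["tag"].to_numpy()
        keep = np.zeros(m.n_loci, dtype=bool)
        seen: set = set()
        for i, t in enumerate(tags):
            if t not in seen:
                seen.add(t)
                keep[i] = True
        removed = int((~keep).sum())
        if removed:
            m = m.subset(loci=keep)
        report.record("one_snp_per_tag", loci_removed=removed,
                      loci_left=m.n_loci, individuals_left=m.n_individuals)

    # reproducibility
    if m.locus_meta is not None and "reproducibility" in m.locus_meta.columns:
        keep = m.locus_meta["reproducibility"].to_numpy() >= min_reproducibility
        removed = int((~keep).sum())
        m = m.subset(loci=keep)
        if m.n_loci == 0:
            raise EmptyPanelError("reproducibility")
        report.record("reproducibility", loci_removed=removed,
                      loci_left=m.n_loci, individuals_left=m.n_individuals)

    # locus / individual missingness, swept to a fixed point
    sweep = 0
    while True:
        sweep += 1
        keep_loci = (1.0 - m.locus_call_rate()) <= max_locus_missing
        n_loci_removed = int((~keep_loci).sum())
        if n_loci_removed:
            m = m.subset(loci=keep_loci)
        if m.n_loci == 0:
            raise EmptyPanelError("locus_missingness")
        keep_ind = (1.0 - m.individual_call_rate()) <= max_individual_missing
        n_ind_removed = int((~keep_ind).sum())
        if n_ind_removed:
            m = m.subset(individuals=keep_ind)
        if m.n_individuals == 0:
            raise EmptyPanelError("individual_missingness")
        report.record(f"missingness_sweep_{sweep}",
                      loci_removed=n_loci_removed,
                      individuals_removed=n_ind_removed,
                      loci_left=m.n_loci, individuals_left=m.n_individuals)
        if n_loci_removed == 0 and n_ind_removed == 0:
            break
        if sweep > 100:  # pragma: no cover - defensive
            raise RuntimeError("missingness filter failed to stabilise")

    # monomorphic loci within the named subset
    if drop_monomorphic_for is None:
        sub = m
    else:
        wanted = [i for i in drop_monomorphic_for if i in set(m.ids)]
        sub = m.subset(individuals=wanted)
    freq = sub.allele_freq()
    with np.errstate(invalid="ignore"):
        poly = (freq > 0) & (freq < 1)
    poly = np.where(np.isnan(freq), False, poly)
    removed = int((~poly).sum())
    m = m.subset(loci=poly)
    if m.n_loci == 0:
        raise EmptyPanelError("monomorphic")
    report.record("monomorphic", loci_removed=removed,
                  loci_left=m.n_loci, individuals_left=m.n_individuals)
    return m, report


def detect_sex_linked(
    matrix: GenotypeMatrix, known_sexes: dict
) -> tuple[list, pd.DataFrame]:
    """Flag loci behaving like sex-linked markers in known-sex individuals.

    A locus is flagged when, ignoring missing calls, every call in one sex
    is homozygous and every call in the other sex is heterozygous — the
    hemizygosity signature that would corrupt codominant analyses.  Loci
    with fewer than two called individuals in either sex are untestable and
    reported as such, never flagged.

    Returns ``(flagged_locus_ids, per_locus_report)``.
    """
    ids = list(matrix.ids)
    males = [i for i in ids if known_sexes.get(i) == "M"]
    females = [i for i in ids if known_sexes.get(i) == "F"]
    rows = []
    flagged = []
    gm = matrix.subset(individuals=males).dosage if males else np.empty((0, matrix.n_loci), dtype=np.int8)
    gf = matrix.subset(individuals=females).dosage if females else np.empty((0, matrix.n_loci), dtype=np.int8)
    for j, locus in enumerate(matrix.loci):
        m_calls = gm[:, j][gm[:, j] != MISSING]
        f_calls = gf[:, j][gf[:, j] != MISSING]
        if len(m_calls) < 2 or len(f_calls) < 2:
            rows.append(dict(locus=locus, status="untestable",
                             n_males=len(m_calls), n_females=len(f_calls)))
            continue
        m_hom = bool(np.all(m_calls != 1))
        m_het = bool(np.all(m_calls == 1))
        f_hom = bool(np.all(f_calls != 1))
        f_het = bool(np.all(f_calls == 1))
        linked = (m_hom and f_het) or (m_het and f_hom)
        rows.append(dict(locus=locus, status="flagged" if linked else "ok",
                         n_males=len(m_calls), n_females=len(f_calls)))
        if linked:
            flagged.append(locus)
    return flagged, pd.DataFrame(rows)
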