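"""End-to-end monitoring analysis: raw samples in, fitted models out.

Mirrors the analysis flow of a two-source reintroduction assessment:

1. SNP QC (panel filtering + sex-linkage screen);
2. identity analysis (recaptures, matches to translocated fish);
3. parent-pair assignment of monitoring fish to broodstock pairs;
4. full-sib clustering of non-stocked fish;
5. per-locus F_ST locus ranking and supervised ancestry assignment;
6. origin calls and age assignment (Gompertz inversion for non-stocked);
7. minimum-survivor table + weighted binomial GLMM model selection;
8. growth-residual mixed models and the summary tallies.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import (
    calibrate_thresholds,
    classify_with_sibships,
    estimate_q_table,
    hybrid_class_table,
    reference_allele_freqs,
    select_informative_loci,
)
from .fitness_models import (
    build_survival_table,
    fit_gompertz,
    growth_residual_lmm,
    select_model,
)
from .gmatrix import GenotypeMatrix
from .origin import age_at_capture, capture_age_table, infer_origin
from .popgen_stats import (
    pair_dissimilarity_table,
    per_locus_fst,
    pht_table,
)
from .relatedness import (
    assign_parent_pairs,
    cluster_full_sibs,
    estimate_allele_freqs,
    match_identities,
)
from .simdata import SimulatedDataset
from .snpqc import detect_sex_linked, filter_panel
from .report import tally_origins, yearly_proportions


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    panel: GenotypeMatrix
    qc_report: dict
    sex_linked: list
    duplicate_groups: pd.DataFrame
    excluded_samples: pd.DataFrame
    assignments: pd.DataFrame
    sibships: pd.DataFrame
    fst_table: pd.DataFrame
    informative_loci: list
    thresholds: object
    ancestry_table: pd.DataFrame
    hybrid_table: pd.DataFrame
    origin_calls: pd.DataFrame
    growth_fit: object
    dissimilarity: pd.DataFrame
    pht: pd.DataFrame
    survival_table: pd.DataFrame
    survival_ranking: pd.DataFrame
    survival_best: object
    growth_ranking: pd.DataFrame
    growth_coefs: dict
    summary: object
    extras: dict = field(default_factory=dict)

    def write_outputs(self, out_dir: str | Path, seed: int | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.duplicate_groups.to_csv(out / "duplicates.csv", index=False)
        self.assignments.to_csv(out / "parentage_assignments.csv", index=False)
        self.sibships.to_csv(out / "sibships.csv", index=False)
        self.fst_table.to_csv(out / "per_locus_fst.csv", index=False)
        self.ancestry_table.to_csv(out / "ancestry.csv", index=False)
        self.hybrid_table.to_csv(out / "hybrid_classes.csv", index=False)
        self.origin_calls.to_csv(out / "origin_calls.csv", index=False)
        self.dissimilarity.to_csv(out / "pair_dissimilarity.csv", index=False)
        self.pht.to_csv(out / "pht.csv", index=False)
        self.survival_table.to_csv(out / "survival_table.csv", index=False)
        self.survival_ranking.to_csv(out / "survival_model_ranking.csv", index=False)
        if self.survival_best is not None:
            self.survival_best.coefficients.to_csv(
                out / "survival_coefficients.csv", index=False
            )
        self.growth_ranking.to_csv(out / "growth_model_ranking.csv", index=False)
        self.summary.per_year.to_csv(out / "summary_per_year.csv", index=False)
        self.summary.unique_counts.to_csv(out / "summary_unique.csv", index=False)
        (out / "qc_report.json").write_text(json.dumps(self.qc_report, indent=2))
        manifest = dict(
            package="perchmon", version=__version__, seed=seed,
            n_panel_loci=int(self.panel.n_loci),
            n_samples=int(self.panel.n_individuals),
            n_informative_loci=len(self.informative_loci),
        )
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(
    dataset: SimulatedDataset,
    seed: int = 0,
    n_sim_parentage: int = 10_000,
    min_fst: float = 0.02,
) -> PipelineResult:
    """Run the full monitoring analysis on a dataset bundle."""
    cfg = dataset.config
    samples = dataset.samples.set_index("sample_id", drop=False)
    e = cfg.genotyping_error_rate

    # ---- 1. QC ---------------------------------------------------------
    panel, qc = filter_panel(dataset.genotypes)
    brood_ids = [s for s in panel.ids if s.startswith("B_")]
    known_sexes = {
        s: samples.loc[s, "sex"] for s in brood_ids if pd.notna(samples.loc[s, "sex"])
    }
    sex_linked, _sex_report = detect_sex_linked(
        panel.subset(individuals=brood_ids), known_sexes
    )
    if sex_linked:
        keep = [l for l in panel.loci if l not in set(sex_linked)]
        panel = panel.subset(loci=keep)

    # ---- 2. identity ---------------------------------------------------
    dup_groups, excluded = match_identities(
        panel, metadata=samples[["role", "capture_year"]]
    )

    # ---- 3. parentage --------------------------------------------------
    freqs = estimate_allele_freqs(panel)
    genotyped = set(panel.ids)
    cand_pairs = dataset.pairs[
        dataset.pairs.broodstock_sampled.astype(bool)
        & dataset.pairs.dam_id.map(lambda f: f"B_{f}" in genotyped)
        & dataset.pairs.sire_id.map(lambda f: f"B_{f}" in genotyped)
    ].copy()
    # candidate-pair genotype rows keyed by founder id
    parent_rows = cand_pairs_parents = sorted(
        set(cand_pairs.dam_id) | set(cand_pairs.sire_id)
    )
    parent_geno = panel.subset(individuals=[f"B_{f}" for f in parent_rows])
    parent_geno = GenotypeMatrix(
        ids=np.array(parent_rows, dtype=object),
        loci=parent_geno.loci,
        dosage=parent_geno.dosage,
        locus_meta=parent_geno.locus_meta,
    )
    monitoring_ids = [s for s in panel.ids if s.startswith("M")]
    monitoring_panel = panel.subset(individuals=monitoring_ids)
    assignments = assign_parent_pairs(
        monitoring_panel,
        cand_pairs[["pair_id", "dam_id", "sire_id"]],
        parent_geno,
        freqs,
        error_rate=e,
        n_sim=n_sim_parentage,
        seed=seed,
    )

    # ---- 4. sibship of non-stocked monitoring fish ---------------------
    assigned = set(
        assignments.loc[assignments.status == "assigned", "offspring_id"]
    )
    nonstocked_ids = [s for s in monitoring_ids if s not in assigned]
    if len(nonstocked_ids) >= 2:
        sib = cluster_full_sibs(
            panel.subset(individuals=nonstocked_ids), freqs,
            error_rate=e, seed=seed + 1,
        )
        sibships = sib.assignments
    else:
        sibships = pd.DataFrame(columns=["sample_id", "group_id", "confidence"])

    # ---- 5. ancestry ---------------------------------------------------
    ref_d_ids = [s for s in panel.ids if s.startswith("RD")]
    ref_y_ids = [s for s in panel.ids if s.startswith("RY")]
    ref_d = panel.subset(individuals=ref_d_ids)
    ref_y = panel.subset(individuals=ref_y_ids)
    fst_table = per_locus_fst(ref_d, ref_y)
    informative = select_informative_loci(fst_table, min_fst=min_fst)
    ref_d_inf = ref_d.subset(loci=informative)
    ref_y_inf = ref_y.subset(loci=informative)
    p_d, p_y = reference_allele_freqs(ref_d_inf, ref_y_inf)

    mon_inf = panel.subset(individuals=monitoring_ids, loci=informative)
    q_mon = estimate_q_table(mon_inf, p_d, p_y)
    q_refs = pd.concat(
        [
            estimate_q_table(ref_d_inf, p_d, p_y),
            estimate_q_table(ref_y_inf, p_d, p_y),
        ],
        ignore_index=True,
    )
    ref_labels = pd.Series(
        {**{s: "D" for s in ref_d_ids}, **{s: "Y" for s in ref_y_ids}}
    )
    thresholds = calibrate_thresholds(q_refs, ref_labels)
    call_rates = pd.Series(
        mon_inf.individual_call_rate(), index=pd.Index(mon_inf.ids)
    )
    ancestry_table = classify_with_sibships(
        q_mon, thresholds, sibships=sibships, call_rates=call_rates
    )
    local_ids = [s for s in nonstocked_ids]
    hybrid_table = (
        hybrid_class_table(panel.subset(individuals=local_ids, loci=informative),
                           p_d, p_y)
        if local_ids
        else pd.DataFrame()
    )

    # ---- 6. growth fit on stocked fish, then origin calls --------------
    monitoring_meta = samples.loc[monitoring_ids, ["sample_id", "capture_year",
                                                   "length_mm"]]
    pair_birth = dict(zip(dataset.pairs.pair_id, dataset.pairs.birth_year))
    stocked_caps = []
    for row in assignments.itertuples():
        if row.status != "assigned":
            continue
        meta = samples.loc[row.offspring_id]
        t = age_at_capture(int(meta.capture_year), int(pair_birth[row.pair_id]))
        stocked_caps.append(
            dict(sample_id=row.offspring_id, pair_id=row.pair_id,
                 age=t, length=float(meta.length_mm))
        )
    stocked_caps = pd.DataFrame(stocked_caps)
    growth_fit = None
    if len(stocked_caps) >= 4 and stocked_caps.age.nunique() >= 2:
        growth_fit = fit_gompertz(stocked_caps.length, stocked_caps.age)

    translocated_samples = set(samples.loc[samples.role == "translocated",
                                           "sample_id"])
    origin_calls = infer_origin(
        monitoring_meta,
        dup_groups,
        assignments,
        translocated_samples,
        ancestry_table,
        dataset.pairs,
        dataset.season_registry,
        growth_fit,
    )

    # ---- 7. survival ---------------------------------------------------
    diss = pair_dissimilarity_table(parent_geno, cand_pairs)
    offspring_ages = capture_age_table(origin_calls)
    survival_table = build_survival_table(
        offspring_ages, cand_pairs, dissimilarities=diss,
        final_year=max(cfg.monitoring_years),
    )
    usable = survival_table.dropna(subset=["dissimilarity"])
    if len(usable) and usable.stock_year.nunique() >= 2:
        ranking, best, fits, failed = select_model(usable)
    else:
        ranking, best, fits, failed = pd.DataFrame(), None, {}, []

    # ---- 8. growth residual models -------------------------------------
    growth_ranking, growth_coefs = pd.DataFrame(), {}
    if growth_fit is not None and len(stocked_caps):
        pair_cross = dict(zip(dataset.pairs.pair_id, dataset.pairs.cross_type))
        pair_year = dict(zip(dataset.pairs.pair_id, dataset.pairs.stock_year))
        diss_of = dict(zip(diss.pair_id, diss.dissimilarity))
        pht_tab = pht_table(panel.subset(individuals=list(stocked_caps.sample_id)))
        pht_of = dict(zip(pht_tab.id, pht_tab.pht))
        gdata = pd.DataFrame(
            dict(
                residual=growth_fit.residuals,
                cross_type=stocked_caps.pair_id.map(pair_cross),
                pht=stocked_caps.sample_id.map(pht_of),
                dissimilarity=stocked_caps.pair_id.map(diss_of),
                stock_year=stocked_caps.pair_id.map(pair_year),
            )
        ).dropna()
        if len(gdata) >= 10 and gdata.stock_year.nunique() >= 2:
            growth_ranking, growth_coefs = growth_residual_lmm(gdata)

    # ---- 9. summaries ---------------------------------------------------
    oc = origin_calls.copy()
    pair_cross = dict(zip(dataset.pairs.pair_id, dataset.pairs.cross_type))
    oc["cross_type"] = oc.pair_id.map(pair_cross)
    summary = tally_origins(oc)

    extras = {}
    try:
        extras["prop_local_nonD"] = yearly_proportions(
            summary,
            [("locally_born", "DxY"), ("locally_born", "YxY")],
        )
    except ValueError:
        pass

    return PipelineResult(
        panel=panel,
        qc_report=qc.to_dict(),
        sex_linked=sex_linked,
        duplicate_groups=dup_groups,
        excluded_samples=excluded,
        assignments=assignments,
        sibships=sibships,
        fst_table=fst_table,
        informative_loci=informative,
        thresholds=thresholds,
        ancestry_table=ancestry_table,
        hybrid_table=hybrid_table,
        origin_calls=origin_calls,
        growth_fit=growth_fit,
        dissimilarity=diss,
        pht=pht_table(monitoring_panel),
        survival_table=survival_table,
        survival_ranking=ranking,
        survival_best=best,
        growth_ranking=growth_ranking,
        growth_coefs=growth_coefs,
        summary=summary,
        extras=extras,
    )
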