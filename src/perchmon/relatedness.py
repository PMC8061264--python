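"""Identity matching, likelihood parentage and full-sib clustering.

All likelihoods share one genotyping-error model: an observed genotype
equals the true one with probability ``1 - e`` and is otherwise replaced by
one of the other two genotypes uniformly — the simplest channel matching a
single per-genotype error rate (default 1e-4).

Parentage follows the classical trio likelihood: the LOD of a candidate
dam/sire pair is the log ratio of the probability of the offspring's
observed genotypes under Mendelian transmission from the pair (integrating
over the parents' true genotypes given their observed ones) versus random
draws from the population allele frequencies.  Assignment confidence is
calibrated by Monte-Carlo simulation under stated sampled-parent and
typed-locus fractions, replacing the Delta-criterion simulation of external
parentage programs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmatrix import MISSING, GenotypeMatrix

__all__ = [
    "estimate_allele_freqs",
    "pair_lod",
    "assign_parent_pairs",
    "match_identities",
    "cluster_full_sibs",
    "ParentageAssignment",
    "SibshipPartition",
]


# ---------------------------------------------------------------------------
# shared probability machinery
# ---------------------------------------------------------------------------
def _error_matrix(e: float) -> np.ndarray:
    """E[true, obs] = P(observed genotype | true genotype)."""
    if not 0.0 < e < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    E = np.full((3, 3), e / 2.0)
    np.fill_diagonal(E, 1.0 - e)
    return E


def _mendel_tensor() -> np.ndarray:
    """M[dam, sire, off] = P(offspring dosage | parental dosages)."""
    M = np.zeros((3, 3, 3))
    for gd in range(3):
        for gs in range(3):
            pd_ = gd / 2.0
            ps_ = gs / 2.0
            M[gd, gs, 0] = (1 - pd_) * (1 - ps_)
            M[gd, gs, 1] = pd_ * (1 - ps_) + (1 - pd_) * ps_
            M[gd, gs, 2] = pd_ * ps_
    return M


def _hwe(p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities, (L, 3)."""
    p = np.asarray(p, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)


def estimate_allele_freqs(matrix: GenotypeMatrix, shrink: float = 0.5) -> np.ndarray:
    """Alternate-allele frequencies with a small pseudo-count.

    Computed once from all genotyped candidates and then held fixed for
    every likelihood (frequencies are not updated during assignment).
    """
    called = matrix.dosage != MISSING
    alt = np.where(called, matrix.dosage, 0).sum(axis=0).astype(float)
    n = called.sum(axis=0).astype(float)
    return (alt + shrink) / (2 * n + 2 * shrink)


def _parent_posterior(obs: np.ndarray, hwe: np.ndarray, E: np.ndarray) -> np.ndarray:
    """P(true parental genotype | observed call), (L, 3); HWE when missing."""
    L = len(obs)
    post = hwe.copy()
    called = obs != MISSING
    lik = E[:, obs[called]].T  # (n_called, 3)
    post[called] = hwe[called] * lik
    post /= post.sum(axis=1, keepdims=True)
    return post


def _pair_offspring_dist(
    dam_obs: np.ndarray, sire_obs: np.ndarray, hwe: np.ndarray, E: np.ndarray
) -> np.ndarray:
    """P(observed offspring genotype | pair's observed genotypes), (L, 3)."""
    M = _mendel_tensor()
    OT = np.einsum("dst,to->dso", M, E)  # transmission to *observed* offspring
    post_d = _parent_posterior(dam_obs, hwe, E)
    post_s = _parent_posterior(sire_obs, hwe, E)
    return np.einsum("ld,ls,dso->lo", post_d, post_s, OT)


def _background_dist(hwe: np.ndarray, E: np.ndarray) -> np.ndarray:
    """P(observed genotype | random population member), (L, 3)."""
    return hwe @ E


def _exclusion_table() -> np.ndarray:
    """X[dam, sire, off] True when the trio is Mendelian-impossible."""
    alleles = {0: [(0, 0)], 1: [(0, 1)], 2: [(1, 1)]}
    X = np.ones((3, 3, 3), dtype=bool)
    for gd in range(3):
        for gs in range(3):
            for ad in alleles[gd][0]:
                for as_ in alleles[gs][0]:
                    X[gd, gs, ad + as_] = False
    return X


def pair_lod(
    off_obs: np.ndarray,
    dam_obs: np.ndarray,
    sire_obs: np.ndarray,
    freqs: np.ndarray,
    error_rate: float = 1e-4,
) -> float:
    """LOD of (dam, sire) parentage for one offspring vs unrelatedness.

    Sum over the offspring's called loci of
    ``log P(g_off | g_dam, g_sire, e) - log P(g_off | allele freqs)``,
    marginalising true genotypes of all three fish under the error model.
    Loci where the offspring call is missing contribute nothing; exclusions
    appear as strongly negative terms rather than hard failures.
    """
    E = _error_matrix(error_rate)
    hwe = _hwe(freqs)
    num = _pair_offspring_dist(np.asarray(dam_obs), np.asarray(sire_obs), hwe, E)
    den = _background_dist(hwe, E)
    off = np.asarray(off_obs)
    called = off != MISSING
    idx = np.flatnonzero(called)
    return float(
        np.log(num[idx, off[idx]]).sum() - np.log(den[idx, off[idx]]).sum()
    )


# ---------------------------------------------------------------------------
# parent-pair assignment
# ---------------------------------------------------------------------------
@dataclass
class ParentageAssignment:
    offspring_id: str
    pair_id: str | None
    lod: float
    margin: float
    confidence: float
    mismatch_count: int
    status: str  # assigned / low_confidence / negative_lod / tie


def _lod_matrix(
    off_dosage: np.ndarray,
    logA: np.ndarray,
    logBG: np.ndarray,
) -> np.ndarray:
    """LOD for every offspring (rows) against every pair (columns)."""
    n_pairs = logA.shape[0]
    N = off_dosage.shape[0]
    lod = np.zeros((N, n_pairs))
    for g in range(3):
        I = (off_dosage == g).astype(np.float64)
        lod += I @ (logA[:, :, g] - logBG[:, g][None, :]).T
    return lod


def assign_parent_pairs(
    offspring: GenotypeMatrix,
    pairs: pd.DataFrame,
    parent_geno: GenotypeMatrix,
    freqs: np.ndarray,
    error_rate: float = 1e-4,
    min_confidence: float = 0.95,
    sampled_parent_fraction: float = 0.7,
    typed_locus_fraction: float = 0.9,
    max_mismatch_frac: float = 0.02,
    n_sim: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each offspring its maximum-LOD candidate pair, with confidence.

    ``pairs`` needs columns ``pair_id``, ``dam_id``, ``sire_id``; both
    parents must be rows of ``parent_geno`` (the caller restricts candidates
    to fish of breeding age for the offspring's possible birth seasons).

    Confidence calibration: ``n_sim`` offspring are simulated from the
    candidate pairs' observed genotypes, with each true pair left out of the
    candidate list with probability ``1 - sampled_parent_fraction`` and each
    locus typed with probability ``typed_locus_fraction``.  An observed
    assignment with LOD margin m over the runner-up gets confidence equal to
    the fraction of simulated offspring with margin >= m that were assigned
    to their true pair.  Assignments are accepted when confidence exceeds
    ``min_confidence``, the LOD is positive, and Mendelian exclusions do not
    exceed ``max_mismatch_frac`` of the trio-complete loci (a true trio at
    error rate 1e-4 shows essentially none, whereas e.g. a grandchild of the
    pair shows several percent); exact ties are left unassigned and reported.
    """
    rng = np.random.default_rng(seed)
    E = _error_matrix(error_rate)
    hwe = _hwe(np.clip(freqs, 1e-6, 1 - 1e-6))
    logBG = np.log(_background_dist(hwe, E))
    X = _exclusion_table()

    pair_ids = list(pairs["pair_id"])
    n_pairs = len(pair_ids)
    if n_pairs == 0:
        return pd.DataFrame(
            columns=["offspring_id", "pair_id", "lod", "margin", "confidence",
                     "mismatch_count", "status"]
        )
    L = offspring.n_loci
    A = np.empty((n_pairs, L, 3))
    dam_rows = np.empty((n_pairs, L), dtype=np.int8)
    sire_rows = np.empty((n_pairs, L), dtype=np.int8)
    for k, row in enumerate(pairs.itertuples()):
        dam_rows[k] = parent_geno.row(row.dam_id)
        sire_rows[k] = parent_geno.row(row.sire_id)
        A[k] = _pair_offspring_dist(dam_rows[k], sire_rows[k], hwe, E)
    logA = np.log(A)

    lod = _lod_matrix(offspring.dosage, logA, logBG)
    best = np.argmax(lod, axis=1)
    best_lod = lod[np.arange(len(lod)), best]
    lod_masked = lod.copy()
    lod_masked[np.arange(len(lod)), best] = -np.inf
    second_lod = lod_masked.max(axis=1) if n_pairs > 1 else np.full(len(lod), -np.inf)
    margin = best_lod - second_lod

    sim_margin, sim_correct = _simulate_assignment_margins(
        dam_rows, sire_rows, hwe, E, logA, logBG,
        sampled_parent_fraction, typed_locus_fraction, n_sim, rng,
    )
    order = np.argsort(sim_margin)
    sim_margin = sim_margin[order]
    sim_correct = sim_correct[order]
    suffix_total = np.arange(len(sim_margin), 0, -1)
    suffix_correct = np.cumsum(sim_correct[::-1])[::-1]

    def confidence_of(m: float) -> float:
        i = np.searchsorted(sim_margin, m, side="left")
        i = min(i, max(len(sim_margin) - 50, 0))  # >=50 sims for stability
        return float(suffix_correct[i] / suffix_total[i])

    out = []
    for n, oid in enumerate(offspring.ids):
        k = int(best[n])
        conf = confidence_of(float(margin[n]))
        mm, n_trio = _mismatch_count(offspring.dosage[n], dam_rows[k],
                                     sire_rows[k], X)
        if n_pairs > 1 and margin[n] <= 1e-9:
            status, assigned = "tie", None
        elif best_lod[n] <= 0:
            status, assigned = "negative_lod", None
        elif n_trio > 0 and mm > max_mismatch_frac * n_trio:
            status, assigned = "excess_mismatch", None
        elif conf <= min_confidence:
            status, assigned = "low_confidence", None
        else:
            status, assigned = "assigned", pair_ids[k]
        out.append(
            dict(offspring_id=oid, pair_id=assigned, best_pair=pair_ids[k],
                 lod=float(best_lod[n]), margin=float(margin[n]),
                 confidence=conf, mismatch_count=int(mm), status=status)
        )
    return pd.DataFrame(out)


def _mismatch_count(off, dam_obs, sire_obs, X) -> tuple[int, int]:
    """(Mendelian-excluded loci, trio-complete loci) for one offspring/pair."""
    called = (off != MISSING) & (dam_obs != MISSING) & (sire_obs != MISSING)
    return int(X[dam_obs[called], sire_obs[called], off[called]].sum()), int(
        called.sum()
    )


def _simulate_assignment_margins(
    dam_rows, sire_rows, hwe, E, logA, logBG,
    sampled_parent_fraction, typed_locus_fraction, n_sim, rng,
):
    """Margins and correctness of simulated known-parentage offspring."""
    n_pairs, L = dam_rows.shape
    true_pair = rng.integers(n_pairs, size=n_sim)
    M = _mendel_tensor()

    # draw true parental genotypes from their posteriors, transmit, observe
    geno = np.empty((n_sim, L), dtype=np.int8)
    for k in range(n_pairs):
        sel = np.flatnonzero(true_pair == k)
        if not len(sel):
            continue
        post_d = _parent_posterior(dam_rows[k], hwe, E)
        post_s = _parent_posterior(sire_rows[k], hwe, E)
        td = _sample_rows(post_d, (len(sel),), rng)
        ts = _sample_rows(post_s, (len(sel),), rng)
        p_off = M[td, ts]  # (n_sel, L, 3)
        to = _sample_categorical(p_off, rng)
        obs = _sample_categorical(E[to], rng)
        geno[sel] = obs
    untyped = rng.random((n_sim, L)) >= typed_locus_fraction
    geno[untyped] = MISSING

    lod = _lod_matrix(geno, logA, logBG)
    unsampled = rng.random(n_sim) >= sampled_parent_fraction
    lod_avail = lod.copy()
    lod_avail[unsampled, true_pair[unsampled]] = -np.inf
    best = np.argmax(lod_avail, axis=1)
    best_lod = lod_avail[np.arange(n_sim), best]
    lod_avail[np.arange(n_sim), best] = -np.inf
    second = lod_avail.max(axis=1) if n_pairs > 1 else np.full(n_sim, -np.inf)
    margins = best_lod - second
    correct = (best == true_pair) & ~unsampled
    return margins, correct


def _sample_rows(post: np.ndarray, lead_shape, rng) -> np.ndarray:
    """Sample genotype indices from per-locus distributions (L, 3)."""
    L = post.shape[0]
    u = rng.random(lead_shape + (L,))
    cdf = np.cumsum(post, axis=1)
    return (u[..., None] > cdf[None, :, :]).sum(axis=-1).astype(np.int8)


def _sample_categorical(p: np.ndarray, rng) -> np.ndarray:
    """Sample the trailing axis of a probability array of shape (..., 3)."""
    u = rng.random(p.shape[:-1])
    cdf = np.cumsum(p, axis=-1)
    return (u[..., None] > cdf).sum(axis=-1).astype(np.int8)


# ---------------------------------------------------------------------------
# identity analysis
# ---------------------------------------------------------------------------
def match_identities(
    matrix: GenotypeMatrix,
    min_match: float = 0.99,
    max_mismatch_loci: int = 50,
    metadata: pd.DataFrame | None = None,
    min_call_rate: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fuzzy-match samples into duplicate groups (recaptures, mislabels).

    Two samples merge when they share >``min_match`` of their allele scores
    over jointly called loci AND differ at <=``max_mismatch_loci`` loci;
    merging is closed transitively (union-find).  Samples called at under
    ``min_call_rate`` of the panel are excluded and reported.

    Returns ``(groups, excluded)``: ``groups`` maps each sample in a
    multi-sample group to ``group_id`` with a coarse classification when
    ``metadata`` (indexed by sample id, columns ``role``/``capture_year``)
    is supplied — conflicting roles suggest a mislabel, repeated monitoring
    captures a recapture.
    """
    if not 2 <= matrix.n_individuals:
        raise ValueError("identity matching needs at least two samples")
    call_rate = matrix.individual_call_rate()
    ok = call_rate >= min_call_rate
    excluded = pd.DataFrame(
        {"sample_id": matrix.ids[~ok], "call_rate": call_rate[~ok]}
    )
    m = matrix.subset(individuals=ok)
    N = m.n_individuals

    called = (m.dosage != MISSING).astype(np.float32)
    shared = called @ called.T
    I = [(m.dosage == g).astype(np.float32) for g in range(3)]
    absdiff = np.zeros((N, N), dtype=np.float32)
    mismatch = np.zeros((N, N), dtype=np.float32)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            cross = I[a] @ I[b].T
            absdiff += abs(a - b) * cross
            mismatch += cross
    with np.errstate(invalid="ignore", divide="ignore"):
        match_frac = np.where(shared > 0, (2 * shared - absdiff) / (2 * shared), 0.0)

    link = (match_frac > min_match) & (mismatch <= max_mismatch_loci) & (shared > 0)
    np.fill_diagonal(link, False)

    parent = list(range(N))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(*np.nonzero(np.triu(link))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri

    roots: dict = {}
    rows = []
    for i in range(N):
        r = find(i)
        roots.setdefault(r, []).append(i)
    gid = 0
    for r, members in roots.items():
        if len(members) < 2:
            continue
        gid += 1
        kind = "duplicate"
        if metadata is not None:
            sub = metadata.loc[[m.ids[i] for i in members]]
            if sub["role"].nunique() > 1:
                kind = "mislabel_suspect"
            elif ("capture_year" in sub
                  and sub["capture_year"].dropna().nunique() > 1):
                kind = "recapture"
        for i in members:
            rows.append(dict(sample_id=m.ids[i], group_id=f"G{gid:03d}", kind=kind))
    groups = pd.DataFrame(rows, columns=["sample_id", "group_id", "kind"])
    return groups, excluded


# ---------------------------------------------------------------------------
# full-sib clustering
# ---------------------------------------------------------------------------
@dataclass
class SibshipPartition:
    """Disjoint, exhaustive full-sib grouping with per-group confidence."""

    assignments: pd.DataFrame  # sample_id, group_id, confidence
    threshold: float
    split_log: list = field(default_factory=list)

    def group_of(self, sample_id: str) -> str:
        row = self.assignments.loc[self.assignments.sample_id == sample_id]
        return row.group_id.iloc[0]


def _sib_weight_tables(freqs: np.ndarray, E: np.ndarray):
    """Per-locus log LR tables W[l, g1, g2] = log P_FS/P_UR for observed pairs."""
    hwe = _hwe(np.clip(freqs, 1e-6, 1 - 1e-6))
    M = _mendel_tensor()
    OT = np.einsum("dst,to->dso", M, E)
    J = np.einsum("ld,ls,dsg,dsh->lgh", hwe, hwe, OT, OT)
    U = _background_dist(hwe, E)
    U2 = U[:, :, None] * U[:, None, :]
    return np.log(J) - np.log(U2), J, U


def cluster_full_sibs(
    matrix: GenotypeMatrix,
    freqs: np.ndarray,
    error_rate: float = 1e-4,
    min_group_confidence: float = 0.98,
    n_cal: int = 2000,
    seed: int = 0,
) -> SibshipPartition:
    """Partition individuals into full-sib groups by pairwise likelihood.

    Each pair's statistic is the summed per-locus log likelihood ratio of
    full-sibship (shared unobserved parents, error-aware) versus
    unrelatedness.  The merge threshold is calibrated on simulated
    unrelated and full-sib pairs; links above threshold are merged by
    single linkage, and any resulting group in which some internal pair
    fails the threshold is split into greedy cliques of mutually passing
    pairs (splits are logged).  A pair's confidence is the fraction of
    simulated unrelated pairs scoring below it; a group's confidence is the
    minimum over its internal pairs (singletons score 1.0).
    """
    if matrix.n_individuals < 2:
        raise ValueError("sibship clustering needs at least two individuals")
    rng = np.random.default_rng(seed)
    E = _error_matrix(error_rate)
    W, J, U = _sib_weight_tables(freqs, E)
    N, L = matrix.dosage.shape

    I = [(matrix.dosage == g).astype(np.float32) for g in range(3)]
    llr = np.zeros((N, N), dtype=np.float64)
    for g in range(3):
        for h in range(3):
            llr += I[g] @ (W[:, g, h].astype(np.float32) * I[h]).T

    ur_llr = _simulate_pair_llrs(U, J, W, n_cal, rng, related=False)
    fs_llr = _simulate_pair_llrs(U, J, W, n_cal, rng, related=True)
    if fs_llr.min() > ur_llr.max():
        threshold = 0.5 * (fs_llr.min() + ur_llr.max())
    else:
        threshold = float(np.quantile(ur_llr, 0.999))

    link = llr >= threshold
    np.fill_diagonal(link, False)

    # single-linkage components
    parent = list(range(N))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(*np.nonzero(np.triu(link))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    comps: dict = {}
    for i in range(N):
        comps.setdefault(find(i), []).append(i)

    ur_sorted = np.sort(ur_llr)

    def pair_conf(i, j) -> float:
        return float(np.searchsorted(ur_sorted, llr[i, j]) / len(ur_sorted))

    split_log = []
    rows = []
    gid = 0
    for members in comps.values():
        cliques = [members]
        if len(members) > 1 and not all(
            link[i, j] for a, i in enumerate(members) for j in members[a + 1:]
        ):
            cliques = _greedy_cliques(members, link)
            split_log.append(
                dict(component=sorted(matrix.ids[i] for i in members),
                     n_cliques=len(cliques))
            )
        for clique in cliques:
            gid += 1
            if len(clique) == 1:
                conf = 1.0
            else:
                conf = min(
                    pair_conf(i, j)
                    for a, i in enumerate(clique) for j in clique[a + 1:]
                )
            for i in clique:
                rows.append(dict(sample_id=matrix.ids[i],
                                 group_id=f"S{gid:04d}", confidence=conf))
    assignments = pd.DataFrame(rows)
    return SibshipPartition(assignments=assignments, threshold=float(threshold),
                            split_log=split_log)


def _greedy_cliques(members, link):
    remaining = list(members)
    cliques = []
    while remaining:
        seed_node = remaining[0]
        clique = [seed_node]
        for cand in remaining[1:]:
            if all(link[cand, c] for c in clique):
                clique.append(cand)
        cliques.append(clique)
        remaining = [m for m in remaining if m not in clique]
    return cliques


def _simulate_pair_llrs(U, J, W, n, rng, related: bool) -> np.ndarray:
    """LLR draws for simulated unrelated or full-sib observed-genotype pairs."""
    L = U.shape[0]
    if related:
        # draw jointly from the full-sib observed-pair distribution
        flat = J.reshape(L, 9)
        flat = flat / flat.sum(axis=1, keepdims=True)
        idx = _sample_categorical_k(flat, (n,), rng)
        g1, g2 = idx // 3, idx % 3
    else:
        g1 = _sample_categorical_k(U, (n,), rng)
        g2 = _sample_categorical_k(U, (n,), rng)
    return W[np.arange(L)[None, :], g1, g2].sum(axis=1)


def _sample_categorical_k(p: np.ndarray, lead_shape, rng) -> np.ndarray:
    """Sample indices from per-locus distributions p of shape (L, K)."""
    L = p.shape[0]
    u = rng.random(lead_shape + (L,))
    cdf = np.cumsum(p, axis=1)
    return (u[..., None] > cdf[None, :, :]).sum(axis=-1)
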