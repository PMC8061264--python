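"""Supervised two-population ancestry estimation and hybrid classification.

Rather than unsupervised MCMC clustering, membership in the source-D gene
pool (q_D, with q_Y = 1 - q_D) is estimated by maximum likelihood against
reference allele frequencies: each allele copy is an independent draw from
the mixture ``q * p_D + (1 - q) * p_Y``, solved by EM.  The estimand is the
same Q-membership a clustering run would report, but the procedure is
deterministic and uses the labelled reference pools directly.  Category
thresholds are calibrated empirically from known-origin reference fish, and
six hybrid classes (pure D, pure Y, F1, F2, and both backcrosses) are
scored by their expected ancestry-pair composition per locus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmatrix import MISSING, GenotypeMatrix

HYBRID_CLASSES = ("pureD", "pureY", "F1", "F2", "BC_D", "BC_Y")

#: Expected fraction of loci whose two allele copies originate (both from D,
#: one from each, both from Y), per hybrid class.
CLASS_WEIGHTS = {
    "pureD": (1.0, 0.0, 0.0),
    "pureY": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC_D": (0.5, 0.5, 0.0),
    "BC_Y": (0.0, 0.5, 0.5),
}


class CalibrationError(RuntimeError):
    pass


@dataclass
class ThresholdSet:
    """Empirical q_D limits of the known-origin reference fish.

    ``upper`` is the minimum q_D seen in source-D references, ``lower`` the
    maximum in source-Y references; fish between the two are of
    two-population ancestry.
    """

    lower: float
    upper: float

    def classify(self, q: float) -> str:
        if q >= self.upper:
            return "sourceD"
        if q <= self.lower:
            return "sourceY"
        return "two_population"


def select_informative_loci(
    fst_table: pd.DataFrame, min_fst: float = 0.02
) -> list:
    """Loci at or above the F_ST threshold, in stable input order."""
    sel = fst_table.loc[fst_table["fst"] >= min_fst, "locus"].tolist()
    if not sel:
        raise ValueError(
            f"no loci reach F_ST >= {min_fst}; lower the threshold"
        )
    return sel


def reference_allele_freqs(
    ref_d: GenotypeMatrix, ref_y: GenotypeMatrix, pseudocount: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-source alternate-allele frequencies with add-one shrinkage.

    The pseudocount keeps every per-locus probability strictly inside
    (0, 1), so no genotype has zero likelihood under any hybrid class.
    """
    if not np.array_equal(ref_d.loci, ref_y.loci):
        raise ValueError("reference matrices must share a locus panel")

    def f(m):
        called = m.dosage != MISSING
        alt = np.where(called, m.dosage, 0).sum(axis=0).astype(float)
        n = called.sum(axis=0).astype(float)
        return (alt + pseudocount) / (2 * n + 2 * pseudocount)

    return f(ref_d), f(ref_y)


def estimate_q(
    genotype_row: np.ndarray,
    p_d: np.ndarray,
    p_y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> float:
    """Maximum-likelihood admixture proportion q_D for one individual.

    EM on the standard mixture: each of the 2L allele copies is from the D
    pool with probability q.  Missing calls are skipped; an all-missing row
    raises ``ValueError``.
    """
    g = np.asarray(genotype_row)
    called = g != MISSING
    if not called.any():
        raise ValueError("q undefined: all calls missing")
    g = g[called].astype(float)
    pd_ = np.asarray(p_d, dtype=float)[called]
    py_ = np.asarray(p_y, dtype=float)[called]
    q = 0.5
    two_l = 2.0 * len(g)
    for _ in range(max_iter):
        alt_d = q * pd_
        alt_mix = alt_d + (1 - q) * py_
        ref_d = q * (1 - pd_)
        ref_mix = ref_d + (1 - q) * (1 - py_)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_alt = np.where(alt_mix > 0, alt_d / alt_mix, 0.0)
            r_ref = np.where(ref_mix > 0, ref_d / ref_mix, 0.0)
        q_new = float((g * r_alt + (2 - g) * r_ref).sum() / two_l)
        if abs(q_new - q) < tol:
            q = q_new
            break
        q = q_new
    # EM crawls near flat optima; polish with a bounded 1-D search
    from scipy.optimize import minimize_scalar

    lo, hi = max(0.0, q - 0.05), min(1.0, q + 0.05)
    res = minimize_scalar(
        lambda qq: -_mixture_loglik(g, qq, pd_, py_),
        bounds=(lo, hi), method="bounded",
        options=dict(xatol=1e-10),
    )
    if -res.fun >= _mixture_loglik(g, q, pd_, py_):
        q = float(res.x)
    return float(np.clip(q, 0.0, 1.0))


def _mixture_loglik(g, q, pd_, py_) -> float:
    pa = np.clip(q * pd_ + (1 - q) * py_, 1e-12, 1 - 1e-12)
    return float((g * np.log(pa) + (2 - g) * np.log(1 - pa)).sum())


def q_loglik(genotype_row: np.ndarray, q: float, p_d, p_y) -> float:
    """Log-likelihood of the admixture mixture at a given q."""
    g = np.asarray(genotype_row)
    called = g != MISSING
    g = g[called].astype(float)
    pa = q * np.asarray(p_d)[called] + (1 - q) * np.asarray(p_y)[called]
    pa = np.clip(pa, 1e-12, 1 - 1e-12)
    return float((g * np.log(pa) + (2 - g) * np.log(1 - pa)).sum())


def estimate_q_table(
    matrix: GenotypeMatrix, p_d: np.ndarray, p_y: np.ndarray
) -> pd.DataFrame:
    rows = []
    for i, iid in enumerate(matrix.ids):
        try:
            q = estimate_q(matrix.dosage[i], p_d, p_y)
            rows.append(dict(id=iid, q_d=q, status="ok"))
        except ValueError:
            rows.append(dict(id=iid, q_d=np.nan, status="all_missing"))
    return pd.DataFrame(rows)


def calibrate_thresholds(
    q_values: pd.DataFrame, ref_labels: pd.Series
) -> ThresholdSet:
    """Empirical membership limits from known-source reference fish.

    ``q_values`` must carry columns ``id``/``q_d``; ``ref_labels`` maps ids
    to 'D' or 'Y'.  Fails loudly (with offending ids) when the reference
    pools overlap in q.
    """
    merged = q_values.merge(
        ref_labels.rename("label"), left_on="id", right_index=True
    )
    d_vals = merged.loc[merged.label == "D", "q_d"]
    y_vals = merged.loc[merged.label == "Y", "q_d"]
    if d_vals.empty or y_vals.empty:
        raise CalibrationError("need at least one reference per source")
    upper = float(d_vals.min())
    lower = float(y_vals.max())
    if lower >= upper:
        off = merged.loc[
            ((merged.label == "D") & (merged.q_d <= lower))
            | ((merged.label == "Y") & (merged.q_d >= upper)), "id"
        ].tolist()
        raise CalibrationError(
            f"reference pools overlap in q (lower={lower:.3f} >= "
            f"upper={upper:.3f}); offending ids: {off}"
        )
    return ThresholdSet(lower=lower, upper=upper)


def classify_with_sibships(
    q_values: pd.DataFrame,
    thresholds: ThresholdSet,
    sibships: pd.DataFrame | None = None,
    call_rates: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign ancestry categories, classifying one representative per sib group.

    Within each full-sib group the member with the least missing data is
    classified and its label propagated to the rest (``representative``
    marks the classified fish).  Without sibship information every fish is
    its own representative.
    """
    df = q_values.copy()
    if sibships is None:
        df["group_id"] = df["id"]
    else:
        df = df.merge(
            sibships.rename(columns={"sample_id": "id"})[["id", "group_id"]],
            on="id", how="left",
        )
        df["group_id"] = df["group_id"].fillna(df["id"])
    if call_rates is not None:
        df["call_rate"] = df["id"].map(call_rates).fillna(0.0)
    else:
        df["call_rate"] = 1.0

    df["representative"] = False
    df["category"] = None
    for _, grp in df.groupby("group_id"):
        grp_ok = grp.dropna(subset=["q_d"])
        if grp_ok.empty:
            continue
        rep_idx = grp_ok["call_rate"].idxmax()
        cat = thresholds.classify(float(df.loc[rep_idx, "q_d"]))
        df.loc[grp.index, "category"] = cat
        df.loc[rep_idx, "representative"] = True
    return df


def hybrid_class_posteriors(
    genotype_row: np.ndarray,
    p_d: np.ndarray,
    p_y: np.ndarray,
    prior: dict | None = None,
) -> dict:
    """Posterior over six hybrid classes for one individual.

    Per locus the genotype distribution under a class is the mixture of the
    three parental-origin genotype distributions (both alleles from D, one
    from each, both from Y) weighted by the class's expected ancestry-pair
    composition.  Independent loci; uniform prior by default.  Frequencies
    must be shrunk away from 0/1 (see :func:`reference_allele_freqs`).
    """
    g = np.asarray(genotype_row)
    called = g != MISSING
    if not called.any():
        raise ValueError("hybrid posterior undefined: all calls missing")
    g = g[called]
    pd_ = np.asarray(p_d, dtype=float)[called]
    py_ = np.asarray(p_y, dtype=float)[called]
    if np.any((pd_ <= 0) | (pd_ >= 1) | (py_ <= 0) | (py_ >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")

    def hwe(p):
        return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)

    dist_dd = hwe(pd_)
    dist_yy = hwe(py_)
    dist_dy = np.stack(
        [(1 - pd_) * (1 - py_), pd_ * (1 - py_) + (1 - pd_) * py_, pd_ * py_],
        axis=1,
    )
    idx = np.arange(len(g))
    logliks = {}
    for cls, (w_dd, w_dy, w_yy) in CLASS_WEIGHTS.items():
        mix = w_dd * dist_dd + w_dy * dist_dy + w_yy * dist_yy
        logliks[cls] = float(np.log(mix[idx, g]).sum())
    prior = prior or {c: 1.0 / len(HYBRID_CLASSES) for c in HYBRID_CLASSES}
    log_post = np.array(
        [logliks[c] + np.log(prior[c]) for c in HYBRID_CLASSES]
    )
    log_post -= log_post.max()
    post = np.exp(log_post)
    total = post.sum()
    if not np.isfinite(total) or total <= 0:  # pragma: no cover - defensive
        raise RuntimeError("zero likelihood under every hybrid class")
    post /= total
    return dict(zip(HYBRID_CLASSES, post))


def hybrid_class_table(
    matrix: GenotypeMatrix, p_d: np.ndarray, p_y: np.ndarray
) -> pd.DataFrame:
    rows = []
    for i, iid in enumerate(matrix.ids):
        try:
            post = hybrid_class_posteriors(matrix.dosage[i], p_d, p_y)
            best = max(post, key=post.get)
            rows.append(dict(id=iid, modal_class=best, **post))
        except ValueError:
            rows.append(dict(id=iid, modal_class=None,
                             **{c: np.nan for c in HYBRID_CLASSES}))
    return pd.DataFrame(rows)
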