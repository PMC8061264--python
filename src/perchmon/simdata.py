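"""Synthetic two-source reintroduction datasets with known truth.

Emulates the data-generating process of a hatchery-supported reintroduction
monitored genetically: two differentiated source populations (labelled D and
Y), a DArT-like biallelic SNP panel with missingness and genotyping error, a
multi-season breeding programme of single-dam x single-sire pairs spanning
three cross-types (DxD, DxY, YxY), larvae-proportional fingerling stocking,
wild-caught translocations, cross-type-dependent annual survival on the
logit scale with a stocking-year random effect, Gompertz growth, age-biased
electrofishing capture, and local recruitment by random mating among mature
survivors.

Every simulated fish carries its truth (origin, parents, birth season,
ancestry fraction, fate) in a :class:`TruthLedger`, so each downstream
analysis stage has a verifiable oracle.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .gmatrix import MISSING, GenotypeMatrix

CROSS_TYPES = ("DxD", "DxY", "YxY")
#: Fraction of a year between 1 December hatching and the ~1 April captures.
CAPTURE_SEASON_OFFSET = 2.0 / 3.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class SurvivalParams:
    """Annual survival model on the logit scale.

    ``P(survive year-of-life a) = expit(intercept + cross_offsets[ct]
    + age_slope * a + u_cohort)`` with ``u_cohort ~ N(0, year_sd^2)`` shared
    by all fish born in the same season.
    """

    intercept: float = -0.8
    cross_offsets: dict = field(
        default_factory=lambda: {"DxD": 0.0, "DxY": 0.6, "YxY": 1.2}
    )
    age_slope: float = 0.5
    year_sd: float = 0.3


@dataclass
class GompertzParams:
    """Length-at-age curve L(t) = linf * exp(-exp(-k * (t - t0)))."""

    linf: float  # asymptotic total length, mm
    k: float  # growth rate, 1/yr
    t0: float  # inflection age, yr
    sigma: float  # residual SD of observed lengths, mm

    def length_at(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.linf * np.exp(-np.exp(-self.k * (np.asarray(age) - self.t0)))


@dataclass
class SeasonPlan:
    """One breeding season: pairs per cross-type and the fingerlings stocked.

    ``season`` strings look like ``"2014/15"``: broodstock mated in
    November of the first year, larvae hatch on 1 December of that year and
    fingerlings are released the following January-February.
    """

    season: str
    pairs: dict
    stocked: int
    mean_larvae: float = 3000.0
    broodstock_sampled: bool = True

    @property
    def birth_year(self) -> int:
        return int(self.season.split("/")[0])

    @property
    def stock_year(self) -> int:
        return self.birth_year + 1


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic study.

    Defaults mirror the management history the analysis pipeline is designed
    for: seven breeding seasons, ~94,000 fingerlings stocked, ~1,800
    translocations predominantly from source D, and three monitoring years.
    """

    n_loci: int = 1100
    n_founders_per_source: int = 150
    fst_target: float = 0.05
    missing_rate: float = 0.03
    genotyping_error_rate: float = 1e-4
    seasons: list = field(default_factory=list)
    translocations: dict = field(default_factory=dict)  # year -> {source: count}
    translocated_genotyped_fraction: float = 0.983
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    gompertz: dict = field(default_factory=dict)  # cross-type -> GompertzParams
    capture_prob_by_age: tuple = (0.0003, 0.002, 0.002, 0.002, 0.002, 0.002)
    monitoring_years: tuple = (2016, 2017, 2018)
    maturity_age: int = 3
    recruitment_rate: float = 9.0  # age-0 recruits per mature adult per season
    n_reference_per_source: int = 51
    high_missing_locus_fraction: float = 0.05
    high_missing_rate: float = 0.15
    low_repro_locus_fraction: float = 0.10
    shared_tag_fraction: float = 0.02
    larvae_cv: float = 0.6
    seed: int = 20201215

    def __post_init__(self) -> None:
        for name in (
            "fst_target",
            "missing_rate",
            "genotyping_error_rate",
            "translocated_genotyped_fraction",
            "high_missing_locus_fraction",
            "high_missing_rate",
            "low_repro_locus_fraction",
            "shared_tag_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a fraction in [0, 1]")
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        probs = np.asarray(self.capture_prob_by_age, dtype=float)
        if probs.min() < 0 or probs.max() > 1:
            raise ValueError("capture probabilities must be fractions")
        if len(probs) > 1 and not probs[0] < probs[1:].min():
            # age-0 fish are systematically harder to catch than older fish
            raise ValueError("capture probability for age<1 must be below older ages")
        for plan in self.seasons:
            if plan.stocked < 0 or plan.mean_larvae <= 0:
                raise ValueError(f"season {plan.season}: larvae/stocked must be positive")
            for ct in plan.pairs:
                if ct not in CROSS_TYPES:
                    raise ValueError(f"unknown cross-type {ct!r}")
        if not self.gompertz:
            self.gompertz = default_gompertz()
        for ct, gp in self.gompertz.items():
            if gp.linf <= 0 or gp.k <= 0:
                raise ValueError(f"gompertz for {ct}: linf and k must be positive")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["seasons"] = [dataclasses.asdict(s) for s in self.seasons]
        raw["gompertz"] = {k: dataclasses.asdict(v) for k, v in self.gompertz.items()}
        raw["survival"] = dataclasses.asdict(self.survival)
        raw["capture_prob_by_age"] = list(self.capture_prob_by_age)
        raw["monitoring_years"] = list(self.monitoring_years)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["seasons"] = [SeasonPlan(**s) for s in raw.get("seasons", [])]
        raw["gompertz"] = {
            k: GompertzParams(**v) for k, v in raw.get("gompertz", {}).items()
        }
        raw["survival"] = SurvivalParams(**raw.get("survival", {}))
        raw["capture_prob_by_age"] = tuple(raw["capture_prob_by_age"])
        raw["monitoring_years"] = tuple(raw["monitoring_years"])
        raw["translocations"] = {
            int(k): dict(v) for k, v in raw.get("translocations", {}).items()
        }
        return cls(**raw)


def default_gompertz() -> dict:
    """Cross-type growth defaults; YxY fish run slightly larger at age."""
    return {
        "DxD": GompertzParams(340.0, 0.75, 1.10, 9.0),
        "DxY": GompertzParams(345.0, 0.75, 1.10, 9.0),
        "YxY": GompertzParams(360.0, 0.78, 1.05, 9.0),
    }


def default_config(**overrides) -> SimConfig:
    """The reference study design: seven seasons, three monitoring years."""
    seasons = [
        SeasonPlan("2010/11", {"DxD": 4, "DxY": 0, "YxY": 2}, 3909,
                   broodstock_sampled=False),
        SeasonPlan("2012/13", {"DxD": 1, "DxY": 0, "YxY": 6}, 6320),
        SeasonPlan("2013/14", {"DxD": 11, "DxY": 0, "YxY": 7}, 40500),
        SeasonPlan("2014/15", {"DxD": 5, "DxY": 5, "YxY": 0}, 13600),
        SeasonPlan("2015/16", {"DxD": 1, "DxY": 2, "YxY": 0}, 6400),
        SeasonPlan("2016/17", {"DxD": 4, "DxY": 1, "YxY": 0}, 8300),
        SeasonPlan("2017/18", {"DxD": 12, "DxY": 1, "YxY": 0}, 15000),
    ]
    translocations = {
        2014: {"D": 226},
        2015: {"D": 490},
        2016: {"D": 386, "Y": 27},
        2017: {"D": 672},
    }
    cfg = dict(seasons=seasons, translocations=translocations)
    cfg.update(overrides)
    return SimConfig(**cfg)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------
@dataclass
class TruthLedger:
    """Ground truth for every simulated fish and sample.

    ``individuals`` has one row per fish: origin, parents, birth year,
    cross-type category, true ancestry fraction ``q_true`` (fraction of the
    genome from source D), sex, and ``death_age`` — the last integer age the
    fish was alive at, so alive-at-age indicators are non-increasing by
    construction.  ``sample_map`` links sample ids back to fish ids.
    """

    individuals: pd.DataFrame
    sample_map: pd.DataFrame
    source_freqs: dict

    def alive_at_age(self, fish_id: str, age: int) -> bool:
        d = self.individuals.loc[self.individuals.fish_id == fish_id, "death_age"]
        return bool(len(d)) and age <= int(d.iloc[0])

    def fish_of_sample(self, sample_id: str) -> str:
        m = self.sample_map.loc[self.sample_map.sample_id == sample_id, "fish_id"]
        if not len(m):
            raise KeyError(sample_id)
        return m.iloc[0]


@dataclass
class SimulatedDataset:
    """Bundle of everything a monitoring analysis consumes, plus the truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    pairs: pd.DataFrame
    season_registry: pd.DataFrame
    truth: TruthLedger

    def write_dir(self, path: str | Path) -> list:
        """Write all tables as plain text; returns the paths written."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(name, fn):
            p = path / name
            fn(p)
            written.append(p)

        _w("genotypes.tsv", self.genotypes.to_tsv)
        _w("locus_meta.csv", lambda p: self.genotypes.locus_meta.to_csv(p))
        _w("samples.csv", lambda p: self.samples.to_csv(p, index=False))
        _w("pairs.csv", lambda p: self.pairs.to_csv(p, index=False))
        _w("season_registry.csv",
           lambda p: self.season_registry.to_csv(p, index=False))
        _w("truth_individuals.csv",
           lambda p: self.truth.individuals.to_csv(p, index=False))
        _w("truth_samples.csv",
           lambda p: self.truth.sample_map.to_csv(p, index=False))
        freq = pd.DataFrame(
            {"locus": self.genotypes.loci,
             "freq_D": self.truth.source_freqs["D"],
             "freq_Y": self.truth.source_freqs["Y"]}
        )
        _w("true_source_freqs.csv", lambda p: freq.to_csv(p, index=False))
        _w("config.yaml", self.config.to_yaml)
        return written

    @classmethod
    def load_dir(cls, path: str | Path) -> "SimulatedDataset":
        path = Path(path)
        config = SimConfig.from_yaml(path / "config.yaml")
        meta = pd.read_csv(path / "locus_meta.csv", index_col=0)
        genotypes = GenotypeMatrix.from_tsv(path / "genotypes.tsv", locus_meta=meta)
        freq = pd.read_csv(path / "true_source_freqs.csv")
        truth = TruthLedger(
            individuals=pd.read_csv(path / "truth_individuals.csv"),
            sample_map=pd.read_csv(path / "truth_samples.csv"),
            source_freqs={"D": freq.freq_D.to_numpy(), "Y": freq.freq_Y.to_numpy()},
        )
        return cls(
            config=config,
            genotypes=genotypes,
            samples=pd.read_csv(path / "samples.csv"),
            pairs=pd.read_csv(path / "pairs.csv"),
            season_registry=pd.read_csv(path / "season_registry.csv"),
            truth=truth,
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def largest_remainder(counts, total: int) -> np.ndarray:
    """Apportion ``total`` proportionally to ``counts`` with exact conservation.

    Integer shares are the floors of the proportional quotas; leftover units
    go to the largest fractional remainders (ties broken by position).
    """
    counts = np.asarray(counts, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if counts.sum() <= 0:
        if total > 0:
            raise ValueError("cannot apportion a positive total over zero counts")
        return np.zeros(len(counts), dtype=int)
    quota = counts / counts.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def apply_genotyping_noise(
    true_geno: np.ndarray,
    error_rate: float,
    locus_missing_rate: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observe true genotypes through the error and missingness channel.

    With probability ``error_rate`` a call is replaced by one of the other
    two genotypes uniformly; calls then go missing at per-locus rates.
    """
    g = np.asarray(true_geno, dtype=np.int8).copy()
    err = rng.random(g.shape) < error_rate
    if err.any():
        shift = rng.integers(1, 3, size=int(err.sum()))
        g[err] = (g[err] + shift) % 3
    miss = rng.random(g.shape) < np.broadcast_to(locus_missing_rate, g.shape)
    g[miss] = MISSING
    return g


def _mendelian_draw(gd: np.ndarray, gs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (
        rng.binomial(1, gd / 2.0) + rng.binomial(1, gs / 2.0)
    ).astype(np.int8)


# ---------------------------------------------------------------------------
# stage 1: source populations
# ---------------------------------------------------------------------------
def simulate_sources(
    config: SimConfig, rng: np.random.Generator | None = None
):
    """Draw per-locus source allele frequencies and founder genotype pools.

    Differentiation follows a Balding-Nichols beta model: each source's
    frequency is a beta draw around a common ancestral frequency with
    variance parameter set so the realised mean Weir-Cockerham F_ST between
    the pools lands near ``fst_target`` (two independently diverged pools
    realise a pairwise F_ST of roughly ``F/(1-F/2)``, so the per-pool
    parameter is pre-adjusted accordingly).  The beta tail supplies the
    highly differentiated loci that ancestry assignment relies on.

    Returns ``(founders, freqs)`` where ``founders`` stacks both pools
    (ids ``D###`` then ``Y###``) and ``freqs`` maps source label to the true
    per-locus alternate-allele frequency vector.
    """
    if not 0.0 <= config.fst_target < 0.5:
        raise ValueError("fst_target must be in [0, 0.5)")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.n_loci
    for _attempt in range(10):
        p_anc = rng.uniform(0.1, 0.9, size=L)
        if config.fst_target == 0.0:
            p_d = p_anc.copy()
            p_y = p_anc.copy()
        else:
            f = config.fst_target / (1.0 + config.fst_target / 2.0)
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            p_d = rng.beta(a, b)
            p_y = rng.beta(a, b)
        polymorphic = ((p_d > 0) & (p_d < 1)) | ((p_y > 0) & (p_y < 1))
        if polymorphic.any():
            break
    else:  # pragma: no cover - astronomically unlikely with uniform ancestors
        raise RuntimeError("degenerate frequency draw: all loci monomorphic "
                           "after 10 attempts")

    nf = config.n_founders_per_source
    geno_d = rng.binomial(2, p_d, size=(nf, L)).astype(np.int8)
    geno_y = rng.binomial(2, p_y, size=(nf, L)).astype(np.int8)
    loci = np.array([f"L{i:05d}" for i in range(L)], dtype=object)
    ids = np.array(
        [f"D{i:03d}" for i in range(nf)] + [f"Y{i:03d}" for i in range(nf)],
        dtype=object,
    )
    founders = GenotypeMatrix(
        ids=ids, loci=loci, dosage=np.vstack([geno_d, geno_y]),
        locus_meta=_draw_locus_meta(config, loci, rng),
    )
    return founders, {"D": p_d, "Y": p_y}


def _draw_locus_meta(config, loci, rng) -> pd.DataFrame:
    L = len(loci)
    repro = np.ones(L)
    low = rng.random(L) < config.low_repro_locus_fraction
    repro[low] = rng.uniform(0.90, 0.999, size=int(low.sum()))
    miss = np.full(L, config.missing_rate)
    high = rng.random(L) < config.high_missing_locus_fraction
    miss[high] = config.high_missing_rate
    # a few loci share a sequencing tag with their neighbour, exercising the
    # one-SNP-per-tag QC rule
    tags = [f"T{i:05d}" for i in range(L)]
    shared = np.flatnonzero(rng.random(L) < config.shared_tag_fraction)
    for i in shared:
        if i > 0:
            tags[i] = tags[i - 1]
    return pd.DataFrame(
        {"reproducibility": repro, "missing_rate": miss, "tag": tags},
        index=pd.Index(loci, name="locus"),
    )


# ---------------------------------------------------------------------------
# stage 2: hatchery breeding programme
# ---------------------------------------------------------------------------
def simulate_breeding_program(
    config: SimConfig,
    founders: GenotypeMatrix,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mate broodstock pairs each season and apportion stocked fingerlings.

    Dams and sires are drawn from the founder pools (each founder at most
    once per season; reuse across seasons is allowed, as for real
    broodstock).  A pair's fingerling count is its larvae share of the
    season total, apportioned by largest remainder so season totals are
    conserved exactly.
    """
    nf = config.n_founders_per_source
    sex = {}
    for src in "DY":
        for i in range(nf):
            sex[f"{src}{i:03d}"] = "F" if i % 2 == 0 else "M"
    pools = {
        ("D", "F"): [f"D{i:03d}" for i in range(nf) if i % 2 == 0],
        ("D", "M"): [f"D{i:03d}" for i in range(nf) if i % 2 == 1],
        ("Y", "F"): [f"Y{i:03d}" for i in range(nf) if i % 2 == 0],
        ("Y", "M"): [f"Y{i:03d}" for i in range(nf) if i % 2 == 1],
    }
    rows = []
    for plan in config.seasons:
        used: set = set()
        season_rows = []
        for ct in CROSS_TYPES:
            n_pairs = int(plan.pairs.get(ct, 0))
            for k in range(n_pairs):
                if ct == "DxD":
                    dam_src, sire_src = "D", "D"
                elif ct == "YxY":
                    dam_src, sire_src = "Y", "Y"
                else:
                    dam_src, sire_src = ("D", "Y") if rng.random() < 0.5 else ("Y", "D")
                dam = _draw_parent(pools[(dam_src, "F")], used, rng, plan.season)
                sire = _draw_parent(pools[(sire_src, "M")], used, rng, plan.season)
                shape = 1.0 / config.larvae_cv**2
                larvae = int(round(rng.gamma(shape, plan.mean_larvae / shape)))
                season_rows.append(
                    dict(
                        pair_id=f"P{plan.birth_year}_{len(season_rows):02d}",
                        season=plan.season,
                        birth_year=plan.birth_year,
                        stock_year=plan.stock_year,
                        cross_type=ct,
                        dam_id=dam,
                        sire_id=sire,
                        larvae=larvae,
                        broodstock_sampled=plan.broodstock_sampled,
                    )
                )
        larvae = [r["larvae"] for r in season_rows]
        if season_rows:
            shares = largest_remainder(larvae, plan.stocked)
            for r, s in zip(season_rows, shares):
                r["fingerlings"] = int(s)
        rows.extend(season_rows)
    pairs = pd.DataFrame(rows)
    pairs["dam_sex"] = "F"
    pairs["sire_sex"] = "M"
    return pairs


def _draw_parent(pool, used, rng, season) -> str:
    free = [p for p in pool if p not in used]
    if not free:
        raise ValueError(f"season {season}: founder pool exhausted")
    pick = free[int(rng.integers(len(free)))]
    used.add(pick)
    return pick


# ---------------------------------------------------------------------------
# stage 3: fates, captures and local recruitment
# ---------------------------------------------------------------------------
class _Registry:
    """Columnar fish registry grown in deterministic order."""

    def __init__(self) -> None:
        self.fish_id: list = []
        self.origin: list = []
        self.cross_cat: list = []
        self.q_true: list = []
        self.birth_year: list = []
        self.dam: list = []
        self.sire: list = []
        self.sex: list = []
        self.death_age: list = []
        self.transloc_year: list = []
        self.pair_id: list = []
        self.genotyped: list = []

    def add(self, **kw) -> None:
        for k in vars(self):
            getattr(self, k).append(kw[k])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in vars(self)})


def _draw_death_ages(
    n: int,
    cross: str,
    u_cohort: float,
    surv: SurvivalParams,
    max_years: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Age reached before death, via sequential annual Bernoulli survival."""
    alive = np.ones(n, dtype=bool)
    death = np.full(n, max_years, dtype=int)
    base = surv.intercept + surv.cross_offsets[cross] + u_cohort
    for a in range(max_years):
        p = expit(base + surv.age_slope * a)
        die = alive & (rng.random(n) >= p)
        death[die] = a
        alive &= ~die
        if not alive.any():
            break
    return death


def _cross_cat_from_q(q: float) -> str:
    if q >= 0.75:
        return "DxD"
    if q <= 0.25:
        return "YxY"
    return "DxY"


def simulate_monitoring(
    config: SimConfig,
    founders: GenotypeMatrix,
    freqs: Mapping[str, np.ndarray],
    pairs: pd.DataFrame,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Run fates, captures and recruitment; assemble the full genotyped dataset.

    Stocked fingerlings, translocated fish and locally-born recruits live or
    die year by year under the configured logit survival model; survivors
    are captured during monitoring with age-class-dependent probabilities
    and measured under their cross-type's Gompertz curve.  Genotypes are
    materialised (Mendelian transmission plus observation noise) only for
    fish that end up genotyped: broodstock of sampled seasons, genotyped
    translocated fish, source reference pools, and every monitoring capture
    (recaptures are re-genotyped independently, as real re-sampled fin clips
    would be).
    """
    surv = config.survival
    last_year = max(config.monitoring_years)
    reg = _Registry()

    cohort_u: dict = {}

    def u_of(year: int) -> float:
        if year not in cohort_u:
            cohort_u[year] = float(rng.normal(0.0, surv.year_sd))
        return cohort_u[year]

    # ensure cohort effects are drawn in a fixed order
    years_all = sorted(
        {int(p.birth_year) for p in config.seasons}
        | set(range(min(int(p.birth_year) for p in config.seasons), last_year + 1))
    )
    for y in years_all:
        u_of(y)

    q_founder = {"D": 1.0, "Y": 0.0}

    # ---- stocked fingerlings -------------------------------------------
    for row in pairs.itertuples():
        n = int(row.fingerlings)
        if n == 0:
            continue
        by = int(row.birth_year)
        max_years = max(last_year - by + 1, 1)
        death = _draw_death_ages(n, row.cross_type, u_of(by), surv, max_years, rng)
        qd = q_founder[row.dam_id[0]]
        qs = q_founder[row.sire_id[0]]
        q = 0.5 * (qd + qs)
        sexes = rng.random(n) < 0.5
        for i in range(n):
            reg.add(
                fish_id=f"S{row.pair_id}_{i:05d}",
                origin="stocked",
                cross_cat=row.cross_type,
                q_true=q,
                birth_year=by,
                dam=row.dam_id,
                sire=row.sire_id,
                sex="F" if sexes[i] else "M",
                death_age=int(death[i]),
                transloc_year=np.nan,
                pair_id=row.pair_id,
                genotyped=False,
            )

    # ---- translocated fish ---------------------------------------------
    for year in sorted(config.translocations):
        for src in sorted(config.translocations[year]):
            count = int(config.translocations[year][src])
            if count == 0:
                continue
            ages = rng.integers(1, 3, size=count)  # wild-caught juveniles
            n_geno = int(round(count * config.translocated_genotyped_fraction))
            geno_mask = np.zeros(count, dtype=bool)
            geno_mask[rng.choice(count, size=n_geno, replace=False)] = True
            cross = "DxD" if src == "D" else "YxY"
            for i in range(count):
                by = year - int(ages[i])
                max_years = max(last_year - by + 1, 1)
                death = _draw_death_ages(1, cross, u_of(by), surv, max_years, rng)[0]
                reg.add(
                    fish_id=f"T{year}{src}_{i:04d}",
                    origin="translocated",
                    cross_cat=cross,
                    q_true=q_founder[src],
                    birth_year=by,
                    dam=None,
                    sire=None,
                    sex="F" if rng.random() < 0.5 else "M",
                    death_age=int(death),
                    transloc_year=year,
                    pair_id=None,
                    genotyped=bool(geno_mask[i]),
                )

    # ---- local recruitment ---------------------------------------------
    frame = reg.frame()
    first_spawn = int(frame.birth_year.min()) + config.maturity_age
    for y in range(first_spawn, last_year):
        frame = reg.frame()
        age_at_spawn = y - frame.birth_year
        present = (
            (age_at_spawn >= config.maturity_age)
            & (frame.death_age >= age_at_spawn)
            & (frame.transloc_year.isna() | (frame.transloc_year <= y))
        )
        mature = frame[present]
        dams = mature[mature.sex == "F"]
        sires = mature[mature.sex == "M"]
        if dams.empty or sires.empty:
            continue
        n_rec = int(rng.poisson(config.recruitment_rate * len(mature)))
        if n_rec == 0:
            continue
        dam_pick = dams.iloc[rng.integers(len(dams), size=n_rec)]
        sire_pick = sires.iloc[rng.integers(len(sires), size=n_rec)]
        q_rec = 0.5 * (dam_pick.q_true.to_numpy() + sire_pick.q_true.to_numpy())
        max_years = max(last_year - y + 1, 1)
        sexes = rng.random(n_rec) < 0.5
        for i in range(n_rec):
            cross = _cross_cat_from_q(q_rec[i])
            death = _draw_death_ages(1, cross, u_of(y), surv, max_years, rng)[0]
            reg.add(
                fish_id=f"L{y}_{i:05d}",
                origin="locally_born",
                cross_cat=cross,
                q_true=float(q_rec[i]),
                birth_year=y,
                dam=dam_pick.fish_id.iloc[i],
                sire=sire_pick.fish_id.iloc[i],
                sex="F" if sexes[i] else "M",
                death_age=int(death),
                transloc_year=np.nan,
                pair_id=None,
                genotyped=False,
            )

    frame = reg.frame()

    # ---- monitoring captures -------------------------------------------
    probs = np.asarray(config.capture_prob_by_age, dtype=float)
    captures = []
    for y in config.monitoring_years:
        age_frac = y - frame.birth_year.to_numpy() - CAPTURE_SEASON_OFFSET
        present = (
            (age_frac >= 0)
            & (frame.death_age.to_numpy() >= np.ceil(age_frac).astype(int))
            & (frame.transloc_year.isna().to_numpy()
               | (frame.transloc_year.to_numpy() < y))
        )
        age_class = np.clip(np.floor(age_frac), 0, len(probs) - 1).astype(int)
        p = np.where(present, probs[age_class], 0.0)
        caught = rng.random(len(frame)) < p
        for idx in np.flatnonzero(caught):
            fish = frame.iloc[idx]
            gp = config.gompertz[fish.cross_cat]
            length = float(gp.length_at(age_frac[idx]) + rng.normal(0.0, gp.sigma))
            captures.append(
                dict(
                    fish_id=fish.fish_id,
                    capture_year=int(y),
                    age_frac=float(age_frac[idx]),
                    length_mm=round(max(length, 5.0), 1),
                )
            )
    captures = pd.DataFrame(
        captures, columns=["fish_id", "capture_year", "age_frac", "length_mm"]
    )

    # ---- genotyped sample assembly -------------------------------------
    dataset = _assemble_samples(config, founders, freqs, pairs, frame, captures, rng)
    return dataset


def _assemble_samples(config, founders, freqs, pairs, frame, captures, rng):
    locus_meta = founders.locus_meta
    locus_missing = locus_meta["missing_rate"].to_numpy()
    e = config.genotyping_error_rate
    L = config.n_loci

    true_cache: dict = {}
    founder_ids = list(founders.ids)
    for i, fid in enumerate(founder_ids):
        true_cache[fid] = founders.dosage[i]
    parent_of = dict(zip(frame.fish_id, zip(frame.dam, frame.sire)))
    origin_of = dict(zip(frame.fish_id, frame.origin))
    q_of = dict(zip(frame.fish_id, frame.q_true))

    def true_geno(fid: str) -> np.ndarray:
        cached = true_cache.get(fid)
        if cached is not None:
            return cached
        dam, sire = parent_of[fid]
        if dam is None:  # wild-caught translocated fish: fresh HWE draw
            src = "D" if q_of[fid] >= 0.5 else "Y"
            g = rng.binomial(2, freqs[src], size=L).astype(np.int8)
        else:
            g = _mendelian_draw(true_geno(dam), true_geno(sire), rng)
        true_cache[fid] = g
        return g

    sample_ids: list = []
    sample_rows: list = []
    observed: list = []
    map_rows: list = []

    def add_sample(sample_id, fid, role, **meta):
        g = apply_genotyping_noise(true_geno(fid), e, locus_missing, rng)
        sample_ids.append(sample_id)
        observed.append(g)
        sample_rows.append(dict(sample_id=sample_id, role=role, **meta))
        map_rows.append(dict(sample_id=sample_id, fish_id=fid))

    # broodstock of genetically sampled seasons (each fish genotyped once)
    sampled_brood = sorted(
        set(pairs.loc[pairs.broodstock_sampled, "dam_id"])
        | set(pairs.loc[pairs.broodstock_sampled, "sire_id"])
    )
    for fid in sampled_brood:
        add_sample(
            f"B_{fid}", fid, "broodstock",
            source_label=fid[0], sex="F" if int(fid[1:]) % 2 == 0 else "M",
            capture_year=np.nan, length_mm=np.nan,
        )

    # genotyped translocated fish
    for fid in frame.loc[
        (frame.origin == "translocated") & frame.genotyped, "fish_id"
    ]:
        src = "D" if q_of[fid] >= 0.5 else "Y"
        add_sample(
            f"T_{fid}", fid, "translocated",
            source_label=src, sex=np.nan, capture_year=np.nan, length_mm=np.nan,
        )

    # reference pools: wild fish from each source, never broodstock
    for src in "DY":
        for i in range(config.n_reference_per_source):
            fid = f"R{src}{i:03d}"
            true_cache[fid] = rng.binomial(2, freqs[src], size=L).astype(np.int8)
            add_sample(
                f"R{src}{i:03d}", fid, "reference",
                source_label=src, sex=np.nan, capture_year=np.nan, length_mm=np.nan,
            )

    # monitoring captures (recaptures re-genotyped independently)
    for k, cap in enumerate(captures.itertuples()):
        add_sample(
            f"M{cap.capture_year}_{k:04d}", cap.fish_id, "monitoring",
            source_label=np.nan, sex=np.nan,
            capture_year=int(cap.capture_year), length_mm=cap.length_mm,
        )

    genotypes = GenotypeMatrix(
        ids=np.array(sample_ids, dtype=object),
        loci=founders.loci.copy(),
        dosage=np.vstack(observed) if observed else np.empty((0, L), dtype=np.int8),
        locus_meta=locus_meta.copy(),
    )
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "role", "source_label", "sex", "capture_year",
                 "length_mm"],
    )

    # truth: founders + reference fish join the per-fish ledger
    founder_truth = pd.DataFrame(
        dict(
            fish_id=founder_ids,
            origin="founder",
            cross_cat=[("DxD" if f[0] == "D" else "YxY") for f in founder_ids],
            q_true=[1.0 if f[0] == "D" else 0.0 for f in founder_ids],
            birth_year=np.nan,
            dam=None,
            sire=None,
            sex=["F" if int(f[1:]) % 2 == 0 else "M" for f in founder_ids],
            death_age=np.nan,
            transloc_year=np.nan,
            pair_id=None,
            genotyped=[f in sampled_brood for f in founder_ids],
        )
    )
    ref_ids = [f"R{s}{i:03d}" for s in "DY"
               for i in range(config.n_reference_per_source)]
    ref_truth = pd.DataFrame(
        dict(
            fish_id=ref_ids,
            origin="reference",
            cross_cat=[("DxD" if f[1] == "D" else "YxY") for f in ref_ids],
            q_true=[1.0 if f[1] == "D" else 0.0 for f in ref_ids],
            birth_year=np.nan, dam=None, sire=None, sex=np.nan,
            death_age=np.nan, transloc_year=np.nan, pair_id=None, genotyped=True,
        )
    )
    individuals = pd.concat([frame, founder_truth, ref_truth], ignore_index=True)
    individuals = individuals.merge(
        captures.groupby("fish_id")
        .agg(n_captures=("capture_year", "size"))
        .reset_index(),
        how="left", on="fish_id",
    )
    individuals["n_captures"] = individuals["n_captures"].fillna(0).astype(int)

    truth = TruthLedger(
        individuals=individuals,
        sample_map=pd.DataFrame(map_rows, columns=["sample_id", "fish_id"]),
        source_freqs=dict(freqs),
    )

    registry = _season_registry(config, pairs)
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        samples=samples,
        pairs=pairs,
        season_registry=registry,
        truth=truth,
    )


def _season_registry(config: SimConfig, pairs: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for plan in config.seasons:
        sub = pairs[pairs.season == plan.season]
        trans = config.translocations.get(plan.stock_year, {})
        n_trans = sum(trans.values())
        n_geno = int(round(n_trans * config.translocated_genotyped_fraction))
        rows.append(
            dict(
                season=plan.season,
                birth_year=plan.birth_year,
                stock_year=plan.stock_year,
                n_pairs=len(sub),
                larvae_total=int(sub.larvae.sum()),
                stocked=plan.stocked,
                transloc_D=int(trans.get("D", 0)),
                transloc_Y=int(trans.get("Y", 0)),
                transloc_ungenotyped=n_trans - n_geno,
                broodstock_sampled=plan.broodstock_sampled,
            )
        )
    # translocation-only years without a breeding season
    season_years = {p.stock_year for p in config.seasons}
    for year in sorted(set(config.translocations) - season_years):
        trans = config.translocations[year]
        n_trans = sum(trans.values())
        n_geno = int(round(n_trans * config.translocated_genotyped_fraction))
        rows.append(
            dict(
                season=f"{year - 1}/{str(year)[-2:]}", birth_year=year - 1,
                stock_year=year, n_pairs=0, larvae_total=0, stocked=0,
                transloc_D=int(trans.get("D", 0)),
                transloc_Y=int(trans.get("Y", 0)),
                transloc_ungenotyped=n_trans - n_geno,
                broodstock_sampled=True,
            )
        )
    return pd.DataFrame(rows).sort_values("stock_year").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------
def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate a complete synthetic monitoring dataset from one seed."""
    config = default_config() if config is None else config
    rng = np.random.default_rng(config.seed)
    founders, freqs = simulate_sources(config, rng)
    pairs = simulate_breeding_program(config, founders, rng)
    return simulate_monitoring(config, founders, freqs, pairs, rng)
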