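"""Per-fish origin calls: stocked, translocated, or locally born.

Composes the upstream evidence — identity matching (recaptures and matches
to translocated samples), parent-pair assignment, ancestry category, and
age — under a fixed precedence: an identity match to a translocated sample
wins, then a parent-pair assignment (stocked), and everything else is
locally born.  Birth seasons come from the assigned pair's mating season
for stocked fish (hatching fixed at 1 December) and from inverting the
fitted growth curve for everyone else.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness_models import GompertzFit, age_from_length

#: Fraction of a year from 1 December hatching to the autumn capture window.
CAPTURE_OFFSET = 2.0 / 3.0
MAX_AGE_CLASS = 5


class OriginConflictError(RuntimeError):
    """A fish matched a translocated sample AND was assigned broodstock parents."""


def age_at_capture(capture_year: int, birth_year: int) -> float:
    """Fractional age of a fish born 1 Dec ``birth_year`` at an autumn capture."""
    return capture_year - birth_year - CAPTURE_OFFSET


def assign_birth_and_age(
    capture_year: int,
    pair_birth_year: int | None = None,
    length_mm: float | None = None,
    growth: GompertzFit | None = None,
) -> dict:
    """Birth year, fractional age and age class for one capture.

    Stocked fish (``pair_birth_year`` given): age is straight date
    arithmetic from the mating season's 1 December hatch date, truncated to
    an integer age class.  Non-stocked fish: age is the rounded Gompertz
    inverse of length and the birth year is back-calculated; lengths at or
    above the asymptote cannot be inverted and are flagged for review.
    """
    if pair_birth_year is not None:
        t = age_at_capture(capture_year, int(pair_birth_year))
        return dict(
            birth_year=int(pair_birth_year), age_frac=t,
            age_class=int(min(np.floor(t), MAX_AGE_CLASS)), age_flag=None,
        )
    if length_mm is None or growth is None:
        raise ValueError("non-stocked fish need a length and a growth model")
    try:
        t = age_from_length(float(length_mm), growth)
    except ValueError:
        return dict(birth_year=None, age_frac=np.nan, age_class=None,
                    age_flag="length_outside_growth_model")
    birth_year = int(round(capture_year - CAPTURE_OFFSET - t))
    t_cal = age_at_capture(capture_year, birth_year)
    return dict(
        birth_year=birth_year, age_frac=t_cal,
        age_class=int(np.clip(np.floor(t_cal), 0, MAX_AGE_CLASS)),
        age_flag=None,
    )


def infer_origin(
    monitoring: pd.DataFrame,
    duplicate_groups: pd.DataFrame,
    assignments: pd.DataFrame,
    translocated_samples: set,
    ancestry: pd.DataFrame,
    pairs: pd.DataFrame,
    season_registry: pd.DataFrame,
    growth: GompertzFit | None,
) -> pd.DataFrame:
    """One OriginCall per unique monitored fish.

    ``monitoring`` has one row per monitoring sample (``sample_id``,
    ``capture_year``, ``length_mm``); ``duplicate_groups`` is the identity
    module's output over *all* samples, so a group joining a monitoring
    sample to a member of ``translocated_samples`` identifies a
    translocated fish.  Precedence: translocated identity match > parent
    pair > locally born.  A fish with both a translocated match and
    assigned broodstock parents is impossible under the release registry
    and raises :class:`OriginConflictError`.

    Flags: locally born fish whose inferred birth season had unsampled
    broodstock parents are marked ``possible_unsampled_broodstock_offspring``;
    locally born source-D fish age-compatible with ungenotyped translocated
    cohorts get ``possible_ungenotyped_translocate``; recaptured fish carry
    ``recapture``.
    """
    sample_to_group = dict(zip(duplicate_groups.sample_id, duplicate_groups.group_id))
    group_members: dict = {}
    for sid, gid in sample_to_group.items():
        group_members.setdefault(gid, []).append(sid)

    # collapse monitoring samples into unique individuals
    individuals: dict = {}
    for row in monitoring.itertuples():
        gid = sample_to_group.get(row.sample_id)
        key = gid if gid is not None else row.sample_id
        individuals.setdefault(key, []).append(row)

    assigned_pair = dict(
        zip(
            assignments.loc[assignments.status == "assigned", "offspring_id"],
            assignments.loc[assignments.status == "assigned", "pair_id"],
        )
    )
    pair_birth = dict(zip(pairs.pair_id, pairs.birth_year))
    ancestry_cat = dict(zip(ancestry["id"], ancestry["category"]))
    ancestry_q = dict(zip(ancestry["id"], ancestry["q_d"]))

    unsampled_birth_years = set(
        season_registry.loc[~season_registry.broodstock_sampled.astype(bool),
                            "birth_year"].astype(int)
    )
    ungeno_transloc_years = set(
        season_registry.loc[season_registry.transloc_ungenotyped > 0,
                            "stock_year"].astype(int)
    )

    calls = []
    for key, caps in individuals.items():
        caps = sorted(caps, key=lambda r: (r.capture_year, r.sample_id))
        rep = caps[0]
        sample_ids = [c.sample_id for c in caps]
        gid = sample_to_group.get(rep.sample_id)
        matched_transloc = bool(gid) and any(
            s in translocated_samples for s in group_members.get(gid, [])
        )
        pair_id = next(
            (assigned_pair[s] for s in sample_ids if s in assigned_pair), None
        )
        if matched_transloc and pair_id is not None:
            raise OriginConflictError(
                f"fish {rep.sample_id}: identity-matched to a translocated "
                f"sample but also assigned broodstock pair {pair_id}"
            )
        if matched_transloc:
            origin = "translocated"
        elif pair_id is not None:
            origin = "stocked"
        else:
            origin = "locally_born"

        age = assign_birth_and_age(
            int(rep.capture_year),
            pair_birth_year=pair_birth.get(pair_id) if pair_id else None,
            length_mm=rep.length_mm,
            growth=growth,
        )
        cat = next((ancestry_cat[s] for s in sample_ids if s in ancestry_cat), None)
        q = next((ancestry_q[s] for s in sample_ids if s in ancestry_q), np.nan)

        flags = []
        if len(caps) > 1:
            flags.append("recapture")
        if age["age_flag"]:
            flags.append(age["age_flag"])
        if origin == "locally_born" and age["birth_year"] in unsampled_birth_years:
            flags.append("possible_unsampled_broodstock_offspring")
        if (
            origin == "locally_born"
            and cat == "sourceD"
            and age["birth_year"] is not None
            and any(
                ty - 3 <= age["birth_year"] <= ty - 1
                for ty in ungeno_transloc_years
            )
        ):
            flags.append("possible_ungenotyped_translocate")

        calls.append(
            dict(
                individual_id=rep.sample_id,
                origin=origin,
                pair_id=pair_id,
                ancestry_category=cat,
                q_d=q,
                birth_year=age["birth_year"],
                age_frac=age["age_frac"],
                age_class=age["age_class"],
                first_capture_year=int(rep.capture_year),
                capture_years=";".join(str(int(c.capture_year)) for c in caps),
                n_captures=len(caps),
                sample_ids=";".join(sample_ids),
                flags=";".join(flags),
            )
        )
    out = pd.DataFrame(calls)
    if len(out):
        assert out.individual_id.is_unique
    return out


def capture_age_table(origin_calls: pd.DataFrame) -> pd.DataFrame:
    """Long table of (individual, pair, age class) per capture of stocked fish.

    Feeds the minimum-survivor reconstruction: each capture of an assigned
    offspring contributes its age class (the carry-back maximum is taken
    downstream).
    """
    rows = []
    for row in origin_calls.itertuples():
        if row.origin != "stocked" or row.pair_id is None:
            continue
        for y in str(row.capture_years).split(";"):
            t = age_at_capture(int(y), int(row.birth_year))
            rows.append(
                dict(
                    individual_id=row.individual_id,
                    pair_id=row.pair_id,
                    age_class=int(min(np.floor(t), MAX_AGE_CLASS)),
                )
            )
    return pd.DataFrame(rows, columns=["individual_id", "pair_id", "age_class"])
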