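"""Likelihood-constraint engine: sign and filter TF-region-gene triples.

For a positive regulation the *perfect* gene level in each population is
``max(1, f - (4 - r))`` given the TF level ``f`` and region level ``r``;
a negative regulation mirrors it through ``5 - g``.  Observed triples may
deviate from the perfect situation per population; how many and which
deviations are tolerated is controlled by a :class:`DeviationPolicy`.

Two interchangeable evaluators are provided: a direct equation evaluator
and a frozen table-driven one (the per-cell status grids hard-coded below).
They must agree cell-for-cell; the test suite asserts this exhaustively.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from signet.discretize import is_constant, is_silent, pattern_levels
from signet.graph import CandidateTriple

POSITIVE = "+"
NEGATIVE = "-"
UNDETERMINED = "ND"

# per-cell statuses
PERFECT = "perfect"            # dark blue: observed == perfect level
RELAXED = "relaxed"            # light blue: off by one, region bound holds
REGION_VIOLATING = "region_violating"  # grey: off by one, region bound fails
FAIL = "fail"                  # white: off by more than one


class DeviationPolicy(str, enum.Enum):
    """Which per-population departures from the perfect triple are tolerated."""

    delta0 = "delta0"
    delta1 = "delta1"
    delta1_regOFF = "delta1_regOFF"
    delta2 = "delta2"


def perfect_gene_level(f_level: int, r_level: int, sign: str) -> int:
    """Gene level forced by a perfect regulation given TF and region levels."""
    for lev in (f_level, r_level):
        if lev not in (1, 2, 3, 4):
            raise ValueError(f"level {lev} outside the variable domain 1..4")
    pos = max(1, f_level - (4 - r_level))
    if sign == POSITIVE:
        return pos
    if sign == NEGATIVE:
        return 5 - pos
    raise ValueError(f"invalid sign {sign!r}")


def cell_status(f: int, r: int, g: int, sign: str) -> str:
    """Status of one population cell, from the equations."""
    if g not in (1, 2, 3, 4):
        raise ValueError(f"gene level {g} outside the variable domain 1..4")
    if sign == NEGATIVE:
        g = 5 - g
        sign = POSITIVE
    l = perfect_gene_level(f, r, POSITIVE)
    if g == l:
        return PERFECT
    if abs(g - l) == 1:
        bound = max(1, f - (4 - r) + 2)
        return RELAXED if g <= bound else REGION_VIOLATING
    return FAIL


# ---------------------------------------------------------------------------
# Frozen status grids.  Key: (sign, region level, TF level); value: statuses
# for gene levels 1..4 encoded P/R/G/W (perfect / relaxed / region-violating
# / fail).  Transcribed once from the threshold tables and never recomputed
# at run time, so the table route is independent of the equations above.

_STATUS_CODE = {"P": PERFECT, "R": RELAXED, "G": REGION_VIOLATING, "W": FAIL}

STATUS_TABLE: dict[tuple[str, int, int], str] = {
    ("+", 4, 1): "PRWW",
    ("+", 4, 2): "RPRW",
    ("+", 4, 3): "WRPR",
    ("+", 4, 4): "WWRP",
    ("+", 3, 1): "PRWW",
    ("+", 3, 2): "PRWW",
    ("+", 3, 3): "RPRW",
    ("+", 3, 4): "WRPR",
    ("+", 2, 1): "PGWW",
    ("+", 2, 2): "PRWW",
    ("+", 2, 3): "PRWW",
    ("+", 2, 4): "RPRW",
    ("+", 1, 1): "PGWW",
    ("+", 1, 2): "PGWW",
    ("+", 1, 3): "PRWW",
    ("+", 1, 4): "PRWW",
    ("-", 4, 1): "WWRP",
    ("-", 4, 2): "WRPR",
    ("-", 4, 3): "RPRW",
    ("-", 4, 4): "PRWW",
    ("-", 3, 1): "WWRP",
    ("-", 3, 2): "WWRP",
    ("-", 3, 3): "WRPR",
    ("-", 3, 4): "RPRW",
    ("-", 2, 1): "WWGP",
    ("-", 2, 2): "WWRP",
    ("-", 2, 3): "WWRP",
    ("-", 2, 4): "WRPR",
    ("-", 1, 1): "WWGP",
    ("-", 1, 2): "WWGP",
    ("-", 1, 3): "WWRP",
    ("-", 1, 4): "WWRP",
}


def cell_status_from_table(f: int, r: int, g: int, sign: str) -> str:
    return _STATUS_CODE[STATUS_TABLE[(sign, r, f)][g - 1]]


def _admits(statuses: Sequence[str], policy: DeviationPolicy) -> bool:
    """Cell-count admission rule for one sign.

    delta0: every cell perfect.
    delta1: at most one relaxed cell, the rest perfect.
    delta1_regOFF: at most one relaxed *or* region-violating cell, rest perfect.
    delta2: at most two relaxed cells (rest perfect), or one cell failing
    outright / violating the region bound with every other cell perfect.
    """
    c = Counter(statuses)
    n_relaxed = c[RELAXED]
    n_grey = c[REGION_VIOLATING]
    n_white = c[FAIL]
    if policy is DeviationPolicy.delta0:
        return n_relaxed == n_grey == n_white == 0
    if policy is DeviationPolicy.delta1:
        return n_grey == n_white == 0 and n_relaxed <= 1
    if policy is DeviationPolicy.delta1_regOFF:
        return n_white == 0 and n_relaxed + n_grey <= 1
    if policy is DeviationPolicy.delta2:
        return (n_grey == n_white == 0 and n_relaxed <= 2) or (
            n_relaxed == 0 and n_grey + n_white <= 1
        )
    raise ValueError(f"unknown policy {policy!r}")


_SUM_DELTA = {
    DeviationPolicy.delta0: 0,
    DeviationPolicy.delta1: 1,
    DeviationPolicy.delta1_regOFF: 1,
    DeviationPolicy.delta2: 2,
}


def _admits_sum(f: Sequence[int], r: Sequence[int], g: Sequence[int],
                sign: str, policy: DeviationPolicy) -> bool:
    # documented alternative: summed deviation from the perfect levels,
    # with the per-cell region bound kept unless the policy disables it
    if sign == NEGATIVE:
        g = [5 - x for x in g]
        sign = POSITIVE
    perfect = [perfect_gene_level(fi, ri, POSITIVE) for fi, ri in zip(f, r)]
    if sum(abs(gi - li) for gi, li in zip(g, perfect)) > _SUM_DELTA[policy]:
        return False
    if policy is DeviationPolicy.delta1_regOFF:
        return True
    return all(
        gi <= max(1, fi - (4 - ri) + 2) for fi, ri, gi in zip(f, r, g)
    )


def evaluate_triple(
    tf_pattern: str,
    region_pattern: str,
    gene_pattern: str,
    policy: DeviationPolicy | str = DeviationPolicy.delta1,
    use_table: bool = False,
    mode: str = "cells",
) -> frozenset[str]:
    """Signs admitted for one (TF, region, gene) pattern triple.

    Returns a subset of ``{"+", "-"}``, or ``{"ND"}`` for triples where all
    three entities are constant (their relation direction cannot be
    qualified).  ``mode="sum"`` switches to the summed-deviation variant.
    """
    policy = DeviationPolicy(policy)
    if not (len(tf_pattern) == len(region_pattern) == len(gene_pattern)):
        raise ValueError("pattern length mismatch")
    pats = (tf_pattern, region_pattern, gene_pattern)
    if any(is_silent(p) for p in pats):
        raise ValueError("silent (all-0) patterns cannot enter constraint evaluation")
    n_const = sum(is_constant(p) for p in pats)
    if n_const == 3:
        return frozenset({UNDETERMINED})
    if n_const:
        raise ValueError("mixed constant/variable triples cannot occur by construction")
    f = pattern_levels(tf_pattern)
    r = pattern_levels(region_pattern)
    g = pattern_levels(gene_pattern)
    admitted = set()
    for sign in (POSITIVE, NEGATIVE):
        if mode == "sum":
            ok = _admits_sum(f, r, g, sign, policy)
        elif mode == "cells":
            status_fn = cell_status_from_table if use_table else cell_status
            statuses = [status_fn(fi, ri, gi, sign) for fi, ri, gi in zip(f, r, g)]
            ok = _admits(statuses, policy)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if ok:
            admitted.add(sign)
    return frozenset(admitted)


# ---------------------------------------------------------------------------
# pipeline-facing records


@dataclass(frozen=True, order=True)
class SignedTriple:
    tf_id: str
    region_id: str
    gene_id: str
    sign: str
    tf_pattern: str
    region_pattern: str
    gene_pattern: str
    distance: int


@dataclass(frozen=True)
class SignedRelation:
    """Unique TF-gene relation merged over its supporting regions."""

    tf_id: str
    gene_id: str
    sign: str
    regions: tuple[str, ...]
    tf_pattern: str
    gene_pattern: str
    conflicting: bool = False


def filter_and_sign(
    triples: Iterable[CandidateTriple],
    policy: DeviationPolicy | str = DeviationPolicy.delta1,
    mode: str = "cells",
) -> list[SignedTriple]:
    """Keep candidate triples admitted under ``policy``, one record per sign.

    Triples involving a silent pattern are dropped (silent entities carry
    no regulatory information); all-constant triples survive with sign ND.
    """
    policy = DeviationPolicy(policy)
    out: list[SignedTriple] = []
    for t in triples:
        pats = (t.tf_pattern, t.region_pattern, t.gene_pattern)
        if any(is_silent(p) for p in pats):
            continue
        if any(is_constant(p) for p in pats) and not all(is_constant(p) for p in pats):
            continue
        for sign in sorted(evaluate_triple(*pats, policy=policy, mode=mode)):
            out.append(
                SignedTriple(
                    t.tf_id, t.region_id, t.gene_id, sign,
                    t.tf_pattern, t.region_pattern, t.gene_pattern, t.distance,
                )
            )
    out.sort()
    return out


def merge_to_tf_gene(signed: Iterable[SignedTriple]) -> list[SignedRelation]:
    """Merge signed TF-region-gene records into unique TF-gene relations.

    Identical (tf, gene, sign) records found through different regions are
    regrouped into one relation listing its supporting regions.  A pair
    admitted with opposite signs through different regions yields two
    records, both flagged ``conflicting``.
    """
    groups: dict[tuple[str, str, str], list[SignedTriple]] = defaultdict(list)
    for rec in signed:
        groups[(rec.tf_id, rec.gene_id, rec.sign)].append(rec)
    signs_by_pair: dict[tuple[str, str], set[str]] = defaultdict(set)
    for tf, gene, sign in groups:
        signs_by_pair[(tf, gene)].add(sign)
    out = []
    for (tf, gene, sign), recs in sorted(groups.items()):
        conflict = {POSITIVE, NEGATIVE} <= signs_by_pair[(tf, gene)]
        out.append(
            SignedRelation(
                tf_id=tf,
                gene_id=gene,
                sign=sign,
                regions=tuple(sorted({r.region_id for r in recs})),
                tf_pattern=recs[0].tf_pattern,
                gene_pattern=recs[0].gene_pattern,
                conflicting=conflict,
            )
        )
    return out
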