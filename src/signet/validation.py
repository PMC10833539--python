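"""Compare an inferred network against curated TF-gene relation tables.

Three checks: which curated relations are reachable given the input
universe, binomial enrichment of curated relations in the inferred
network, and sign concordance among the relations found in both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from signet.constraints import NEGATIVE, POSITIVE, SignedRelation


@dataclass(frozen=True)
class CuratedRelation:
    tf_id: str
    gene_id: str
    sign: str  # "+", "-", or "unknown"


def normalize_symbol(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    s = symbol.strip().upper()
    if aliases:
        s = aliases.get(s, s)
    return s


def reachable_relations(
    db: Iterable[CuratedRelation],
    universe_tfs: Iterable[str],
    universe_genes: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> list[CuratedRelation]:
    """Curated relations whose TF and gene both exist in the input universe."""
    tfs = {normalize_symbol(t, aliases) for t in universe_tfs}
    genes = {normalize_symbol(g, aliases) for g in universe_genes}
    out = []
    for rel in db:
        tf = normalize_symbol(rel.tf_id, aliases)
        gene = normalize_symbol(rel.gene_id, aliases)
        if tf in tfs and gene in genes:
            out.append(CuratedRelation(tf, gene, rel.sign))
    return out


def enrichment_pvalue(
    found: int, reachable: int, network_size: int, universe_size: int
) -> float:
    """Upper-tail binomial p-value for curated-relation enrichment.

    Null: each of the ``reachable`` curated relations lands in the network
    independently with probability network_size / universe_size;
    p = P(X >= found) with X ~ Binomial(reachable, rate).
    """
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= found <= reachable):
        raise ValueError("need 0 <= found <= reachable")
    if not (0 <= network_size <= universe_size):
        raise ValueError("need network_size <= universe_size")
    rate = network_size / universe_size
    if found == 0:
        return 1.0
    return float(stats.binom.sf(found - 1, reachable, rate))


def sign_concordance(
    inferred: Sequence[SignedRelation],
    db: Sequence[CuratedRelation],
    aliases: Mapping[str, str] | None = None,
) -> dict[str, float | int]:
    """Sign agreement over the inferred-intersect-curated pairs.

    Curated pairs that are unsigned, or carry both signs, count as
    ``unknown``; among the sign-determined rest, ``true_pct`` is the
    percentage where the inferred sign matches.
    """
    db_signs: dict[tuple[str, str], set[str]] = {}
    for rel in db:
        key = (normalize_symbol(rel.tf_id, aliases), normalize_symbol(rel.gene_id, aliases))
        db_signs.setdefault(key, set()).add(rel.sign)
    inferred_signs: dict[tuple[str, str], set[str]] = {}
    for rel in inferred:
        key = (normalize_symbol(rel.tf_id, aliases), normalize_symbol(rel.gene_id, aliases))
        inferred_signs.setdefault(key, set()).add(rel.sign)

    same = different = unknown = 0
    for key, inf_signs in inferred_signs.items():
        if key not in db_signs:
            continue
        determined = db_signs[key] & {POSITIVE, NEGATIVE}
        if len(determined) != 1:
            unknown += 1
            continue
        (db_sign,) = determined
        if db_sign in inf_signs:
            same += 1
        else:
            different += 1
    decided = same + different
    return {
        "true_pct": 100.0 * same / decided if decided else float("nan"),
        "unknown_count": unknown,
        "different_count": different,
        "same_count": same,
    }
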