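"""Key-regulator selection by coverage/specificity, plus annotation scores.

Coverage of a TF for a gene pattern = percentage of the pattern's genes
that are targets of the TF.  Specificity = percentage of the TF's targets
that belong to the pattern.  A TF is a key regulator of a pattern when
both metrics pass a user-chosen threshold policy.  An annotation-based
score built from local GO/citation tables supports the final short-list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from signet.constraints import SignedRelation

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdPolicy:
    """mean_sd: mean + 1 sd of each metric distribution.
    quantile: the q-th quantile (inclusive, linear interpolation).
    fixed: explicit coverage/specificity percentages.
    Ties at the threshold are kept (>=)."""

    kind: str  # mean_sd | quantile | fixed
    q: float | None = None
    coverage: float | None = None
    specificity: float | None = None

    def cutoffs(self, metrics: pd.DataFrame) -> tuple[float, float]:
        if self.kind == "fixed":
            if self.coverage is None or self.specificity is None:
                raise ValueError("fixed policy requires both cutoffs")
            return self.coverage, self.specificity
        cov = metrics["coverage"].to_numpy(dtype=float)
        spe = metrics["specificity"].to_numpy(dtype=float)
        if self.kind == "mean_sd":
            return (
                float(cov.mean() + cov.std(ddof=1)) if cov.size > 1 else float(cov.mean()),
                float(spe.mean() + spe.std(ddof=1)) if spe.size > 1 else float(spe.mean()),
            )
        if self.kind == "quantile":
            if self.q is None:
                raise ValueError("quantile policy requires q")
            return float(np.quantile(cov, self.q)), float(np.quantile(spe, self.q))
        raise ValueError(f"unknown threshold policy {self.kind!r}")


LAST_QUARTILE = ThresholdPolicy(kind="quantile", q=0.75)


def _target_map(
    relations: Iterable[SignedRelation], sign: str | None = None
) -> dict[str, set[str]]:
    targets: dict[str, set[str]] = {}
    for rel in relations:
        if sign is not None and rel.sign != sign:
            continue
        targets.setdefault(rel.tf_id, set()).add(rel.gene_id)
    return targets


def coverage(
    tf: str,
    pattern: str,
    relations: Iterable[SignedRelation],
    genes_by_pattern: Mapping[str, set[str]],
) -> float:
    """Percent of the pattern's genes targeted by ``tf``.

    Beware small patterns: a 1-gene pattern is trivially fully covered.
    """
    genes = genes_by_pattern.get(pattern, set())
    if not genes:
        raise UndefinedMetricError(f"pattern {pattern!r} has no genes")
    targets = _target_map(relations).get(tf, set())
    return 100.0 * len(targets & set(genes)) / len(genes)


def specificity(
    tf: str,
    pattern: str,
    relations: Iterable[SignedRelation],
    gene_patterns: Mapping[str, str],
) -> float:
    """Percent of ``tf``'s targets that belong to ``pattern``."""
    targets = _target_map(relations).get(tf, set())
    if not targets:
        raise UndefinedMetricError(f"TF {tf!r} has no targets")
    in_pattern = sum(1 for g in targets if gene_patterns.get(g) == pattern)
    return 100.0 * in_pattern / len(targets)


def regulator_metrics(
    relations: Sequence[SignedRelation],
    gene_patterns: Mapping[str, str],
    per_sign: bool = False,
) -> pd.DataFrame:
    """Coverage/specificity for every (tf, pattern[, sign]) with >=1 target.

    Both signs are pooled by default; ``per_sign=True`` computes the
    metrics within each sign separately.
    """
    genes_by_pattern: dict[str, set[str]] = {}
    for gene, pat in gene_patterns.items():
        genes_by_pattern.setdefault(pat, set()).add(gene)
    signs: list[str | None] = (
        sorted({r.sign for r in relations}) if per_sign else [None]
    )
    rows = []
    for sign in signs:
        targets = _target_map(relations, sign)
        for tf, tf_targets in sorted(targets.items()):
            n_targets = len(tf_targets)
            by_pat: dict[str, int] = {}
            for g in tf_targets:
                pat = gene_patterns.get(g)
                if pat is not None:
                    by_pat[pat] = by_pat.get(pat, 0) + 1
            for pat, n_in in sorted(by_pat.items()):
                row = {
                    "tf_id": tf,
                    "pattern": pat,
                    "coverage": 100.0 * n_in / len(genes_by_pattern[pat]),
                    "specificity": 100.0 * n_in / n_targets,
                }
                if per_sign:
                    row["sign"] = sign
                rows.append(row)
    cols = ["tf_id", "pattern"] + (["sign"] if per_sign else []) + ["coverage", "specificity"]
    return pd.DataFrame(rows, columns=cols)


def select_key_regulators(
    metrics: pd.DataFrame, policy: ThresholdPolicy = LAST_QUARTILE
) -> list[tuple[str, str]]:
    """(tf, pattern) pairs whose coverage AND specificity pass the policy."""
    if metrics.empty:
        return []
    cov_thr, spe_thr = policy.cutoffs(metrics)
    keep = metrics[(metrics["coverage"] >= cov_thr) & (metrics["specificity"] >= spe_thr)]
    return sorted(zip(keep["tf_id"], keep["pattern"]))


@dataclass(frozen=True)
class AnnotationScore:
    tf_id: str
    go_hits: int
    context_citations: int
    broad_citations: int
    composite: float


def annotation_score(
    tfs: Sequence[str],
    go_table: Mapping[str, set[str]],
    citation_table: Mapping[str, tuple[int, int]],
    go_terms: set[str],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[AnnotationScore]:
    """Composite = weighted sum of GO hits against the user's term list and
    context/broad citation counts.  A zero composite marks TFs not yet
    studied in the biological context."""
    out = []
    for tf in tfs:
        if tf not in go_table and tf not in citation_table:
            warnings.warn(f"TF {tf!r} absent from annotation tables; scored 0")
        go_hits = len(go_table.get(tf, set()) & go_terms)
        ctx, broad = citation_table.get(tf, (0, 0))
        composite = weights[0] * go_hits + weights[1] * ctx + weights[2] * broad
        out.append(AnnotationScore(tf, go_hits, ctx, broad, composite))
    return out
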