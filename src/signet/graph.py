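"""Entity graph integration and the candidate-triple query.

Entities (genes, TFs, regions) carry their activity patterns; the two
relation kinds are reified so they can bear attributes: region-gene
neighborhood (with its bp distance) and TF-region binding inclusion.  The
candidate query joins them: every (TF, region, gene) combination where the
TF binds the region, the region neighbors the gene, and the TF is
expressed.

Storage is plain in-memory maps; a Turtle export/import is provided for
interoperability with triple stores but is not used by the query itself.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

from signet.discretize import is_silent
from signet.genomic_links import RegionClosest, TFInclusion

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class CandidateTriple:
    tf_id: str
    region_id: str
    gene_id: str
    tf_pattern: str
    region_pattern: str
    gene_pattern: str
    distance: int


@dataclass
class RegulatoryGraph:
    """Patterns plus reified relations, indexed for the join."""

    genes: dict[str, str] = field(default_factory=dict)
    tfs: dict[str, str] = field(default_factory=dict)
    regions: dict[str, str] = field(default_factory=dict)
    region_closest: set[RegionClosest] = field(default_factory=set)
    tf_inclusion: set[TFInclusion] = field(default_factory=set)
    xrefs: dict[str, dict[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        for rel in self.region_closest:
            if rel.region_id not in self.regions or rel.gene_id not in self.genes:
                raise ValueError(f"dangling neighborhood relation {rel}")
        for rel in self.tf_inclusion:
            if rel.tf_id not in self.tfs or rel.region_id not in self.regions:
                raise ValueError(f"dangling inclusion relation {rel}")
        for tf, pat in self.tfs.items():
            if tf in self.genes and self.genes[tf] != pat:
                raise ValueError(
                    f"TF {tf!r} pattern {pat!r} differs from its coding gene's"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryGraph):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.tfs == other.tfs
            and self.regions == other.regions
            and self.region_closest == other.region_closest
            and self.tf_inclusion == other.tf_inclusion
        )


def tf_patterns_from_genes(
    gene_patterns: Mapping[str, str], tf_symbols: Iterable[str]
) -> dict[str, str]:
    """TF patterns are those of their coding genes; TFs whose gene is
    absent from the expression table are excluded (logged)."""
    out: dict[str, str] = {}
    missing = []
    for tf in sorted(set(tf_symbols)):
        if tf in gene_patterns:
            out[tf] = gene_patterns[tf]
        else:
            missing.append(tf)
    if missing:
        logger.info("excluded %d TFs without a coding-gene pattern: %s",
                    len(missing), missing[:10])
    return out


def build_graph(
    gene_patterns: Mapping[str, str],
    tf_patterns: Mapping[str, str],
    region_patterns: Mapping[str, str],
    neighbors: Iterable[RegionClosest],
    inclusions: Iterable[TFInclusion],
) -> RegulatoryGraph:
    """Assemble the graph, dropping relations whose endpoints lack a pattern."""
    g = RegulatoryGraph(
        genes=dict(gene_patterns),
        tfs=dict(tf_patterns),
        regions=dict(region_patterns),
    )
    dropped = 0
    for rel in neighbors:
        if rel.region_id in g.regions and rel.gene_id in g.genes:
            g.region_closest.add(rel)
        else:
            dropped += 1
    for rel in inclusions:
        if rel.tf_id in g.tfs and rel.region_id in g.regions:
            g.tf_inclusion.add(rel)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d relations with missing pattern endpoints", dropped)
    g.validate()
    return g


def candidate_triples(
    graph: RegulatoryGraph,
    gene_pattern_filter: set[str] | None = None,
) -> list[CandidateTriple]:
    """The 3-step join: gene -> neighboring regions -> TFs bound there.

    Silent (all-0) TFs are excluded: an unexpressed TF cannot regulate.
    Output order is deterministic (tf, region, gene lexicographic).
    """
    regions_to_genes: dict[str, list[RegionClosest]] = {}
    for rel in graph.region_closest:
        regions_to_genes.setdefault(rel.region_id, []).append(rel)
    out: list[CandidateTriple] = []
    for inc in graph.tf_inclusion:
        tf_pat = graph.tfs[inc.tf_id]
        if is_silent(tf_pat):
            continue
        for rel in regions_to_genes.get(inc.region_id, []):
            gene_pat = graph.genes[rel.gene_id]
            if gene_pattern_filter is not None and gene_pat not in gene_pattern_filter:
                continue
            out.append(
                CandidateTriple(
                    tf_id=inc.tf_id,
                    region_id=inc.region_id,
                    gene_id=rel.gene_id,
                    tf_pattern=tf_pat,
                    region_pattern=graph.regions[inc.region_id],
                    gene_pattern=gene_pat,
                    distance=rel.distance,
                )
            )
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Turtle serialization.  The vocabulary mirrors the reified data model:
# entity nodes with pattern literals, relation nodes bearing distance or
# inclusion.  The parser only accepts the exact shape this writer emits.

_PREFIX = "http://signet.local/vocab#"


def _iri(kind: str, ident: str) -> str:
    return f":{kind}__{quote(ident, safe='')}"


def _lit(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _unlit(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def export_graph(graph: RegulatoryGraph, path: str) -> None:
    """Serialize to Turtle; reified relation ids are deterministic so the
    export is byte-identical for identical graphs."""
    lines = [f"@prefix : <{_PREFIX}> .", ""]
    for kind, table in (("Gene", graph.genes), ("TF", graph.tfs), ("Region", graph.regions)):
        for ident in sorted(table):
            lines.append(
                f"{_iri(kind.lower(), ident)} a :{kind} ; "
                f":symbol {_lit(ident)} ; :pattern {_lit(table[ident])} ."
            )
    for rel in sorted(graph.region_closest):
        node = _iri("closest", f"{rel.region_id}__{rel.gene_id}")
        lines.append(
            f"{node} a :RegionClosest ; :region {_iri('region', rel.region_id)} ; "
            f":gene {_iri('gene', rel.gene_id)} ; :distance {rel.distance} ."
        )
    for rel in sorted(graph.tf_inclusion):
        node = _iri("binds", f"{rel.tf_id}__{rel.region_id}")
        lines.append(
            f"{node} a :TFInclusion ; :tf {_iri('tf', rel.tf_id)} ; "
            f":region {_iri('region', rel.region_id)} ."
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


_ENTITY_RE = re.compile(
    r"^:(gene|tf|region)__\S+ a :(Gene|TF|Region) ; "
    r':symbol "((?:[^"\\]|\\.)*)" ; :pattern "((?:[^"\\]|\\.)*)" \.$'
)
_CLOSEST_RE = re.compile(
    r"^:closest__\S+ a :RegionClosest ; :region :region__(\S+) ; "
    r":gene :gene__(\S+) ; :distance (\d+) \.$"
)
_BINDS_RE = re.compile(
    r"^:binds__\S+ a :TFInclusion ; :tf :tf__(\S+) ; :region :region__(\S+) \.$"
)


def import_graph(path: str) -> RegulatoryGraph:
    """Parse a Turtle file produced by :func:`export_graph`."""
    g = RegulatoryGraph()
    tables = {"Gene": g.genes, "TF": g.tfs, "Region": g.regions}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("@prefix"):
                continue
            m = _ENTITY_RE.match(line)
            if m:
                tables[m.group(2)][_unlit(m.group(3))] = _unlit(m.group(4))
                continue
            m = _CLOSEST_RE.match(line)
            if m:
                g.region_closest.add(
                    RegionClosest(unquote(m.group(1)), unquote(m.group(2)), int(m.group(3)))
                )
                continue
            m = _BINDS_RE.match(line)
            if m:
                g.tf_inclusion.add(TFInclusion(unquote(m.group(1)), unquote(m.group(2))))
                continue
            raise ValueError(f"unparseable graph line: {line!r}")
    g.validate()
    return g
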