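"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from signet.constraints import SignedRelation, SignedTriple
from signet.genomic_links import GenomicInterval, RegionClosest, TFInclusion
from signet.graph import CandidateTriple
from signet.validation import CuratedRelation


def read_activity_tsv(path: str | Path) -> pd.DataFrame:
    """Entity x sample table: first column entity id, remaining samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate entity ids in {path}: {dups}")
    return df


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample, population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_class_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["entity_id", "class"],
                     dtype=str, comment="#")
    return dict(zip(df["entity_id"], df["class"]))


def read_bed(path: str | Path, name_prefix: str = "feat") -> list[GenomicInterval]:
    """BED3+; the 4th column supplies names when present, otherwise ids are
    synthesized as ``<prefix>_<rownumber>``."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i + 1}: fewer than 3 BED columns")
            name = fields[3] if len(fields) > 3 and fields[3] else f"{name_prefix}_{i + 1}"
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def write_patterns(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_patterns(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["entity_id"], df["pattern"]))


def write_neighbors(records: Iterable[RegionClosest], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tgene_id\tdistance\n")
        for r in records:
            fh.write(f"{r.region_id}\t{r.gene_id}\t{r.distance}\n")


def read_neighbors(path: str | Path) -> list[RegionClosest]:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "gene_id": str})
    return [RegionClosest(r.region_id, r.gene_id, int(r.distance))
            for r in df.itertuples()]


def write_inclusions(records: Iterable[TFInclusion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tregion_id\n")
        for r in records:
            fh.write(f"{r.tf_id}\t{r.region_id}\n")


def read_inclusions(path: str | Path) -> list[TFInclusion]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [TFInclusion(r.tf_id, r.region_id) for r in df.itertuples()]


def write_candidates(triples: Iterable[CandidateTriple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tregion_id\tgene_id\ttf_pattern\tregion_pattern\t"
                 "gene_pattern\tdistance\n")
        for t in triples:
            fh.write(f"{t.tf_id}\t{t.region_id}\t{t.gene_id}\t{t.tf_pattern}\t"
                     f"{t.region_pattern}\t{t.gene_pattern}\t{t.distance}\n")


def read_candidates(path: str | Path) -> list[CandidateTriple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CandidateTriple(t.tf_id, t.region_id, t.gene_id, t.tf_pattern,
                        t.region_pattern, t.gene_pattern, int(t.distance))
        for t in df.itertuples()
    ]


def write_signed(records: Iterable[SignedTriple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tregion_id\tgene_id\ttf_pattern\tregion_pattern\t"
                 "gene_pattern\tsign\n")
        for r in records:
            fh.write(f"{r.tf_id}\t{r.region_id}\t{r.gene_id}\t{r.tf_pattern}\t"
                     f"{r.region_pattern}\t{r.gene_pattern}\t{r.sign}\n")


def write_merged(records: Iterable[SignedRelation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tgene_id\tsign\tn_regions\tregion_ids\tconflict_flag\n")
        for r in records:
            fh.write(f"{r.tf_id}\t{r.gene_id}\t{r.sign}\t{len(r.regions)}\t"
                     f"{','.join(r.regions)}\t{int(r.conflicting)}\n")


def read_merged(path: str | Path, gene_patterns: Mapping[str, str] | None = None,
                tf_patterns: Mapping[str, str] | None = None) -> list[SignedRelation]:
    gene_patterns = gene_patterns or {}
    tf_patterns = tf_patterns or {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SignedRelation(
            tf_id=r.tf_id, gene_id=r.gene_id, sign=r.sign,
            regions=tuple(r.region_ids.split(",")) if r.region_ids else (),
            tf_pattern=tf_patterns.get(r.tf_id, ""),
            gene_pattern=gene_patterns.get(r.gene_id, ""),
            conflicting=bool(int(r.conflict_flag)),
        )
        for r in df.itertuples()
    ]


def read_curated(path: str | Path) -> list[CuratedRelation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [CuratedRelation(r.tf_id, r.gene_id, r.sign) for r in df.itertuples()]
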