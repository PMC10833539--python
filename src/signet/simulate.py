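"""Synthetic input bundles with planted signed regulations and ground truth.

The generator inverts the discretization: it emits raw per-sample activity
values whose per-population log-means realize target patterns with margins
wide enough that binning is unambiguous, so the real pipeline (including
the discretize stage) is exercised end-to-end.  Planted (TF, region, gene,
sign) relations are constructed so their pattern triples are perfect; in
noise mode exactly one gene-pattern cell is moved by one level, which
makes the relation recoverable at delta1 but not delta0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from signet import io
from signet.constraints import (
    NEGATIVE,
    PERFECT,
    POSITIVE,
    RELAXED,
    cell_status,
    perfect_gene_level,
)
from signet.discretize import is_variable, pattern_levels
from signet.genomic_links import GenomicInterval

logger = logging.getLogger(__name__)

_SLOT = 3_000_000  # bp per gene slot; keeps slots regulatorily independent
_GENE_OFFSET = 1_000_000
_GENE_LEN = 1_000
_REGION_LEN = 500
_MAX_GAP = 400_000
_FAR_OFFSET = 2_450_000


class InfeasiblePattern(ValueError):
    """The perfect gene pattern for (tf, region, sign) is not a valid
    variable pattern (misses a 1 or a 4)."""


@dataclass(frozen=True)
class PlantedRelation:
    tf_id: str
    region_id: str
    gene_id: str
    sign: str
    perturbed: bool = False


@dataclass
class FixtureSpec:
    n_populations: int = 4
    n_genes: int = 50
    n_tfs: int = 10
    n_regions: int = 30
    n_planted: int = 20
    noise_prob: float = 0.0
    samples_per_population: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > min(self.n_genes, self.n_regions):
            raise ValueError("cannot plant more relations than genes or regions")
        if self.n_planted > self.n_tfs * self.n_genes:
            raise ValueError("cannot plant more relations than TF x gene pairs")
        if self.samples_per_population < 2:
            raise ValueError("need >=2 samples per population")
        if not 2 <= self.n_populations <= 9:
            raise ValueError("populations must be between 2 and 9")


@dataclass
class Fixture:
    spec: FixtureSpec
    truth: list[PlantedRelation]
    expression: pd.DataFrame
    region_activity: pd.DataFrame
    sample_map: dict[str, str]
    populations: list[str]
    genes_bed: list[GenomicInterval]
    regions_bed: list[GenomicInterval]
    tfbs_bed: list[GenomicInterval]
    gene_patterns: dict[str, str] = field(default_factory=dict)
    region_patterns: dict[str, str] = field(default_factory=dict)


def plant_regulation(tf_pattern: str, region_pattern: str, sign: str) -> str:
    """The unique perfect gene pattern for (tf_pattern, region_pattern, sign).

    Raises :class:`InfeasiblePattern` when that pattern is not itself a
    valid variable pattern; callers resample.
    """
    gene = "".join(
        str(perfect_gene_level(f, r, sign))
        for f, r in zip(pattern_levels(tf_pattern), pattern_levels(region_pattern))
    )
    if not is_variable(gene):
        raise InfeasiblePattern(
            f"perfect pattern {gene!r} for ({tf_pattern}, {region_pattern}, {sign}) "
            "is not a valid variable pattern"
        )
    return gene


def _random_variable_pattern(rng: np.random.Generator, n: int) -> str:
    while True:
        levels = rng.integers(1, 5, size=n)
        if 1 in levels and 4 in levels:
            return "".join(map(str, levels))


def _perturb_one_cell(gene_pattern: str, tf_pattern: str, region_pattern: str,
                      sign: str, rng: np.random.Generator) -> str | None:
    """Move one cell by one level such that the result is a valid variable
    pattern and the moved cell is relaxed (light blue) for ``sign`` --
    i.e. the planted relation needs delta1 but survives it."""
    g = list(pattern_levels(gene_pattern))
    f = pattern_levels(tf_pattern)
    r = pattern_levels(region_pattern)
    candidates = [(i, d) for i in range(len(g)) for d in (-1, 1)]
    for pick in rng.permutation(len(candidates)):
        i, d = candidates[pick]
        new = g[i] + d
        if not 1 <= new <= 4:
            continue
        moved = g.copy()
        moved[i] = new
        pat = "".join(map(str, moved))
        if not is_variable(pat):
            continue
        if cell_status(f[i], r[i], new, sign) != RELAXED:
            continue
        if any(cell_status(f[j], r[j], moved[j], sign) != PERFECT
               for j in range(len(g)) if j != i):
            continue
        return pat
    return None


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the full in-memory bundle; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_populations
    populations = [f"P{i + 1}" for i in range(n)]
    samples = [f"{p}_s{j + 1}" for p in populations
               for j in range(spec.samples_per_population)]
    sample_map = {s: s.split("_")[0] for s in samples}

    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(spec.n_tfs)]
    region_ids = [f"R{i + 1:04d}" for i in range(spec.n_regions)]

    tf_patterns: dict[str, str] = {}
    gene_patterns: dict[str, str] = {}
    region_patterns: dict[str, str] = {}
    truth: list[PlantedRelation] = []
    genes_bed: list[GenomicInterval] = []
    regions_bed: list[GenomicInterval] = []
    tfbs_bed: list[GenomicInterval] = []

    def gene_interval(slot: int, name: str) -> GenomicInterval:
        start = slot * _SLOT + _GENE_OFFSET
        return GenomicInterval("chr1", start, start + _GENE_LEN, name)

    def region_interval(slot: int, name: str, far: bool) -> GenomicInterval:
        if far:
            start = slot * _SLOT + _FAR_OFFSET
        else:
            gap = int(rng.integers(0, _MAX_GAP))
            gene_start = slot * _SLOT + _GENE_OFFSET
            if rng.random() < 0.5:
                start = max(slot * _SLOT, gene_start - gap - _REGION_LEN)
            else:
                start = gene_start + _GENE_LEN + gap
        return GenomicInterval("chr1", start, start + _REGION_LEN, name)

    # --- planted relations: gene i / region i / TF round-robin -------------
    for k in range(spec.n_planted):
        tf = tf_ids[k % spec.n_tfs]
        for _ in range(500):
            tf_pat = tf_patterns.get(tf) or _random_variable_pattern(rng, n)
            reg_pat = _random_variable_pattern(rng, n)
            sign = POSITIVE if rng.random() < 0.5 else NEGATIVE
            try:
                gene_pat = plant_regulation(tf_pat, reg_pat, sign)
            except InfeasiblePattern:
                continue
            break
        else:
            raise RuntimeError(f"could not plant relation {k} for TF {tf}")
        tf_patterns[tf] = tf_pat
        region_patterns[region_ids[k]] = reg_pat

        perturbed = False
        if spec.noise_prob > 0 and rng.random() < spec.noise_prob:
            moved = _perturb_one_cell(gene_pat, tf_pat, reg_pat, sign, rng)
            if moved is not None:
                gene_pat = moved
                perturbed = True
            else:
                logger.info("no feasible one-cell perturbation for relation %d", k)
        gene_patterns[gene_ids[k]] = gene_pat

        genes_bed.append(gene_interval(k, gene_ids[k]))
        region = region_interval(k, region_ids[k], far=False)
        regions_bed.append(region)
        tfbs_bed.append(GenomicInterval("chr1", region.start + 10,
                                        region.start + 30, tf))
        truth.append(PlantedRelation(tf, region_ids[k], gene_ids[k], sign, perturbed))

    # TFs never planted still need a pattern (decoy regulators)
    for tf in tf_ids:
        tf_patterns.setdefault(tf, _random_variable_pattern(rng, n))

    # --- decoy genes: variable, plus one silent and one constant -----------
    for i in range(spec.n_planted, spec.n_genes):
        gid = gene_ids[i]
        genes_bed.append(gene_interval(i, gid))
        tail = spec.n_genes - 1 - i
        if tail == 0 and spec.n_genes - spec.n_planted >= 2:
            gene_patterns[gid] = "0" * n
        elif tail == 1 and spec.n_genes - spec.n_planted >= 2:
            gene_patterns[gid] = "5" * n
        else:
            gene_patterns[gid] = _random_variable_pattern(rng, n)

    # --- decoy regions, alternately near a decoy gene and far from all -----
    slot_gene: dict[int, str] = {i: gene_ids[i] for i in range(spec.n_genes)}
    for j, i in enumerate(range(spec.n_planted, spec.n_regions)):
        rid = region_ids[i]
        far = j % 2 == 1
        slot = int(rng.integers(0, spec.n_genes))
        region = region_interval(slot, rid, far=far)
        regions_bed.append(region)
        reg_pat = _random_variable_pattern(rng, n)
        region_patterns[rid] = reg_pat
        if far:
            continue
        # decoy binding sites with rejection against accidental perfect triples
        neighbor_gene = slot_gene[slot]
        gene_pat = gene_patterns[neighbor_gene]
        for _ in range(int(rng.integers(1, 3))):
            for _try in range(25):
                tf = tf_ids[int(rng.integers(0, spec.n_tfs))]
                f = pattern_levels(tf_patterns[tf])
                r = pattern_levels(reg_pat)
                if not is_variable(gene_pat):
                    break
                g = pattern_levels(gene_pat)
                perfect = any(
                    all(cell_status(fi, ri, gi, s) == PERFECT
                        for fi, ri, gi in zip(f, r, g))
                    for s in (POSITIVE, NEGATIVE)
                )
                if not perfect:
                    break
            else:
                logger.info("rejection failed for decoy region %s; keeping TFBS", rid)
            tfbs_bed.append(GenomicInterval("chr1", region.start + 50,
                                            region.start + 70, tf))

    # TF coding genes occupy their own slots past the regular genes
    for j, tf in enumerate(tf_ids):
        genes_bed.append(gene_interval(spec.n_genes + j, tf))
        gene_patterns[tf] = tf_patterns[tf]

    expression = _realize_values(gene_patterns, populations, samples, sample_map, rng)
    region_activity = _realize_values(region_patterns, populations, samples,
                                      sample_map, rng)
    return Fixture(
        spec=spec,
        truth=truth,
        expression=expression,
        region_activity=region_activity,
        sample_map=sample_map,
        populations=populations,
        genes_bed=genes_bed,
        regions_bed=regions_bed,
        tfbs_bed=sorted(tfbs_bed, key=lambda iv: (iv.start, iv.name)),
        gene_patterns=gene_patterns,
        region_patterns=region_patterns,
    )


def _realize_values(
    patterns: dict[str, str],
    populations: Sequence[str],
    samples: Sequence[str],
    sample_map: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit per-sample raw values whose population log10 means hit the
    target level exactly: level L maps to a mean of 10**L, with symmetric
    +/-1% within-population jitter that cancels in the mean."""
    eps = 0.01
    k = sum(1 for s in samples if sample_map[s] == populations[0])
    jitter = np.linspace(-eps, eps, k)  # symmetric around 0
    rows = {}
    for entity, pattern in sorted(patterns.items()):
        vals = []
        for pop, level_char in zip(populations, pattern):
            level = int(level_char)
            if level == 0:
                mean = 0.0
            elif level == 5:
                mean = 100.0
            else:
                mean = 10.0 ** level
            vals.extend(mean * (1.0 + jitter))
        rows[entity] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    df.index.name = "entity_id"
    return df


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the pipeline's plain-text input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "region_activity": outdir / "region_activity.tsv",
        "sample_map": outdir / "sample_map.tsv",
        "genes_bed": outdir / "genes.bed",
        "regions_bed": outdir / "regions.bed",
        "tfbs_bed": outdir / "tfbs.bed",
        "truth": outdir / "truth.tsv",
    }
    fixture.expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    fixture.region_activity.to_csv(paths["region_activity"], sep="\t",
                                   float_format="%.6f")
    with open(paths["sample_map"], "w") as fh:
        for s in fixture.expression.columns:
            fh.write(f"{s}\t{fixture.sample_map[s]}\n")
    io.write_bed(fixture.genes_bed, paths["genes_bed"])
    io.write_bed(fixture.regions_bed, paths["regions_bed"])
    io.write_bed(fixture.tfbs_bed, paths["tfbs_bed"])
    with open(paths["truth"], "w") as fh:
        fh.write("tf_id\tregion_id\tgene_id\tsign\tperturbed\n")
        for rel in fixture.truth:
            fh.write(f"{rel.tf_id}\t{rel.region_id}\t{rel.gene_id}\t{rel.sign}\t"
                     f"{int(rel.perturbed)}\n")
    return paths


def read_truth(path: str | Path) -> list[PlantedRelation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [PlantedRelation(r.tf_id, r.region_id, r.gene_id, r.sign,
                            bool(int(r.perturbed)))
            for r in df.itertuples()]


def recall_against_truth(signed_keys: set[tuple[str, str, str, str]],
                         truth: Sequence[PlantedRelation]) -> float:
    """Fraction of planted (tf, region, gene, sign) tuples recovered."""
    if not truth:
        return float("nan")
    hits = sum((rel.tf_id, rel.region_id, rel.gene_id, rel.sign) in signed_keys
               for rel in truth)
    return hits / len(truth)
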