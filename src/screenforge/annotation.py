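"""Toy genome annotations for truth-known screen simulations.

A `GenomeAnnotation` holds gene spans (0-based half-open), strands and exon
intervals on one or more chromosomes.  Real genome builds are abstracted to
this container; the generator below lays out non-overlapping genes on a
single toy chromosome so that every downstream classification rule can be
exercised with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "make_toy_annotation",
    "make_toy_genome",
    "write_annotation_tsv",
    "read_annotation_tsv",
]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    exons: tuple[tuple[int, int], ...]  # half-open, non-overlapping, sorted


@dataclass
class GenomeAnnotation:
    chrom_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def validate(self) -> None:
        """Raise ValueError on any structural invariant violation."""
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.strand not in "+-":
                raise ValueError(f"{g.gene_id}: bad strand {g.strand!r}")
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"{g.gene_id}: unknown chrom {g.chrom}")
            if not (0 <= g.start < g.end <= self.chrom_lengths[g.chrom]):
                raise ValueError(f"{g.gene_id}: span outside chromosome")
            if not g.exons:
                raise ValueError(f"{g.gene_id}: gene without exons")
            prev_end = g.start
            for (s, e) in g.exons:
                if s < prev_end or e <= s or e > g.end:
                    raise ValueError(f"{g.gene_id}: bad exon ({s},{e})")
                prev_end = e

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def _place_exons(rng: np.random.Generator, start: int, end: int,
                 exon_fraction: float) -> tuple[tuple[int, int], ...]:
    """Split ~exon_fraction of a gene span into 1-5 non-overlapping exons."""
    length = end - start
    exon_total = max(1, int(round(length * exon_fraction)))
    n_exons = int(rng.integers(1, min(5, max(1, exon_total)) + 1))
    # sizes: multinomial split of exonic bp, each exon >= 1 bp
    sizes = np.full(n_exons, 1)
    extra = rng.multinomial(exon_total - n_exons, np.full(n_exons, 1 / n_exons))
    sizes = sizes + extra
    gap_total = length - exon_total
    gaps = rng.multinomial(gap_total, np.full(n_exons + 1, 1 / (n_exons + 1)))
    exons = []
    pos = start
    for i in range(n_exons):
        pos += int(gaps[i])
        exons.append((pos, pos + int(sizes[i])))
        pos += int(sizes[i])
    return tuple(exons)


def make_toy_annotation(
    n_genes: int,
    chrom_length: int = 1_000_000,
    exon_fraction: float = 0.3,
    seed: int = 0,
    chrom: str = "chr1",
    min_gene_length: int = 1000,
    max_gene_length: int = 5000,
) -> GenomeAnnotation:
    """Lay out ``n_genes`` non-overlapping genes on one toy chromosome.

    Gene lengths are uniform on [min_gene_length, max_gene_length], strands
    ~50/50, leftover chromosome distributed as random intergenic gaps.
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_gene_length, max_gene_length + 1, size=n_genes)
    total = int(lengths.sum())
    slack = chrom_length - total
    if slack < 0:
        raise ValueError(
            f"chromosome of {chrom_length} bp cannot hold {n_genes} genes "
            f"totalling {total} bp"
        )
    gaps = rng.multinomial(slack, np.full(n_genes + 1, 1 / (n_genes + 1)))
    strands = rng.choice(["+", "-"], size=n_genes)
    width = len(str(n_genes - 1))
    genes = []
    pos = 0
    for i in range(n_genes):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        exons = _place_exons(rng, start, end, exon_fraction)
        genes.append(Gene(f"G{i:0{width}d}", chrom, str(strands[i]), start, end, exons))
        pos = end
    ann = GenomeAnnotation({chrom: chrom_length}, genes)
    ann.validate()
    return ann


def make_toy_genome(annotation: GenomeAnnotation, seed: int = 0) -> dict[str, str]:
    """Random nucleotide sequence for each chromosome of ``annotation``."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(bases[rng.integers(0, 4, size=length)])
        for chrom, length in annotation.chrom_lengths.items()
    }


def write_annotation_tsv(annotation: GenomeAnnotation, path) -> None:
    """BED12-like TSV: one gene per row with comma-joined exon block coords."""
    rows = []
    for g in annotation.genes:
        rows.append({
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "gene_id": g.gene_id,
            "strand": g.strand,
            "exon_starts": ",".join(str(s) for s, _ in g.exons),
            "exon_ends": ",".join(str(e) for _, e in g.exons),
            "chrom_length": annotation.chrom_lengths[g.chrom],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    chrom_lengths = {
        str(r.chrom): int(r.chrom_length)
        for r in df.drop_duplicates("chrom").itertuples()
    }
    genes = []
    for r in df.itertuples():
        starts = [int(x) for x in str(r.exon_starts).split(",")]
        ends = [int(x) for x in str(r.exon_ends).split(",")]
        genes.append(Gene(str(r.gene_id), str(r.chrom), str(r.strand),
                          int(r.start), int(r.end),
                          tuple(zip(starts, ends))))
    ann = GenomeAnnotation(chrom_lengths, genes)
    ann.validate()
    return ann
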