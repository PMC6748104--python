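"""Haploid gene-trap screen hit calling.

A selected (resistant) and an unselected (control) population of mapped
retroviral gene-trap insertion sites are compared per gene: insertions are
deduplicated, near-duplicate sites 1-2 bp apart are collapsed as mapping
artifacts, insertions predicted to disrupt gene function are assigned to
genes, and per-gene enrichment in the selected pool is scored with a
one-sided Fisher exact test followed by Benjamini-Hochberg FDR control.

Insertion tables are pandas DataFrames with columns
``chrom`` (str), ``pos`` (0-based int), ``strand`` ('+'/'-'),
``read_support`` (int >= 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation
from .stats import bh_adjust, fisher_enrichment_vec

log = logging.getLogger(__name__)

INSERTION_COLUMNS = ["chrom", "pos", "strand", "read_support"]

__all__ = [
    "align_reads_exact",
    "deduplicate",
    "collapse_proximal",
    "classify_disruptive",
    "count_per_gene",
    "call_genetrap_hits",
    "read_insertions_bed",
    "write_insertions_bed",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _iter_reads(reads):
    """Accept a FASTQ path or an iterable of sequence strings."""
    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        from Bio import SeqIO

        for rec in SeqIO.parse(reads, "fastq"):
            yield str(rec.seq)
    else:
        for r in reads:
            yield str(getattr(r, "seq", r))


def align_reads_exact(genome: dict[str, str], reads) -> tuple[pd.DataFrame, dict]:
    """Exact-substring alignment of insertion-flank reads to a toy genome.

    A read maps iff it occurs exactly once in the genome across both strands;
    reads with zero matches are counted as unmapped and reads with two or more
    matches are discarded as multi-mappers, mirroring how ambiguous alignments
    are dropped from real screens.  A forward match at offset i is the flank
    of a '+' insertion at i; a reverse-complement match starting at j is the
    flank of a '-' insertion at j + len(read) - 1.

    Returns (insertion table, QC dict with mapped/unmapped/multimapped counts).
    """
    sites: dict[tuple[str, int, str], int] = {}
    qc = {"mapped": 0, "unmapped": 0, "multimapped": 0}
    n_reads = 0
    for read in _iter_reads(reads):
        n_reads += 1
        hits: list[tuple[str, int, str]] = []
        rc = _revcomp(read)
        for chrom, seq in genome.items():
            start = seq.find(read)
            while start != -1:
                hits.append((chrom, start, "+"))
                start = seq.find(read, start + 1)
            start = seq.find(rc)
            while start != -1:
                hits.append((chrom, start + len(read) - 1, "-"))
                start = seq.find(rc, start + 1)
        if not hits:
            qc["unmapped"] += 1
        elif len(hits) > 1:
            qc["multimapped"] += 1
        else:
            qc["mapped"] += 1
            sites[hits[0]] = sites.get(hits[0], 0) + 1
    if n_reads == 0:
        log.warning("empty reads input: returning empty insertion table")
    table = pd.DataFrame(
        [(c, p, s, n) for (c, p, s), n in sites.items()],
        columns=INSERTION_COLUMNS,
    )
    return table.sort_values(["chrom", "pos", "strand"], ignore_index=True), qc


def deduplicate(table: pd.DataFrame) -> pd.DataFrame:
    """Merge records sharing (chrom, pos, strand); read_support counts merges."""
    if table.empty:
        return table.copy()
    out = (
        table.groupby(["chrom", "pos", "strand"], as_index=False)
        .size()
        .rename(columns={"size": "read_support"})
    )
    return out[INSERTION_COLUMNS].sort_values(
        ["chrom", "pos", "strand"], ignore_index=True
    )


def collapse_proximal(
    table: pd.DataFrame, window: int = 2, drop_entire_cluster: bool = False
) -> pd.DataFrame:
    """Remove insertions 1-2 bp apart that likely stem from mapping errors.

    Same-strand sites on one chromosome are single-link chained at inter-site
    gap <= ``window``.  By default each chain is replaced by its single
    highest-support site (ties broken toward the smallest position); supports
    of discarded satellites are NOT summed, since they are deemed artifacts.
    With ``drop_entire_cluster`` every chain of size > 1 is removed outright.
    """
    if table.empty:
        return table.copy()
    df = table.sort_values(["chrom", "strand", "pos"], ignore_index=True)
    same_group = (df["chrom"] == df["chrom"].shift()) & (
        df["strand"] == df["strand"].shift()
    )
    gap_ok = df["pos"].diff() <= window
    chain_id = (~(same_group & gap_ok)).cumsum()
    if drop_entire_cluster:
        sizes = chain_id.map(chain_id.value_counts())
        out = df[sizes == 1]
    else:
        # highest support first, then smallest pos: first row of each chain wins
        df = df.assign(_chain=chain_id).sort_values(
            ["_chain", "read_support", "pos"], ascending=[True, False, True]
        )
        out = df.groupby("_chain", as_index=False).head(1).drop(columns="_chain")
    return out[INSERTION_COLUMNS].sort_values(
        ["chrom", "pos", "strand"], ignore_index=True
    )


def classify_disruptive(
    table: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Assign insertions to genes and flag those predicted to disrupt function.

    Convention (the standard haploid gene-trap rule): an insertion is
    disruptive when it lies inside a gene span in the sense orientation
    (insertion strand == gene strand), or inside an exon in either
    orientation.  Intergenic insertions get gene_id None and are never
    disruptive; insertions overlapping several genes are assigned to each.

    Returns one row per (insertion, overlapped gene) with an ``insertion_idx``
    column identifying the source record, plus ``gene_id`` and ``disruptive``.
    """
    genes = annotation.genes
    rows = []
    missing_chroms: set[str] = set()
    by_chrom: dict[str, list[int]] = {}
    for gi, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(gi)

    def _emit(idx, chrom, pos, strand, gi):
        g = genes[gi]
        disruptive = strand == g.strand or any(s <= pos < e for s, e in g.exons)
        rows.append((idx, chrom, pos, strand, g.gene_id, disruptive))

    for chrom, sub in table.groupby("chrom", sort=False):
        if chrom not in annotation.chrom_lengths:
            missing_chroms.add(chrom)
            continue
        gidx = by_chrom.get(chrom, [])
        order = sorted(gidx, key=lambda gi: genes[gi].start)
        starts = np.array([genes[gi].start for gi in order])
        ends = np.array([genes[gi].end for gi in order])
        non_overlapping = bool((starts[1:] >= ends[:-1]).all()) if len(order) > 1 else True
        pos = sub["pos"].to_numpy()
        if non_overlapping:
            # vectorized point-in-interval lookup for the common layout
            cand = np.searchsorted(starts, pos, side="right") - 1
            inside = (cand >= 0) & (pos < ends[np.clip(cand, 0, None)])
            for idx, p, strand, hit, ci in zip(
                sub.index, pos, sub["strand"], inside, cand
            ):
                if hit:
                    _emit(idx, chrom, int(p), strand, order[ci])
                else:
                    rows.append((idx, chrom, int(p), strand, None, False))
        else:
            tree = IntervalTree()
            for gi in order:
                tree[genes[gi].start:genes[gi].end] = gi
            for idx, p, strand in zip(sub.index, pos, sub["strand"]):
                overlaps = tree[int(p)]
                if not overlaps:
                    rows.append((idx, chrom, int(p), strand, None, False))
                    continue
                for iv in overlaps:
                    _emit(idx, chrom, int(p), strand, iv.data)
    if missing_chroms:
        log.warning(
            "skipped insertions on chromosomes absent from annotation: %s",
            sorted(missing_chroms),
        )
    return pd.DataFrame(
        rows,
        columns=["insertion_idx", "chrom", "pos", "strand", "gene_id", "disruptive"],
    )


def count_per_gene(
    selected: pd.DataFrame, control: pd.DataFrame
) -> tuple[pd.DataFrame, int, int]:
    """Per-gene disruptive insertion counts and pool totals.

    ``selected``/``control`` are classified tables from `classify_disruptive`.
    Returns (per-gene table with columns gene_id, a, b; A; B) where a/b are
    disruptive counts in the gene and A/B count each disruptive insertion once
    even if it overlaps several genes.  Genes untouched in both pools are
    omitted.
    """

    def _per_gene(df: pd.DataFrame) -> tuple[pd.Series, int]:
        d = df.loc[df["disruptive"].astype(bool)]
        per_gene = d.groupby("gene_id").size()
        total = d["insertion_idx"].nunique()
        return per_gene, total

    a, A = _per_gene(selected)
    b, B = _per_gene(control)
    genes = sorted(set(a.index) | set(b.index))
    counts = pd.DataFrame({
        "gene_id": genes,
        "a": a.reindex(genes).fillna(0).astype(int).to_numpy(),
        "b": b.reindex(genes).fillna(0).astype(int).to_numpy(),
    })
    return counts, int(A), int(B)


def call_genetrap_hits(
    selected: pd.DataFrame,
    control: pd.DataFrame,
    annotation: GenomeAnnotation,
    alpha: float = 0.05,
    label_threshold: float = 1e-10,
    window: int = 2,
    drop_entire_cluster: bool = False,
    return_all: bool = False,
) -> pd.DataFrame:
    """Full gene-trap hit-calling chain.

    dedup -> proximity collapse -> disruptive classification -> per-gene
    counting -> one-sided Fisher vs control -> BH-FDR.  Hits are genes with
    adjusted p <= ``alpha``, sorted by ascending adjusted p (ties: descending
    selected insertions, then gene_id); ``labeled`` marks strong drivers with
    adjusted p below ``label_threshold``.  With ``return_all`` every tested
    gene is returned together with a ``significant`` column.
    """
    stage_counts = {}
    tables = {}
    for name, tab in (("selected", selected), ("control", control)):
        dd = deduplicate(tab)
        cc = collapse_proximal(dd, window=window,
                               drop_entire_cluster=drop_entire_cluster)
        stage_counts[name] = (len(tab), len(dd), len(cc))
        tables[name] = classify_disruptive(cc, annotation)
    for name, (raw, dd, cc) in stage_counts.items():
        log.info("%s: %d records -> %d deduplicated -> %d after collapse",
                 name, raw, dd, cc)
    counts, A, B = count_per_gene(tables["selected"], tables["control"])
    if counts.empty or A < 1 or B < 1:
        empty = pd.DataFrame(columns=[
            "gene_id", "n_insertions_selected", "n_insertions_control",
            "p_value", "padj", "labeled", "significant",
        ])
        return empty if return_all else empty.drop(columns="significant")
    p = fisher_enrichment_vec(counts["a"], counts["b"], A, B)
    padj = bh_adjust(p)  # universe = genes hit in either pool
    out = pd.DataFrame({
        "gene_id": counts["gene_id"],
        "n_insertions_selected": counts["a"],
        "n_insertions_control": counts["b"],
        "p_value": p,
        "padj": padj,
    })
    out["labeled"] = out["padj"] < label_threshold
    out["significant"] = out["padj"] <= alpha
    out = out.sort_values(
        ["padj", "p_value", "n_insertions_selected", "gene_id"],
        ascending=[True, True, False, True],
        ignore_index=True,
    )
    log.info("tested %d genes (A=%d selected, B=%d control disruptive "
             "insertions); %d significant at BH %g",
             len(out), A, B, int(out["significant"].sum()), alpha)
    if return_all:
        return out
    return out[out["significant"]].drop(columns="significant").reset_index(drop=True)


def write_insertions_bed(table: pd.DataFrame, path) -> None:
    """BED6: name '.', score = read support, 1 bp interval per insertion."""
    bed = pd.DataFrame({
        "chrom": table["chrom"],
        "start": table["pos"],
        "end": table["pos"] + 1,
        "name": ".",
        "score": table["read_support"],
        "strand": table["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_insertions_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return pd.DataFrame({
        "chrom": bed["chrom"],
        "pos": bed["start"].astype(int),
        "strand": bed["strand"],
        "read_support": bed["score"].astype(int),
    })
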