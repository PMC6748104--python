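"""Truth-known synthetic data for every pipeline stage.

The generators emulate the data-generating processes the analyses assume:

* gene-trap insertion populations drawn multinomially over genes, with
  resistance genes enriched under selection by a fold factor;
* pooled CRISPR sgRNA count matrices with log-normal baseline library
  representation, negative-binomial sequencing noise, per-sgRNA Bernoulli
  efficacy, and treatment-dependent enrichment of resistance-gene sgRNAs at
  the final timepoint (essential-control guides deplete with time);
* spectral-count tables with over-dispersed counts and condition shifts.

Every generator is a pure function of its parameters and seed, and each
returns a truth ledger naming the genes/sgRNAs/proteins that truly carry
signal, so that recall and false-discovery calibration can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

__all__ = [
    "GeneTrapSimParams",
    "CrisprSimParams",
    "ScreenTruth",
    "simulate_genetrap",
    "simulate_crispr_counts",
    "emit_genetrap_fastq",
    "simulate_spectral_counts",
    "make_slc_library",
    "make_design",
]


@dataclass
class ScreenTruth:
    """Ledger of planted signal: per-gene flags/effects, per-sgRNA efficacy."""

    genes: pd.DataFrame  # gene_id, is_resistance, true_effect
    sgrnas: pd.DataFrame | None = None  # sgrna_id, efficacious (CRISPR only)

    def resistance_genes(self) -> set[str]:
        g = self.genes
        return set(g.loc[g["is_resistance"], "gene_id"])

    def true_sgrnas(self) -> set[str]:
        """sgRNAs that truly enrich: efficacious guides of resistance genes."""
        if self.sgrnas is None:
            return set()
        s = self.sgrnas
        return set(s.loc[s["truly_enriched"], "sgrna_id"])


# ---------------------------------------------------------------------------
# gene-trap arm
# ---------------------------------------------------------------------------

@dataclass
class GeneTrapSimParams:
    """Defaults mirror a desk-scale haploid screen: a deeply sampled
    unselected mutagenized pool versus a smaller drug-selected pool, with
    resistance genes accumulating insertions ~50-fold faster under selection."""

    insertions_control: int = 100_000
    insertions_selected: int = 10_000
    resistance_genes: set[str] = field(default_factory=set)
    enrichment_fold: float = 50.0
    baseline_weights: np.ndarray | None = None  # default: gene length
    intergenic_fraction: float = 0.3
    mean_extra_reads: float = 1.0  # read support = 1 + Poisson(mean)
    seed: int = 0

    def validate(self, annotation: GenomeAnnotation) -> None:
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.insertions_control <= 0 or self.insertions_selected <= 0:
            raise ValueError("insertion totals must be positive")
        if not (0 <= self.intergenic_fraction < 1):
            raise ValueError("intergenic_fraction must lie in [0, 1)")
        unknown = self.resistance_genes - set(annotation.gene_ids())
        if unknown:
            raise ValueError(f"resistance genes not in annotation: {sorted(unknown)}")


def _intergenic_intervals(annotation: GenomeAnnotation):
    """Per-chrom complement of gene spans, as (chrom, start, end) triples."""
    out = []
    for chrom, length in annotation.chrom_lengths.items():
        spans = sorted(
            (g.start, g.end) for g in annotation.genes if g.chrom == chrom
        )
        pos = 0
        for s, e in spans:
            if s > pos:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append((chrom, pos, length))
    return out


def _draw_insertions(
    rng: np.random.Generator,
    annotation: GenomeAnnotation,
    weights: np.ndarray,
    total: int,
    intergenic_fraction: float,
    mean_extra_reads: float,
) -> pd.DataFrame:
    genes = annotation.genes
    n_intergenic = rng.binomial(total, intergenic_fraction)
    n_genic = total - n_intergenic
    per_gene = rng.multinomial(n_genic, weights / weights.sum())
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for g, n in zip(genes, per_gene):
        if n == 0:
            continue
        positions.append(rng.integers(g.start, g.end, size=n))
        chroms.extend([g.chrom] * n)
    inter = _intergenic_intervals(annotation)
    if n_intergenic and inter:
        lens = np.array([e - s for _, s, e in inter], dtype=float)
        picks = rng.choice(len(inter), size=n_intergenic, p=lens / lens.sum())
        for i in picks:
            chrom, s, e = inter[i]
            positions.append(rng.integers(s, e, size=1))
            chroms.append(chrom)
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    strands = rng.choice(["+", "-"], size=pos.size)
    support = 1 + rng.poisson(mean_extra_reads, size=pos.size)
    return pd.DataFrame({
        "chrom": chroms,
        "pos": pos.astype(int),
        "strand": strands,
        "read_support": support.astype(int),
    })


def simulate_genetrap(
    annotation: GenomeAnnotation, params: GeneTrapSimParams
) -> tuple[pd.DataFrame, pd.DataFrame, ScreenTruth]:
    """Simulate (control, selected) insertion tables plus the truth ledger.

    Control insertions follow the baseline multinomial over genes; in the
    selected pool, resistance-gene weights are multiplied by
    ``enrichment_fold``.  Positions are uniform within the assigned gene body
    on a random strand; a configurable fraction lands intergenic.
    """
    params.validate(annotation)
    rng = np.random.default_rng(params.seed)
    genes = annotation.genes
    if params.baseline_weights is None:
        weights = np.array([g.end - g.start for g in genes], dtype=float)
    else:
        weights = np.asarray(params.baseline_weights, dtype=float)
        if weights.size != len(genes) or np.any(weights <= 0):
            raise ValueError("baseline_weights must be positive, one per gene")
    is_res = np.array([g.gene_id in params.resistance_genes for g in genes])
    sel_weights = np.where(is_res, weights * params.enrichment_fold, weights)
    control = _draw_insertions(
        rng, annotation, weights, params.insertions_control,
        params.intergenic_fraction, params.mean_extra_reads,
    )
    selected = _draw_insertions(
        rng, annotation, sel_weights, params.insertions_selected,
        params.intergenic_fraction, params.mean_extra_reads,
    )
    truth = ScreenTruth(genes=pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "is_resistance": is_res,
        "true_effect": np.where(is_res, params.enrichment_fold, 1.0),
    }))
    return control, selected, truth


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def emit_genetrap_fastq(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    table: pd.DataFrame,
    path,
    read_len: int = 50,
    seed: int = 0,
) -> int:
    """Write one flank read per supporting fragment of each insertion.

    A '+' insertion at pos yields the genomic substring [pos, pos+read_len);
    a '-' insertion yields the reverse complement of (pos-read_len, pos].
    Insertions closer than ``read_len`` to the chromosome end produce
    truncated reads whose names carry a ``/trunc`` flag.  Phred-33 quality is
    constant 'I'.  Returns the number of reads written.
    """
    n = 0
    with open(path, "w") as fh:
        for i, (chrom, pos, strand, support) in enumerate(
            zip(table["chrom"], table["pos"], table["strand"],
                table["read_support"])
        ):
            seq = genome[chrom]
            if strand == "+":
                read = seq[pos:pos + read_len]
            else:
                read = seq[max(0, pos - read_len + 1):pos + 1]
                read = read.translate(_RC)[::-1]
            trunc = "/trunc" if len(read) < read_len else ""
            for j in range(int(support)):
                fh.write(f"@ins{i}:{chrom}:{pos}:{strand}:{j}{trunc}\n"
                         f"{read}\n+\n{'I' * len(read)}\n")
                n += 1
    return n


# ---------------------------------------------------------------------------
# CRISPR arm
# ---------------------------------------------------------------------------

def make_slc_library(seed: int = 0) -> pd.DataFrame:
    """Synthetic pooled KO library matching the screened composition:
    388 target genes with six sgRNAs each, 120 sgRNAs against 20 essential
    control genes, and 120 non-targeting sgRNAs (2,568 guides total).

    Columns: sgrna_id, spacer (unique 20-nt), gene_id (None for
    non-targeting), class in {target, essential_control, non_targeting}.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rows = []
    spacers: set[str] = set()

    def _spacer() -> str:
        while True:
            s = "".join(bases[rng.integers(0, 4, size=20)])
            if s not in spacers:
                spacers.add(s)
                return s

    for gi in range(388):
        gene = f"SLC{gi:03d}"
        for k in range(6):
            rows.append((f"{gene}_sg{k}", _spacer(), gene, "target"))
    for gi in range(20):
        gene = f"ESS{gi:02d}"
        for k in range(6):
            rows.append((f"{gene}_sg{k}", _spacer(), gene, "essential_control"))
    for k in range(120):
        rows.append((f"NT_{k:03d}", _spacer(), None, "non_targeting"))
    return pd.DataFrame(rows, columns=["sgrna_id", "spacer", "gene_id", "class"])


def make_design(n_replicates: int = 2) -> pd.DataFrame:
    """Sample sheet with ``n_replicates`` per time x treatment cell.

    The screened design had duplicate screens per condition; initial samples
    are library-representation controls taken before treatment.
    """
    rows = []
    for time in ("initial", "final"):
        for treatment in ("control", "treated"):
            for rep in range(1, n_replicates + 1):
                rows.append((f"{time[:4]}_{treatment[:4]}_r{rep}",
                             time, treatment, rep))
    return pd.DataFrame(rows, columns=["sample_id", "time", "treatment",
                                       "replicate"])


def validate_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "time", "treatment", "replicate"}
    if not required <= set(design.columns):
        raise ValueError(f"design sheet must have columns {sorted(required)}")
    bad_time = set(design["time"]) - {"initial", "final"}
    bad_treat = set(design["treatment"]) - {"control", "treated"}
    if bad_time or bad_treat:
        raise ValueError(f"unknown factor levels: {bad_time | bad_treat}")
    final = design[design["time"] == "final"]
    if not (design["time"] == "initial").any():
        raise ValueError("design needs at least one initial sample")
    if not ((final["treatment"] == "treated").any()
            and (final["treatment"] == "control").any()):
        raise ValueError("design needs treated-final and control-final samples")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")


@dataclass
class CrisprSimParams:
    """Defaults mirror the screened conditions: a skewed (log-normal) library
    infected at high coverage, negative-binomial sequencing noise, duplicate
    screens, and efficacious resistance-gene guides enriching in
    treated-final samples."""

    library: pd.DataFrame = field(default_factory=make_slc_library)
    design: pd.DataFrame = field(default_factory=make_design)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    resistance_genes: set[str] = field(default_factory=set)
    effect_lfc: float = 2.0
    efficacy_prob: float = 0.8
    essential_depletion_lfc: float = 1.0  # essential guides drop with time
    library_coverage: float = 500.0  # mean count per sgRNA per sample
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0 <= self.efficacy_prob <= 1):
            raise ValueError("efficacy_prob must lie in [0, 1]")
        validate_design(self.design)
        lib = self.library
        if lib["sgrna_id"].duplicated().any() or lib["spacer"].duplicated().any():
            raise ValueError("library sgrna_ids and spacers must be unique")
        targeted = set(lib.loc[lib["gene_id"].notna(), "gene_id"])
        unknown = self.resistance_genes - targeted
        if unknown:
            raise ValueError(f"resistance genes not in library: {sorted(unknown)}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion alpha (var = mu + alpha mu^2)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_crispr_counts(
    params: CrisprSimParams,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate an sgRNA x sample count matrix plus the truth ledger.

    count(i, j) ~ NB(mean = q_i * e_ij, dispersion) with q_i log-normal
    scaled to mean ``library_coverage``.  e_ij = 2^effect_lfc for efficacious
    resistance-gene guides in treated-final samples, 2^-essential_depletion_lfc
    for essential-control guides in all final samples, else 1.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lib = params.library.reset_index(drop=True)
    design = params.design.reset_index(drop=True)
    n_g, n_s = len(lib), len(design)

    q = rng.lognormal(mean=0.0, sigma=params.baseline_log_sd, size=n_g)
    q *= params.library_coverage / q.mean()

    is_res_gene = lib["gene_id"].isin(params.resistance_genes).to_numpy()
    efficacious = rng.random(n_g) < params.efficacy_prob
    truly_enriched = is_res_gene & efficacious
    is_essential = (lib["class"] == "essential_control").to_numpy()

    final = (design["time"] == "final").to_numpy()
    treated_final = final & (design["treatment"] == "treated").to_numpy()

    log2_e = np.zeros((n_g, n_s))
    log2_e[np.ix_(truly_enriched, treated_final)] = params.effect_lfc
    log2_e[np.ix_(is_essential, final)] -= params.essential_depletion_lfc
    mean = q[:, None] * np.exp2(log2_e)
    counts = _nb_sample(rng, mean, params.dispersion)

    matrix = pd.DataFrame(counts, index=lib["sgrna_id"],
                          columns=design["sample_id"])
    matrix.index.name = "sgrna_id"
    gene_truth = (
        lib.loc[lib["gene_id"].notna(), ["gene_id"]]
        .drop_duplicates()
        .assign(is_resistance=lambda d: d["gene_id"].isin(params.resistance_genes))
    )
    gene_truth["true_effect"] = np.where(gene_truth["is_resistance"],
                                         params.effect_lfc, 0.0)
    truth = ScreenTruth(
        genes=gene_truth.reset_index(drop=True),
        sgrnas=pd.DataFrame({
            "sgrna_id": lib["sgrna_id"],
            "efficacious": efficacious,
            "truly_enriched": truly_enriched,
        }),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# proteomics arm
# ---------------------------------------------------------------------------

def simulate_spectral_counts(
    n_proteins: int = 2000,
    n_diff: int = 0,
    effect_lfc: float = 2.0,
    dispersion: float = 0.2,
    mean_count: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spectral-count table under the 2 conditions x 2 biological x 2
    technical replicate layout the membrane-proteome comparison used.

    The first ``n_diff`` proteins are shifted up by ``effect_lfc`` log2 units
    in the case condition.  Returns (counts, design, truth).
    """
    if n_diff > n_proteins:
        raise ValueError("n_diff cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    design = pd.DataFrame([
        (f"{cond}_b{b}_t{t}", cond, b, t)
        for cond in ("case", "control") for b in (1, 2) for t in (1, 2)
    ], columns=["sample_id", "condition", "biological", "technical"])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_proteins)
    base *= mean_count / base.mean()
    shifted = np.zeros(n_proteins, dtype=bool)
    shifted[:n_diff] = True
    is_case = (design["condition"] == "case").to_numpy()
    mean = base[:, None] * np.exp2(
        np.where(shifted[:, None] & is_case[None, :], effect_lfc, 0.0)
    )
    counts = _nb_sample(rng, mean, dispersion)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    table = pd.DataFrame(counts, index=pd.Index(proteins, name="protein_id"),
                         columns=design["sample_id"])
    truth = pd.DataFrame({"protein_id": proteins, "is_shifted": shifted,
                          "true_effect": np.where(shifted, effect_lfc, 0.0)})
    return table, design, truth
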