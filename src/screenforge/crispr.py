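"""Pooled CRISPR screen caller: per-sgRNA negative-binomial differential
abundance under an additive time + treatment design, followed by GSEA-style
aggregation of significantly enriched sgRNAs to genes with the
>= 2-significant-sgRNA rule.

The per-sgRNA model is an NB GLM with log link,

    log mu_ij = beta0_i + betaT_i * [time_j = final]
              + betaR_i * [treatment_j = treated] + log s_j,

fitted by IRLS with a fixed per-sgRNA dispersion; the Wald statistic on the
treatment coefficient is the enrichment readout.  Initial (pre-treatment)
samples carry treatment = control regardless of the arm they seed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import enrichment_score, permutation_p
from .simulate import validate_design
from .stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "count_sgrnas",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "select_significant",
    "aggregate_to_genes",
    "run_crispr_screen",
    "read_library_tsv",
    "read_counts_tsv",
    "read_design_tsv",
]

LN2 = float(np.log(2.0))
ALPHA_MIN = 1e-8


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def _iter_read_seqs(reads):
    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        from Bio import SeqIO

        for rec in SeqIO.parse(reads, "fastq"):
            yield str(rec.seq)
    else:
        for r in reads:
            yield str(getattr(r, "seq", r))


def count_sgrnas(
    reads, library: pd.DataFrame, hamming1: bool = False
) -> tuple[pd.Series, dict]:
    """Assign reads to library spacers by exact substring match.

    A read counts for the unique spacer it contains; reads containing no
    spacer are unassigned, reads containing two or more distinct spacers are
    ambiguous and dropped.  ``hamming1`` additionally rescues reads whose
    best window is one mismatch from a unique spacer (off by default).
    """
    if library["spacer"].duplicated().any():
        raise ValueError("duplicate spacers in library index")
    lengths = library["spacer"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError("all spacers must have the same length")
    k = int(lengths[0])
    lookup = dict(zip(library["spacer"], library["sgrna_id"]))
    counts = pd.Series(0, index=pd.Index(library["sgrna_id"], name="sgrna_id"))
    qc = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    for seq in _iter_read_seqs(reads):
        windows = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        matches = {lookup[w] for w in windows if w in lookup}
        if not matches and hamming1:
            for w in windows:
                for i, base in enumerate(w):
                    for alt in "ACGT":
                        if alt != base:
                            v = w[:i] + alt + w[i + 1:]
                            if v in lookup:
                                matches.add(lookup[v])
        if len(matches) == 1:
            counts[matches.pop()] += 1
            qc["assigned"] += 1
        elif not matches:
            qc["unassigned"] += 1
        else:
            qc["ambiguous"] += 1
    return counts, qc


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample scaling, rescaled to geometric mean 1.

    s_j = median over all-positive sgRNAs of count_ij / geomean_i(count).
    Falls back to total-count scaling (with a warning) when no sgRNA has
    positive counts in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        geomean = np.exp(np.log(sub).mean(axis=1))
        s = np.median(sub / geomean[:, None], axis=0)
    else:
        warnings.warn("no sgRNA with all-positive counts; "
                      "falling back to total-count size factors")
        totals = mat.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total count")
        s = totals
    s = s / np.exp(np.log(s).mean())
    return pd.Series(s, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.DataFrame,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-sgRNA NB dispersion with trend shrinkage.

    Method-of-moments alpha per sgRNA is pooled across design cells (time x
    treatment groups with >= 2 samples): alpha_hat = weighted mean over cells
    of (var - mean) / mean^2 with df weights.  A mean-dispersion trend
    alpha(mu) = a0 + a1/mu is least-squares fitted over sgRNAs with positive
    alpha_hat, and the final value is the log-space midpoint of the per-sgRNA
    estimate and the trend, floored at ``alpha_min``.
    """
    s = size_factors.loc[counts.columns].to_numpy()
    y = counts.to_numpy(dtype=float) / s
    cells = design.set_index("sample_id").loc[counts.columns]
    labels = cells["time"].astype(str) + "/" + cells["treatment"].astype(str)

    num = np.zeros(y.shape[0])
    den = 0.0
    for lab in labels.unique():
        cols = (labels == lab).to_numpy()
        n_c = int(cols.sum())
        if n_c < 2:
            continue
        sub = y[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += (n_c - 1) * term
        den += n_c - 1
    if den == 0:
        raise ValueError("no design cell with >= 2 samples")
    alpha_hat = num / den

    mu = y.mean(axis=1)
    fit_mask = (alpha_hat > 0) & (mu > 0)
    if fit_mask.sum() >= 2:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, alpha_hat[fit_mask], rcond=None)
        trend = coef[0] + coef[1] / np.maximum(mu, 1e-12)
    else:
        trend = np.full_like(alpha_hat, max(np.median(alpha_hat), alpha_min))
    alpha_hat = np.maximum(alpha_hat, alpha_min)
    trend = np.maximum(trend, alpha_min)
    final = np.exp(0.5 * (np.log(alpha_hat) + np.log(trend)))
    final = np.maximum(final, alpha_min)
    return pd.Series(final, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB Wald test (vectorized IRLS across sgRNAs)
# ---------------------------------------------------------------------------

def design_matrix(design: pd.DataFrame, sample_order) -> np.ndarray:
    """[1, time==final, treatment==treated] rows; initial samples are coded
    as untreated since treatment has not yet been applied."""
    d = design.set_index("sample_id").loc[list(sample_order)]
    final = (d["time"] == "final").to_numpy(dtype=float)
    treated = ((d["treatment"] == "treated") & (d["time"] == "final")).to_numpy(
        dtype=float
    )
    return np.column_stack([np.ones(len(d)), final, treated])


def _nb_deviance(y, mu, alpha):
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    a = alpha[:, None]
    term2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Per-sgRNA NB Wald test of the treatment coefficient.

    Fits every sgRNA's GLM simultaneously by IRLS (working weights
    w = mu / (1 + alpha * mu)); convergence is a deviance change below
    ``tol``.  The Wald z is beta_treated / SE from the observed information
    X' W X; p-values are two-sided and BH-adjusted across all sgRNAs.
    Non-converged or all-zero sgRNAs are reported with p = 1 and flagged.
    """
    validate_design(design)
    X = design_matrix(design, counts.columns)
    Y = counts.to_numpy(dtype=float)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(s)[None, :]
    disp = dispersions.loc[counts.index].to_numpy(dtype=float)
    G, S = Y.shape
    P = X.shape[1]

    nonzero = Y.sum(axis=1) > 0
    beta = np.zeros((G, P))
    beta[:, 0] = np.log(np.maximum((Y / s).mean(axis=1), 1e-8))
    eta = beta @ X.T + offset
    mu = np.maximum(np.exp(np.clip(eta, -30, 30)), 1e-10)
    dev = _nb_deviance(Y, mu, disp)
    converged = ~nonzero  # degenerate rows are never iterated
    ridge = 1e-10 * np.eye(P)

    for _ in range(max_iter):
        W = mu / (1.0 + disp[:, None] * mu)
        z = (eta - offset) + (Y - mu) / mu
        XtWX = np.einsum("sp,gs,sq->gpq", X, W, X) + ridge
        XtWz = np.einsum("sp,gs,gs->gp", X, W, z)
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        beta = np.where(converged[:, None], beta, new_beta)
        eta = beta @ X.T + offset
        mu = np.maximum(np.exp(np.clip(eta, -30, 30)), 1e-10)
        new_dev = _nb_deviance(Y, mu, disp)
        delta = np.abs(new_dev - dev)
        dev = new_dev
        converged = converged | (delta < tol)
        if converged.all():
            break

    W = mu / (1.0 + disp[:, None] * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, W, X) + ridge
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(cov[:, P - 1, P - 1], 0.0))

    ok = nonzero & converged & (se > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_z = np.where(ok, beta[:, P - 1] / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(ok, 2.0 * norm.sf(np.abs(wald_z)), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    n_bad = int((~(nonzero & converged)).sum())
    if n_bad:
        log.info("%d sgRNAs degenerate or non-converged; reported with p = 1",
                 n_bad)
    padj = bh_adjust(p)
    log2fc = np.where(nonzero, beta[:, P - 1] / LN2, 0.0)
    out = pd.DataFrame({
        "sgrna_id": counts.index,
        "log2fc": log2fc,
        "se": se / LN2,
        "wald_z": wald_z,
        "p": p,
        "padj": padj,
        "converged": nonzero & converged,
    })
    out["significant_enriched"] = (out["padj"] <= alpha) & (out["log2fc"] > 0)
    return out


def select_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significantly enriched sgRNAs (padj <= alpha and log2fc > 0), stably
    sorted by descending log2 fold change."""
    sig = results[(results["padj"] <= alpha) & (results["log2fc"] > 0)]
    return sig.sort_values("log2fc", ascending=False, kind="mergesort",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# gene aggregation
# ---------------------------------------------------------------------------

def aggregate_to_genes(
    ranked: pd.DataFrame,
    library: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_sgrnas: int = 2,
    significant_ids: set | None = None,
) -> pd.DataFrame:
    """GSEA aggregation of a ranked sgRNA list to gene hits.

    ``ranked`` carries sgrna_id and log2fc, sorted by descending log2fc.  For
    every gene with at least ``min_sgrnas`` significantly enriched sgRNAs the
    enrichment score of its guides within the ranked list is computed (weight
    exponent 1) with a permutation p-value, and p-values are BH-adjusted
    across tested genes.  ``significant_ids`` defaults to all ranked sgRNAs
    (the ranked list is then the significant-only list); aLFC is the mean
    log2fc of the gene's significantly enriched guides.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation p floor")
    if ranked.empty:
        return pd.DataFrame(columns=["gene_id", "n_sig_sgrnas", "alfc", "es",
                                     "p_perm", "padj"])
    lib = library.set_index("sgrna_id")
    gene_of = lib["gene_id"]
    ranked = ranked.reset_index(drop=True)
    ranked_genes = ranked["sgrna_id"].map(gene_of)
    if significant_ids is None:
        significant_ids = set(ranked["sgrna_id"])
    scores = ranked["log2fc"].to_numpy(dtype=float)

    rows = []
    rng = np.random.default_rng(seed)
    for gene, idx in ranked.groupby(ranked_genes).groups.items():
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        members = ranked.loc[idx, "sgrna_id"]
        n_sig = int(members.isin(significant_ids).sum())
        if n_sig < min_sgrnas:
            continue
        mask = np.zeros(len(ranked), dtype=bool)
        mask[np.asarray(idx, dtype=int)] = True
        sig_members = members[members.isin(significant_ids)]
        alfc = float(ranked.loc[sig_members.index, "log2fc"].mean())
        es, p = permutation_p(
            scores, member_mask=mask, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows.append((gene, n_sig, alfc, es, p))
    hits = pd.DataFrame(rows, columns=["gene_id", "n_sig_sgrnas", "alfc",
                                       "es", "p_perm"])
    if hits.empty:
        hits["padj"] = pd.Series(dtype=float)
        return hits
    hits["padj"] = bh_adjust(hits["p_perm"].to_numpy())
    return hits.sort_values(
        ["padj", "p_perm", "n_sig_sgrnas", "gene_id"],
        ascending=[True, True, False, True],
        ignore_index=True,
    )


def run_crispr_screen(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    rank_all: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end two-step screen analysis.

    Step 1: size factors, dispersion shrinkage and the per-sgRNA NB Wald test.
    Step 2: significant enriched sgRNAs (padj <= alpha, log2fc > 0) sorted by
    log2fc feed the GSEA aggregation to genes; only genes with >= 2
    significant sgRNAs are reported.  With ``rank_all`` the ranked list
    contains every sgRNA instead of the significant-only subset (the >= 2
    rule still applies).  Returns (per-sgRNA results, gene hits).
    """
    s = size_factors(counts)
    disp = estimate_dispersion(counts, s, design)
    results = nb_wald_test(counts, design, s, disp, alpha=alpha)
    sig = select_significant(results, alpha=alpha)
    log.info("%d / %d sgRNAs significantly enriched at BH %g",
             len(sig), len(results), alpha)
    if rank_all:
        ranked = results.sort_values("log2fc", ascending=False,
                                     kind="mergesort", ignore_index=True)
        gene_hits = aggregate_to_genes(
            ranked[["sgrna_id", "log2fc"]], library, n_perm=n_perm, seed=seed,
            significant_ids=set(sig["sgrna_id"]),
        )
    else:
        gene_hits = aggregate_to_genes(
            sig[["sgrna_id", "log2fc"]], library, n_perm=n_perm, seed=seed,
        )
    return results, gene_hits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_library_tsv(path) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t")
    required = {"sgrna_id", "spacer", "gene_id", "class"}
    if not required <= set(lib.columns):
        raise ValueError(f"library index needs columns {sorted(required)}")
    lib["gene_id"] = lib["gene_id"].where(lib["gene_id"].notna(), None)
    return lib


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    validate_design(design)
    return design
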