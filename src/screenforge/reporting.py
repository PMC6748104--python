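"""Assay-level utilities and figure-data exports.

Covers the two simple readouts that accompany screen validation — viability
normalization against untreated controls and the GFP+/mCherry+ multi-color
competition index — plus writers for the plot-ready hit tables (Circos-style
dot tables for gene-trap screens, bubble tables for CRISPR screens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionMeasurement",
    "normalize_viability",
    "competition_index",
    "export_circos_table",
    "export_bubble_table",
]


def normalize_viability(raw, untreated_refs) -> np.ndarray:
    """Luminescence values as fractions of the mean untreated control."""
    refs = np.asarray(untreated_refs, dtype=float)
    if refs.size == 0 or refs.mean() <= 0:
        raise ValueError("untreated reference mean must be positive")
    return np.asarray(raw, dtype=float) / refs.mean()


@dataclass(frozen=True)
class CompetitionMeasurement:
    """Flow-cytometry readout of a 1:1 GFP+/mCherry+ co-culture."""

    condition: str
    pct_gfp: float
    pct_mcherry: float
    is_reference: bool = False

    def __post_init__(self):
        if not (0 <= self.pct_gfp <= 100 and 0 <= self.pct_mcherry <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.pct_gfp + self.pct_mcherry > 100:
            raise ValueError("GFP+ and mCherry+ fractions exceed 100%")


def competition_index(
    treated: CompetitionMeasurement, untreated: CompetitionMeasurement
) -> float | None:
    """Selective advantage of the GFP+ (sgRNA) population under treatment.

    (GFP/mCherry)_treated / (GFP/mCherry)_untreated; 1.0 means no advantage.
    Returns None ('n.d.') when a well shows no mCherry+ outgrowth.
    """
    if treated.pct_mcherry == 0 or untreated.pct_mcherry == 0 \
            or untreated.pct_gfp == 0:
        return None
    return (treated.pct_gfp / treated.pct_mcherry) / (
        untreated.pct_gfp / untreated.pct_mcherry
    )


def export_circos_table(hits: pd.DataFrame, path) -> None:
    """Gene-trap hit table in the dot-plot encoding: dot size = number of
    independent insertions, radial distance = -log10 adjusted p, strong
    drivers labeled."""
    out = pd.DataFrame({
        "gene_id": hits.get("gene_id", pd.Series(dtype=str)),
        "n_insertions": hits.get("n_insertions_selected",
                                 pd.Series(dtype=int)),
        "neg_log10_padj": -np.log10(hits["padj"]) if len(hits) else
        pd.Series(dtype=float),
        "labeled": hits.get("labeled", pd.Series(dtype=bool)),
    })
    out.to_csv(path, sep="\t", index=False)


def export_bubble_table(gene_hits: pd.DataFrame, path) -> None:
    """CRISPR gene-hit table in the bubble-plot encoding: bubble size =
    number of significantly enriched sgRNAs, color = aLFC, position =
    -log10 adjusted p."""
    out = pd.DataFrame({
        "gene_id": gene_hits.get("gene_id", pd.Series(dtype=str)),
        "n_sig_sgrnas": gene_hits.get("n_sig_sgrnas", pd.Series(dtype=int)),
        "alfc": gene_hits.get("alfc", pd.Series(dtype=float)),
        "neg_log10_padj": -np.log10(gene_hits["padj"]) if len(gene_hits)
        else pd.Series(dtype=float),
    })
    out.to_csv(path, sep="\t", index=False)
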