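"""Transcriptome integration: FPKM, group fold changes, and the
transcript-protein abundance correlation.

Transcript differential calling is consumed, not reimplemented: this
module prepares fold-change profiles (with a pseudocount-stabilized log)
for the 2-D enrichment comparison and computes the cross-feature Pearson
correlation between log FPKM and log protein abundance, using group-mean
pairing by default because the proteome and RNA animals differ.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import stats
from .containers import AbundanceMatrix
from .synthetic import StudyDesign


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, float] | pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (length_bp * library_size).

    Library sizes default to the column sums (total mapped reads per
    sample).  Zero or negative gene lengths raise, naming the gene.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes without lengths: {missing[:10]}")
    bad = lengths.index[lengths <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive gene length for: {bad[:10]}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1.0e9).div(lengths, axis=0).div(library_sizes, axis=1)


def group_means(table: pd.DataFrame, design: StudyDesign, assay: str = "rna") -> pd.DataFrame:
    cols = {}
    for g in design.groups:
        samples = [s for s in design.samples_for(assay, g) if s in table.columns]
        if samples:
            cols[g] = table[samples].mean(axis=1)
    return pd.DataFrame(cols)


def group_fold_changes(
    group_mean_expr: pd.DataFrame,
    control: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2((mean_g + pc) / (mean_control + pc)) per non-control group."""
    if control not in group_mean_expr.columns:
        raise ValueError(f"control group {control!r} absent")
    ctrl = group_mean_expr[control] + pseudocount
    out = {}
    for g in group_mean_expr.columns:
        if g == control:
            continue
        out[g] = np.log2((group_mean_expr[g] + pseudocount) / ctrl)
    return pd.DataFrame(out)


def protein_transcript_correlation(
    protein_matrix: AbundanceMatrix,
    fpkm: pd.DataFrame,
    design: StudyDesign,
    id_map: Optional[Mapping[str, str]] = None,
    pseudocount: float = 1.0,
    logger=None,
) -> tuple[float, int]:
    """Cross-feature Pearson r between log FPKM and log protein abundance.

    Protein features map to genes through ``id_map`` (identity by
    default).  Both sides are averaged per group and then across groups
    (group-mean pairing: the proteome and RNA-seq animals are different
    mice), log-transformed with a pseudocount on the FPKM side.  Returns
    (r, matched feature count) and logs the mapped coverage.
    """
    id_map = dict(id_map) if id_map is not None else {f: f for f in protein_matrix.feature_ids}
    mapped = {f: g for f, g in id_map.items()
              if f in protein_matrix.values.index and g in fpkm.index}
    coverage = len(mapped) / max(1, len(protein_matrix.feature_ids))
    if logger is not None:
        logger.log(f"protein_transcript_correlation: matched {len(mapped)} features "
                   f"({coverage:.0%} of proteins)", matched=len(mapped))
    if coverage < 0.5 and logger is not None:
        logger.log("warning: fewer than half of the proteins map to transcripts")
    if len(mapped) < 3:
        raise ValueError("fewer than 3 matched protein-transcript features")
    prots = list(mapped)
    genes = [mapped[f] for f in prots]
    if protein_matrix.value_scale == "raw_intensity":
        prot_vals = np.log2(
            protein_matrix.values.loc[prots].mean(axis=1).to_numpy(dtype=float) + pseudocount
        )
    else:  # already on a log scale (log2_intensity); ratios would be centered
        prot_vals = protein_matrix.values.loc[prots].mean(axis=1).to_numpy(dtype=float)
    rna_vals = np.log2(fpkm.loc[genes].mean(axis=1).to_numpy(dtype=float) + pseudocount)
    r, _p = stats.correlation(prot_vals, rna_vals, method="pearson")
    return r, len(mapped)
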