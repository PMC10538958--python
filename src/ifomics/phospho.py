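"""Phosphoproteome stage: class-I site filtering, down-shifted normal
imputation, Dunnett differential calling and sign-pattern clustering of the
significant sites, plus flanking-window extraction.

The pipeline order is fixed: class-I filter, then the >=2-replicates-per-
group filter on observed values, then per-sample imputation, then testing —
so no site is ever tested on purely imputed values in any group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .io import PHOSPHO_META_COLS
from .proteome import DifferentialRecord, differential_proteome
from .synthetic import StudyDesign


def filter_class1(sites: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Keep class-I sites: localization probability >= threshold (inclusive)."""
    probs = sites["localization_prob"]
    if probs.isna().any():
        bad = sites.loc[probs.isna(), "id"].tolist()
        raise ValueError(f"sites with missing localization probability: {bad}")
    return sites.loc[probs >= threshold].reset_index(drop=True)


def sites_to_matrix(sites: pd.DataFrame, design: StudyDesign) -> AbundanceMatrix:
    """Phosphosite table -> log2-intensity AbundanceMatrix (samples only)."""
    sample_cols = [c for c in sites.columns if c not in PHOSPHO_META_COLS]
    values = sites.set_index("id")[sample_cols].astype(float)
    groups = {s: design.group_of(s) for s in sample_cols}
    return AbundanceMatrix(values=values, sample_groups=groups,
                           value_scale="log2_intensity")


def impute_downshifted_normal(
    matrix: AbundanceMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int = 0,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Per-sample down-shifted normal imputation of missing log intensities.

    For each sample with observed mean mu and sd s, missing cells draw
    i.i.d. from Normal(mu - shift*s, (width*s)^2) — the convention for
    representing intensities of proteins near the detection limit.
    Returns the completed matrix and a boolean audit table flagging the
    imputed cells.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    audit = values.isna()
    for sample in values.columns:
        col = values[sample]
        observed = col.dropna()
        if observed.empty:
            raise ValueError(f"sample {sample!r} has no observed values")
        if observed.size < 3:
            raise ValueError(f"sample {sample!r} has fewer than 3 observed values")
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - shift * sd, width * sd, n_missing)
        values.loc[col.isna(), sample] = draws
    return matrix.with_values(values), audit


def differential_phospho(
    matrix: AbundanceMatrix,
    control: str = "AL",
    alpha: float = 0.05,
    min_per_group: int = 2,
    width: float = 0.3,
    shift: float = 1.8,
    mc_reps: int = 50_000,
    seed: int = 0,
    logger=None,
) -> tuple[list[DifferentialRecord], pd.DataFrame]:
    """Replicate-filter, impute, then test phosphosites against control.

    Flags use the inclusive ``adjusted p <= alpha`` rule.  Returns the
    differential records together with a cluster-assignment table: every
    significant site is labelled by the sign pattern of its significant
    group effects (e.g. ``IF12+/EOD-``), the deterministic stand-in for a
    hierarchical-cluster cut when selecting altered-site clusters for
    kinase motif enrichment.
    """
    from .proteome import filter_min_replicates

    filtered = filter_min_replicates(matrix, min_per_group, logger=logger)
    completed, audit = impute_downshifted_normal(filtered, width, shift, seed)
    records = differential_proteome(
        completed, control=control, alpha=alpha, strict=False,
        mc_reps=mc_reps, seed=seed,
    )
    if logger is not None:
        n_sig = sum(any(r.significant.values()) for r in records)
        logger.log(f"differential_phospho: {n_sig} significant sites of {len(records)}",
                   sites_tested=len(records), sites_significant=n_sig,
                   cells_imputed=int(audit.to_numpy().sum()))
    rows = []
    for r in records:
        pattern = "/".join(
            f"{g}{'+' if r.log2_fc[g] > 0 else '-'}"
            for g, sig in r.significant.items() if sig
        )
        if pattern:
            rows.append({"id": r.feature, "cluster": pattern})
    clusters = pd.DataFrame(rows, columns=["id", "cluster"])
    return records, clusters


def extract_window(sequence: str, position: int, half_width: int = 6) -> str:
    """Flanking window around a 1-based residue position, '_'-padded."""
    if not sequence.isalpha():
        raise ValueError("sequence must be alphabetic")
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    idx = position - 1
    left = sequence[max(0, idx - half_width): idx]
    right = sequence[idx + 1: idx + 1 + half_width]
    return ("_" * (half_width - len(left)) + left
            + sequence[idx]
            + right + "_" * (half_width - len(right)))
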