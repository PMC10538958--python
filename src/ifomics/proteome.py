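"""TMT proteome stage: reporter normalization, reference-channel ratios,
replicate filtering, and Dunnett differential calling against the control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import stats
from .containers import AbundanceMatrix
from .synthetic import StudyDesign


@dataclass
class DifferentialRecord:
    """Per-feature result of the many-to-one differential test."""

    feature: str
    log2_fc: dict[str, float]          # group -> mean difference vs control
    p_raw: dict[str, float]
    p_adjusted: dict[str, float]
    significant: dict[str, bool]
    degenerate: bool = False


def normalize_tmt_and_ratio(
    tables: dict[str, pd.DataFrame],
    design: StudyDesign,
    logger=None,
) -> AbundanceMatrix:
    """Equal-total-intensity normalization then log2 reference ratios.

    Within each plex every channel column is rescaled so its total equals
    the grand mean of the channel totals; each sample value then becomes
    log2(normalized sample intensity / normalized reference intensity) for
    that protein, using the reference channel of the sample's own plex.
    Plexes are merged on protein id (outer join).  Proteins with a zero
    reference intensity in a plex become missing there (count logged).
    """
    merged: Optional[pd.DataFrame] = None
    zero_ref_total = 0
    for plex in design.plex_ids:
        table = tables[plex]
        if np.any(table.to_numpy() < 0):
            raise ValueError(f"negative intensities in plex {plex!r}")
        ref_channel = design.reference_channel[plex]
        if ref_channel not in table.columns:
            raise ValueError(f"reference channel {ref_channel!r} missing from plex {plex!r}")
        totals = table.sum(axis=0)
        normalized = table * (totals.mean() / totals)
        ref = normalized[ref_channel]
        zero_ref = ref <= 0
        zero_ref_total += int(zero_ref.sum())
        cols = {}
        for sample, (p, channel) in design.plex_assignment.items():
            if p != plex:
                continue
            ratio = np.log2(normalized[channel].where(~zero_ref) /
                            ref.where(~zero_ref))
            cols[sample] = ratio
        part = pd.DataFrame(cols)
        merged = part if merged is None else merged.join(part, how="outer")
    if logger is not None:
        logger.log(f"normalize_tmt_and_ratio: {len(merged)} proteins, "
                   f"{zero_ref_total} zero-reference values set missing",
                   proteins=len(merged), zero_reference=zero_ref_total)
    sample_order = design.proteome_samples()
    merged = merged[[s for s in sample_order if s in merged.columns]]
    groups = {s: design.group_of(s) for s in merged.columns}
    plex_map = {s: design.plex_assignment[s][0] for s in merged.columns}
    return AbundanceMatrix(values=merged, sample_groups=groups,
                           value_scale="log2_ratio", sample_plex=plex_map)


def normalized_log2_intensity(
    tables: dict[str, pd.DataFrame],
    design: StudyDesign,
) -> AbundanceMatrix:
    """Equal-total-intensity normalized log2 abundances (no reference ratio).

    This is the "normalized protein abundance" scale used for the
    transcript-protein correlation, where the between-protein abundance
    spread must be preserved.
    """
    merged: Optional[pd.DataFrame] = None
    for plex in design.plex_ids:
        table = tables[plex]
        totals = table.sum(axis=0)
        normalized = table * (totals.mean() / totals)
        cols = {}
        for sample, (p, channel) in design.plex_assignment.items():
            if p != plex:
                continue
            cols[sample] = np.log2(normalized[channel].where(normalized[channel] > 0))
        part = pd.DataFrame(cols)
        merged = part if merged is None else merged.join(part, how="outer")
    sample_order = design.proteome_samples()
    merged = merged[[s for s in sample_order if s in merged.columns]]
    groups = {s: design.group_of(s) for s in merged.columns}
    plex_map = {s: design.plex_assignment[s][0] for s in merged.columns}
    return AbundanceMatrix(values=merged, sample_groups=groups,
                           value_scale="log2_intensity", sample_plex=plex_map)


def filter_min_replicates(
    matrix: AbundanceMatrix, min_per_group: int = 3, logger=None
) -> AbundanceMatrix:
    """Keep features quantified in >= min_per_group samples of EVERY group."""
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    for g in matrix.groups:
        if len(matrix.samples_in_group(g)) < min_per_group:
            raise ValueError(f"min_per_group={min_per_group} exceeds size of group {g!r}")
    keep = pd.Series(True, index=matrix.values.index)
    for g in matrix.groups:
        counts = matrix.values[matrix.samples_in_group(g)].notna().sum(axis=1)
        keep &= counts >= min_per_group
    filtered = matrix.values.loc[keep]
    if logger is not None:
        logger.log(f"filter_min_replicates(min={min_per_group}): "
                   f"{len(matrix.values)} -> {len(filtered)} features",
                   features_in=len(matrix.values), features_out=len(filtered))
    return matrix.with_values(filtered)


def zscore_rows(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-feature z-scores across samples (mean 0, sd 1), for heatmaps."""
    v = matrix.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=0)
    return v.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)


def differential_proteome(
    matrix: AbundanceMatrix,
    control: str = "AL",
    alpha: float = 0.01,
    strict: bool = True,
    mc_reps: int = 50_000,
    seed: int = 0,
) -> list[DifferentialRecord]:
    """One-way ANOVA + Dunnett many-to-one differential calls per feature.

    Flags use a strict ``p < alpha`` by default (the proteome convention);
    pass ``strict=False`` for the inclusive ``p <= alpha`` rule used for
    phosphosites.
    """
    if control not in matrix.groups:
        raise ValueError(f"control group {control!r} absent")
    records = []
    for feature in matrix.feature_ids:
        groups = matrix.group_values(feature)
        res = stats.anova_dunnett(groups, control, mc_reps=mc_reps, seed=seed)
        ctrl_mean = float(np.nanmean(groups[control]))
        rec = DifferentialRecord(feature=feature, log2_fc={}, p_raw={},
                                 p_adjusted={}, significant={},
                                 degenerate=any(r.degenerate for r in res))
        for r in res:
            g = r.comparison.split(" vs ")[0]
            rec.log2_fc[g] = float(np.nanmean(groups[g])) - ctrl_mean
            rec.p_raw[g] = r.p_raw
            rec.p_adjusted[g] = r.p_adjusted
            rec.significant[g] = (
                r.p_adjusted < alpha if strict else r.p_adjusted <= alpha
            )
        records.append(rec)
    return records


def differential_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Flat table: one row per feature with per-group fc/p/q/flag columns."""
    if not records:
        return pd.DataFrame()
    groups = list(records[0].log2_fc)
    rows = []
    for r in records:
        row: dict = {"feature": r.feature}
        for g in groups:
            row[f"log2fc_{g}"] = r.log2_fc[g]
            row[f"p_{g}"] = r.p_raw[g]
            row[f"padj_{g}"] = r.p_adjusted[g]
            row[f"sig_{g}"] = r.significant[g]
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def significant_sets(records: list[DifferentialRecord]) -> dict[str, set]:
    """Per-group sets of features flagged significant."""
    out: dict[str, set] = {}
    for r in records:
        for g, flag in r.significant.items():
            if flag:
                out.setdefault(g, set()).add(r.feature)
    return out
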