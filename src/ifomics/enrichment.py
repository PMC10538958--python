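"""Annotation enrichment: Fisher exact over selected sets, and the
rank-based 1-D / 2-D position-score analyses over value profiles.

The 1-D/2-D position score s in [-1, 1] reports whether a term's members
sit at systematically higher (s > 0) or lower (s < 0) values than the
remaining features; significance comes from the Mann-Whitney test (1-D)
or a Hotelling-type T-squared on the rank-transformed coordinates (2-D),
with Benjamini-Hochberg control across the terms of each run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import stats
from .containers import AnnotationCollection


@dataclass
class EnrichmentRecord:
    term: str
    mode: str                     # fisher | 1d | 2d
    p: float
    q: float
    term_size: int
    score: Optional[float] = None      # s (1d) or None
    score_x: Optional[float] = None    # 2d
    score_y: Optional[float] = None
    overlap: Optional[int] = None      # fisher
    significant: bool = False


def fisher_enrichment(
    selected: set,
    universe: set,
    annotations: AnnotationCollection,
    fdr: float = 0.05,
    logger=None,
) -> list[EnrichmentRecord]:
    """Fisher exact (one-sided) term enrichment of a selected feature set.

    The 2x2 table is restricted to the supplied universe; terms with no
    members in the universe are skipped (logged).  Significance is
    ``q <= fdr``.
    """
    stray = selected - universe
    if stray:
        raise ValueError(f"selected features outside universe: {sorted(stray)[:10]}")
    N = len(universe)
    n_sel = len(selected)
    records = []
    skipped = []
    for term in sorted(annotations.terms):
        members = annotations.members(term) & universe
        if not members:
            skipped.append(term)
            continue
        K = len(members)
        k = len(members & selected)
        p = stats.hypergeom_upper_tail(N, K, n_sel, k)
        records.append(EnrichmentRecord(term=term, mode="fisher", p=p, q=np.nan,
                                        term_size=K, overlap=k))
    if skipped and logger is not None:
        logger.log(f"fisher_enrichment: skipped {len(skipped)} terms with no "
                   f"members in universe", skipped_terms=len(skipped))
    _attach_q(records, fdr)
    return records


def enrichment_1d(
    values: Mapping[str, float],
    annotations: AnnotationCollection,
    fdr: float = 0.05,
    min_size: int = 5,
    logger=None,
) -> list[EnrichmentRecord]:
    """1-D rank annotation enrichment over a feature -> value mapping.

    Positive scores mean term members concentrate at higher values.  Terms
    with fewer than ``min_size`` members carrying values are skipped.
    """
    features = sorted(values)
    vals = np.array([values[f] for f in features], dtype=float)
    index = {f: i for i, f in enumerate(features)}
    records = []
    skipped = 0
    for term in sorted(annotations.terms):
        members = annotations.members(term)
        flags = np.zeros(len(features), dtype=bool)
        for m in members:
            i = index.get(m)
            if i is not None:
                flags[i] = True
        n_in = int(flags.sum())
        if n_in < min_size or n_in == len(features):
            skipped += 1
            continue
        s, p = stats.position_score_1d(vals, flags)
        records.append(EnrichmentRecord(term=term, mode="1d", p=p, q=np.nan,
                                        term_size=n_in, score=s))
    if skipped and logger is not None:
        logger.log(f"enrichment_1d: skipped {skipped} terms below min_size={min_size}",
                   skipped_terms=skipped)
    _attach_q(records, fdr)
    return records


def enrichment_2d(
    values_x: Mapping[str, float],
    values_y: Mapping[str, float],
    annotations: AnnotationCollection,
    fdr: float = 0.05,
    min_size: int = 5,
    logger=None,
) -> list[EnrichmentRecord]:
    """2-D rank annotation enrichment over two value profiles (e.g. protein
    and transcript fold changes vs the control diet).

    Operates on the feature intersection of the two mappings; per-term
    scores come from the 1-D position score in each dimension and the
    p-value from a rank Hotelling T-squared.
    """
    shared = sorted(set(values_x) & set(values_y))
    if len(shared) < 2 * min_size:
        raise ValueError(
            f"intersection of the two profiles has only {len(shared)} features"
        )
    if logger is not None:
        logger.log(f"enrichment_2d: {len(shared)} features in both profiles",
                   shared_features=len(shared))
    x = np.array([values_x[f] for f in shared], dtype=float)
    y = np.array([values_y[f] for f in shared], dtype=float)
    index = {f: i for i, f in enumerate(shared)}
    records = []
    for term in sorted(annotations.terms):
        flags = np.zeros(len(shared), dtype=bool)
        for m in annotations.members(term):
            i = index.get(m)
            if i is not None:
                flags[i] = True
        n_in = int(flags.sum())
        if n_in < min_size or n_in == len(shared):
            continue
        s_x, s_y, p, _reg = stats.rank_manova_2d(x, y, flags)
        records.append(EnrichmentRecord(term=term, mode="2d", p=p, q=np.nan,
                                        term_size=n_in, score_x=s_x, score_y=s_y))
    _attach_q(records, fdr)
    return records


def _attach_q(records: list[EnrichmentRecord], fdr: float) -> None:
    if not records:
        return
    q = stats.bh_adjust([r.p for r in records])
    for r, qi in zip(records, q):
        r.q = float(qi)
        r.significant = r.q <= fdr


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "term": r.term, "mode": r.mode, "size": r.term_size,
            "score": r.score, "score_x": r.score_x, "score_y": r.score_y,
            "overlap": r.overlap, "p": r.p, "q": r.q, "significant": r.significant,
        })
    return pd.DataFrame(rows)


def scatter_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """(s_x, s_y) per significant 2-D term, ready for a scatter plot."""
    rows = [
        {"term": r.term, "score_x": r.score_x, "score_y": r.score_y, "q": r.q}
        for r in records
        if r.mode == "2d" and r.significant
    ]
    return pd.DataFrame(rows, columns=["term", "score_x", "score_y", "q"])
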