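"""Kinase substrate motif matching and per-cluster motif enrichment.

A motif is a set of positional residue constraints relative to the
phosphoacceptor (offset 0).  Matching is position-exact and case-
insensitive; the '_' padding character never satisfies a constraint.
Enrichment of a motif within a cluster of altered phosphosites uses the
one-sided Fisher exact test against the background of all quantified
sites, reported at raw p < 0.05 with a BH q column alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import stats


@dataclass(frozen=True)
class KinaseMotif:
    """Positional residue constraints; offset 0 is the phosphoacceptor."""

    name: str
    constraints: dict[int, frozenset]

    def __post_init__(self) -> None:
        if 0 not in self.constraints:
            raise ValueError(f"motif {self.name!r} lacks a center constraint")
        center = self.constraints[0]
        if not center <= {"S", "T", "Y"}:
            raise ValueError(f"motif {self.name!r}: center residues must be S/T/Y")

    @property
    def span(self) -> int:
        return max(abs(o) for o in self.constraints)


def match_motif(window: str, motif: KinaseMotif) -> bool:
    """True iff every constrained offset holds an allowed residue."""
    if len(window) % 2 == 0:
        raise ValueError("window length must be odd (centered on the site)")
    center = len(window) // 2
    if motif.span > center:
        raise ValueError(
            f"motif {motif.name!r} spans +/-{motif.span}, window half-width is {center}"
        )
    w = window.upper()
    for offset, allowed in motif.constraints.items():
        residue = w[center + offset]
        if residue == "_" or residue not in allowed:
            return False
    return True


def kinase_cluster_enrichment(
    site_clusters: dict[str, set],
    all_sites: dict[str, str],
    motifs: list[KinaseMotif],
    p_threshold: float = 0.05,
    logger=None,
) -> pd.DataFrame:
    """Fisher enrichment of each motif within each altered-site cluster.

    ``all_sites`` maps site id -> flanking window for the full quantified
    background; ``site_clusters`` maps cluster label -> site-id subset.
    Returns one row per (cluster, motif) with match counts, one-sided p,
    BH q (computed across the whole table) and the raw-p significance flag.
    """
    for label, members in site_clusters.items():
        stray = set(members) - set(all_sites)
        if stray:
            raise ValueError(f"cluster {label!r} has sites outside background: "
                             f"{sorted(stray)[:5]}")
    matches: dict[str, set] = {
        m.name: {sid for sid, win in all_sites.items() if match_motif(win, m)}
        for m in motifs
    }
    N = len(all_sites)
    rows = []
    for label in sorted(site_clusters):
        members = site_clusters[label]
        if not members:
            if logger is not None:
                logger.log(f"kinase_cluster_enrichment: skipped empty cluster {label!r}")
            continue
        for m in motifs:
            hit = matches[m.name]
            k = len(hit & members)
            p = stats.hypergeom_upper_tail(N, len(hit), len(members), k)
            rows.append({
                "cluster": label, "kinase": m.name,
                "cluster_size": len(members), "motif_matches": len(hit),
                "overlap": k, "p": p,
            })
    table = pd.DataFrame(rows, columns=["cluster", "kinase", "cluster_size",
                                        "motif_matches", "overlap", "p"])
    if not table.empty:
        table["q"] = stats.bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p"] < p_threshold
    return table
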