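"""Co-regulation perturbation analysis (IMAHP-style).

Pipeline: (1) Spearman correlation of every protein pair across all
samples, BH-filtered to a high-confidence co-regulation network;
(2) per-edge Mahalanobis distances of each sample from the pair's
bivariate distribution, screened for a single outlying sample with
Grubbs's test; (3) a hypergeometric test for proteins whose perturbation
instances concentrate in one dietary group; (4) extraction of the
annotated (e.g. mitochondrial) sub-network of consensus-perturbed
proteins with their retained co-regulation edges.

Distances have a known null under bivariate normality (the include-all
squared distance times n/(n-1)^2 is Beta(1, (n-3)/2)-distributed), so
they are mapped to exact-null normal scores before the Grubbs test,
which assumes normal values; on the raw chi-distributed distances the
test is anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .containers import AbundanceMatrix, AnnotationCollection, EdgeList, canonical_edge
from .synthetic import StudyDesign


@dataclass(frozen=True)
class CoregEdge:
    """A retained co-regulated protein pair."""

    pair: tuple[str, str]
    rho: float
    p: float
    q: float
    sign: int  # +1 positive, -1 negative co-regulation


@dataclass
class PerturbationEvent:
    """One sample's outlying deviation from one co-regulation edge."""

    sample: str
    pair: tuple[str, str]
    distance: float
    grubbs_G: float
    grubbs_p: float
    implicated: tuple[str, str]
    covariance_regularized: bool = False


def coreg_network(
    matrix: AbundanceMatrix,
    q_threshold: float = 0.01,
    logger=None,
) -> list[CoregEdge]:
    """All-pairs Spearman co-regulation network with BH FDR control.

    Samples from all groups are pooled; features with zero variance are
    excluded (logged); edges with q <= q_threshold are retained, keeping
    both positive and negative correlations.
    """
    if len(matrix.sample_ids) < 6:
        raise ValueError("need at least 6 samples for a stable correlation network")
    values = matrix.values.dropna(axis=0)
    variances = values.var(axis=1, ddof=1)
    degenerate = variances[variances == 0.0].index.tolist()
    if degenerate and logger is not None:
        logger.log(f"coreg_network: excluded {len(degenerate)} zero-variance features",
                   excluded_features=len(degenerate))
    values = values.drop(index=degenerate)
    features = list(values.index)
    n = values.shape[1]
    ranks = np.apply_along_axis(sps.rankdata, 1, values.to_numpy(dtype=float))
    corr = np.corrcoef(ranks)
    iu = np.triu_indices(len(features), k=1)
    rho = np.clip(corr[iu], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    q = stats.bh_adjust(p)
    keep = q <= q_threshold
    edges = []
    for i, j, r, pv, qv in zip(iu[0][keep], iu[1][keep], rho[keep], p[keep], q[keep]):
        pair = canonical_edge(features[i], features[j])
        edges.append(CoregEdge(pair=pair, rho=float(r), p=float(pv), q=float(qv),
                               sign=1 if r >= 0 else -1))
    if logger is not None:
        logger.log(f"coreg_network: {len(edges)} of {len(p)} pairs retained at "
                   f"q<={q_threshold}", pairs_tested=len(p), edges_retained=len(edges))
    return edges


def _distance_normal_scores(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Mahalanobis distances of each row of X (n x 2) from the sample
    mean/covariance, plus their exact-null normal scores.

    With mean and covariance estimated from all n points, d^2 * n/(n-1)^2
    follows Beta(p/2, (n-p-1)/2) under multivariate normality; mapping
    through that cdf and the normal quantile yields marginally standard-
    normal scores on which Grubbs's test is calibrated.
    """
    n, p = X.shape
    mu = X.mean(axis=0)
    S = np.cov(X.T)
    regularized = False
    if np.linalg.cond(S) > 1e8:
        S = S + 1e-6 * (np.trace(S) / p) * np.eye(p)
        regularized = True
    diff = X - mu
    d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(S), diff)
    d2 = np.maximum(d2, 0.0)
    u = sps.beta.cdf(d2 * n / (n - 1) ** 2, p / 2.0, (n - p - 1) / 2.0)
    z = sps.norm.ppf(np.clip(u, 1e-15, 1.0 - 1e-15))
    return np.sqrt(d2), z, regularized


def sample_deviations(
    matrix: AbundanceMatrix,
    edges: list[CoregEdge],
    grubbs_alpha: float = 0.1,
    outlier_test: str = "max_normal",
    logger=None,
) -> list[PerturbationEvent]:
    """Per-edge outlier screen for sample-specific perturbations.

    For each retained edge, every sample's (x_i, x_j) is scored by
    Mahalanobis distance against the bivariate mean/covariance estimated
    from all samples, and the distances are mapped to their exact-null
    standard-normal scores.  The default single-outlier screen
    (``outlier_test="max_normal"``) is the one-sided maximum test with
    Bonferroni correction on that known null — the known-scale form of
    Grubbs's procedure, calibrated here because re-estimating the scale
    from the scores (classical Grubbs, ``outlier_test="grubbs"``) is
    biased by the sum constraint the estimated covariance imposes.  When
    significant at ``grubbs_alpha``, the maximum-distance sample is
    recorded as a perturbation implicating both member proteins.
    """
    if outlier_test not in ("max_normal", "grubbs"):
        raise ValueError(f"unknown outlier_test {outlier_test!r}")
    values = matrix.values
    samples = matrix.sample_ids
    events = []
    skipped = 0
    for edge in edges:
        a, b = edge.pair
        sub = values.loc[[a, b]].to_numpy(dtype=float).T  # n x 2
        if np.isnan(sub).any():
            skipped += 1
            continue
        if np.any(sub.std(axis=0) == 0.0):
            skipped += 1
            continue
        d, z, reg = _distance_normal_scores(sub)
        res = stats.grubbs_one_sided_max(z, alpha=grubbs_alpha)
        if outlier_test == "max_normal":
            idx = int(np.argmax(z))
            p = float(min(1.0, len(z) * sps.norm.sf(z[idx])))
        else:
            idx, p = res.index, res.p
        if p <= grubbs_alpha:
            events.append(PerturbationEvent(
                sample=samples[idx], pair=edge.pair, distance=float(d[idx]),
                grubbs_G=res.G, grubbs_p=p, implicated=edge.pair,
                covariance_regularized=reg,
            ))
    if skipped and logger is not None:
        logger.log(f"sample_deviations: skipped {skipped} degenerate/missing edges",
                   skipped_edges=skipped)
    return events


def perturbation_instances(events: list[PerturbationEvent]) -> set[tuple[str, str]]:
    """Deduplicated (sample, protein) perturbation instances.

    A protein counts once per sample no matter how many of its edges
    flagged that sample, so high-degree proteins do not inflate their own
    background.
    """
    out: set[tuple[str, str]] = set()
    for ev in events:
        for prot in ev.implicated:
            out.add((ev.sample, prot))
    return out


def consensus_perturbed(
    events: list[PerturbationEvent],
    design: StudyDesign,
    p_threshold: float = 0.05,
    logger=None,
) -> pd.DataFrame:
    """Hypergeometric test for group-consensus perturbed proteins.

    Population: all deduplicated (sample, protein) instances.  For group g
    and protein P: N = all instances, K = instances of P, n = instances in
    g's samples, k = instances of P in g; P is consensus-perturbed in g
    iff the upper-tail p <= p_threshold.
    """
    instances = perturbation_instances(events)
    if not instances:
        if logger is not None:
            logger.log("consensus_perturbed: no perturbation events; empty result")
        return pd.DataFrame(columns=["group", "protein", "k", "n", "K", "N",
                                     "p", "consensus"])
    N = len(instances)
    proteins = sorted({p for _s, p in instances})
    rows = []
    for group in design.groups:
        in_group = {(s, p) for s, p in instances if design.group_of(s) == group}
        n = len(in_group)
        if n == 0:
            continue
        for prot in proteins:
            K = sum(1 for _s, p in instances if p == prot)
            k = sum(1 for _s, p in in_group if p == prot)
            if k == 0:
                continue
            p_val = stats.hypergeom_upper_tail(N, K, n, k)
            rows.append({"group": group, "protein": prot, "k": k, "n": n,
                         "K": K, "N": N, "p": p_val,
                         "consensus": p_val <= p_threshold})
    return pd.DataFrame(rows, columns=["group", "protein", "k", "n", "K", "N",
                                       "p", "consensus"])


def mito_subnetwork(
    events: list[PerturbationEvent],
    edges: list[CoregEdge],
    annotation: frozenset | set,
    consensus: pd.DataFrame | None = None,
    design: StudyDesign | None = None,
) -> EdgeList:
    """Sub-network of annotated consensus-perturbed proteins.

    Nodes are the consensus-perturbed proteins carrying the annotation
    (e.g. "mitochondria"); edges are their retained co-regulation edges;
    node attributes record which group(s) called each protein.
    """
    if not annotation:
        raise ValueError("annotation set is empty")
    if consensus is None:
        if design is None:
            raise ValueError("need either a consensus table or a design")
        consensus = consensus_perturbed(events, design)
    called = consensus.loc[consensus["consensus"]] if not consensus.empty else consensus
    selected = {p for p in (set(called["protein"]) if not called.empty else set())
                if p in annotation}
    net = EdgeList()
    for prot in selected:
        groups = sorted(called.loc[called["protein"] == prot, "group"]) if not called.empty else []
        net.node_attributes[prot] = {
            "groups": ";".join(groups),
            "annotation": "mitochondria",
        }
    for edge in edges:
        a, b = edge.pair
        if a in selected or b in selected:
            net.add_edge(a, b, relation="coreg", weight=edge.rho)
            for node in (a, b):
                net.node_attributes.setdefault(node, {"groups": "", "annotation": ""})
    return net


def edges_frame(edges: list[CoregEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"protein_a": e.pair[0], "protein_b": e.pair[1], "rho": e.rho,
          "p": e.p, "q": e.q, "sign": e.sign} for e in edges],
        columns=["protein_a", "protein_b", "rho", "p", "q", "sign"],
    )


def events_frame(events: list[PerturbationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": ev.sample, "protein_a": ev.pair[0], "protein_b": ev.pair[1],
          "distance": ev.distance, "grubbs_G": ev.grubbs_G,
          "grubbs_p": ev.grubbs_p} for ev in events],
        columns=["sample", "protein_a", "protein_b", "distance",
                 "grubbs_G", "grubbs_p"],
    )
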