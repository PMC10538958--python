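"""Synthetic multi-omics data generators with planted ground truth.

These generators emulate the statistical structure of a four-arm dietary
study (ad libitum control plus three intermittent-fasting regimens) as it
appears after quantification: two TMT 10-plex sets of reporter intensities
with a pooled-control reference channel, a label-free phosphosite table
with intensity-dependent missingness, negative-binomial RNA-seq counts
coupled to the proteome, GMT annotation collections, correlated protein
pairs with planted per-sample perturbations, and protein-protein
interaction graphs with planted cliques and motif-bearing phosphosite
windows.  Every generator records what it planted in a `GroundTruth`
object so recovery can be scored.

Randomness: one integer seed is split into per-generator child seeds with
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` where ``k`` is a fixed
per-generator constant, so partial re-runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, AnnotationCollection, EdgeList, canonical_edge

TMT10_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# background residue frequencies (vertebrate average, rounded)
_AA_FREQS = np.array([
    0.074, 0.025, 0.054, 0.068, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

# spawn keys, one per generator
_SPAWN = {"proteome": 1, "phospho": 2, "rna": 3, "annotations": 4, "coreg": 5, "ppi": 6}


def child_rng(seed: int, generator: str) -> np.random.Generator:
    """Deterministic per-generator RNG derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SPAWN[generator],)))


# ---------------------------------------------------------------------------
# Study design


@dataclass(frozen=True)
class StudyDesign:
    """Group structure and TMT plex layout of the study.

    The control group is first in ``groups``.  ``plex_assignment`` maps
    each proteome sample to a ``(set id, channel)`` pair; the reference
    channel of each set carries the pooled control and is never assigned
    to a sample.
    """

    groups: tuple[str, ...]
    samples_per_group_proteome: dict[str, int]
    samples_per_group_phospho: dict[str, int]
    samples_per_group_rna: dict[str, int]
    plex_assignment: dict[str, tuple[str, str]]
    reference_channel: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.groups) != len(set(self.groups)):
            raise ValueError("duplicate group labels")
        for sample, (plex, channel) in self.plex_assignment.items():
            if channel == self.reference_channel.get(plex):
                raise ValueError(
                    f"sample {sample!r} assigned to reference channel of set {plex!r}"
                )
        # one channel per sample within a set
        used: set[tuple[str, str]] = set()
        for sample, key in self.plex_assignment.items():
            if key in used:
                raise ValueError(f"channel {key} assigned twice")
            used.add(key)

    @property
    def control(self) -> str:
        return self.groups[0]

    @property
    def plex_ids(self) -> list[str]:
        return sorted({p for p, _ in self.plex_assignment.values()})

    def proteome_samples(self, group: str | None = None) -> list[str]:
        out = []
        for g in self.groups:
            if group is not None and g != group:
                continue
            out.extend(f"{g}_{i + 1}" for i in range(self.samples_per_group_proteome[g]))
        return out

    def samples_for(self, assay: str, group: str) -> list[str]:
        n = {
            "proteome": self.samples_per_group_proteome,
            "phospho": self.samples_per_group_phospho,
            "rna": self.samples_per_group_rna,
        }[assay][group]
        return [f"{group}_{i + 1}" for i in range(n)]

    def group_of(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]


def default_design() -> StudyDesign:
    """The study layout: AL=4, IF12=5, IF16=5, EOD=4 proteome animals over
    two TMT 10-plex sets (9 samples + pooled-AL reference channel each);
    3 animals/group phospho; 5 animals/group RNA."""
    groups = ("AL", "IF12", "IF16", "EOD")
    prot = {"AL": 4, "IF12": 5, "IF16": 5, "EOD": 4}
    # split each group across the two sets so plex effects are not
    # confounded with diet
    split = {
        "set1": ["AL_1", "AL_2", "IF12_1", "IF12_2", "IF12_3", "IF16_1", "IF16_2", "EOD_1", "EOD_2"],
        "set2": ["AL_3", "AL_4", "IF12_4", "IF12_5", "IF16_3", "IF16_4", "IF16_5", "EOD_3", "EOD_4"],
    }
    assignment: dict[str, tuple[str, str]] = {}
    for plex, samples in split.items():
        channels = [c for c in TMT10_CHANNELS if c != "126"]
        for sample, channel in zip(samples, channels):
            assignment[sample] = (plex, channel)
    return StudyDesign(
        groups=groups,
        samples_per_group_proteome=prot,
        samples_per_group_phospho={g: 3 for g in groups},
        samples_per_group_rna={g: 5 for g in groups},
        plex_assignment=assignment,
        reference_channel={"set1": "126", "set2": "126"},
    )


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Planted effects a generator introduced, for recovery scoring.

    differential_features: feature -> (group, planted log2 effect)
    enriched_terms: term -> (dimension tag, planted shift direction)
    perturbation_events: set of (sample, protein) displacements
    planted_clusters: node sets planted as dense subgraphs
    target_mrna_protein_corr: the transcript-protein coupling the RNA
    generator aimed for.
    """

    differential_features: dict[str, tuple[str, float]] = field(default_factory=dict)
    enriched_terms: dict[str, tuple[str, str]] = field(default_factory=dict)
    perturbation_events: set[tuple[str, str]] = field(default_factory=set)
    planted_clusters: list[frozenset] = field(default_factory=list)
    planted_motif_clusters: dict[str, str] = field(default_factory=dict)
    target_mrna_protein_corr: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, (g, eff) in sorted(self.differential_features.items()):
            rows.append(("differential_feature", f, g, format(eff, ".6g")))
        for t, (dim, direction) in sorted(self.enriched_terms.items()):
            rows.append(("enriched_term", t, dim, direction))
        for s, p in sorted(self.perturbation_events):
            rows.append(("perturbation_event", p, s, ""))
        for i, nodes in enumerate(self.planted_clusters):
            rows.append(("planted_cluster", f"cluster{i + 1}", ";".join(sorted(nodes)), ""))
        for cl, motif in sorted(self.planted_motif_clusters.items()):
            rows.append(("motif_cluster", cl, motif, ""))
        if self.target_mrna_protein_corr is not None:
            rows.append(("target_mrna_protein_corr", "", "",
                         format(self.target_mrna_protein_corr, ".6g")))
        return pd.DataFrame(rows, columns=["kind", "entity", "context", "value"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        gt = cls()
        for _, row in df.iterrows():
            kind = row["kind"]
            if kind == "differential_feature":
                gt.differential_features[row["entity"]] = (row["context"], float(row["value"]))
            elif kind == "enriched_term":
                gt.enriched_terms[row["entity"]] = (row["context"], row["value"])
            elif kind == "perturbation_event":
                gt.perturbation_events.add((row["context"], row["entity"]))
            elif kind == "planted_cluster":
                gt.planted_clusters.append(frozenset(row["context"].split(";")))
            elif kind == "motif_cluster":
                gt.planted_motif_clusters[row["entity"]] = row["context"]
            elif kind == "target_mrna_protein_corr":
                gt.target_mrna_protein_corr = float(row["value"])
        return gt


# ---------------------------------------------------------------------------
# TMT proteome


def simulate_proteome_tmt(
    design: StudyDesign,
    n_proteins: int = 2000,
    frac_differential: float = 0.05,
    effect_log2: float = 1.0,
    sigma: float = 0.25,
    batch_sd: float = 0.3,
    channel_loading_sd: float = 0.15,
    base_mean_log2: float = 20.0,
    base_sd_log2: float = 2.0,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Reporter-ion intensity tables for a two-set TMT experiment.

    Latent protein abundances are log-normal on the log2 scale.  Each plex
    adds a per-protein batch shift ~ N(0, batch_sd); each channel carries a
    multiplicative loading factor (lognormal, sd ``channel_loading_sd`` on
    the log2 scale) that total-intensity normalization must remove.  The
    reference channel of each set holds the pooled control sample: the mean
    of the control latent abundances plus measurement noise of sd
    ``sigma / sqrt(n_control)`` (pooling the control animals averages their
    biological variability).  A ``frac_differential`` fraction of proteins
    carries a +/- ``effect_log2`` shift in one randomly chosen non-control
    group.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if not 0.0 <= frac_differential <= 0.5:
        raise ValueError("frac_differential must be in [0, 0.5]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n_samples = len(design.plex_assignment)
    if sum(design.samples_per_group_proteome.values()) != n_samples:
        raise ValueError("plex capacity exceeded: design samples do not fit the plex layout")
    rng = child_rng(seed, "proteome")

    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    base = rng.normal(base_mean_log2, base_sd_log2, n_proteins)

    truth = GroundTruth()
    n_diff = int(round(frac_differential * n_proteins))
    effects = np.zeros((n_proteins, len(design.groups)))
    if n_diff > 0:
        picked = rng.choice(n_proteins, n_diff, replace=False)
        for idx in picked:
            gi = int(rng.integers(1, len(design.groups)))  # never the control
            signed = effect_log2 * (1.0 if rng.random() < 0.5 else -1.0)
            effects[idx, gi] = signed
            truth.differential_features[proteins[idx]] = (design.groups[gi], signed)

    n_control = design.samples_per_group_proteome[design.control]
    tables: dict[str, pd.DataFrame] = {}
    plex_ids = design.plex_ids
    batch = {p: rng.normal(0.0, batch_sd, n_proteins) for p in plex_ids}
    group_index = {g: i for i, g in enumerate(design.groups)}

    for plex in plex_ids:
        ref_channel = design.reference_channel[plex]
        samples_here = [s for s, (p, _c) in design.plex_assignment.items() if p == plex]
        channels = {design.plex_assignment[s][1]: s for s in samples_here}
        cols = {}
        loading = {c: rng.normal(0.0, channel_loading_sd) for c in TMT10_CHANNELS}
        # pooled control reference
        ref_log2 = base + batch[plex] + rng.normal(0.0, sigma / np.sqrt(n_control), n_proteins)
        cols[ref_channel] = np.exp2(ref_log2 + loading[ref_channel])
        for channel, sample in channels.items():
            g = design.group_of(sample)
            log2_val = (
                base
                + effects[:, group_index[g]]
                + batch[plex]
                + rng.normal(0.0, sigma, n_proteins)
            )
            cols[channel] = np.exp2(log2_val + loading[channel])
        ordered = [c for c in TMT10_CHANNELS if c in cols]
        tables[plex] = pd.DataFrame({c: cols[c] for c in ordered}, index=proteins)
    return tables, truth


# ---------------------------------------------------------------------------
# Label-free phosphoproteome


def random_windows(rng: np.random.Generator, n: int, half_width: int = 6,
                   residues: Sequence[str] | None = None) -> tuple[list[str], list[str]]:
    """Random flanking windows with S/T/Y centers at ~80/19/1 frequencies."""
    if residues is None:
        residues = rng.choice(["S", "T", "Y"], size=n, p=[0.80, 0.19, 0.01]).tolist()
    width = 2 * half_width + 1
    flanks = rng.choice(_AMINO_ACIDS, size=(n, width), p=_AA_FREQS)
    windows = []
    for i in range(n):
        w = flanks[i].copy()
        w[half_width] = residues[i]
        windows.append("".join(w))
    return windows, list(residues)


def simulate_phospho_lfq(
    design: StudyDesign,
    n_sites: int = 1000,
    frac_differential: float = 0.05,
    effect_log2: float = 1.5,
    sigma: float = 0.3,
    missing_steepness: float = 0.8,
    baseline_missing: float = 0.25,
    base_mean_log2: float = 23.0,
    base_sd_log2: float = 2.0,
    half_width: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Label-free phosphosite table with MNAR missingness.

    Sites carry a flanking window (center residue S/T/Y at ~80/19/1%), a
    localization probability drawn from a two-component Beta mixture with
    weight 0.84 on the high-confidence component (so ~84% of sites are
    class I at the 0.75 cutoff), and per-sample log2 intensities.  The
    probability that a cell is missing follows a logistic curve in the
    centered log2 intensity: ``P(missing) = expit(-missing_steepness * (x -
    median_sample) + logit(baseline_missing))``, so lower-abundance sites
    drop out more often; steepness 0 reduces to uniform missingness at the
    baseline rate.
    """
    if n_sites < 10:
        raise ValueError("n_sites must be >= 10")
    if missing_steepness < 0:
        raise ValueError("missing_steepness must be >= 0")
    rng = child_rng(seed, "phospho")

    proteins = [f"PH{i // 2 + 1:04d}" for i in range(n_sites)]
    positions = rng.integers(8, 800, n_sites)
    windows, residues = random_windows(rng, n_sites, half_width)

    is_class1 = rng.random(n_sites) < 0.84
    loc = np.where(
        is_class1,
        rng.beta(60.0, 2.0, n_sites),
        rng.beta(6.0, 6.0, n_sites),
    )

    samples = [s for g in design.groups for s in design.samples_for("phospho", g)]
    base = rng.normal(base_mean_log2, base_sd_log2, n_sites)
    truth = GroundTruth()
    effects = np.zeros((n_sites, len(design.groups)))
    n_diff = int(round(frac_differential * n_sites))
    if n_diff > 0:
        picked = rng.choice(n_sites, n_diff, replace=False)
        for idx in picked:
            gi = int(rng.integers(1, len(design.groups)))
            signed = effect_log2 * (1.0 if rng.random() < 0.5 else -1.0)
            effects[idx, gi] = signed

    site_ids = [f"{proteins[i]}_{residues[i]}{positions[i]}" for i in range(n_sites)]
    # make ids unique if a protein got the same site twice
    seen: dict[str, int] = {}
    for i, sid in enumerate(site_ids):
        if sid in seen:
            seen[sid] += 1
            site_ids[i] = f"{sid}.{seen[sid]}"
        else:
            seen[sid] = 0
    for idx in np.flatnonzero(effects.any(axis=1)):
        gi = int(np.flatnonzero(effects[idx])[0])
        truth.differential_features[site_ids[idx]] = (design.groups[gi], float(effects[idx, gi]))

    group_index = {g: i for i, g in enumerate(design.groups)}
    data: dict[str, np.ndarray] = {}
    for s in samples:
        g = design.group_of(s)
        x = base + effects[:, group_index[g]] + rng.normal(0.0, sigma, n_sites)
        if baseline_missing > 0.0:
            logit_base = np.log(baseline_missing / (1.0 - baseline_missing))
            p_miss = 1.0 / (1.0 + np.exp(missing_steepness * (x - np.median(x)) - logit_base))
            x[rng.random(n_sites) < p_miss] = np.nan
        data[s] = x

    table = pd.DataFrame({
        "id": site_ids,
        "protein": proteins,
        "position": positions,
        "residue": residues,
        "window": windows,
        "localization_prob": loc,
        **data,
    })
    return table, truth


# ---------------------------------------------------------------------------
# Transcriptome


def simulate_transcriptome(
    design: StudyDesign,
    n_genes: int = 2000,
    target_corr: float = 0.47,
    protein_latent: Optional[np.ndarray] = None,
    planted_effects: Optional[dict[str, tuple[str, float]]] = None,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Negative-binomial count table plus gene lengths, coupled to the
    proteome.

    Gene-level log latent expression shares a component with the proteome
    latent abundances (standardized ``protein_latent`` deviations, or a
    fresh standard-normal draw) with weight ``target_corr``, so the
    realized cross-feature Pearson correlation between mean log FPKM and
    mean log2 protein abundance approaches ``target_corr``.  Counts are
    NB with gene-wise means ``FPKM-like latent * length * depth`` and
    constant dispersion.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not -1.0 < target_corr < 1.0:
        raise ValueError("|target_corr| must be < 1")
    rng = child_rng(seed, "rna")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]

    if protein_latent is None:
        z = rng.standard_normal(n_genes)
    else:
        if len(protein_latent) < n_genes:
            raise ValueError("protein_latent shorter than n_genes")
        pl = np.asarray(protein_latent[:n_genes], dtype=float)
        z = (pl - pl.mean()) / pl.std()
    eps = rng.standard_normal(n_genes)
    latent_log = target_corr * z + np.sqrt(1.0 - target_corr**2) * eps
    # mean log2-FPKM around 5 with sd 2 (matching the proteome latent spread)
    log2_fpkm = 5.0 + 2.0 * latent_log

    lengths = pd.Series(rng.integers(300, 10_000, n_genes), index=genes, name="length")
    samples = [s for g in design.groups for s in design.samples_for("rna", g)]
    depth = 1.0e7

    truth = GroundTruth(target_mrna_protein_corr=target_corr)
    effects = {g: np.zeros(n_genes) for g in design.groups}
    if planted_effects:
        gene_idx = {g: i for i, g in enumerate(genes)}
        for gene, (grp, eff) in planted_effects.items():
            if gene not in gene_idx:
                raise ValueError(f"planted gene {gene!r} not generated")
            effects[grp][gene_idx[gene]] += eff
            truth.differential_features[gene] = (grp, eff)

    counts = {}
    for s in samples:
        grp = design.group_of(s)
        fpkm = np.exp2(log2_fpkm + effects[grp] + rng.normal(0.0, 0.15, n_genes))
        mu = fpkm * lengths.to_numpy() * depth / 1.0e9
        # NB via gamma-Poisson mixture
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        counts[s] = rng.poisson(lam)
    table = pd.DataFrame(counts, index=genes)
    return table, lengths, truth


# ---------------------------------------------------------------------------
# Annotation collections


def simulate_annotations(
    features: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 60),
    n_planted: int = 5,
    planted_features: Optional[Sequence[str]] = None,
    planted_purity: float = 0.8,
    seed: int = 0,
) -> tuple[AnnotationCollection, GroundTruth]:
    """GMT-style annotation collection with planted enriched terms.

    Planted terms draw ``planted_purity`` of their members from
    ``planted_features`` (e.g. the differential features of another
    generator); remaining members and all non-planted terms are uniform
    draws from the feature universe.
    """
    features = list(features)
    lo, hi = term_size_range
    if hi > len(features):
        raise ValueError("max term size exceeds number of features")
    if n_planted > n_terms:
        raise ValueError("n_planted exceeds n_terms")
    if n_planted > 0 and not planted_features:
        raise ValueError("planted_features required when n_planted > 0")
    rng = child_rng(seed, "annotations")

    truth = GroundTruth()
    terms: dict[str, tuple[str, frozenset]] = {}
    planted_pool = list(planted_features or [])
    for t in range(n_terms):
        name = f"T{t + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if t < n_planted:
            n_from_planted = min(int(round(planted_purity * size)), len(planted_pool))
            chosen = list(rng.choice(planted_pool, n_from_planted, replace=False))
            rest_pool = [f for f in features if f not in set(chosen)]
            chosen += list(rng.choice(rest_pool, size - n_from_planted, replace=False))
            truth.enriched_terms[name] = ("planted", "up")
        else:
            chosen = list(rng.choice(features, size, replace=False))
        terms[name] = (f"synthetic term {name}", frozenset(chosen))
    return AnnotationCollection(terms=terms), truth


# ---------------------------------------------------------------------------
# Co-regulated pairs with perturbation events


def simulate_coreg_perturbations(
    design: StudyDesign,
    n_proteins: int = 300,
    n_correlated_pairs: int = 50,
    n_events: int = 30,
    displacement: float = 5.0,
    member_noise_sd: float = 0.15,
    event_samples: Optional[dict[int, Sequence[str]]] = None,
    seed: int = 0,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Log2-ratio style matrix with planted co-regulated pairs and
    per-sample perturbation events.

    Each designated pair shares a standard-normal latent profile across
    the proteome samples, plus member noise of sd ``member_noise_sd``
    (|rho| >= 0.9 requires member_noise_sd <= 0.33); half the pairs are
    sign-flipped to give negative co-regulation.  A perturbation event
    displaces one sample's value in one member of one pair by
    ``displacement`` units of the pair's conditional (residual-from-
    correlation) sd — the scale on which a deviation from the correlation
    is measured.  ``event_samples`` optionally restricts which samples the
    i-th event may hit (for planting group-specific perturbations).
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if 2 * n_correlated_pairs > n_proteins:
        raise ValueError("n_correlated_pairs exceeds available disjoint pairs")
    if n_events > n_correlated_pairs:
        raise ValueError("n_events exceeds n_correlated_pairs")
    rng = child_rng(seed, "coreg")

    samples = design.proteome_samples()
    n = len(samples)
    proteins = [f"C{i + 1:04d}" for i in range(n_proteins)]
    X = rng.standard_normal((n_proteins, n))

    pairs = []
    for i in range(n_correlated_pairs):
        a, b = 2 * i, 2 * i + 1
        latent = rng.standard_normal(n)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        X[a] = latent + member_noise_sd * rng.standard_normal(n)
        X[b] = sign * latent + member_noise_sd * rng.standard_normal(n)
        pairs.append((a, b))

    # conditional sd of one member given the other
    v = 1.0 + member_noise_sd**2
    sigma_cond = float(np.sqrt(v - 1.0 / v))

    truth = GroundTruth()
    truth.planted_clusters = [frozenset((proteins[a], proteins[b])) for a, b in pairs]
    if n_events > 0 and displacement >= 0:
        event_pairs = rng.choice(n_correlated_pairs, n_events, replace=False)
        for i, pi in enumerate(event_pairs):
            a, b = pairs[pi]
            member = b if rng.random() < 0.5 else a
            allowed = list(event_samples[i]) if event_samples and i in event_samples else samples
            s = allowed[int(rng.integers(len(allowed)))]
            si = samples.index(s)
            X[member, si] += displacement * sigma_cond * (1.0 if rng.random() < 0.5 else -1.0)
            truth.perturbation_events.add((s, proteins[member]))

    values = pd.DataFrame(X, index=proteins, columns=samples)
    groups = {s: design.group_of(s) for s in samples}
    matrix = AbundanceMatrix(values=values, sample_groups=groups, value_scale="log2_ratio")
    return matrix, truth


# ---------------------------------------------------------------------------
# PPI graphs and motif-bearing phosphosite windows


def simulate_ppi_and_motifs(
    features: Sequence[str],
    n_cliques: int = 2,
    clique_size: int = 6,
    background_edge_prob: float = 0.02,
    kinase_motifs: Sequence | None = None,
    n_sites_per_cluster: int = 30,
    planted_match_fraction: float = 0.6,
    background_match_fraction: float = 0.1,
    half_width: int = 6,
    seed: int = 0,
) -> tuple[EdgeList, pd.DataFrame, GroundTruth]:
    """PPI edge list with planted cliques plus motif-bearing site windows.

    The graph is the union of ``n_cliques`` fully connected node sets
    (taken from the front of ``features``) and Erdős–Rényi background
    edges at ``background_edge_prob``.  For each supplied kinase motif, a
    cluster of phosphosite windows is generated in which
    ``planted_match_fraction`` of windows match the motif, against a
    shared background cluster matching at ``background_match_fraction``.
    """
    features = list(features)
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ValueError("background_edge_prob must lie in [0, 1]")
    if n_cliques * clique_size > len(features):
        raise ValueError("planted cliques need more nodes than available")
    rng = child_rng(seed, "ppi")

    truth = GroundTruth()
    el = EdgeList()
    used = 0
    for _ in range(n_cliques):
        members = features[used: used + clique_size]
        used += clique_size
        truth.planted_clusters.append(frozenset(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                el.add_edge(members[i], members[j])
    if background_edge_prob > 0:
        n = len(features)
        for i in range(n):
            for j in range(i + 1, n):
                key = canonical_edge(features[i], features[j])
                if key in el.edges:
                    continue
                if rng.random() < background_edge_prob:
                    el.add_edge(*key)

    rows = []
    motifs = list(kinase_motifs or [])
    for m in motifs:
        cluster = f"cluster_{m.name}"
        truth.planted_motif_clusters[cluster] = m.name
        for k in range(n_sites_per_cluster):
            match = rng.random() < planted_match_fraction
            rows.append((f"{cluster}_s{k + 1}", cluster,
                         _motif_window(rng, m, half_width, match)))
    for k in range(n_sites_per_cluster * max(1, len(motifs))):
        m = motifs[int(rng.integers(len(motifs)))] if motifs else None
        match = m is not None and rng.random() < background_match_fraction
        rows.append((f"background_s{k + 1}", "background",
                     _motif_window(rng, m, half_width, match) if m is not None
                     else random_windows(rng, 1, half_width)[0][0]))
    sites = pd.DataFrame(rows, columns=["id", "cluster", "window"])
    return el, sites, truth


def _motif_window(rng: np.random.Generator, motif, half_width: int, match: bool) -> str:
    """A random window that does (or deliberately does not) match a motif."""
    window, _ = random_windows(rng, 1, half_width)
    w = list(window[0])
    center_allowed = sorted(motif.constraints[0])
    if match:
        for off, allowed in motif.constraints.items():
            w[half_width + off] = sorted(allowed)[int(rng.integers(len(allowed)))]
    else:
        w[half_width] = center_allowed[int(rng.integers(len(center_allowed)))]
        # break one non-center constraint
        offs = [o for o in motif.constraints if o != 0]
        if offs:
            off = offs[int(rng.integers(len(offs)))]
            banned = motif.constraints[off]
            choices = [aa for aa in _AMINO_ACIDS if aa not in banned]
            w[half_width + off] = choices[int(rng.integers(len(choices)))]
    return "".join(w)
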