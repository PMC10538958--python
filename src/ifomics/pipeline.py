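"""Stage drivers behind the CLI: each stage reads its inputs from the
output directory, runs the corresponding library code, and writes
byte-stable result tables.  `run_all` chains every stage in the standard
order; with a fixed config and seed the whole output tree (everything
except the timestamped log under ``logs/``) is byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coregulation, enrichment, io, kinase, networks, phospho, proteome, synthetic, transcriptome
from .containers import AbundanceMatrix
from .io import RunLogger
from .synthetic import GroundTruth, StudyDesign, default_design

STAGE_ORDER = [
    "simulate", "proteome-diff", "phospho-diff", "enrich-fisher", "enrich-1d",
    "enrich-2d", "kinase-enrich", "coreg", "cluster", "rna-integrate",
]


def _seed(cfg: dict) -> int:
    return int(cfg.get("seed", 0))


def _design(cfg: dict) -> StudyDesign:
    # only the default four-arm layout is built in; a custom design would
    # be supplied as a design TSV plus plex map
    return default_design()


def _dirs(out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    data, results = out / "data", out / "results"
    data.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    return data, results


def stage_simulate(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, _results = _dirs(out_dir)
    design = _design(cfg)
    seed = _seed(cfg)
    sim = cfg.get("simulate", {})

    tables, truth_prot = synthetic.simulate_proteome_tmt(
        design, seed=seed, **sim.get("proteome", {}))
    for plex, table in tables.items():
        mat_cols = {f"{plex}_{c}": table[c] for c in table.columns}
        pd.DataFrame(mat_cols, index=table.index).rename_axis("feature").pipe(
            io.write_table, data / f"proteome_{plex}.tsv", index=True)
    logger.log(f"simulate: proteome {len(next(iter(tables.values())))} proteins x "
               f"{len(design.plex_assignment)} samples",
               proteins=len(next(iter(tables.values()))))

    sites, truth_phos = synthetic.simulate_phospho_lfq(
        design, seed=seed, **sim.get("phospho", {}))
    io.write_phospho_table(sites, data / "phospho.tsv")
    logger.log(f"simulate: phospho {len(sites)} sites")

    n_prot = len(tables[design.plex_ids[0]])
    proteins = list(tables[design.plex_ids[0]].index)
    base_log2 = np.log2(tables[design.plex_ids[0]]).mean(axis=1).to_numpy()
    counts, lengths, truth_rna = synthetic.simulate_transcriptome(
        design, protein_latent=base_log2, seed=seed, **sim.get("rna", {}))
    counts.rename_axis("feature").pipe(io.write_table, data / "rna_counts.tsv", index=True)
    lengths.rename_axis("gene").reset_index().pipe(io.write_table, data / "gene_lengths.tsv")
    id_map = pd.DataFrame({
        "protein": proteins[: len(counts)],
        "gene": list(counts.index)[: min(n_prot, len(counts))],
    })
    io.write_table(id_map, data / "id_map.tsv")
    logger.log(f"simulate: rna {len(counts)} genes")

    ann_cfg = dict(sim.get("annotations", {}))
    planted_feats = sorted(truth_prot.differential_features) or proteins[:20]
    collection, truth_ann = synthetic.simulate_annotations(
        proteins, planted_features=planted_feats, seed=seed, **ann_cfg)
    io.write_gmt(collection, data / "annotations.gmt")

    coreg_matrix, truth_coreg = synthetic.simulate_coreg_perturbations(
        design, seed=seed, **sim.get("coreg", {}))
    io.write_matrix(coreg_matrix, data / "coreg_matrix.tsv")
    io.write_design(coreg_matrix, data / "coreg_design.tsv")
    rng = synthetic.child_rng(seed, "coreg")
    mito = sorted(rng.choice(coreg_matrix.feature_ids,
                             max(2, len(coreg_matrix.feature_ids) // 3),
                             replace=False))
    (data / "mito_annotation.tsv").write_text(
        "protein\n" + "".join(f"{p}\n" for p in mito), encoding="utf-8")

    motifs = io.read_motifs(Path(__file__).parent / "data" / "kinase_motifs.tsv")
    ppi, motif_sites, truth_ppi = synthetic.simulate_ppi_and_motifs(
        proteins, kinase_motifs=motifs, seed=seed, **sim.get("ppi", {}))
    io.write_sif(ppi, data / "ppi.sif")
    io.write_table(motif_sites, data / "motif_sites.tsv")

    truth = GroundTruth(
        differential_features={**truth_prot.differential_features,
                               **{f"phospho:{k}": v for k, v in truth_phos.differential_features.items()}},
        enriched_terms=truth_ann.enriched_terms,
        perturbation_events=truth_coreg.perturbation_events,
        planted_clusters=truth_ppi.planted_clusters,
        planted_motif_clusters=truth_ppi.planted_motif_clusters,
        target_mrna_protein_corr=truth_rna.target_mrna_protein_corr,
    )
    truth.write(data / "ground_truth.tsv")
    with open(data / "design.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\tplex\tchannel\n")
        for sample in design.proteome_samples():
            plex, channel = design.plex_assignment[sample]
            fh.write(f"{sample}\t{design.group_of(sample)}\t{plex}\t{channel}\n")
    logger.log("simulate: wrote ground truth and design")


def _strip_prefix(table: pd.DataFrame, plex: str) -> pd.DataFrame:
    return table.rename(columns=lambda c: c.removeprefix(f"{plex}_"))


def _read_reporter_tables(data: Path, design: StudyDesign) -> dict[str, pd.DataFrame]:
    return {
        p: _strip_prefix(pd.read_csv(data / f"proteome_{p}.tsv", sep="\t", index_col=0), p)
        for p in design.plex_ids
    }


def stage_proteome_diff(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    design = _design(cfg)
    pcfg = cfg.get("proteome", {})
    tables = _read_reporter_tables(data, design)
    matrix = proteome.normalize_tmt_and_ratio(tables, design, logger=logger)
    io.write_matrix(matrix, results / "proteome_log2_ratios.tsv")
    filtered = proteome.filter_min_replicates(
        matrix, int(pcfg.get("min_per_group", 3)), logger=logger)
    records = proteome.differential_proteome(
        filtered, control=design.control, alpha=float(pcfg.get("alpha", 0.01)),
        mc_reps=int(pcfg.get("mc_reps", 50_000)), seed=_seed(cfg))
    frame = proteome.differential_frame(records)
    io.write_table(frame, results / "proteome_differential.tsv", index=True)
    sig = {f for r in records if any(r.significant.values()) for f in [r.feature]}
    z = proteome.zscore_rows(filtered.with_values(filtered.values.loc[sorted(sig)])) \
        if sig else pd.DataFrame()
    io.write_table(z.rename_axis("feature"), results / "proteome_zscores.tsv", index=True)
    logger.log(f"proteome-diff: {len(sig)} significant of {len(records)} tested",
               significant=len(sig), tested=len(records))


def stage_phospho_diff(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    design = _design(cfg)
    pcfg = cfg.get("phospho", {})
    sites = io.read_phospho_table(data / "phospho.tsv")
    class1 = phospho.filter_class1(sites, float(pcfg.get("class1_threshold", 0.75)))
    logger.log(f"phospho-diff: {len(class1)} of {len(sites)} sites are class I",
               class1=len(class1), total=len(sites))
    matrix = phospho.sites_to_matrix(class1, design)
    records, clusters = phospho.differential_phospho(
        matrix, control=design.control, alpha=float(pcfg.get("alpha", 0.05)),
        min_per_group=int(pcfg.get("min_per_group", 2)),
        mc_reps=int(pcfg.get("mc_reps", 50_000)), seed=_seed(cfg), logger=logger)
    io.write_table(proteome.differential_frame(records),
                   results / "phospho_differential.tsv", index=True)
    io.write_table(clusters, results / "phospho_clusters.tsv")
    class1.to_csv(results / "phospho_class1_sites.tsv", sep="\t", index=False,
                  lineterminator="\n")


def _proteome_fold_changes(results: Path) -> pd.DataFrame:
    frame = pd.read_csv(results / "proteome_differential.tsv", sep="\t", index_col=0)
    fc = frame[[c for c in frame.columns if c.startswith("log2fc_")]]
    return fc.rename(columns=lambda c: c.removeprefix("log2fc_"))


def stage_enrich_fisher(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    ecfg = cfg.get("enrichment", {})
    annotations = io.read_gmt(data / "annotations.gmt")
    frame = pd.read_csv(results / "proteome_differential.tsv", sep="\t", index_col=0)
    universe = set(frame.index)
    sig_cols = [c for c in frame.columns if c.startswith("sig_")]
    selected = set(frame.index[frame[sig_cols].any(axis=1)])
    records = enrichment.fisher_enrichment(
        selected, universe, annotations, fdr=float(ecfg.get("fdr", 0.05)),
        logger=logger)
    io.write_table(enrichment.enrichment_frame(records),
                   results / "enrich_fisher.tsv")
    logger.log(f"enrich-fisher: {sum(r.significant for r in records)} significant terms")


def stage_enrich_1d(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    ecfg = cfg.get("enrichment", {})
    annotations = io.read_gmt(data / "annotations.gmt")
    fc = _proteome_fold_changes(results)
    for group in fc.columns:
        values = fc[group].dropna().to_dict()
        records = enrichment.enrichment_1d(
            values, annotations, fdr=float(ecfg.get("fdr", 0.05)),
            min_size=int(ecfg.get("min_size", 5)), logger=logger)
        io.write_table(enrichment.enrichment_frame(records),
                       results / f"enrich_1d_{group}.tsv")
    logger.log("enrich-1d: wrote per-group tables")


def stage_enrich_2d(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    ecfg = cfg.get("enrichment", {})
    annotations = io.read_gmt(data / "annotations.gmt")
    fc_prot = _proteome_fold_changes(results)
    fc_rna = pd.read_csv(results / "rna_fold_changes.tsv", sep="\t", index_col=0)
    id_map = pd.read_csv(data / "id_map.tsv", sep="\t")
    gene_to_prot = dict(zip(id_map["gene"], id_map["protein"]))
    for group in fc_prot.columns:
        if group not in fc_rna.columns:
            continue
        x = fc_prot[group].dropna().to_dict()
        y = {gene_to_prot[g]: v for g, v in fc_rna[group].dropna().items()
             if g in gene_to_prot}
        records = enrichment.enrichment_2d(
            x, y, annotations, fdr=float(ecfg.get("fdr", 0.05)),
            min_size=int(ecfg.get("min_size", 5)), logger=logger)
        io.write_table(enrichment.enrichment_frame(records),
                       results / f"enrich_2d_{group}.tsv")
        io.write_table(enrichment.scatter_table(records),
                       results / f"enrich_2d_{group}_scatter.tsv")
    logger.log("enrich-2d: wrote per-group tables")


def stage_kinase_enrich(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    _data, results = _dirs(out_dir)
    kcfg = cfg.get("kinase", {})
    motif_path = kcfg.get("motifs") or Path(__file__).parent / "data" / "kinase_motifs.tsv"
    motifs = io.read_motifs(motif_path)
    class1 = pd.read_csv(results / "phospho_class1_sites.tsv", sep="\t")
    all_sites = dict(zip(class1["id"], class1["window"]))
    clusters_df = pd.read_csv(results / "phospho_clusters.tsv", sep="\t")
    clusters: dict[str, set] = {}
    for _i, row in clusters_df.iterrows():
        clusters.setdefault(row["cluster"], set()).add(row["id"])
    table = kinase.kinase_cluster_enrichment(
        clusters, all_sites, motifs,
        p_threshold=float(kcfg.get("p_threshold", 0.05)), logger=logger)
    io.write_table(table, results / "kinase_enrichment.tsv")
    logger.log(f"kinase-enrich: {len(table)} (cluster, motif) tests")


def stage_coreg(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    ccfg = cfg.get("coreg", {})
    design = _design(cfg)
    matrix = io.read_matrix(data / "coreg_matrix.tsv",
                            design_path=data / "coreg_design.tsv",
                            value_scale="log2_ratio")
    edges = coregulation.coreg_network(
        matrix, q_threshold=float(ccfg.get("q_threshold", 0.01)), logger=logger)
    io.write_table(coregulation.edges_frame(edges), results / "coreg_edges.tsv")
    events = coregulation.sample_deviations(
        matrix, edges, grubbs_alpha=float(ccfg.get("grubbs_alpha", 0.1)),
        logger=logger)
    io.write_table(coregulation.events_frame(events), results / "coreg_events.tsv")
    consensus = coregulation.consensus_perturbed(
        events, design, p_threshold=float(ccfg.get("consensus_p", 0.05)),
        logger=logger)
    io.write_table(consensus, results / "consensus_perturbed.tsv")
    mito = set(pd.read_csv(data / "mito_annotation.tsv", sep="\t")["protein"])
    net = coregulation.mito_subnetwork(events, edges, mito, consensus=consensus)
    io.write_sif(net, results / "mito_subnetwork.sif")
    logger.log(f"coreg: {len(edges)} edges, {len(events)} events, "
               f"{int(consensus['consensus'].sum()) if not consensus.empty else 0} consensus calls")


def stage_cluster(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    ncfg = cfg.get("cluster", {})
    ppi = io.read_sif(data / "ppi.sif")
    frame = pd.read_csv(results / "proteome_differential.tsv", sep="\t", index_col=0)
    differential = {
        c.removeprefix("sig_"): set(frame.index[frame[c]])
        for c in frame.columns if c.startswith("sig_")
    }
    overlaid = networks.overlay_responsive(ppi, differential, logger=logger)
    io.write_sif(overlaid, results / "responsive_network.sif")
    graph = overlaid.to_networkx()
    records = networks.greedy_clusters(
        graph, min_size=int(ncfg.get("min_size", 3)),
        p_penalty=float(ncfg.get("p_penalty", 2.0)),
        overlap_threshold=float(ncfg.get("overlap_threshold", 0.8)),
        p_threshold=float(ncfg.get("p_threshold", 0.1)),
        n_rewires=int(ncfg.get("n_rewires", 100)),
        seed=_seed(cfg), logger=logger)
    io.write_table(networks.clusters_frame(records), results / "network_clusters.tsv")
    degrees, dist = networks.degree_summary(graph)
    io.write_table(degrees, results / "network_degrees.tsv")
    io.write_table(dist, results / "network_degree_distribution.tsv")


def stage_rna_integrate(cfg: dict, out_dir: str | Path, logger: RunLogger) -> None:
    data, results = _dirs(out_dir)
    rcfg = cfg.get("rna", {})
    design = _design(cfg)
    counts = pd.read_csv(data / "rna_counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(data / "gene_lengths.tsv", sep="\t", index_col=0)["length"]
    fpkm = transcriptome.compute_fpkm(counts, lengths)
    io.write_table(fpkm.rename_axis("feature"), results / "fpkm.tsv", index=True)
    means = transcriptome.group_means(fpkm, design, "rna")
    fc = transcriptome.group_fold_changes(
        means, design.control, pseudocount=float(rcfg.get("pseudocount", 1.0)))
    io.write_table(fc.rename_axis("feature"), results / "rna_fold_changes.tsv", index=True)
    tables = _read_reporter_tables(data, design)
    prot_matrix = proteome.normalized_log2_intensity(tables, design)
    id_map = pd.read_csv(data / "id_map.tsv", sep="\t")
    r, matched = transcriptome.protein_transcript_correlation(
        prot_matrix, fpkm, design,
        id_map=dict(zip(id_map["protein"], id_map["gene"])),
        pseudocount=float(rcfg.get("pseudocount", 1.0)), logger=logger)
    report = {"pearson_r": round(float(r), 6), "matched_features": int(matched)}
    with open(results / "transcript_protein_correlation.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.log(f"rna-integrate: transcript-protein r={r:.3f} over {matched} features",
               **report)


_STAGES = {
    "simulate": stage_simulate,
    "proteome-diff": stage_proteome_diff,
    "phospho-diff": stage_phospho_diff,
    "enrich-fisher": stage_enrich_fisher,
    "enrich-1d": stage_enrich_1d,
    "enrich-2d": stage_enrich_2d,
    "kinase-enrich": stage_kinase_enrich,
    "coreg": stage_coreg,
    "cluster": stage_cluster,
    "rna-integrate": stage_rna_integrate,
}

# enrich-2d consumes rna fold changes, so run-all orders rna-integrate first
_RUN_ALL_ORDER = [
    "simulate", "proteome-diff", "phospho-diff", "rna-integrate",
    "enrich-fisher", "enrich-1d", "enrich-2d", "kinase-enrich",
    "coreg", "cluster",
]


def run_stage(stage: str, cfg: dict, out_dir: str | Path) -> None:
    logger = RunLogger(out_dir, name=stage.replace("-", "_"))
    # only run-relative information goes into the manifest so that two runs
    # of the same config are byte-identical
    logger.set(stage=stage, config_hash=io.config_hash(cfg), seed=_seed(cfg))
    try:
        _STAGES[stage](cfg, out_dir, logger)
        logger.write_manifest(name=f"manifest_{stage.replace('-', '_')}.json")
    finally:
        logger.close()


def run_all(cfg: dict, out_dir: str | Path) -> None:
    for stage in _RUN_ALL_ORDER:
        run_stage(stage, cfg, out_dir)
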