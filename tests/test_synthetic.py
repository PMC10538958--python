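"""Tests of the synthetic generators: determinism, ground-truth closure,
and the statistical structure they are meant to emulate."""

import numpy as np
import pandas as pd
import pytest

from ifomics import io, synthetic
from ifomics.synthetic import (
    GroundTruth,
    default_design,
    simulate_annotations,
    simulate_coreg_perturbations,
    simulate_phospho_lfq,
    simulate_ppi_and_motifs,
    simulate_proteome_tmt,
    simulate_transcriptome,
)


class TestStudyDesign:
    def test_default_layout(self, design):
        assert design.groups[0] == "AL"
        assert design.samples_per_group_proteome == {"AL": 4, "IF12": 5, "IF16": 5, "EOD": 4}
        assert all(v == 3 for v in design.samples_per_group_phospho.values())
        assert all(v == 5 for v in design.samples_per_group_rna.values())
        assert len(design.plex_assignment) == 18

    def test_reference_channel_unassigned(self, design):
        for _sample, (plex, channel) in design.plex_assignment.items():
            assert channel != design.reference_channel[plex]

    def test_reference_channel_conflict_rejected(self, design):
        bad = dict(design.plex_assignment)
        bad["AL_1"] = ("set1", "126")
        with pytest.raises(ValueError):
            synthetic.StudyDesign(
                groups=design.groups,
                samples_per_group_proteome=design.samples_per_group_proteome,
                samples_per_group_phospho=design.samples_per_group_phospho,
                samples_per_group_rna=design.samples_per_group_rna,
                plex_assignment=bad,
                reference_channel=design.reference_channel,
            )


class TestProteomeTMT:
    def test_determinism(self, design):
        t1, g1 = simulate_proteome_tmt(design, n_proteins=50, seed=7)
        t2, g2 = simulate_proteome_tmt(design, n_proteins=50, seed=7)
        for plex in t1:
            pd.testing.assert_frame_equal(t1[plex], t2[plex])
        assert g1.differential_features == g2.differential_features

    def test_zero_fraction_no_planted(self, design):
        _t, truth = simulate_proteome_tmt(design, n_proteins=30,
                                          frac_differential=0.0, seed=1)
        assert truth.differential_features == {}

    def test_two_plexes_ten_channels(self, design):
        tables, _ = simulate_proteome_tmt(design, n_proteins=20, seed=0)
        assert set(tables) == {"set1", "set2"}
        for table in tables.values():
            assert table.shape == (20, 10)
            assert (table.to_numpy() > 0).all()

    def test_truth_refers_to_generated_features(self, design):
        tables, truth = simulate_proteome_tmt(design, n_proteins=100,
                                              frac_differential=0.2, seed=2)
        ids = set(tables["set1"].index)
        assert set(truth.differential_features) <= ids
        for _f, (group, eff) in truth.differential_features.items():
            assert group in design.groups[1:]
            assert abs(eff) == pytest.approx(1.0)

    def test_invalid_parameters(self, design):
        with pytest.raises(ValueError):
            simulate_proteome_tmt(design, n_proteins=5)
        with pytest.raises(ValueError):
            simulate_proteome_tmt(design, n_proteins=20, sigma=0.0)
        with pytest.raises(ValueError):
            simulate_proteome_tmt(design, n_proteins=20, frac_differential=0.9)

    def test_oversized_design_rejected(self, design):
        big = synthetic.StudyDesign(
            groups=design.groups,
            samples_per_group_proteome={"AL": 10, "IF12": 5, "IF16": 5, "EOD": 4},
            samples_per_group_phospho=design.samples_per_group_phospho,
            samples_per_group_rna=design.samples_per_group_rna,
            plex_assignment=design.plex_assignment,
            reference_channel=design.reference_channel,
        )
        with pytest.raises(ValueError, match="plex capacity exceeded"):
            simulate_proteome_tmt(big, n_proteins=20)


class TestPhosphoLFQ:
    def test_residue_fractions_near_80_19_1(self, design):
        sites, _ = simulate_phospho_lfq(design, n_sites=10_000, seed=11)
        frac = sites["residue"].value_counts(normalize=True)
        assert frac["S"] == pytest.approx(0.80, abs=0.03)
        assert frac["T"] == pytest.approx(0.19, abs=0.03)
        assert frac["Y"] == pytest.approx(0.01, abs=0.03)

    def test_class1_fraction_near_084(self, design):
        sites, _ = simulate_phospho_lfq(design, n_sites=10_000, seed=11)
        frac = (sites["localization_prob"] >= 0.75).mean()
        assert frac == pytest.approx(0.84, abs=0.02)

    def test_zero_steepness_missingness_uniform(self, design):
        sites, _ = simulate_phospho_lfq(design, n_sites=4000,
                                        missing_steepness=0.0,
                                        baseline_missing=0.2, seed=5)
        sample_cols = [c for c in sites.columns if c not in io.PHOSPHO_META_COLS]
        rate = sites[sample_cols].isna().to_numpy().mean()
        assert rate == pytest.approx(0.2, abs=0.02)
        # missingness should not depend on the site's observed intensity
        mean_int = sites[sample_cols].mean(axis=1)
        n_missing = sites[sample_cols].isna().sum(axis=1)
        r = np.corrcoef(mean_int.fillna(mean_int.mean()), n_missing)[0, 1]
        assert abs(r) < 0.07

    def test_steepness_makes_low_abundance_drop_out(self, design):
        sites, _ = simulate_phospho_lfq(design, n_sites=4000,
                                        missing_steepness=1.5, seed=5)
        sample_cols = [c for c in sites.columns if c not in io.PHOSPHO_META_COLS]
        observed_mean = sites[sample_cols].mean(axis=1)
        n_missing = sites[sample_cols].isna().sum(axis=1)
        mask = observed_mean.notna()
        r = np.corrcoef(observed_mean[mask], n_missing[mask])[0, 1]
        assert r < -0.3

    def test_negative_steepness_rejected(self, design):
        with pytest.raises(ValueError):
            simulate_phospho_lfq(design, n_sites=100, missing_steepness=-1.0)

    def test_windows_centered_on_residue(self, design):
        sites, _ = simulate_phospho_lfq(design, n_sites=200, seed=1)
        for _i, row in sites.iterrows():
            assert len(row["window"]) == 13
            assert row["window"][6] == row["residue"]

    def test_determinism(self, design):
        s1, _ = simulate_phospho_lfq(design, n_sites=100, seed=9)
        s2, _ = simulate_phospho_lfq(design, n_sites=100, seed=9)
        pd.testing.assert_frame_equal(s1, s2)


class TestTranscriptome:
    def test_determinism(self, design):
        c1, l1, _ = simulate_transcriptome(design, n_genes=100, seed=3)
        c2, l2, _ = simulate_transcriptome(design, n_genes=100, seed=3)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)

    def test_gene_lengths_positive_integers(self, design):
        _c, lengths, _ = simulate_transcriptome(design, n_genes=100, seed=3)
        assert (lengths > 0).all()
        assert lengths.dtype.kind in "iu"

    def test_target_corr_zero(self, design):
        from ifomics.transcriptome import compute_fpkm

        rng = np.random.default_rng(0)
        latent = rng.normal(20, 2, 2000)
        counts, lengths, _ = simulate_transcriptome(
            design, n_genes=2000, target_corr=0.0, protein_latent=latent, seed=4)
        fpkm = compute_fpkm(counts, lengths)
        log_fpkm = np.log2(fpkm.mean(axis=1) + 1)
        r = np.corrcoef(latent, log_fpkm)[0, 1]
        assert abs(r) < 0.05

    def test_invalid_target_corr(self, design):
        with pytest.raises(ValueError):
            simulate_transcriptome(design, n_genes=100, target_corr=1.0)


class TestAnnotations:
    def test_term_sizes_in_range(self):
        features = [f"F{i}" for i in range(500)]
        coll, _ = simulate_annotations(features, n_terms=30,
                                       term_size_range=(5, 15), n_planted=0, seed=6)
        sizes = [len(coll.members(t)) for t in coll]
        assert all(5 <= s <= 15 for s in sizes)

    def test_planted_overlap_exceeds_random_baseline(self, rng):
        features = [f"F{i}" for i in range(500)]
        planted_feats = [f"F{i}" for i in range(40)]
        coll, truth = simulate_annotations(
            features, n_terms=30, term_size_range=(20, 30), n_planted=5,
            planted_features=planted_feats, seed=6)
        pf = set(planted_feats)

        def jaccard(a, b):
            return len(a & b) / len(a | b)

        planted_j = np.mean([jaccard(set(coll.members(t)), pf)
                             for t in truth.enriched_terms])
        random_j = np.mean([jaccard(set(rng.choice(features, 25, replace=False)), pf)
                            for _ in range(50)])
        assert planted_j > 3 * random_j

    def test_too_many_planted_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotations([f"F{i}" for i in range(100)], n_terms=5,
                                 term_size_range=(5, 10), n_planted=6,
                                 planted_features=["F1"])

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotations(["A", "B"], n_terms=2, term_size_range=(1, 5),
                                 n_planted=0)


class TestCoregPerturbations:
    def test_determinism(self, design):
        m1, g1 = simulate_coreg_perturbations(design, n_proteins=60,
                                              n_correlated_pairs=10,
                                              n_events=5, seed=8)
        m2, g2 = simulate_coreg_perturbations(design, n_proteins=60,
                                              n_correlated_pairs=10,
                                              n_events=5, seed=8)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert g1.perturbation_events == g2.perturbation_events

    def test_planted_pairs_highly_correlated(self, design):
        matrix, truth = simulate_coreg_perturbations(
            design, n_proteins=100, n_correlated_pairs=20, n_events=0, seed=2)
        for pair in truth.planted_clusters:
            a, b = sorted(pair)
            r = np.corrcoef(matrix.values.loc[a], matrix.values.loc[b])[0, 1]
            assert abs(r) >= 0.9

    def test_events_reference_existing_entities(self, design):
        matrix, truth = simulate_coreg_perturbations(
            design, n_proteins=100, n_correlated_pairs=20, n_events=10, seed=2)
        for sample, protein in truth.perturbation_events:
            assert protein in matrix.values.index
            assert sample in matrix.values.columns

    def test_capacity_checks(self, design):
        with pytest.raises(ValueError):
            simulate_coreg_perturbations(design, n_proteins=10, n_correlated_pairs=6)
        with pytest.raises(ValueError):
            simulate_coreg_perturbations(design, n_proteins=100,
                                         n_correlated_pairs=10, n_events=11)


class TestPPIAndMotifs:
    def test_zero_background_exactly_cliques(self):
        features = [f"F{i}" for i in range(30)]
        el, _sites, truth = simulate_ppi_and_motifs(
            features, n_cliques=2, clique_size=5, background_edge_prob=0.0,
            seed=4)
        expected = set()
        for clique in truth.planted_clusters:
            nodes = sorted(clique)
            for i in range(len(nodes)):
                for j in range(i + 1, len(nodes)):
                    expected.add((nodes[i], nodes[j]))
        assert set(el.edges) == expected

    def test_cliques_fully_connected_with_background(self):
        features = [f"F{i}" for i in range(40)]
        el, _s, truth = simulate_ppi_and_motifs(
            features, n_cliques=2, clique_size=6, background_edge_prob=0.05,
            seed=4)
        for clique in truth.planted_clusters:
            nodes = sorted(clique)
            for i in range(len(nodes)):
                for j in range(i + 1, len(nodes)):
                    assert (nodes[i], nodes[j]) in el.edges

    def test_motif_windows_enriched_in_planted_cluster(self):
        from ifomics.kinase import KinaseMotif, match_motif

        pka = KinaseMotif("PKA", {-3: frozenset("R"), -2: frozenset("R"),
                                  0: frozenset("ST")})
        _el, sites, truth = simulate_ppi_and_motifs(
            [f"F{i}" for i in range(20)], n_cliques=1, clique_size=5,
            background_edge_prob=0.0, kinase_motifs=[pka], seed=4)
        cluster = sites[sites["cluster"] == "cluster_PKA"]
        bg = sites[sites["cluster"] == "background"]
        rate_cluster = cluster["window"].map(lambda w: match_motif(w, pka)).mean()
        rate_bg = bg["window"].map(lambda w: match_motif(w, pka)).mean()
        assert rate_cluster > rate_bg + 0.2

    def test_invalid_background_prob(self):
        with pytest.raises(ValueError):
            simulate_ppi_and_motifs(["A", "B", "C"], n_cliques=1, clique_size=2,
                                    background_edge_prob=1.5)

    def test_too_many_clique_nodes(self):
        with pytest.raises(ValueError):
            simulate_ppi_and_motifs(["A", "B", "C"], n_cliques=2, clique_size=2)


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path):
        gt = GroundTruth(
            differential_features={"P1": ("IF16", 1.0), "P2": ("EOD", -1.0)},
            enriched_terms={"T1": ("planted", "up")},
            perturbation_events={("AL_1", "C0003")},
            planted_clusters=[frozenset({"A", "B", "C"})],
            planted_motif_clusters={"cluster_PKA": "PKA"},
            target_mrna_protein_corr=0.47,
        )
        gt.write(tmp_path / "gt.tsv")
        back = GroundTruth.read(tmp_path / "gt.tsv")
        assert back.differential_features == gt.differential_features
        assert back.enriched_terms == gt.enriched_terms
        assert back.perturbation_events == gt.perturbation_events
        assert back.planted_clusters == gt.planted_clusters
        assert back.target_mrna_protein_corr == pytest.approx(0.47)
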