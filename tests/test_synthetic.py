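import numpy as np
import pytest

from paravar.conservation import build_profile, column_substitution_counts
from paravar.coords import to_domain_position
from paravar.synthetic import (
    FamilySimConfig,
    records_for_planted,
    simulate_orthologs,
    simulate_variant_tables,
    write_fasta,
    write_fixtures,
)
from paravar.variants import SOURCES, annotate_sites, overlap_categories, read_variants_tsv


class TestConfigValidation:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="21"):
            FamilySimConfig(protein_length=20, domain_start=1, domain_end=10)

    def test_bad_domain_bounds(self):
        with pytest.raises(ValueError):
            FamilySimConfig(protein_length=50, domain_start=30, domain_end=20)

    def test_bad_probability(self):
        with pytest.raises(ValueError):
            FamilySimConfig(p_sub_flank=1.5)

    def test_unknown_source(self):
        with pytest.raises(ValueError, match="unknown variant sources"):
            FamilySimConfig(n_variants_per_source={"hgmd": 3})

    def test_quota_beyond_site_capacity_rejected(self):
        cfg = FamilySimConfig(
            n_genes=1,
            species_per_gene=5,
            protein_length=30,
            domain_start=6,
            domain_end=25,
            n_variants_per_source={"gnomad": 40},
            seed=0,
        )
        alignments, truth = simulate_orthologs(cfg)
        with pytest.raises(ValueError, match="distinct sites"):
            simulate_variant_tables(cfg, truth, alignments)


class TestSimulateOrthologs:
    def test_no_substitution_limit(self):
        cfg = FamilySimConfig(
            n_genes=2,
            species_per_gene=8,
            protein_length=30,
            domain_start=10,
            domain_end=20,
            p_sub_domain=0.0,
            p_sub_flank=0.0,
            seed=5,
        )
        alignments, truth = simulate_orthologs(cfg)
        for gene, aln in alignments.items():
            ref = aln.sequences["human"]
            assert all(seq == ref for seq in aln.sequences.values())
            assert truth.s_counts[gene].sum() == 0
            assert truth.n_counts[gene].sum() == 0

    def test_determinism_byte_identical(self, tmp_path):
        cfg = FamilySimConfig(
            seed=42, n_genes=2, species_per_gene=10, protein_length=30,
            domain_start=6, domain_end=25,
        )
        a1, _ = simulate_orthologs(cfg)
        a2, _ = simulate_orthologs(cfg)
        for gene in a1:
            p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
            write_fasta(a1[gene], p1)
            write_fasta(a2[gene], p2)
            assert p1.read_bytes() == p2.read_bytes()

    def test_binomial_expectation_flank_nonsyn(self):
        # omega_flank=1, p_sub_flank=0.5, 50 species: every substituted codon
        # becomes nonsynonymous, so flank counts ~ Binomial(49, 0.5)
        means = []
        for seed in range(10):
            cfg = FamilySimConfig(
                n_genes=1,
                species_per_gene=50,
                protein_length=30,
                domain_start=1,
                domain_end=1,
                p_sub_flank=0.5,
                omega_flank=1.0,
                p_sub_domain=0.0,
                seed=seed,
            )
            _, truth = simulate_orthologs(cfg)
            flank = np.array(truth.region["GENE1"]) == "flank"
            assert truth.s_counts["GENE1"][flank].sum() == 0
            means.append(truth.n_counts["GENE1"][flank].mean())
        n_samples = 10 * 29  # seeds x flank codons
        se = np.sqrt(49 * 0.25 / n_samples)
        assert abs(np.mean(means) - 24.5) < 4 * se

    def test_truth_oracle_exact(self, small_family):
        alignments, truth = small_family
        for gene, aln in alignments.items():
            for i in range(1, aln.n_codons + 1):
                st = column_substitution_counts(aln, i)
                assert st.s == truth.s_counts[gene][i - 1]
                assert st.n == truth.n_counts[gene][i - 1]

    def test_reference_has_no_stops(self, small_family):
        alignments, _ = small_family
        for aln in alignments.values():
            assert "*" not in aln.reference_protein()

    def test_skipped_attempts_recorded_for_met_trp(self):
        # force omega=0 (synonymous required): M/W codons have no synonymous
        # neighbors, so attempts there must be skipped and recorded
        cfg = FamilySimConfig(
            n_genes=1,
            species_per_gene=40,
            protein_length=40,
            domain_start=1,
            domain_end=40,
            p_sub_domain=1.0,
            omega_domain=0.0,
            seed=2,
        )
        alignments, truth = simulate_orthologs(cfg)
        aln = alignments["GENE1"]
        protein = aln.reference_protein()
        mw_positions = {i + 1 for i, aa in enumerate(protein) if aa in "MW"}
        if mw_positions:  # overwhelmingly likely at length 40
            skipped_positions = {idx for _, _, idx in truth.skipped}
            assert mw_positions <= skipped_positions
            for pos in mw_positions:
                assert truth.s_counts["GENE1"][pos - 1] == 0
                assert truth.n_counts["GENE1"][pos - 1] == 0


class TestVariantTables:
    def test_zero_quota_empty_tables(self, tmp_path):
        cfg = FamilySimConfig(
            n_genes=1,
            species_per_gene=5,
            protein_length=30,
            domain_start=5,
            domain_end=25,
            n_variants_per_source={s: 0 for s in SOURCES},
            seed=1,
        )
        alignments, truth = simulate_orthologs(cfg)
        tables = simulate_variant_tables(cfg, truth, alignments)
        assert all(recs == [] for recs in tables.values())
        manifest = write_fixtures(cfg, tmp_path)
        for source in SOURCES:
            recs = read_variants_tsv(manifest[f"variants:{source}"], source)
            assert recs == []

    def test_quotas_met_and_truth_recorded(self, small_config, small_family):
        alignments, truth = small_family
        tables = simulate_variant_tables(small_config, truth, alignments)
        for source, n in small_config.n_variants_per_source.items():
            assert len(tables[source]) == n
        planted_rows = sum(len(p.sources) for p in truth.variants)
        assert planted_rows == sum(len(t) for t in tables.values())

    def test_planted_domain_variant_round_trip(self, small_config, small_family):
        alignments, truth = small_family
        tables = simulate_variant_tables(small_config, truth, alignments)
        records = [r for recs in tables.values() for r in recs]
        anns = {g: small_config.annotation(g) for g in alignments}
        summaries = annotate_sites(records, anns)
        by_site = {s.site: s for s in summaries}
        for planted in truth.variants:
            summ = by_site[(planted.gene, planted.protein_pos)]
            assert summ.sources == set(planted.sources)
            expected_in = (
                small_config.domain_start <= planted.protein_pos <= small_config.domain_end
            )
            assert summ.in_domain == expected_in
            assert summ.domain_pos == to_domain_position(
                planted.protein_pos, anns[planted.gene]
            )

    def test_planted_membership_maps_to_overlap_category(self, small_config):
        from paravar.synthetic import PlantedVariant

        planted = PlantedVariant(
            gene="GENE1",
            protein_pos=15,
            ref_aa="A",
            alt_aa="T",
            sources=("geno2mp", "gnomad"),
            attributes={"allele_count": 3, "cadd": 25.0, "hpo_profile_count": 2},
        )
        summaries = annotate_sites(records_for_planted(planted))
        cats = overlap_categories(summaries)
        assert set(cats) == {("geno2mp", "gnomad")}
        assert cats[("geno2mp", "gnomad")].n_sites == 1

    def test_variant_tables_deterministic(self, small_config, small_family):
        alignments, truth1 = small_family
        t1 = simulate_variant_tables(small_config, truth1, alignments)
        _, truth2 = simulate_orthologs(small_config)
        t2 = simulate_variant_tables(small_config, truth2, alignments)
        assert t1 == t2


class TestWriteFixtures:
    def test_round_trip_parsing(self, tmp_path, small_config):
        from paravar.conservation import read_codon_fasta
        from paravar.coords import read_annotations_tsv

        manifest = write_fixtures(small_config, tmp_path)
        alignments, truth = simulate_orthologs(small_config)
        for gene in small_config.gene_names():
            aln = read_codon_fasta(manifest[f"alignment:{gene}"], gene, "human")
            assert aln.sequences == alignments[gene].sequences
        anns = read_annotations_tsv(manifest["annotations"])
        assert anns["GENE1"].start == small_config.domain_start
        for source in SOURCES:
            read_variants_tsv(manifest[f"variants:{source}"], source)

    def test_packaged_tables_installed(self, tmp_path, small_config):
        manifest = write_fixtures(small_config, tmp_path)
        import pandas as pd

        t3 = pd.read_csv(manifest["fixture:table3"], sep="\t")
        t5 = pd.read_csv(manifest["fixture:table5"], sep="\t")
        assert len(t3) == 97
        assert len(t5) == 56


class TestEffectRecovery:
    def test_domain_flank_separation(self):
        # fast variant of the recovery invariant: 20 seeds, smaller family
        wins = 0
        for seed in range(20):
            cfg = FamilySimConfig(
                n_genes=1,
                species_per_gene=40,
                protein_length=60,
                domain_start=21,
                domain_end=40,
                p_sub_domain=0.3,
                p_sub_flank=0.3,
                omega_domain=0.05,
                omega_flank=0.8,
                seed=seed,
            )
            alignments, truth = simulate_orthologs(cfg)
            profile = build_profile(alignments["GENE1"])
            region = np.array(truth.region["GENE1"])
            dom = profile.score[region == "domain"].mean()
            flank = profile.score[region == "flank"].mean()
            if dom > flank:
                wins += 1
        assert wins >= 19
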