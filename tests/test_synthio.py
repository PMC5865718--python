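import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rdnamap as rm
from rdnamap import synthio
from rdnamap.contactmap import bin_genome
from rdnamap.synthio import (
    ContactPropensityModel,
    PseudogenePlant,
    SyntheticGenomeSpec,
    make_gene_models,
    make_toy_genome,
    simulate_contact_pairs,
    simulate_contact_records,
)


class TestMakeToyGenome:
    def test_sizes_table_and_no_plants(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("chr1", 3_500_000), ("chr2", 2_200_000)], seed=1
        )
        g = make_toy_genome(spec)
        sizes = g.sizes_table()
        assert len(sizes) == 2
        assert sizes.set_index("chrom")["length"].to_dict() == {
            "chr1": 3_500_000,
            "chr2": 2_200_000,
        }
        assert len(g.plant_truth()) == 0

    def test_fasta_output_deterministic(self, tmp_path):
        spec = SyntheticGenomeSpec(chromosomes=[("chr1", 200_000)], seed=42)
        out = []
        for i in range(2):
            g = make_toy_genome(spec)
            path = tmp_path / f"g{i}.fa"
            synthio.write_fasta(g.chromosomes, path)
            synthio.write_fasta(g.rdna, tmp_path / f"r{i}.fa")
            out.append(path.read_bytes() + (tmp_path / f"r{i}.fa").read_bytes())
        assert out[0] == out[1]

    def test_identity_one_plant_is_verbatim_copy(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("chr1", 2_000_000)],
            pseudogene_plants=[PseudogenePlant("chr1", 1_200_000, "45S", 500, 1.0)],
            seed=5,
        )
        g = make_toy_genome(spec)
        assert g.chromosomes["chr1"][1_200_000:1_200_500] == g.rdna["45S"][:500]

    def test_partial_identity_plant_matches_at_stated_rate(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("chr1", 1_000_000)],
            pseudogene_plants=[PseudogenePlant("chr1", 100_000, "5S", 1000, 0.85)],
            seed=5,
        )
        g = make_toy_genome(spec)
        copy = g.chromosomes["chr1"][100_000:101_000]
        ident = np.mean([a == b for a, b in zip(copy, g.rdna["5S"][:1000])])
        assert 0.80 <= ident <= 0.90

    def test_overlapping_plants_rejected(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("chr1", 1_000_000)],
            pseudogene_plants=[
                PseudogenePlant("chr1", 1000, "45S", 500, 1.0),
                PseudogenePlant("chr1", 1300, "5S", 500, 1.0),
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            make_toy_genome(spec)

    def test_plant_outside_chromosome_rejected(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[("chr1", 10_000)],
            pseudogene_plants=[PseudogenePlant("chr1", 9_800, "45S", 500, 1.0)],
        )
        with pytest.raises(ValueError, match="outside"):
            make_toy_genome(spec)

    def test_rdna_shares_no_kmer_with_genome(self, clean_genome):
        # rejection sampling: no 21-mer of either array occurs in the genome
        for seq in clean_genome.rdna.values():
            for start in range(0, len(seq) - 21, 97):
                kmer = seq[start : start + 21]
                assert all(kmer not in c for c in clean_genome.chromosomes.values())


class TestSimulateContactPairs:
    def test_degenerate_fractions_give_all_both_end(self, clean_genome):
        model = ContactPropensityModel(
            frac_rdna_pairs=1.0, frac_both_end_rdna=1.0, frac_repeat_mate=0.0, seed=1
        )
        ps = simulate_contact_pairs(clean_genome, model, n_pairs=200)
        assert set(ps.truth["category"]) == {"rdna_both"}

    def test_category_counts_conserve_n_pairs(self, mined_pairs):
        pairs, _, _ = mined_pairs
        assert pairs.truth["category"].value_counts().sum() == 50_000

    def test_category_fractions_match_model(self, mined_pairs):
        pairs, _, model = mined_pairs
        frac = pairs.truth["category"].value_counts(normalize=True)
        p_r = model.frac_rdna_pairs
        expected = {
            "rdna_genome": p_r * (1 - model.frac_both_end_rdna - model.frac_repeat_mate),
            "rdna_both": p_r * model.frac_both_end_rdna,
            "repeat_excluded": p_r * model.frac_repeat_mate,
            "non_rdna": 1 - p_r,
        }
        for cat, p in expected.items():
            # 4 sigma binomial tolerance at n=50,000
            tol = 4 * np.sqrt(p * (1 - p) / 50_000)
            assert abs(frac[cat] - p) < tol, cat

    def test_uniform_weights_pass_chi_square_gof(self, clean_genome):
        scheme = bin_genome(clean_genome.chrom_sizes)
        model = ContactPropensityModel(
            bin_weights=np.ones(scheme.n_bins),
            frac_rdna_pairs=1.0,
            frac_both_end_rdna=0.0,
            frac_repeat_mate=0.0,
            seed=2,
        )
        ps = simulate_contact_pairs(clean_genome, model, n_pairs=50_000)
        counts = ps.truth["bin_id"].value_counts().reindex(range(scheme.n_bins), fill_value=0)
        widths = (scheme.bins["end"] - scheme.bins["start"]).to_numpy()
        # oracle: multinomial over bins proportional to nothing but the
        # (uniform) weights; partial bins carry the same weight
        expected = np.full(scheme.n_bins, 50_000 / scheme.n_bins)
        p = stats.chisquare(counts.to_numpy(), f_exp=expected).pvalue
        assert p > 0.001

    def test_annotation_multiplier_recovered(self, clean_genome):
        scheme = bin_genome(clean_genome.chrom_sizes)
        ann = set(range(2))  # 2 of 5 bins
        model = ContactPropensityModel(
            bin_weights=np.ones(scheme.n_bins),
            annotation_multipliers={"boost": 4.0},
            annotation_bins={"boost": ann},
            frac_rdna_pairs=1.0,
            frac_both_end_rdna=0.0,
            frac_repeat_mate=0.0,
            seed=3,
        )
        ps = simulate_contact_pairs(clean_genome, model, n_pairs=20_000)
        truth = ps.truth
        in_ann = truth["bin_id"].isin(ann)
        # per-bin mean count ratio recovers the multiplier
        ratio = (in_ann.sum() / len(ann)) / ((~in_ann).sum() / (scheme.n_bins - len(ann)))
        assert ratio == pytest.approx(4.0, rel=0.2)

    def test_invalid_inputs_rejected(self, clean_genome):
        with pytest.raises(ValueError, match="n_pairs"):
            simulate_contact_pairs(clean_genome, ContactPropensityModel(), 0)
        with pytest.raises(ValueError, match="frac"):
            ContactPropensityModel(frac_both_end_rdna=0.7, frac_repeat_mate=0.5).validate()
        with pytest.raises(ValueError, match="read_len"):
            simulate_contact_pairs(clean_genome, ContactPropensityModel(), 10, read_len=10_000)

    def test_fastq_roundtrip_and_determinism(self, clean_genome, tmp_path):
        model = ContactPropensityModel(seed=9)
        fq = []
        for i in range(2):
            ps = simulate_contact_pairs(clean_genome, model, n_pairs=50)
            ps.to_fastq(tmp_path / f"a{i}.fq", tmp_path / f"b{i}.fq")
            fq.append((tmp_path / f"a{i}.fq").read_bytes())
        assert fq[0] == fq[1]
        from rdnamap.readprep import read_fastq_pairs

        back = list(read_fastq_pairs(tmp_path / "a0.fq", tmp_path / "b0.fq"))
        assert len(back) == 50
        assert back[0][1] == ps.pairs[0][1]


class TestSimulateContactRecords:
    def test_record_bins_follow_weights(self):
        sizes = {"chrA": 3_000_000, "chrB": 2_000_000}
        w = np.array([1.0, 2.0, 3.0, 2.0, 2.0])
        model = ContactPropensityModel(bin_weights=w, seed=4)
        rec = simulate_contact_records(sizes, model, 50_000)
        counts = rec["bin_id"].value_counts().reindex(range(5), fill_value=0)
        p = stats.chisquare(counts, f_exp=50_000 * w / w.sum()).pvalue
        assert p > 0.001

    def test_positions_lie_inside_their_bin(self):
        sizes = {"chrA": 2_500_000}
        model = ContactPropensityModel(seed=4)
        rec = simulate_contact_records(sizes, model, 5_000)
        scheme = bin_genome(sizes)
        recomputed = scheme.bin_index(rec["chrom"], rec["pos"])
        assert (recomputed == rec["bin_id"].to_numpy()).all()


class TestMakeGeneModels:
    def test_zero_genes_gives_empty_table(self):
        assert len(make_gene_models({"chr1": 100_000}, 0)) == 0

    def test_span_covers_first_to_last_exon(self):
        genes = make_gene_models({"chr1": 500_000}, 10, seed=2)
        for gid, grp in genes.groupby("gene_id"):
            assert grp["exon_start"].min() == grp["start"].iloc[0]
            assert grp["exon_end"].max() == grp["end"].iloc[0]
            assert (grp["exon_end"] > grp["exon_start"]).all()

    def test_genes_do_not_overlap(self):
        genes = make_gene_models({"chr1": 400_000, "chr2": 300_000}, 30, seed=3)
        spans = genes.drop_duplicates("gene_id").sort_values(["chrom", "start"])
        for _, grp in spans.groupby("chrom"):
            starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_gtf_text_deterministic_and_parsable(self, tmp_path):
        text = []
        for i in range(2):
            genes = make_gene_models({"chr1": 500_000}, 5, seed=9)
            path = tmp_path / f"g{i}.gtf"
            synthio.write_gtf(genes, path)
            text.append(path.read_text())
        assert text[0] == text[1]
        from rdnamap.genecontacts import read_gene_models

        back = read_gene_models(tmp_path / "g0.gtf")
        orig = make_gene_models({"chr1": 500_000}, 5, seed=9)
        # GTF round-trip preserves 0-based spans
        got = back.drop_duplicates("gene_id").set_index("gene_id")
        want = orig.drop_duplicates("gene_id").set_index("gene_id")
        assert got["start"].to_dict() == want["start"].to_dict()
        assert got["end"].to_dict() == want["end"].to_dict()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            make_gene_models({"chr1": 30_000}, 50, length_range=(2_000, 3_000))
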