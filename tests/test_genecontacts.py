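import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdnamap.genecontacts import (
    assign_gene_contacts,
    geneset_enrichment,
    gene_spans,
    ks_compare,
    select_quantile,
)
from rdnamap.masking import MaskSet
from rdnamap.synthio import ContactPropensityModel, make_gene_models, simulate_contact_records


def _records(rows, array="45S"):
    return pd.DataFrame(
        [("d", array, c, p, "rdna_genome") for c, p in rows],
        columns=["dataset", "array", "chrom", "pos", "category"],
    )


@pytest.fixture
def two_genes():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gB"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [100, 100, 1000],
            "end": [400, 400, 3000],
            "exon_start": [100, 300, 1000],
            "exon_end": [200, 400, 3000],
        }
    )


class TestAssignGeneContacts:
    def test_position_inside_span_counts(self, two_genes):
        table = assign_gene_contacts(_records([("chr1", 150)]), two_genes)
        assert table.set_index("gene_id").loc["gA", "count"] == 1

    def test_intron_position_counts(self, two_genes):
        # 250 falls between gA's exons but inside its first-to-last-exon span
        table = assign_gene_contacts(_records([("chr1", 250)]), two_genes)
        assert table.set_index("gene_id").loc["gA", "count"] == 1

    def test_cpgn_definition(self, two_genes):
        table = assign_gene_contacts(_records([("chr1", 1500)] * 5), two_genes)
        row = table.set_index("gene_id").loc["gB"]
        assert row["length"] == 2000
        assert row["cpgn"] == pytest.approx(5 / 2000)
        # invariant: cpgn * length = count
        assert (table["cpgn"] * table["length"]).round(9).tolist() == table["count"].tolist()

    def test_overlapping_genes_both_counted(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 500],
                "end": [1000, 1500],
                "exon_start": [0, 500],
                "exon_end": [1000, 1500],
            }
        )
        table = assign_gene_contacts(_records([("chr1", 700)]), genes)
        assert table["count"].tolist() == [1, 1]
        assert table.attrs["multiplicity"] == 2.0

    def test_masked_genes_removed(self, two_genes):
        mask = MaskSet(excluded_genes={"45S": {"gA"}})
        table = assign_gene_contacts(_records([("chr1", 150)]), two_genes, mask, array="45S")
        assert "gA" not in set(table["gene_id"])

    def test_half_open_boundary(self, two_genes):
        table = assign_gene_contacts(_records([("chr1", 400)]), two_genes)
        assert table.set_index("gene_id").loc["gA", "count"] == 0

    def test_length_proportional_contacts_debias(self):
        """CPGN removes the length correlation that raw counts carry.

        With uniform per-bp contact placement, P(record hits gene) is
        proportional to span length, so counts correlate strongly with
        length while CPGN does not.
        """
        sizes = {"chr1": 6_000_000, "chr2": 4_000_000}
        genes = make_gene_models(sizes, 500, length_range=(2_000, 20_000), seed=5)
        scheme_bins = 10  # 1 Mb bins
        model = ContactPropensityModel(bin_weights=np.ones(scheme_bins), frac_5s=0.0, seed=7)
        rec = simulate_contact_records(sizes, model, 150_000)
        table = assign_gene_contacts(rec, genes, array="45S")
        rho_count = stats.spearmanr(table["count"], table["length"]).statistic
        rho_cpgn = stats.spearmanr(table["cpgn"], table["length"]).statistic
        assert rho_count > 0.5
        assert abs(rho_cpgn) < 0.1


class TestSelectQuantile:
    @pytest.mark.parametrize("n,frac,expected", [(9864, 0.05, 494), (9595, 0.05, 480)])
    def test_top_fraction_size_uses_ceiling(self, n, frac, expected):
        table = pd.DataFrame({"gene_id": [f"g{i:05d}" for i in range(n)],
                              "cpgn": np.arange(n, dtype=float)})
        assert len(select_quantile(table, frac, "top")) == expected

    def test_bottom_half_returns_smallest(self):
        table = pd.DataFrame({"gene_id": list("abcdefghij"),
                              "cpgn": np.arange(10, dtype=float)})
        assert select_quantile(table, 0.5, "bottom") == list("abcde")

    def test_ties_break_lexicographically(self):
        table = pd.DataFrame({"gene_id": ["z", "a", "m"], "cpgn": [1.0, 1.0, 1.0]})
        assert select_quantile(table, 0.3, "top") == ["a"]
        assert select_quantile(table, 0.5, "bottom") == ["a", "m"]

    def test_invalid_arguments(self):
        table = pd.DataFrame({"gene_id": ["a"], "cpgn": [1.0]})
        with pytest.raises(ValueError):
            select_quantile(table, 0.9)
        with pytest.raises(ValueError):
            select_quantile(table.iloc[:0], 0.05)


class TestKsCompare:
    def test_identical_samples_give_zero_d(self):
        vals = np.arange(50, dtype=float)
        d, p = ks_compare(vals, vals)
        assert d == 0.0 and p == 1.0

    def test_large_shift_drives_d_to_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 100)
        d, p = ks_compare(a + 100, a)
        assert d == 1.0 and p < 1e-10

    def test_planted_shift_detected_at_moderate_n(self):
        # genes planted with 3x contact propensity vs background
        rng = np.random.default_rng(2)
        background = rng.poisson(10, 200).astype(float)
        shifted = rng.poisson(30, 200).astype(float)
        _, p = ks_compare(shifted, background)
        assert p < 0.01

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestGenesetEnrichment:
    def test_category_equal_to_selection_is_extreme(self):
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(10)}
        out = geneset_enrichment(selected, universe, {"self": set(selected)})
        assert np.isinf(out.loc[0, "odds_ratio"])
        assert out.loc[0, "p"] < 1e-10

    def test_fisher_p_matches_hypergeometric_oracle(self):
        # 2x2 table (20, 480, 80, 9020): p from summing hypergeometric tails
        a, b, c, d = 20, 480, 80, 9020
        universe = [f"g{i}" for i in range(a + b + c + d)]
        selected = universe[: a + b]
        category = universe[:a] + universe[a + b : a + b + c]
        out = geneset_enrichment(selected, universe, {"cat": category})
        M, n, N = a + b + c + d, a + c, a + b
        rv = stats.hypergeom(M, n, N)
        support = np.arange(max(0, N + n - M), min(n, N) + 1)
        pmf = rv.pmf(support)
        oracle = pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum()
        assert out.loc[0, "p"] == pytest.approx(oracle, rel=1e-6)

    def test_independent_category_p_roughly_uniform(self):
        # permutation oracle: random 10% categories give uniform p
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(1000)]
        selected = set(rng.choice(universe, 50, replace=False))
        ps = []
        for _ in range(200):
            cat = set(rng.choice(universe, 100, replace=False))
            out = geneset_enrichment(selected, universe, {"cat": cat})
            ps.append(out.loc[0, "p"])
        # discrete conservative p: check no spurious enrichment at the tail
        assert np.mean(np.array(ps) < 0.05) < 0.08

    def test_empty_category_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            out = geneset_enrichment({"a"}, {"a", "b"}, {"nil": {"zzz"}})
        assert len(out) == 0

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(500)]
        selected = set(universe[:50])
        cats = {f"c{j}": set(rng.choice(universe, 40, replace=False)) for j in range(20)}
        out = geneset_enrichment(selected, universe, cats)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        assert (out.sort_values("p")["p_adj"].diff().dropna() >= -1e-12).all()


def test_gene_spans_requires_positive_length():
    bad = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [10], "end": [10]})
    with pytest.raises(ValueError):
        gene_spans(bad)
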