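"""QC statistics: exact table arithmetic, coverage, GC windows, k-mer
signatures, taxonomy, pathway coverage."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramansort import data, seqqc
from ramansort import synthetic as syn


class TestMeanPct:
    @pytest.mark.parametrize(
        "values,decimals,expected",
        [
            (["80.11", "66.35", "19.13", "94.41"], 2, 65.00),
            (["58.66", "34.99", "48.39", "12.23", "19.44", "20.85", "13.01"], 2, 29.65),
            (["99.79", "97.86"], 2, 98.83),  # exercises half-up at the .825 boundary
            ([42.5], 2, 42.5),
        ],
    )
    def test_published_style_means(self, values, decimals, expected):
        assert seqqc.mean_pct(values, decimals) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seqqc.mean_pct([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            seqqc.mean_pct([50, 101])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.decimals(0, 100, places=2), min_size=1, max_size=10))
    def test_matches_rational_arithmetic(self, decimals):
        values = [str(d) for d in decimals]
        exact = sum(Fraction(v) for v in values) / len(values)
        got = Fraction(str(seqqc.mean_pct(values, 2)))
        assert abs(got - exact) <= Fraction(1, 200)  # within half of the last digit


class TestSuccessRate:
    @pytest.mark.parametrize(
        "pos,total,decimals,expected",
        [(26, 60, 1, 43.3), (45, 126, 0, 36.0), (9, 33, 2, 27.27),
         (10, 33, 2, 30.30), (7, 11, 2, 63.64), (0, 10, 2, 0.0)],
    )
    def test_benchmark_count_pairs(self, pos, total, decimals, expected):
        assert seqqc.success_rate(pos, total, decimals) == expected

    @pytest.mark.parametrize("pos,total", [(26, 60), (9, 33), (10, 33), (45, 126), (7, 11)])
    def test_rate_recovers_numerator(self, pos, total):
        rate = seqqc.success_rate(pos, total, 2)
        assert round(rate * total / 100) == pos

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            seqqc.success_rate(1, 0)


class TestCellSeqRecord:
    def test_row_sum_slack_warns(self):
        with pytest.warns(UserWarning, match="rounding slack"):
            seqqc.CellSeqRecord("s", "E", {"A": 40.0}, 10.0, "A")

    def test_negative_controls_exempt_from_row_sum(self):
        r = seqqc.CellSeqRecord("nc", "E", {"A": 0.0}, 74.4, None, is_negative_control=True)
        assert r.own_mapping_pct is None

    def test_bundled_benchmark_rows_load(self):
        records = data.mock_benchmark_records()
        assert len(records) == 52
        assert sum(r.is_negative_control for r in records) == 7
        assert all(0 <= r.hit_no_genomes_pct <= 100 for r in records)


class TestBatchSummary:
    def test_single_record_average_is_itself(self):
        r = seqqc.CellSeqRecord("s", "E", {"A": 90.0, "B": 1.0}, 9.0, "A", completeness_pct=50.0)
        summary = seqqc.batch_summary([r], {"E": 1})
        assert summary.per_group.loc[0, "mean_mapping_pct"] == 90.00
        assert summary.success_rates["E"] == 100.0

    def test_matches_naive_groupby_oracle(self, rng):
        refs = ["A", "B", "C"]
        records = []
        for i in range(30):
            own = refs[rng.integers(3)]
            own_pct = float(np.round(rng.uniform(60, 99), 2))
            mapped = {ref: 0.0 for ref in refs}
            mapped[own] = own_pct
            records.append(
                seqqc.CellSeqRecord(
                    f"s{i}", f"E{rng.integers(2)}", mapped, round(100 - own_pct, 2),
                    own, completeness_pct=float(np.round(rng.uniform(10, 99), 2)),
                )
            )
        summary = seqqc.batch_summary(records, {"E0": 20, "E1": 20})
        df = pd.DataFrame(
            {
                "expt": [r.experiment_id for r in records],
                "species": [r.taxonomy_bin for r in records],
                "mapping": [r.own_mapping_pct for r in records],
            }
        )
        oracle = df.groupby(["expt", "species"])["mapping"].mean()
        for row in summary.per_group.itertuples():
            assert row.mean_mapping_pct == pytest.approx(
                oracle[(row.experiment_id, row.species)], abs=0.005
            )

    def test_unknown_experiment_rejected(self):
        r = seqqc.CellSeqRecord("s", "E9", {"A": 95.0}, 5.0, "A")
        with pytest.raises(KeyError, match="unknown experiment"):
            seqqc.batch_summary([r], {"E1": 5})

    def test_benchmark_species_average_range(self):
        """Morphology-sorted groups span the published mapping-average range."""
        records = [r for r in data.mock_benchmark_records() if r.experiment_id.startswith("A-")]
        summary = seqqc.batch_summary(records, {"A-1": 20, "A-2": 20, "A-3": 20})
        assert summary.min_species_mapping == 52.79
        assert summary.max_species_mapping == 98.83


class TestCompleteness:
    def test_exact_tiling_gives_100(self):
        g = syn.SyntheticGenome("t", 10_000, 0.5, seed=1)
        ref = g.sequence()
        tiles = [(f"t{i}", ref[i : i + 500]) for i in range(0, 10_000, 500)]
        assert seqqc.completeness_by_aligned_bases(tiles, ref) == 100.00

    def test_half_reference_contig(self):
        g = syn.SyntheticGenome("h", 20_000, 0.5, seed=2)
        ref = g.sequence()
        assert seqqc.completeness_by_aligned_bases([("c", ref[:10_000])], ref) == 50.00

    def test_matches_boolean_array_oracle(self):
        g = syn.SyntheticGenome("o", 50_000, 0.45, seed=3)
        ref = g.sequence()
        rng = np.random.default_rng(4)
        starts = rng.choice(np.arange(0, 50_000 - 1000, 1000), size=20, replace=False)
        contigs = [(f"c{i}", ref[s : s + 1000]) for i, s in enumerate(starts)]
        got = seqqc.completeness_by_aligned_bases(contigs, ref)
        mask = np.zeros(len(ref), dtype=bool)
        for _cid, c in contigs:
            idx = ref.find(c)
            while idx != -1:
                mask[idx : idx + len(c)] = True
                idx = ref.find(c, idx + 1)
        oracle = round(100 * mask.sum() / mask.size, 2)
        assert got == oracle

    def test_k_longer_than_contig_rejected(self):
        with pytest.raises(ValueError, match="shortest contig"):
            seqqc.completeness_by_aligned_bases([("c", "ACGT")], "ACGT" * 100, anchor_k=31)


class TestGCWindows:
    def test_alternating_sequence_all_windows_half(self):
        gc = seqqc.gc_windows("ATGC" * 100, window=200)
        assert np.all(gc == 50.0)

    def test_all_g_sequence(self):
        gc = seqqc.gc_windows("G" * 1000, window=200)
        assert np.all(gc == 100.0)

    def test_matches_naive_count_oracle(self):
        g = syn.SyntheticGenome("gc62", 10_000, 0.62, seed=6)
        seq = g.sequence()
        got = seqqc.gc_windows(seq, window=200)
        naive = []
        for s in range(0, len(seq) - 199, 200):
            frag = seq[s : s + 200]
            naive.append(100 * sum(b in "GC" for b in frag) / 200)
        np.testing.assert_allclose(got, naive)
        assert abs(got.mean() - 62.0) < 2.0

    def test_ambiguity_codes_excluded_from_both_counts(self):
        seq = "G" * 100 + "N" * 100
        gc = seqqc.gc_windows(seq, window=200)
        assert gc[0] == 100.0  # 100 G out of 100 unambiguous

    def test_all_ambiguous_window_skipped(self):
        seq = "N" * 200 + "ATGC" * 50
        gc = seqqc.gc_windows(seq, window=200)
        assert gc.tolist() == [50.0]

    def test_tiling_mean_equals_whole_sequence_gc(self):
        g = syn.SyntheticGenome("w", 4_000, 0.4, seed=7)
        seq = g.sequence()
        whole = 100 * sum(b in "GC" for b in seq) / len(seq)
        assert seqqc.gc_windows(seq, window=200).mean() == pytest.approx(whole)


class TestGCProfile:
    def test_order0_contigs_near_normal(self):
        g = syn.SyntheticGenome("n", 500_000, 0.5, seed=8)
        contigs = syn.make_contigs(g, 100, 5000)
        prof = seqqc.gc_profile(contigs)
        assert prof.n_windows >= 2000
        assert abs(prof.skewness) < 0.2
        assert abs(prof.excess_kurtosis) < 0.3
        assert prof.normal_overlay_params == (prof.mean, prof.sd)

    def test_mixture_is_overdispersed(self):
        lo = syn.make_contigs(syn.SyntheticGenome("lo", 100_000, 0.30, seed=9), 20, 5000)
        hi = syn.make_contigs(syn.SyntheticGenome("hi", 100_000, 0.62, seed=10), 20, 5000)
        single_sd = seqqc.gc_profile(lo).sd
        mixed_sd = seqqc.gc_profile(lo + hi).sd
        assert mixed_sd > 2 * single_sd

    def test_constant_sequence_sd_zero(self):
        prof = seqqc.gc_profile([("c", "G" * 20_000)])
        assert prof.sd == 0.0

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            seqqc.gc_profile([("c", "ATGC" * 100)])


class TestKmerFeatures:
    def test_canonical_feature_count_is_136(self):
        assert len(seqqc.canonical_kmers(4)) == 136

    def test_poly_a_contig_single_feature(self):
        feats = seqqc.kmer_features([("pa", "A" * 1603)])
        row = feats.loc["pa"]
        assert row["AAAA"] == 1.0
        assert row.drop("AAAA").sum() == 0.0

    def test_rows_on_simplex(self):
        g = syn.SyntheticGenome("s", 50_000, 0.5, seed=11)
        feats = seqqc.kmer_features(syn.make_contigs(g, 10, 3000))
        np.testing.assert_allclose(feats.sum(axis=1), 1.0, atol=1e-9)

    def test_reverse_complement_invariance(self):
        g = syn.SyntheticGenome("rc", 10_000, 0.45, seed=12)
        (cid, seq), = syn.make_contigs(g, 1, 2000)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        feats = seqqc.kmer_features([("fwd", seq), ("rev", rc)])
        np.testing.assert_allclose(feats.loc["fwd"], feats.loc["rev"], atol=1e-12)

    def test_short_contigs_filtered_and_empty_rejected(self):
        with pytest.raises(ValueError, match="no contig longer"):
            seqqc.kmer_features([("short", "ACGT" * 100)])

    def test_non_acgt_kmers_skipped(self):
        feats = seqqc.kmer_features([("n", "A" * 1000 + "N" + "A" * 1000)])
        assert feats.loc["n", "AAAA"] == 1.0


@pytest.fixture(scope="module")
def three_genome_features():
    feats, labels = [], []
    for i, (gc, label) in enumerate(((0.30, "lo"), (0.45, "mid"), (0.62, "hi"))):
        g = syn.SyntheticGenome(label, 150_000, gc, seed=100 + i)
        f = seqqc.kmer_features(syn.make_contigs(g, 40, 2000))
        feats.append(f)
        labels += [label] * len(f)
    return pd.concat(feats), labels


class TestEmbedding:
    def test_species_separate_in_embedding(self, three_genome_features):
        from sklearn.metrics import silhouette_score

        feats, labels = three_genome_features
        coords = seqqc.embed_features(feats, perplexity=30, seed=0)
        assert silhouette_score(coords.to_numpy(), labels) > 0.5

    def test_same_seed_identical_duplicates_near(self, three_genome_features):
        feats, _ = three_genome_features
        a = seqqc.embed_features(feats, perplexity=30, seed=1)
        b = seqqc.embed_features(feats, perplexity=30, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_rows_rejected(self, three_genome_features):
        feats, _ = three_genome_features
        with pytest.raises(ValueError, match="rows"):
            seqqc.embed_features(feats.iloc[:10], perplexity=30)


class TestTopBinTaxonomy:
    def test_single_genus(self):
        genus, frac = seqqc.top_bin_taxonomy([("c1", 100, "Pantoea"), ("c2", 50, "Pantoea")])
        assert (genus, frac) == ("Pantoea", 1.0)

    def test_weighted_majority(self):
        genus, frac = seqqc.top_bin_taxonomy(
            [("c1", 800_000, "A"), ("c2", 200_000, "B")]
        )
        assert genus == "A"
        assert frac == pytest.approx(0.8)

    def test_matches_groupby_oracle(self, rng):
        genera = ["A", "B", "C", "D"]
        ann = [(f"c{i}", int(rng.integers(1, 10_000)), genera[rng.integers(4)]) for i in range(50)]
        genus, _ = seqqc.top_bin_taxonomy(ann)
        totals = {}
        for _c, ln, g in ann:
            totals[g] = totals.get(g, 0) + ln
        assert totals[genus] == max(totals.values())

    def test_tie_breaks_alphabetically_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            genus, _ = seqqc.top_bin_taxonomy([("c1", 10, "B"), ("c2", 10, "A")])
        assert genus == "A"


class TestPathwayCoverage:
    def test_bundled_modules_present(self):
        modules = seqqc.load_pathway_modules()
        assert set(modules) == {"MEP", "beta_carotene", "astaxanthin"}
        assert modules["astaxanthin"].steps == ("crtW", "crtZ")
        assert "ispA" in modules["MEP"].steps and "dxr" in modules["MEP"].steps

    def test_full_and_empty_label_sets(self):
        modules = seqqc.load_pathway_modules()
        mep = modules["MEP"]
        assert seqqc.pathway_step_coverage(mep.steps, "MEP") == (1.0, [])
        frac, missing = seqqc.pathway_step_coverage([], "MEP")
        assert frac == 0.0 and missing == list(mep.steps)

    def test_half_covered_astaxanthin_pair(self):
        frac, missing = seqqc.pathway_step_coverage({"crtZ"}, "astaxanthin")
        assert frac == 0.5
        assert missing == ["crtW"]

    def test_union_mode_pools_samples(self):
        frac, missing = seqqc.pathway_step_coverage([{"crtW", "crtZ"}, {"crtZ"}], "astaxanthin")
        assert frac == 1.0 and missing == []

    def test_unknown_module_rejected(self):
        with pytest.raises(KeyError, match="unknown pathway module"):
            seqqc.pathway_step_coverage({"crtZ"}, "zeaxanthin")
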