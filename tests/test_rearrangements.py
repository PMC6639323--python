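import numpy as np
import pandas as pd
import pytest
from scipy import stats

import soma
from soma.io import GenomeIndex, SvRecord, ValidationError
from soma.rearrangements import (
    CATEGORIES_32,
    build_rearrangement_catalog,
    chromosome_nonrandomness_test,
    classify_sv,
    consensus_cluster,
    flag_clustered_breakpoints,
    high_translocation_chromosomes,
    ks_uniform_pvalue,
    outlier_chromosomes,
)

from oracles import clustered_flags_oracle


def sv(pos1, pos2, sv_type="DEL", chrom1="chr1", chrom2=None, sample="s"):
    return SvRecord(sample, chrom1, pos1, chrom2 or chrom1, pos2, sv_type)


class TestClassification:
    def test_category_count(self):
        assert len(CATEGORIES_32) == 32
        assert sum(1 for c in CATEGORIES_32 if c.startswith("clustered")) == 16

    @pytest.mark.parametrize(
        "record,clustered,expected",
        [
            (sv(1000, 6000), False, "non-clustered:Del:1-10kb"),
            (sv(1000, 11_000, "DUP"), False, "non-clustered:Dup:10-100kb"),  # 10 kb boundary
            (sv(1000, 1_001_000, "INV"), True, "clustered:Inv:1-10Mb"),
            (sv(10, 20_000_011, "DEL"), False, "non-clustered:Del:>10Mb"),
            (sv(100, 200, "TRA", "chr5", "chr12"), True, "clustered:T"),
        ],
    )
    def test_examples(self, record, clustered, expected):
        assert classify_sv(record, clustered) == expected

    def test_sub_kb_folds_into_lowest_bin(self, caplog):
        with caplog.at_level("WARNING", logger="soma"):
            cat = classify_sv(sv(1000, 1500), False)
        assert cat == "non-clustered:Del:1-10kb" and "folded" in caplog.text

    def test_total_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = ["DEL", "DUP", "INV", "TRA"][int(rng.integers(4))]
            if t == "TRA":
                record = sv(int(rng.integers(1, 10**7)), int(rng.integers(1, 10**7)),
                            "TRA", "chr1", "chr2")
            else:
                p1 = int(rng.integers(1, 10**8))
                record = sv(p1, p1 + int(rng.integers(1, 3 * 10**7)), t)
            label = classify_sv(record, bool(rng.integers(2)))
            assert label in CATEGORIES_32


class TestWindowRule:
    def test_ten_in_900kb_all_flagged(self):
        svs = [sv(100_000 * i + 1, 100_000 * i + 5_000_000 + 90 * 10**6)
               for i in range(5)]
        # 5 DELs -> 5 left breakpoints in 400 kb + 5 right far away; add 5 more lefts
        svs += [sv(100_000 * i + 50_001, 200_000_000 + 3_000_000 * i) for i in range(5)]
        pairs, flags = flag_clustered_breakpoints(svs)
        assert all(p[0] for p in pairs)      # all left ends clustered
        assert all(flags)                    # OR rule marks every SV

    def test_nine_close_not_flagged(self):
        svs = [sv(10_000 * i + 1, 50_000_000 + 5_000_000 * i) for i in range(9)]
        pairs, flags = flag_clustered_breakpoints(svs)
        assert not any(p[0] for p in pairs) and not any(flags)

    def test_spread_beyond_window_not_flagged(self):
        # 10 left breakpoints spread over 1.8 Mb: max 6 in any 1 Mb window
        svs = [sv(200_000 * i + 1, 50_000_000 + 5_000_000 * i) for i in range(10)]
        _, flags = flag_clustered_breakpoints(svs)
        assert not any(flags)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        positions = np.sort(rng.integers(1, 30_000_000, size=2 * n))
        svs = [
            SvRecord("s", "chr1", int(a), "chr2", int(b), "TRA")
            for a, b in zip(positions[:n], positions[n:])
        ]
        pairs, _ = flag_clustered_breakpoints(svs)
        got_chr1 = np.array([p[0] for p in pairs])
        want = clustered_flags_oracle(
            np.array([s.pos1 for s in svs]), 1_000_000, 10
        )
        np.testing.assert_array_equal(got_chr1, want)


class TestCatalog:
    def test_row_sums_conserved(self):
        svs, truth = soma.simulate_sv_cohort(
            soma.SvSimulationConfig(
                counts={"non-clustered:Del:1-10kb": 5, "non-clustered:T": 3},
                n_samples=2, seed=1,
            )
        )
        cat = build_rearrangement_catalog(svs)
        assert (cat.sum(axis=1) == 8).all()

    def test_zero_row_for_empty_sample(self):
        cat = build_rearrangement_catalog(
            [sv(1000, 6000)], samples=["s", "empty"]
        )
        assert cat.loc["empty"].sum() == 0 and cat.loc["s"].sum() == 1

    def test_single_sv_single_cell(self):
        cat = build_rearrangement_catalog([sv(1000, 6000)])
        assert cat.to_numpy().sum() == 1
        assert cat.loc["s", "non-clustered:Del:1-10kb"] == 1


class TestNonRandomness:
    def test_tightly_packed_positions_flagged(self):
        positions = np.linspace(1_000_000, 1_900_000, 50).astype(int)
        p, flagged = chromosome_nonrandomness_test(positions, 100_000_000)
        assert p < 1e-5 and flagged

    def test_uniform_quantiles_not_flagged(self):
        n, length = 50, 100_000_000
        positions = [int(length * i / (n + 1)) for i in range(1, n + 1)]
        p, flagged = chromosome_nonrandomness_test(positions, length)
        assert p > 0.99 and not flagged

    def test_too_few_breakpoints_is_p1(self):
        p, flagged = chromosome_nonrandomness_test([10, 20, 30, 40], 1_000_000)
        assert p == 1.0 and not flagged

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            chromosome_nonrandomness_test([10, 2_000_000], 1_000_000)

    def test_agrees_with_scipy_kstest(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.uniform(0, 1000, size=40)
            ours = ks_uniform_pvalue(x, 1000)
            ref = stats.kstest(x / 1000, "uniform", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-8)


class TestOutlierAndTranslocation:
    def _genome(self, n=22):
        return GenomeIndex(tuple((f"chr{i + 1}", 1_000_000) for i in range(n)))

    def test_single_hot_chromosome_flagged(self):
        genome = self._genome()
        counts = {f"chr{i + 1}": 1 for i in range(21)}
        counts["chr22"] = 60  # 60 bp/Mb on a 1 Mb chromosome
        assert outlier_chromosomes(counts, genome) == {"chr22"}

    def test_count_floor_blocks_flag(self):
        genome = self._genome()
        counts = {f"chr{i + 1}": 1 for i in range(21)}
        counts["chr22"] = 20
        assert outlier_chromosomes(counts, genome) == set()

    def test_equal_rates_nothing_flagged(self):
        genome = self._genome()
        counts = {f"chr{i + 1}": 40 for i in range(22)}
        assert outlier_chromosomes(counts, genome) == set()

    def test_iqr_rule_matches_direct_quantiles(self):
        genome = self._genome(10)
        rng = np.random.default_rng(5)
        counts = {f"chr{i + 1}": int(rng.integers(30, 80)) for i in range(10)}
        rates = np.array([counts[c] for c in genome.names], float)  # 1 Mb chroms
        q25, q75 = np.percentile(rates, [25, 75])
        expected = {
            c for c in genome.names
            if counts[c] > q75 + 1.5 * (q75 - q25) and counts[c] >= 35
        }
        assert outlier_chromosomes(counts, genome) == expected

    def test_translocation_threshold(self):
        svs = [sv(100 + i, 200 + i, "TRA", "chr12", f"c{i}") for i in range(10)]
        assert high_translocation_chromosomes(svs) == {"chr12"}
        assert high_translocation_chromosomes(svs[:9]) == set()

    def test_tra_counts_both_sides(self):
        svs = [sv(100 + i, 200 + i, "TRA", "chr5", "chr12") for i in range(10)]
        assert high_translocation_chromosomes(svs) == {"chr5", "chr12"}


class TestConsensusClustering:
    def _two_group_exposures(self, seed=0, n_per=10, spread=0.02):
        rng = np.random.default_rng(seed)
        g1 = np.array([0.40, 0.40, 0.10, 0.05, 0.05])   # clustered-dominant
        g2 = np.array([0.05, 0.05, 0.20, 0.35, 0.35])   # non-clustered-dominant
        X = np.vstack(
            [g + spread * rng.standard_normal(5) for g in [g1] * n_per + [g2] * n_per]
        )
        X = np.clip(X, 1e-4, None)
        X = X / X.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            X, index=[f"S{i:02d}" for i in range(2 * n_per)],
            columns=[f"RS{j + 1}" for j in range(5)],
        )

    def test_planted_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        expo = self._two_group_exposures(seed=3)
        res = consensus_cluster(expo, k_range=[2], reps=100, seed=7)
        ari = adjusted_rand_score([0] * 10 + [1] * 10, res.assignments[2].to_numpy())
        assert ari == 1.0
        assert res.cluster_consensus[2].min() > 0.9

    def test_identical_samples_degenerate(self):
        expo = pd.DataFrame(
            np.tile([0.2, 0.2, 0.2, 0.2, 0.2], (8, 1)),
            index=[f"S{i}" for i in range(8)],
            columns=[f"RS{j + 1}" for j in range(5)],
        )
        with pytest.warns(UserWarning, match="degenerate|indistinguishable"):
            res = consensus_cluster(expo, k_range=[2], reps=10, seed=0)
        assert (res.consensus[2].to_numpy() == 1.0).all()

    def test_deterministic_under_seed(self):
        expo = self._two_group_exposures(seed=5)
        a = consensus_cluster(expo, k_range=[2, 3], reps=50, seed=11)
        b = consensus_cluster(expo, k_range=[2, 3], reps=50, seed=11)
        for k in (2, 3):
            np.testing.assert_array_equal(
                a.consensus[k].to_numpy(), b.consensus[k].to_numpy()
            )

    def test_too_few_samples_rejected(self):
        expo = self._two_group_exposures().iloc[:5]
        with pytest.raises(ValidationError):
            consensus_cluster(expo, k_range=[2], reps=5, seed=0)
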