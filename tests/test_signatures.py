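import numpy as np
import pandas as pd
import pytest

import soma
from soma.io import SnvRecord, ValidationError
from soma.signatures import (
    CHANNELS_96,
    TableContext,
    build_96_catalog,
    channel_of,
    cosine_match,
    dinucleotide_tally,
    extract_signatures_nmf,
    fit_exposures_qp,
    refit_with_threshold,
    strand_bias_counts,
)

from oracles import simplex_ls_oracle, refit_threshold_oracle


def snv(pos, ref, alt, sample="s", chrom="chr1"):
    return SnvRecord(sample, chrom, pos, ref, alt, tumor_depth=50,
                     tumor_alt_count=20, vaf=0.4)


class TestChannels:
    def test_layout(self):
        assert len(CHANNELS_96) == 96
        assert CHANNELS_96[0] == "A[C>A]A" and CHANNELS_96[-1] == "T[T>G]T"

    @pytest.mark.parametrize(
        "args,expected",
        [
            (("C", "T", "A", "G"), "A[C>T]G"),
            (("G", "A", "C", "T"), "A[C>T]G"),   # purine ref -> pyrimidine strand
            (("A", "C", "A", "T"), "A[T>G]T"),
            (("T", "G", "A", "T"), "A[T>G]T"),
        ],
    )
    def test_canonicalization(self, args, expected):
        assert channel_of(*args) == expected


class TestCatalog:
    def test_counts_and_strand_convention(self):
        ctx = TableContext({("chr1", 100): "ACG", ("chr1", 200): "CGT"})
        records = [snv(100, "C", "T"), snv(200, "G", "A")]
        cat = build_96_catalog(records, ctx)
        # G>A with genome context CGT maps to revcomp channel A[C>T]G
        assert cat.loc["s", "A[C>T]G"] == 2
        assert cat.sum(axis=1).tolist() == [2]

    def test_conservation_on_simulated_cohort(self, separated_signatures):
        expo = np.tile([0.5, 0.3, 0.2], (3, 1))
        cfg = soma.SnvSimulationConfig(
            signature_profiles=separated_signatures, exposures=expo,
            mutations_per_sample=500, seed=11,
        )
        cohort = soma.simulate_snv_cohort(cfg)
        cat = build_96_catalog(cohort.records, cohort.context)
        assert cat.to_numpy().sum() == 1500
        assert (cat.sum(axis=1) == 500).all()

    def test_ref_mismatch_raises(self):
        ctx = TableContext({("chr1", 100): "ATG"})  # center T, record says C
        with pytest.raises(ValidationError, match="disagree"):
            build_96_catalog([snv(100, "C", "T")], ctx)


class TestNmfExtraction:
    def test_deterministic_under_seed(self, separated_signatures):
        rng = np.random.default_rng(0)
        expo = rng.dirichlet([1, 1, 1], size=12)
        cfg = soma.SnvSimulationConfig(
            signature_profiles=separated_signatures, exposures=expo,
            mutations_per_sample=400, seed=5,
        )
        cohort = soma.simulate_snv_cohort(cfg)
        cat = build_96_catalog(cohort.records, cohort.context)
        a = extract_signatures_nmf(cat, [2], n_restarts=2, n_bootstrap=4, seed=9)
        b = extract_signatures_nmf(cat, [2], n_restarts=2, n_bootstrap=4, seed=9)
        pd.testing.assert_frame_equal(a[2].signatures, b[2].signatures)

    def test_rank1_catalog_degenerates_at_k2(self, reference_signatures):
        profile = reference_signatures.loc[["SBS2"]]
        expo = np.ones((10, 1))
        cfg = soma.SnvSimulationConfig(
            signature_profiles=profile, exposures=expo,
            mutations_per_sample=1500, seed=2,
        )
        cohort = soma.simulate_snv_cohort(cfg)
        cat = build_96_catalog(cohort.records, cohort.context)
        res = extract_signatures_nmf(
            cat, [1, 2], n_restarts=2, n_bootstrap=8, seed=3
        )
        assert res[1].reconstruction_error < 0.1   # sampling noise only
        assert res[2].mean_silhouette < 0.7        # stability collapses

    def test_invalid_rank(self, reference_signatures):
        cat = pd.DataFrame(
            np.ones((3, 96)), index=list("abc"), columns=list(CHANNELS_96)
        )
        with pytest.raises(ValidationError):
            extract_signatures_nmf(cat, [5], seed=0)


class TestCosineMatch:
    def test_identity_and_orthogonality(self, reference_signatures):
        sigs = reference_signatures.iloc[:2]
        matches = cosine_match(sigs, reference_signatures)
        assert all(m.similarity == pytest.approx(1.0) for m in matches)
        assert [m.best_reference_id for m in matches] == list(sigs.index)
        a = np.zeros(96); a[:10] = 0.1
        b = np.zeros(96); b[50:60] = 0.1
        disjoint = pd.DataFrame([a, b], index=["x", "y"], columns=list(CHANNELS_96))
        m = cosine_match(disjoint.iloc[[0]], disjoint.iloc[[1]])
        assert m[0].similarity == 0.0 and not m[0].assigned

    def test_noisy_copy_matches(self, reference_signatures):
        rng = np.random.default_rng(4)
        base = reference_signatures.loc["SBS7a"].to_numpy()
        noisy = rng.dirichlet(base * 20_000)  # ~5% relative perturbation
        query = pd.DataFrame([noisy], index=["q"], columns=list(CHANNELS_96))
        (m,) = cosine_match(query, reference_signatures)
        assert m.best_reference_id == "SBS7a" and m.similarity > 0.98 and m.assigned

    def test_channel_mismatch(self, reference_signatures):
        bad = reference_signatures.iloc[:, ::-1]
        with pytest.raises(ValidationError):
            cosine_match(bad, reference_signatures)


class TestExposureFit:
    def test_exact_mixture_recovered(self, separated_signatures):
        S = separated_signatures.to_numpy()
        m = 0.7 * S[0] + 0.3 * S[1]
        fit = fit_exposures_qp(m * 1000, separated_signatures)
        np.testing.assert_allclose(fit.proportions, [0.7, 0.3, 0.0], atol=1e-6)

    def test_single_signature_forced_to_one(self, reference_signatures):
        sig = reference_signatures.iloc[[3]]
        fit = fit_exposures_qp(np.ones(96), sig)
        assert fit.proportions.tolist() == [1.0]

    def test_empty_row_rejected(self, separated_signatures):
        with pytest.raises(ValidationError, match="no mutations"):
            fit_exposures_qp(np.zeros(96), separated_signatures)

    def test_qp_beats_random_simplex_points(self, reference_signatures):
        rng = np.random.default_rng(7)
        sigs = reference_signatures.iloc[:5]
        S = sigs.to_numpy()
        m = rng.dirichlet(np.ones(96))
        fit = fit_exposures_qp(m, sigs)
        random_objs = [
            float(np.sum((m - e @ S) ** 2))
            for e in rng.dirichlet(np.ones(5), size=1000)
        ]
        assert fit.objective <= min(random_objs) + 1e-12

    def test_matches_enumeration_oracle(self, reference_signatures):
        rng = np.random.default_rng(12)
        sigs = reference_signatures.iloc[:4]
        S = sigs.to_numpy()
        for _ in range(10):
            e_true = rng.dirichlet(np.ones(4))
            m = rng.dirichlet(200 * (e_true @ S))  # noisy mixture
            fit = fit_exposures_qp(m, sigs)
            e_star, obj_star = simplex_ls_oracle(S, m)
            assert fit.objective <= obj_star + 1e-9
            np.testing.assert_allclose(fit.proportions, e_star, atol=1e-4)


class TestRefitRule:
    def test_small_contributions_dropped(self, separated_signatures):
        S = separated_signatures.to_numpy()
        m = 0.87 * S[0] + 0.08 * S[1] + 0.05 * S[2]
        fit = refit_with_threshold(m * 5000, separated_signatures)
        assert fit.proportions.tolist() == [1.0]
        assert set(fit.dropped) == set(separated_signatures.index[1:])

    def test_balanced_mixture_unchanged(self, separated_signatures):
        S = separated_signatures.to_numpy()
        m = 0.55 * S[0] + 0.45 * S[1]
        fit = refit_with_threshold(m * 5000, separated_signatures.iloc[:2])
        np.testing.assert_allclose(fit.proportions, [0.55, 0.45], atol=1e-6)
        assert fit.dropped == {}

    def test_all_retained_meet_threshold(self, reference_signatures):
        rng = np.random.default_rng(21)
        sigs = reference_signatures.iloc[:5]
        S = sigs.to_numpy()
        for _ in range(20):
            e = rng.dirichlet(np.ones(5) * 0.5)
            m = rng.multinomial(3000, e @ S).astype(float)
            fit = refit_with_threshold(m, sigs)
            retained = fit.proportions[fit.proportions > 1e-12]
            assert len(retained) == 1 or (retained >= 0.10 - 1e-9).all()

    def test_matches_subset_refit_oracle(self, reference_signatures):
        rng = np.random.default_rng(31)
        sigs = reference_signatures.iloc[[0, 1, 2, 4, 5]]
        S = sigs.to_numpy()
        for _ in range(8):
            e = rng.dirichlet(np.ones(5) * 0.7)
            m = rng.multinomial(4000, e @ S).astype(float)
            fit = refit_with_threshold(m, sigs)
            full = fit.as_series().reindex(sigs.index).fillna(0.0).to_numpy()
            e_oracle = refit_threshold_oracle(S, m)
            np.testing.assert_allclose(full, e_oracle, atol=1e-3)


class TestStrandBias:
    def _footprints(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 5000],        # BED 0-based
                "end": [1000, 6000],
                "name": ["plusG", "minusG"],
                "score": [0, 0],
                "strand": ["+", "-"],
            }
        )

    def test_pyrimidine_on_coding_strand_is_untranscribed(self):
        df = strand_bias_counts([snv(100, "C", "T")], self._footprints())
        assert df.loc["C>T", "untranscribed"] == 1
        assert df.loc["C>T", "transcribed"] == 0

    def test_minus_strand_gene_flips_orientation(self):
        df = strand_bias_counts([snv(5500, "C", "T")], self._footprints())
        assert df.loc["C>T", "transcribed"] == 1

    def test_purine_reference_counts_on_opposite_strand(self):
        # G>A under a '+' gene: pyrimidine on the template strand -> transcribed
        df = strand_bias_counts([snv(100, "G", "A")], self._footprints())
        assert df.loc["C>T", "transcribed"] == 1

    def test_intergenic_excluded(self):
        df = strand_bias_counts([snv(3000, "C", "T")], self._footprints())
        assert df[["transcribed", "untranscribed"]].to_numpy().sum() == 0
        assert df.attrs["excluded_intergenic"] == 1


class TestDinucleotides:
    def test_adjacent_cc_tt(self):
        tally = dinucleotide_tally([snv(100, "C", "T"), snv(101, "C", "T")])
        assert tally["CC>TT"] == 1

    def test_gap_is_no_event(self):
        tally = dinucleotide_tally([snv(100, "C", "A"), snv(102, "T", "C")])
        assert tally.empty

    def test_purine_pair_canonicalized(self):
        tally = dinucleotide_tally([snv(100, "G", "A"), snv(101, "G", "A")])
        assert tally["CC>TT"] == 1

    def test_ct_ac_reported_as_printed(self):
        tally = dinucleotide_tally([snv(100, "C", "A"), snv(101, "T", "C")])
        assert tally["CT>AC"] == 1
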