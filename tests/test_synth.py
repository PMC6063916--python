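"""Generator-level tests: determinism, planted-feature calibration, IO."""

import numpy as np
import pytest

import equimsy as e
from equimsy._seq import encode


class TestDeterminism:
    def test_reference_bit_identical_for_same_config(self):
        cfg = dict(seed=42, ref_length=30_000,
                   amplicons=[e.AmpliconSpec(1000, 3, 0.05)],
                   transposition=e.TranspositionSpec(5000, 0.97, "direct"))
        r1, s1, t1 = e.simulate_reference(e.SynthConfig(**cfg))
        r2, s2, t2 = e.simulate_reference(e.SynthConfig(**cfg))
        assert r1.seq == r2.seq and s1.seq == s2.seq
        assert t1.class_intervals == t2.class_intervals

    def test_calls_and_counts_reproducible(self):
        cfg = e.SynthConfig(seed=7, ref_length=20_000,
                            samples=[e.SampleSpec("s1", "g", 5.0, 0.01)],
                            counts=e.CountsSpec(genes=["a", "b"],
                                                groups={"x": 2, "y": 2}))
        ref, _, _ = e.simulate_reference(cfg)
        c1, _ = e.simulate_calls(ref, cfg)
        c2, _ = e.simulate_calls(ref, cfg)
        assert np.array_equal(c1[0].depth, c2[0].depth)
        assert np.array_equal(c1[0].base, c2[0].base)
        m1, _ = e.simulate_counts(cfg)
        m2, _ = e.simulate_counts(cfg)
        assert m1.counts.equals(m2.counts)

    def test_streams_independent_of_other_outputs(self):
        """Adding a counts spec must not change the reference stream."""
        base = e.SynthConfig(seed=3, ref_length=10_000)
        with_counts = e.SynthConfig(seed=3, ref_length=10_000,
                                    counts=e.CountsSpec(genes=["g"],
                                                        groups={"a": 1, "b": 1}))
        assert e.simulate_reference(base)[0].seq == \
            e.simulate_reference(with_counts)[0].seq


class TestReference:
    def test_degenerate_config_is_all_single_copy(self):
        ref, source, truth = e.simulate_reference(e.SynthConfig(seed=1, ref_length=5000))
        assert source is None
        assert truth.class_intervals["single-copy"] == [(0, 5000)]
        assert not truth.class_intervals["ampliconic"]

    def test_planted_length_overflow_raises(self):
        cfg = e.SynthConfig(seed=1, ref_length=5000,
                            amplicons=[e.AmpliconSpec(2000, 3, 0.0)])
        with pytest.raises(ValueError, match="ref_length"):
            e.simulate_reference(cfg)

    def test_transposition_identity_matches_spec_within_binomial_noise(
            self, transposition_dataset):
        """Planted identity 0.988 over 125,171 bp: observed within 3 binomial SD."""
        ref = transposition_dataset["reference"]
        src = transposition_dataset["source"]
        tp = transposition_dataset["truth"].transposition
        a, b = tp["y_interval"]
        sa, sb = tp["source_interval"]
        from equimsy._seq import revcomp_codes

        seg = revcomp_codes(ref.codes[a:b])
        ident = float(np.mean(seg == src.codes[sa:sb]))
        assert b - a == 125_171
        assert abs(ident - 0.988) <= 0.003

    def test_amplicon_pairwise_divergence_brute_force(self):
        """Mean pairwise mismatch fraction across copies ~ the planted 9.8%."""
        cfg = e.SynthConfig(seed=21, ref_length=20_000,
                            amplicons=[e.AmpliconSpec(1500, 6, 0.098)])
        ref, _, truth = e.simulate_reference(cfg)
        copies = [ref.codes[a:b] for a, b in truth.amplicon_copies[0]]
        divs = [np.mean(copies[i] != copies[j])
                for i in range(len(copies)) for j in range(i + 1, len(copies))]
        assert abs(np.mean(divs) - 0.098) <= 0.01

    def test_dispersed_layout_one_interval_per_copy(self):
        cfg = e.SynthConfig(seed=2, ref_length=30_000,
                            amplicons=[e.AmpliconSpec(1000, 4, 0.01, "dispersed")])
        _, _, truth = e.simulate_reference(cfg)
        assert len(truth.class_intervals["ampliconic"]) == 4

    def test_truth_intervals_within_bounds_and_disjoint(self, amplicon_dataset):
        truth = amplicon_dataset["truth"]
        L = amplicon_dataset["reference"].length
        for label, ivs in truth.class_intervals.items():
            ivs = sorted(ivs)
            for (a, b) in ivs:
                assert 0 <= a < b <= L
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                assert b1 <= a2


class TestGametologs:
    def test_target_zero_gives_identical_pair(self):
        cfg = e.SynthConfig(seed=5, strata=[e.StratumSpec(1, 3, 0.0, (0, 100))])
        pairs, _ = e.simulate_gametologs(cfg)
        assert all(p.y_cds == p.x_cds for p in pairs)

    def test_saturation_bound_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            e.StratumSpec(1, 1, 2.5, (0, 100))

    @pytest.mark.parametrize("target,tol", [(0.32, 0.05), (1.18, 0.30)])
    def test_mean_estimated_ks_recovers_target(self, target, tol):
        cfg = e.SynthConfig(seed=17, cds_codons=600,
                            strata=[e.StratumSpec(1, 50, target, (0, 10**6))])
        pairs, _ = e.simulate_gametologs(cfg)
        ks = [e.li93_kaks(p)[1] for p in pairs]
        ks = [k for k in ks if k is not None]
        assert len(ks) >= 45
        assert abs(np.mean(ks) - target) <= tol

    def test_monotone_in_planted_divergence(self):
        """Larger planted Ks never gives a smaller mean estimate."""
        means = []
        for target in (0.05, 0.2, 0.5, 1.0):
            cfg = e.SynthConfig(seed=23, cds_codons=600,
                                strata=[e.StratumSpec(1, 10, target, (0, 1000))])
            pairs, _ = e.simulate_gametologs(cfg)
            means.append(np.mean([e.li93_kaks(p)[1] for p in pairs]))
        assert means == sorted(means)

    def test_cds_stop_free(self):
        cfg = e.SynthConfig(seed=29, cds_codons=200,
                            strata=[e.StratumSpec(1, 5, 1.5, (0, 100))])
        pairs, _ = e.simulate_gametologs(cfg)
        stops = {"TAA", "TAG", "TGA"}
        for p in pairs:
            for cds in (p.y_cds, p.x_cds):
                assert not any(cds[i:i + 3] in stops for i in range(0, len(cds), 3))


class TestCalls:
    def test_no_snps_no_cnv_matches_reference(self):
        cfg = e.SynthConfig(seed=31, ref_length=5000,
                            samples=[e.SampleSpec("s", "g", 8.0, 0.0)])
        ref, _, _ = e.simulate_reference(cfg)
        calls, _ = e.simulate_calls(ref, cfg)
        sc = calls[0]
        assert np.array_equal(sc.base[sc.called], ref.codes[sc.called])

    def test_deletion_zero_depth_uncalled(self):
        cfg = e.SynthConfig(seed=33, ref_length=5000,
                            samples=[e.SampleSpec("s", "g", 8.0, 0.0,
                                                  [e.CnvSpec(1000, 2000, 0.0)])])
        ref, _, _ = e.simulate_reference(cfg)
        calls, _ = e.simulate_calls(ref, cfg)
        sc = calls[0]
        assert not sc.depth[1000:2000].any()
        assert not sc.called[1000:2000].any()

    def test_duplication_poisson_mean(self):
        """Copy factor 2 at mean depth 10 over 200 kb: mean depth 20 +- 1."""
        cfg = e.SynthConfig(seed=35, ref_length=400_000,
                            samples=[e.SampleSpec("s", "g", 10.0, 0.0,
                                                  [e.CnvSpec(100_000, 300_000, 2.0)])])
        ref, _, _ = e.simulate_reference(cfg)
        calls, _ = e.simulate_calls(ref, cfg)
        assert abs(calls[0].depth[100_000:300_000].mean() - 20.0) <= 1.0

    def test_group_snps_shared_within_group(self):
        cfg = e.SynthConfig(seed=37, ref_length=20_000,
                            samples=[e.SampleSpec("a1", "grp", 50.0, 0.0),
                                     e.SampleSpec("a2", "grp", 50.0, 0.0)],
                            group_snp_rates={"grp": 0.01})
        ref, _, _ = e.simulate_reference(cfg)
        calls, _ = e.simulate_calls(ref, cfg)
        both = calls[0].called & calls[1].called
        assert np.array_equal(calls[0].base[both], calls[1].base[both])
        assert (calls[0].base[both] != ref.codes[both]).sum() > 50


class TestCounts:
    def test_fold_one_gives_unit_ratio(self):
        cfg = e.SynthConfig(seed=41, counts=e.CountsSpec(
            genes=[f"g{i}" for i in range(30)], groups={"a": 10, "b": 10}))
        cm, _ = e.simulate_counts(cfg)
        tab = e.expression_compare(cm, "a", "b")
        assert np.all(np.abs(np.log2(tab["fold"])) < 0.5)
        assert not tab["flagged"].any()

    def test_zero_expression_all_zero(self):
        cfg = e.SynthConfig(seed=43, counts=e.CountsSpec(
            genes=["dead", "alive"], groups={"a": 3, "b": 3},
            fold_changes={"dead": {"a": 0.0, "b": 0.0}}))
        cm, _ = e.simulate_counts(cfg)
        assert (cm.counts.loc["dead"] == 0).all()
        assert (cm.counts.loc["alive"] > 0).any()

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            e.CountsSpec(genes=["g"], groups={"a": 1, "b": 1}, dispersion=0.0)


class TestIO:
    def test_write_outputs_and_roundtrips(self, tmp_path):
        cfg = e.SynthConfig(seed=51, ref_length=4000,
                            amplicons=[e.AmpliconSpec(500, 3, 0.02)],
                            strata=[e.StratumSpec(1, 2, 0.1, (0, 1000))],
                            samples=[e.SampleSpec("s1", "g", 6.0, 0.005)],
                            counts=e.CountsSpec(genes=["a", "b"],
                                                groups={"x": 2, "y": 2}))
        paths = e.synth.write_outputs(tmp_path, cfg)
        for key in ("reference", "truth_bed", "gametologs", "calls", "counts",
                    "config"):
            assert (tmp_path / paths[key].split("/")[-1]).exists()

        # call-table roundtrip reproduces the in-memory arrays
        ref, _, _ = e.simulate_reference(cfg)
        calls, _ = e.simulate_calls(ref, cfg)
        back = e.synth.read_calls_tsv(paths["calls"])
        assert np.array_equal(back[0].called, calls[0].called)
        assert np.array_equal(back[0].depth, calls[0].depth)
        assert np.array_equal(back[0].base[back[0].called],
                              calls[0].base[calls[0].called])

        # config roundtrip drives an identical simulation
        cfg2 = e.synth.load_config(paths["config"])
        assert e.simulate_reference(cfg2)[0].seq == ref.seq
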