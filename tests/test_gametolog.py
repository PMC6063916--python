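"""Codon degeneracy, the LPB93 estimator, strata DP, topology, gene conversion."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import equimsy as e
from equimsy._seq import decode, mutate_codes, random_codes
from equimsy.gametolog import codon_degeneracy


BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def oracle_degeneracy(codon: str) -> tuple[int, int, int]:
    """Independent enumeration via biopython translation."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    out = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOPS and str(Seq(alt).translate()) == aa:
                syn += 1
        out.append(0 if syn == 0 else (4 if syn == 3 else 2))
    return tuple(out)


class TestDegeneracy:
    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if codon in STOPS:
                continue
            assert codon_degeneracy(codon) == oracle_degeneracy(codon), codon

    @pytest.mark.parametrize("cds,expected", [
        ("ATG", (3, 0, 0)),   # Met: no synonymous change anywhere
        ("GGG", (2, 0, 1)),   # Gly: fourfold third position
        ("AAA", (2, 1, 0)),   # Lys: twofold third position (AAA/AAG)
        ("ATT", (2, 1, 0)),   # Ile: threefold site folds into class 2
    ])
    def test_site_class_counts(self, cds, expected):
        assert e.classify_codon_sites(cds) == expected

    def test_internal_stop_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="stop"):
            counts = e.classify_codon_sites("ATGTAAGGG")
        assert sum(counts) == 6  # two usable codons

    def test_terminal_stop_dropped_silently(self):
        assert sum(e.classify_codon_sites("ATGTAA")) == 3


class TestLi93:
    def test_identical_sequences_zero(self):
        ka, ks, lc = e.li93_kaks(e.GametologPair("g", "ATGGCTAAA" * 5,
                                                 "ATGGCTAAA" * 5))
        assert ka == 0.0 and ks == 0.0 and not lc.undefined

    def test_closed_form_constructed_counts(self):
        """L=(300,200,100), P4=0.1, rest 0: Ka=0, Ks = 100*A4/300, A4=ln(1/0.8)/2."""
        ka, ks, _, _ = e.kaks_from_counts((300, 200, 100), (0, 0, 0.1), (0, 0, 0))
        a4 = 0.5 * math.log(1 / 0.8)
        assert ka == pytest.approx(0.0, abs=1e-9)
        assert ks == pytest.approx(100 * a4 / 300, abs=1e-9)

    @given(st.floats(0.0, 0.35), st.floats(0.0, 0.35))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_k2p_limit(self, p, q):
        """A + B equals the Kimura two-parameter distance for any (P, Q), so
        an all-fourfold alignment would reduce Ks to the K2P distance."""
        from hypothesis import assume

        assume(2 * p + q < 0.98 and 2 * q < 0.98)
        _, _, A, B = e.kaks_from_counts((1, 1, 1), (p, p, p), (q, q, q))
        k2p = -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
        assert A[2] + B[2] == pytest.approx(k2p, abs=1e-12)

    def test_symmetry_in_sequence_order(self):
        rng = np.random.default_rng(8)
        cfg = e.SynthConfig(seed=8, cds_codons=300,
                            strata=[e.StratumSpec(1, 3, 0.5, (0, 10))])
        pairs, _ = e.simulate_gametologs(cfg)
        for p in pairs:
            ka1, ks1, _ = e.li93_kaks(p)
            ka2, ks2, _ = e.li93_kaks(e.GametologPair(p.gene, p.x_cds, p.y_cds))
            assert ka1 == pytest.approx(ka2) and ks1 == pytest.approx(ks2)

    def test_saturated_transversions_flag_undefined(self):
        """Fourfold transversion proportion >= 1/2 makes the log undefined."""
        y = "GGA" * 10
        x = "GGC" * 8 + "GGA" * 2
        ka, ks, lc = e.li93_kaks(e.GametologPair("g", y, x))
        assert ka is None and ks is None and lc.undefined

    def test_gap_and_n_columns_dropped(self):
        base = "ATGGCTAAAGTT"
        with_gap = e.GametologPair("g", base + "---", base + "GCA")
        clean = e.li93_kaks(e.GametologPair("g", base, base))
        gapped = e.li93_kaks(with_gap)
        assert gapped[2].usable_codons == clean[2].usable_codons == 4
        assert gapped[:2] == clean[:2]

    def test_site_counts_sum_rule(self):
        _, _, lc = e.li93_kaks(e.GametologPair("g", "ATGGCTAAA" * 4,
                                               "ATGGCAAAA" * 4))
        assert sum(lc.L) == pytest.approx(3 * lc.usable_codons)


def brute_force_segmentation(values, k):
    """Exhaustive optimal contiguous k-segmentation (the oracle)."""
    n = len(values)
    best = (math.inf, None)
    for bounds in itertools.combinations(range(1, n), k - 1):
        cuts = [0, *bounds, n]
        cost = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            seg = values[a:b]
            cost += float(np.sum((seg - np.mean(seg)) ** 2))
        if cost < best[0] - 1e-12:
            best = (cost, list(bounds))
    return best


def pairs_from_ks(ks_values):
    out = []
    for i, k in enumerate(ks_values):
        p = e.GametologPair(f"g{i}", "ATG", "ATG", x_position=i * 10)
        p.ks = float(k)
        out.append(p)
    return out


class TestStrata:
    def test_constant_series_ties_to_earliest_boundary(self):
        res = e.assign_strata(pairs_from_ks([0.3] * 6), n_strata=2)
        assert res.boundaries == [1]
        assert res.cost == pytest.approx(0.0)

    def test_step_series_boundary_exact(self):
        vals = [1.2] * 10 + [0.3] * 10
        res = e.assign_strata(pairs_from_ks(vals), n_strata=2)
        assert res.boundaries == [10]
        assert [s.mean_ks for s in res.strata] == pytest.approx([1.2, 0.3])

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_dp_equals_exhaustive_search(self, seed, k):
        rng = np.random.default_rng(seed)
        vals = rng.random(12)
        res = e.assign_strata(pairs_from_ks(vals), n_strata=k)
        cost, bounds = brute_force_segmentation(vals, k)
        assert res.cost == pytest.approx(cost, abs=1e-9)
        assert res.boundaries == bounds

    def test_auto_mode_finds_three_clear_strata(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(1.18, 0.05, 10),
                               rng.normal(0.32, 0.03, 20),
                               rng.normal(0.13, 0.02, 10)])
        res = e.assign_strata(pairs_from_ks(vals), n_strata="auto")
        assert len(res.strata) == 3
        assert res.boundaries == [10, 30]

    def test_more_strata_than_genes_rejected(self):
        with pytest.raises(ValueError):
            e.assign_strata(pairs_from_ks([0.1, 0.2]), n_strata=3)

    def test_every_gene_assigned_once(self):
        res = e.assign_strata(pairs_from_ks([1.0, 0.9, 0.2, 0.1]), n_strata=2)
        assert sorted(res.gene_to_stratum) == [f"g{i}" for i in range(4)]
        assert sum(len(s.genes) for s in res.strata) == 4


class TestTopology:
    def test_monophyletic_pair(self):
        res = e.classify_y_topology("((a|Y,b|Y),(a|X,b|X));")
        assert res.pattern == "monophyletic" and res.n_y_clades == 1

    def test_polyphyletic_two_origins(self):
        res = e.classify_y_topology("(((a|Y,a|X),(b|Y,b|X)),og|A);",
                                    outgroup="og|A")
        assert res.pattern == "polyphyletic" and res.n_y_clades == 2

    def test_single_y_tip_monophyletic_by_convention(self):
        res = e.classify_y_topology("((a|Y,a|X),(b|X,c|X));")
        assert res.pattern == "monophyletic" and res.n_y_clades == 1

    def test_no_y_tips_rejected(self):
        with pytest.raises(ValueError, match="no Y"):
            e.classify_y_topology("((a|X,b|X),c|A);")


def diverged_triple(seed, length=3000, rate=0.05):
    rng = np.random.default_rng(seed)
    anc = random_codes(rng, length)
    return (anc, mutate_codes(anc, rate, rng), mutate_codes(anc, rate, rng),
            mutate_codes(anc, 2 * rate, rng))


class TestGeneconv:
    def test_identical_alignment_empty(self):
        assert e.geneconv_scan({"a": "ACGT" * 50, "b": "ACGT" * 50,
                                "c": "ACGT" * 50}) == []

    def test_planted_tract_detected(self):
        _, a, b, og = diverged_triple(300)
        b = b.copy()
        b[1200:1500] = a[1200:1500]
        frags = e.geneconv_scan({"A": decode(a), "B": decode(b), "OG": decode(og)},
                                n_perm=2000, seed=11)
        top = frags[0]
        assert top.pair == ("A", "B")
        assert top.p <= 0.01
        overlap = min(top.col_end, 1500) - max(top.col_start, 1200)
        assert overlap >= 200

    def test_order_invariance_and_determinism(self):
        _, a, b, og = diverged_triple(301)
        seqs = {"A": decode(a), "B": decode(b), "OG": decode(og)}
        f1 = e.geneconv_scan(seqs, n_perm=500, seed=5)
        f2 = e.geneconv_scan(dict(reversed(list(seqs.items()))), n_perm=500, seed=5)
        assert [(f.pair, f.p, f.score) for f in f1] == \
            [(f.pair, f.p, f.score) for f in f2]

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            e.geneconv_scan({"a": "ACGT", "b": "ACGT"})

    def test_low_n_perm_rejected(self):
        _, a, b, og = diverged_triple(302, length=200)
        with pytest.raises(ValueError, match="n_perm"):
            e.geneconv_scan({"A": decode(a), "B": decode(b), "OG": decode(og)},
                            n_perm=10)


class TestClockDate:
    def test_zero_ks_zero_time(self):
        assert e.clock_date(0.0, rate=1e-9) == 0.0

    def test_rate_formula(self):
        assert e.clock_date(0.2, rate=1e-9) == pytest.approx(1e8)

    def test_calibration_proportionality(self):
        assert e.clock_date(0.2, calibration=(0.1, 5e7)) == pytest.approx(1e8)

    @given(st.floats(1e-6, 2.0), st.floats(1e-6, 2.0), st.floats(1e3, 1e9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_calibration_scales_linearly(self, ks, ks_cal, t_cal):
        t = e.clock_date(ks, calibration=(ks_cal, t_cal))
        assert t == pytest.approx(ks * t_cal / ks_cal)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            e.clock_date(0.1)
        with pytest.raises(ValueError):
            e.clock_date(0.1, rate=0.0)
        with pytest.raises(ValueError):
            e.clock_date(0.1, rate=1e-9, calibration=(0.1, 1e7))
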