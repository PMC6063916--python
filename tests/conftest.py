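"""Shared fixtures: synthetic datasets reused across test modules.

The expensive fixtures (the assembly-scale reference with its mappability
track, the planted amplicon array, the planted transposition) are
session-scoped so the scans run once.
"""

from __future__ import annotations

import numpy as np
import pytest

import equimsy as e


@pytest.fixture(scope="session")
def amplicon_dataset():
    """120 kb reference with one planted 15-copy tandem array (3 kb unit,
    2% pairwise divergence) and the 0.9-identity self-scan hits."""
    cfg = e.SynthConfig(
        seed=105,
        ref_length=120_000,
        amplicons=[e.AmpliconSpec(unit_length=3000, copies=15, divergence=0.02,
                                  layout="tandem")],
    )
    ref, _, truth = e.simulate_reference(cfg)
    hits = e.self_identity_hits(ref, window=100, step=20, min_identity=0.9,
                                search_inverted=True)
    return {"config": cfg, "reference": ref, "truth": truth, "hits": hits}


@pytest.fixture(scope="session")
def transposition_dataset():
    """160 kb Y-like reference with the planted 125,171 bp inverted segment
    copied from a separately emitted X-PAR source at 98.8% identity."""
    cfg = e.SynthConfig(
        seed=107,
        ref_length=160_000,
        transposition=e.TranspositionSpec(length=125_171, identity=0.988,
                                          orientation="inverted"),
    )
    ref, source, truth = e.simulate_reference(cfg)
    segments = e.find_transposed_segment(ref, source)
    return {"config": cfg, "reference": ref, "source": source, "truth": truth,
            "segments": segments}


@pytest.fixture(scope="session")
def assembly_scale_dataset():
    """Assembly-scale (9.5 Mb) random reference with two samples: one carries a
    planted 200 kb x2 duplication, plus mappability track and 50 kb block
    means.  Shared by the block-diagnostic tests and the acceptance suite."""
    L = 9_500_000
    dup = e.CnvSpec(start=5_500_000, end=5_700_000, copy_factor=2.0)
    cfg = e.SynthConfig(
        seed=109,
        ref_length=L,
        samples=[
            e.SampleSpec("ancient1", "ancient", mean_depth=10.0, snp_rate=0.001,
                         cnvs=[dup]),
            e.SampleSpec("modern1", "modern", mean_depth=10.0, snp_rate=0.0005),
        ],
    )
    ref, _, _ = e.simulate_reference(cfg)
    calls, truth = e.simulate_calls(ref, cfg)
    track = e.mappability_track(ref, k=100)
    bmap50 = e.block_mean_mappability(track, 50_000)
    return {"config": cfg, "reference": ref, "calls": calls, "truth": truth,
            "track": track, "bmap50": bmap50, "dup": dup}


@pytest.fixture(scope="session")
def clade_calls_dataset():
    """200 kb reference, four samples in two clades (caballine/asine-shaped):
    group-level stem SNPs plus individual tip SNPs."""
    cfg = e.SynthConfig(
        seed=111,
        ref_length=200_000,
        samples=[
            e.SampleSpec("horse1", "caballine", 8.0, 0.0005),
            e.SampleSpec("horse2", "caballine", 8.0, 0.0005),
            e.SampleSpec("donkey", "asine", 8.0, 0.002),
            e.SampleSpec("onager", "asine", 8.0, 0.002),
        ],
        group_snp_rates={"caballine": 0.001, "asine": 0.008},
    )
    ref, _, _ = e.simulate_reference(cfg)
    calls, _ = e.simulate_calls(ref, cfg)
    track = e.mappability_track(ref, k=100)
    return {"config": cfg, "reference": ref, "calls": calls, "track": track}


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
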