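"""Multi-sample block diagnostics on a haploid reference.

Implements the read-mapping-free half of an equid MSY resequencing
comparison: a k-mer mappability track (1/occurrences, both strands),
fixed-width block coverage restricted to called sites, normalization by the
mean coverage of high-mappability blocks, per-block mismatch rates averaged
within sample groups, and run-based CNV flagging on normalized coverage.

Blocks are fixed-width in reference coordinates; the called-site
restriction is applied inside each block.  Undefined blocks (no called
sites, or below the mappability cutoff where one applies) propagate as NaN,
never as zero — zero coverage is a biological signal (deletion), missing is
not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import GenomeSequence, revcomp

__all__ = [
    "MappabilityTrack",
    "SampleCalls",
    "mappability_track",
    "block_mean_mappability",
    "block_coverage",
    "normalize_coverage",
    "mismatch_rates",
    "flag_cnv",
]


@dataclass
class MappabilityTrack:
    """Per-position k-mer uniqueness scores for a reference.

    ``scores[i]`` = 1 / (occurrences of the k-mer starting at i, counted on
    both strands); defined for i in [0, L-k].  K-mers containing N score 1
    by convention and are flagged in ``ambiguous``.
    """

    k: int
    scores: np.ndarray
    ambiguous: np.ndarray  # bool, same length as scores
    ref_length: int


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """64-bit polynomial hashes of every k-mer and of its reverse complement.

    Horner evaluation with a fixed odd multiplier; a k-mer and its reverse
    complement started at the same position hash through the same scheme,
    so occurrence counting over both strands reduces to joint lookups.
    Collisions are astronomically unlikely at genome scale and impossible
    to matter for the short fixtures the oracle tests use.
    """
    from ._seq import _COMPLEMENT

    B = np.uint64(0x9E3779B97F4A7C15)
    n = codes.size - k + 1
    h_f = np.zeros(n, dtype=np.uint64)
    h_r = np.zeros(n, dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    comp64 = _COMPLEMENT[codes].astype(np.uint64)
    tmp = np.empty(n, dtype=np.uint64)
    bp = np.uint64(1)
    with np.errstate(over="ignore"):
        for j in range(k):
            h_f *= B
            h_f += codes64[j : j + n]
            np.multiply(comp64[j : j + n], bp, out=tmp)
            h_r += tmp
            bp = bp * B
    return h_f, h_r


def mappability_track(reference: GenomeSequence, k: int = 100) -> MappabilityTrack:
    """k-mer mappability: score = 1/occurrences over both strands.

    K-mers containing N score 1 by convention and are flagged as ambiguous
    (ambiguity must not look like multi-mapping).
    """
    codes = reference.codes
    L = codes.size
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    h_f, h_r = _kmer_hashes(codes, k)
    ncum = np.concatenate([[0], np.cumsum(codes == 4)])
    has_n = (ncum[k:] - ncum[: L - k + 1]) > 0
    uniq, inv, cnt = np.unique(h_f, return_inverse=True, return_counts=True)
    occ_fwd = cnt[inv].astype(np.int64)
    # occurrences of each k-mer's reverse complement on the forward strand
    pos = np.searchsorted(uniq, h_r)
    pos_clip = np.minimum(pos, uniq.size - 1)
    found = uniq[pos_clip] == h_r
    occ_rc = np.where(found, cnt[pos_clip], 0).astype(np.int64)
    occ = occ_fwd + occ_rc
    scores = np.where(has_n, 1.0, 1.0 / occ)
    return MappabilityTrack(k=k, scores=scores, ambiguous=has_n, ref_length=L)


def block_mean_mappability(track: MappabilityTrack, block: int) -> np.ndarray:
    """Mean mappability score of each fixed-width block (NaN where no k-mer starts)."""
    n_blocks = math.ceil(track.ref_length / block)
    out = np.full(n_blocks, np.nan)
    starts = np.arange(track.scores.size)
    idx = starts // block
    sums = np.bincount(idx, weights=track.scores, minlength=n_blocks)
    cnts = np.bincount(idx, minlength=n_blocks)
    with np.errstate(invalid="ignore"):
        out[: sums.size] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return out


@dataclass
class SampleCalls:
    """Per-position genotyping summary for one sample on the reference.

    Arrays are reference-length: ``called`` (bool), ``depth`` (int),
    ``base`` (uint8 codes; only meaningful where called).
    """

    sample: str
    group: str
    called: np.ndarray
    depth: np.ndarray
    base: np.ndarray

    def __post_init__(self) -> None:
        L = self.called.size
        if self.depth.size != L or self.base.size != L:
            raise ValueError(f"{self.sample}: call arrays have unequal lengths")
        if (self.depth < 0).any():
            raise ValueError(f"{self.sample}: negative depth")


def _block_index(L: int, block: int) -> tuple[int, np.ndarray]:
    n_blocks = math.ceil(L / block)
    return n_blocks, np.arange(L) // block


def block_coverage(calls: SampleCalls, block: int = 50_000) -> np.ndarray:
    """Mean depth over called sites per block; NaN where a block has no called site."""
    L = calls.called.size
    n_blocks, idx = _block_index(L, block)
    called = calls.called
    depth_sum = np.bincount(idx[called], weights=calls.depth[called], minlength=n_blocks)
    n_called = np.bincount(idx[called], minlength=n_blocks)
    with np.errstate(invalid="ignore"):
        cov = np.where(n_called > 0, depth_sum / np.maximum(n_called, 1), np.nan)
    return cov


def normalize_coverage(raw: np.ndarray, block_mappability: np.ndarray,
                       high_map_threshold: float = 0.9) -> np.ndarray:
    """Divide block coverages by the sample's mean over high-mappability blocks.

    By construction the mean of the normalized values over high-mappability
    blocks with defined coverage is exactly 1.0.
    """
    if raw.size != block_mappability.size:
        raise ValueError("coverage and mappability block counts differ")
    high = (block_mappability >= high_map_threshold) & ~np.isnan(raw)
    if not high.any():
        raise ValueError("no high-mappability blocks with defined coverage")
    return raw / np.nanmean(raw[high])


def mismatch_rates(calls: list[SampleCalls], reference: GenomeSequence,
                   block: int = 50_000,
                   block_mappability: np.ndarray | None = None,
                   high_map_threshold: float = 0.9) -> pd.DataFrame:
    """Per-block mismatch rate per sample, with group means.

    Rate = (called sites with a non-reference base) / (called sites) per
    block; only high-mappability blocks are reported when a mappability
    vector is given.  Returns a long DataFrame with one row per
    (block, sample) plus rows per (block, group) where sample == "" and the
    ``rate`` is the group mean over its samples' defined blocks.
    """
    if not calls:
        raise ValueError("no samples")
    ref_codes = reference.codes
    L = len(reference)
    n_blocks, idx = _block_index(L, block)
    if block_mappability is not None and block_mappability.size != n_blocks:
        raise ValueError("block mappability length mismatch")
    rows = []
    per_sample = {}
    for sc in calls:
        called = sc.called
        mism = called & (sc.base != ref_codes)
        n_called = np.bincount(idx[called], minlength=n_blocks).astype(float)
        n_mism = np.bincount(idx[mism], minlength=n_blocks).astype(float)
        with np.errstate(invalid="ignore"):
            rate = np.where(n_called > 0, n_mism / np.maximum(n_called, 1), np.nan)
        if block_mappability is not None:
            rate = np.where(block_mappability >= high_map_threshold, rate, np.nan)
        per_sample[sc.sample] = (sc.group, rate)
        for b in range(n_blocks):
            rows.append((b, b * block, min((b + 1) * block, L), sc.sample, sc.group,
                         rate[b]))
    groups = sorted({g for g, _ in per_sample.values()})
    for g in groups:
        rates = np.stack([r for gg, r in per_sample.values() if gg == g])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            gmean = np.nanmean(rates, axis=0)
        for b in range(n_blocks):
            rows.append((b, b * block, min((b + 1) * block, L), "", g, gmean[b]))
    return pd.DataFrame(rows, columns=["block", "start", "end", "sample", "group", "rate"])


@dataclass
class CnvCall:
    sample: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    mean_normalized: float


def flag_cnv(normalized: np.ndarray, sample: str, block: int = 50_000,
             gain_threshold: float = 1.5, loss_threshold: float = 0.5,
             min_consecutive: int = 3, ref_length: int | None = None) -> list[CnvCall]:
    """Flag runs of aberrant normalized coverage as copy-number candidates.

    Maximal runs of >= ``min_consecutive`` consecutive blocks above
    ``gain_threshold`` (or below ``loss_threshold``) are reported with their
    merged reference interval.  NaN blocks break runs.
    """
    L = ref_length if ref_length is not None else normalized.size * block
    calls = []
    for kind, mask in (
        ("gain", normalized > gain_threshold),
        ("loss", normalized < loss_threshold),
    ):
        mask = mask & ~np.isnan(normalized)
        i = 0
        n = mask.size
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                if j - i >= min_consecutive:
                    calls.append(CnvCall(
                        sample=sample, start=i * block, end=min(j * block, L),
                        kind=kind,
                        mean_normalized=float(np.mean(normalized[i:j])),
                    ))
                i = j
            else:
                i += 1
    calls.sort(key=lambda c: c.start)
    return calls
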