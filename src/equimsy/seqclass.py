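"""Sequence-class delineation for a haploid Y assembly.

A triangular self-identity dot-plot (fixed-width motifs on a fixed step)
drives everything here: windows that match many other windows mark
ampliconic arrays; collinear runs of cross-sequence matches against an
X/PAR source sequence mark transposed segments; the remainder is
single-copy.  The final partition assigns every base exactly one class
with precedence XY-array > PAR-transposed > ampliconic > single-copy.

Windows are anchored at 0, step, 2*step, ...; a trailing partial window is
ignored (fixed-motif semantics).  Exact (identity 1.0) matching goes
through window hashing; sub-1.0 identity through a dense one-hot window
comparison, vectorised and chunked.  The segment model is indel-free: a
transposed segment pairs equal-length intervals on the two sequences.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._seq import GenomeSequence, N, revcomp

__all__ = [
    "GenomeSequence",
    "IdentityHit",
    "AmpliconBlock",
    "TransposedSegment",
    "self_identity_hits",
    "detect_ampliconic_blocks",
    "find_transposed_segment",
    "class_partition",
]


@dataclass(frozen=True)
class IdentityHit:
    """One off-diagonal dot: two windows matching at >= the scan identity."""

    a: int  # start of first window (a < b for self-hits)
    b: int  # start of second window
    orientation: str  # "direct" | "inverted"
    identity: float


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    return np.arange(0, length - window + 1, step)


def _window_matrix(codes: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    return codes[starts[:, None] + np.arange(window)[None, :]]


def _onehot(mat: np.ndarray) -> np.ndarray:
    """(W, window) codes -> (W, window*4) float32 one-hot; N rows are all-zero."""
    W, win = mat.shape
    out = np.zeros((W, win, 4), dtype=np.float32)
    valid = mat < 4
    idx = np.nonzero(valid)
    out[idx[0], idx[1], mat[valid]] = 1.0
    return out.reshape(W, win * 4)


def _identity_pairs(mat_a: np.ndarray, mat_b: np.ndarray, min_identity: float,
                    chunk: int = 1024) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (i, j, identity) with identity >= min_identity between two window sets."""
    window = mat_a.shape[1]
    oh_a = _onehot(mat_a)
    oh_b = _onehot(mat_b)
    ia_all, ib_all, id_all = [], [], []
    thresh = min_identity * window - 1e-9
    for lo in range(0, oh_a.shape[0], chunk):
        hi = min(lo + chunk, oh_a.shape[0])
        matches = oh_a[lo:hi] @ oh_b.T
        ii, jj = np.nonzero(matches >= thresh)
        if ii.size:
            ia_all.append(ii + lo)
            ib_all.append(jj)
            id_all.append(matches[ii, jj] / window)
    if not ia_all:
        empty = np.array([], dtype=int)
        return empty, empty.copy(), np.array([])
    return (np.concatenate(ia_all), np.concatenate(ib_all),
            np.concatenate(id_all).astype(float))


def self_identity_hits(seq: GenomeSequence, window: int = 100, step: int = 20,
                       min_identity: float = 1.0,
                       search_inverted: bool = False) -> list[IdentityHit]:
    """All off-diagonal window pairs matching at >= ``min_identity``.

    Each unordered pair is reported once with a < b.  With
    ``search_inverted``, one window is also compared against the reverse
    complement of the other.  At ``min_identity=1.0`` windows containing N
    never match (ambiguity is not identity); below 1.0, N positions count
    as mismatches.
    """
    starts = _window_starts(len(seq), window, step)
    mat = _window_matrix(seq.codes, starts, window)
    hits: list[IdentityHit] = []

    if min_identity >= 1.0:
        valid = ~np.any(mat == N, axis=1)
        buckets: dict[bytes, list[int]] = defaultdict(list)
        for w in np.flatnonzero(valid):
            buckets[mat[w].tobytes()].append(w)
        for idxs in buckets.values():
            for x in range(len(idxs)):
                for y in range(x + 1, len(idxs)):
                    hits.append(IdentityHit(int(starts[idxs[x]]), int(starts[idxs[y]]),
                                            "direct", 1.0))
        if search_inverted:
            from ._seq import revcomp_codes
            for w in np.flatnonzero(valid):
                rc_key = revcomp_codes(mat[w]).tobytes()
                for j in buckets.get(rc_key, ()):
                    if w < j:
                        hits.append(IdentityHit(int(starts[w]), int(starts[j]),
                                                "inverted", 1.0))
    else:
        ia, ib, ident = _identity_pairs(mat, mat, min_identity)
        keep = ia < ib
        for i, j, d in zip(ia[keep], ib[keep], ident[keep]):
            hits.append(IdentityHit(int(starts[i]), int(starts[j]), "direct", float(d)))
        if search_inverted:
            from ._seq import revcomp_codes
            rc_mat = np.stack([revcomp_codes(row) for row in mat])
            ia, ib, ident = _identity_pairs(mat, rc_mat, min_identity)
            keep = ia < ib
            for i, j, d in zip(ia[keep], ib[keep], ident[keep]):
                hits.append(IdentityHit(int(starts[i]), int(starts[j]),
                                        "inverted", float(d)))
    hits.sort(key=lambda h: (h.a, h.b, h.orientation))
    return hits


@dataclass
class AmpliconBlock:
    """A merged run of repeat-dense windows: one ampliconic array candidate."""

    start: int
    end: int
    hit_density: float  # mean off-diagonal hits per qualifying window
    copy_estimate: int
    mean_pairwise_divergence: float | None
    unit_length: int | None


def detect_ampliconic_blocks(hits: list[IdentityHit], seq: GenomeSequence,
                             window: int = 100, step: int = 20,
                             min_density: float = 1.0,
                             merge_gap: int = 2000) -> list[AmpliconBlock]:
    """Merge repeat-dense windows into ampliconic blocks.

    Per-window off-diagonal hit counts are thresholded at ``min_density``;
    qualifying windows <= ``merge_gap`` bases apart merge into one block.
    The copy estimate is 1 + the modal hit multiplicity of the block's
    windows; the repeat unit length is the modal hit lag, used to extract
    consecutive copies whose pairwise mismatch fractions give the block's
    mean divergence.
    """
    if not hits:
        return []
    starts = _window_starts(len(seq), window, step)
    n_win = starts.size
    counts = np.zeros(n_win, dtype=int)
    lag_by_window: dict[int, list[int]] = defaultdict(list)
    for h in hits:
        wa, wb = h.a // step, h.b // step
        counts[wa] += 1
        counts[wb] += 1
        lag = abs(h.b - h.a)
        lag_by_window[wa].append(lag)
        lag_by_window[wb].append(lag)

    qual = np.flatnonzero(counts >= min_density)
    if qual.size == 0:
        return []
    blocks = []
    run = [qual[0]]
    for w in qual[1:]:
        if (w - run[-1]) * step <= merge_gap:
            run.append(w)
        else:
            blocks.append(run)
            run = [w]
    blocks.append(run)

    out = []
    for run in blocks:
        b_start = int(starts[run[0]])
        b_end = int(starts[run[-1]]) + window
        mult = counts[run]
        copy_est = 1 + int(Counter(mult.tolist()).most_common(1)[0][0])
        lags = [lag for w in run for lag in lag_by_window.get(int(w), [])]
        unit = int(Counter(lags).most_common(1)[0][0]) if lags else None
        divergence = None
        if unit and unit > 0:
            n_copies = (b_end - b_start) // unit
            if n_copies >= 2:
                copies = [seq.codes[b_start + c * unit : b_start + (c + 1) * unit]
                          for c in range(n_copies)]
                divs = [float(np.mean(copies[x] != copies[y]))
                        for x in range(n_copies) for y in range(x + 1, n_copies)]
                divergence = float(np.mean(divs))
        out.append(AmpliconBlock(start=b_start, end=b_end,
                                 hit_density=float(np.mean(mult)),
                                 copy_estimate=copy_est,
                                 mean_pairwise_divergence=divergence,
                                 unit_length=unit))
    return out


@dataclass
class TransposedSegment:
    """An indel-free high-identity segment shared between two sequences."""

    y_start: int
    y_end: int
    source_start: int
    source_end: int
    orientation: str  # "direct" | "inverted"
    mean_identity: float

    @property
    def length(self) -> int:
        return self.y_end - self.y_start


_SEED_K = 24  # exact-seed length for candidate diagonals


def _candidate_offsets(y: str, other: str, min_votes: int,
                       max_bucket: int = 16) -> list[int]:
    """Diagonal offsets (y_pos - other_pos) supported by exact seed matches.

    Exact ``_SEED_K``-mers shared between the sequences vote for their
    diagonal; high-copy seeds (> ``max_bucket`` source occurrences) are
    skipped so repeats cannot flood the vote.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(other) - _SEED_K + 1):
        index[other[i : i + _SEED_K]].append(i)
    votes: Counter[int] = Counter()
    for i in range(len(y) - _SEED_K + 1):
        hits = index.get(y[i : i + _SEED_K])
        if hits and len(hits) <= max_bucket:
            for j in hits:
                votes[i - j] += 1
    return sorted(off for off, v in votes.items() if v >= min_votes)


def _diagonal_segments(y_codes: np.ndarray, other_codes: np.ndarray, offset: int,
                       window: int, step: int, min_identity: float,
                       merge_gap: int) -> list[tuple[int, int]]:
    """Qualifying-window runs along one indel-free diagonal (y coordinates).

    Windowed identity is evaluated at the y-grid anchors (multiples of
    ``step``) that fit inside the overlap; runs of qualifying windows with
    gaps <= ``merge_gap`` merge into candidate segments.
    """
    a0 = max(0, offset)
    a1 = min(y_codes.size, other_codes.size + offset)
    if a1 - a0 < window:
        return []
    match = (y_codes[a0:a1] == other_codes[a0 - offset : a1 - offset]).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(match)])
    first = ((a0 + step - 1) // step) * step
    anchors = np.arange(first, a1 - window + 1, step)
    if anchors.size == 0:
        return []
    rel = anchors - a0
    ident = (cum[rel + window] - cum[rel]) / window
    qual = anchors[ident >= min_identity - 1e-12]
    if qual.size == 0:
        return []
    runs = []
    run_start = prev = qual[0]
    for s in qual[1:]:
        if s - prev <= merge_gap:
            prev = s
        else:
            runs.append((int(run_start), int(prev) + window))
            run_start = prev = s
    runs.append((int(run_start), int(prev) + window))
    return runs


def find_transposed_segment(y_seq: GenomeSequence, source_seq: GenomeSequence,
                            window: int = 100, step: int = 20,
                            min_identity: float = 0.95, min_length: int = 5000,
                            merge_gap: int = 1000) -> list[TransposedSegment]:
    """Locate high-identity transposed segments of ``source_seq`` in ``y_seq``.

    Candidate collinear diagonals are seeded by exact shared k-mers in both
    orientations; along each candidate diagonal a base-level windowed
    identity scan (same window/step grid as the self dot-plot) marks
    qualifying windows, whose merged runs become segments.  Runs shorter
    than ``min_length`` are dropped and the mean identity is recomputed
    base-by-base over each merged segment.
    """
    if len(y_seq) == 0 or len(source_seq) == 0:
        raise ValueError("empty sequence")
    from ._seq import revcomp_codes

    segments: list[TransposedSegment] = []
    Ls = len(source_seq)
    # a genuine segment of min_length contributes ~min_length intact seeds at
    # high identity; demand a small fixed fraction of that
    min_votes = max(3, min_length // 2000)

    for orientation in ("direct", "inverted"):
        if orientation == "direct":
            other_str = source_seq.seq
            other_codes = source_seq.codes
        else:
            other_str = revcomp(source_seq.seq)
            other_codes = revcomp_codes(source_seq.codes)
        for off in _candidate_offsets(y_seq.seq, other_str, min_votes):
            for a_start, a_end in _diagonal_segments(
                    y_seq.codes, other_codes, off, window, step,
                    min_identity, merge_gap):
                if a_end - a_start < min_length:
                    continue
                b_start, b_end = a_start - off, a_end - off
                ident = float(np.mean(
                    y_seq.codes[a_start:a_end] == other_codes[b_start:b_end]))
                if orientation == "direct":
                    s_start, s_end = b_start, b_end
                else:
                    s_start, s_end = Ls - b_end, Ls - b_start
                segments.append(TransposedSegment(
                    y_start=a_start, y_end=a_end,
                    source_start=s_start, source_end=s_end,
                    orientation=orientation, mean_identity=ident))
    segments.sort(key=lambda s: (s.y_start, s.y_end, s.orientation))
    return segments


# class labels in increasing precedence order
CLASS_SINGLE = "single-copy"
CLASS_AMPLICONIC = "ampliconic"
CLASS_TRANSPOSED = "PAR-transposed"
CLASS_XY_ARRAY = "XY-ampliconic-array"


def _check_overlap(name: str, intervals: list[tuple[int, int]]) -> None:
    ivs = sorted(intervals)
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 < b1:
            warnings.warn(f"overlapping {name} intervals merged: "
                          f"({a1},{b1}) and ({a2},{b2})")


def class_partition(seq_length: int,
                    amplicon_blocks: list[tuple[int, int]] = (),
                    transposed_segments: list[tuple[int, int]] = (),
                    xy_array_intervals: list[tuple[int, int]] = (),
                    ) -> tuple[dict[str, list[tuple[int, int]]], dict[str, float]]:
    """Partition [0, seq_length) into labelled sequence classes.

    Precedence when features overlap: XY-array > PAR-transposed >
    ampliconic > single-copy.  Returns (intervals per class, class
    fractions); fractions sum to exactly 1.
    """
    label = np.zeros(seq_length, dtype=np.uint8)
    layers = [
        (1, CLASS_AMPLICONIC, amplicon_blocks),
        (2, CLASS_TRANSPOSED, transposed_segments),
        (3, CLASS_XY_ARRAY, xy_array_intervals),
    ]
    for code, name, intervals in layers:
        intervals = list(intervals)
        _check_overlap(name, intervals)
        for a, b in intervals:
            if not (0 <= a <= b <= seq_length):
                raise ValueError(f"{name} interval ({a},{b}) out of bounds")
            label[a:b] = code
    names = {0: CLASS_SINGLE, 1: CLASS_AMPLICONIC, 2: CLASS_TRANSPOSED, 3: CLASS_XY_ARRAY}
    out: dict[str, list[tuple[int, int]]] = {v: [] for v in names.values()}
    if seq_length:
        change = np.flatnonzero(np.diff(label)) + 1
        bounds = np.concatenate([[0], change, [seq_length]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            out[names[int(label[a])]].append((int(a), int(b)))
    counts = np.bincount(label, minlength=4)
    fractions = {names[i]: counts[i] / seq_length for i in range(4)}
    return out, fractions
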