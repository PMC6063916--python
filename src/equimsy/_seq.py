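"""Low-level DNA helpers shared across modules.

Sequences are handled in two forms: python strings over {A,C,G,T,N} for IO
and small cases, and uint8 code arrays (A=0, C=1, G=2, T=3, N=4) for the
vectorised scans.  Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# complement in code space; N maps to N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# transitions in code space: A<->G, C<->T
_TRANSITION = np.array([G, T, A, C, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate_codes(
    codes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    ts_tv: float | None = None,
) -> np.ndarray:
    """Return a copy with each site substituted independently at ``rate``.

    With ``ts_tv`` unset the alternative base is uniform over the three
    non-identical bases.  With ``ts_tv`` set, transitions are chosen over
    transversions in that ratio (e.g. 2.0 for a 2:1 transition excess).
    N sites are never mutated.
    """
    out = codes.copy()
    hit = np.flatnonzero((rng.random(codes.size) < rate) & (codes < 4))
    if hit.size == 0:
        return out
    if ts_tv is None:
        # uniform among the 3 alternatives: add 1..3 mod 4
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        out[hit] = (out[hit] + shift) % 4
    else:
        p_ts = ts_tv / (ts_tv + 1.0)
        is_ts = rng.random(hit.size) < p_ts
        ts_new = _TRANSITION[out[hit]]
        # two transversion choices per base: the complement and the remaining base
        comp = _COMPLEMENT[out[hit]]
        other = (0 + 1 + 2 + 3) - out[hit].astype(np.int64) - ts_new - comp
        pick_comp = rng.random(hit.size) < 0.5
        tv_new = np.where(pick_comp, comp, other.astype(np.uint8))
        out[hit] = np.where(is_ts, ts_new, tv_new)
    return out


@dataclass
class GenomeSequence:
    """A haploid reference sequence with an identifier.

    The canonical form is uppercase over {A,C,G,T,N}; ``codes`` is the
    uint8 representation, computed lazily.
    """

    id: str
    seq: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set(ALPHABET)
        if bad:
            raise ValueError(f"non-DNA characters in sequence {self.id!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.seq)
        return self._codes


def kimura2p_probs(t: float, ts_tv: float = 2.0) -> tuple[float, float]:
    """Closed-form K2P substitution probabilities after branch length ``t``.

    Rates are scaled so one substitution is expected per site per unit time,
    with transitions : transversions = ``ts_tv`` : 1 among substitutions.
    Returns (P transition, Q total transversion).
    """
    # alpha + 2 beta = 1 and alpha / (2 beta) = ts_tv
    beta = 1.0 / (2.0 * (ts_tv + 1.0))
    alpha = 1.0 - 2.0 * beta
    p = 0.25 + 0.25 * np.exp(-4.0 * beta * t) - 0.5 * np.exp(-2.0 * (alpha + beta) * t)
    q = 0.5 - 0.5 * np.exp(-4.0 * beta * t)
    return float(p), float(q)


def evolve_k2p(
    codes: np.ndarray, t: float, rng: np.random.Generator, ts_tv: float = 2.0
) -> np.ndarray:
    """Evolve each site under the K2P model for branch length ``t``.

    Exact closed-form site-substitution probabilities are used, so the
    expected corrected distance between the input and output equals ``t``.
    """
    p, q = kimura2p_probs(t, ts_tv)
    u = rng.random(codes.size)
    out = codes.copy()
    valid = codes < 4
    ts = valid & (u < p)
    tv = valid & (u >= p) & (u < p + q)
    out[ts] = _TRANSITION[out[ts]]
    if tv.any():
        comp = _COMPLEMENT[out[tv]]
        other = (6 - out[tv].astype(np.int64) - _TRANSITION[out[tv]] - comp).astype(np.uint8)
        pick = rng.random(int(tv.sum())) < 0.5
        out[tv] = np.where(pick, comp, other)
    return out
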