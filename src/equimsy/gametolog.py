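"""Molecular evolution of X-Y gametolog pairs.

This module covers the coding-sequence side of MSY analysis: codon
degeneracy classification, the Li/Pamilo-Bianchi (1993) Ka/Ks estimator,
dynamic-programming segmentation of X-ordered Ks values into evolutionary
strata, classification of Y-clade topology in gene trees, a Sawyer-style
permutation scan for gene conversion, and a strict-clock dating utility.

Estimator notes
---------------
The Ka/Ks estimator implemented here is the Pamilo-Bianchi-Li form (the
variant reported by PAML's yn00 under its "LPB93" label): sites are
classified as nondegenerate (0-fold), twofold or fourfold degenerate;
transition (P) and transversion (Q) difference proportions per class are
corrected with Kimura-style logs,

    A_i = 1/2 ln(1/(1 - 2 P_i - Q_i)) - 1/4 ln(1/(1 - 2 Q_i))
    B_i = 1/2 ln(1/(1 - 2 Q_i))

and combined as

    Ks = (L2 A2 + L4 A4) / (L2 + L4) + B4
    Ka = A0 + (L0 B0 + L2 B2) / (L0 + L2).

When any log argument is non-positive (saturation) the estimate is flagged
undefined rather than returned as NaN.  Threefold-degenerate positions
(the Ile family) are folded into the twofold class, following the LWL/LPB
convention; each codon is classified with its own degeneracy in each
sequence and the site counts averaged over the two sequences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Data import CodonTable

from ._seq import encode

__all__ = [
    "GametologPair",
    "LiCounts",
    "StratumAssignment",
    "ConversionFragment",
    "TopologyResult",
    "classify_codon_sites",
    "codon_degeneracy",
    "li93_kaks",
    "kaks_from_counts",
    "assign_strata",
    "classify_y_topology",
    "geneconv_scan",
    "clock_date",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)
_BASES = "ACGT"

# purine/pyrimidine membership for transition vs transversion calls
_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _translate(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _STANDARD.forward_table.get(codon)


def codon_degeneracy(codon: str) -> tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each position of ``codon``.

    A position's class is the number of synonymous single-base alternatives
    among its three neighbours: 0 synonymous -> 0-fold, 1 or 2 -> 2-fold,
    3 -> 4-fold.  Changes to or from stop codons are counted as
    nonsynonymous.  Raises ValueError for stop or ambiguous codons.
    """
    codon = codon.upper()
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"unrecognised codon {codon!r}")
    classes = []
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _translate(alt) == aa:
                syn += 1
        classes.append(0 if syn == 0 else (4 if syn == 3 else 2))
    return tuple(classes)


# cache: codon string -> per-position degeneracy classes
_DEGENERACY: dict[str, tuple[int, int, int]] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _cod = _b1 + _b2 + _b3
            if _cod not in _STOPS:
                _DEGENERACY[_cod] = codon_degeneracy(_cod)


def classify_codon_sites(cds: str) -> tuple[float, float, float]:
    """Total (L0, L2, L4) site counts for an in-frame CDS.

    Internal stop codons are excluded with a warning; a terminal stop is
    silently dropped.  The three counts sum to 3 x (usable codons).
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    counts = [0.0, 0.0, 0.0]
    for idx, cod in enumerate(codons):
        deg = _DEGENERACY.get(cod)
        if deg is None:
            if cod in _STOPS:
                warnings.warn(f"internal stop codon at codon {idx}; excluded")
            continue  # codons with N/gaps contribute nothing
        for cls in deg:
            if cls == 0:
                counts[0] += 1
            elif cls == 2:
                counts[1] += 1
            else:
                counts[2] += 1
    return tuple(counts)


@dataclass
class LiCounts:
    """Site counts and corrected distance components per degeneracy class."""

    L: tuple[float, float, float]  # (L0, L2, L4), averaged over both sequences
    P: tuple[float, float, float]  # transition difference proportions
    Q: tuple[float, float, float]  # transversion difference proportions
    A: tuple[float, float, float]  # transition-corrected distances
    B: tuple[float, float, float]  # transversion-corrected distances
    usable_codons: int
    undefined: bool = False


@dataclass
class GametologPair:
    """An aligned Y/X coding-sequence pair with its divergence estimates."""

    gene: str
    y_cds: str
    x_cds: str
    x_position: int = 0
    ks: float | None = None
    ka: float | None = None
    li_counts: LiCounts | None = None

    def __post_init__(self) -> None:
        if len(self.y_cds) != len(self.x_cds):
            raise ValueError(f"{self.gene}: aligned CDS lengths differ")
        if len(self.y_cds) % 3:
            raise ValueError(f"{self.gene}: aligned length not divisible by 3")


def kaks_from_counts(L: tuple[float, float, float], P: tuple[float, float, float],
                     Q: tuple[float, float, float],
                     ) -> tuple[float | None, float | None,
                                tuple[float, ...], tuple[float, ...]]:
    """(Ka, Ks, A, B) from per-class site counts and difference proportions.

    Applies the correction and combination formulas directly; Ka/Ks are
    None (with NaN A/B) when any required log argument is non-positive.
    """
    AB = [_corrected(P[i], Q[i]) for i in range(3)]
    if any(ab is None for ab in AB):
        return None, None, (math.nan,) * 3, (math.nan,) * 3
    A = tuple(ab[0] for ab in AB)
    B = tuple(ab[1] for ab in AB)
    ks = (L[1] * A[1] + L[2] * A[2]) / (L[1] + L[2]) + B[2] if (L[1] + L[2]) > 0 else None
    ka = A[0] + (L[0] * B[0] + L[1] * B[1]) / (L[0] + L[1]) if (L[0] + L[1]) > 0 else None
    return ka, ks, A, B


def _corrected(p: float, q: float) -> tuple[float, float] | None:
    """(A, B) distance components; None when a log argument is <= 0."""
    x1 = 1.0 - 2.0 * p - q
    x2 = 1.0 - 2.0 * q
    if x1 <= 0.0 or x2 <= 0.0:
        return None
    a = 0.5 * math.log(1.0 / x1) - 0.25 * math.log(1.0 / x2)
    b = 0.5 * math.log(1.0 / x2)
    return a, b


def li93_kaks(pair: GametologPair) -> tuple[float | None, float | None, LiCounts]:
    """Pamilo-Bianchi-Li Ka/Ks for one aligned gametolog pair.

    Codon columns containing a gap, an N, or a stop in either sequence are
    dropped before counting.  Returns (ka, ks, counts); ka/ks are None and
    ``counts.undefined`` is True when saturation makes a correction log
    undefined.  The estimate is symmetric in the two sequences.
    """
    y = pair.y_cds.upper()
    x = pair.x_cds.upper()
    L = [0.0, 0.0, 0.0]
    S = [0.0, 0.0, 0.0]  # transition difference counts per class
    V = [0.0, 0.0, 0.0]  # transversion difference counts per class
    usable = 0
    for i in range(0, len(y), 3):
        cy, cx = y[i : i + 3], x[i : i + 3]
        dy = _DEGENERACY.get(cy)
        dx = _DEGENERACY.get(cx)
        if dy is None or dx is None:
            continue  # gap/N/stop column
        usable += 1
        for pos in range(3):
            iy = {0: 0, 2: 1, 4: 2}[dy[pos]]
            ix = {0: 0, 2: 1, 4: 2}[dx[pos]]
            L[iy] += 0.5
            L[ix] += 0.5
            if cy[pos] != cx[pos]:
                tgt = S if _is_transition(cy[pos], cx[pos]) else V
                tgt[iy] += 0.5
                tgt[ix] += 0.5
    P = [S[i] / L[i] if L[i] > 0 else 0.0 for i in range(3)]
    Q = [V[i] / L[i] if L[i] > 0 else 0.0 for i in range(3)]
    ka, ks, A, B = kaks_from_counts(tuple(L), tuple(P), tuple(Q))
    counts = LiCounts(tuple(L), tuple(P), tuple(Q), A, B, usable,
                      undefined=ka is None)
    pair.ks, pair.ka, pair.li_counts = ks, ka, counts
    return ka, ks, counts


# ---------------------------------------------------------------------------
# Evolutionary strata segmentation
# ---------------------------------------------------------------------------

@dataclass
class Stratum:
    stratum_id: int
    genes: list[str]
    mean_ks: float
    x_interval: tuple[int, int]


@dataclass
class StratumAssignment:
    strata: list[Stratum]
    boundaries: list[int]  # gene-index boundaries (start of each stratum after the first)
    gene_to_stratum: dict[str, int]
    cost: float


def _segment_cost_matrix(values: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of values[i:j+1] around its mean, via prefix sums."""
    n = values.size
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = (j - i + 1).astype(float)
    tot = s1[j + 1] - s1[i]
    sq = s2[j + 1] - s2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = sq - tot**2 / cnt
    return np.where(j >= i, np.maximum(cost, 0.0), np.inf)


def assign_strata(pairs: list[GametologPair], n_strata: int | str = "auto",
                  max_strata: int = 6) -> StratumAssignment:
    """Segment X-ordered gametolog Ks values into contiguous strata.

    The gene series, ordered by X position, is split into ``n_strata``
    contiguous segments minimising the within-segment sum of squared
    deviations from the segment mean (exact dynamic programming).  Ties are
    broken toward the smaller first segment.  ``n_strata="auto"`` picks the
    number of strata at the elbow of the cost curve (largest second
    difference of cost over 1..max_strata).
    """
    usable = [p for p in pairs if p.ks is not None]
    usable.sort(key=lambda p: p.x_position)
    ks = np.array([p.ks for p in usable], float)
    n = ks.size
    if n == 0:
        raise ValueError("no genes with defined Ks")

    cost = _segment_cost_matrix(ks)

    def dp(k: int) -> tuple[float, list[int]]:
        # best[k][j] = min cost of splitting values[0..j] into k segments
        best = np.full((k + 1, n), np.inf)
        back = np.zeros((k + 1, n), dtype=int)
        best[1] = cost[0]
        for m in range(2, k + 1):
            for j in range(m - 1, n):
                # candidate last-segment starts s: segment values[s..j]
                cands = best[m - 1, m - 2 : j] + cost[m - 1 : j + 1, j]
                s = int(np.argmin(cands))  # earliest index on ties -> smaller first segments
                best[m, j] = cands[s]
                back[m, j] = s + m - 1  # start index of last segment
        bounds = []
        j = n - 1
        for m in range(k, 1, -1):
            s = back[m, j]
            bounds.append(s)
            j = s - 1
        return float(best[k, n - 1]), sorted(bounds)

    if n_strata == "auto":
        kmax = min(max_strata, n)
        costs = [dp(k)[0] for k in range(1, kmax + 1)]
        # elbow: grow k while each extra boundary at least halves the
        # residual SSE; stop at the first boundary that does not
        k_opt = 1
        for k in range(2, kmax + 1):
            if costs[k - 2] <= 0 or costs[k - 1] > 0.5 * costs[k - 2]:
                break
            k_opt = k
        n_strata = k_opt
    if not isinstance(n_strata, int) or n_strata < 1:
        raise ValueError(f"invalid n_strata {n_strata!r}")
    if n_strata > n:
        raise ValueError(f"{n_strata} strata requested for {n} genes")

    total, bounds = dp(n_strata)
    starts = [0] + bounds
    ends = bounds + [n]
    strata = []
    gene_to = {}
    for sid, (a, b) in enumerate(zip(starts, ends), start=1):
        seg = usable[a:b]
        strata.append(
            Stratum(
                stratum_id=sid,
                genes=[p.gene for p in seg],
                mean_ks=float(np.mean(ks[a:b])),
                x_interval=(seg[0].x_position, seg[-1].x_position),
            )
        )
        for p in seg:
            gene_to[p.gene] = sid
    return StratumAssignment(strata=strata, boundaries=bounds, gene_to_stratum=gene_to,
                             cost=total)


# ---------------------------------------------------------------------------
# Y-clade topology classification
# ---------------------------------------------------------------------------

@dataclass
class TopologyResult:
    pattern: str  # "monophyletic" | "polyphyletic"
    n_y_clades: int
    y_tips: list[str]


def _tip_chromosome(label: str) -> str:
    """Chromosome field of a 'species|chrom|gene' or 'species|chrom' label."""
    parts = label.split("|")
    if len(parts) >= 2:
        return parts[1].strip().upper()
    raise ValueError(f"tip label {label!r} lacks a '|chrom' field")


def classify_y_topology(tree: dendropy.Tree | str, outgroup: str | None = None) -> TopologyResult:
    """Classify whether the Y-linked tips of a gene tree are monophyletic.

    Tips are labelled ``species|chromosome[|gene]``; chromosome ``Y`` marks a
    Y homolog.  Unrooted trees must supply ``outgroup`` (a tip label) for
    rooting.  Returns the pattern and the number of maximal Y-only clades
    (1 for monophyly; e.g. 2 for the two-independent-origins pattern).  A
    single Y tip is monophyletic by convention.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not found")
        tree.reroot_at_edge(og.edge, update_bipartitions=False)
    y_tips = [lf for lf in tree.leaf_node_iter()
              if _tip_chromosome(lf.taxon.label) == "Y"]
    if not y_tips:
        raise ValueError("tree contains no Y tips")
    labels = [lf.taxon.label for lf in y_tips]
    if len(y_tips) == 1:
        return TopologyResult("monophyletic", 1, labels)

    y_set = set(id(lf) for lf in y_tips)

    def is_y_only(node) -> bool:
        return all(id(lf) in y_set for lf in node.leaf_iter())

    # count maximal Y-only clades by preorder traversal
    n_clades = 0
    skip = set()
    for node in tree.preorder_node_iter():
        if any(id(a) in skip for a in node.ancestor_iter()):
            continue
        if is_y_only(node):
            n_clades += 1
            skip.add(id(node))
    pattern = "monophyletic" if n_clades == 1 else "polyphyletic"
    return TopologyResult(pattern, n_clades, labels)


# ---------------------------------------------------------------------------
# Gene-conversion permutation scan (Sawyer-style)
# ---------------------------------------------------------------------------

@dataclass
class ConversionFragment:
    """A candidate converted tract between one sequence pair.

    ``start``/``end`` index the run in polymorphic-column space (half-open);
    ``col_start``/``col_end`` map it back to alignment columns.  ``p`` is
    the permutation-based global p-value.
    """

    pair: tuple[str, str]
    start: int
    end: int
    col_start: int
    col_end: int
    score: float
    p: float


def _max_fragment(scores: np.ndarray) -> tuple[float, int, int]:
    """Best-scoring contiguous run (Kadane), with its half-open bounds."""
    best = 0.0
    best_rng = (0, 0)
    cur = 0.0
    start = 0
    for i, s in enumerate(scores):
        if cur <= 0.0:
            cur = 0.0
            start = i
        cur += s
        if cur > best:
            best = cur
            best_rng = (start, i + 1)
    return best, best_rng[0], best_rng[1]


def _perm_max(scores_by_pair: list[np.ndarray], n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the global max fragment score.

    Each permutation shuffles polymorphic-column order (one shared
    permutation across all pairs, preserving the site-pattern coupling) and
    takes the maximum fragment score over pairs.  Vectorised Kadane: the max
    subarray sum of s equals max_j(prefix[j] - min_{i<j} prefix[i]).
    """
    ncols = scores_by_pair[0].size
    out = np.zeros(n_perm)
    mat = np.stack(scores_by_pair)  # pairs x cols
    for b in range(n_perm):
        perm = rng.permutation(ncols)
        sp = mat[:, perm]
        pref = np.cumsum(sp, axis=1)
        run_min = np.minimum.accumulate(np.concatenate(
            [np.zeros((sp.shape[0], 1)), pref[:, :-1]], axis=1), axis=1)
        out[b] = np.max(pref - run_min)
    return out


def geneconv_scan(sequences: dict[str, str], n_perm: int = 10_000,
                  seed: int = 0, penalty: float | None = None,
                  ) -> list[ConversionFragment]:
    """Scan an alignment of >= 3 sequences for gene-conversion tracts.

    Following Sawyer's approach, the alignment is reduced to its polymorphic
    columns.  For every sequence pair, each polymorphic column scores +1 if
    the two sequences match there and ``-penalty`` if they differ; the
    maximal-scoring run is the candidate converted tract.  The default
    penalty is (1 - q)/q for pair mismatch fraction q over polymorphic
    columns, which makes the expected score of a random stretch zero, so
    only unusually match-dense tracts accumulate score.  Significance is a
    global permutation test: polymorphic-column order is permuted
    ``n_perm`` times and the observed maximum compared with the null maxima,
    p = (1 + #{perm max >= observed}) / (1 + n_perm).

    Results are sorted by p then score and are independent of input
    sequence order.
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    names = sorted(sequences)
    L = len(sequences[names[0]])
    if any(len(sequences[nm]) != L for nm in names):
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.stack([encode(sequences[nm].upper()) for nm in names])
    informative = np.all(arr < 4, axis=0)
    poly = informative & (np.ptp(arr, axis=0) > 0)
    poly_cols = np.flatnonzero(poly)
    if poly_cols.size < 2:
        return []
    sub = arr[:, poly_cols]

    rng = np.random.default_rng(seed)
    pair_scores: list[np.ndarray] = []
    pair_names: list[tuple[str, str]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            match = sub[i] == sub[j]
            q = 1.0 - match.mean()
            if q == 0.0 or q == 1.0:
                continue  # identical or fully diverged pair: no contrast
            pen = penalty if penalty is not None else (1.0 - q) / q
            pair_scores.append(np.where(match, 1.0, -pen))
            pair_names.append((names[i], names[j]))
    if not pair_scores:
        return []

    observed = [_max_fragment(s) for s in pair_scores]
    null_max = _perm_max(pair_scores, n_perm, rng)

    frags = []
    for (nm, (score, a, b)) in zip(pair_names, observed):
        if score <= 0.0:
            continue
        p = (1.0 + np.sum(null_max >= score)) / (1.0 + n_perm)
        frags.append(
            ConversionFragment(
                pair=nm, start=a, end=b,
                col_start=int(poly_cols[a]), col_end=int(poly_cols[b - 1]) + 1,
                score=float(score), p=float(p),
            )
        )
    frags.sort(key=lambda f: (f.p, -f.score, f.pair))
    return frags


# ---------------------------------------------------------------------------
# Strict-clock dating
# ---------------------------------------------------------------------------

def clock_date(ks: float, rate: float | None = None,
               calibration: tuple[float, float] | None = None) -> float:
    """Divergence time in years under a strict molecular clock.

    Either ``rate`` (substitutions/site/year per lineage; T = Ks / (2 rate))
    or a ``calibration`` pair (Ks_cal, T_cal) with T = Ks * T_cal / Ks_cal.
    """
    if ks < 0:
        raise ValueError("ks must be non-negative")
    if (rate is None) == (calibration is None):
        raise ValueError("provide exactly one of rate or calibration")
    if rate is not None:
        if rate <= 0:
            raise ValueError("rate must be positive")
        return ks / (2.0 * rate)
    ks_cal, t_cal = calibration
    if ks_cal <= 0 or t_cal <= 0:
        raise ValueError("calibration values must be positive")
    return ks * t_cal / ks_cal
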