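"""Synthetic MSY-like data with exact ground truth.

Every downstream stage of the package can be exercised without external
data: this module emits (i) a haploid reference built from a random
single-copy background with planted tandem/dispersed ampliconic arrays and
a PAR-style transposed segment copied from a separately emitted X-PAR
source; (ii) codon-level gametolog pairs evolved under an exact K2P
process calibrated so the expected synonymous divergence equals a stratum
target; (iii) per-sample per-site call tables with Poisson depth,
sample-specific SNPs and planted copy-number variants; and (iv)
negative-binomial count matrices with planted fold changes.  Each
generator records everything it plants in a TruthSet with exact 0-based
half-open coordinates, so recovery tests never re-derive truth.

Reproducibility: a single global seed feeds independent sub-streams (one
per output kind), so byte-identical outputs follow from an identical
config regardless of which generators are invoked.

Calibration notes: an amplicon spec's divergence d is the expected
*pairwise* divergence between copies; each copy is mutated from the array
master at per-site rate m solving 2m - (4/3)m^2 = d (uniform alternative
bases), which makes the expected pairwise mismatch fraction equal d.  A
transposition spec's identity is exact in expectation because every
mutation changes the base.  Gametolog targets use branch length t =
target Ks per pair (t/2 per lineage) under K2P with a 2:1
transition:transversion ratio, for which the Li/Pamilo-Bianchi estimator
is consistent; targets above 2.0 are rejected (log corrections saturate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._seq import (
    GenomeSequence,
    decode,
    encode,
    evolve_k2p,
    mutate_codes,
    random_codes,
    revcomp_codes,
)
from .catalog import CountMatrix
from .gametolog import GametologPair
from .popblocks import SampleCalls

__all__ = [
    "AmpliconSpec",
    "TranspositionSpec",
    "StratumSpec",
    "SampleSpec",
    "CnvSpec",
    "CountsSpec",
    "SynthConfig",
    "TruthSet",
    "simulate_reference",
    "simulate_gametologs",
    "simulate_calls",
    "simulate_counts",
    "write_outputs",
    "read_calls_tsv",
    "load_config",
]

KS_SATURATION_BOUND = 2.0

# stream indices for the per-output random sub-streams
_STREAM_REFERENCE, _STREAM_GAMETOLOGS, _STREAM_CALLS, _STREAM_COUNTS = range(4)


def _fraction(name: str, x: float) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")
    return float(x)


@dataclass
class AmpliconSpec:
    """A planted repeat array: unit length, copy count, pairwise divergence."""

    unit_length: int
    copies: int
    divergence: float
    layout: str = "tandem"  # "tandem" | "dispersed"

    def __post_init__(self) -> None:
        if self.unit_length <= 0 or self.copies < 2:
            raise ValueError("amplicon needs unit_length > 0 and copies >= 2")
        _fraction("divergence", self.divergence)
        if self.layout not in ("tandem", "dispersed"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass
class TranspositionSpec:
    length: int
    identity: float
    orientation: str = "inverted"  # "direct" | "inverted"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("transposition length must be positive")
        _fraction("identity", self.identity)
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class StratumSpec:
    stratum_id: int
    n_genes: int
    target_ks: float
    x_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("stratum needs >= 1 gene")
        if self.target_ks < 0:
            raise ValueError("target Ks must be >= 0")
        if self.target_ks > KS_SATURATION_BOUND:
            raise ValueError(
                f"target Ks {self.target_ks} exceeds the estimator saturation "
                f"bound {KS_SATURATION_BOUND}")
        if self.x_range[0] >= self.x_range[1]:
            raise ValueError("empty X-position range")


@dataclass
class CnvSpec:
    start: int
    end: int
    copy_factor: float  # 0 = deletion, 2 = duplication, ...

    def __post_init__(self) -> None:
        if self.start >= self.end or self.copy_factor < 0:
            raise ValueError("invalid CNV spec")


@dataclass
class SampleSpec:
    sample_id: str
    group: str
    mean_depth: float
    snp_rate: float = 0.0
    cnvs: list[CnvSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")
        _fraction("snp_rate", self.snp_rate)


@dataclass
class CountsSpec:
    genes: list[str]
    groups: dict[str, int]  # group label -> replicate count
    base_mean: float = 3000.0
    dispersion: float = 20.0  # NB size parameter; var = mu + mu^2/size
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) < 2 or any(n < 1 for n in self.groups.values()):
            raise ValueError("need >= 2 groups with >= 1 replicate each")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SynthConfig:
    seed: int = 0
    ref_length: int = 200_000
    chrom: str = "synthY"
    amplicons: list[AmpliconSpec] = field(default_factory=list)
    transposition: TranspositionSpec | None = None
    strata: list[StratumSpec] = field(default_factory=list)
    cds_codons: int = 600
    samples: list[SampleSpec] = field(default_factory=list)
    group_snp_rates: dict[str, float] = field(default_factory=dict)
    counts: CountsSpec | None = None

    def __post_init__(self) -> None:
        if self.ref_length <= 0:
            raise ValueError("ref_length must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


@dataclass
class TruthSet:
    """Exact coordinates and values of everything a generator planted."""

    class_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    amplicon_copies: list[list[tuple[int, int]]] = field(default_factory=list)
    transposition: dict | None = None
    snp_positions: dict[str, np.ndarray] = field(default_factory=dict)
    cnv_intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    gene_truth: pd.DataFrame | None = None
    fold_truth: dict[str, dict[str, float]] = field(default_factory=dict)


def _pairwise_to_percopy_rate(d: float) -> float:
    """Per-copy mutation rate m with expected pairwise divergence d.

    Two copies independently mutated at rate m (uniform alternatives)
    differ at a site with probability 2m - (4/3)m^2; invert that.
    """
    if d == 0.0:
        return 0.0
    disc = 4.0 - 16.0 * d / 3.0
    if disc < 0:
        raise ValueError(f"pairwise divergence {d} not reachable")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def simulate_reference(config: SynthConfig) -> tuple[GenomeSequence, GenomeSequence | None, TruthSet]:
    """Build the synthetic reference, its X-PAR source, and the truth set.

    Returns (reference, xpar_source, truth); the source is None when no
    transposition is configured.  Features are laid out left to right with
    equal single-copy spacers; the total planted length must fit within
    ``ref_length``.
    """
    rng = config.rng(_STREAM_REFERENCE)
    L = config.ref_length

    # feature payloads, left to right: tandem arrays as one feature, dispersed
    # arrays as one feature per copy, then the transposed segment
    features: list[tuple[str, int, dict]] = []
    for ai, spec in enumerate(config.amplicons):
        master = random_codes(rng, spec.unit_length)
        m = _pairwise_to_percopy_rate(spec.divergence)
        copies = [mutate_codes(master, m, rng) for _ in range(spec.copies)]
        if spec.layout == "tandem":
            features.append(("amplicon", spec.unit_length * spec.copies,
                             {"array": ai, "copies": copies}))
        else:
            for ci, cp in enumerate(copies):
                features.append(("amplicon", spec.unit_length,
                                 {"array": ai, "copies": [cp], "dispersed": True}))

    source: GenomeSequence | None = None
    seg_payload = None
    if config.transposition is not None:
        tp = config.transposition
        flank = min(10_000, max(tp.length // 10, 100))
        src_codes = random_codes(rng, tp.length + 2 * flank)
        seg_src = src_codes[flank : flank + tp.length]
        seg = mutate_codes(seg_src, 1.0 - tp.identity, rng)
        if tp.orientation == "inverted":
            seg = revcomp_codes(seg)
        source = GenomeSequence("synthX_PAR", decode(src_codes))
        seg_payload = {"seg": seg, "src_interval": (flank, flank + tp.length),
                       "orientation": tp.orientation, "identity": tp.identity}
        features.append(("transposed", tp.length, seg_payload))

    planted = sum(f[1] for f in features)
    if planted > L:
        raise ValueError(f"planted features total {planted} bp > ref_length {L}")

    gap = (L - planted) // (len(features) + 1) if features else L
    ref = random_codes(rng, L)
    truth = TruthSet(class_intervals={"single-copy": [], "ampliconic": [],
                                      "PAR-transposed": []})
    arrays_copy_ivs: dict[int, list[tuple[int, int]]] = {}
    pos = gap
    for kind, flen, payload in features:
        if kind == "amplicon":
            cursor = pos
            ivs = arrays_copy_ivs.setdefault(payload["array"], [])
            for cp in payload["copies"]:
                ref[cursor : cursor + cp.size] = cp
                ivs.append((cursor, cursor + cp.size))
                cursor += cp.size
            truth.class_intervals["ampliconic"].append((pos, pos + flen))
        else:
            ref[pos : pos + flen] = payload["seg"]
            truth.class_intervals["PAR-transposed"].append((pos, pos + flen))
            truth.transposition = {
                "y_interval": (pos, pos + flen),
                "source_interval": payload["src_interval"],
                "orientation": payload["orientation"],
                "identity": payload["identity"],
            }
        pos += flen + gap

    truth.amplicon_copies = [arrays_copy_ivs[k] for k in sorted(arrays_copy_ivs)]

    # single-copy = complement of the planted intervals
    planted_ivs = sorted(truth.class_intervals["ampliconic"]
                         + truth.class_intervals["PAR-transposed"])
    prev = 0
    for a, b in planted_ivs:
        if a > prev:
            truth.class_intervals["single-copy"].append((prev, a))
        prev = b
    if prev < L:
        truth.class_intervals["single-copy"].append((prev, L))

    return GenomeSequence(config.chrom, decode(ref)), source, truth


_SENSE_CODONS: list[str] = []
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            if _b1 + _b2 + _b3 not in ("TAA", "TAG", "TGA"):
                _SENSE_CODONS.append(_b1 + _b2 + _b3)
_SENSE_CODES = np.stack([encode(c) for c in _SENSE_CODONS])
_STOP_CODES = {encode(c).tobytes() for c in ("TAA", "TAG", "TGA")}


def _random_cds(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    picks = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return _SENSE_CODES[picks].reshape(-1)


def _has_stop(codes: np.ndarray) -> np.ndarray:
    """Boolean per-codon mask of stop codons."""
    cods = codes.reshape(-1, 3)
    return np.array([c.tobytes() in _STOP_CODES for c in cods])


def _evolve_cds(codes: np.ndarray, t: float, rng: np.random.Generator,
                max_tries: int = 200) -> np.ndarray:
    """K2P-evolve a CDS, resampling any codon that becomes a stop."""
    out = evolve_k2p(codes, t, rng)
    for _ in range(max_tries):
        stops = _has_stop(out)
        if not stops.any():
            return out
        idx = np.flatnonzero(stops)
        for ci in idx:
            out[ci * 3 : ci * 3 + 3] = evolve_k2p(codes[ci * 3 : ci * 3 + 3], t, rng)
    raise RuntimeError("could not avoid stop codons")  # pragma: no cover


def simulate_gametologs(config: SynthConfig) -> tuple[list[GametologPair], TruthSet]:
    """Evolve X/Y gametolog pairs to per-stratum target Ks values.

    Each gene starts from a random stop-free ancestral CDS that is
    duplicated and evolved independently along the X and Y branches (t/2
    each) under K2P; X positions are drawn uniformly within the stratum's
    range.  Genes are returned in X order.
    """
    if not config.strata:
        raise ValueError("strata_spec is empty")
    rng = config.rng(_STREAM_GAMETOLOGS)
    pairs: list[GametologPair] = []
    rows = []
    for spec in config.strata:
        xs = np.sort(rng.integers(spec.x_range[0], spec.x_range[1],
                                  size=spec.n_genes))
        for gi in range(spec.n_genes):
            anc = _random_cds(rng, config.cds_codons)
            t_half = spec.target_ks / 2.0
            y = _evolve_cds(anc, t_half, rng)
            x = _evolve_cds(anc, t_half, rng)
            gene = f"S{spec.stratum_id}_g{gi}"
            pairs.append(GametologPair(gene=gene, y_cds=decode(y), x_cds=decode(x),
                                       x_position=int(xs[gi])))
            rows.append((gene, spec.stratum_id, spec.target_ks, int(xs[gi])))
    pairs.sort(key=lambda p: p.x_position)
    truth = TruthSet(gene_truth=pd.DataFrame(
        rows, columns=["gene", "stratum", "target_ks", "x_position"]))
    return pairs, truth


def simulate_calls(reference: GenomeSequence, config: SynthConfig,
                   ) -> tuple[list[SampleCalls], TruthSet]:
    """Per-sample per-site calls: Poisson depth, planted SNPs and CNVs.

    Depth at a site is Poisson(mean_depth x copy factor of any overlapping
    CNV); a site is called when depth >= 1; the called base is the sample
    haplotype base.  SNPs come in two layers: group-level variants shared
    by every sample of a group (``config.group_snp_rates``, emulating clade
    stem branches so samples carry phylogenetic structure) plus
    sample-specific variants at the sample's own SNP rate.
    """
    if not config.samples:
        raise ValueError("no sample specs")
    rng = config.rng(_STREAM_CALLS)
    L = len(reference)
    ref_codes = reference.codes
    group_haps: dict[str, np.ndarray] = {}
    for group in sorted(config.group_snp_rates):
        rate = _fraction(f"group_snp_rates[{group}]", config.group_snp_rates[group])
        ghap = ref_codes.copy()
        gpos = np.flatnonzero(rng.random(L) < rate)
        if gpos.size:
            shift = rng.integers(1, 4, size=gpos.size).astype(np.uint8)
            ghap[gpos] = (ghap[gpos] + shift) % 4
        group_haps[group] = ghap
    calls = []
    truth = TruthSet()
    for spec in config.samples:
        hap = group_haps.get(spec.group, ref_codes).copy()
        snp_pos = np.flatnonzero(rng.random(L) < spec.snp_rate)
        if snp_pos.size:
            shift = rng.integers(1, 4, size=snp_pos.size).astype(np.uint8)
            hap[snp_pos] = (hap[snp_pos] + shift) % 4
        factor = np.ones(L)
        for cnv in spec.cnvs:
            if cnv.end > L:
                raise ValueError(f"CNV ({cnv.start},{cnv.end}) beyond reference")
            factor[cnv.start : cnv.end] = cnv.copy_factor
        depth = rng.poisson(spec.mean_depth * factor).astype(np.int32)
        called = depth >= 1
        calls.append(SampleCalls(sample=spec.sample_id, group=spec.group,
                                 called=called, depth=depth, base=hap))
        truth.snp_positions[spec.sample_id] = snp_pos
        truth.cnv_intervals[spec.sample_id] = [
            (c.start, c.end, c.copy_factor) for c in spec.cnvs]
    return calls, truth


def simulate_counts(config: SynthConfig) -> tuple[CountMatrix, TruthSet]:
    """Negative-binomial count matrix with planted per-group fold changes.

    Counts for gene g, group G are NB with mean base_mean x fold(g, G) and
    size = dispersion (variance mu + mu^2/size).  A fold of 0 gives all-zero
    counts for that gene/group.
    """
    if config.counts is None:
        raise ValueError("counts_spec missing")
    spec = config.counts
    rng = config.rng(_STREAM_COUNTS)
    samples = []
    groups = {}
    for g, n in spec.groups.items():
        for i in range(n):
            name = f"{g}_{i + 1}"
            samples.append(name)
            groups[name] = g
    data = np.zeros((len(spec.genes), len(samples)), dtype=np.int64)
    for gi, gene in enumerate(spec.genes):
        for si, sm in enumerate(samples):
            fold = spec.fold_changes.get(gene, {}).get(groups[sm], 1.0)
            mu = spec.base_mean * fold
            if mu <= 0:
                continue
            size = spec.dispersion
            p = size / (size + mu)
            data[gi, si] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(data, index=spec.genes, columns=samples)
    cm = CountMatrix(counts=counts, groups=groups)
    return cm, TruthSet(fold_truth={g: dict(v) for g, v in spec.fold_changes.items()})


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def write_fasta(path, records: list[GenomeSequence]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def write_bed(path, chrom: str, intervals: dict[str, list[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(intervals):
            for a, b in intervals[name]:
                fh.write(f"{chrom}\t{a}\t{b}\t{name}\n")


def write_calls_tsv(path, calls: list[SampleCalls], reference: GenomeSequence) -> None:
    """Long-format call table: sample, chrom, pos (1-based), ref_base, called, depth, base."""
    from ._seq import ALPHABET

    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref_base\tcalled\tdepth\tbase\n")
        for c in calls:
            for i in range(len(reference)):
                base = ALPHABET[c.base[i]] if c.called[i] else "."
                fh.write(f"{c.sample}\t{reference.id}\t{i + 1}\t{reference.seq[i]}"
                         f"\t{int(c.called[i])}\t{int(c.depth[i])}\t{base}\n")


def read_calls_tsv(path, groups: dict[str, str] | None = None) -> list[SampleCalls]:
    """Read a call table written by :func:`write_calls_tsv`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for sample, sub in df.groupby("sample", sort=True):
        sub = sub.sort_values("pos")
        L = int(sub["pos"].max())
        called = np.zeros(L, dtype=bool)
        depth = np.zeros(L, dtype=np.int32)
        base = np.full(L, 4, dtype=np.uint8)
        pos = sub["pos"].to_numpy() - 1
        called[pos] = sub["called"].to_numpy().astype(bool)
        depth[pos] = sub["depth"].to_numpy()
        bases = sub["base"].astype(str).to_numpy()
        enc = np.array([encode(b)[0] if b in "ACGTN" else 4 for b in bases],
                       dtype=np.uint8)
        base[pos] = enc
        group = groups.get(str(sample), "all") if groups else "all"
        out.append(SampleCalls(sample=str(sample), group=group,
                               called=called, depth=depth, base=base))
    return out


def write_counts_tsv(path, cm: CountMatrix) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


def write_config(path, config: SynthConfig) -> None:
    """Key-value dump of every generator parameter (YAML)."""
    def enc_obj(o):
        if isinstance(o, (AmpliconSpec, TranspositionSpec, StratumSpec, SampleSpec,
                          CnvSpec, CountsSpec)):
            return {k: enc_obj(v) for k, v in vars(o).items()}
        if isinstance(o, (list, tuple)):
            return [enc_obj(x) for x in o]
        if isinstance(o, dict):
            return {k: enc_obj(v) for k, v in o.items()}
        return o

    with open(path, "w") as fh:
        yaml.safe_dump(enc_obj(config.__dict__) | {"_config": "SynthConfig"}, fh,
                       sort_keys=True)


def load_config(path) -> SynthConfig:
    """Read a YAML config into a SynthConfig (inverse of :func:`write_config`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.pop("_config", None)
    amplicons = [AmpliconSpec(**a) for a in raw.pop("amplicons", [])]
    tp = raw.pop("transposition", None)
    transposition = TranspositionSpec(**tp) if tp else None
    strata = [StratumSpec(stratum_id=s["stratum_id"], n_genes=s["n_genes"],
                          target_ks=s["target_ks"], x_range=tuple(s["x_range"]))
              for s in raw.pop("strata", [])]
    samples = []
    for s in raw.pop("samples", []):
        cnvs = [CnvSpec(**c) for c in s.pop("cnvs", [])]
        samples.append(SampleSpec(cnvs=cnvs, **s))
    cs = raw.pop("counts", None)
    counts = CountsSpec(**cs) if cs else None
    return SynthConfig(amplicons=amplicons, transposition=transposition,
                       strata=strata, samples=samples, counts=counts, **raw)


def write_outputs(outdir, config: SynthConfig) -> dict[str, str]:
    """Run every configured generator and write all standard outputs."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    ref, source, truth = simulate_reference(config)
    refs = [ref] + ([source] if source is not None else [])
    paths["reference"] = os.path.join(outdir, "reference.fa")
    write_fasta(paths["reference"], refs)
    paths["truth_bed"] = os.path.join(outdir, "truth_classes.bed")
    write_bed(paths["truth_bed"], ref.id, truth.class_intervals)
    if config.strata:
        pairs, _ = simulate_gametologs(config)
        paths["gametologs"] = os.path.join(outdir, "gametologs.fa")
        recs = []
        for p in pairs:
            recs.append(GenomeSequence(f"{p.gene}|Y", p.y_cds))
            recs.append(GenomeSequence(f"{p.gene}|X", p.x_cds))
        write_fasta(paths["gametologs"], recs)
        paths["x_positions"] = os.path.join(outdir, "x_positions.tsv")
        with open(paths["x_positions"], "w") as fh:
            fh.write("gene\tx_position\n")
            for p in pairs:
                fh.write(f"{p.gene}\t{p.x_position}\n")
    if config.samples:
        calls, _ = simulate_calls(ref, config)
        paths["calls"] = os.path.join(outdir, "calls.tsv")
        write_calls_tsv(paths["calls"], calls, ref)
    if config.counts is not None:
        cm, _ = simulate_counts(config)
        paths["counts"] = os.path.join(outdir, "counts.tsv")
        write_counts_tsv(paths["counts"], cm)
    paths["config"] = os.path.join(outdir, "config_used.yaml")
    write_config(paths["config"], config)
    return paths
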