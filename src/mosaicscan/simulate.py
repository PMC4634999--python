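"""Synthetic read, amplicon, panel and cohort generators.

Every pipeline stage can be exercised without any external data: these
generators emulate the statistical structure of deep targeted sequencing of
a two-gene locus — mosaic SNVs/indels spiked at a target allele fraction
into 500-5,000x pileups with per-base substitution error and optional
strand asymmetry, paired-end libraries whose deletion-spanning pairs show
inserts inflated by the deletion length, ultra-deep single-amplicon pools
(1e4-1e6 reads), 25-sample control panels, and phenotype cohorts.

Defaults mirror the study conditions: read length 75 nt (50-75 nt
paired-end sequencing), insert size ~ Normal(400, 80), depth 5,000x for
long-range-PCR libraries and 500x for hybrid capture, substitution error
0.1-0.3% per base (the regime implied by observed control-panel noise of
0.07-0.16% per allele).  A fixed seed makes every generator byte-identical
across runs; a run-level seed derives per-generator child seeds
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplicon import ControlPanel, count_kmer, reverse_complement
from .cohort import ORGAN_SYSTEMS, SubjectRecord, load_table1
from .io import AlignedRead, Reference

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

DEFAULT_READ_LENGTH = 75
DEFAULT_QUALITY = 37


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic per-generator child seed below 2**31."""
    ss = np.random.SeedSequence([seed, abs(hash_label(label))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_label(label: str) -> int:
    # stable across processes (unlike builtin hash)
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def random_reference(length: int, seed: int, name: str = "locus") -> Reference:
    """Uniform-random DNA reference, for tests and demos."""
    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=length)
    return Reference(name=name, sequence=_BASES[seq].tobytes().decode())


@dataclass(frozen=True)
class VariantSpec:
    """A variant to spike into simulated reads at a target allele fraction."""

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    type: str  # "SNV" | "insertion" | "deletion_small"
    target_af: float

    def __post_init__(self) -> None:
        if not 0 <= self.target_af <= 1:
            raise ValueError(f"target_af {self.target_af} outside [0, 1]")


@dataclass(frozen=True)
class SimulationProfile:
    """Sequencing regime for read simulation."""

    depth: float = 5000.0  # mean reads per position
    read_length: int = DEFAULT_READ_LENGTH
    per_base_error: float = 0.001
    strand_asymmetry: float = 1.0  # error multiplier on reverse-orientation reads
    insert_mu: float = 400.0
    insert_sigma: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.per_base_error < 0.05:
            raise ValueError("per_base_error outside [0, 0.05)")


def _inject_errors(codes: np.ndarray, error_p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases in an integer-coded matrix at per-row error rates."""
    if codes.size == 0 or not error_p.any():
        return codes
    mask = rng.random(codes.shape) < error_p[:, None]
    if mask.any():
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=int(mask.sum()))
        codes[mask] = (codes[mask] + shift) % 4
    return codes


def simulate_reads(
    reference: Reference,
    variants: list[VariantSpec],
    profile: SimulationProfile,
) -> list[AlignedRead]:
    """Simulate aligned single-end reads with spiked variants.

    Read starts are uniform over the mappable range, orientation is
    Bernoulli(0.5) per read (the reported sequence stays in reference
    orientation, as in SAM), and each read covering a variant position
    carries the alternate allele independently with probability
    ``target_af``.  Substitution errors are injected per base at
    ``per_base_error`` (times ``strand_asymmetry`` on reverse reads);
    indel carriers keep the read length constant by trimming or extending
    at the 3' end.  Mean depth over the contig equals ``profile.depth``.
    """
    rng = np.random.default_rng(profile.seed)
    L = len(reference)
    rl = min(profile.read_length, L)
    n_reads = int(round(profile.depth * L / rl))
    if n_reads == 0:
        return []
    for v in variants:
        if not 1 <= v.position <= L:
            raise ValueError(f"variant position {v.position} outside reference")
        if v.type != "insertion" and reference.sequence[v.position - 1 : v.position - 1 + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(f"ref allele mismatch at {v.position}")

    starts = rng.integers(1, L - rl + 2, size=n_reads)
    reverse = rng.random(n_reads) < 0.5
    carrier = {
        id(v): rng.random(n_reads) < v.target_af for v in variants
    }

    ref_codes = np.frombuffer(reference.sequence.encode(), dtype="S1")
    ref_int = np.zeros(L, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        ref_int[ref_codes == b.encode()] = i
    # N bases (rare) coded as A; references from random_reference have none
    offsets = np.arange(rl)
    codes = ref_int[(starts[:, None] - 1) + offsets]

    error_p = np.full(n_reads, profile.per_base_error)
    error_p[reverse] *= profile.strand_asymmetry
    codes = _inject_errors(codes, error_p, rng)

    # apply SNV alt alleles vectorised; indels handled per carrier read below
    for v in variants:
        if v.type != "SNV":
            continue
        covers = (starts <= v.position) & (v.position <= starts + rl - 1)
        rows = np.where(covers & carrier[id(v)])[0]
        codes[rows, v.position - starts[rows]] = _BASE_INDEX[v.alt_allele]

    seqs = [row.tobytes() for row in _BASES[codes]]
    quals = np.full(rl, DEFAULT_QUALITY, dtype=np.int16)
    reads: list[AlignedRead] = []
    indel_variants = [v for v in variants if v.type != "SNV"]
    for i in range(n_reads):
        seq = seqs[i].decode()
        cigar = f"{rl}M"
        start = int(starts[i])
        for v in indel_variants:
            if not carrier[id(v)][i]:
                continue
            offset = v.position - start  # 0-based index of the anchor base
            if v.type == "insertion":
                ins = v.alt_allele
                if 0 <= offset < rl - len(ins) - 1:
                    seq = seq[: offset + 1] + ins + seq[offset + 1 : rl - len(ins)]
                    cigar = f"{offset + 1}M{len(ins)}I{rl - offset - 1 - len(ins)}M"
            else:  # deletion_small: anchor at position, deleted run follows
                dlen = len(v.ref_allele)
                if 0 <= offset < rl - 1 and start + rl - 1 + dlen <= L:
                    tail_start = v.position + dlen  # 1-based
                    tail_len = rl - offset - 1
                    tail = reference.sequence[tail_start - 1 : tail_start - 1 + tail_len]
                    seq = seq[: offset + 1] + tail
                    cigar = f"{offset + 1}M{dlen}D{tail_len}M"
        reads.append(
            AlignedRead(
                read_id=f"sim{i}",
                contig=reference.name,
                start=start,
                orientation="reverse" if reverse[i] else "forward",
                sequence=seq,
                base_qualities=quals.copy(),
                mapping_quality=60,
                cigar=cigar,
                sample_id="sim",
            )
        )
    return reads


def simulate_deletion_library(
    reference: Reference,
    del_start: int,
    del_end: int,
    n_pairs: int,
    carrier_fraction: float,
    profile: SimulationProfile,
) -> list[tuple[AlignedRead, AlignedRead]]:
    """Simulate read pairs over a region harbouring a mosaic genomic deletion.

    All pairs are drawn so their physical fragment straddles the deletion
    start; a fraction ``carrier_fraction`` come from the deleted allele, so
    their apparent insert (outer distance on the reference) is inflated by
    the deletion length.  Inserts are Normal(insert_mu, insert_sigma),
    truncated to at least twice the read length.
    """
    if not 0 <= carrier_fraction <= 1:
        raise ValueError(f"carrier_fraction {carrier_fraction} outside [0, 1]")
    if del_end - del_start + 1 < 1000:
        raise ValueError("deletion must be >= 1,000 nt for insert-size detection")
    rng = np.random.default_rng(profile.seed)
    rl = profile.read_length
    del_len = del_end - del_start + 1
    pairs: list[tuple[AlignedRead, AlignedRead]] = []
    if n_pairs == 0:
        return pairs
    inserts = np.maximum(
        rng.normal(profile.insert_mu, profile.insert_sigma, size=n_pairs), 2 * rl
    ).astype(int)
    carriers = rng.random(n_pairs) < carrier_fraction
    # left start placed so a concordant fragment straddles del_start
    lo = max(1, del_start - int(profile.insert_mu) + rl)
    hi = max(lo + 1, del_start - rl)
    starts = rng.integers(lo, hi + 1, size=n_pairs)
    quals = np.full(rl, DEFAULT_QUALITY, dtype=np.int16)
    for i in range(n_pairs):
        insert = int(inserts[i]) + (del_len if carriers[i] else 0)
        s1 = int(starts[i])
        s2 = min(s1 + insert - rl, len(reference) - rl + 1)
        seq1 = reference.sequence[s1 - 1 : s1 - 1 + rl]
        seq2 = reference.sequence[s2 - 1 : s2 - 1 + rl]
        left = AlignedRead(
            read_id=f"pair{i}",
            contig=reference.name,
            start=s1,
            orientation="forward",
            sequence=seq1,
            base_qualities=quals.copy(),
            insert_size=insert,
            sample_id="sim",
        )
        right = AlignedRead(
            read_id=f"pair{i}",
            contig=reference.name,
            start=s2,
            orientation="reverse",
            sequence=seq2,
            base_qualities=quals.copy(),
            insert_size=-insert,
            sample_id="sim",
        )
        pairs.append((left, right))
    return pairs


def _simulate_pool_exact(
    wt_sequence: str,
    mut_sequence: str,
    n_wt: int,
    n_mut: int,
    per_base_error: float,
    rng: np.random.Generator,
) -> list[str]:
    """Pool with exact wild-type/mutant read counts (errors then injected)."""
    out: list[str] = []
    for template, count in ((wt_sequence, n_wt), (mut_sequence, n_mut)):
        if count == 0:
            continue
        codes = np.zeros(len(template), dtype=np.int8)
        tarr = np.frombuffer(template.encode(), dtype="S1")
        for b, i in _BASE_INDEX.items():
            codes[tarr == b.encode()] = i
        mat = np.tile(codes, (count, 1))
        mat = _inject_errors(mat, np.full(count, per_base_error), rng)
        seqs = _BASES[mat]
        flip = rng.random(count) < 0.5
        for i in range(count):
            s = seqs[i].tobytes().decode()
            out.append(reverse_complement(s) if flip[i] else s)
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def simulate_amplicon_pool(
    wt_sequence: str,
    mut_sequence: str,
    af: float,
    n_reads: int,
    per_base_error: float = 0.001,
    seed: int = 0,
) -> list[str]:
    """Simulate a deep amplicon pool: each read is mutant with probability ``af``.

    Roughly half the reads are emitted reverse-complemented, as amplicon
    sequencing reads both strands of the product.
    """
    if not 0 <= af <= 1:
        raise ValueError(f"af {af} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_mut = int(rng.binomial(n_reads, af))
    return _simulate_pool_exact(wt_sequence, mut_sequence, n_reads - n_mut, n_mut, per_base_error, rng)


def make_pool_with_counts(
    wt_sequence: str,
    mut_sequence: str,
    n_wt: int,
    n_mut: int,
    per_base_error: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Amplicon pool with exact allele counts (no binomial draw)."""
    rng = np.random.default_rng(seed)
    return _simulate_pool_exact(wt_sequence, mut_sequence, n_wt, n_mut, per_base_error, rng)


def simulate_control_panel(
    wt_sequence: str,
    variant_kmer: str,
    wt_kmer: str,
    n_controls: int = 25,
    error_rate_range: tuple[float, float] = (0.0021, 0.0048),
    n_reads: int = 20000,
    seed: int = 0,
) -> ControlPanel:
    """Background AF of a variant k-mer across error-only control pools.

    Each control is a wild-type-only pool with its own per-base substitution
    rate drawn uniformly from ``error_rate_range``; the panel AF is the
    variant k-mer's mutant fraction in that pool.  A pool whose error rate
    is e yields a background AF near e/3 (the one specific substitution,
    undamaged elsewhere in the k-mer); the default range reproduces
    per-control noise of roughly 0.07-0.16%.
    """
    rng = np.random.default_rng(seed)
    afs = []
    for _ in range(n_controls):
        e = float(rng.uniform(*error_rate_range))
        pool = _simulate_pool_exact(wt_sequence, wt_sequence, n_reads, 0, e, rng)
        n_mut = count_kmer(pool, variant_kmer)
        n_wt = count_kmer(pool, wt_kmer)
        afs.append(n_mut / (n_mut + n_wt) if n_mut + n_wt else 0.0)
    return ControlPanel(variant_key=variant_kmer, afs=tuple(afs))


@dataclass(frozen=True)
class CohortProfile:
    """Per-status Poisson rates for organ major-feature counts.

    Defaults approximate the study cohort's group means: heterozygous
    subjects trend most severe, persistent-NMI least.
    """

    organ_rates: dict = field(
        default_factory=lambda: {
            "heterozygous": {"skin": 2.3, "brain": 2.2, "heart": 0.5, "kidney_lung": 0.5},
            "mosaic": {"skin": 1.9, "brain": 1.6, "heart": 0.4, "kidney_lung": 0.5},
            "persistent_NMI": {"skin": 1.1, "brain": 1.5, "heart": 0.0, "kidney_lung": 0.5},
        }
    )


def generate_cohort(
    n_subjects: int,
    status_mix: dict[str, float] | None = None,
    seed: int = 0,
    profile: CohortProfile | None = None,
) -> list[SubjectRecord]:
    """Draw a synthetic cohort with per-status phenotype distributions.

    ``status_mix`` gives the probability of each status (defaults to the
    study mix 19:26:8).  Mosaic AFs are log-uniform over [0.002, 0.34];
    heterozygous subjects get AF 0.5.
    """
    mix = status_mix or {"heterozygous": 19 / 53, "mosaic": 26 / 53, "persistent_NMI": 8 / 53}
    prof = profile or CohortProfile()
    rng = np.random.default_rng(seed)
    statuses = list(mix)
    probs = np.array([mix[s] for s in statuses], dtype=float)
    probs = probs / probs.sum()
    subjects = []
    for i in range(n_subjects):
        status = statuses[int(rng.choice(len(statuses), p=probs))]
        organs = {
            organ: int(rng.poisson(rate))
            for organ, rate in prof.organ_rates[status].items()
        }
        if status == "persistent_NMI":
            gene, af, mtype = "none", None, "none"
        else:
            gene = "TSC2" if rng.random() < 37 / 45 else "TSC1"
            mtype = str(rng.choice(["nonsense", "missense", "indel", "splice", "large_del"]))
            af = 0.5 if status == "heterozygous" else float(
                np.exp(rng.uniform(np.log(0.002), np.log(0.34)))
            )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1}",
                status=status,
                gene=gene,
                mutation_type=mtype,
                af=af,
                age_years=float(rng.integers(1, 58)),
                sex="F" if rng.random() < 0.5 else "M",
                organ_majors=organs,
            )
        )
    return subjects


def load_table1_fixture() -> list[SubjectRecord]:
    """The packaged 53-subject study table (checksum-verified)."""
    return load_table1()
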