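"""Grep-style exact k-mer quantification of a known variant in deep amplicon pools.

Ultra-deep sequencing of a single PCR product can quantify a known mutation
far below the reach of pileup calling.  The approach here mirrors counting
reads with ``grep``: build a 20-mer spanning the variant for the wild-type
and the mutant allele, count reads containing either k-mer (or its reverse
complement) and report AF = mutant / (mutant + wild-type).  Significance
against sequencing noise is judged from the same counting applied to a
panel of unrelated control samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerQueryPair:
    """The wild-type and mutant k-mers interrogating one variant."""

    wt_kmer: str
    mut_kmer: str

    def __post_init__(self) -> None:
        if self.wt_kmer == self.mut_kmer:
            raise ValueError("wild-type and mutant k-mers are identical")

    @property
    def k(self) -> int:
        return len(self.wt_kmer)


@dataclass(frozen=True)
class ControlPanel:
    """Background AF of a variant k-mer across unrelated control samples."""

    variant_key: str
    afs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.afs) < 1:
            raise ValueError("control panel needs at least one sample")

    @property
    def n_controls(self) -> int:
        return len(self.afs)

    @property
    def mean_af(self) -> float:
        return sum(self.afs) / len(self.afs)

    @property
    def min_af(self) -> float:
        return min(self.afs)

    @property
    def max_af(self) -> float:
        return max(self.afs)


@dataclass
class AmpliconResult:
    """Counts and noise comparison for one amplicon quantification."""

    mutant_count: int
    wt_count: int
    total_reads: int
    af: float
    panel_mean: float | None = None
    panel_max: float | None = None
    above_noise: bool | None = None
    binomial_p: float | None = None


def make_query_kmers(context_sequence: str, variant, k: int = 20) -> KmerQueryPair:
    """Build the WT/mutant k-mer pair for a variant inside its context.

    ``variant`` needs attributes ``position`` (1-based within the context),
    ``ref_allele`` and ``alt_allele`` (empty alt = deletion of ref_allele;
    empty ref = insertion after position).  SNV k-mers are centred with
    ceil(k/2) - 1 bases of left flank; indel k-mers span the novel junction.
    Both k-mers must occur exactly once in their respective allele context.
    """
    pos0 = variant.position - 1
    ref = variant.ref_allele
    alt = variant.alt_allele
    if ref and context_sequence[pos0 : pos0 + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match context at position {variant.position}"
        )
    mut_context = context_sequence[:pos0] + alt + context_sequence[pos0 + len(ref) :]
    left = -(-k // 2)  # ceil(k/2) bases of left flank; indel k-mers span the junction
    start = max(pos0 - left, 0)
    wt_kmer = context_sequence[start : start + k]
    mut_kmer = mut_context[start : start + k]
    if len(wt_kmer) < k or len(mut_kmer) < k:
        raise ValueError(f"context too short for k={k} around the variant")
    for kmer, ctx, label in ((wt_kmer, context_sequence, "wild-type"), (mut_kmer, mut_context, "mutant")):
        if ctx.count(kmer) + ctx.count(reverse_complement(kmer)) != 1:
            raise ValueError(
                f"{label} k-mer {kmer} is not unique in its context; increase k"
            )
    return KmerQueryPair(wt_kmer=wt_kmer, mut_kmer=mut_kmer)


def count_kmer(reads: Iterable[str], kmer: str) -> int:
    """Count reads containing ``kmer`` or its reverse complement.

    Each read is counted at most once, even if both orientations match.
    """
    rc = reverse_complement(kmer)
    return sum(1 for read in reads if kmer in read or rc in read)


def amplicon_af(mut_count: int, wt_count: int) -> float:
    """Mutant allele fraction mut/(mut+wt); 0.0 when both counts are zero.

    Reads matching neither k-mer (sequencing errors at the query locus) are
    excluded from the denominator by construction.
    """
    total = mut_count + wt_count
    return mut_count / total if total else 0.0


def quantify(reads: Sequence[str], queries: KmerQueryPair) -> AmpliconResult:
    """Count both k-mers over a pool and compute the allele fraction."""
    mut = count_kmer(reads, queries.mut_kmer)
    wt = count_kmer(reads, queries.wt_kmer)
    return AmpliconResult(
        mutant_count=mut,
        wt_count=wt,
        total_reads=len(reads),
        af=amplicon_af(mut, wt),
    )


def compare_to_panel(
    result: AmpliconResult,
    panel: ControlPanel,
    alpha: float = 0.01,
) -> AmpliconResult:
    """Judge a quantification against control-panel noise.

    ``above_noise`` requires strict exceedance of the panel maximum AND a
    one-sided binomial tail probability < ``alpha`` of observing at least
    ``mutant_count`` successes in mut+wt trials at the pooled panel rate.
    The result is annotated in place and returned.
    """
    n = result.mutant_count + result.wt_count
    pooled_rate = panel.mean_af
    if n > 0 and 0 < pooled_rate < 1:
        p = float(stats.binom.sf(result.mutant_count - 1, n, pooled_rate))
    elif pooled_rate == 0:
        p = 0.0 if result.mutant_count > 0 else 1.0
    else:
        p = 1.0
    result.panel_mean = panel.mean_af
    result.panel_max = panel.max_af
    result.binomial_p = p
    result.above_noise = result.af > panel.max_af and p < alpha
    return result
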