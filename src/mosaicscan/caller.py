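"""Low allele-fraction mosaic SNV/indel calling from orientation-split pileups.

The calling path is deliberately simple and auditable, built for detecting
mosaic mutations down to ~0.2% allele fraction in very deep (500-5,000x)
targeted sequencing of a tumor-suppressor locus:

1. drop low-mapping-quality reads and mask low-quality base calls;
2. normalise redundancy to at most ``redundancy_cap`` reads starting at each
   (position, orientation), so PCR jackpots cannot dominate a column;
3. tally base and indel observations per column, split by read orientation;
4. emit candidate calls under a tiered threshold scheme — a *review* tier
   (AF >= 1%) and a *sensitive* tier (SNV: AF >= 0.5% and >= 3 reads;
   indel: AF >= 0.2% and >= 2 reads);
5. flag artifacts: support confined to a single read orientation, and
   candidates recurring across samples of a cohort (sequencing-process
   artifacts strike the same positions in everyone).

AF is always the combined-orientation fraction, support / total depth at the
column; the orientation split is used only by the artifact filter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .io import AlignedRead, Reference, parse_cigar

_MASKED_BASE = "N"  # masked calls never enter pileup counts


@dataclass(frozen=True)
class TierConfig:
    """Thresholds of the tiered calling scheme.

    Defaults are the scheme's operating point: candidates at >= 1% AF go to
    the review tier; the sensitive tier lowers the cut-off to 0.5% AF and
    three supporting reads for SNVs, and 0.2% and two reads for indels.
    Redundancy is capped at 50 reads per (start, orientation).
    """

    review_af: float = 0.01
    snv_af: float = 0.005
    snv_min_reads: int = 3
    indel_af: float = 0.002
    indel_min_reads: int = 2
    redundancy_cap: int = 50
    min_base_quality: int = 20
    min_mapping_quality: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.indel_af <= self.snv_af <= self.review_af < 1):
            raise ValueError("need 0 < indel_af <= snv_af <= review_af < 1")
        if self.snv_min_reads < 1 or self.indel_min_reads < 1:
            raise ValueError("minimum read support must be >= 1")
        if self.redundancy_cap < 1:
            raise ValueError("redundancy_cap must be >= 1")


@dataclass
class PileupColumn:
    """Per-position, per-orientation tallies of base and indel observations.

    Insertions are keyed ``+SEQ`` at the anchor base before the inserted
    sequence; small deletions are keyed ``-LEN`` at the anchor base before
    the deleted run.  ``depth_*`` counts quality-passing base calls only.
    """

    contig: str
    position: int
    ref_base: str
    counts_forward: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    counts_reverse: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    indel_obs_forward: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    indel_obs_reverse: dict[str, int] = field(default_factory=lambda: defaultdict(int))

    @property
    def depth_forward(self) -> int:
        return sum(self.counts_forward.values())

    @property
    def depth_reverse(self) -> int:
        return sum(self.counts_reverse.values())

    @property
    def depth_total(self) -> int:
        return self.depth_forward + self.depth_reverse


@dataclass
class VariantCall:
    """A candidate or confirmed SNV/indel with support accounting."""

    contig: str
    position: int
    ref: str
    alt: str
    variant_type: str  # "SNV" | "insertion" | "deletion_small"
    af: float
    support_forward: int
    support_reverse: int
    depth_total: int
    tier: str  # "review" | "sensitive"
    filters: set[str] = field(default_factory=set)
    sample_id: str = ""

    @property
    def support_total(self) -> int:
        return self.support_forward + self.support_reverse

    @property
    def passes(self) -> bool:
        return not self.filters

    @property
    def key(self) -> tuple:
        return (self.contig, self.position, self.ref, self.alt)


def filter_reads(reads: list[AlignedRead], config: TierConfig) -> list[AlignedRead]:
    """Quality filtering: drop low-MAPQ reads, mask low-quality base calls.

    Masked bases are replaced by ``N`` (never counted in any pileup) and the
    read retained, so a single bad cycle does not discard its whole read.
    """
    out: list[AlignedRead] = []
    for read in reads:
        if read.mapping_quality < config.min_mapping_quality:
            continue
        low = read.base_qualities < config.min_base_quality
        if low.any():
            seq = np.frombuffer(read.sequence.encode(), dtype="S1").copy()
            seq[low] = _MASKED_BASE.encode()
            read = replace(read, sequence=seq.tobytes().decode())
        out.append(read)
    return out


def downsample_redundancy(reads: list[AlignedRead], cap: int = 50) -> list[AlignedRead]:
    """Reduce redundancy to at most ``cap`` reads per (start, orientation).

    Within an over-full group the ``cap`` reads with highest mapping quality
    are kept, ties broken by read_id lexicographic order, so the selection
    is deterministic.  Input order of the surviving reads is preserved.
    """
    groups: dict[tuple[int, str], list[AlignedRead]] = defaultdict(list)
    for read in reads:
        groups[(read.start, read.orientation)].append(read)
    keep: set[int] = set()
    for members in groups.values():
        if len(members) <= cap:
            keep.update(id(r) for r in members)
        else:
            ranked = sorted(members, key=lambda r: (-r.mapping_quality, r.read_id))
            keep.update(id(r) for r in ranked[:cap])
    return [r for r in reads if id(r) in keep]


def build_pileup(
    reads: list[AlignedRead],
    reference: Reference,
    region: tuple[int, int] | None = None,
) -> list[PileupColumn]:
    """Tally per-position, per-orientation base and indel observations.

    ``region`` is a closed 1-based interval restricting the columns built
    (the whole contig when omitted).  Read bases beyond the reference end
    are truncated.  ``N`` bases (masked or ambiguous) are not counted.
    """
    lo, hi = region if region is not None else (1, len(reference))
    hi = min(hi, len(reference))
    columns: dict[int, PileupColumn] = {}

    def col(pos: int) -> PileupColumn:
        c = columns.get(pos)
        if c is None:
            c = PileupColumn(contig=reference.name, position=pos, ref_base=reference.base(pos))
            columns[pos] = c
        return c

    for read in reads:
        if read.end < lo or read.start > hi:
            continue
        fwd = read.orientation == "forward"
        ref_pos = read.start
        q_pos = 0
        for length, op in parse_cigar(read.cigar):
            if op == "M":
                a = max(ref_pos, lo)
                b = min(ref_pos + length - 1, hi)
                for pos in range(a, b + 1):
                    base = read.sequence[q_pos + (pos - ref_pos)]
                    if base != _MASKED_BASE:
                        c = col(pos)
                        (c.counts_forward if fwd else c.counts_reverse)[base] += 1
                ref_pos += length
                q_pos += length
            elif op == "I":
                anchor = ref_pos - 1
                if lo <= anchor <= hi:
                    key = "+" + read.sequence[q_pos : q_pos + length]
                    c = col(anchor)
                    (c.indel_obs_forward if fwd else c.indel_obs_reverse)[key] += 1
                q_pos += length
            elif op == "D":
                anchor = ref_pos - 1
                if lo <= anchor <= hi:
                    key = f"-{length}"
                    c = col(anchor)
                    (c.indel_obs_forward if fwd else c.indel_obs_reverse)[key] += 1
                ref_pos += length
    return [columns[p] for p in sorted(columns)]


def _qualifies(af: float, support: int, variant_type: str, cfg: TierConfig, tier: str) -> bool:
    if af >= cfg.review_af:
        return True  # candidates at/above the review cut are always emitted
    if tier != "sensitive":
        return False
    if variant_type == "SNV":
        return af >= cfg.snv_af and support >= cfg.snv_min_reads
    return af >= cfg.indel_af and support >= cfg.indel_min_reads


def call_candidates(
    columns: list[PileupColumn],
    tier_config: TierConfig | None = None,
    tier: str = "sensitive",
    sample_id: str = "",
) -> list[VariantCall]:
    """Emit candidate variant calls from pileup columns under a tier.

    AF is combined-orientation: support / depth_total at the column.  Calls
    at AF >= ``review_af`` are labelled tier ``review`` (the direct-review
    set); calls admitted only by the lowered cut-offs are labelled
    ``sensitive``.  Zero-depth columns are skipped.
    """
    cfg = tier_config or TierConfig()
    if tier not in ("review", "sensitive"):
        raise ValueError(f"unknown tier {tier!r}")
    calls: list[VariantCall] = []
    for c in columns:
        depth = c.depth_total
        if depth == 0:
            continue
        alleles: list[tuple[str, str, int, int]] = []  # (alt_key, type, fwd, rev)
        bases = set(c.counts_forward) | set(c.counts_reverse)
        for base in sorted(bases):
            if base == c.ref_base:
                continue
            alleles.append(("SNV:" + base, "SNV", c.counts_forward.get(base, 0), c.counts_reverse.get(base, 0)))
        for key in sorted(set(c.indel_obs_forward) | set(c.indel_obs_reverse)):
            vt = "insertion" if key.startswith("+") else "deletion_small"
            alleles.append((key, vt, c.indel_obs_forward.get(key, 0), c.indel_obs_reverse.get(key, 0)))
        for key, vtype, fwd, rev in alleles:
            support = fwd + rev
            if support == 0:
                continue
            af = support / depth
            if not _qualifies(af, support, vtype, cfg, tier):
                continue
            if vtype == "SNV":
                ref, alt = c.ref_base, key.split(":", 1)[1]
            elif vtype == "insertion":
                ref, alt = c.ref_base, c.ref_base + key[1:]
            else:
                ref, alt = c.ref_base, f"<DEL{key[1:]}>"
            calls.append(
                VariantCall(
                    contig=c.contig,
                    position=c.position,
                    ref=ref,
                    alt=alt,
                    variant_type=vtype,
                    af=af,
                    support_forward=fwd,
                    support_reverse=rev,
                    depth_total=depth,
                    tier="review" if af >= cfg.review_af else "sensitive",
                    sample_id=sample_id,
                )
            )
    return calls


def apply_orientation_filter(calls: list[VariantCall]) -> list[VariantCall]:
    """Flag calls whose support is confined to a single read orientation.

    A genuine variant on double-stranded template appears in both read
    orientations; polymerase- and alignment-driven artifacts are frequently
    strand-confined.  Calls are mutated in place and returned.
    """
    for call in calls:
        if call.support_forward == 0 or call.support_reverse == 0:
            call.filters.add("single_orientation")
    return calls


def apply_panel_filter(
    calls: list[VariantCall],
    cohort_calls_by_sample: dict[str, list[VariantCall]],
    min_other_samples: int = 2,
) -> list[VariantCall]:
    """Flag calls recurring as candidates in other samples of the cohort.

    A (contig, position, alt) seen in >= ``min_other_samples`` samples other
    than the call's own is a sequencing-process artifact signature and gains
    the ``panel_recurrent`` flag.
    """
    samples_by_key: dict[tuple, set[str]] = defaultdict(set)
    for sample, sample_calls in cohort_calls_by_sample.items():
        for call in sample_calls:
            samples_by_key[call.key].add(sample)
    for call in calls:
        others = samples_by_key.get(call.key, set()) - {call.sample_id}
        if len(others) >= min_other_samples:
            call.filters.add("panel_recurrent")
    return calls


def call_sample(
    reads: list[AlignedRead],
    reference: Reference,
    tier_config: TierConfig | None = None,
    tier: str = "sensitive",
    region: tuple[int, int] | None = None,
    sample_id: str = "",
) -> list[VariantCall]:
    """Full single-sample path: filter, downsample, pileup, call, flag strand."""
    cfg = tier_config or TierConfig()
    reads = filter_reads(reads, cfg)
    reads = downsample_redundancy(reads, cfg.redundancy_cap)
    columns = build_pileup(reads, reference, region)
    calls = call_candidates(columns, cfg, tier, sample_id=sample_id)
    return apply_orientation_filter(calls)
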