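"""Mosaic multi-kilobase deletion detection from paired-end insert sizes.

A read pair straddling a genomic deletion aligns with an apparent insert
(outer distance) inflated by the deletion length.  Pairs with insert
> 1,200 nt are flagged and binned as *large* (> 2,000) or *intermediate*
(1,200-2,000); a deletion is called where at least three large-category or
five intermediate-category pairs cluster with leftmost coordinates within a
500 nt region.  Allele fraction is the local fraction of discordant among
breakpoint-spanning pairs, directly comparable to an SNV AF.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .io import AlignedRead

LARGE_INSERT = 2000
MIN_FLAG_INSERT = 1200


@dataclass(frozen=True)
class FlaggedPair:
    """One discordant read pair (represented by its leftmost mate)."""

    pair_id: str
    left_coord: int  # 1-based leftmost mapped position of the pair
    left_end: int  # rightmost base of the left read
    mate_start: int  # leftmost base of the right read
    insert_size: int  # absolute outer distance
    category: str  # "large" (>2000) | "intermediate" (1200-2000)

    def __post_init__(self) -> None:
        if self.insert_size <= MIN_FLAG_INSERT:
            raise ValueError(f"pair {self.pair_id}: insert {self.insert_size} not discordant")
        expected = "large" if self.insert_size > LARGE_INSERT else "intermediate"
        if self.category != expected:
            raise ValueError(f"pair {self.pair_id}: category {self.category!r} != {expected!r}")


@dataclass
class DeletionCall:
    """A genomic deletion inferred from clustered large-insert pairs."""

    contig: str
    window_start: int
    window_end: int
    supporting_pairs: int
    category: str
    estimated_del_start: int
    estimated_del_end: int
    af: float = 0.0
    confirmed: bool = False

    @property
    def position(self) -> int:
        return self.estimated_del_start

    @property
    def end(self) -> int:
        return self.estimated_del_end

    @property
    def size(self) -> int:
        return self.estimated_del_end - self.estimated_del_start + 1


def flag_discordant_pairs(
    reads: list[AlignedRead],
    min_insert: int = MIN_FLAG_INSERT,
    contig: str | None = None,
) -> list[FlaggedPair]:
    """Flag pairs with |insert| > ``min_insert`` and categorize them.

    Each pair is counted once, via its leftmost mate (positive TLEN).
    """
    flagged: list[FlaggedPair] = []
    for read in reads:
        if read.insert_size is None or read.insert_size <= 0:
            continue
        if contig is not None and read.contig != contig:
            continue
        insert = read.insert_size
        if insert <= min_insert:
            continue
        category = "large" if insert > LARGE_INSERT else "intermediate"
        flagged.append(
            FlaggedPair(
                pair_id=read.read_id,
                left_coord=read.start,
                left_end=read.end,
                mate_start=read.start + insert - len(read.sequence),
                insert_size=insert,
                category=category,
            )
        )
    return flagged


def cluster_flagged(
    flagged: list[FlaggedPair],
    window: int = 500,
    min_large: int = 3,
    min_intermediate: int = 5,
    contig: str = "",
) -> list[DeletionCall]:
    """Call deletions from clustered discordant pairs.

    For each category independently, every maximal set of pairs whose
    leftmost coordinates span <= ``window`` nt and whose size meets the
    category minimum seeds a call; overlapping qualifying windows are merged
    into one call.  Breakpoints are estimated as median(left read end) + 1
    and median(mate start) - 1 over the cluster's pairs.
    """
    calls: list[DeletionCall] = []
    for category, min_pairs in (("large", min_large), ("intermediate", min_intermediate)):
        members = sorted(
            (p for p in flagged if p.category == category), key=lambda p: p.left_coord
        )
        if len(members) < min_pairs:
            continue
        coords = [p.left_coord for p in members]
        n = len(members)
        # index intervals [i, j] of maximal windows meeting the minimum
        qualifying: list[tuple[int, int]] = []
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and coords[j + 1] - coords[i] <= window:
                j += 1
            if j - i + 1 >= min_pairs:
                qualifying.append((i, j))
        if not qualifying:
            continue
        # merge overlapping index intervals
        merged: list[list[int]] = []
        for i, j in qualifying:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            cluster = members[i : j + 1]
            calls.append(
                DeletionCall(
                    contig=contig,
                    window_start=cluster[0].left_coord,
                    window_end=cluster[-1].left_coord,
                    supporting_pairs=len(cluster),
                    category=category,
                    estimated_del_start=int(median(p.left_end for p in cluster)) + 1,
                    estimated_del_end=int(median(p.mate_start for p in cluster)) - 1,
                )
            )
    calls.sort(key=lambda c: (c.window_start, c.category))
    return calls


def deletion_af(
    reads_in_region: list[AlignedRead],
    deletion: DeletionCall,
    min_insert: int = MIN_FLAG_INSERT,
) -> float:
    """Estimate deletion AF as discordant / (discordant + concordant-spanning).

    Concordant pairs enter the denominator only when their expected fragment
    straddles the deletion start, so the fraction is local and comparable to
    an SNV allele fraction.  For this straddle test the deletion start is
    taken as one past the rightmost discordant left-read end — the tightest
    bound the flanking reads give (the reported ``estimated_del_start`` stays
    the median-based estimate).  Pairs are counted once via the leftmost mate.
    """
    discordant = [
        r for r in reads_in_region
        if r.insert_size is not None and r.insert_size > min_insert
    ]
    breakpoint_pos = (
        max(r.end for r in discordant) + 1 if discordant else deletion.estimated_del_start
    )
    n_discordant = len(discordant)
    n_concordant = 0
    for read in reads_in_region:
        if read.insert_size is None or read.insert_size <= 0:
            continue
        if read.insert_size <= min_insert and (
            read.start <= breakpoint_pos <= read.start + read.insert_size - 1
        ):
            n_concordant += 1
    total = n_discordant + n_concordant
    af = n_discordant / total if total else 0.0
    deletion.af = af
    return af
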