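"""Intronic variant parsing, splice-element classification and allelic distortion.

Variants are taken in HGVS-like coding notation ("c.976-15G>A"): the coding
position anchors the nearest exon boundary and the signed intron offset
places the variant on the donor (+n, downstream of an exon) or acceptor
(-n, upstream of an exon) side.  Classification bins a variant by its
distance from the splice elements: the invariant GT/AG dinucleotides
(canonical), the branch-point region upstream of the acceptor, the
remaining near-exon positions, or deep intronic territory.

Allelic distortion scores nonsense-mediated decay in expression data: a
heterozygous exonic SNP whose lower-frequency allele falls below the
population 99th-percentile ratio (0.43, from GTEx RNA-seq of a TSC2 coding
SNP) is evidence that one allele's transcript is being degraded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class ParseError(ValueError):
    """Raised when a variant notation cannot be parsed."""


@dataclass(frozen=True)
class SpliceWindows:
    """Classification windows (intron offsets, 1-based distance from the exon).

    Defaults: |offset| 1-2 canonical; acceptor-side 10-40 branch region;
    donor-side 3-50 and acceptor-side 3-9 / 41-50 near-exon; beyond 50 on
    either side deep intronic.  The branch window brackets the typical
    branch-point adenosine position (~18-40 nt upstream of the acceptor).
    """

    canonical_max: int = 2
    branch_acceptor_min: int = 10
    branch_acceptor_max: int = 40
    near_exon_max: int = 50


@dataclass(frozen=True)
class CdnaVariant:
    """A variant in coding-anchored notation."""

    raw_notation: str
    cdna_position: int
    intron_offset: int  # 0 exonic; +n donor side; -n acceptor side
    kind: str  # "substitution" | "deletion" | "insertion" | "delins" | "complex"
    ref: str = ""
    alt: str = ""
    cdna_end: int | None = None
    end_offset: int | None = None

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset != 0

    @property
    def is_utr(self) -> bool:
        return self.cdna_position < 0

    def to_notation(self) -> str:
        """Regenerate the HGVS-like string (verbatim for complex forms)."""
        if self.kind == "complex":
            return self.raw_notation

        def _pos(pos: int, off: int | None) -> str:
            s = str(pos)
            if off:
                s += f"{off:+d}"
            return s

        left = _pos(self.cdna_position, self.intron_offset)
        if self.kind == "substitution":
            return f"c.{left}{self.ref}>{self.alt}"
        span = left
        if self.cdna_end is not None:
            span += "_" + _pos(self.cdna_end, self.end_offset)
        if self.kind == "deletion":
            return f"c.{span}del{self.ref}"
        if self.kind == "insertion":
            return f"c.{span}ins{self.alt}"
        return f"c.{span}delins{self.alt}"


_POS = r"(-?\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_POS}([ACGT]+)>([ACGT]+)$")
_DEL_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?del([ACGT]*)$")
_INS_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?ins([ACGT]+)$")
_DELINS_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?delins([ACGT]+)$")


def parse_cdna_variant(notation: str) -> CdnaVariant:
    """Parse an HGVS-like coding notation string.

    Substitutions, deletions, insertions and delins with optional intron
    offsets are fully parsed.  Forms with unknown breakpoints ("?"),
    5'UTR/downstream anchors or fusion-gene coordinates parse into the
    ``complex`` bucket (excluded from splice classification) rather than
    failing, since whole-gene deletions are legitimate cohort entries.
    """
    notation = notation.strip()
    if not notation.startswith("c."):
        raise ParseError(f"not a coding notation: {notation!r}")
    m = _SUB_RE.match(notation)
    if m:
        return CdnaVariant(
            raw_notation=notation,
            cdna_position=int(m.group(1)),
            intron_offset=int(m.group(2) or 0),
            kind="substitution",
            ref=m.group(3),
            alt=m.group(4),
        )
    for regex, kind in ((_DELINS_RE, "delins"), (_DEL_RE, "deletion"), (_INS_RE, "insertion")):
        m = regex.match(notation)
        if m:
            seq = m.group(5)
            return CdnaVariant(
                raw_notation=notation,
                cdna_position=int(m.group(1)),
                intron_offset=int(m.group(2) or 0),
                kind=kind,
                ref=seq if kind == "deletion" else "",
                alt=seq if kind != "deletion" else "",
                cdna_end=int(m.group(3)) if m.group(3) else None,
                end_offset=int(m.group(4)) if m.group(4) else None,
            )
    if "?" in notation or "*" in notation or ":" in notation or "del" in notation:
        return CdnaVariant(raw_notation=notation, cdna_position=0, intron_offset=0, kind="complex")
    raise ParseError(f"cannot parse variant notation: {notation!r}")


def classify_splice_position(
    variant: CdnaVariant,
    windows: SpliceWindows | None = None,
) -> str:
    """Bin a variant by intron offset relative to the splice elements.

    Returns one of ``exonic``, ``canonical``, ``branch_region``,
    ``near_exon``, ``deep_intronic``.  The windows are mutually exclusive
    and exhaustive over all nonzero offsets.  Complex/UTR variants raise —
    they have no single splice-relative position.
    """
    w = windows or SpliceWindows()
    if variant.kind == "complex" or variant.is_utr:
        raise ValueError(f"{variant.raw_notation}: not classifiable by splice position")
    off = variant.intron_offset
    if off == 0:
        return "exonic"
    dist = abs(off)
    if dist <= w.canonical_max:
        return "canonical"
    if off < 0 and w.branch_acceptor_min <= dist <= w.branch_acceptor_max:
        return "branch_region"
    if dist <= w.near_exon_max:
        return "near_exon"
    return "deep_intronic"


@dataclass(frozen=True)
class AllelicRatioResult:
    """Allelic ratio of a heterozygous SNP in expression data."""

    count_allele_a: int
    count_allele_b: int
    ratio: float  # lower / higher count, in [0, 1]
    distorted: bool
    threshold: float


#: 99th-percentile lower-allele ratio across GTEx samples heterozygous for a
#: TSC2 coding SNP; ratios below it are called distorted.
DEFAULT_DISTORTION_THRESHOLD = 0.43


def allelic_ratio(
    count_a: int,
    count_b: int,
    threshold: float = DEFAULT_DISTORTION_THRESHOLD,
) -> AllelicRatioResult:
    """Score allelic distortion: ratio = min/max, distorted when ratio < threshold."""
    if count_a < 0 or count_b < 0:
        raise ValueError("allele counts must be non-negative")
    if count_a + count_b == 0 or max(count_a, count_b) == 0:
        raise ValueError("allelic ratio undefined for two zero counts")
    ratio = min(count_a, count_b) / max(count_a, count_b)
    return AllelicRatioResult(
        count_allele_a=count_a,
        count_allele_b=count_b,
        ratio=ratio,
        distorted=ratio < threshold,
        threshold=threshold,
    )
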