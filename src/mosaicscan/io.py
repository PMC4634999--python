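"""Readers and writers for the formats the pipeline touches.

All genomic coordinates throughout the package are 1-based and inclusive:
``AlignedRead.start`` is the leftmost mapped base, exon intervals are closed,
and deletions are reported as ``[start, end]`` of the deleted bases
(``size = end - start + 1``).  This matches the SAM/VCF convention of the
files read and written here.

Supported formats: FASTA (reference in), SAM (alignments in/out, plain text),
VCF 4.2 (variant and deletion calls out), BED-like TSV (gene model in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: CIGAR operations the pileup engine understands.
SUPPORTED_CIGAR_OPS = frozenset("MID")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class Reference:
    """A single reference contig: uppercase DNA over {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError("reference sequence is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(f"reference contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        return self.sequence[position - 1]


@dataclass
class AlignedRead:
    """One mapped read, the unit every analysis stage consumes.

    ``insert_size`` is the signed outer distance of the pair (SAM TLEN):
    positive on the leftmost mate, ``None`` for single-end reads.
    """

    read_id: str
    contig: str
    start: int  # 1-based leftmost mapped position
    orientation: str  # "forward" | "reverse"
    sequence: str
    base_qualities: np.ndarray
    mapping_quality: int = 60
    cigar: str = ""
    insert_size: int | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.int16)
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.sequence)} bases but "
                f"{len(self.base_qualities)} quality values"
            )
        if self.start < 1:
            raise ValueError(f"read {self.read_id}: start {self.start} < 1")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"read {self.read_id}: bad orientation {self.orientation!r}")
        if not self.cigar:
            self.cigar = f"{len(self.sequence)}M"
        if _cigar_query_length(self.cigar) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: CIGAR {self.cigar} consumes "
                f"{_cigar_query_length(self.cigar)} query bases, read has {len(self.sequence)}"
            )

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        return self.start + _cigar_reference_length(self.cigar) - 1


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) tuples; ops restricted to M/I/D."""
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"malformed CIGAR {cigar!r}")
            if ch not in SUPPORTED_CIGAR_OPS:
                raise FormatError(f"unsupported CIGAR op {ch!r} in {cigar!r}")
            ops.append((int(num), ch))
            num = ""
    if num:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return ops


def _cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MI")


def _cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MD")


@dataclass
class GeneModel:
    """Exon structure of a gene, exons in transcript (5'->3') order.

    ``cdna_offsets[i]`` is the number of coding nucleotides upstream of exon
    ``i``, so coding position ``cdna_offsets[i] + 1`` is the first base of
    exon ``i``.
    """

    gene: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cdna_offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise FormatError(f"overlapping exons ({s1},{e1}) and ({s2},{e2})")
            if s2 - e1 - 1 < 1:
                raise FormatError(f"intron of length < 1 between ({s1},{e1}) and ({s2},{e2})")
        if not self.cdna_offsets:
            offsets, total = [], 0
            for s, e in self.exons:
                offsets.append(total)
                total += e - s + 1
            self.cdna_offsets = offsets

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)


def read_reference(path: str | Path) -> Reference:
    """Read the first record of a FASTA file as the analysis reference.

    Multi-record files are accepted; a warning is logged and the first
    record used (each analysis run is restricted to one contig).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        logger.warning("%s: %d FASTA records, using first (%s)", path, len(records), records[0].id)
    rec = records[0]
    return Reference(name=rec.id, sequence=str(rec.seq).upper())


def read_alignments(path: str | Path) -> list[AlignedRead]:
    """Read mapped primary reads from a SAM file.

    Only QNAME, FLAG, RNAME, POS, MAPQ, CIGAR, TLEN, SEQ, QUAL (and the SM
    tag for the sample label) are consumed.  Unmapped, secondary and
    supplementary records are dropped; reads whose CIGAR uses ops outside
    M/I/D are skipped with a logged count rather than failing the run.
    """
    reads: list[AlignedRead] = []
    n_skipped_cigar = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigarstring is None or any(
                op_char not in SUPPORTED_CIGAR_OPS
                for op_char in rec.cigarstring
                if op_char.isalpha()
            ):
                n_skipped_cigar += 1
                continue
            quals = (
                np.array(rec.query_qualities, dtype=np.int16)
                if rec.query_qualities is not None
                else np.full(len(rec.query_sequence), 30, dtype=np.int16)
            )
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name or "*",
                    start=rec.reference_start + 1,
                    orientation="reverse" if rec.is_reverse else "forward",
                    sequence=rec.query_sequence,
                    base_qualities=quals,
                    mapping_quality=rec.mapping_quality,
                    cigar=rec.cigarstring,
                    insert_size=rec.template_length if rec.template_length != 0 else None,
                    sample_id=rec.get_tag("SM") if rec.has_tag("SM") else "",
                )
            )
    if n_skipped_cigar:
        logger.warning("%s: skipped %d reads with unsupported CIGAR ops", path, n_skipped_cigar)
    return reads


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    """Write reads as plain-text SAM (header from ``contig_lengths``)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.reference_id = out.header.get_tid(read.contig)
            rec.reference_start = read.start - 1
            rec.mapping_quality = read.mapping_quality
            rec.cigarstring = read.cigar
            rec.query_sequence = read.sequence
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.base_qualities)
            )
            flag = 0
            if read.orientation == "reverse":
                flag |= 0x10
            if read.insert_size is not None:
                flag |= 0x1
                rec.template_length = read.insert_size
            rec.flag = flag
            if read.sample_id:
                rec.set_tag("SM", read.sample_id)
            out.write(rec)


def write_variant_calls(
    calls: Sequence,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write SNV/indel and deletion calls as VCF 4.2.

    SNV/indel calls carry INFO ``AF`` (allele fraction), ``DPF``/``DPR``
    (per-orientation alt support), ``DP`` and ``TIER``; filter flags map to
    the FILTER column (PASS when none).  Genomic deletions use symbolic
    ``<DEL>`` ALT with INFO ``END``, ``SVLEN``, ``SUPPORT``.  Calls are
    sorted by (contig, position) before writing.
    """
    calls = sorted(calls, key=lambda c: (c.contig, c.position))
    if contig_lengths is None:
        contig_lengths = {}
        for c in calls:
            end = getattr(c, "end", c.position)
            contig_lengths[c.contig] = max(contig_lengths.get(c.contig, 0), end + 1000)
    header = pysam.VariantHeader()
    header.add_line('##source=mosaicscan')
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("AF", "A", "Float", "Mutant allele fraction")
    header.info.add("DPF", 1, "Integer", "Alt-supporting reads, forward orientation")
    header.info.add("DPR", 1, "Integer", "Alt-supporting reads, reverse orientation")
    header.info.add("DP", 1, "Integer", "Total depth at site")
    header.info.add("TIER", 1, "String", "Calling tier (review or sensitive)")
    header.info.add("END", 1, "Integer", "End of deletion (1-based inclusive)")
    header.info.add("SVLEN", 1, "Integer", "Deletion length")
    header.info.add("SUPPORT", 1, "Integer", "Discordant pairs supporting the deletion")
    header.filters.add("single_orientation", None, None, "Support confined to one read orientation")
    header.filters.add("panel_recurrent", None, None, "Seen as a candidate in multiple samples")
    header.filters.add("below_threshold", None, None, "Below the tier frequency/support cut-off")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            if hasattr(call, "supporting_pairs"):  # deletion call
                # VCF symbolic-DEL convention: POS anchors the base before the
                # deleted run, INFO END is the last deleted base.
                rec = out.new_record(
                    contig=call.contig,
                    start=max(call.position - 2, 0),
                    stop=call.end,  # writes INFO END
                    alleles=("N", "<DEL>"),
                )
                rec.info["SVLEN"] = call.size
                rec.info["SUPPORT"] = call.supporting_pairs
                rec.info["AF"] = float(call.af)
                rec.filter.add("PASS")
            else:
                rec = out.new_record()
                rec.contig = call.contig
                rec.start = call.position - 1
                rec.alleles = (call.ref, call.alt)
                rec.info["AF"] = float(call.af)
                rec.info["DPF"] = call.support_forward
                rec.info["DPR"] = call.support_reverse
                rec.info["DP"] = call.depth_total
                rec.info["TIER"] = call.tier
                if call.filters:
                    for f in sorted(call.filters):
                        rec.filter.add(f)
                else:
                    rec.filter.add("PASS")
            out.write(rec)


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a BED-like TSV gene model: contig, start, end, exon_index, gene, strand.

    Coordinates are 1-based inclusive.  Exons are returned in transcript
    order (reverse genomic order for minus-strand genes) with cumulative
    coding offsets.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: expected 6 columns, got {len(parts)}")
            contig, start, end, idx, gene, strand = parts[:6]
            rows.append((contig, int(start), int(end), int(idx), gene, strand))
    if not rows:
        raise FormatError(f"{path}: empty gene model")
    contig = rows[0][0]
    gene = rows[0][4]
    strand = rows[0][5]
    exons_genomic = sorted((r[1], r[2]) for r in rows)
    if strand == "-":
        exons = exons_genomic[::-1]
    else:
        exons = exons_genomic
    return GeneModel(gene=gene, contig=contig, strand=strand, exons=exons)


def validate_sam(path: str | Path) -> dict:
    """Light validation pass over a SAM file; returns summary counts."""
    reads = read_alignments(path)
    return {
        "n_reads": len(reads),
        "n_forward": sum(r.orientation == "forward" for r in reads),
        "n_reverse": sum(r.orientation == "reverse" for r in reads),
        "contigs": sorted({r.contig for r in reads}),
        "samples": sorted({r.sample_id for r in reads if r.sample_id}),
    }
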