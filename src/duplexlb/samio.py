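"""SAM interchange for duplex-tagged and consensus reads.

Duplex tags travel as read tags: ``XA``/``XB`` hold the barcode pair as seen
from the read and ``XO`` the strand orientation (``ab``/``ba`` for raw reads,
``dx`` for duplex consensus reads). SAM (text) is the interchange format so
fixtures stay diffable; coordinates in SAM are handled by pysam.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pysam

from . import __version__
from .consensus import DCSRead
from .reference import SimReference
from .simulate import TaggedRead

_DEFAULT_QUAL = 37


def _cigar_and_seq(read) -> tuple[list[tuple[int, int]], str]:
    """Convert the aligned allele representation to CIGAR + SEQ."""
    ins = dict(read.insertions)
    cigar: list[tuple[int, int]] = []
    seq: list[str] = []

    def _emit(op: int, length: int) -> None:
        if length == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    for col, b in enumerate(read.bases.decode()):
        if b == "-":
            _emit(2, 1)  # D
        else:
            _emit(0, 1)  # M (N consensus calls stay M with base N)
            seq.append(b)
        if col in ins:
            _emit(1, len(ins[col]))  # I
            seq.append(ins[col])
    return cigar, "".join(seq)


def _from_alignment(aln: pysam.AlignedSegment) -> TaggedRead:
    """Rebuild the aligned allele representation from CIGAR + SEQ."""
    bases: list[str] = []
    insertions: list[tuple[int, str]] = []
    seq = aln.query_sequence or ""
    qpos = 0
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M/=/X
            bases.append(seq[qpos : qpos + length])
            qpos += length
        elif op == 2:  # D
            bases.append("-" * length)
        elif op == 1:  # I anchored after the previous reference column
            col = len("".join(bases)) - 1
            if col < 0:
                raise ValueError(f"{aln.query_name}: leading insertion unsupported")
            insertions.append((col, seq[qpos : qpos + length]))
            qpos += length
        else:
            raise ValueError(f"{aln.query_name}: unsupported CIGAR op {op}")
    return TaggedRead(
        read_id=aln.query_name,
        tag_a=aln.get_tag("XA") if aln.has_tag("XA") else "",
        tag_b=aln.get_tag("XB") if aln.has_tag("XB") else "",
        orientation=aln.get_tag("XO") if aln.has_tag("XO") else "",
        chrom=aln.reference_name,
        fragment_start=aln.reference_start,
        fragment_end=aln.reference_end,
        bases="".join(bases).encode(),
        insertions=tuple(insertions),
    )


def _header(ref: SimReference, meta: dict[str, str] | None) -> pysam.AlignmentHeader:
    head = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.contig, "LN": len(ref.sequence)}],
        "PG": [{"ID": "duplexlb", "PN": "duplexlb", "VN": __version__}],
    }
    if meta:
        head["CO"] = [f"{k}:{v}" for k, v in sorted(meta.items())]
    return pysam.AlignmentHeader.from_dict(head)


def write_sam(
    reads: Iterable[TaggedRead | DCSRead],
    path: str,
    ref: SimReference,
    meta: dict[str, str] | None = None,
) -> None:
    """Write reads coordinate-sorted as text SAM with XA/XB/XO tags."""
    header = _header(ref, meta)
    ordered = sorted(reads, key=lambda r: (r.fragment_start, r.read_id))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in ordered:
            aln = pysam.AlignedSegment(header)
            aln.query_name = read.read_id
            aln.flag = 0
            aln.reference_id = 0
            aln.reference_start = read.fragment_start
            aln.mapping_quality = 60
            cigar, seq = _cigar_and_seq(read)
            aln.cigartuples = cigar
            aln.query_sequence = seq
            aln.query_qualities = pysam.qualitystring_to_array(
                chr(_DEFAULT_QUAL + 33) * len(seq)
            )
            if isinstance(read, DCSRead):
                tags = [
                    ("XA", read.key.tag1),
                    ("XB", read.key.tag2),
                    ("XO", "dx"),
                ]
            else:
                tags = [("XA", read.tag_a), ("XB", read.tag_b), ("XO", read.orientation)]
            aln.set_tags(tags)
            out.write(aln)


def read_sam(path: str) -> list[TaggedRead]:
    """Read a SAM/BAM produced by this package back into tagged reads."""
    reads: list[TaggedRead] = []
    with pysam.AlignmentFile(path, "r") as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            reads.append(_from_alignment(aln))
    return reads


def read_reference(fasta_path: str, panel: Sequence | None = None) -> SimReference:
    """Load a single-contig FASTA (plus optional panel regions) via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    names = list(fa.keys())
    if len(names) != 1:
        raise ValueError("expected a single-contig reference")
    return SimReference(names[0], str(fa[names[0]][:]), list(panel or []))
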