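"""Pileup-based low-VAF variant calling in two modes.

LB (liquid biopsy) mode runs on duplex consensus reads with a limit of blank
of 0.25% VAF and a minimum of eight supporting consensus reads; tissue mode
runs on raw reads with a 5% limit of blank and no read-support rule. "Above
the LOB" is a strict inequality throughout.

Allele bookkeeping: N consensus calls are excluded from both the allele
counts and the depth denominator (they carry no allele information). A read
carrying an InDel contributes the InDel allele at its anchor column instead
of the anchor base, so allele counts never exceed depth. InDel alleles are
anchored at the base preceding the event and left-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .reference import PanelRegion, SimReference

_SYMBOLS = b"ACGT-N"
PASS = "PASS"
BELOW_LOB = "below_LOB"
LOW_SUPPORT = "low_support"


@dataclass
class CallerConfig:
    mode: str = "lb"  # "lb" | "tissue"
    lob_vaf: float = 0.25  # percent VAF, strict cutoff
    min_alt_reads: int = 8

    def __post_init__(self) -> None:
        if self.mode not in ("lb", "tissue"):
            raise ValueError("mode must be 'lb' or 'tissue'")
        if not 0.0 <= self.lob_vaf <= 100.0:
            raise ValueError("lob_vaf must be in [0, 100]")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")

    @classmethod
    def lb(cls, lob_vaf: float = 0.25, min_alt_reads: int = 8) -> "CallerConfig":
        return cls("lb", lob_vaf, min_alt_reads)

    @classmethod
    def tissue(cls, lob_vaf: float = 5.0) -> "CallerConfig":
        return cls("tissue", lob_vaf, 0)


@dataclass
class PileupColumn:
    """Allele counts at one panel position (1-based).

    ``counts`` keys: plain bases, ``+SEQ`` for an insertion of SEQ after the
    position, ``-SEQ`` for a deletion of SEQ starting after the position.
    ``depth`` counts covering reads with an informative (non-N) allele.
    """

    chrom: str
    pos: int
    ref: str
    counts: dict[str, int] = field(default_factory=dict)
    depth: int = 0
    n_count: int = 0


@dataclass
class PileupResult:
    columns: list[PileupColumn]
    rejected: list

    def __iter__(self):
        return iter(self.columns)

    def __len__(self) -> int:
        return len(self.columns)

    def __getitem__(self, i):
        return self.columns[i]


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    vaf: float  # percent
    filter: str

    @property
    def klass(self) -> str:
        return "SNV" if len(self.ref) == len(self.alt) == 1 else "InDel"

    @property
    def is_pass(self) -> bool:
        return self.filter == PASS

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def pileup(reads: Iterable, ref: SimReference, panel: Sequence[PanelRegion]) -> PileupResult:
    """Build one pileup column per panel base from co-aligned reads.

    Accepts TaggedRead (raw/tissue mode) or DCSRead (LB mode); both expose
    chrom, fragment coordinates, an aligned ``bases`` vector and anchored
    ``insertions``. Reads on contigs absent from the reference go to a reject
    list.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    npos = sum(len(r) for r in panel)
    pos0: list[int] = []
    for region in panel:
        pos0.extend(range(region.start, region.end))
    pos0_arr = np.asarray(pos0, np.int64)
    pos2idx = np.full(len(ref.sequence), -1, np.int64)
    pos2idx[pos0_arr] = np.arange(npos)

    sym_counts = np.zeros((len(_SYMBOLS), npos), np.int64)
    cover = np.zeros(npos, np.int64)
    indel_counts: dict[int, dict[str, int]] = {}

    def _bump_indel(idx: int, allele: str) -> None:
        indel_counts.setdefault(idx, {})
        indel_counts[idx][allele] = indel_counts[idx].get(allele, 0) + 1

    groups: dict[tuple[int, int], list] = {}
    rejected = []
    for read in reads:
        if read.chrom != ref.contig:
            rejected.append(read)
            continue
        groups.setdefault((read.fragment_start, read.fragment_end), []).append(read)

    n_code = _SYMBOLS.index(ord("N"))
    for (start, end), members in sorted(groups.items()):
        length = end - start
        mat = np.frombuffer(b"".join(r.bases for r in members), np.uint8).reshape(
            len(members), length
        )
        col_idx = pos2idx[start:end]
        valid = col_idx >= 0
        tgt = col_idx[valid]
        cover[tgt] += len(members)
        for s, sym in enumerate(_SYMBOLS):
            sym_counts[s, tgt] += (mat[:, valid] == sym).sum(axis=0)

        # Deletion events: runs of '-' anchored at the preceding column.
        gap = mat == ord("-")
        if gap.any():
            starts = gap.copy()
            starts[:, 1:] &= ~gap[:, :-1]
            for row, col in zip(*np.nonzero(starts)):
                run = 1
                while col + run < length and gap[row, col + run]:
                    run += 1
                if col == 0:
                    continue  # unanchored within this fragment; gap stays depth-only
                anchor = int(col) - 1
                if mat[row, anchor] == ord("N"):
                    continue  # no reliable anchor call on this read
                gidx = pos2idx[start + anchor]
                if gidx < 0:
                    continue
                deleted = ref.sequence[start + col : start + col + run]
                _bump_indel(int(gidx), "-" + deleted)
                sym_counts[_SYMBOLS.index(mat[row, anchor]), gidx] -= 1

        for row, read in enumerate(members):
            for col, seq in read.insertions:
                if mat[row, col] == ord("N"):
                    continue
                gidx = pos2idx[start + col]
                if gidx < 0:
                    continue
                _bump_indel(int(gidx), "+" + seq)
                sym_counts[_SYMBOLS.index(mat[row, col]), gidx] -= 1

    columns: list[PileupColumn] = []
    for i in range(npos):
        p0 = int(pos0_arr[i])
        counts: dict[str, int] = {}
        for s, sym in enumerate(b"ACGT"):
            c = int(sym_counts[s, i])
            if c > 0:
                counts[chr(sym)] = c
        for allele, c in sorted(indel_counts.get(i, {}).items()):
            counts[allele] = c
        n_count = int(sym_counts[n_code, i])
        columns.append(
            PileupColumn(
                chrom=ref.contig,
                pos=p0 + 1,
                ref=ref.sequence[p0],
                counts=counts,
                depth=int(cover[i]) - n_count,
                n_count=n_count,
            )
        )
    return PileupResult(columns=columns, rejected=rejected)


def _allele_pair(col: PileupColumn, allele: str) -> tuple[str, str]:
    if allele.startswith("+"):
        return col.ref, col.ref + allele[1:]
    if allele.startswith("-"):
        return col.ref + allele[1:], col.ref
    return col.ref, allele


def call_variants(columns: Iterable[PileupColumn], cfg: CallerConfig) -> list[VariantCall]:
    """Emit one VariantCall per non-reference allele with count > 0.

    PASS requires VAF strictly above the limit of blank AND at least
    ``min_alt_reads`` supporting reads; multi-allelic sites are filtered
    independently per alt allele.
    """
    calls: list[VariantCall] = []
    for col in columns:
        if col.depth <= 0:
            continue
        for allele, count in col.counts.items():
            if allele == col.ref or count <= 0:
                continue
            ref_a, alt_a = _allele_pair(col, allele)
            vaf = 100.0 * count / col.depth
            if vaf <= cfg.lob_vaf:
                flt = BELOW_LOB
            elif count < cfg.min_alt_reads:
                flt = LOW_SUPPORT
            else:
                flt = PASS
            calls.append(
                VariantCall(
                    chrom=col.chrom,
                    pos=col.pos,
                    ref=ref_a,
                    alt=alt_a,
                    alt_count=count,
                    depth=col.depth,
                    vaf=vaf,
                    filter=flt,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls


def write_vcf(
    calls: list[VariantCall],
    path: str,
    ref: SimReference,
    cfg: CallerConfig,
    sample_name: str = "sample",
    meta: dict[str, str] | None = None,
) -> None:
    """Write calls as VCF 4.2 with AD/DP/AF genotype fields and the caller
    configuration recorded in the header."""
    import pysam

    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    if [
        (c.chrom, c.pos) for c in calls
    ] != [(c.chrom, c.pos) for c in ordered]:
        raise ValueError("calls must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    header.contigs.add(ref.contig, length=len(ref.sequence))
    header.filters.add(BELOW_LOB, None, None, "VAF not strictly above the limit of blank")
    header.filters.add(LOW_SUPPORT, None, None, "Fewer supporting reads than required")
    header.formats.add("AD", "A", "Integer", "Alt-supporting read count")
    header.formats.add("DP", 1, "Integer", "Informative read depth at the site")
    header.formats.add("AF", "A", "Float", "Alt allele fraction")
    header.add_meta("duplexlb_mode", value=cfg.mode)
    header.add_meta("duplexlb_lob_vaf", value=str(cfg.lob_vaf))
    header.add_meta("duplexlb_min_alt_reads", value=str(cfg.min_alt_reads))
    for k, v in (meta or {}).items():
        header.add_meta(k, value=str(v))
    header.add_sample(sample_name)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for c in ordered:
            rec = vcf.new_record(contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt))
            if c.filter == PASS:
                rec.filter.add("PASS")
            else:
                rec.filter.add(c.filter)
            rec.samples[sample_name]["AD"] = (c.alt_count,)
            rec.samples[sample_name]["DP"] = c.depth
            rec.samples[sample_name]["AF"] = (round(c.vaf / 100.0, 6),)
            vcf.write(rec)


def read_vcf(path: str) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            alt_count = int(sample["AD"][0])
            depth = int(sample["DP"])
            flt = list(rec.filter.keys())
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    alt_count=alt_count,
                    depth=depth,
                    vaf=100.0 * alt_count / depth if depth else 0.0,
                    filter=flt[0] if flt else PASS,
                )
            )
    return calls
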