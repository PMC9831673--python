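"""Duplex consensus construction: read families -> SSCS -> DCS.

Reads sharing a duplex tag pair and fragment coordinates form a family, split
into the αβ and βα strand families of the original molecule. Each strand with
at least ``min_reads`` reads yields a single-strand consensus (SSCS) by strict
per-column majority vote; the duplex consensus (DCS) keeps a base only where
both strand consensuses agree and are non-N, which suppresses single-strand
artifacts (sequencing errors and PCR errors confined to one strand).

Reads within a family are co-aligned (same fragment window), so voting is per
reference column over aligned alleles, with ``-`` as the gap symbol for
deleted columns and anchored insertions voted as discrete alleles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .reference import PanelRegion
from .simulate import TaggedRead

_N = ord("N")


class FamilyKey(NamedTuple):
    """Canonical family key: tag pair sorted lexicographically so that an αβ
    read and its βα mate (which carry the tags in swapped order) collide."""

    tag1: str
    tag2: str
    chrom: str
    start: int
    end: int

    @classmethod
    def from_read(cls, read: TaggedRead) -> "FamilyKey":
        t1, t2 = sorted((read.tag_a, read.tag_b))
        return cls(t1, t2, read.chrom, read.fragment_start, read.fragment_end)


@dataclass
class ReadFamily:
    key: FamilyKey
    ab_reads: list[TaggedRead] = field(default_factory=list)
    ba_reads: list[TaggedRead] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.ab_reads) + len(self.ba_reads)


@dataclass
class GroupingResult:
    families: list[ReadFamily]
    rejected: list[TaggedRead]

    @property
    def n_assigned(self) -> int:
        return sum(f.n_reads for f in self.families)


@dataclass
class SSCSRead:
    key: FamilyKey
    orientation: str  # "ab" or "ba"
    calls: bytes  # A/C/G/T/-/N per reference column
    support: np.ndarray  # per-column count backing the winning allele
    insertions: tuple[tuple[int, str], ...]
    n_input_reads: int

    @property
    def read_id(self) -> str:
        return f"sscs:{self.key.tag1}/{self.key.tag2}:{self.key.start}:{self.orientation}"


@dataclass
class DCSRead:
    """Duplex consensus read; exposes the same positional surface as a
    TaggedRead so pileup code can consume either."""

    key: FamilyKey
    calls: bytes
    insertions: tuple[tuple[int, str], ...]
    source_ids: tuple[str, str]

    @property
    def chrom(self) -> str:
        return self.key.chrom

    @property
    def fragment_start(self) -> int:
        return self.key.start

    @property
    def fragment_end(self) -> int:
        return self.key.end

    @property
    def bases(self) -> bytes:
        return self.calls

    @property
    def read_id(self) -> str:
        return f"dcs:{self.key.tag1}/{self.key.tag2}:{self.key.start}"


def group_families(reads: Iterable[TaggedRead]) -> GroupingResult:
    """Assign every read to exactly one family by canonical key.

    Reads missing tags or with an unknown strand orientation go to the reject
    list (counted, never silently dropped). Read order within a family is
    deterministic (sorted by read id).
    """
    buckets: dict[FamilyKey, ReadFamily] = {}
    rejected: list[TaggedRead] = []
    for read in reads:
        if not read.tag_a or not read.tag_b or read.orientation not in ("ab", "ba"):
            rejected.append(read)
            continue
        key = FamilyKey.from_read(read)
        fam = buckets.get(key)
        if fam is None:
            fam = buckets[key] = ReadFamily(key)
        (fam.ab_reads if read.orientation == "ab" else fam.ba_reads).append(read)
    families = [buckets[k] for k in sorted(buckets)]
    for fam in families:
        fam.ab_reads.sort(key=lambda r: r.read_id)
        fam.ba_reads.sort(key=lambda r: r.read_id)
    return GroupingResult(families=families, rejected=rejected)


def _vote(
    reads: Sequence[TaggedRead], majority_frac: float
) -> tuple[bytes, np.ndarray, tuple[tuple[int, str], ...]]:
    n = len(reads)
    length = len(reads[0].bases)
    if any(len(r.bases) != length for r in reads):
        raise ValueError("family members must be co-aligned to the same fragment span")
    mat = np.frombuffer(b"".join(r.bases for r in reads), np.uint8).reshape(n, length)
    calls = mat[0].copy()
    support = np.full(length, n, np.int32)
    unanimous = (mat == mat[0]).all(axis=0)
    for col in np.flatnonzero(~unanimous):
        allele, count = Counter(mat[:, col].tolist()).most_common(1)[0]
        if count > majority_frac * n:
            calls[col] = allele
            support[col] = count
        else:
            calls[col] = _N
            support[col] = 0
    ins: tuple[tuple[int, str], ...] = ()
    if any(r.insertions for r in reads):
        counts: Counter = Counter()
        for r in reads:
            counts.update(r.insertions)
        ins = tuple(sorted(k for k, c in counts.items() if c > majority_frac * n))
    return calls.tobytes(), support, ins


def build_sscs(
    family: ReadFamily, min_reads: int = 2, majority_frac: float = 0.5
) -> list[SSCSRead]:
    """Build 0-2 single-strand consensus reads (one per strand side with at
    least ``min_reads`` reads). Per column the call is the allele backed by
    strictly more than ``majority_frac`` of the side's reads, else N."""
    if min_reads < 2:
        raise ValueError("min_reads must be >= 2 (a single read is no consensus)")
    out: list[SSCSRead] = []
    for orientation, side in (("ab", family.ab_reads), ("ba", family.ba_reads)):
        if len(side) < min_reads:
            continue
        calls, support, ins = _vote(side, majority_frac)
        out.append(
            SSCSRead(
                key=family.key,
                orientation=orientation,
                calls=calls,
                support=support,
                insertions=ins,
                n_input_reads=len(side),
            )
        )
    return out


def build_dcs(sscs_ab: SSCSRead, sscs_ba: SSCSRead) -> DCSRead:
    """Combine the two strand consensuses: a base is kept only where both are
    non-N and identical; anywhere else the duplex call is N. Insertions are
    kept only when both strands voted the identical anchored insertion."""
    if sscs_ab.key != sscs_ba.key:
        raise ValueError("SSCS mates must share a family key")
    a = np.frombuffer(sscs_ab.calls, np.uint8)
    b = np.frombuffer(sscs_ba.calls, np.uint8)
    calls = np.where((a == b) & (a != _N), a, _N).astype(np.uint8)
    ins = tuple(sorted(set(sscs_ab.insertions) & set(sscs_ba.insertions)))
    return DCSRead(
        key=sscs_ab.key,
        calls=calls.tobytes(),
        insertions=ins,
        source_ids=(sscs_ab.read_id, sscs_ba.read_id),
    )


@dataclass
class DuplexResult:
    dcs_reads: list[DCSRead]
    n_raw_reads: int
    n_families: int
    n_sscs: int
    n_rejected: int


def duplex_consensus(
    reads: Iterable[TaggedRead], min_reads: int = 2, majority_frac: float = 0.5
) -> DuplexResult:
    """Full raw-reads -> DCS pipeline (pure duplex mode: families with only one
    usable strand contribute nothing)."""
    reads = list(reads)
    grouping = group_families(reads)
    dcs: list[DCSRead] = []
    n_sscs = 0
    for fam in grouping.families:
        sides = build_sscs(fam, min_reads=min_reads, majority_frac=majority_frac)
        n_sscs += len(sides)
        if len(sides) == 2:
            dcs.append(build_dcs(sides[0], sides[1]))
    return DuplexResult(
        dcs_reads=dcs,
        n_raw_reads=len(reads),
        n_families=len(grouping.families),
        n_sscs=n_sscs,
        n_rejected=len(grouping.rejected),
    )


@dataclass
class ConsensusMetrics:
    total_raw_reads: int
    dcs_reads: int
    reduction_pct: float
    mean_effective_coverage: float | None = None
    pct_target_ge_threshold: float | None = None
    coverage_threshold: int | None = None

    def to_dict(self) -> dict:
        return {
            "total_raw_reads": self.total_raw_reads,
            "dcs_reads": self.dcs_reads,
            "reduction_pct": round(self.reduction_pct, 2),
            "mean_effective_coverage": (
                None
                if self.mean_effective_coverage is None
                else round(self.mean_effective_coverage, 1)
            ),
            f"pct_target_ge_{self.coverage_threshold}x": (
                None
                if self.pct_target_ge_threshold is None
                else round(self.pct_target_ge_threshold, 1)
            ),
        }


def _panel_depth(reads: Sequence, panel: Sequence[PanelRegion]) -> np.ndarray:
    """Per-base read depth over the panel (concatenated region coordinates)."""
    depths = []
    for region in panel:
        d = np.zeros(len(region), np.int64)
        for r in reads:
            if r.chrom != region.chrom:
                continue
            lo = max(r.fragment_start, region.start)
            hi = min(r.fragment_end, region.end)
            if lo < hi:
                d[lo - region.start : hi - region.start] += 1
        depths.append(d)
    return np.concatenate(depths) if depths else np.zeros(0, np.int64)


def consensus_metrics(
    raw_reads,
    dcs_reads,
    panel: Sequence[PanelRegion] | None = None,
    coverage_threshold: int = 250,
) -> ConsensusMetrics:
    """Consensus-reduction and effective-coverage summary.

    ``raw_reads``/``dcs_reads`` may be read lists or plain counts; coverage
    fields are computed from the consensus reads (the effective depth of a
    liquid-biopsy run) when a read list and a non-empty panel are supplied.
    """
    n_raw = raw_reads if isinstance(raw_reads, (int, float)) else len(raw_reads)
    n_dcs = dcs_reads if isinstance(dcs_reads, (int, float)) else len(dcs_reads)
    if n_raw <= 0:
        raise ValueError("total_raw_reads must be positive")
    if n_dcs > n_raw:
        raise ValueError("consensus reads cannot exceed raw reads")
    reduction = 100.0 * (1.0 - n_dcs / n_raw)
    mean_cov = pct_ge = None
    if panel is not None:
        if len(panel) == 0:
            raise ValueError("panel must be non-empty")
        cov_reads = dcs_reads if not isinstance(dcs_reads, (int, float)) else (
            raw_reads if not isinstance(raw_reads, (int, float)) else None
        )
        if cov_reads is not None:
            depth = _panel_depth(cov_reads, panel)
            mean_cov = float(depth.mean())
            pct_ge = float(100.0 * (depth >= coverage_threshold).mean())
    return ConsensusMetrics(
        total_raw_reads=int(n_raw),
        dcs_reads=int(n_dcs),
        reduction_pct=reduction,
        mean_effective_coverage=mean_cov,
        pct_target_ge_threshold=pct_ge,
        coverage_threshold=coverage_threshold,
    )
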