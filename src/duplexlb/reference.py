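"""Synthetic reference sequences and target-panel regions.

Coordinate conventions: BED-style panel regions are 0-based half-open;
variant positions elsewhere in the package are 1-based (VCF-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"


@dataclass(frozen=True)
class PanelRegion:
    """A targeted interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""
    is_hotspot: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass
class SimReference:
    """A single synthetic contig plus its target panel.

    The panel stands in for a hybrid-capture target region; intervals must be
    non-overlapping and lie within the contig.
    """

    contig: str
    sequence: str
    panel: list[PanelRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not 1 <= n <= 200_000:
            raise ValueError("reference length must be in [1, 200 kb]")
        regions = sorted(self.panel, key=lambda r: (r.chrom, r.start))
        prev_end = -1
        for r in regions:
            if r.chrom != self.contig:
                raise ValueError(f"panel region on unknown contig {r.chrom!r}")
            if r.end > n:
                raise ValueError(f"panel region {r.start}-{r.end} beyond contig end {n}")
            if r.start < prev_end:
                raise ValueError("panel regions overlap")
            prev_end = r.end
        self.panel = regions

    def fetch(self, start: int, end: int) -> str:
        """Sequence for [start, end), 0-based half-open."""
        return self.sequence[start:end]

    def base(self, pos_1based: int) -> str:
        return self.sequence[pos_1based - 1]

    @property
    def hotspots(self) -> list[PanelRegion]:
        return [r for r in self.panel if r.is_hotspot]

    @property
    def panel_length(self) -> int:
        return sum(len(r) for r in self.panel)

    def in_panel(self, pos_1based: int) -> bool:
        return any(r.contains(pos_1based) for r in self.panel)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def default_reference(seed: int = 1729) -> SimReference:
    """Scaled-down stand-in for a targeted panel: 2 kb contig, 1.2 kb panel.

    Four target regions, the last flagged as a cancer-hotspot subset, tiled by
    the simulator into 120 bp fragment windows.
    """
    rng = np.random.default_rng(seed)
    seq = random_sequence(2000, rng)
    panel = [
        PanelRegion("sim1", 100, 460, "target_01"),
        PanelRegion("sim1", 600, 960, "target_02"),
        PanelRegion("sim1", 1100, 1340, "target_03"),
        PanelRegion("sim1", 1500, 1740, "hotspot_01", is_hotspot=True),
    ]
    return SimReference("sim1", seq, panel)


def merge_regions(regions: list[PanelRegion]) -> list[PanelRegion]:
    """Sort and merge overlapping/adjacent-overlapping intervals per contig."""
    merged: list[PanelRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == r.chrom and r.start < merged[-1].end:
            last = merged[-1]
            merged[-1] = PanelRegion(
                last.chrom,
                last.start,
                max(last.end, r.end),
                last.label,
                last.is_hotspot or r.is_hotspot,
            )
        else:
            merged.append(r)
    return merged


def total_length(regions: list[PanelRegion]) -> int:
    return sum(len(r) for r in regions)


def read_bed(path: str, contig_lengths: dict[str, int] | None = None) -> list[PanelRegion]:
    """Read a 3+ column BED (0-based half-open) into sorted, merged regions.

    Column 4 (if present) is the label; a label containing "hotspot" marks the
    region as part of the hotspot subset. Malformed lines raise with their
    line number.
    """
    regions: list[PanelRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: require 0 <= start < end")
            if contig_lengths is not None:
                if chrom not in contig_lengths:
                    raise ValueError(f"{path}:{lineno}: unknown contig {chrom!r}")
                if end > contig_lengths[chrom]:
                    raise ValueError(f"{path}:{lineno}: interval beyond contig end")
            label = fields[3] if len(fields) > 3 else ""
            regions.append(PanelRegion(chrom, start, end, label, "hotspot" in label.lower()))
    if not regions:
        raise ValueError(f"{path}: empty BED file")
    return merge_regions(regions)


def write_bed(path: str, regions: list[PanelRegion], comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"#{comment}\n")
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def write_fasta(path: str, ref: SimReference, width: int = 70) -> None:
    """Write the reference as FASTA and index it (.fai)."""
    import pysam

    with open(path, "w") as fh:
        fh.write(f">{ref.contig}\n")
        for i in range(0, len(ref.sequence), width):
            fh.write(ref.sequence[i : i + width] + "\n")
    pysam.faidx(path)
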