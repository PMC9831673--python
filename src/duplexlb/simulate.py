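"""Synthetic duplex-tagged read simulator.

Emulates the data-generating process a duplex-sequencing liquid-biopsy assay
assumes: original double-stranded cfDNA molecules are tagged with a barcode
pair, both strands are PCR-amplified into an αβ and a βα read family, and
families are sequenced with independent per-base errors. PCR errors are
injected once per molecule-strand and therefore propagate to every read of
that strand family but never to the mate family — the signal the duplex
consensus exploits.

Fragmentation model: every panel region is tiled into fixed fragment windows
of ``read_length`` bases; each window receives ``n_molecules`` original
molecules whose reads fully span the window. Fragment endpoints are therefore
exact, which keeps family grouping and pileup bookkeeping exact.

Coordinates: fragment intervals are 0-based half-open; variant positions are
1-based and InDels are anchored at the base preceding the event and
left-aligned at generation time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .norm import normalize_variant, variant_key
from .reference import SimReference

_CODES = np.full(256, 255, np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
_ASCII = np.frombuffer(b"ACGT-N", np.uint8)
DEL_CODE = 4  # gap symbol in the aligned allele matrix


@dataclass(frozen=True)
class SpikeInVariant:
    """A truth variant with a nominal allele fraction (percent)."""

    chrom: str
    pos: int  # 1-based, anchor base for InDels
    ref: str
    alt: str
    nominal_vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nominal_vaf <= 100.0:
            raise ValueError("nominal_vaf must be in [0, 100]")
        if self.ref == self.alt or not self.ref or not self.alt:
            raise ValueError(f"bad alleles {self.ref!r}>{self.alt!r}")
        if self.klass == "InDel":
            if self.ref[0] != self.alt[0] or min(len(self.ref), len(self.alt)) != 1:
                raise ValueError("InDels must be single-event and anchored (ref[0]==alt[0])")

    @property
    def klass(self) -> str:
        return "SNV" if len(self.ref) == len(self.alt) == 1 else "InDel"

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def at_level(self, vaf: float) -> "SpikeInVariant":
        return dataclasses.replace(self, nominal_vaf=vaf)


@dataclass
class SimConfig:
    """Simulator knobs. Rates are probabilities; seed fixes all randomness."""

    n_molecules: int = 12_000  # original molecules per fragment window
    family_size_mean: float = 4.0  # Poisson mean reads per strand family
    strand_dropout_prob: float = 0.05  # whole strand family lost
    seq_error_rate: float = 1e-3  # per read base, i.i.d. substitutions
    pcr_error_rate: float = 1e-3  # per molecule-strand, one substitution
    read_length: int = 120
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("strand_dropout_prob", "seq_error_rate", "pcr_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.family_size_mean < 0:
            raise ValueError("family_size_mean must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(slots=True)
class TaggedRead:
    """One sequenced read in reference-aligned allele representation.

    ``bases`` has one byte per reference column of the fragment: A/C/G/T, or
    ``-`` where the molecule carries a deletion. Insertions are anchored after
    a column: ``insertions`` holds (column offset, inserted sequence) pairs.
    """

    read_id: str
    tag_a: str
    tag_b: str
    orientation: str  # "ab" (αβ) or "ba" (βα)
    chrom: str
    fragment_start: int  # 0-based
    fragment_end: int  # 0-based exclusive
    bases: bytes
    insertions: tuple[tuple[int, str], ...] = ()
    quals: bytes | None = None

    @property
    def sequence(self) -> str:
        """Read sequence as sequenced (gaps removed, insertions included)."""
        ins = dict(self.insertions)
        out: list[str] = []
        for col, b in enumerate(self.bases.decode()):
            if b != "-":
                out.append(b)
            if col in ins:
                out.append(ins[col])
        return "".join(out)


@dataclass
class SimulatedSample:
    """Reads plus ground-truth bookkeeping for oracle-style tests."""

    reads: list[TaggedRead]
    truth: list[SpikeInVariant]
    molecules: pd.DataFrame  # molecule, window_start, n_ab, n_ba
    carriers: dict[str, np.ndarray]  # variant key -> bool per molecule
    pcr_errors: list[tuple[int, str, int, str, str]]  # (mol, strand, pos1, from, to)
    ref: SimReference
    cfg: SimConfig

    def __iter__(self):
        return iter((self.reads, self.truth))


def fragment_windows(ref: SimReference, read_length: int) -> list[tuple[int, int]]:
    """Tile each panel region into fragment windows of ``read_length``."""
    windows = []
    for region in ref.panel:
        pos = region.start
        while pos < region.end:
            windows.append((pos, min(pos + read_length, region.end)))
            pos += read_length
    return windows


def _barcode(index: int, length: int = 12) -> str:
    chars = []
    for _ in range(length):
        chars.append("ACGT"[index & 3])
        index >>= 2
    return "".join(chars)


def _window_variants(
    variants: list[SpikeInVariant], wstart: int, wend: int
) -> list[SpikeInVariant]:
    out = []
    for v in variants:
        if wstart < v.pos <= wend:
            if v.pos - 1 + len(v.ref) > wend:
                raise ValueError(f"variant {v.key} crosses a fragment-window boundary")
            out.append(v)
    return out


def simulate_sample(
    ref: SimReference,
    variants: list[SpikeInVariant],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedSample:
    """Simulate one duplex-tagged read set over the panel.

    Each fragment window receives ``cfg.n_molecules`` molecules; every molecule
    carries each overlapping variant with probability nominal_vaf/100
    (independent Bernoulli), then yields a Poisson(family_size_mean) number of
    reads per strand, each strand independently dropped with
    ``strand_dropout_prob``. Returns reads plus a truth echo and per-molecule
    bookkeeping. Fixed config + seed gives byte-identical output.
    """
    for v in variants:
        if v.chrom != ref.contig:
            raise ValueError(f"variant {v.key} on unknown contig")
        if ref.sequence[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
            raise ValueError(f"variant {v.key} ref allele mismatches reference")
        if not ref.in_panel(v.pos):
            raise ValueError(f"variant {v.key} lies outside the panel")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    windows = fragment_windows(ref, cfg.read_length)
    n_mol = cfg.n_molecules
    reads: list[TaggedRead] = []
    mol_rows: list[tuple[int, int, int, int]] = []
    carrier_slices: dict[str, tuple[int, np.ndarray]] = {}
    pcr_errors: list[tuple[int, str, int, str, str]] = []

    for widx, (wstart, wend) in enumerate(windows):
        L = wend - wstart
        ref_codes = _CODES[np.frombuffer(ref.sequence[wstart:wend].encode(), np.uint8)]
        win_vars = _window_variants(variants, wstart, wend)

        flags = {
            v.key: rng.random(n_mol) < v.nominal_vaf / 100.0 for v in win_vars
        }
        for key, arr in flags.items():
            carrier_slices[key] = (widx, arr)

        sizes = rng.poisson(cfg.family_size_mean, (n_mol, 2))
        dropped = rng.random((n_mol, 2)) < cfg.strand_dropout_prob
        sizes[dropped] = 0
        ms_sizes = sizes.reshape(-1)  # molecule-strand, strand-major per molecule
        n_reads = int(ms_sizes.sum())
        read_ms = np.repeat(np.arange(2 * n_mol), ms_sizes)
        read_mol = read_ms >> 1
        read_strand = read_ms & 1

        mat = np.tile(ref_codes, (n_reads, 1))
        read_ins: dict[int, list[tuple[int, str]]] = {}
        for v in win_vars:
            carrier_reads = np.flatnonzero(flags[v.key][read_mol])
            col = v.pos - 1 - wstart
            if v.klass == "SNV":
                mat[carrier_reads, col] = _CODES[ord(v.alt)]
            elif len(v.ref) > len(v.alt):  # deletion of ref[1:]
                mat[carrier_reads[:, None], np.arange(col + 1, col + len(v.ref))] = DEL_CODE
            else:  # insertion of alt[1:] after the anchor column
                for r in carrier_reads:
                    read_ins.setdefault(int(r), []).append((col, v.alt[1:]))

        # PCR errors: one substitution per affected molecule-strand, shared by
        # all of that strand family's reads.
        err_ms = np.flatnonzero(rng.random(2 * n_mol) < cfg.pcr_error_rate)
        err_cols = rng.integers(0, L, err_ms.size)
        err_shift = rng.integers(1, 4, err_ms.size)
        read_starts = np.zeros(2 * n_mol + 1, np.int64)
        np.cumsum(ms_sizes, out=read_starts[1:])
        for ms, col, shift in zip(err_ms, err_cols, err_shift):
            rows = np.arange(read_starts[ms], read_starts[ms + 1])
            if rows.size == 0:
                continue
            cur = mat[rows[0], col]
            if cur >= DEL_CODE:  # deleted in this molecule: no substrate
                continue
            new = (cur + shift) % 4
            mat[rows, col] = new
            pcr_errors.append(
                (
                    widx * n_mol + int(ms >> 1),
                    "ab" if ms & 1 == 0 else "ba",
                    wstart + int(col) + 1,
                    "ACGT"[cur],
                    "ACGT"[new],
                )
            )

        # Sequencing errors: i.i.d. substitutions per read base.
        if cfg.seq_error_rate > 0 and n_reads > 0:
            err = rng.random((n_reads, L)) < cfg.seq_error_rate
            err &= mat < DEL_CODE
            idx = np.nonzero(err)
            if idx[0].size:
                shifts = rng.integers(1, 4, idx[0].size).astype(np.uint8)
                mat[idx] = (mat[idx] + shifts) % 4

        ascii_mat = _ASCII[mat]
        per_strand_count = np.zeros(2 * n_mol, np.int64)
        for i in range(n_reads):
            m = int(read_mol[i])
            s = int(read_strand[i])
            k = per_strand_count[read_ms[i]]
            per_strand_count[read_ms[i]] += 1
            g = widx * n_mol + m
            tag_a, tag_b = _barcode(2 * g), _barcode(2 * g + 1)
            if s == 0:
                rid, orient, t1, t2 = f"r{g}a{k}", "ab", tag_a, tag_b
            else:
                rid, orient, t1, t2 = f"r{g}b{k}", "ba", tag_b, tag_a
            reads.append(
                TaggedRead(
                    read_id=rid,
                    tag_a=t1,
                    tag_b=t2,
                    orientation=orient,
                    chrom=ref.contig,
                    fragment_start=wstart,
                    fragment_end=wend,
                    bases=ascii_mat[i].tobytes(),
                    insertions=tuple(read_ins.get(i, ())),
                )
            )
        for m in range(n_mol):
            mol_rows.append((widx * n_mol + m, wstart, int(sizes[m, 0]), int(sizes[m, 1])))

    molecules = pd.DataFrame(mol_rows, columns=["molecule", "window_start", "n_ab", "n_ba"])
    total_molecules = len(windows) * n_mol
    carrier_arrays: dict[str, np.ndarray] = {}
    for v in variants:
        full = np.zeros(total_molecules, bool)
        if v.key in carrier_slices:
            widx, arr = carrier_slices[v.key]
            full[widx * n_mol : (widx + 1) * n_mol] = arr
        carrier_arrays[v.key] = full
    return SimulatedSample(
        reads=reads,
        truth=list(variants),
        molecules=molecules,
        carriers=carrier_arrays,
        pcr_errors=pcr_errors,
        ref=ref,
        cfg=cfg,
    )


# ---------------------------------------------------------------------------
# Validation series: WT once + each spike-in level in replicates
# ---------------------------------------------------------------------------


@dataclass
class SeriesSample:
    sample_id: str
    level: float  # nominal spike-in VAF percent; 0 for the WT blank
    replicate: int
    is_wt: bool
    variants: list[SpikeInVariant]  # spike-ins at level + germline background
    seed_seq: np.random.SeedSequence


@dataclass
class ValidationSeries:
    """The spec of a dilution-series experiment; samples generate lazily."""

    ref: SimReference
    cfg: SimConfig
    spike_ins: list[SpikeInVariant]
    background: list[SpikeInVariant]
    levels: list[float]
    replicates: int
    samples: list[SeriesSample]

    def generate(self, sample: SeriesSample) -> SimulatedSample:
        rng = np.random.default_rng(sample.seed_seq)
        return simulate_sample(self.ref, sample.variants, self.cfg, rng=rng)

    def observation_counts(self, lob: float = 0.25) -> dict[str, int]:
        """Series composition arithmetic: one observation per variant/sample."""
        n_samples = len(self.samples)
        counts = {
            "n_samples": n_samples,
            "background_total": len(self.background) * n_samples,
            "background_snv": sum(v.klass == "SNV" for v in self.background) * n_samples,
            "background_indel": sum(v.klass == "InDel" for v in self.background) * n_samples,
        }
        above = [s for s in self.samples if not s.is_wt and s.level > lob]
        counts["spikein_above_lob"] = len(self.spike_ins) * len(above)
        counts["spikein_snv"] = sum(v.klass == "SNV" for v in self.spike_ins) * len(above)
        counts["spikein_indel"] = sum(v.klass == "InDel" for v in self.spike_ins) * len(above)
        return counts


def make_validation_series(
    ref: SimReference,
    base_variants: list[SpikeInVariant],
    levels: list[float],
    replicates: int = 2,
    include_wt: bool = True,
    cfg: SimConfig | None = None,
    background_variants: list[SpikeInVariant] | None = None,
) -> ValidationSeries:
    """Build the WT + per-level replicate sample set of an analytical validation.

    Every sample carries the fixed heterozygous/homozygous germline background;
    level samples additionally carry each spike-in at the level's nominal VAF.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(set(levels)) != len(levels) or any(lv < 0 for lv in levels):
        raise ValueError("levels must be distinct and >= 0")
    cfg = cfg if cfg is not None else SimConfig()
    background = (
        background_variants
        if background_variants is not None
        else default_background_variants(ref)
    )
    samples: list[SeriesSample] = []
    if include_wt:
        samples.append(
            SeriesSample("WT", 0.0, 1, True, list(background), None)  # type: ignore[arg-type]
        )
    for level in sorted(levels):
        for rep in range(1, replicates + 1):
            variants = [v.at_level(level) for v in base_variants] + list(background)
            samples.append(
                SeriesSample(f"L{level:g}_R{rep}", level, rep, False, variants, None)  # type: ignore[arg-type]
            )
    for child, sample in zip(np.random.SeedSequence(cfg.seed).spawn(len(samples)), samples):
        sample.seed_seq = child
    return ValidationSeries(
        ref=ref,
        cfg=cfg,
        spike_ins=list(base_variants),
        background=background,
        levels=sorted(levels),
        replicates=replicates,
        samples=samples,
    )


def dilute_in_silico(
    sample_reads: list[TaggedRead],
    background_reads: list[TaggedRead],
    fraction: float,
    seed: int,
) -> list[TaggedRead]:
    """Mix two read sets: keep each sample read with probability ``fraction``
    and each background read with probability ``1 - fraction``, so a variant
    at VAF v in the sample is expected at fraction*v in the mixture."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    contigs = {r.chrom for r in sample_reads} | {r.chrom for r in background_reads}
    if len(contigs) > 1:
        raise ValueError("read sets must be aligned to the same reference")
    rng = np.random.default_rng(seed)
    keep_s = rng.random(len(sample_reads)) < fraction
    keep_b = rng.random(len(background_reads)) < (1.0 - fraction)
    out = [r for r, k in zip(sample_reads, keep_s) if k]
    out += [r for r, k in zip(background_reads, keep_b) if k]
    return out


# ---------------------------------------------------------------------------
# Default truth sets for the bundled demo panel
# ---------------------------------------------------------------------------

_SLOT_OFFSETS = (6, 20, 34, 48, 62, 76, 90, 104)


def _slot_positions(ref: SimReference, read_length: int) -> list[int]:
    """Evenly spaced candidate anchor positions (1-based), >=14 bp apart."""
    out = []
    for wstart, wend in fragment_windows(ref, read_length):
        for off in _SLOT_OFFSETS:
            if wstart + off + 12 < wend:  # leave room for a 10 bp event
                out.append(wstart + off + 1)
    return out


def _next_base(b: str, shift: int = 1) -> str:
    return "ACGT"[("ACGT".index(b) + shift) % 4]


def _left_aligned(ref: SimReference, pos: int, r: str, a: str) -> bool:
    return normalize_variant(pos, r, a, ref.sequence) == (pos, r, a)


def _make_snv(ref: SimReference, pos: int, vaf: float) -> SpikeInVariant:
    b = ref.base(pos)
    return SpikeInVariant(ref.contig, pos, b, _next_base(b), vaf)


def _make_deletion(ref: SimReference, pos: int, length: int, vaf: float) -> SpikeInVariant:
    # Homopolymer context can defeat left-alignment at a given anchor; scan a
    # few anchors rightward until the representation is already canonical.
    for p in range(pos, pos + 5):
        for ln in range(length, 0, -1):
            r = ref.sequence[p - 1 : p + ln]
            a = r[0]
            if _left_aligned(ref, p, r, a):
                return SpikeInVariant(ref.contig, p, r, a, vaf)
    raise ValueError(f"no left-aligned deletion constructible near {pos}")


def _make_insertion(ref: SimReference, pos: int, length: int, vaf: float) -> SpikeInVariant:
    for p in range(pos, pos + 5):
        anchor = ref.base(p)
        nxt = ref.base(p + 1)
        for shift in (1, 2, 3):
            ins = "".join(_next_base(nxt, shift) for _ in range(length))
            a = anchor + ins
            if _left_aligned(ref, p, anchor, a):
                return SpikeInVariant(ref.contig, p, anchor, a, vaf)
    raise ValueError(f"no left-aligned insertion constructible near {pos}")


def default_spike_ins(ref: SimReference, read_length: int = 120) -> list[SpikeInVariant]:
    """Fifteen spike-in variants (8 SNVs, 7 InDels), one or two per fragment
    window, mirroring a ctDNA reference-material truth set."""
    slots = _slot_positions(ref, read_length)
    per_window = len(_SLOT_OFFSETS)
    n_windows = len(slots) // per_window
    picks = [slots[w * per_window] for w in range(n_windows)]
    picks += [slots[w * per_window + 4] for w in range(max(0, 15 - n_windows))]
    picks = sorted(picks[:15])
    indel_plan = {1: ("del", 2), 3: ("ins", 1), 5: ("del", 4), 7: ("ins", 2),
                  9: ("del", 6), 11: ("ins", 4), 13: ("del", 3)}
    variants = []
    for i, pos in enumerate(picks):
        if i in indel_plan:
            kind, ln = indel_plan[i]
            maker = _make_deletion if kind == "del" else _make_insertion
            variants.append(maker(ref, pos, ln, 5.0))
        else:
            variants.append(_make_snv(ref, pos, 5.0))
    assert sum(v.klass == "SNV" for v in variants) == 8
    assert sum(v.klass == "InDel" for v in variants) == 7
    return variants


def default_background_variants(
    ref: SimReference, read_length: int = 120
) -> list[SpikeInVariant]:
    """Sixty germline-background variants (59 SNVs, 1 InDel) at 50%/100% VAF,
    standing in for a well-characterized genomic background."""
    taken = {v.pos for v in default_spike_ins(ref, read_length)}
    slots = [p for p in _slot_positions(ref, read_length) if p not in taken]
    variants: list[SpikeInVariant] = []
    for i, pos in enumerate(slots):
        if len(variants) == 60:
            break
        vaf = 100.0 if i % 10 == 9 else 50.0
        if len(variants) == 30:
            variants.append(_make_deletion(ref, pos, 2, vaf))
        else:
            variants.append(_make_snv(ref, pos, vaf))
    if len(variants) != 60:
        raise ValueError("panel too small for the default background set")
    return variants


# ---------------------------------------------------------------------------
# Truth file writers
# ---------------------------------------------------------------------------


def write_truth_tsv(path: str, variants: list[SpikeInVariant]) -> None:
    df = pd.DataFrame(
        [(v.chrom, v.pos, v.ref, v.alt, v.klass, v.nominal_vaf) for v in variants],
        columns=["chrom", "pos", "ref", "alt", "class", "nominal_vaf"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_truth_vcf(path: str, variants: list[SpikeInVariant], ref: SimReference,
                    meta: dict[str, str] | None = None) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(ref.contig, length=len(ref.sequence))
    header.info.add("NVAF", 1, "Float", "Nominal variant allele fraction (percent)")
    header.info.add("VCLASS", 1, "String", "Variant class (SNV or InDel)")
    for k, v in (meta or {}).items():
        header.add_meta(key=k, value=v)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["NVAF"] = v.nominal_vaf
            rec.info["VCLASS"] = v.klass
            vcf.write(rec)


def read_truth_tsv(path: str) -> list[SpikeInVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        SpikeInVariant(r.chrom, int(r.pos), r.ref, r.alt, float(r.nominal_vaf))
        for r in df.itertuples()
    ]
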