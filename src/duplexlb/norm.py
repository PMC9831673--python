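"""Variant normalization: parsimony trimming and left-alignment.

Positions are 1-based. `seq` is the full contig sequence. This is the exact,
deterministic normalization used both when generating truth variants and when
matching calls against truth; it handles single-event SNVs and InDels (no
haplotype-aware rescue).
"""

from __future__ import annotations


def normalize_variant(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Return the minimal, left-aligned representation of (pos, ref, alt)."""
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty (anchored representation)")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    ref, alt = ref.upper(), alt.upper()
    while True:
        # Trim a shared trailing base while both alleles keep >=1 base ...
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # ... or rotate an indel one base to the left when its last base
        # matches the reference base preceding the event.
        elif (
            len(ref) != len(alt)
            and ref[-1] == alt[-1]
            and min(len(ref), len(alt)) == 1
            and pos > 1
        ):
            prev = seq[pos - 2]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"
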