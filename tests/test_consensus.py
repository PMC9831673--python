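import random

import numpy as np
import pytest

from duplexlb.consensus import (
    FamilyKey,
    build_dcs,
    build_sscs,
    consensus_metrics,
    duplex_consensus,
    group_families,
)
from duplexlb.calling import pileup
from duplexlb.reference import PanelRegion, SimReference
from duplexlb.simulate import SimConfig, TaggedRead, simulate_sample

from test_simulate import clean_cfg, small_ref


def mk_read(rid, bases, tag_a="T1", tag_b="T2", orientation="ab", start=0, ins=()):
    return TaggedRead(
        read_id=rid,
        tag_a=tag_a,
        tag_b=tag_b,
        orientation=orientation,
        chrom="c1",
        fragment_start=start,
        fragment_end=start + len(bases),
        bases=bases.encode(),
        insertions=tuple(ins),
    )


def family_of(*reads):
    grouping = group_families(list(reads))
    assert len(grouping.families) == 1
    return grouping.families[0]


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def test_ab_and_ba_reads_collapse_into_one_family():
    # βα reads carry the tag pair in swapped order; canonical keying must
    # still send both strands to one family.
    reads = [mk_read(f"a{i}", "ACGT") for i in range(3)]
    reads += [mk_read(f"b{i}", "ACGT", tag_a="T2", tag_b="T1", orientation="ba") for i in range(3)]
    fam = family_of(*reads)
    assert len(fam.ab_reads) == 3 and len(fam.ba_reads) == 3
    assert fam.key == FamilyKey("T1", "T2", "c1", 0, 4)


def test_different_fragment_start_means_different_family():
    reads = [mk_read("a0", "ACGT"), mk_read("a1", "ACGT", start=1)]
    grouping = group_families(reads)
    assert len(grouping.families) == 2


def test_reads_missing_tags_are_rejected_not_dropped():
    good = [mk_read("a0", "ACGT"), mk_read("a1", "ACGT")]
    bad = [mk_read("x0", "ACGT", tag_a=""), mk_read("x1", "ACGT", orientation="??")]
    grouping = group_families(good + bad)
    assert grouping.n_assigned + len(grouping.rejected) == 4
    assert len(grouping.rejected) == 2


def test_family_count_matches_simulator_bookkeeping():
    ref = small_ref()
    sample = simulate_sample(
        ref, [], clean_cfg(n_molecules=5000, family_size_mean=1.0, strand_dropout_prob=0.3)
    )
    surviving = int(((sample.molecules["n_ab"] + sample.molecules["n_ba"]) > 0).sum())
    grouping = group_families(sample.reads)
    assert len(grouping.families) == surviving
    assert grouping.n_assigned == len(sample.reads)


# ---------------------------------------------------------------------------
# SSCS
# ---------------------------------------------------------------------------


def test_single_read_side_yields_no_sscs():
    fam = family_of(
        mk_read("a0", "ACGT"),
        mk_read("b0", "ACGT", orientation="ba"),
        mk_read("b1", "ACGT", orientation="ba"),
    )
    out = build_sscs(fam)
    assert [s.orientation for s in out] == ["ba"]
    assert out[0].n_input_reads == 2


def test_min_reads_below_two_is_rejected():
    fam = family_of(mk_read("a0", "ACGT"), mk_read("a1", "ACGT"))
    with pytest.raises(ValueError):
        build_sscs(fam, min_reads=1)


def test_majority_vote_and_tie_to_N():
    fam = family_of(
        mk_read("a0", "ACGA"), mk_read("a1", "ACGA"), mk_read("a2", "CCGC")
    )
    (sscs,) = build_sscs(fam)
    assert sscs.calls == b"ACGA"  # 2/3 strict majority at every column
    assert list(sscs.support) == [2, 3, 3, 2]
    fam2 = family_of(mk_read("a0", "AC"), mk_read("a1", "CC"))
    (sscs2,) = build_sscs(fam2)
    assert sscs2.calls == b"NC"  # 1/2 is not a strict majority
    assert list(sscs2.support) == [0, 2]


def test_insertion_allele_requires_strict_majority():
    fam = family_of(
        mk_read("a0", "ACGT", ins=[(1, "TT")]),
        mk_read("a1", "ACGT", ins=[(1, "TT")]),
        mk_read("a2", "ACGT"),
    )
    (sscs,) = build_sscs(fam)
    assert sscs.insertions == ((1, "TT"),)
    fam2 = family_of(mk_read("a0", "ACGT", ins=[(1, "TT")]), mk_read("a1", "ACGT"))
    (sscs2,) = build_sscs(fam2)
    assert sscs2.insertions == ()


# ---------------------------------------------------------------------------
# DCS
# ---------------------------------------------------------------------------


def duplex_family(ab_bases, ba_bases, **kw):
    reads = [mk_read(f"a{i}", b, **kw) for i, b in enumerate(ab_bases)]
    reads += [
        mk_read(f"b{i}", b, orientation="ba", **kw) for i, b in enumerate(ba_bases)
    ]
    fam = family_of(*reads)
    ab, ba = build_sscs(fam)
    return build_dcs(ab, ba)


def test_dcs_identity_and_disagreement():
    assert duplex_family(["ACGT"] * 2, ["ACGT"] * 2).calls == b"ACGT"
    assert duplex_family(["ACGT"] * 2, ["ACTT"] * 2).calls == b"ACNT"


def test_dcs_requires_matching_keys():
    f1 = family_of(mk_read("a0", "ACGT"), mk_read("a1", "ACGT"))
    f2 = family_of(mk_read("b0", "ACGT", start=4), mk_read("b1", "ACGT", start=4))
    (s1,) = build_sscs(f1)
    (s2,) = build_sscs(f2)
    with pytest.raises(ValueError):
        build_dcs(s1, s2)


def test_single_strand_pcr_errors_never_reach_dcs():
    """A PCR artifact lives on one strand family only; the duplex consensus
    must call N (or the true base) there, never the artifact base."""
    ref = small_ref()
    sample = simulate_sample(ref, [], clean_cfg(n_molecules=500, pcr_error_rate=0.05))
    assert sample.pcr_errors
    result = duplex_consensus(sample.reads)
    from duplexlb.simulate import _barcode

    dcs_by_tags = {(d.key.tag1, d.key.tag2): d for d in result.dcs_reads}
    strand_hits = {}
    for mol, strand, pos, frm, to in sample.pcr_errors:
        strand_hits.setdefault((mol, pos), set()).add(strand)
    checked = 0
    for mol, strand, pos, frm, to in sample.pcr_errors:
        if len(strand_hits[(mol, pos)]) == 2:
            continue  # both strands independently hit; agreement is possible
        tags = tuple(sorted((_barcode(2 * mol), _barcode(2 * mol + 1))))
        dcs = dcs_by_tags.get(tags)
        if dcs is None:
            continue  # molecule produced no duplex consensus
        call = chr(dcs.calls[pos - 1 - dcs.fragment_start])
        assert call != to
        checked += 1
    assert checked > 0


def test_duplex_output_is_input_order_invariant():
    ref = small_ref()
    sample = simulate_sample(
        ref, [], clean_cfg(n_molecules=300, seq_error_rate=5e-3, pcr_error_rate=5e-3)
    )
    shuffled = list(sample.reads)
    random.Random(1).shuffle(shuffled)
    a = duplex_consensus(sample.reads)
    b = duplex_consensus(shuffled)
    fp = lambda res: sorted((d.key, d.calls, d.insertions) for d in res.dcs_reads)
    assert fp(a) == fp(b)


def test_every_dcs_read_is_backed_by_two_reads_per_strand():
    ref = small_ref()
    sample = simulate_sample(
        ref, [], clean_cfg(n_molecules=2000, family_size_mean=1.2, strand_dropout_prob=0.2)
    )
    grouping = group_families(sample.reads)
    result = duplex_consensus(sample.reads)
    sizes = {f.key: (len(f.ab_reads), len(f.ba_reads)) for f in grouping.families}
    for d in result.dcs_reads:
        ab, ba = sizes[d.key]
        assert ab >= 2 and ba >= 2


def test_duplex_error_suppression_vs_raw_pileup():
    """At wild-type positions, duplex consensus suppresses the non-reference
    allele fraction by >=100x relative to the raw pileup."""
    ref = small_ref(length=240)
    cfg = clean_cfg(
        n_molecules=4000, family_size_mean=4.0, seq_error_rate=1e-3, pcr_error_rate=1e-3
    )
    sample = simulate_sample(ref, [], cfg)

    def nonref_fraction(reads):
        cols = pileup(reads, ref, ref.panel)
        nonref = sum(c.depth - c.counts.get(c.ref, 0) for c in cols)
        depth = sum(c.depth for c in cols)
        return nonref / depth

    raw = nonref_fraction(sample.reads)
    dcs = nonref_fraction(duplex_consensus(sample.reads).dcs_reads)
    assert raw > 1e-4  # the raw data is genuinely noisy
    assert dcs * 100 <= raw


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def test_consensus_reduction_arithmetic():
    cm = consensus_metrics(89.8e6, 3.6e6)
    assert cm.reduction_pct == pytest.approx(100 * (1 - 3.6 / 89.8), abs=1e-9)
    assert consensus_metrics(1000, 1000).reduction_pct == 0.0
    with pytest.raises(ValueError):
        consensus_metrics(100, 200)


def test_uniform_depth_gives_exact_mean_coverage():
    panel = [PanelRegion("c1", 0, 50)]
    reads = [mk_read(f"r{i}", "A" * 50) for i in range(7)]
    cm = consensus_metrics(reads, reads, panel, coverage_threshold=5)
    assert cm.mean_effective_coverage == 7.0
    assert cm.pct_target_ge_threshold == 100.0
    with pytest.raises(ValueError):
        consensus_metrics(reads, reads, [], coverage_threshold=5)
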