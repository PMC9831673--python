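import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from duplexlb.calling import PASS, PileupColumn, VariantCall
from duplexlb.norm import normalize_variant
from duplexlb.reference import PanelRegion, SimReference
from duplexlb.simulate import SpikeInVariant
from duplexlb.validation import (
    ConfusionCounts,
    LodResult,
    TruthSet,
    UndefinedMetricError,
    ValidationReport,
    compare_to_truth,
    detection_rate,
    determine_loq,
    establish_lod,
    estimate_lob,
    level_stats,
    performance,
    render_report,
)

# Printed confusion counts of the assay validation (LB full panel, LB hotspot,
# tissue; SNV and InDel) and the percentages they imply.
TABLE1 = [
    ("lb_full_snv", 48, 0, 28, 100.0, 63.2),
    ("lb_full_indel", 39, 3, 7, 92.9, 84.8),
    ("lb_hotspot_snv", 48, 0, 4, 100.0, 92.3),
    ("lb_hotspot_indel", 33, 3, 0, 91.7, 100.0),
    ("tissue_snv", 515, 3, 0, 99.4, 100.0),
    ("tissue_indel", 22, 0, 3, 100.0, 88.0),
]


# ---------------------------------------------------------------------------
# Sensitivity / PPV
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name,tp,fn,fp,sens,ppv", TABLE1)
def test_performance_reproduces_validation_table(name, tp, fn, fp, sens, ppv):
    pm = performance(ConfusionCounts(tp=tp, fn=fn, fp=fp))
    assert round(pm.sensitivity, 1) == sens
    assert round(pm.ppv, 1) == ppv


def test_performance_undefined_denominators():
    with pytest.raises(UndefinedMetricError):
        performance(ConfusionCounts(0, 0, 5)).sensitivity
    with pytest.raises(UndefinedMetricError):
        performance(ConfusionCounts(0, 5, 0)).ppv


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------


def _mk_truth_universe(seed):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    regions = [
        PanelRegion("c1", 0, 200, "t1"),
        PanelRegion("c1", 250, 400, "hot", is_hotspot=True),
    ]
    in_region = np.array(list(range(1, 201)) + list(range(251, 401)))
    positions = rng.choice(in_region, size=40, replace=False)
    variants = []
    for p in positions:
        b = seq[p - 1]
        variants.append(SpikeInVariant("c1", int(p), b, "ACGT"[("ACGT".index(b) + 1) % 4], 5.0))
    return seq, regions, variants


def _call_for(v, flt=PASS):
    return VariantCall(v.chrom, v.pos, v.ref, v.alt, 50, 1000, 5.0, flt)


def test_compare_to_truth_matches_set_arithmetic_oracle():
    """Random subsets removed/added must reproduce brute-force TP/FN/FP."""
    for trial in range(300):
        rng = np.random.default_rng(trial)
        seq, regions, variants = _mk_truth_universe(trial % 7)
        truth_vars = [v for v in variants if rng.random() < 0.7]
        if not truth_vars:
            continue
        called = {v.key for v in truth_vars if rng.random() < 0.8}
        calls = [_call_for(v) for v in variants if v.key in called or (
            v.key not in {t.key for t in truth_vars} and rng.random() < 0.3)]
        truth = TruthSet(truth_vars, regions)
        result = compare_to_truth(calls, truth, seq)
        for rs_name, rs in (("full_panel", regions), ("hotspot", [regions[1]])):
            for klass in ("SNV",):
                t_in = {v.key for v in truth_vars if any(r.contains(v.pos) for r in rs)}
                c_in = {c.key for c in calls if any(r.contains(c.pos) for r in rs)}
                cc = result[(klass, rs_name)]
                assert cc.tp == len(t_in & c_in)
                assert cc.fn == len(t_in - c_in)
                assert cc.fp == len(c_in - t_in)


def test_only_pass_calls_count_and_truth_outside_regions_rejected():
    seq, regions, variants = _mk_truth_universe(3)
    truth = TruthSet(variants[:5], regions)
    calls = [_call_for(v, flt="below_LOB") for v in variants[:5]]
    result = compare_to_truth(calls, truth, seq)
    assert result[("SNV", "full_panel")].tp == 0
    assert result[("SNV", "full_panel")].fn == 5
    with pytest.raises(ValueError, match="outside trusted regions"):
        TruthSet([SpikeInVariant("c1", 230, seq[229], "ACGT"[("ACGT".index(seq[229]) + 1) % 4], 5.0)], regions)


def test_padded_deletion_matches_trimmed_call():
    seq = "GGATCGATCG"
    regions = [PanelRegion("c1", 0, 10)]
    # same deletion written with redundant padding vs minimal form
    truth = TruthSet([SpikeInVariant("c1", 4, "TCGA", "T", 5.0)], regions)
    padded = VariantCall("c1", 3, "ATCGAT", "ATT", 20, 400, 5.0, PASS)
    result = compare_to_truth([padded], truth, seq)
    assert result[("InDel", "full_panel")].tp == 1
    assert result[("InDel", "full_panel")].fp == 0


def test_normalization_agrees_with_bcftools_norm(tmp_path):
    """Independent oracle: bcftools norm left-aligns the same records."""
    seq = "GACTTTTCGATCGTAGGATCGTAAC"
    fa = tmp_path / "ref.fa"
    fa.write_text(">c1\n" + seq + "\n")
    subprocess.run(["samtools", "faidx", str(fa)], check=True)
    records = [
        (5, "TT", "T"),      # mid-homopolymer deletion, must shift left
        (11, "T", "TT"),     # right-shifted insertion representation
        (17, "GATC", "GA"),  # leading padding to trim
        (18, "ATCG", "AG"),  # trailing padding to trim
    ]
    vcf = tmp_path / "in.vcf"
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=c1,length=25>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for pos, ref, alt in records:
        lines.append(f"c1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.")
    vcf.write_text("\n".join(lines) + "\n")
    out = subprocess.run(
        ["bcftools", "norm", "-f", str(fa), str(vcf)],
        check=True, capture_output=True, text=True,
    ).stdout
    normed = [
        (int(f[1]), f[3], f[4])
        for f in (l.split("\t") for l in out.splitlines() if not l.startswith("#"))
    ]
    ours = [normalize_variant(pos, ref, alt, seq) for pos, ref, alt in records]
    assert ours == normed


# ---------------------------------------------------------------------------
# LOB
# ---------------------------------------------------------------------------


def _noise_columns(fractions, depth=10_000):
    cols = []
    for i, frac in enumerate(fractions):
        nonref = int(round(frac / 100.0 * depth))
        cols.append(
            PileupColumn("c1", i + 1, "A", {"A": depth - nonref, "T": nonref}, depth=depth)
        )
    return cols


def test_lob_zero_noise_gives_zero():
    est = estimate_lob([_noise_columns([0.0] * 100)])
    assert est.lob == 0.0
    assert est.n_positions == 100


def test_lob_percentile_rounds_up_to_step():
    fractions = [0.0] * 95 + [0.21] * 5
    est = estimate_lob([_noise_columns(fractions)])
    oracle = float(np.percentile(np.array(fractions), 95, method="higher"))
    assert oracle == 0.21
    assert est.lob == 0.25


def test_lob_requires_enough_wt_positions():
    with pytest.raises(ValueError, match="59"):
        estimate_lob([_noise_columns([0.0] * 59)])


def test_lob_parametric_method_and_exclusions():
    fractions = [0.1] * 100
    est = estimate_lob([_noise_columns(fractions)], method="parametric")
    assert est.lob == pytest.approx(0.1, abs=1e-9)  # zero SD; ceil hits the value
    est2 = estimate_lob(
        [_noise_columns([0.0] * 100 + [50.0])], exclude_positions={101}
    )
    assert est2.lob == 0.0


# ---------------------------------------------------------------------------
# Detection rate and LOD
# ---------------------------------------------------------------------------


def _obs(rows):
    return pd.DataFrame(rows, columns=["variant", "klass", "level", "replicate", "detected"])


def test_detection_rate_whole_percent_reporting():
    rows = [(f"v{i}", "InDel", 0.5, 1 + i % 2, i < 11) for i in range(14)]
    assert detection_rate(_obs(rows), "InDel", 0.5).percent == 79
    rows = [(f"v{i}", "SNV", 0.5, 1, True) for i in range(16)]
    assert detection_rate(_obs(rows), "SNV", 0.5).percent == 100
    rows = [(f"v{i}", "SNV", 1.0, 1, False) for i in range(5)]
    assert detection_rate(_obs(rows), "SNV", 1.0).percent == 0
    with pytest.raises(ValueError):
        detection_rate(_obs(rows), "InDel", 5.0)


def test_lod_establishment_rules():
    hits = {0.5: (27, 30), 1.0: (30, 30), 5.0: (30, 30)}
    res = establish_lod(hits, confidence_goal=90.0)
    assert res.lod == 0.5 and res.achieved_confidence == pytest.approx(90.0)
    res95 = establish_lod(hits, confidence_goal=95.0)
    assert res95.lod == 1.0
    res_all = establish_lod({0.1: (10, 10), 1.0: (10, 10)}, confidence_goal=90)
    assert res_all.lod == 0.1
    res_none = establish_lod({0.5: (1, 30)}, confidence_goal=90)
    assert not res_none.established and res_none.lod is None
    assert res_none.best_level == 0.5


# ---------------------------------------------------------------------------
# Level statistics and LOQ
# ---------------------------------------------------------------------------


def test_level_stats_perfect_measurements():
    stats = level_stats({f"v{i}": (5.0, 5.0) for i in range(10)}, 5.0)
    assert stats.trueness == 100.0
    assert stats.repeatability == 100.0
    assert stats.total_error == 0.0


def test_level_stats_duplicate_pair_formulas():
    stats = level_stats({"v1": (5.0, 5.4), "v2": (4.8, 5.2)}, 5.0)
    assert stats.pooled_sd == pytest.approx(math.sqrt((0.16 + 0.16) / 4))
    assert stats.cv == pytest.approx(5.6569, abs=1e-3)
    assert stats.repeatability == pytest.approx(94.343, abs=1e-2)
    assert stats.mean_relative_bias == pytest.approx(2.0)


def test_level_stats_total_error_composition():
    # bias +0.1% with CV 8.05% combine into a 16.2% total error
    d = 0.4025 * math.sqrt(2)
    measured = {f"v{i}": (5.005 - d / 2, 5.005 + d / 2) for i in range(30)}
    stats = level_stats(measured, 5.0)
    assert stats.mean_relative_bias == pytest.approx(0.1, abs=1e-9)
    assert stats.cv == pytest.approx(8.05, abs=1e-9)
    assert stats.total_error == pytest.approx(16.2, abs=1e-9)
    assert stats.trueness == pytest.approx(99.9)


def test_pooled_sd_matches_two_pass_oracle():
    rng = np.random.default_rng(12)
    measured = {f"v{i}": tuple(5 + rng.normal(0, 0.5, 2)) for i in range(50)}
    stats = level_stats(measured, 5.0)
    oracle = math.sqrt(
        np.mean([np.var(pair, ddof=1) for pair in measured.values()])
    )
    assert abs(stats.pooled_sd - oracle) <= 1e-12 * oracle


def test_level_stats_rejects_non_duplicates():
    with pytest.raises(ValueError, match="exactly 2"):
        level_stats({"v1": (5.0,)}, 5.0)


def test_loq_decision_from_printed_level_triples():
    triples = [(0.5, 85.0, 34.4), (1.0, 92.5, 65.2), (5.0, 99.9, 91.9)]
    assert determine_loq(triples) == 5.0
    assert determine_loq(triples, precision_goal=95.0) is None
    assert determine_loq([(0.5, 95.0, 90.0), (5.0, 99.0, 95.0)]) == 0.5


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _demo_report():
    perf = {}
    for name, tp, fn, fp, _, _ in TABLE1[:4]:
        rs = "hotspot" if "hotspot" in name else "full_panel"
        klass = "InDel" if "indel" in name else "SNV"
        perf[(klass, rs)] = ConfusionCounts(tp, fn, fp, klass, rs)
    detection = pd.DataFrame(
        [
            {"klass": "SNV", "level": 0.5, "detected": 16, "total": 16, "percent": 100},
            {"klass": "InDel", "level": 0.5, "detected": 11, "total": 14, "percent": 79},
            {"klass": "InDel", "level": 5.0, "detected": 0, "total": 0, "percent": float("nan")},
        ]
    )
    return ValidationReport(
        lob=0.25,
        lob_cutoff=0.25,
        lod=LodResult(0.5, 90.0, True, 0.5, 90.0, 30),
        loq=5.0,
        performance=perf,
        level_stats=[level_stats({f"v{i}": (5.0, 5.1) for i in range(10)}, 5.0)],
        detection=detection,
    )


def test_report_renders_table_cells_and_round_trips():
    doc, text = render_report(_demo_report())
    assert doc["performance"]["full_panel/SNV"] == {
        "tp": 48, "fn": 0, "fp": 28, "sensitivity": 100.0, "ppv": 63.2,
    }
    assert doc["performance"]["hotspot/InDel"]["ppv"] == 100.0
    assert doc["detection_rates_pct"]["InDel"]["5"] == "n/a"
    assert json.loads(json.dumps(doc)) == doc
    assert "LOD: 0.5% VAF at 90.0% confidence" in text


def test_report_enforces_lob_lod_loq_ordering():
    rep = _demo_report()
    rep.lob = 1.0  # above the established LOD
    with pytest.raises(ValueError, match="LOB exceeds LOD"):
        render_report(rep)
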