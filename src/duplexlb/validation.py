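"""Analytical validation of the assay: LOB, LOD, LOQ, sensitivity and PPV.

Implements the validation procedure of a low-VAF liquid-biopsy workflow:

* LOB (limit of blank) from the background noise at wild-type positions of
  blank samples — nonparametric 95th percentile by default, a parametric
  mean + 1.645·SD alternative is available.
* LOD (limit of detection) as the lowest spike-in level whose hit rate meets
  a stated confidence goal.
* Sensitivity and PPV from exact variant matching against a truth set after
  normalization, per variant class and per region set (full panel vs
  hotspot subset).
* LOQ (limit of quantification) from per-level trueness (100 − |mean relative
  bias|), repeatability (100 − CV, with CV the pooled duplicate standard
  deviation over the nominal VAF) and a Westgard-style total error
  |bias| + 2·CV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import PileupColumn, VariantCall
from .norm import normalize_variant
from .reference import PanelRegion
from .simulate import SpikeInVariant


class UndefinedMetricError(ValueError):
    """A performance metric whose denominator is zero."""


# ---------------------------------------------------------------------------
# Truth sets and confusion counting
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Expected variants restricted to trusted regions."""

    variants: list[SpikeInVariant]
    regions: list[PanelRegion]

    def __post_init__(self) -> None:
        for v in self.variants:
            if not any(r.contains(v.pos) for r in self.regions):
                raise ValueError(f"truth variant {v.key} outside trusted regions")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    klass: str = ""
    region_set: str = ""

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp,
            self.klass or other.klass, self.region_set or other.region_set,
        )


@dataclass
class PerformanceMetrics:
    counts: ConfusionCounts

    @property
    def sensitivity(self) -> float:
        d = self.counts.tp + self.counts.fn
        if d == 0:
            raise UndefinedMetricError("sensitivity undefined: tp + fn == 0")
        return 100.0 * self.counts.tp / d

    @property
    def ppv(self) -> float:
        d = self.counts.tp + self.counts.fp
        if d == 0:
            raise UndefinedMetricError("PPV undefined: tp + fp == 0")
        return 100.0 * self.counts.tp / d

    def rounded(self) -> dict[str, float]:
        return {
            "sensitivity": round(self.sensitivity, 1),
            "ppv": round(self.ppv, 1),
        }


def performance(counts: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity = 100·TP/(TP+FN); PPV = 100·TP/(TP+FP). Raises when a
    denominator is zero."""
    return PerformanceMetrics(counts)


def _klass(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == len(alt) == 1 else "InDel"


def compare_to_truth(
    calls: Sequence[VariantCall],
    truth: TruthSet,
    reference_seq: str,
    region_sets: Mapping[str, Sequence[PanelRegion]] | None = None,
) -> dict[tuple[str, str], ConfusionCounts]:
    """Exact truth comparison after normalization (left-align + trim).

    Only PASS calls count. TP = truth variant matched by identical
    (chrom, pos, ref, alt); FN = unmatched truth; FP = unmatched PASS call,
    restricted to each region set and split by variant class.
    """
    if region_sets is None:
        hotspots = [r for r in truth.regions if r.is_hotspot]
        region_sets = {"full_panel": truth.regions}
        if hotspots:
            region_sets = {"full_panel": truth.regions, "hotspot": hotspots}

    def _norm_truth(v: SpikeInVariant) -> tuple[int, str, str]:
        return normalize_variant(v.pos, v.ref, v.alt, reference_seq)

    def _norm_call(c: VariantCall) -> tuple[int, str, str]:
        return normalize_variant(c.pos, c.ref, c.alt, reference_seq)

    pass_calls = [(c, _norm_call(c)) for c in calls if c.is_pass]
    truth_norm = [(v, _norm_truth(v)) for v in truth.variants]

    out: dict[tuple[str, str], ConfusionCounts] = {}
    for rs_name, regions in region_sets.items():
        regions = list(regions)

        def _in(pos: int) -> bool:
            return any(r.contains(pos) for r in regions)

        call_keys = {(c.chrom, *n) for c, n in pass_calls if _in(n[0])}
        truth_keys = {(v.chrom, *n) for v, n in truth_norm if _in(n[0])}
        for klass in ("SNV", "InDel"):
            cc = ConfusionCounts(klass=klass, region_set=rs_name)
            for v, n in truth_norm:
                if not _in(n[0]) or _klass(n[1], n[2]) != klass:
                    continue
                if (v.chrom, *n) in call_keys:
                    cc.tp += 1
                else:
                    cc.fn += 1
            for c, n in pass_calls:
                if not _in(n[0]) or _klass(n[1], n[2]) != klass:
                    continue
                if (c.chrom, *n) not in truth_keys:
                    cc.fp += 1
            out[(klass, rs_name)] = cc
    return out


# ---------------------------------------------------------------------------
# LOB
# ---------------------------------------------------------------------------


@dataclass
class LobEstimate:
    lob: float  # percent VAF
    n_positions: int
    method: str


def estimate_lob(
    blank_pileups: Sequence[Iterable[PileupColumn]],
    exclude_positions: set[int] | None = None,
    method: str = "percentile",
    step: float = 0.05,
    min_positions: int = 60,
) -> LobEstimate:
    """LOB from per-position non-reference allele fractions of blank samples.

    Pools the noise fraction (non-ref allele count over informative depth) over
    all wild-type positions of all blanks, takes the nonparametric 95th
    percentile (or mean + 1.645·SD with method="parametric"), and rounds UP to
    the nearest ``step`` VAF-percent. Requires at least ``min_positions``
    pooled WT positions.
    """
    exclude_positions = exclude_positions or set()
    fractions: list[float] = []
    for columns in blank_pileups:
        for col in columns:
            if col.pos in exclude_positions or col.depth <= 0:
                continue
            non_ref = col.depth - col.counts.get(col.ref, 0)
            fractions.append(100.0 * non_ref / col.depth)
    if len(fractions) < min_positions:
        raise ValueError(
            f"only {len(fractions)} WT positions available; >= {min_positions} required"
        )
    arr = np.asarray(fractions)
    if method == "percentile":
        raw = float(np.percentile(arr, 95, method="higher"))
    elif method == "parametric":
        raw = float(arr.mean() + 1.645 * arr.std(ddof=1))
    else:
        raise ValueError(f"unknown LOB method {method!r}")
    lob = math.ceil(raw / step - 1e-9) * step if raw > 0 else 0.0
    return LobEstimate(lob=round(lob, 10), n_positions=len(fractions), method=method)


# ---------------------------------------------------------------------------
# Detection rates and LOD
# ---------------------------------------------------------------------------


@dataclass
class DetectionRate:
    detected: int
    total: int

    @property
    def rate(self) -> float:
        return 100.0 * self.detected / self.total

    @property
    def percent(self) -> int:
        """Whole-percent figure used for reporting."""
        return round(self.rate)


def detection_rate(
    observations: pd.DataFrame, klass: str, level: float
) -> DetectionRate:
    """Detection rate for one (variant class, nominal level) cell, pooled over
    replicates. ``observations`` needs columns klass, level, detected."""
    cell = observations[
        (observations["klass"] == klass) & (observations["level"] == level)
    ]
    if cell.empty:
        raise ValueError(f"no observations for class={klass} level={level}")
    return DetectionRate(int(cell["detected"].sum()), len(cell))


@dataclass
class LodResult:
    lod: float | None  # percent VAF; None if not established
    achieved_confidence: float | None
    established: bool
    best_level: float | None = None
    best_rate: float | None = None
    n_at_lod: int | None = None


def establish_lod(
    hit_rates: Mapping[float, tuple[int, int]], confidence_goal: float = 90.0
) -> LodResult:
    """LOD = lowest nominal level whose hit rate (detected/total) reaches the
    confidence goal; the achieved confidence is the hit rate at that level."""
    if not hit_rates:
        raise ValueError("no hit-rate levels supplied")
    best_level = best_rate = None
    for level in sorted(hit_rates):
        detected, total = hit_rates[level]
        if total <= 0:
            raise ValueError(f"level {level}: no observations")
        rate = 100.0 * detected / total
        if best_rate is None or rate > best_rate:
            best_level, best_rate = level, rate
        if rate >= confidence_goal:
            return LodResult(
                lod=level,
                achieved_confidence=rate,
                established=True,
                best_level=level,
                best_rate=rate,
                n_at_lod=total,
            )
    return LodResult(
        lod=None, achieved_confidence=None, established=False,
        best_level=best_level, best_rate=best_rate,
    )


# ---------------------------------------------------------------------------
# Per-level quantification statistics and LOQ
# ---------------------------------------------------------------------------


@dataclass
class VafLevelStats:
    nominal_vaf: float
    n_variants: int
    mean_relative_bias: float  # percent of nominal
    pooled_sd: float  # percent-VAF units
    cv: float  # percent
    trueness: float  # 100 - |bias|
    repeatability: float  # 100 - cv
    total_error: float  # |bias| + 2*cv


def level_stats(
    measured: Mapping[str, tuple[float, float]] | pd.DataFrame,
    nominal_vaf: float,
) -> VafLevelStats:
    """Trueness/repeatability statistics for one nominal VAF level.

    ``measured`` maps each variant to its two replicate VAF measurements (in
    percent), or is a DataFrame with columns variant, replicate, vaf. The
    pooled standard deviation over duplicates is sqrt(sum(d_i^2) / (2n)) with
    d_i the within-variant duplicate difference.
    """
    if isinstance(measured, pd.DataFrame):
        pairs: dict[str, tuple[float, ...]] = {}
        for variant, grp in measured.groupby("variant"):
            pairs[str(variant)] = tuple(grp.sort_values("replicate")["vaf"])
        measured = pairs
    if nominal_vaf <= 0:
        raise ValueError("nominal_vaf must be positive")
    for variant, values in measured.items():
        if len(values) != 2:
            raise ValueError(f"variant {variant}: expected exactly 2 replicates")
    n = len(measured)
    if n == 0:
        raise ValueError("no variants supplied")
    values = np.asarray(list(measured.values()), float)  # (n, 2)
    diffs = values[:, 0] - values[:, 1]
    pooled_sd = float(np.sqrt((diffs**2).sum() / (2 * n)))
    rel_bias = float((100.0 * (values.mean(axis=1) - nominal_vaf) / nominal_vaf).mean())
    cv = 100.0 * pooled_sd / nominal_vaf
    return VafLevelStats(
        nominal_vaf=nominal_vaf,
        n_variants=n,
        mean_relative_bias=rel_bias,
        pooled_sd=pooled_sd,
        cv=cv,
        trueness=100.0 - abs(rel_bias),
        repeatability=100.0 - cv,
        total_error=abs(rel_bias) + 2.0 * cv,
    )


def determine_loq(
    levels: Sequence[VafLevelStats | tuple[float, float, float]],
    trueness_goal: float = 90.0,
    precision_goal: float = 80.0,
) -> float | None:
    """LOQ = lowest nominal VAF with trueness > trueness_goal and
    repeatability > precision_goal; None when no level qualifies."""
    if not levels:
        raise ValueError("no levels supplied")
    rows = []
    for lv in levels:
        if isinstance(lv, VafLevelStats):
            rows.append((lv.nominal_vaf, lv.trueness, lv.repeatability))
        else:
            rows.append(tuple(lv))
    for nominal, trueness, repeat in sorted(rows):
        if trueness > trueness_goal and repeat > precision_goal:
            return nominal
    return None


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    lob: float  # percent VAF (estimated from blanks)
    lob_cutoff: float  # LOB actually applied by the caller
    lod: LodResult = field(default_factory=lambda: LodResult(None, None, False))
    loq: float | None = None
    performance: dict[tuple[str, str], ConfusionCounts] = field(default_factory=dict)
    level_stats: list[VafLevelStats] = field(default_factory=list)
    detection: pd.DataFrame | None = None  # klass x level detection percents
    meta: dict = field(default_factory=dict)


def _check_ordering(report: ValidationReport) -> None:
    if report.lod.established and report.lob > report.lod.lod:
        raise ValueError("LOB exceeds LOD")
    if report.lod.established and report.loq is not None and report.lod.lod > report.loq:
        raise ValueError("LOD exceeds LOQ")


def render_report(report: ValidationReport) -> tuple[dict, str]:
    """Render to a JSON-serializable dict (deterministic field order, one
    decimal on percentages, counts verbatim) plus a human-readable text."""
    _check_ordering(report)
    perf = {}
    for (klass, rs), cc in sorted(report.performance.items()):
        entry: dict = {"tp": cc.tp, "fn": cc.fn, "fp": cc.fp}
        pm = PerformanceMetrics(cc)
        try:
            entry["sensitivity"] = round(pm.sensitivity, 1)
        except UndefinedMetricError:
            entry["sensitivity"] = None
        try:
            entry["ppv"] = round(pm.ppv, 1)
        except UndefinedMetricError:
            entry["ppv"] = None
        perf[f"{rs}/{klass}"] = entry
    levels = [
        {
            "nominal_vaf": ls.nominal_vaf,
            "n_variants": ls.n_variants,
            "mean_relative_bias": round(ls.mean_relative_bias, 1),
            "pooled_sd": round(ls.pooled_sd, 4),
            "cv": round(ls.cv, 1),
            "trueness": round(ls.trueness, 1),
            "repeatability": round(ls.repeatability, 1),
            "total_error": round(ls.total_error, 1),
        }
        for ls in sorted(report.level_stats, key=lambda x: x.nominal_vaf)
    ]
    detection: dict = {}
    if report.detection is not None and not report.detection.empty:
        for klass in sorted(report.detection["klass"].unique()):
            sub = report.detection[report.detection["klass"] == klass]
            detection[klass] = {
                f"{lv:g}": (int(p) if p == p else "n/a")
                for lv, p in zip(sub["level"], sub["percent"])
            }
    doc = {
        "lob_pct": round(report.lob, 4),
        "lob_cutoff_pct": round(report.lob_cutoff, 4),
        "lod_pct": report.lod.lod,
        "lod_confidence_pct": (
            None
            if report.lod.achieved_confidence is None
            else round(report.lod.achieved_confidence, 1)
        ),
        "lod_established": report.lod.established,
        "loq_pct": report.loq,
        "performance": perf,
        "level_stats": levels,
        "detection_rates_pct": detection,
        "meta": report.meta,
    }
    lines = [
        "Analytical validation report",
        f"  LOB (estimated): {doc['lob_pct']:.2f}% VAF; applied cutoff {doc['lob_cutoff_pct']:.2f}%",
        (
            f"  LOD: {report.lod.lod:g}% VAF at {doc['lod_confidence_pct']}% confidence"
            if report.lod.established
            else "  LOD: not established"
        ),
        f"  LOQ: {report.loq:g}% VAF" if report.loq is not None else "  LOQ: not established",
        "  Sensitivity / PPV:",
    ]
    for name, entry in perf.items():
        sens = "n/a" if entry["sensitivity"] is None else f"{entry['sensitivity']:.1f}%"
        ppv = "n/a" if entry["ppv"] is None else f"{entry['ppv']:.1f}%"
        lines.append(
            f"    {name}: TP={entry['tp']} FN={entry['fn']} FP={entry['fp']}"
            f" sensitivity={sens} PPV={ppv}"
        )
    if detection:
        lines.append("  Detection rates (%):")
        for klass, cells in detection.items():
            cells_s = ", ".join(f"{lv}%: {p}" for lv, p in cells.items())
            lines.append(f"    {klass}: {cells_s}")
    for ls in levels:
        lines.append(
            f"  level {ls['nominal_vaf']:g}%: trueness {ls['trueness']:.1f}%,"
            f" repeatability {ls['repeatability']:.1f}%, total error {ls['total_error']:.1f}%"
        )
    return doc, "\n".join(lines) + "\n"


def report_to_json(report: ValidationReport) -> str:
    doc, _ = render_report(report)
    return json.dumps(doc, indent=2)
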