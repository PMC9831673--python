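# duplexlb

Duplex-sequencing consensus calling, low-VAF variant calling and analytical
validation for combined liquid-biopsy (LB) / tissue targeted panels — with a
bundled synthetic duplex-read simulator so the whole workflow is testable
end-to-end without any sequencing data.

## Who this is for

Clinical-bioinformatics and assay-validation teams who need to (a) collapse
duplex-tagged reads into high-accuracy consensus reads, (b) call somatic
variants down to fractions of a percent VAF in plasma cfDNA (and at ≥5% VAF
in tissue), and (c) run the standard analytical-validation battery — limit of
blank (LOB), limit of detection (LOD), limit of quantification (LOQ),
sensitivity and positive predictive value (PPV) — against spike-in reference
materials.

## The method

**Duplex consensus.** Each original double-stranded cfDNA molecule is tagged
with a barcode pair; PCR copies of its forward strand form the αβ read
family, copies of the complementary strand the βα family. Reads sharing a
canonical (tag pair, fragment coordinates) key are grouped; each strand side
with ≥2 reads yields a single-strand consensus (SSCS) by strict per-column
majority vote, and the duplex consensus (DCS) keeps a base only where both
SSCS mates agree (disagreement → N). Errors confined to one strand —
sequencing errors and late PCR artifacts — cannot survive this agreement
rule.

**Dual-mode calling.** From pileups of consensus (LB mode) or raw (tissue
mode) reads, one candidate per non-reference allele is emitted with

    VAF = 100 · alt_count / depth        (N-calls excluded from both)

and PASS requires `VAF > LOB` (strict; LOB 0.25% in LB mode, 5% in tissue
mode) and, in LB mode only, `alt_count ≥ 8` consensus reads.

**Validation statistics.** LOB is the 95th percentile of non-reference
fractions at wild-type positions of blank samples (rounded up to a 0.05%
step); LOD is the lowest spike-in level whose hit rate reaches the
confidence goal; sensitivity = 100·TP/(TP+FN) and PPV = 100·TP/(TP+FP)
per variant class and region set; per level, trueness = 100 − |mean relative
bias|, repeatability = 100 − CV with CV = pooled duplicate SD / nominal VAF
(pooled SD = √(Σdᵢ²/2n)), and total error = |bias| + 2·CV; LOQ is the lowest
level with trueness > 90% and repeatability > 80%.

## Worked example

```python
from duplexlb import (CallerConfig, call_variants, consensus_metrics,
                      default_reference, default_spike_ins, duplex_consensus,
                      pileup, simulate_sample)
from duplexlb.simulate import SimConfig

ref = default_reference()                      # 2 kb contig, 1.2 kb panel
spikes = default_spike_ins(ref)                # 8 SNVs + 7 InDels
cfg = SimConfig(n_molecules=3000, seed=7)
reads, truth = simulate_sample(ref, [v.at_level(1.0) for v in spikes], cfg)

result = duplex_consensus(reads, min_reads=2)
cm = consensus_metrics(result.n_raw_reads, result.dcs_reads, ref.panel)
calls = call_variants(pileup(result.dcs_reads, ref, ref.panel), CallerConfig.lb())
```

With these inputs the run prints 227,222 raw reads collapsed to 22,240 DCS
reads (90.2% consensus reduction, mean effective coverage 2224×) and exactly
15 PASS calls — every spike-in at its 1% nominal level and nothing else,
e.g.:

```
sim1:107 T>A    alt=22 depth=2229 vaf=0.99%
sim1:164 AAC>A  alt=26 depth=2230 vaf=1.17%
sim1:227 A>C    alt=21 depth=2230 vaf=0.94%
```

Each call reports the supporting consensus-read count, the informative
consensus depth, and the measured VAF; all pass both the 0.25% LOB and the
8-read rule.

## Command line

```bash
duplexlb simulate  --config run.yaml --out DIR --seed 1   # reads + truth + panel
duplexlb consensus --in reads.sam --ref ref.fa --panel panel.bed --out dcs.sam
duplexlb call      --mode lb --in dcs.sam --ref ref.fa --panel panel.bed --out calls.vcf
duplexlb dilute    --sample a.sam --background b.sam --ref ref.fa --fraction 0.1 --seed 1 --out mix.sam
duplexlb validate  --manifest series.yaml --truth truth.tsv --ref ref.fa --panel panel.bed --out report.json
duplexlb run       --config run.yaml --out DIR            # all of the above, composed
```

`duplexlb run` is byte-for-byte identical to invoking the stages manually.

## Layout

- `duplexlb.reference` — synthetic references, panel/hotspot BED handling
- `duplexlb.simulate` — duplex-read simulator, validation series, in-silico dilution
- `duplexlb.consensus` — family grouping, SSCS/DCS building, reduction metrics
- `duplexlb.calling` — pileup, LB/tissue caller, VCF 4.2 I/O
- `duplexlb.validation` — LOB/LOD/LOQ, truth comparison, report rendering
- `duplexlb.samio`, `duplexlb.pipeline`, `duplexlb.cli` — SAM I/O, orchestration, CLI

See `docs/methods.md` for the model, parameter defaults and known limits.
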