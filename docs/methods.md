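# Methods

## Scope

`duplexlb` implements a duplex-sequencing liquid-biopsy workflow as three
layers: a generative model of duplex-tagged reads (the simulator), the
consensus/calling machinery that is the analytical core, and the
assay-validation statistics built on top. Everything below documents the
model assumptions, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate about real sequencing data.

## Generative model (simulator)

A sample is simulated per *fragment window*: each targeted panel region is
tiled into fixed windows of `read_length` (default 120 bp) and each window
receives `n_molecules` original double-stranded molecules whose reads span
the window exactly. For every molecule:

1. **Variants.** Each truth variant overlapping the window is carried with
   independent Bernoulli probability `nominal_vaf/100`. InDels are
   single-event, anchored at the preceding base and left-aligned at
   generation time.
2. **Strand families.** The molecule yields an αβ and a βα family with
   independent Poisson(`family_size_mean`) read counts; each whole family is
   lost with probability `strand_dropout_prob` (strand dropout).
3. **PCR errors.** With probability `pcr_error_rate` per molecule-strand,
   one substitution at a uniform position is applied to *every* read of that
   strand family and to *no* read of the mate family. This is the artifact
   class duplex consensus exists to remove, and the simulator's bookkeeping
   exposes each injected error so tests can verify the suppression directly.
4. **Sequencing errors.** I.i.d. substitutions per read base at
   `seq_error_rate`.

Reads carry a reference-aligned allele representation (per-column base, `-`
for deleted columns, anchored insertion list); SAM round-trips convert this
to/from SEQ + CIGAR. Duplex tags are exact, collision-free synthetic
barcodes (no tag sequencing errors); βα reads carry the tag pair in swapped
order, which is what the canonical family key has to undo.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `n_molecules` | 12 000 per window | chosen so a 0.5% VAF variant clears both calling rules with a ~3σ margin: expected alt consensus depth ≈ 12 000 · 0.005 · 0.74 ≈ 45 reads against the 8-read rule, and twice the 0.25% VAF cutoff |
| `family_size_mean` | 4 reads/strand | typical duplex family scale; gives ≈0.86 per-strand and ≈0.74 duplex conversion together with dropout |
| `strand_dropout_prob` | 0.05 | a small fraction of strands leaves no usable copies |
| `seq_error_rate` | 1e-3 /base | order of magnitude of Illumina substitution error |
| `pcr_error_rate` | 1e-3 /molecule-strand | sparse late-PCR artifacts, the duplex-specific failure mode |
| `read_length` | 120 bp | fragment = window = read; keeps family and pileup bookkeeping exact |

The bundled demo reference is a deliberately scaled problem: a 2 kb contig
with a 1.2 kb panel in four regions (one flagged as the cancer-hotspot
subset), i.e. 10 fragment windows. The *composition* of the validation
series is not scaled: 15 spike-ins (8 SNVs, 7 InDels) at nominal levels
0.05/0.1/0.5/1/5% VAF in duplicates plus one wild-type blank, and a fixed
germline background of 60 variants (59 SNVs, 1 InDel) at 50%/100% VAF in
every sample — 11 samples, 660 background observations, and 90 spike-in
observations above a 0.25% cutoff (48 SNV, 42 InDel). The series object
generates each sample lazily from its own spawned seed, so bookkeeping is
instant and per-sample output is independent of generation order.

### What the simulator does not model

Fragment-length distributions and nucleosome footprints, GC bias, tag
cross-contamination or tag sequencing errors, paired-end mates (one spanning
read per fragment), multi-nucleotide or clustered variants, and InDel errors
from PCR/sequencing (error processes are substitution-only; InDels enter
only through truth variants). Consequently the synthetic experiments
demonstrate the *logic* of the workflow — family grouping, strand-agreement
error suppression, threshold behaviour, validation arithmetic — not the
error spectrum of any particular chemistry. Detection rates on real InDels
in repetitive contexts will be worse than the near-perfect synthetic ones.

## Consensus rules

- Family key: `(min(tag_a, tag_b), max(tag_a, tag_b), chrom, fragment_start,
  fragment_end)`; orientation is kept per read. Reads missing tags go to a
  counted reject list.
- SSCS: per strand side with ≥ `min_reads` (default 2, the duplex minimum)
  reads; per column the winning allele needs strictly more than half the
  side's reads (ties → N). Voting is count-based, not quality-weighted: no
  quality model is assumed, and count voting is exactly testable. Anchored
  insertions are voted as discrete alleles under the same strict-majority
  rule.
- DCS: base kept only where both SSCS are non-N and equal; insertion kept
  only when both strands voted the identical insertion. Families with one
  usable strand contribute nothing (pure duplex mode; no SSCS-only rescue).
- Determinism: reads are sorted by id within families, families by key, so
  output is independent of input order.

## Calling rules

- Pileup: one column per panel base. N consensus calls are excluded from
  both allele counts and depth — an N carries no allele information, and
  counting it in the denominator would deflate VAFs by an arbitrary amount.
  A read whose InDel is anchored at a column contributes the InDel allele
  there *instead of* its anchor base, so `sum(allele counts) ≤ depth` holds;
  mid-deletion columns keep the deleted reads in depth but give them no
  base allele.
- Filters: `PASS ⇔ VAF > lob_vaf AND alt_count ≥ min_alt_reads`, with
  strict inequality on the LOB ("above the blank" excludes the blank
  itself). LB mode: 0.25% / 8 consensus reads. Tissue mode: 5% / no read
  rule, on raw reads (no consensus, no deduplication). Multi-allelic sites
  are filtered per alt allele.
- The 8-read rule applies to the alt-supporting consensus-read count, not to
  depth, and only in LB mode — it is a consensus-read criterion and has no
  analogue on raw tissue pileups.

## Validation statistics

- **LOB**: nonparametric 95th percentile (numpy `method="higher"`, i.e. an
  observed order statistic, CLSI-EP17 style) of pooled per-position
  non-reference fractions at wild-type positions, rounded *up* to the
  nearest 0.05 VAF-percent; a parametric mean + 1.645·SD estimator is
  available. At least 60 pooled WT positions are required.
- **LOD**: lowest level with hit rate ≥ the confidence goal (default 90%);
  the achieved confidence is the hit rate itself. Detection rates are
  reported per class and level as whole percents, pooled over replicates.
- **Truth comparison**: exact `(chrom, pos, ref, alt)` matching after
  parsimony trimming and left-alignment, restricted to trusted regions,
  split by SNV/InDel and full-panel/hotspot. This is deliberately simpler
  than haplotype-aware comparison engines: matching is deterministic and
  auditable, at the cost of missing equivalent complex representations
  (which the single-event simulator never produces). The normalizer is
  cross-checked against `bcftools norm` in the test suite.
- **Quantification**: per level with duplicate measurements,
  `pooled_sd = sqrt(Σ dᵢ²/(2n))`, `CV = 100·pooled_sd/nominal`,
  `trueness = 100 − |mean relative bias|`, `repeatability = 100 − CV`,
  `total error = |bias| + 2·CV` (Westgard-style). An undetected replicate
  enters as 0.0% VAF, which correctly punishes repeatability at levels near
  the LOD. **LOQ** = lowest level with trueness > 90 and repeatability > 80.
  These trueness/repeatability definitions are reconstructions of standard
  practice and are configurable; reported percentages are rounded to one
  decimal, detection rates to whole percents.
- Report invariant: LOB ≤ LOD ≤ LOQ is checked at render time.

## Numerical and design choices

- Coordinates: BED intervals 0-based half-open; variants and pileup columns
  1-based; conversion happens only at format boundaries.
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence`; per-sample child seeds make series generation
  order-independent and byte-reproducible.
- Degenerate inputs are errors, not silence: zero molecules, variants
  outside the panel or mismatching the reference, empty panels, fewer than
  60 WT positions, non-duplicate measurements, zero metric denominators.
- The end-to-end test suite runs the full default series (11 samples,
  ~0.9 M reads each) once per session; unit tests use hundreds of molecules.

## Known limitations

- Pure duplex mode only; molecules with a single usable strand are discarded
  rather than rescued, which costs sensitivity at very low inputs.
- Tissue mode performs no duplicate removal; PCR duplicates inflate its
  depths on real data.
- The variant matcher has no haplotype rescue; representation-equivalent
  complex calls would count as FP+FN.
- The validate-from-VCF path cannot re-estimate the LOB (no pileups in its
  inputs); it reports the applied cutoff instead. The in-memory pipeline
  estimates the LOB from the blank sample's consensus pileup.
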