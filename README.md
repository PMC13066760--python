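# ffsig — fetal-fraction signatures for RHDO-based NIPD

`ffsig` is a quality-control toolkit for noninvasive prenatal diagnosis of
monogenic disease (NIPD-M).  Relative haplotype dosage (RHDO) infers the
transmitted parental haplotype from small allelic imbalances across SNPs in
maternal plasma cfDNA — and is silently corrupted by trisomy, monosomy,
uniparental disomy, dizygotic twins, and mosaics of the target chromosome.
`ffsig` detects those situations from the very same SNP allele-count data,
with no extra wet-lab work.

## How it works

SNPs are classified from phased parental genotypes into five types:

| Type | Parents                          | Use                                   |
|------|----------------------------------|---------------------------------------|
| 1    | both homozygous, different alleles | fetal fraction (FF = 2 × paternal-allele frequency) |
| 2    | both homozygous, same allele     | background noise (2nd-most-frequent allele) |
| 3    | father heterozygous              | transmitted paternal haplotype (subtypes P1/P2) |
| 4    | mother heterozygous              | transmitted maternal haplotype (subtypes alpha/beta; FF = freq(M1) − freq(M2)) |
| 5    | both heterozygous                | consanguinity workflows (classified only) |

In a normal pregnancy, Type-1, one Type-3 subtype and one Type-4 subtype
agree on FF while the remaining subtypes sit at background.  Each anomaly
breaks this *FF signature* in a characteristic way (e.g. a maternal
meiosis-I trisomy puts *both* Type-4 subtypes at half the Type-1 FF).  For
subtle cases, plasma counts are diluted in silico with matched maternal
counts and the two signed Type-4 FF estimates are regressed against the
Type-1 estimate: slopes are (+1, 0) or (0, −1) in a normal pregnancy and
shift characteristically otherwise (e.g. (1 − m/2, −m/2) for a maternal
MI trisomy in mosaic fraction m).

The package provides:

- `ffsig.panel` — SNP classification and panel model;
- `ffsig.signature` — per-class FF estimators and the signature object;
- `ffsig.oracle` — an exact mixture model of plasma (mother + fetal
  clones with mass weights) giving noise-free expected signatures and
  regression slopes for every scenario;
- `ffsig.dilution` — in-silico dilution and the Type-4-vs-Type-1 slope
  regression;
- `ffsig.caller` — alert rule, slope flags, scenario classification (with
  explicitly reported indistinguishable scenario sets), mosaic-fraction
  estimation;
- `ffsig.simulate` — a seeded composite-sample simulator (multinomial
  consensus counts at ~640× molecular depth with a low substitution-error
  model);
- `ffsig.io` / `ffsig.cli` — TSV/VCF/JSON readers & writers and the CLI.

## CLI

A full pipeline from a single seed, no external data:

```bash
# simulate a mosaic maternal MI trisomy case
ffsig simulate --scenario tri_mat_mei1 --ff 0.10 --mosaic 0.125 \
    --depth 640 --seed 42 --out-prefix case1

# FF signature of the plasma sample
ffsig signature --counts case1.counts.tsv --panel case1.panel.tsv \
    --out case1.sig.json

# dilution-regression slopes
ffsig regress --sample case1.counts.tsv --maternal case1.maternal_counts.tsv \
    --panel case1.panel.tsv --proportions 1,0.8,0.6,0.4,0.2 \
    --out case1.reg.json

# full QC call: alert, slope flag, ranked scenario fits
ffsig call --sample case1.counts.tsv --maternal case1.maternal_counts.tsv \
    --panel case1.panel.tsv --out case1.call.json
```

Panels can also be read from a phased VCF (`--vcf trio.vcf
--mother-id MOTHER --father-id FATHER`); the first allele of a phased
genotype is haplotype 1 (M1/P1).

## File formats

- **Panel TSV**: `snp_id  chrom  pos  M1  M2  P1  P2  is_y` (1-based
  positions; Y loci use `.` alleles and `is_y=1`).
- **Counts TSV**: `snp_id  A  C  G  T` (non-negative integer consensus
  counts; no coordinates, keyed by `snp_id`).
- **Reports**: self-contained JSON with estimates, dispersions, SNP
  counts, slopes, alert reasons, ranked scenario fits and the
  configuration echo.
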