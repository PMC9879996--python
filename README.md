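# mbescope

Targeting-scope analysis for miniature (Cas12f-derived) base editors:
editor-aware PAM scanning, variant correctability classification, sgRNA
design with bystander prediction, and quantification of base-editing
outcomes from amplicon reads and variant-call records.

## The problem

Adenine and cytosine base editors (ABEs, A→G; CBEs, C→T) built on the
hypercompact Un1Cas12f1 nuclease are small enough for single-AAV delivery,
but their targeting rules differ from SpCas9 editors: they require a strict
TTTR PAM 5′ of the protospacer, and protospacer positions are numbered from
the R of the PAM (R = 0, the next base 3′ = 1). Each construct edits only
within a characteristic *activity window* of protospacer positions — from
single-base windows (C3) up to wide windows (C3–C20) — sometimes with a
narrower high-precision tier and preferred positions. Whether a pathogenic
SNV can be corrected (and corrected *cleanly*, without bystander edits)
therefore depends jointly on the PAM landscape around the variant, the
strand, and the editor's window geometry.

`mbescope` formalises each editor as data (chemistry, PAM, coordinate
convention, windows, context preference), and everything downstream is
parameterised by that specification:

* **scan** — enumerate oriented PAM placements on both strands and convert
  between genomic coordinates and protospacer positions under either the
  Cas12f (R = 0) or SpCas9 (PAM-distal 1..20) convention.
* **targetability** — a variant is *correctable* when the patient (alt)
  allele, on either strand, is the editor's substrate base and some
  placement puts it in the activity window so the programmed edit restores
  the reference allele; *precisely correctable* additionally requires a
  precision-window placement with zero same-substrate bystanders. Cohort
  scans report per-transition-class fractions with auditable numerators and
  denominators; installation mode ranks sgRNAs for introducing a mutation.
* **quant** — from gapless amplicon reads: per-position substitution
  matrices, strand-aware editing profiles f(position) = n(edit)/depth,
  cross-site mean ± SEM aggregation, window calling at half-max, product
  purity among edited reads, joint allele tables over window positions,
  dinucleotide context preference, on/off-target ratios (zero off-target
  floored at one read), and R-loop sum/max statistics.
* **filters** — the GATK-style hard filter
  `QUAL < 25 || MQ < 20.0 || QD < 2.0 || FS > 30.0 || DP < 20`
  (fail on any clause; boundary values pass) plus A-to-I / C-to-U edit
  counting with a full 12-class transition table.
* **simulate** — seeded generators for every input, with certified ground
  truth (planted cohort fractions, planted editing frequencies, scheduled
  filter outcomes).

## Worked example

Design an sgRNA to install a C→T mutation with the TadA-reprogrammed CBE
`N-dRRACBE-8e(GGATY)` (single-base window C3), then scan a simulated
ClinVar-style cohort:

```python
import mbescope as m

reg = m.load_registry()
cbe = reg["N-dRRACBE-8e(GGATY)"]

# 60-nt locus with a TTTA PAM at offset 20 and the target C at offset 26
seq = list("G" * 60)
seq[20:23] = "TTT"; seq[23] = "A"; seq[26] = "C"
seq = "".join(seq)
for r in m.design_installation(seq, 26, "C", "T", cbe):
    h = r.placements[0]
    print(f"strand={h.placement.strand} target_position=C{h.target_position} "
          f"bystanders={list(h.bystander_positions)} precise={r.precise}")

cfg = m.SimConfig(seed=1)   # 100 variants, 25 correctable, 10 precisely
variants, truth = m.simulate_cohort(cfg, reg, "miniABE-any")
tab = m.cohort_fractions(variants, reg, ["miniABE-any", "miniCBE-any"])
print(tab[tab["class"] == "all"].to_string(index=False))
```

Output:

```
strand=+ target_position=C3 bystanders=[] precise=True
     editor class   n  n_correctable  n_precise  frac_correctable  frac_precise  frac_precise_of_correctable
miniABE-any   all 100             25         10              0.25           0.1                          0.4
miniCBE-any   all 100              4          0              0.04           0.0                          0.0
```

The single candidate places the target at protospacer position 3 — inside
the editor's precision window — with no other C in the window, so the
install is flagged precise. The cohort table recovers the planted 25%
correctable / 10% precise fractions for the editor the cohort was built
against (`frac_precise_of_correctable` = 0.4 is the precise share of the
targetable subset); the CBE row shows the incidental overlap of the same
variants with the CBE union window.

The same operations are exposed on the command line:

```sh
mbescope simulate --preset cohort --seed 1 --outdir sim/
mbescope classify --vcf sim/cohort.vcf --fasta sim/flanks.fa \
    --editors miniABE-any,miniCBE-any --out fractions.tsv
mbescope scan --fasta ref.fa --editor miniCBE-any --out hits.tsv
mbescope quant --fastq reads.fq --fasta amplicon.fa \
    --editor "N-dRRAABE-TadA*(82G)" --outdir quant/
mbescope filter-rna --vcf calls.vcf --out counts.tsv
```

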