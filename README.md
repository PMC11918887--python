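# tp53kit

Analysis toolkit for *TP53* mutation cohorts in chronic lymphocytic
leukemia (CLL): HGVS-based variant annotation on the major transcript
(NM_000546 / NP_000537), mutation-spectrum and hotspot statistics,
subclonal architecture from variant allele frequencies, read-backed
cis/trans phasing, SNP-based copy-neutral LOH calling, and
protein-consequence prediction including the cryptic-acceptor
(p53ψ-type) splice isoform.

It is written for hematology/molecular-biology groups who assemble
multicenter *TP53* variant tables (NGS and Sanger) and want the cohort
analyses behind such datasets to be reproducible: which variant classes
dominate, whether specific variants are enriched relative to another
cohort, how many patients carry multiple variants and on which alleles,
and which patients show copy-neutral loss of heterozygosity that would
otherwise masquerade as a simple heterozygous mutation.

## The models at the core

**Coordinates and consequences.** All variants are HGVS `c.`
descriptions on a single gene model (1-based CDS coordinates, intronic
positions as `anchor±offset`, e.g. `c.673-2`). A variant is classified
by translation: substitutions into missense / nonsense / synonymous,
exonic indels into frameshift (net length ≢ 0 mod 3) or in-frame, and
positions at ±1/±2 of an exon boundary into splice. Frameshifts are
translated to the first stop in the shifted frame and named
`p.<Ref><pos><Alt>fsTer<N>` with *N* counted from the first changed
residue. A disrupted splice acceptor is modelled by cryptic-acceptor
usage: the nearest surviving upstream `AG` (or a fixed, experimentally
supported offset — 49 nt for *TP53* intron 6) splices instead, the
intervening intronic 3′ segment is retained in the mRNA, and the product
is translated through the retention; products terminating around the
exon 6/7 boundary are tagged `psi_like`, the architecture of the
naturally occurring truncated isoform p53ψ.

**Subclonal architecture.** A patient is a mixture of subclones with
cell fractions $f_i$, $\sum_i f_i \le 1$; a heterozygous variant in
clone $i$ has VAF $= f_i/2$ under diploidy and $= f_i$ under CN-LOH or
del(17p). Cumulated VAF $\le 100\%$ across a patient's variants is the
signature of variants living on different alleles or in different
subclones. Read-backed phasing tests this directly: for two variants
covered by the same reads, *trans* requires both single-alt haplotypes
at ≥ `min_support` reads with the alt/alt count below a binomial
99.9%-quantile error bound, *cis* the reverse.

**CN-LOH.** A variant VAF > 50% without del(17p), together with
homozygosity of every informative locus SNP (alt fraction outside a
heterozygous band, default [0.10, 0.90], at depth ≥ 100), is called
copy-neutral LOH; any heterozygous SNP forces a heterozygous call.

**Enrichment.** Hotspot enrichment between cohorts is a 2×2 Pearson
chi-square (no continuity correction; Fisher fallback when an expected
cell < 5) with Haldane-corrected odds ratios.

## Worked example

```python
from tp53kit.reference import tp53_model
from tp53kit.hgvs import parse_hgvs_c, classify_variant
from tp53kit.consequence import translate_frameshift, predict_splice_outcome

model = tp53_model()                      # packaged NM_000546 model
a = classify_variant(parse_hgvs_c("c.700T>C"), model)
print(a.var_class, a.codon, a.protein_hgvs, a.event)
# missense 234 p.Tyr234His AT>GC

fs = translate_frameshift(parse_hgvs_c("c.626_627del"), model)
print(fs.protein_hgvs, fs.novel_cterm, fs.isoform_tag)
# p.Arg209LysfsTer6 KHFST psi_like

out = predict_splice_outcome(parse_hgvs_c("c.673-2A>G"), model)
print(len(out.retained_sequence), out.consequence.isoform_tag)
# 49 psi_like
```

The CLL frameshift hotspot `c.626_627del` replaces Arg209 with Lys and
terminates five residues later (`KHFST`), truncating p53 inside exon 6;
the intron-6 acceptor variant `c.673-2A>G` retains the 49 nt upstream of
the canonical acceptor and terminates early in exon 7 — both products
share the p53ψ-like architecture.

From the shell:

```bash
tp53kit simulate --n-patients 500 --seed 7 --out cohort.tsv --truth truth.json
tp53kit spectrum cohort.tsv --out spectrum.json
tp53kit multiclonality cohort.tsv --out mc.json
tp53kit consequence c.626_627del
tp53kit enrich --focal-a 17 --total-a 100 --focal-b 2 --total-b 100
```

The bundled simulator draws cohorts under an explicit clone model whose
defaults match the CLL study conditions the package targets
(missense-dominant class mix, transition-heavy substitution spectrum
with ≈20% AT>GC, ≈31% multi-mutated NGS patients, hotspot-weighted
variant menu); every run is reproducible from its seed and emits a
ground-truth JSON of clones and phases.

## Data notes

The packaged gene model ships the canonical *TP53* CDS and coding-exon
table; the intron 6 sequence is a **synthetic stand-in** reproducing
only the 3′-end architecture required for cryptic-acceptor prediction
(see the data file headers and `docs/methods.md`). Cohort tables are
consumed as TSV with named columns
(`patient_id, assay, hgvs_c, vaf, pathogenicity, del17p, treatment`);
reads as SAM or a simplified per-read call TSV; SNP profiles as TSV of
`snp_id, position, alt_fraction, depth`.
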