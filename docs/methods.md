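# Methods

## Gene model and coordinates

All computation runs in HGVS cDNA coordinates on one gene model:
position 1 is the A of the start codon, exonic positions are 1-based
inclusive, intronic positions are written `anchor±offset` relative to
the nearest exonic base. Genomic coordinates are never exposed; for a
single-gene toolkit they add nothing and multicenter variant tables are
reported in transcript terms anyway.

The packaged TP53 model covers the major transcript NM_000546 and its
protein NP_000537: a 1,182-nt CDS encoding 393 residues over ten coding
exons (numbered 2–11; exon 1 is noncoding), with the canonical junction
table (74, 96, 375, 559, 672, 782, 919, 993, 1100). The gene's ten
introns yield the twenty canonical splice signals (donor +1/+2,
acceptor −2/−1). Intron 1 flanks the noncoding first exon, so its two
signals exist in the catalogue but carry no cDNA-addressable
coordinates: the supported HGVS grammar is restricted to coding-anchored
positions (`pos ≥ 1`), and 5′UTR coordinates are out of scope. In
practice every splice variant seen in coding-region screens hits
introns 2–10.

The model loader validates hard invariants (CDS a multiple of 3, ATG
start, terminal stop, no internal stop, contiguous non-overlapping
exons covering the CDS exactly) and rejects violations rather than
warning: a silently wrong reference corrupts every downstream count.

**Intron 6 stand-in.** Only the intron 6 sequence is required (for
cryptic-acceptor prediction); the packaged file is a labelled synthetic
stand-in that reproduces the 3′-end architecture the model needs — a
canonical acceptor `AG`, a cryptic acceptor `AG` exactly 49 nt upstream,
no intervening `AG`, no in-frame stop inside the retained segment, and a
pyrimidine-rich tail. Consequences computed *downstream* of the
junction (reading frame, early stop in exon 7) depend only on the real
CDS and are exact; the identity of the 16 intron-derived residues in the
predicted ψ-type product is synthetic and should not be quoted as the
biological peptide. Other intron sequences are absent and
splice-consequence prediction raises a capability error for them.

## Variant grammar, normalization, classification

The HGVS `c.` subset parsed is exactly what cohort tables contain:
substitutions `N[±off]R>A`, deletions `N[_M]del[seq]`, duplications
`N[_M]dup`, insertions `N_Mins<seq>`, and `delins`. Inversions and
other rarities raise an explicit unsupported-feature error; malformed
text names the offending token. Parsing is lossless over the subset
(`parse(format(v)) == v`).

Indels are 3′-shifted per HGVS convention before counting (idempotent;
insertions that duplicate the preceding sequence become duplications).
Tables can disable normalization, since some sources count variants as
submitted; the default normalizes so that duplicate entries unify.

Classification is mechanical: |intronic offset| ∈ {1,2} → splice; other
intronic → intronic_other; exonic substitutions by codon translation
(missense/nonsense/synonymous); exonic indels by net length mod 3
(frameshift / inframe_indel). A stated reference allele disagreeing
with the model is a hard error. Substitutions touching the stop codon
(c.1180–1182) are a documented edge outside the cohort's variant
universe: stop-retaining changes are synonymous, stop-loss is carried
as missense-class with `ext` naming.

Substitutions collapse onto six strand-symmetric event classes
(GC>AT, AT>GC, GC>TA, GC>CG, AT>TA, AT>CG) — the granularity at which
CLL's transition-heavy spectrum is analysed; the 96-class signature
taxonomy is deliberately out of scope. The CpG flag marks C>T (or G>A)
at a CG dinucleotide, the deamination hotspot mechanism; at the CDS
edges or without intronic context the flag is unknown rather than
false.

Pathogenicity labels (P/LP/VUS/LB/B) and certified-oncogenic flags are
consumed from the input table and never derived: deriving them requires
a curated database and ACMG evidence outside this package's scope.

## Protein consequences

Frameshifts are translated from codon 1 of the edited CDS to the first
stop in the shifted frame (standard nuclear code; selenocysteine and
alternative initiation ignored). Naming follows HGVS: the first changed
residue anchors the name, coincidental matches shift the anchor
rightward, `fsTer N` counts the stop with the changed residue as 1, and
a frame that runs off the sequence end yields `fsTer?` plus an explicit
no-stop flag. Nonsense substitutions truncate the reference protein
before the new stop.

Splice-acceptor disruption is modelled as cryptic-acceptor usage with
partial intron retention. Two site rules: `fixed_offset` (default 49 nt
for TP53 intron 6 — the experimentally supported ψ-site; asserted, not
discovered) and `scan` (nearest upstream `AG` whose dinucleotide
survives the variant, ties broken toward the canonical site; intended
for synthetic genes). The predicted transcript keeps all exons plus the
retained intronic 3′ segment and is translated in full.

`psi_like` is a structural tag only: a product whose stop falls in the
window from exon 6 through the first 20 codons of exon 7 (where the
natural truncated isoform and the recurrent CLL truncating variants
end), for splice outcomes additionally requiring a frame-shifting
retention. No functional claim (mitochondrial localization, gain of
function) is attached.

## Cohort statistics

Denominators are fixed explicitly because mixed denominators are the
main source of irreproducible cohort numbers: class and event spectra
are per *variant* (events per substitution); multiclonality (SM/DM/MM3/
MM4plus = 1/2/3/>3 distinct variants) is per *patient* over the NGS
subset — Sanger cannot resolve low-VAF clones — and a patient assayed by
both methods counts once under NGS; hotspot shares are per class subset
(frameshifts for the codon-209 deletion, splice variants for the
intron-6 acceptor). The frameshift codon is the codon containing the
first changed base after 3′ normalization. The default NGS reporting
cutoff is VAF ≥ 1% (the practice-guideline value for CLL *TP53*
screening); rows below it are reported as errors, not silently dropped.
The 1–5% VAF census counts patients with at least one variant in the
closed band [lo, hi].

Hotspot enrichment: Pearson chi-square on the 2×2 without continuity
correction, automatic Fisher exact fallback when any expected cell is
below 5, odds ratio with Haldane 0.5 correction on zero cells. VAF
group comparisons use the two-sided Mann–Whitney U test per group pair,
skipping groups with fewer than two observations; a fully degenerate
pair (all observations identical) reports p = 1 by convention since the
rank-sum statistic is 0/0 there.

## Phasing

Reads enter either as SAM over the spliced-CDS reference (flags
honored: unmapped/secondary/supplementary/duplicate skipped;
substitutions matched by exact base, deletions by absent query bases
with aligned flanks, insertions/duplications by inserted length at the
anchor; soft-clipped positions uncalled) or as a simplified per-read
call TSV. Pairs are eligible when both variants are exonic, in the same
exon, and ≤ 50 nt apart (inclusive; the span short reads cover
reliably).

Decision rule over doubly-called reads: with `min_support` (default 20,
conservative at the ~5000× coverage of clinical *TP53* panels) and an
error bound equal to the 99.9% binomial quantile at the per-site error
rate, *cis* needs alt/alt ≥ min_support with both single-alt counts
within the bound, *trans* needs both single-alt counts ≥ min_support
with alt/alt within the bound; everything else — including insufficient
coverage — is ambiguous with a reason, never an exception. If both
rules fire simultaneously (possible at high error bounds) the call is
ambiguous, keeping the cis/trans regions disjoint.

Long-read (SMRT-style) reconstruction groups reads spanning *all*
variant positions by their full variant-combination signature and
reports counts and frequencies including wild type; signatures below a
1% noise floor are flagged as possible chimeras rather than removed.

## CN-LOH

Genotypes per SNP from alt fraction: heterozygous inside [0.10, 0.90]
at depth ≥ 100 (invented, config-exposed defaults), homozygous outside,
uninformative below depth. Dominant-clone decision rule: del(17p)=yes
short-circuits to a hemizygous interpretation; otherwise CN-LOH requires
variant VAF > 50%, at least one informative SNP, and homozygosity of
*all* informative SNPs; any heterozygous SNP forces a heterozygous call
(monotone: extra het evidence can never create a CN-LOH call); all-hom
with VAF ≤ 50% stays uninformative because germline homozygosity cannot
be excluded. CN-LOH confined to minor subclones is deliberately not
called — subclonal LOH leaves the germline-het SNP pattern intact, and
only the near-clonal event produces the full-homozygosity signature the
rule targets.

## Synthetic data: what it emulates and what it does not

The generator encodes the study conditions as defaults: variant class
mix 73/11/2/6/8% (missense/frameshift/inframe/nonsense/splice),
SM/DM/MM3/MM4+ patient weights 0.69/0.16/0.08/0.07 with 4+-variant
counts capped at 14, the codon-209 deletion at 16% of frameshift
weight, the three intron-6 acceptor substitutions jointly at 22% of
splice weight split equally, a transition-heavy background substitution
mixture giving ≈20% AT>GC overall, a Sanger patient fraction of
172/683 restricted to the exon 4–8 region, and FISH testing in 61% of
NGS patients. The hotspot catalogue is fixed; background variants are
chosen deterministically once (a fixed internal catalogue seed separate
from per-run randomness).

The clone model is the package's VAF map made explicit: clone fractions
are drawn from a Dirichlet scaled by a log-uniform tumor burden
(0.045–0.92, floored so every VAF clears the 1% cutoff), each variant
sits in its own subclone on one allele (hence trans; cis architectures
are constructed explicitly for phasing experiments), VAF = f/2 diploid,
VAF = f under CN-LOH/del(17p). Cumulated VAF ≤ 100% is therefore a hard
guarantee, not a tendency. For CN-LOH patients the LOH event's own cell
fraction is drawn near-clonal (95–100%) independently of the variant
clone (52–98%), since full SNP homozygosity — the observable the caller
keys on — only arises when the LOH is near-clonal. SNP profiles sample
binomially at Poisson-jittered depth: het SNPs at 0.5, shifted by
±f_LOH/2 per SNP under LOH, non-het panel SNPs near 0/1 with a 0.2%
error floor.

Known deviations from real data: per-site sequencing error is a uniform
allele flip (no homopolymer or strand-bias structure); reads span all
requested variant positions (amplicon abstraction; SAM emission covers
substitutions and deletions); Sanger assay noise is not modelled; and
weighted sampling *without replacement* within a patient slightly
deflates the realized share of high-weight hotspots in multi-mutated
patients — the codon-209 deletion realizes at ≈14% of frameshift
variants against its 16% draw weight. Passing tests therefore
demonstrate correctness of the decision rules and statistics under this
generative model, not robustness to platform-specific artifacts.

## Numerical and design choices

* Error bound quantile 0.999 (phasing): at 5000× coverage a 0.5%
  per-site error yields a bound ≈ 40 reads, far below true-haplotype
  support, so calls stay stable without tuning.
* Allele-frequency reconstruction reports exact empirical frequencies;
  convergence to clone fractions is Monte-Carlo (≈ ±3 percentage points
  at 2,000 reads, 3σ).
* Spectra are exact rational proportions; comparisons against printed
  cohort percentages round to the nearest integer.
* Chi-square uses no continuity correction so the statistic equals the
  closed form Σ(O−E)²/E; the Fisher fallback threshold is the classical
  expected-cell < 5 rule.
* Ties toward the canonical site in `scan` mode (retained length 0 wins)
  keep the no-op control exact.
* Simulation sizes in the test suite and acceptance script (cohorts of
  1,000–2,000 patients, 300 CN-LOH replicates, 2,000-read phasing
  experiments, 150 null rank-sum replicates) were chosen so Monte-Carlo
  noise sits well inside the asserted tolerances while the whole suite
  runs in seconds.

## Limitations

Single-gene, single-transcript scope; no genomic liftover, no
multi-transcript annotation, no donor-site splice outcomes, no NMD
modelling, no RNA-based validation of predicted isoforms. CN-LOH
calling ignores subclonal LOH by design. Pathogenicity is consumed,
never computed. Survival and treatment-outcome modelling are out of
scope.
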