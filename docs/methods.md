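# Methods

## Scope and model

`mirtas` catalogs trait-associated SNPs (TASs) in the miRNA regulome and
prioritizes them as candidate causal variants. A TAS is a GWAS index SNP
or any SNP in linkage disequilibrium with one (*r*² > 0.6) in a
population-matched phased haplotype panel. The miRNA regulome comprises
three element classes: miRNA hairpin precursors, miRNA promoters
(consumed as intervals from epigenomic annotation — no promoter discovery
is performed), and predicted miRNA target sites in 3′-UTRs.

## Linkage disequilibrium

*r*² is the squared allelic correlation estimated directly from phased
haplotype frequencies: *D* = p_AB − p_A·p_B and
*r*² = *D*² / (p_A(1−p_A) p_B(1−p_B)). With phased data this is exact and
needs no EM reconstruction of haplotype phase. Haplotypes missing an
allele at either SNP of a pair are excluded pairwise; a monomorphic SNP
gives *r*² = 0 by convention (the correlation is undefined and such a
pair carries no LD information). Panels must be bi-allelic SNVs;
multi-allelic records are dropped at load with a warning. An odd
haplotype count (broken diploid pairing) warns but does not fail.

Block expansion searches ±1 Mb around the index SNP (configurable).
Useful LD decays well inside this window in human panels, and restricting
the search keeps the computation linear in panel size; the window is a
package choice, not an estimate. The threshold is strict: a SNP at
exactly *r*² = 0.6 is excluded. An index SNP absent from the panel
produces an empty block flagged `unresolved` rather than an error, so one
unmatched association cannot abort a run.

MAF ties at exactly 0.5 report the alternate allele as minor. Any rule
works; a fixed one makes output deterministic, and 50/50 SNPs do occur.

Cohort ancestry is matched to a super-population by case-insensitive
substring search against four keyword rows scanned in a fixed order
(EUR, AFR, AMR, ASN), with EUR as the fallback for unmatched text. Row
order is the tie-break when a description matches two rows; the function
is total — every string maps to exactly one code.

## Seed-site prediction

Site types, in increasing efficacy: `7mer-1a`, `7mer-m8`, `8mer-1a`.
In mRNA-sense 5′→3′ coordinates the match patterns derive from the miRNA
seed: `8mer-1a` = revcomp(positions 2–8) + A, `7mer-m8` =
revcomp(2–8), `7mer-1a` = revcomp(2–7) + A. DNA and RNA alphabets are
interchangeable (T ≡ U); `N` never matches. Because an 8mer-1a match
necessarily contains both 7mer matches, overlapping matches at the same
seed-core location collapse to the strongest type. The engine is a plain
pattern scan; its contract is verified against an independent
sliding-window Watson–Crick complementarity oracle in the test suite.

**Conservation** is alignment-free: a site counts as conserved in a
species iff the orthologous UTR contains a same-type site for the same
miRNA *anywhere*, giving a number 1 (human only) to 5 (all of human,
mouse, rat, dog, chicken). A positional definition through a multiple
alignment would be stricter; the presence-based form needs no MSA, is
reproducible from sequence tables alone, and is recorded in output
metadata so downstream users know which definition they are getting.
Missing ortholog UTRs count as absent.

**Allelic complements.** SNPs on a UTR are grouped into clusters by
transitive proximity ≤ 7 nt (the widest site span); each cluster of k
SNPs yields all 2ᵏ−1 non-reference allele combinations, applied on a
reference background, with clusters varying independently. Combinations
are enumerated regardless of observed haplotype phase — rare combinations
are included for completeness. Clusters are capped at 10 SNPs (1,023
combinations); a denser cluster is a data error rather than a silent
combinatorial explosion. SNPs arriving in genomic coordinates are
projected onto the transcript strand (position reflected,
alleles complemented) for minus-strand genes before substitution, since
UTR sequences are sense-strand; this is the classic silent failure mode
of UTR variant analysis and is covered by a dedicated strand-planted
fixture event. Site identity for diffing is (miRNA, UTR offset, type);
only bi-allelic SNVs are supported, so alternate sequences never change
length and offsets stay comparable. A type change (e.g. 8mer-1a →
7mer-m8) reports as one abolished plus one created site.

## UTR admission

Human 3′-UTR records are admitted only with exactly one candidate genomic
mapping, unspliced (single aligned segment), and sequence length ≥ 20 nt;
rejections record a reason (`multi_mapped`, `spliced`, `too_short`,
`unmapped`). Real mappings are an *input*; the bundled `naive_map_utr`
exact-substring mapper exists for synthetic fixture genomes only.
Ortholog records are sequence-only and bypass the filter. Sequence IDs
are converted to gene symbols through a two-column lookup; unmapped IDs
are kept verbatim with one warning.

## Prioritization

Each LD block is annotated against independent datasets: coding-exon
intervals, nonsynonymous SNP IDs, transcriptional-regulatory SNP IDs
(RegulomeDB-style; score categories are carried but unused), eQTL IDs,
and validated miRNA:gene pairs. Tiering is per element kind, with an
asymmetric default policy: exonic variants disqualify pre-miRNA and
promoter TASs; nonsynonymous or transcriptional variants disqualify
target-site TASs. The asymmetry follows the distinct filters the two
element families face in practice (a promoter variant's obvious competing
explanation is a coding variant anywhere in the block; a UTR site
variant's is a protein-altering or transcriptional variant), and the
policy is configurable. Demoted records are rescued to `supported` by a
validated miRNA:gene interaction matching a predicted pair in the block,
or by very strong LD (*r*² > 0.9) with the index SNP (or being the index
SNP). eQTL hits annotate but never disqualify. Tier assignment is
monotone: adding annotations can only demote.

## Hub Monte Carlo test

For one miRNA and one trait gene list, the targeting score is the sum
over qualifying sites (conservation ≥ 5 by default, since the classical
conserved-site definition spans all five species) of a weight: 1.5 for an
8mer-1a site or for a site within 60 nt (start-to-start) of another site
for the same miRNA in the same UTR — proximal sites act cooperatively —
else 1. The "within 60 nt" reading is pairwise site proximity, both
partners weighted; a gene-level mode (max site weight per gene) is
available behind `score_mode="gene"` for sensitivity analysis, with the
site-level weighted sum as default.

The null repeatedly draws the same number of genes uniformly without
replacement from the universe of genes with admitted UTRs (100,000
replicates by default). Each null score *T* is rescaled to
*T* × L̄_test ∕ L̄_rand, where L̄_test and L̄_rand are the mean 3′-UTR
lengths of the candidate set and the draw — longer random UTRs would
otherwise inflate the background; the ratio uses exactly those two
quantities. The empirical p-value uses add-one smoothing,
(1 + #{null ≥ observed}) ∕ (reps + 1), so it lies in (0, 1] and never
returns an exact zero from a finite simulation. Significance is flagged
at p ≤ 0.01 (raw; no multiple-testing correction across miRNAs).

Because the proximity weighting looks only within a gene's own UTR, a
gene's contribution is constant across gene sets; contributions are
precomputed per gene and the null loop reduces to sums over sampled rows.
In `hub_scan`, null draws are seeded per *trait* and replayed for every
miRNA (common random numbers), so results are independent of iteration
order, reproducible bit-for-bit under a fixed seed, and miRNAs with
identical seed sequences receive identical scores and p-values.
Calibration is verified in the suite: with candidate sets drawn from the
null itself, the p-value distribution is approximately uniform.

## Synthetic fixtures

The generator emulates the study's input universe at desk scale, writing
only the standard formats the real pipeline reads (no privileged
in-memory path). Default conditions: 200 phased haplotypes (100 diploid
samples); one 10-kb locus per planted event plus decoy loci on a
synthetic chromosome; 8 miRNAs of 22 nt with distinct seeds; a 60-gene
hub universe with 3′-UTRs of 200–400 nt; a 15-gene trait list in which
the planted hub miRNA targets 40% of genes versus 5% of the background.

LD is engineered in closed form: the index SNP sits at allele frequency
1/2 and the partner's alternate haplotypes are a nested subset of size m,
giving *r*² = m ∕ (H − m) exactly — so a target of 0.6 or 1.0 is exact at
H = 200, and the boundary locus plants a TAS at exactly the threshold to
pin down the strict inequality end-to-end. Background SNPs are sampled
independently, so between-locus *r*² is O(1/H). Sequence plants are
*verified*: after embedding a site pattern or a site-breaking/creating
allele, the generator re-runs the site finder and differ over all fixture
miRNAs and resamples until the observed outcome equals the requested one,
which makes every manifest expectation exact rather than probable.
Catalog decoys exercise each filter: above-threshold p-values, a
multi-SNP haplotype row, a malformed p-value, a duplicated row, and an
index SNP absent from the panel.

What the fixtures do **not** emulate: coalescent LD structure and
recombination gradients, realistic allele-frequency spectra, GC and
length biases of real UTRs, paralogy, alignment error in UTR mappings,
and miRNA family structure. Passing tests therefore demonstrate
correctness of the computations and bookkeeping under controlled truth,
not the biological yield of the method on real catalogs.

## Numerical and degenerate-input choices

- *r*² is clipped into [0, 1] against floating-point drift; oracle
  comparisons in the suite are exact to 1e-12.
- Fewer than two complete haplotypes for a pair is a data error.
- Empty catalogs run to completion with empty outputs and a warning.
- Stage outputs are stable-sorted (blocks by position; intersections by
  chrom, position, element kind; hub results by p then miRNA name), so
  reruns are byte-identical.
- Monte Carlo problem sizes in the test suite and acceptance script
  (2,000 replicates for planted-enrichment detection, 200 × 500 for null
  calibration) are the package's fixture-scale operating point; the
  pipeline default remains 100,000 replicates.

## Known limitations

- Conservation is presence-based, not alignment-positional.
- Only canonical seed sites are predicted: no context scoring,
  thermodynamics, centered or 3′-compensatory sites, and no ORF sites.
- No imputation or genotype-likelihood handling; panels must be phased.
- Null gene sampling is uniform, not matched for GC or expression.
- Multi-SNP haplotype associations are out of scope by design.
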