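# Methods

This note records the models, rules and numerical choices behind
faw-haplotyper, and what the synthetic-data generator does and does not
emulate.

## Biological setting and assumptions

Fall armyworm comprises two host strains (C and R) that are morphologically
identical but genetically distinct. Two marker systems are typed here:

* **COIB** — the 3' half of mitochondrial *COI*. Mitochondria are
  maternally inherited and effectively haploid, so a COIB Sanger read is a
  single allele; ambiguity at a defining site signals a technical problem,
  not heterozygosity.
* ***Tpi*** — Z-linked. Males (the sex caught in pheromone traps) carry
  two Z chromosomes. Directly sequencing the diploid PCR product
  superimposes both alleles: a substitution difference appears as the IUPAC
  letter for the union of the two bases, and an indel difference throws the
  two traces out of register so that everything downstream is unreadable.

All classification rules assume amplicon-scale Sanger consensus reads over
the 15-letter IUPAC alphabet, not chromatograms; base-calling and quality
filtering happen upstream.

## Classification rules

**COIB categories** are a fixed lookup on the unambiguous base pair at
mCOI1164D/mCOI1287R: (T,A)→R_COIB, (A,A)→CSh1, (A,G)→CSh2, (G,A)→CSh3,
(G,G)→CSh4. Pairs outside the table are reported as `unknown_combo` rather
than rejected, since the defining sites' allowed states encode what has
been observed, not what is possible. An uncovered defining site yields
`no_call`; any ambiguity or read gap yields `ambiguous`. CSh3 is retained
as a first-class category despite its rarity.

**CSh lettered variants** are exact-match dereplication over a comparison
span that defaults to the full inter-primer COIB interval (configurable),
because variant-defining polymorphisms occur across the whole segment.
Novel sequences mint the next unused letter within their category in
discovery order; letters already present in a loaded canonical registry
are skipped, so canonical labels survive re-analysis. Minting is therefore
order-dependent by construction for novel data — the canonical-registry
workflow (ship `registry.fasta` + `registry.tsv`, pass `--registry`) is
the supported way to stabilise names across datasets.

**Tpi strain** is decided solely by the state set at gTpi183Y:
{C}→C_Tpi, {T}→R_Tpi, {C,T}→H_Tpi, anything else `undetermined`.
gTpi165Y/gTpi168Y produce consistency flags (expected C/C for C_Tpi, T/T
for R_Tpi, the overlap for H_Tpi) that are reported but never override the
183 call, since 183 corresponds most consistently with host plant.

**TpiI4a200 extraction.** The analysis window covers the first
`round(0.6 × L_intron)` reference columns of the intron, inclusive
(`round` = nearest integer, half away from zero; the fraction is a
configurable parameter, default 0.6). The segment consists of the read
bases aligned to those columns *plus* read insertions strictly inside the
window; insertions at the right window edge are excluded (half-open
behaviour at the boundary), so haplotypes have variable length when indels
are present. A specimen is usable only if its read spans the whole window
and the segment is pure A/C/G/T; otherwise it is excluded with reason
`incomplete-coverage` or `ambiguous-base`. H_Tpi specimens are never
intron-haplotyped (`strain-mismatch-policy`): their two alleles come from
different strains, so even coincidentally identical window segments would
mix within-strain and between-strain variation in one haplotype pool.
Usable segments are exact-match dereplicated into `iCnn` labels, next free
two-digit index first.

## Alignment

Reads are globally aligned to an annotated reference amplicon
(Needleman–Wunsch with affine gaps, via Biopython's `PairwiseAligner`)
with match +1, mismatch −1, gap open −2, gap extend −0.5 — permissive
settings suited to high-identity Sanger amplicons. A gap run of length L
costs `open + (L−1)·extend`. Two IUPAC letters score as a match whenever
their state sets intersect, so a heterozygous overlap never penalises the
alignment against either allele; N behaves as {A,C,G,T} in alignment but
always yields an ambiguous site call. Both orientations are tried and the
higher-scoring one kept (ties → forward). Among co-optimal alignments the
aligner's deterministic first traceback is returned; optimality is checked
against exhaustive enumeration in the tests, and none of the downstream
rules depend on which co-optimal path is chosen (segment content is
invariant to gap placement within the window thanks to the edit margins
used by the simulator, and marker sites are never adjacent to indels in
clean data).

Coordinates are 1-based and closed throughout. Reference amplicons carry
an explicit `coordinate_offset` so marker positions live in the gene-level
numbering used by their names; the COIB and *Tpi* site numbering systems
are independent annotations, never derived arithmetically from primer
names. The bundled references are synthetic backbones (fixed internal
seed) carrying the field-standard annotations; the COIB frame places
mCOI1164D/mCOI1287R at positions 1164/1287 with offset 891, and the *Tpi*
frame uses amplicon-local numbering with exon 4 at 1–280 (sites
165/168/183), a 333-bp intron at 281–613 (hence a 200-column window) and
an 80-bp exon-5 stub. The 333-bp intron length is a stand-in chosen so
that 60% rounds to 200 columns; references built from annotated GenBank
sequences can be loaded from FASTA + sidecar TSV for real data.

## Profiles, G-test, trees

Frequency profiles count typed specimens per category, grouped by any
metadata keys (population, year, habitat); ambiguous/no-call specimens are
tallied separately and never enter frequencies, which sum to 1 exactly for
non-empty profiles.

Profile differentiation is tested with the log-likelihood-ratio G statistic
over the 2×k table (O=0 terms contribute 0; categories absent from both
populations are dropped). Because published FAW profile contrasts are
descriptive, the formal test is this package's own addition; the null
distribution is obtained by permuting specimens between the two
populations with fixed margins (equivalently, multivariate hypergeometric
resampling), default 10,000 replicates, with the add-one estimator
(1 + #{G* ≥ G}) / (1 + R). This is exact under small counts and needs no
asymptotic assumptions; the asymptotic χ² p-value is reported alongside,
and Holm adjustment is applied across pairwise comparisons. Calibration is
verified in the acceptance checks (type-I error at α = 0.05 within the 99%
binomial CI over 200 null comparisons).

p-distances use pairwise deletion: columns where either sequence carries a
gap or ambiguity are dropped, and a pair with no comparable columns is an
error. The joint alignment of a haplotype set is reference-anchored (each
haplotype aligned to the reference window, insertion columns merged,
left-justified) — adequate for high-identity haplotypes that all derive
from one reference segment, not a general MSA. Neighbor-Joining is
implemented from scratch (Q-criterion with the Studier–Keppler update)
because the haplotype tree is part of the analysis being provided, with
ties broken toward the lexicographically smallest index pair for
determinism; negative branch lengths are reported as computed with an
optional clamp, and Newick output uses 6-decimal lengths. The
implementation is cross-checked against scikit-bio's NJ and against a
random-additive-tree oracle (distance recovery to 1e-9). The distance
model is p-distance by default and pluggable by supplying any
`DistanceMatrix`.

## Synthetic-data generator

The generator plants known truth at every level so each pipeline stage can
be tested quantitatively.

* **Pools.** For each COIB category, `n` distinct full-amplicon variants:
  variant 0 is the plain defining-site edit of the reference, later
  variants add `1 + Binomial(L, 0.01)` substitutions. Intron pools add
  1–3 bp indels (per-base rate 0.01) confined to the window interior.
  Edits keep an 8-column margin from window/amplicon boundaries and the
  splice donor so planted indels can never slide across a boundary during
  alignment. Canonical registries (`CSh1[a]…`, `iC01…`) are minted in pool
  order.
* **Specimens.** Maternal strain ~ `strain_profile`; an R-strain mother
  transmits R_COIB, a C-strain mother a category from
  `coib_category_profile` and a lettered variant from its category
  profile. The two Z alleles are: with probability `hybrid_rate` an
  inter-strain pair (independent intron haplotypes, automatically
  heterozygous); otherwise, with probability `heterozygosity`
  (*conditional on not being a hybrid*), a same-strain pair differing by
  exactly one edit inside the window — an indel with probability
  `indel_het_fraction`, else a substitution; otherwise two identical
  alleles. The merged read takes the IUPAC union at substitution
  differences and N at every position from the first indel difference
  onward. Optional per-base noise (default 0) substitutes random bases
  last.
* **Reproducibility.** Each specimen draws from its own RNG stream seeded
  by `(seed, population index, specimen index)`; pools use `(seed, 0)`.
  Adding populations or specimens never perturbs earlier draws, and
  repeated runs are byte-identical.

Under these rules the expected outcomes in the truth table are exact
functions of the planted alleles: H_Tpi rate = `hybrid_rate`; intron
usability = homozygosity (hybrids with coincidentally equal haplotypes are
policy-excluded); zero-noise classification is error-free.

**What the generator does not emulate:** chromatogram signal, base-quality
variation, primer-region artefacts, PCR chimeras/recombination,
within-category phylogenetic structure (pool variants are star-like around
the reference), linkage between intron haplotype and exon beyond strain,
or population-genetic dynamics (drift, migration). Passing tests therefore
demonstrate the correctness of the classification logic and the
calibration of the statistics under the stated read model — not robustness
to base-calling error or to real FAW haplotype diversity, where canonical
registries and per-site review remain essential.

## Default study conditions

The study-scale checks use three populations × 500 specimens,
heterozygosity 0.5 and hybrid rate 0.1 (roughly half of directly sequenced
males unusable for the intron, matching the motivation for the windowed
analysis), category profiles of CSh2- and CSh4-majority type with an 80/20
C/R strain split, five intron haplotypes with a dominant first haplotype,
and zero sequencing noise (no quantitative Sanger error model is
available, so noise is a free parameter defaulting to 0). Frequency
recovery is checked against 3·√(p(1−p)/n) per category over five seeds;
rate recoveries use 99% binomial intervals at n = 1000.

## Known limitations

* Novel-variant letter minting depends on input order; stability requires
  the canonical-registry workflow.
* The reference-anchored joint alignment can misplace insertions shared by
  several haplotypes relative to a true MSA; with the short, high-identity
  TpiI4a200 segments this affects at most a few columns under pairwise
  deletion.
* The G-test permutation assumes specimens are exchangeable between the
  two collections under the null (no within-collection clustering, e.g.
  sibling larvae from one egg mass).
* `unknown_combo` COIB pairs and `undetermined` strains are excluded from
  profiles rather than modelled.
* No AB1/chromatogram parsing; inputs are consensus FASTA only.
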