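# Methods

This note documents the models and procedures implemented in `xeno`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinate and sequence conventions

All intervals are 0-based, half-open; strand is `+`/`-`. DNA is upper-cased
on ingestion; IUPAC ambiguity codes other than `N` are mapped to `N` with a
warning. A `dna_cds` record must be a whole number of codons with no
internal stop under the standard nuclear code (a terminal stop is allowed
and is treated as the termination signal in codon-usage profiling).
Calibrated trees carry absolute node ages in MYA; tips sit at age 0 and
every parent is strictly older than its children. Newick input may carry
ages as `[&age=X]` comments; plain ultrametric Newick derives ages from
branch lengths.

## Synthetic sequence evolution

The generator's purpose is to produce data for which every downstream claim
has a known truth value.

**Substitution process.** Each codon evolves as a continuous-time Markov
chain over its single-nucleotide neighbours. A synonymous change fires at
rate `syn_rate_per_my / 3`, a nonsynonymous change at ω times that. Because
a codon has nine single-nucleotide neighbours and S (the Nei–Gojobori
synonymous site count) equals one third of the synonymous neighbour count,
this parameterisation makes the expected number of synonymous substitutions
per synonymous site per MY exactly `syn_rate_per_my`, and the nonsynonymous
rate per nonsynonymous site ω × that. The estimator used downstream is the
same counting scheme, so simulator and estimator agree by construction and
rate-recovery tests compare like with like. Changes that would create an
internal stop codon are assigned rate zero (rejected); a terminal stop
drifts only within {TAA, TAG, TGA}. There are no indels and no sequencing
errors beyond what the substitution process produces.

**Divergence-time convention.** Two extant taxa whose split is T MY old are
separated by 2T MY of evolution, so the expected pairwise Ks is
`2 × T × syn_rate`. The group summaries divide the average distance by T
once (not 2T) because that is the arithmetic the source data tables use;
the simulator documents the factor of two so tests apply it explicitly.

**Defaults.** `syn_rate_per_my = 0.015` is a free calibration chosen so
that group-average Ks values over the tested divergence ages land in the
published 0.14–1.06 range; it is not a measured value. ω defaults are 0.30
(host) and 0.35 (donor) — purifying selection of the strength implied by
the published Ka/Ks ratios (0.36–0.38). Genes are 300 codons. Template tree
calibrations: Brachypodieae split carried at 39 MYA (the upper value of the
published 32–39 interval, configurable), Triticeae–Poeae 21 MYA,
*Claviceps*–*Epichloë* 58.8 MYA, *Epichloë* crown 7.2 MYA; other node ages
(grass root 160, rice 50, panicoid split 45, Triticeae crown 9, Poeae crown
15, Loliinae crown 4, *Epichloë* subclade 4) are round figures consistent
with those calibrations, chosen for the topology, not as claims. Default
planted events: a gain on the Triticeae+Poeae stem at 30 MYA sourced from
the *Epichloë* stem (sister-to-crown placement) and a gain on the Loliinae
stem at 5 MYA sourced from within the *Epichloë* crown (nested placement) —
the two scenarios of interest.

**Read libraries.** Reads are drawn uniformly along source genes at
140–150 nt on random strands, with per-library expression weights (the
default pair of libraries gives one transfer a leaf-tip-specific pattern
and the other a ubiquitous one). The default library holds 4000 reads with
a duplicate fraction of 0.83, carrying over the ~17% unique-read share of
the motivating 8.2-million-read library at a size the test suite can screen
in seconds; the library size is a scale choice of this package, and all
counting logic is size-independent. Contaminants: "microbiome" reads are
verbatim donor reads drawn from donor-specific genes (genes with no host
counterpart, mirroring fungus-specific marker genes); "conserved" reads
come from slow-evolving genes (rate 0.001/MY, ω 0.05) present in all host
and donor taxa, emulating actin/ubiquitin-like confounders. Adapters are
not simulated; reads are emitted clean. Every sequence and read carries
exactly one truth label (vertical / hgt / microbiome / conserved).

**What passing tests do and do not show.** The generator has no indels, no
paralogy, no assembly artefacts, no quality noise and uniform base
composition, so perfect triage accuracy on the bundle demonstrates the
rules are implemented coherently — not that they would reproduce an
expert's manual curation on real libraries.

## Similarity screen

Reads are first collapsed to unique sequences with multiplicities (exact
string identity, stable by first occurrence). The search indexes subject
words of `word_size` (default 28, megablast-like) and extends each seed on
both strands: banded gapped dynamic programming (band 16 around the seed
diagonal) anchored at the seed, with linear gap cost (default 4 per gap
column; match +1, mismatch −2) and an X-drop of 20 score units. Raw scores
become bit scores (λS − ln K)/ln 2 and E-values K·m·n·e^{−λS} with m the
query length and n the total subject length. λ is solved to 10⁻⁹ by
bracketed root finding on Σ pᵢpⱼ e^{λs} = 1; K is a configured constant
(default 0.3) rather than estimated — at a 10⁻¹⁰ threshold the decision is
insensitive to K to within an order of magnitude, and full Karlin–Altschul
K estimation is out of proportion to that effect. Ties and duplicate seeds
resolving to the same alignment keep the best score; within-alignment seeds
are skipped.

Triage applies rules in a fixed order; all thresholds are explicit
operationalisations of what is, in the motivating workflow, expert
judgement (hence the exact published triage split is not a target):

1. `low_similarity`: identity < 60% or aligned length < 50 nt;
2. `conserved_eukaryote`: the query also hits an outgroup-plant panel at
   the E-threshold;
3. `microbiome`: identity ≥ 98% to the donor and no supporting match in
   the host genome assembly;
4. `hgt_candidate` otherwise.

A second parameter set (`cross_species`: word 12, +2/−3, gap 5) serves the
presence/absence search across host taxa, where orthologues diverged over
tens of MY fall well below what a word-28 +1/−2 scheme can seed — the same
division of labour as using megablast for near-identical screening but
BLASTN-style settings for cross-species ortholog checks.

## Transfer dating

The gain model is Dollo: a gene arises once and is never lost (default).
Given presence calls, the gain branch is the branch above the MRCA of the
carrying taxa; `lower = age(MRCA)`, `upper = age(parent(MRCA))`, and a
donor-side constraint caps `upper` when given. Absent taxa nested inside
the presence clade are an error under the strict policy; the
`dollo_losses` policy instead reports them as implied losses (the window is
unchanged: placing the gain higher only adds losses). PCR evidence
overrides in-silico evidence in the presence matrix because a positive
assay is direct evidence while database absence may reflect expression or
coverage; in-silico-only absences are flagged low-confidence.

The donor-side constraint comes from a clade-nesting test on a
neighbour-joining phylogram of protein p-distances: transferred sequences
nesting inside the donor crown bound the event by the crown age (7.2 MYA by
default); sequences attaching on the crown's stem bound it only by the stem
age (58.8 MYA).

In-silico PCR is exact-match by design (primers are assumed to sit in
fully conserved regions, as cross-species assays are designed); both
strands are scanned, and products longer than `max_amplicon_len` (default
250 bp) are discarded. The primer-design helper exploits the generator's
indel-free homology (columns are positionally aligned) and picks fully
conserved windows; it returns nothing when no such windows exist.

## Ka/Ks, codon usage, phylograms

Site counts: each of a codon's nine single-nucleotide changes is classified
under the standard code; changes to stop codons count as nonsynonymous;
S + N = 3 exactly. Differences: minimal mutational pathways between two
codons (1, 2 or 6 orderings) are averaged with equal weights; pathways
through stop codons are excluded, with a warned fall-back to all pathways
if none survive. Codons containing gaps or N in either sequence, and stop
codons, are skipped. ps = Sd/S and pn = Nd/N are Jukes–Cantor corrected;
p ≥ 0.75 raises a saturation flag and the pair is excluded from group
averages (a fully saturated group is reported as skipped). Group summaries
report means, population standard deviations, rates (mean / T, the source
tables' convention) and the ratio as Ka_avg/Ks_avg; a mean-of-per-pair-
ratios mode is available because the source tables' last digits are
ambiguous between the two conventions.

Codon usage pools codon counts over a CDS set and normalises within each
multi-codon amino acid (Met and Trp excluded) and within the termination
signal; a CDS lacking a terminal stop contributes no termination count and
warns.

Neighbour joining is canonical (Q criterion, standard branch lengths) with
deterministic tie-breaking by lexicographic pair order; negative branch
lengths are clamped to zero with the deficit transferred to the sibling.
p-distances ignore columns with a gap in either sequence. Hexaploid
sub-genomes, where present in inputs, are treated as separate taxa.

## Expression

A read counts for a gene when they share an exact common substring of at
least `min_perfect` nt (default 60) on either strand — implemented by
hashing the gene's 60-mers, which is equivalent to the substring criterion.
Duplicate reads count individually; reads matching two genes count for
both (per-gene queries are independent). CPM = count / library size × 10⁶;
zero counts stand for "below detection". No alignment-based quantification
and no differential-expression statistics are attempted.

## Pipeline and reproducibility

Stage order: screen → triage → presence/absence → dating → Ka/Ks → codon
usage → expression. Each stage logs its counts as structured entries in the
report; the report is JSON with sorted keys and contains no timestamps, so
identical configurations and seeds produce byte-identical files. All
randomness flows from the single configured seed; per-gene streams are
derived by hashing gene ids so adding a gene does not perturb the others.
When multiple transcript isoforms hit the same donor gene, candidates are
collapsed per subject gene (best identity, union coverage, hit count) —
the mapping of transcripts to loci is otherwise ambiguous.

Problem sizes used by the test suite and acceptance script (whole-suite
runtime well under a minute apart from the end-to-end demo): 300-codon
genes, 4000-read libraries, 900–1000-codon sequences for rate-recovery
checks, 20-replicate recovery experiments, and 100-replicate window
coverage under 5% false-absence noise.

## Known limitations

* No indel model, so real alignment uncertainty is absent; codon
  alignments are inputs, never inferred.
* The local search is not a reimplementation of NCBI megablast internals;
  scores and E-values follow the stated scheme only.
* K in the E-value is a constant, adequate at stringent thresholds but not
  for marginal-significance work.
* Dollo dating assumes a single gain; gene-tree/species-tree
  reconciliation and molecular-clock estimation of node ages are out of
  scope (ages are inputs).
* Conserved-gene confounders share a root sequence across host and donor
  trees rather than evolving down a joint eukaryote phylogeny; their
  host–donor divergence is therefore a device, not an estimate.
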