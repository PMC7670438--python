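# xeno

Detection, dating and molecular-evolution profiling of fungus-to-grass
horizontal gene transfers (HGT).

Cool-season grasses (Poeae and Triticeae tribes) carry a small number of
nuclear genes acquired from their *Epichloë* endophyte lineage — fungal
symbionts whose sister genus is the ergot fungus *Claviceps*. Finding such
genes means screening a host transcriptome against a donor (fungal)
transcriptome for anomalously similar sequences, weeding out conserved
housekeeping genes and microbiome contamination, bounding the age of each
transfer on calibrated phylogenies, and showing that the transferred genes
still behave like genes (purifying selection, host-like codon usage,
expression in host tissue). `xeno` implements that whole workflow as a
reusable, tested library with a CLI, plus a synthetic sequence-evolution
generator that plants HGT events at known times so every stage can be
validated against ground truth.

## Methods at the core

* **Similarity screen** — exact de-duplication of short reads, then a
  megablast-style seeded local search (word hits extended ungapped and by
  banded gapped DP with an X-drop). Significance uses Karlin–Altschul
  statistics: λ is the positive root of Σ pᵢpⱼ e^{λs(i,j)} = 1 and
  E = K·m·n·e^{−λS}, thresholded at E ≤ 10⁻¹⁰. Hits are triaged into
  low-similarity / conserved-eukaryote / microbiome / HGT-candidate
  categories by explicit, configurable rules.
* **Transfer dating** — a Dollo (single-gain) model on a calibrated species
  tree: for a gene present in a set of taxa, the gain lies on the branch
  above their MRCA, so age(MRCA) ≤ t ≤ age(parent), optionally capped by a
  donor-side constraint (crown vs stem placement of the transferred
  sequences in the donor phylogeny, decided by a neighbour-joining phylogram
  and a clade-nesting test). In-silico PCR provides exact-match
  presence/absence evidence that overrides database absence.
* **Ka/Ks** — Nei–Gojobori (1986) counting: fractional synonymous (S) and
  nonsynonymous (N) site counts per codon, equal-weight averaging over
  minimal mutational pathways for differences, Jukes–Cantor correction
  d = −(3/4)·ln(1 − (4/3)p), group means normalised by divergence age T.
* **Codon usage** — per-amino-acid synonymous codon ratios for the 18
  redundant amino acids plus the termination signal {TAA, TAG, TGA}.
* **Expression** — a read supports a gene if they share a perfect common
  substring of ≥ 60 nt on either strand; counts are normalised to CPM.

## Worked example

The demo needs no input files — the generator supplies a dated host grass
tree (Brachypodieae split 39 MYA, Triticeae–Poeae split 21 MYA), a dated
fungal tree (*Claviceps*–*Epichloë* 58.8 MYA, *Epichloë* crown 7.2 MYA),
and two planted transfers: one into the Triticeae+Poeae ancestor at 30 MYA
and one into the Loliinae ancestor at 5 MYA.

```sh
xeno run -o demo_out
```

prints the triage counts and writes `demo_out/report.json`:

```
{"conserved_eukaryote": 136, "hgt_candidate": 283, "low_similarity": 0, "microbiome": 68}
```

With seed 1 the screen collapses 8000 reads to 1349 unique sequences and
finds 487 hits against the donor transcriptome; all 68 microbiome-labelled
contaminant reads and all 283 transferred-gene hits are triaged correctly,
and `duf3632_like` is reported as an HGT candidate. Its dating entry is

```json
"duf3632_like": {"lower_mya": 4.0, "upper_mya": 7.2,
                 "donor_placement": "nested_in_crown",
                 "donor_constraint_mya": 7.2}
```

i.e. the gene is carried by both Loliinae tips (MRCA age 4), and because
its sequences nest inside the *Epichloë* crown the transfer must postdate
7.2 MYA — the true planted time (5 MYA) sits inside the window. The 30-MYA
transfer is present in wheat, barley and the Poeae tips but, like its real
counterpart, has diverged too far from the donor copy to be recovered by a
megablast-style screen; the cross-species presence search and the dating
machinery still handle it (see `tests/test_dating.py`).

The expression stage shows the candidate's per-library CPM, e.g. 156500 CPM
in the leaf-tip library versus 296000 CPM in leaf blade for the ubiquitous
`duf3632_like` (raw counts 626 and 1184 of 4000 reads each).

Other entry points: `xeno simulate` (write a labelled synthetic bundle),
`xeno screen`, `xeno kaks`, `xeno usage`, `xeno expr`, `xeno pcr`,
`xeno date` — see `xeno --help`.

## Layout

```
src/xeno/
  records.py     sequence/read containers, genetic-code helpers
  io.py          FASTA/FASTQ/Newick/TSV/JSON
  tree.py        calibrated (dated) species trees
  simulate.py    codon evolution along trees, HGT planting, read libraries
  screen.py      read collapsing, seeded local search, hit triage
  dating.py      presence/absence, Dollo gain windows, in-silico PCR
  molevol.py     Nei–Gojobori Ka/Ks, JC, codon usage, NJ, clade nesting
  expression.py  exact-substring read counts, CPM
  pipeline.py    end-to-end orchestration and reporting
  cli.py         `xeno` subcommands
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
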