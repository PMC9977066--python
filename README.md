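# htr3evo

Curation, conservation profiling and distance-based phylogenetics for
5-HT3 receptor subunit protein families.

The 5-HT3 receptor is a serotonin-gated pentameric ion channel of the
Cys-loop family. Humans carry five subunit genes (A–E); only the A subunit
forms functional homopentamers, and the orthosteric ligand-binding site sits
at the interface of two adjacent A subunits, built from six extracellular
loops (A–F). Each subunit shares a stereotyped architecture in reference
(human 5HT3A-style) numbering: a signal peptide (M1–P21), the ligand-binding
loops within T87–K239, the signature Cys-loop (C163–C177, 15 residues), four
transmembrane helices TM1 (V252–L272), TM2 (R279–D299), TM3 (C318–K338) and
TM4 (K457–W478), and a large intracellular loop (L341–L455) carrying four
conductance-modulating arginines (R432, R438, R442, R446).

`htr3evo` is for molecular evolution and receptor-pharmacology researchers
who want to survey subunit homologs across animal phyla: it curates candidate
sequences from homology-search output, expresses every observation in
reference residue numbering, measures per-column conservation in bits,
classifies substitutions at functionally critical residues by
physico-chemical class, and builds bootstrapped neighbor-joining trees.

## Methods at a glance

* **Curation** applies the selection protocol stage by stage: exclude hits
  with E-value > 0.004, similarity < 40 % or length < 100 aa (boundary values
  are kept); keep the best-annotated record per species and at most four per
  genus; require every B–E record's species to retain an A record; require
  all four TM helices and the Cys-loop to be present and ≥ 20 % identical to
  the reference; and flag B–E records that align clearly better to the A
  reference as mis-annotated A subunits. Every exclusion is ledgered with a
  stage and a reason.
* **Conservation** of an alignment column is sequence-logo information
  content, `I = log2(20) − H` with `H = −Σ pₐ log2 pₐ` over non-gap
  residues: 4.32 bits when fully conserved, exactly 2 bits for five
  equiprobable residues, 0 for a uniform column.
* **Substitution classes** follow the five-way chemistry partition
  polar {G,S,T,Y,C}, neutral {Q,N}, basic {K,R,H}, acidic {D,E},
  hydrophobic {A,V,L,I,P,W,F,M}: a replacement within a class is
  *conservative*, across classes *non-conservative*.
* **Trees** come from neighbor joining on p-distances or Poisson-corrected
  distances (`d = −ln(1 − p)`) after a 95 % site-coverage mask, with
  bootstrap support from column resampling.
* **Synthetic families**: a seeded generator evolves the packaged
  pseudo-reference along a taxonomy-structured tree with a realistic
  conservation gradient (TM/Cys-loop slow, intracellular loop fast) and
  plants curation violations with a truth table, so every stage is testable
  without downloads.

The packaged reference is a *synthetic pseudo-reference*: its domain
coordinates and critical-residue catalogue use human 5HT3A numbering, but the
inter-domain sequence is generated. Any real reference can be supplied as a
directory of three plain-text files (FASTA + two TSV tables).

## Worked example

Generate a family of 4 phyla × 3 genera × 3 species (A and B subunits) with
five planted rule violations, then curate, analyse and build a tree:

```sh
cat > genconf.yaml <<EOF
planted_violations:
  short_seq: 2
  high_evalue_hit: 2
  excess_genus_members: 1
EOF
htr3evo generate --seed 17 --config genconf.yaml --out demo
htr3evo curate --fasta demo/sequences.fasta --meta demo/metadata.tsv \
               --hits demo/hits.tsv --out demo/curated
```

```
filter_hits: 74 -> 70
select_best_per_species: 70 -> 70
cap_genus: 70 -> 69
require_subunit_A: 69 -> 69
check_domains: 69 -> 69
flag_misannotation: 69 -> 69
curated 69 of 74 records
```

The four hit-level exclusions are the two planted short sequences and the two
planted high-E-value hits; the genus-cap stage removes exactly the one
planted overflow record. `demo/curated/exclusions.tsv` lists each accession
with its stage and reason.

```sh
htr3evo analyze --msa demo/msa.fasta --meta demo/metadata.tsv --out demo/analysis
htr3evo tree --msa demo/msa.fasta --bootstrap 100 --seed 17 --out demo/tree.nwk
```

```
analysed 37 rows x 491 columns
37 leaves, 469 columns -> demo/tree.nwk
```

`demo/analysis/phylum_summary.tsv` reports, per critical residue and phylum,
the observed substituents and class tallies — e.g. for the glycosylation
asparagine N34:

```
ref_pos expected_aa phylum     substituents identical conservative non_conservative absent
34      N           Phylum01                9         0            0                0
34      N           Phylum02   Q            1         8            0                0
```

so N34 is untouched in Phylum01 while Phylum02 mostly carries the
conservative (neutral-class) substitution N→Q. The Newick tree carries
bootstrap percentages as internal labels:

```
((SYNA_01_03_03:0.016932,(SYNA_01_03_01:0.011071,SYNA_01_03_02:0.006134)100:0.022513)100:0.028347,...
```

`htr3evo run --config pipeline.yaml` chains all stages (optionally starting
from the generator) and writes a JSON summary with the stage-by-stage audit
trail.

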