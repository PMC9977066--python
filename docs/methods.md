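# Methods

## Reference annotation

All coordinates are 1-based and inclusive, with M1 the first residue — the
convention every published residue label (W91, C163, …) uses. The annotation
bundles the sequence, a region table and a critical-residue catalogue as
plain-text files so other references (e.g. a mouse ortholog) can be dropped
in. Loading validates every invariant: regions inside the sequence, exactly
four non-overlapping TM regions, a Cys-loop, and the catalogued residue
present at each catalogued position.

Design choices where the layout was genuinely open:

* The packaged reference is **synthetic**: domain geometry and catalogue
  follow human 5HT3A numbering, while inter-domain residues are drawn from a
  seeded generator (hydrophobically biased inside TM helices). Nothing
  downstream depends on the filler residues; tests that need real biology pin
  the catalogued positions, which are authentic.
* Per-loop spans for the binding loops A–F are not fixed by a single public
  coordinate table; the packaged spans are synthetic choices consistent with
  the residues each loop must contain (loop D 87–97, A 117–133, E 140–155,
  B 175–192, F 193–207, C 225–239) inside the documented T87–K239 envelope.
* The RIC-3 chaperone-binding segment is stored as a named region anchored at
  the ICL start with length 24. It is reported, never used as a filter,
  because only its approximate location is established.
* Glycosylation sites are catalogued as single asparagine positions (N34,
  N83, N176, N192), not sequon motifs, since positions are what the source
  annotations give.
* Loop C's key tyrosine is catalogued at 235; the occasionally-cited alias
  Y234 is recorded as a note on that row and never asserted.

## Pairwise alignment and coordinate mapping

Affine-gap global alignment over BLOSUM62 via Biopython's `PairwiseAligner`;
a gap of length L costs `gap_open + gap_extend·L` with defaults 10 and 1 (the
common protein defaults). Ties between equal-scoring paths resolve to the
aligner's canonical first traceback, which is deterministic. The letter X is
unknown: it scores 0 against everything and never counts toward identity.
Optimality is tested against exhaustive enumeration of all alignments for
sequences up to length 8.

`domain_identity` semi-globally aligns a reference region segment against the
full candidate (candidate overhangs free) and reports identity and coverage
with the **reference region length** as denominator — the inclusion rule is
anchored on the reference domain, not on whatever the alignment happens to
span. The "≥ 20 % homologous" rule is implemented as percent *identity*:
identity is reproducible without committing to a similarity ("positives")
convention; hit-table similarity remains available for the hit-level filter.

For domain **presence** the segment-based alignment is the wrong tool: a
15-residue segment aligned semi-globally inside a 450-residue candidate
always finds *some* contiguous placement, so its coverage cannot distinguish
a deleted domain from a present one. The domain check therefore uses an
anchored variant: the full reference is globally aligned to the candidate and
identity/coverage are read off the region's own columns. A domain deleted
from the candidate then shows as gap columns (coverage ≈ 0). A domain counts
as present when ≥ 50 % of its reference positions align to candidate
residues; 50 % is a package choice (configurable) that keeps the literal
"entire domain missing" case excluded while tolerating ragged partial
alignments.

Column maps are built from the reference row of an MSA: reference residue i
maps to the column holding its i-th non-gap character (both sides 1-based).

## Curation

Thresholds follow the printed exclusion rules with **strict comparators**
(exclude iff E-value > 0.004, similarity < 40 %, length < 100 aa, genus
members beyond 4): boundary values are kept. Each hit-level exclusion carries
the first failed rule in the order E-value, similarity, length. Survivor
ranking everywhere is annotation quality (named > receptor-like >
unnamed/hypothetical), then E-value, then accession — the accession tie-break
makes every selection deterministic.

The mis-annotation test flags a B–E record when its global identity to the A
reference exceeds identity to its own subunit's reference by more than 5
percentage points. The margin is a package choice (configurable): it keeps a
sequence equidistant to both references unflagged rather than guessing.

Because the genus cap and the domain checks can remove a species' A record
after its B–E records were admitted, the A-requirement is re-applied after
the final stage until a fixpoint (each pass removes at least one record, so
it terminates in at most |records| passes). The report ledger is validated at
every stage: records in = records out + exclusions, and no accession is both
included and excluded.

## Conservation and substitution classes

Information content of a column is `log2 20 − H` with frequencies over
non-gap characters; gaps are excluded and reported separately as a gap
fraction, mirroring how logo tools reduce stack height. An all-gap column
reports 0 bits with gap fraction 1. No small-sample correction is applied by
default so the analytic anchors hold exactly (single residue → log2 20 ≈
4.32 bits; five equiprobable residues → 2.0 bits; uniform over 20 → 0); a
flag enables the standard `(20−1)/(2·ln2·n)` correction for visual parity
with published logos, which shifts those anchors.

Substitutions at catalogued residues are classified strictly by the five-way
chemistry partition (identical / conservative / non-conservative / absent on
gap; X is non-conservative). Because aromatic swaps such as F↔Y cross the
partition yet are often tolerated at binding sites, a softer
`hydropathy_conservative` tag is additionally set when both residues lie in
the hydrophobic class extended by tyrosine; default reporting uses the strict
classes.

## Phylogenetics

The tree pipeline is **pure distance NJ**: columns below the 95 % coverage
cutoff are dropped, remaining gaps handled by pairwise deletion, distances
are p-distances or Poisson-corrected (`−ln(1−p)`), and neighbor joining uses
the Q criterion with ties broken to the lexicographically smallest index pair
(determinism) and negative limb lengths clamped to zero with a warning.
Maximum-likelihood refinement under an empirical substitution model is
deliberately out of scope; NJ is the standard initializer for such searches
and is provably consistent on additive matrices, which the tests exercise
directly (exact topology recovery on random additive matrices, four-point
quartet oracle). Poisson distances cannot be computed for a saturated pair
(p = 1), which is reported as an error naming the pair, as is any pair
sharing no aligned sites.

Bootstrap support of an internal bipartition is the percentage of
column-resampled replicates whose NJ tree contains it; supports are invariant
under row permutation and reproducible under a fixed seed. Replicates that
lose all shared sites for some pair are skipped (counted as non-supporting).

## Synthetic data generator

The generator emulates the study's input: domain-structured protein families
with taxonomy labels, a known tree and planted rule violations.

* **Tree**: species join randomly within genus, genera within phylum, phyla
  at the root, with exponential branch lengths (means 0.08 / 0.15 / 0.4
  expected substitutions per site per unit rate) plus a minimum branch length
  of 0.05. The floor keeps every internal edge identifiable — an
  effectively-zero edge makes topology recovery ill-posed for any method —
  and is the generator's definition of a resolvable family.
* **Rates**: per-region substitution rates default to 0.15 (extracellular),
  0.04 (TM and Cys-loop) and 0.30 (intracellular loop), reproducing the
  observed conservation gradient. Substitutions preserve chemistry class with
  probability 0.7. Each tree edge mutates under its own deterministically
  derived generator, so raising a rate adds substituted sites without
  reshuffling existing ones — the monotonicity property the tests check.
* **Indels**: insertions (geometric length, capped at 39 residues — the
  longest loop insert reported in real homolog families) and short deletions
  occur outside TM regions and the Cys-loop only. Inserted residues do not
  further mutate along the tree; this second-order effect is irrelevant to
  every quantity the pipeline measures.
* **Violations**: each planted violation is booked exactly once with the
  exclusion reason curation must emit. Sequence-modifying violations go to
  non-A records when a second subunit is simulated (and mis-annotation
  plants get a private genus/species) so a planted exclusion never cascades
  into untracked secondary exclusions. Genus-cap overflow tops the first
  genus up to cap + k members with hypothetical, poorly-ranked extras so
  exactly the k worst fall to the cap under the curation ranking rule.
* **Limits**: evolution is protein-level with i.i.d. sites per region — no
  codon structure, no site-specific rate variation beyond the region
  gradient, no exchangeability matrix. Passing tests therefore demonstrate
  the pipeline's bookkeeping and statistical machinery, not that real
  families satisfy the generator's assumptions; on real data the curation
  thresholds and alignment parameters carry the burden they carry in any
  survey.

## Problem sizes

Default test and demonstration runs use families of 12–36 species (478
reference positions, ~490 alignment columns), 100-replicate bootstraps, and
25-seed replication for topology-recovery checks — sizes at which every
statistical property under test is already well-resolved while the whole
suite runs in seconds to minutes on one CPU.
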