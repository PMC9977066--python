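"""Pairwise protein alignment, reference-coordinate mapping and per-domain identity.

Results throughout the package are expressed in reference residue numbering
("W91", "C163", ...), so two primitives recur everywhere: aligning a candidate
against the reference (or one of its domain segments), and mapping reference
residue numbers to columns of a multiple sequence alignment.

Alignment is affine-gap Needleman-Wunsch over BLOSUM62 via Biopython's
``PairwiseAligner``.  A gap of length L costs ``gap_open + gap_extend * L``
(defaults 10 and 1).  The letter X is treated as unknown: it scores 0 against
everything and never counts as an identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

GAP = "-"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


def scoring_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix with the X (unknown) row/column zeroed."""
    m = substitution_matrices.load(name)
    if "X" in m.alphabet:
        xi = m.alphabet.index("X")
        for j in range(len(m.alphabet)):
            m[xi, j] = 0.0
            m[j, xi] = 0.0
    return m


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix if matrix is not None else scoring_matrix()
    # first gapped position costs open+extend, each further one extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pair of rows with the optimal affine-gap score."""

    ref_aligned: str
    cand_aligned: str
    score: float

    def __post_init__(self):
        if len(self.ref_aligned) != len(self.cand_aligned):
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.ref_aligned)

    def identity_count(self) -> int:
        """Columns where both rows carry the same non-gap, non-X residue."""
        return sum(
            1
            for a, b in zip(self.ref_aligned, self.cand_aligned)
            if a == b and a not in (GAP, "X")
        )

    def identity_pct(self) -> float:
        """Percent identity over alignment columns."""
        return 100.0 * self.identity_count() / self.n_columns


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two protein sequences.

    Ties between equally scoring paths are broken by the aligner's canonical
    first traceback, which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    ra, ca = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ra, ca, float(aln.score))


def semiglobal_align(
    segment: str,
    candidate: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Align ``segment`` within ``candidate`` with free end gaps on the candidate.

    Candidate overhangs on either side of the segment are not penalised;
    internal gaps are scored normally.  Returns rows (segment, candidate
    window) trimmed to nothing — the full candidate stays in the alignment so
    columns remain addressable.
    """
    if not segment or not candidate:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aligner.end_deletion_score = 0.0  # gaps in the segment row at the ends are free
    aln = aligner.align(candidate, segment)[0]
    cand_row, seg_row = str(aln[0]), str(aln[1])
    return PairwiseAlignment(seg_row, cand_row, float(aln.score))


def domain_identity(
    ann,
    region: str,
    candidate: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, float]:
    """Percent identity and coverage of a reference domain in a candidate.

    The reference region segment is semi-globally aligned against the full
    candidate (free end gaps on the candidate).  Both percentages use the
    reference region length as denominator: identity counts columns with the
    identical residue, coverage counts region positions aligned to a non-gap
    candidate residue.
    """
    if not candidate:
        raise ValueError("empty candidate sequence")
    segment = ann.region_segment(region)
    aln = semiglobal_align(segment, candidate, matrix, gap_open, gap_extend)
    n = len(segment)
    ident = 0
    cover = 0
    for s, c in zip(aln.ref_aligned, aln.cand_aligned):
        if s == GAP:
            continue
        if c != GAP:
            cover += 1
            if s == c and s != "X":
                ident += 1
    return 100.0 * ident / n, 100.0 * cover / n


# ---------------------------------------------------------------------------
# MSA view and reference-coordinate mapping
# ---------------------------------------------------------------------------


@dataclass
class MSAView:
    """A rectangular multiple sequence alignment: (accession, gapped row) pairs."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged MSA: row lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.rows]

    def row(self, accession: str) -> str:
        for acc, seq in self.rows:
            if acc == accession:
                return seq
        raise KeyError(f"accession {accession!r} not in MSA")

    def column(self, col: int) -> list[str]:
        """Characters of a 1-based column."""
        return [seq[col - 1] for _, seq in self.rows]

    def subset(self, accessions) -> "MSAView":
        wanted = set(accessions)
        return MSAView([(a, s) for a, s in self.rows if a in wanted])

    @classmethod
    def read(cls, path: str | Path, fmt: str = "fasta") -> "MSAView":
        """Read an aligned FASTA ('fasta') or Clustal ('clustal') file."""
        aln = AlignIO.read(str(path), fmt)
        return cls([(rec.id, str(rec.seq).upper()) for rec in aln])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for acc, seq in self.rows:
                fh.write(f">{acc}\n{seq}\n")


@dataclass
class ColumnMap:
    """Bijection between reference residue numbers and MSA columns (both 1-based)."""

    ref_to_col: dict[int, int]

    def __post_init__(self):
        cols = list(self.ref_to_col.values())
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("column map is not strictly increasing")
        self.col_to_ref = {c: r for r, c in self.ref_to_col.items()}

    def __len__(self) -> int:
        return len(self.ref_to_col)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_pos\tcolumn\n")
            for r, c in sorted(self.ref_to_col.items()):
                fh.write(f"{r}\t{c}\n")


def build_column_map(msa: MSAView, ref_accession: str) -> ColumnMap:
    """Map reference residue i to the column holding its i-th non-gap character."""
    row = msa.row(ref_accession)
    mapping = {}
    res = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            res += 1
            mapping[res] = col
    return ColumnMap(mapping)


def residue_at(msa: MSAView, cmap: ColumnMap, accession: str, ref_pos: int) -> str:
    """Character of a row at the column corresponding to a reference position."""
    try:
        col = cmap.ref_to_col[ref_pos]
    except KeyError:
        raise KeyError(f"reference position {ref_pos} outside column map") from None
    return msa.row(accession)[col - 1]
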