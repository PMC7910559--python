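"""Per-residue sequence-divergence mapping between two channel orthologs.

The procedure behind chimera design: align two protein sequences globally
(BLOSUM62, affine gaps: opening 8, extension 1, a length-L gap costing
open + extend*(L-1)), score every alignment column, convert the scores to a
deviation-from-average divergence value per residue of a chosen reference
sequence, smooth with a five-residue moving average, rescale to [0, 1], and
write the result into the B-factor column of a structural model so it can be
rendered as a color gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AlignedPair",
    "ColumnScores",
    "DivergenceScale",
    "global_align_affine",
    "column_scores",
    "divergence_scale",
    "percent_identity",
    "count_substitutions",
    "map_scale_to_structure",
    "read_fasta",
]

DEFAULT_OPEN = 8.0
DEFAULT_EXTEND = 1.0
GAP = "-"


def _matrix(name_or_matrix="BLOSUM62"):
    if isinstance(name_or_matrix, str):
        return substitution_matrices.load(name_or_matrix)
    return name_or_matrix


@dataclass
class AlignedPair:
    """A global pairwise alignment: gapped rows plus its total score."""

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        if self.aligned_a.replace(GAP, "") != self.seq_a:
            raise ValueError("aligned_a does not reduce to seq_a")
        if self.aligned_b.replace(GAP, "") != self.seq_b:
            raise ValueError("aligned_b does not reduce to seq_b")

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass
class ColumnScores:
    """Per-column similarity score and gap state of an alignment."""

    scores: np.ndarray  # matrix units, gap columns carry -open/-extend
    gap_state: list[str]  # "none" | "open" | "extend" per column

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.gap_state):
            raise ValueError("scores and gap_state must have equal length")


@dataclass
class DivergenceScale:
    """Divergence in [0, 1] per reference residue (1-based numbering)."""

    values: np.ndarray
    residue_numbers: np.ndarray  # 1-based positions in the reference sequence
    window: int
    raw_mean: float  # mean per-residue similarity before normalization
    raw_range: tuple[float, float]  # (min, max) of smoothed deviations


def _validate_sequence(seq: str, alphabet: str, name: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{name} contains invalid residue characters: {sorted(bad)}")


def global_align_affine(
    seq_a: str,
    seq_b: str,
    matrix="BLOSUM62",
    open: float = DEFAULT_OPEN,
    extend: float = DEFAULT_EXTEND,
    end_gaps_free: bool = False,
) -> AlignedPair:
    """Optimal global alignment with affine gap penalties.

    A gap of length L costs open + extend*(L-1).  Terminal gaps are scored
    like internal ones unless ``end_gaps_free``.  Ties between co-optimal
    alignments are broken deterministically (the aligner's first path, which
    prefers substitutions over gaps in b over gaps in a).
    """
    matrix = _matrix(matrix)
    alphabet = str(matrix.alphabet)
    _validate_sequence(seq_a, alphabet, "seq_a")
    _validate_sequence(seq_b, alphabet, "seq_b")
    if not seq_a or not seq_b:
        # degenerate: one sequence empty -> single all-gap run
        longer = seq_a or seq_b
        if not longer:
            raise ValueError("both sequences are empty")
        cost = 0.0 if end_gaps_free else -(open + extend * (len(longer) - 1))
        gaps = GAP * len(longer)
        return AlignedPair(
            seq_a=seq_a,
            seq_b=seq_b,
            aligned_a=seq_a or gaps,
            aligned_b=seq_b or gaps,
            score=cost,
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -open
    aligner.extend_gap_score = -extend
    if end_gaps_free:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    a_row, b_row = best[0], best[1]
    return AlignedPair(
        seq_a=seq_a,
        seq_b=seq_b,
        aligned_a=str(a_row),
        aligned_b=str(b_row),
        score=float(best.score),
    )


def column_scores(
    pair: AlignedPair,
    matrix="BLOSUM62",
    open: float = DEFAULT_OPEN,
    extend: float = DEFAULT_EXTEND,
) -> ColumnScores:
    """Score every alignment column: matrix value for residue pairs, -open
    for the first column of a gap run, -extend for its continuation."""
    matrix = _matrix(matrix)
    scores = np.empty(len(pair))
    state: list[str] = []
    prev_gap_row = 0  # 0 none, 1 gap in a, 2 gap in b
    for k, (ca, cb) in enumerate(zip(pair.aligned_a, pair.aligned_b)):
        if ca == GAP and cb == GAP:
            raise ValueError(f"column {k} has gaps in both rows")
        if ca == GAP or cb == GAP:
            row = 1 if ca == GAP else 2
            if prev_gap_row == row:
                scores[k] = -extend
                state.append("extend")
            else:
                scores[k] = -open
                state.append("open")
            prev_gap_row = row
        else:
            scores[k] = float(matrix[ca, cb])
            state.append("none")
            prev_gap_row = 0
    return ColumnScores(scores=scores, gap_state=state)


def divergence_scale(
    cols: ColumnScores,
    pair: AlignedPair,
    reference: str = "a",
    window: int = 5,
) -> DivergenceScale:
    """Per-residue divergence of the reference sequence, in [0, 1].

    Each reference residue takes its column's similarity score; columns with
    a gap in the reference row (insertions in the other sequence) have no
    residue of their own, so their penalty is added to the flanking
    reference residue (the preceding one, or the following one at the
    N-terminus).  Divergence is the deviation from the average score,
    d_i = mean(w) - w_i, smoothed by a centered moving average over
    ``window`` residues (truncated symmetrically at the termini) and min-max
    rescaled to [0, 1]; a constant profile maps to all zeros.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    ref_row = pair.aligned_a if reference == "a" else pair.aligned_b
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    w: list[float] = []
    pending = 0.0  # gap-in-reference penalties awaiting a flanking residue
    for score, c in zip(cols.scores, ref_row):
        if c == GAP:
            if w:
                w[-1] += score
            else:
                pending += score
        else:
            w.append(float(score) + pending)
            pending = 0.0
    if not w:
        raise ValueError("alignment covers no reference residues")
    if pending:  # reference ended in a gap run; fold into the last residue
        w[-1] += pending
    w_arr = np.asarray(w)
    d = w_arr.mean() - w_arr

    smoothed = _centered_moving_average(d, window)
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi > lo:
        values = (smoothed - lo) / (hi - lo)
    else:
        values = np.zeros_like(smoothed)
    return DivergenceScale(
        values=values,
        residue_numbers=np.arange(1, len(w) + 1),
        window=window,
        raw_mean=float(w_arr.mean()),
        raw_range=(lo, hi),
    )


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Adjacent averaging with a symmetric window truncated at the ends."""
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        k = min(half, i, x.size - 1 - i)  # symmetric truncation
        out[i] = x[i - k : i + k + 1].mean()
    return out


def percent_identity(pair: AlignedPair, denominator: str = "alignment") -> float:
    """Percent identical columns.

    ``denominator``: 'alignment' (default, full aligned length including
    gap columns), 'shorter' (length of the shorter input sequence), or
    'columns' (residue-residue columns only).
    """
    if len(pair) == 0:
        raise ValueError("empty alignment")
    ident = sum(
        1
        for ca, cb in zip(pair.aligned_a, pair.aligned_b)
        if ca == cb and ca != GAP
    )
    if denominator == "alignment":
        denom = len(pair)
    elif denominator == "shorter":
        denom = min(len(pair.seq_a), len(pair.seq_b))
    elif denominator == "columns":
        denom = sum(
            1
            for ca, cb in zip(pair.aligned_a, pair.aligned_b)
            if ca != GAP and cb != GAP
        )
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ValueError("denominator is zero for this convention")
    return 100.0 * ident / denom


def count_substitutions(
    seq_a: str, seq_b: str, with_gaps: bool = False, **align_kwargs
):
    """Number of mismatching aligned residue pairs between two sequences.

    Equal-length sequences are compared position by position; otherwise a
    global alignment is computed first.  Gapped columns are counted
    separately and returned when ``with_gaps``.
    """
    if len(seq_a) == len(seq_b):
        pairs = zip(seq_a, seq_b)
        subs = sum(1 for a, b in pairs if a != b and GAP not in (a, b))
        gaps = 0
    else:
        aln = global_align_affine(seq_a, seq_b, **align_kwargs)
        subs = sum(
            1
            for a, b in zip(aln.aligned_a, aln.aligned_b)
            if a != b and GAP not in (a, b)
        )
        gaps = sum(
            1 for a, b in zip(aln.aligned_a, aln.aligned_b) if GAP in (a, b)
        )
    return (subs, gaps) if with_gaps else subs


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (plain or aligned) FASTA file into an ordered id->sequence map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def map_scale_to_structure(
    scale: DivergenceScale,
    model_file: str | Path,
    out_file: str | Path,
    chain: str = "A",
    numbering_offset: int = 0,
) -> list[int]:
    """Write divergence values into a PDB model's temperature-factor column.

    Every atom of chain ``chain`` whose residue number equals a reference
    residue number plus ``numbering_offset`` receives the residue's scale
    value multiplied by 100 (rounded to 2 decimals); unmatched residues are
    set to 0 and their numbers returned.  The output stays a standard PDB.
    """
    import gemmi

    structure = gemmi.read_structure(str(model_file))
    lookup = {
        int(num) + numbering_offset: float(round(val * 100.0, 2))
        for num, val in zip(scale.residue_numbers, scale.values)
    }
    unmatched: list[int] = []
    matched = 0
    chain_found = False
    for mdl in structure:
        for ch in mdl:
            if ch.name != chain:
                continue
            chain_found = True
            for res in ch:
                num = res.seqid.num
                if num in lookup:
                    matched += 1
                    for atom in res:
                        atom.b_iso = lookup[num]
                else:
                    unmatched.append(num)
                    for atom in res:
                        atom.b_iso = 0.0
    if not chain_found:
        raise ValueError(f"chain {chain!r} not found in {model_file}")
    if matched == 0:
        raise ValueError("no residues matched the divergence scale numbering")
    structure.setup_entities()
    structure.write_pdb(str(out_file))
    return unmatched
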