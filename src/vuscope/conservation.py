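"""Per-column conservation of a multiple sequence alignment.

Conservation is quantified as Shannon information content in bits,
``IC = log2(20) - H`` with ``H = -sum f log2 f`` over the 20 canonical
residues observed at the column (gaps excluded from frequencies, reported
separately).  A mutated reference position is then categorised as
high / moderate / low conservation from the reference residue's frequency
and frequency rank, mirroring the qualitative labels used when reading a
sequence logo.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import AlignIO

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"
MAX_BITS = float(np.log2(20))       # 4.3219...


class AlignmentFormatError(ValueError):
    pass


class UndefinedProfileError(ValueError):
    """All-gap column: no residue frequencies exist."""


@dataclass
class Alignment:
    """Equal-length aligned residue strings; one row is the reference target.

    Non-canonical residues (B, Z, X, ambiguity codes) are treated as gaps,
    keeping the entropy bound at log2(20).
    """

    sequences: list[str]
    ids: list[str]
    target_index: int = 0

    def __post_init__(self):
        if not self.sequences:
            raise AlignmentFormatError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment, lengths {sorted(lengths)}")
        self.sequences = [
            "".join(c if c in _AA_SET else GAP for c in s.upper().replace(".", GAP))
            for s in self.sequences
        ]
        if not (0 <= self.target_index < len(self.sequences)):
            raise IndexError("target_index out of range")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def target(self) -> str:
        return self.sequences[self.target_index]


@dataclass(frozen=True)
class ConservationProfile:
    column: int
    frequencies: dict            # residue -> fraction over non-gap symbols
    gap_fraction: float
    info_bits: float
    ref_residue: Optional[str]   # None when target is gapped at the column
    ref_rank: Optional[int]      # 1 = modal residue
    unreliable: bool = False     # gap_fraction > 0.5

    @property
    def ref_frequency(self) -> float:
        if self.ref_residue is None:
            return 0.0
        return self.frequencies.get(self.ref_residue, 0.0)


def parse_alignment(path: str | Path, target_id: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment; format is sniffed from content."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise AlignmentFormatError(f"empty alignment file {path}")
    fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(str(exc)) from exc
    ids = [rec.id for rec in aln]
    target_index = ids.index(target_id) if target_id is not None else 0
    return Alignment([str(rec.seq) for rec in aln], ids, target_index)


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def column_profile(aln: Alignment, column: int,
                   small_sample_correction: bool = False) -> ConservationProfile:
    """Residue frequencies and information content of one alignment column.

    ``small_sample_correction`` subtracts the standard logo correction
    e_n = (|alphabet|-1) / (2 ln2 n) from the information content.
    """
    if not (0 <= column < aln.length):
        raise IndexError(f"column {column} outside alignment of length {aln.length}")
    symbols = [s[column] for s in aln.sequences]
    residues = [c for c in symbols if c != GAP]
    n = len(residues)
    if n == 0:
        raise UndefinedProfileError(f"column {column} is all-gap")
    counts = pd.Series(residues).value_counts()
    freqs = {aa: counts.get(aa, 0) / n for aa in AMINO_ACIDS if counts.get(aa, 0) > 0}
    f = np.array(list(freqs.values()))
    entropy = float(-(f * np.log2(f)).sum())
    info = MAX_BITS - entropy
    if small_sample_correction:
        info -= (len(AMINO_ACIDS) - 1) / (2 * np.log(2) * n)
    info = max(info, 0.0)
    gap_fraction = 1.0 - n / len(symbols)
    ref = aln.target[column]
    if ref == GAP:
        ref_residue, ref_rank = None, None
    else:
        ref_residue = ref
        # rank 1 = modal; ties share the better (smaller) rank
        ref_freq = freqs.get(ref, 0.0)
        ref_rank = 1 + sum(1 for v in freqs.values() if v > ref_freq)
    return ConservationProfile(
        column=column, frequencies=freqs, gap_fraction=gap_fraction,
        info_bits=info, ref_residue=ref_residue, ref_rank=ref_rank,
        unreliable=gap_fraction > 0.5)


def map_residue_to_column(aln: Alignment, residue_number: int) -> int:
    """Alignment column (0-based) holding 1-based target residue ``residue_number``."""
    target = aln.target
    count = 0
    for col, c in enumerate(target):
        if c != GAP:
            count += 1
            if count == residue_number:
                return col
    raise IndexError(
        f"residue {residue_number} beyond ungapped target length {count}")


def map_column_to_residue(aln: Alignment, column: int) -> int:
    """Inverse of :func:`map_residue_to_column`; errors on gapped columns."""
    if not (0 <= column < aln.length):
        raise IndexError(f"column {column} out of range")
    target = aln.target
    if target[column] == GAP:
        raise IndexError(f"target is gapped at column {column}")
    return sum(1 for c in target[:column + 1] if c != GAP)


def conservation_category(profile: ConservationProfile,
                          high_threshold: float = 0.80,
                          moderate_threshold: float = 0.05) -> str:
    """Label the reference residue's conservation.

    high: the reference residue is modal and dominates (freq >= 0.80);
    moderate: it is among the top three residues with non-negligible
    frequency (>= 0.05), e.g. the second-most-prevalent residue at a column
    where another residue predominates; low: everything else.
    """
    if profile.ref_residue is None:
        return "low"
    if profile.ref_rank == 1 and profile.ref_frequency >= high_threshold:
        return "high"
    if profile.ref_rank is not None and profile.ref_rank <= 3 \
            and profile.ref_frequency >= moderate_threshold:
        return "moderate"
    return "low"


def profile_table(aln: Alignment, positions: list[int],
                  small_sample_correction: bool = False) -> pd.DataFrame:
    """Conservation report for 1-based target residue positions."""
    rows = []
    for pos in positions:
        col = map_residue_to_column(aln, pos)
        prof = column_profile(aln, col, small_sample_correction)
        top5 = sorted(prof.frequencies.items(), key=lambda kv: -kv[1])[:5]
        rows.append({
            "position": pos, "column": col, "ref_residue": prof.ref_residue,
            "ref_frequency": prof.ref_frequency, "ref_rank": prof.ref_rank,
            "gap_fraction": prof.gap_fraction, "info_bits": prof.info_bits,
            "category": conservation_category(prof),
            "top5": ";".join(f"{aa}:{f:.3f}" for aa, f in top5),
        })
    return pd.DataFrame(rows)


def logo_matrix(aln: Alignment, scaling: str = "bits",
                small_sample_correction: bool = False) -> pd.DataFrame:
    """Per-column residue matrix for sequence-logo plotting.

    ``scaling="bits"`` returns frequency * information content (letter
    heights of a bit-scaled logo); ``"probability"`` returns raw
    frequencies.  Columns that are entirely gap yield a zero row.
    """
    if scaling not in ("bits", "probability"):
        raise ValueError("scaling must be 'bits' or 'probability'")
    data = np.zeros((aln.length, len(AMINO_ACIDS)))
    for col in range(aln.length):
        try:
            prof = column_profile(aln, col, small_sample_correction)
        except UndefinedProfileError:
            continue
        scale = prof.info_bits if scaling == "bits" else 1.0
        for j, aa in enumerate(AMINO_ACIDS):
            data[col, j] = prof.frequencies.get(aa, 0.0) * scale
    return pd.DataFrame(data, columns=list(AMINO_ACIDS))
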