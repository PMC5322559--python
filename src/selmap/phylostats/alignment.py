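"""Conserved-residue and motif scanning on protein alignments.

Used to check the diagnostic residues of candidate families: the invariant
Cys of the YedE-like transporters, the CPXP motif of the SirA-like domain,
the CGXC redox motif of the DsrE-like domain, and the conserved Pro of the
Se-associated LysR subfamily.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .trees import GAP_CHARS, as_records

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ColumnConservation:
    column: int  # 1-based alignment column
    consensus: str
    frequency: float  # among non-gap rows
    n_non_gap: int
    skipped: bool = False  # > 50% gaps


@dataclass
class ConservationProfile:
    columns: list[ColumnConservation]
    flagged: list[int]  # 1-based columns meeting the threshold (and filter)


def conservation_scan(msa, min_freq: float = 0.9,
                      residue_filter: str | None = None,
                      max_gap_fraction: float = 0.5) -> ConservationProfile:
    """Per-column consensus frequencies, flagging conserved columns.

    Frequencies are computed over non-gap rows only; columns with more than
    ``max_gap_fraction`` gaps are skipped (reported but never flagged).
    ``residue_filter`` restricts flags to columns whose consensus is that
    residue (e.g. ``"C"`` for an invariant cysteine).  Consensus ties break
    to the alphabetically first residue.
    """
    if not (0.0 < min_freq <= 1.0):
        raise ValueError(f"min_freq must be in (0, 1], got {min_freq}")
    records = as_records(msa)
    if len(records) < 2:
        raise ValueError("need >= 2 sequences")
    if residue_filter is not None:
        residue_filter = residue_filter.upper()
        if residue_filter not in AMINO_ACIDS:
            raise ValueError(f"residue_filter {residue_filter!r} is not an amino acid")
    length = len(records[0][1])
    nrows = len(records)
    columns: list[ColumnConservation] = []
    flagged: list[int] = []
    for col in range(length):
        residues = [seq[col] for _rid, seq in records if seq[col] not in GAP_CHARS]
        n_non_gap = len(residues)
        if n_non_gap < nrows * (1.0 - max_gap_fraction):
            columns.append(ColumnConservation(column=col + 1, consensus="-",
                                              frequency=0.0, n_non_gap=n_non_gap,
                                              skipped=True))
            continue
        counts = Counter(residues)
        top = max(counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
        consensus, freq = top[0], top[1] / n_non_gap
        cc = ColumnConservation(column=col + 1, consensus=consensus,
                                frequency=freq, n_non_gap=n_non_gap)
        columns.append(cc)
        if freq >= min_freq and (residue_filter is None or consensus == residue_filter):
            flagged.append(cc.column)
    return ConservationProfile(columns=columns, flagged=flagged)


@dataclass(frozen=True)
class MotifMatch:
    seq_id: str
    position: int  # 1-based on the ungapped sequence
    column: int    # 1-based alignment column of the match start


def motif_scan(msa, pattern: str) -> list[MotifMatch]:
    """Locate a motif (X = any residue, other letters exact) in every
    sequence of an alignment.

    Matching runs on the ungapped sequences; each match reports both the
    1-based ungapped position and the alignment column where it starts.
    Overlapping matches are all reported.
    """
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("empty pattern")
    bad = set(pattern) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValueError(f"pattern characters outside amino-acid alphabet + X: {sorted(bad)}")
    records = as_records(msa)
    matches: list[MotifMatch] = []
    k = len(pattern)
    for rid, aligned in records:
        ungapped = []
        col_of = []  # alignment column (1-based) of each ungapped residue
        for col, ch in enumerate(aligned, start=1):
            if ch not in GAP_CHARS:
                ungapped.append(ch)
                col_of.append(col)
        seq = "".join(ungapped)
        for i in range(len(seq) - k + 1):
            if all(p == "X" or p == seq[i + j] for j, p in enumerate(pattern)):
                matches.append(MotifMatch(seq_id=rid, position=i + 1, column=col_of[i]))
    return matches
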