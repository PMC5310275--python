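"""Per-column conservation profiles and motif scanning for class alignments.

Information content per alignment column is the sequence-logo measure:
IC = log2(20) - H, where H is the Shannon entropy (bits) of the residue
distribution with gaps excluded from the denominator. No small-sample
correction is applied (that adjustment is presentation-only in logo
renderers); an all-gap column is recorded with IC 0 and gap fraction 1.

Motif scanning supports the field's "x = any residue" notation (e.g.
LxLxL, the EAR-type repression motif; SKYQ and AAYIGP, class-diagnostic
blocks downstream of the LOB domain). Matching is case-insensitive and
overlapping matches are all reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MAX_IC = math.log2(20)

Alignment = Sequence[tuple[str, str]]  # (sequence_id, aligned sequence)


@dataclass(frozen=True)
class ColumnProfile:
    column: int  # 1-based
    frequencies: Mapping[str, float]  # gap-excluded; sums to 1 unless all-gap
    gap_fraction: float
    information: float  # bits, in [0, log2(20)]


def _as_alignment(aln) -> list[tuple[str, str]]:
    try:  # Bio.Align.MultipleSeqAlignment ducks as iterable of records
        rows = [(rec.id, str(rec.seq)) for rec in aln]
    except AttributeError:
        rows = [(name, seq) for name, seq in aln]
    if len(rows) < 2:
        raise ValidationError("alignment needs at least 2 sequences")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValidationError(f"ragged alignment: lengths {sorted(lengths)}")
    return rows


def column_information(aln: Alignment) -> list[ColumnProfile]:
    """Per-column residue frequencies, gap fraction and information content."""
    rows = _as_alignment(aln)
    n_seq = len(rows)
    length = len(rows[0][1])
    profiles: list[ColumnProfile] = []
    for col in range(length):
        counts: dict[str, int] = {}
        gaps = 0
        for name, seq in rows:
            ch = seq[col].upper()
            if ch == GAP:
                gaps += 1
                continue
            if ch not in AMINO_ACIDS:
                raise ValidationError(
                    f"sequence {name!r}, column {col + 1}: "
                    f"character {seq[col]!r} outside alphabet"
                )
            counts[ch] = counts.get(ch, 0) + 1
        total = n_seq - gaps
        if total == 0:
            profiles.append(
                ColumnProfile(col + 1, {}, 1.0, 0.0)
            )
            continue
        freqs = {aa: c / total for aa, c in sorted(counts.items())}
        entropy = -sum(f * math.log2(f) for f in freqs.values())
        ic = max(0.0, MAX_IC - entropy)
        profiles.append(ColumnProfile(col + 1, freqs, gaps / n_seq, ic))
    return profiles


def scan_motif(sequence: str, pattern: str) -> list[int]:
    """All (overlapping) 1-based start positions of the motif, ascending.

    ``x``/``X`` in the pattern matches any residue; other letters match
    exactly, case-insensitively. A pattern longer than the sequence yields
    an empty list.
    """
    if not pattern:
        raise ValidationError("empty motif pattern")
    seq = sequence.upper()
    pat = pattern.upper()
    hits: list[int] = []
    for start in range(len(seq) - len(pat) + 1):
        if all(p == "X" or p == seq[start + i] for i, p in enumerate(pat)):
            hits.append(start + 1)
    return hits


def write_profile_table(profiles: Sequence[ColumnProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tinformation_bits\tgap_fraction\ttop_residue\ttop_frequency\n")
        for p in profiles:
            if p.frequencies:
                top = max(p.frequencies, key=lambda aa: (p.frequencies[aa], aa))
                fh.write(
                    f"{p.column}\t{p.information:.4f}\t{p.gap_fraction:.4f}\t"
                    f"{top}\t{p.frequencies[top]:.4f}\n"
                )
            else:
                fh.write(f"{p.column}\t0.0000\t1.0000\t-\t0.0000\n")
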