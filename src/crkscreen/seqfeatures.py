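"""Motif-level sequence features of receptor ectodomains.

Scanners for the features that matter in tandem-DUF26 receptor ectodomains:
N-glycosylation sequons (N-X-S/T with X != Pro), the cysteine census, the
DUF26-defining C-X8-C-X2-C motif, vicinal (sequentially adjacent) cysteine
pairs, region splitting by domain annotation, and mapping of selected sites
onto regions.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .popgen import AlignmentSet, round_half_up

AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "RegionAnnotation",
    "MotifHitSet",
    "scan_sequons",
    "cysteine_census",
    "find_crr_motif",
    "find_vicinal_cysteines",
    "fraction_in_region",
    "conservation_at_positions",
    "split_regions",
    "hits_to_frame",
]


@dataclass(frozen=True)
class RegionAnnotation:
    """Named 1-based inclusive regions of one sequence (e.g. ECD, DUF26-A)."""

    seq_id: str
    regions: Dict[str, Tuple[int, int]]

    def validate(self, seq_length: int) -> None:
        for name, (start, end) in self.regions.items():
            if not (1 <= start <= end <= seq_length):
                raise ValueError(
                    f"region {name} ({start},{end}) out of bounds for length {seq_length}"
                )


@dataclass(frozen=True)
class MotifHitSet:
    """Hits of one motif in one sequence; positions are 1-based match starts."""

    motif: str
    positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        if tuple(sorted(self.positions)) != self.positions:
            raise ValueError("positions must be sorted ascending")


def scan_sequons(seq: str) -> MotifHitSet:
    """N-glycosylation sequons: positions i with N at i, non-P at i+1, S/T at i+2.

    Overlapping hits are all reported.  Only the middle residue is
    restricted (X != P); a proline after the sequon does not veto the hit.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 residues")
    hits = [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]
    return MotifHitSet(motif="N-X-S/T", positions=tuple(hits))


def cysteine_census(seq: str) -> MotifHitSet:
    """All 1-based cysteine positions."""
    seq = seq.upper()
    return MotifHitSet(motif="C", positions=tuple(i + 1 for i, c in enumerate(seq) if c == "C"))


def find_crr_motif(seq: str) -> MotifHitSet:
    """The C-X8-C-X2-C cysteine motif: C, 8 spacers, C, 2 spacers, C.

    A hit at 1-based position i means seq[i]='C', seq[i+9]='C', seq[i+12]='C'
    in 1-based coordinates (match length 13).
    """
    seq = seq.upper()
    hits = [
        i + 1
        for i in range(len(seq) - 12)
        if seq[i] == "C" and seq[i + 9] == "C" and seq[i + 12] == "C"
    ]
    return MotifHitSet(motif="C-X8-C-X2-C", positions=tuple(hits))


def find_vicinal_cysteines(seq: str) -> List[Tuple[int, int]]:
    """All (i, i+1) pairs of sequentially adjacent cysteines; overlaps reported."""
    seq = seq.upper()
    return [(i + 1, i + 2) for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "C"]


def fraction_in_region(
    sites: Sequence[int], region: Tuple[int, int]
) -> Tuple[int, int, int]:
    """How many of ``sites`` fall inside a 1-based inclusive interval.

    Returns (count_in, count_total, percent) with the percent rounded
    half-up to an integer, the convention used for printed shares such as
    "47% (16 out of 34)".
    """
    if not sites:
        raise ValueError("empty site list")
    start, end = region
    count_in = sum(1 for s in sites if start <= s <= end)
    total = len(sites)
    return count_in, total, round_half_up(100.0 * count_in / total)


def conservation_at_positions(
    aln: AlignmentSet,
    ref_id: str,
    ref_positions: Sequence[int],
    conserved_threshold: float = 0.9,
) -> pd.DataFrame:
    """Residue distribution at alignment columns hit by reference positions.

    ``ref_positions`` are 1-based *ungapped* coordinates of the reference
    row; each is mapped through the alignment (skipping reference gaps) and
    the residue distribution of that column (over non-gap rows) reported.
    A position is flagged conserved when the reference residue's frequency
    is >= ``conserved_threshold``.
    """
    if ref_id not in aln.ids:
        raise ValueError(f"{ref_id} not in alignment")
    ref_row = aln.rows[aln.ids.index(ref_id)]
    # ungapped position -> alignment column (both 1-based)
    colmap: Dict[int, int] = {}
    p = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch != "-":
            p += 1
            colmap[p] = col
    records = []
    for pos in ref_positions:
        if pos not in colmap:
            raise ValueError(f"position {pos} beyond reference ungapped length {p}")
        col = colmap[pos]
        column = [row[col - 1] for row in aln.rows if row[col - 1] != "-"]
        ref_res = ref_row[col - 1]
        freq = column.count(ref_res) / len(column)
        records.append(
            {
                "ref_position": pos,
                "alignment_column": col,
                "ref_residue": ref_res,
                "ref_frequency": freq,
                "conserved": freq >= conserved_threshold,
                "distribution": {r: column.count(r) / len(column) for r in sorted(set(column))},
            }
        )
    return pd.DataFrame.from_records(records)


def split_regions(seq: str, annotation: RegionAnnotation) -> Dict[str, str]:
    """Exact substrings per named region (1-based inclusive intervals)."""
    annotation.validate(len(seq))
    return {name: seq[start - 1 : end] for name, (start, end) in annotation.regions.items()}


def hits_to_frame(hits_by_id: Mapping[str, Sequence[MotifHitSet]]) -> pd.DataFrame:
    """One row per hit: sequence id, motif name, 1-based position (TSV-ready)."""
    rows = [
        {"id": sid, "motif": hs.motif, "position": pos}
        for sid, hitsets in hits_by_id.items()
        for hs in hitsets
        for pos in hs.positions
    ]
    return pd.DataFrame(rows, columns=["id", "motif", "position"])
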