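"""Sequence-diversity statistics for multiple alignments.

Implements the classical summary statistics used to profile diversity of a
gene family across a population sample: segregating sites :math:`S`, mean
pairwise difference count :math:`\\hat{k}`, per-site nucleotide diversity
:math:`\\pi`, Watterson's :math:`\\theta_W = S/a_1` and Tajima's D, plus
haplotype collapsing (classes of >= 2 identical sequences), pairwise percent
identity and logo-ready per-column residue frequencies.

Site filtering for S, k_hat and D is listwise by default: only columns with
no gap ('-') and no ambiguity ('N'/'X') in any row are usable.  This keeps a
single, pair-independent denominator; the convention is configurable via the
``usable_columns`` helper should a caller need pairwise deletion instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"
AMBIGUOUS = {"N", "X"}
GAP = "-"

__all__ = [
    "AlignmentSet",
    "DiversityResult",
    "HaplotypeTable",
    "segregating_sites",
    "nucleotide_diversity",
    "tajimas_d",
    "tajima_constants",
    "collapse_haplotypes",
    "pairwise_identity_matrix",
    "column_frequencies",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (0.5 -> 1).

    Used for printed percent shares so that e.g. 28.5 -> 29, matching the
    usual report convention rather than banker's rounding.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class AlignmentSet:
    """A multiple alignment: unique ids and equal-length rows.

    Columns are addressed 1-based throughout the package, matching residue
    numbering conventions in structural biology.
    """

    ids: Tuple[str, ...]
    rows: Tuple[str, ...]
    alphabet: str = "nucleotide"  # or "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("all alignment rows must have equal length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_mapping(cls, seqs: Mapping[str, str], alphabet: str = "nucleotide") -> "AlignmentSet":
        ids = tuple(seqs)
        return cls(ids=ids, rows=tuple(seqs[i].upper() for i in ids), alphabet=alphabet)

    @classmethod
    def from_fasta(cls, path, alphabet: str = "nucleotide") -> "AlignmentSet":
        seqs: Dict[str, List[str]] = {}
        current: Optional[str] = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line:
                    continue
                if line.startswith(">"):
                    current = line[1:].split()[0]
                    if current in seqs:
                        raise ValueError(f"duplicate id in FASTA: {current}")
                    seqs[current] = []
                else:
                    if current is None:
                        raise ValueError("FASTA sequence data before first header")
                    seqs[current].append(line)
        return cls.from_mapping({k: "".join(v) for k, v in seqs.items()}, alphabet=alphabet)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    def matrix(self) -> np.ndarray:
        """Rows as a (n, L) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")


def usable_columns(aln: AlignmentSet) -> np.ndarray:
    """Boolean mask of columns free of gaps and ambiguity codes in every row."""
    m = aln.matrix()
    bad = (m == GAP)
    for code in AMBIGUOUS:
        bad |= (m == code)
    return ~bad.any(axis=0)


def segregating_sites(aln: AlignmentSet) -> int:
    """Count usable columns carrying >= 2 distinct states."""
    if aln.n < 2:
        raise ValueError("segregating_sites requires at least 2 sequences")
    m = aln.matrix()[:, usable_columns(aln)]
    if m.shape[1] == 0:
        return 0
    return int(((m != m[0]).any(axis=0)).sum())


def nucleotide_diversity(aln: AlignmentSet) -> Tuple[float, float]:
    """Return (k_hat, pi).

    k_hat is the mean, over all n(n-1)/2 sequence pairs, of per-pair
    difference counts on usable columns; pi = k_hat / L_usable.
    """
    if aln.n < 2:
        raise ValueError("nucleotide_diversity requires at least 2 sequences")
    mask = usable_columns(aln)
    L = int(mask.sum())
    if L == 0:
        raise ValueError("no usable (gap- and ambiguity-free) columns")
    m = aln.matrix()[:, mask]
    n = aln.n
    # plain average over pairs, via per-column allele counts:
    # pairs differing at a column = C(n,2) - sum_allele C(count,2)
    states = np.unique(m)
    counts = np.zeros((L, states.size))
    for k, st in enumerate(states):
        counts[:, k] = (m == st).sum(axis=0)
    same = (counts * (counts - 1) / 2.0).sum(axis=1)
    diff_pairs = float((n * (n - 1) / 2.0 - same).sum())
    k_hat = diff_pairs / (n * (n - 1) / 2)
    return k_hat, k_hat / L


def tajima_constants(n: int) -> Dict[str, float]:
    """Tajima (1989) normalising constants a1..e2 for sample size n."""
    if n < 2:
        raise ValueError("constants defined for n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass(frozen=True)
class DiversityResult:
    """Per-locus diversity summary; tajimas_d is None when S = 0.

    ``|D| > 2`` is conventionally flagged as departing from neutrality.
    """

    n: int
    L: int
    S: int
    k_hat: float
    pi: float
    theta_w: float
    tajimas_d: Optional[float]
    constants: Dict[str, float] = field(default_factory=dict)

    @property
    def nonneutral(self) -> bool:
        return self.tajimas_d is not None and abs(self.tajimas_d) > 2.0

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n,
                "L": self.L,
                "S": self.S,
                "k_hat": self.k_hat,
                "pi": self.pi,
                "theta_w": self.theta_w,
                "tajimas_d": np.nan if self.tajimas_d is None else self.tajimas_d,
            }
        )


def tajimas_d(aln: AlignmentSet) -> DiversityResult:
    """Tajima's D with the 1989 constants.

    D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)); undefined (None) when
    S = 0.  The formulas are defined for n >= 2 and are evaluated as such;
    values for n = 2 or 3 are numerically valid but of little inferential
    use and should be interpreted with care.
    """
    if aln.n < 2:
        raise ValueError("tajimas_d requires at least 2 sequences")
    mask = usable_columns(aln)
    L = int(mask.sum())
    if L == 0:
        raise ValueError("no usable columns")
    S = segregating_sites(aln)
    k_hat, pi = nucleotide_diversity(aln)
    const = tajima_constants(aln.n)
    theta_w = S / const["a1"]
    if S == 0:
        d: Optional[float] = None
    else:
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        d = (k_hat - theta_w) / math.sqrt(var)
    return DiversityResult(
        n=aln.n, L=L, S=S, k_hat=k_hat, pi=pi, theta_w=theta_w, tajimas_d=d, constants=const
    )


@dataclass(frozen=True)
class HaplotypeTable:
    """Exact-sequence equivalence classes; classes of size >= 2 are haplotypes."""

    groups: Tuple[Tuple[str, ...], ...]
    singletons: Tuple[str, ...]

    @property
    def grouped_count(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def total_count(self) -> int:
        return self.grouped_count + len(self.singletons)

    @property
    def grouped_share(self) -> int:
        """Integer percent of sequences falling in a haplotype class."""
        if self.total_count == 0:
            return 0
        return round_half_up(100.0 * self.grouped_count / self.total_count)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups, start=1):
            for member in g:
                rows.append({"haplotype": f"H{i}", "id": member, "size": len(g)})
        for s in self.singletons:
            rows.append({"haplotype": "singleton", "id": s, "size": 1})
        return pd.DataFrame(rows, columns=["haplotype", "id", "size"])


def collapse_haplotypes(seqs: Mapping[str, str]) -> HaplotypeTable:
    """Collapse sequences into identical-sequence classes.

    Identity is exact character equality after upper-casing; a stop codon
    '*' is an ordinary character.  Classes of size >= 2 are haplotypes;
    the rest are singletons.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    classes: Dict[str, List[str]] = {}
    for sid in seqs:
        classes.setdefault(seqs[sid].upper(), []).append(sid)
    groups = []
    singletons = []
    for members in classes.values():
        if len(members) >= 2:
            groups.append(tuple(sorted(members)))
        else:
            singletons.append(members[0])
    groups.sort(key=lambda g: (-len(g), g))
    return HaplotypeTable(groups=tuple(groups), singletons=tuple(sorted(singletons)))


def pairwise_identity_matrix(aln: AlignmentSet) -> pd.DataFrame:
    """Symmetric percent-identity matrix.

    identity(i, j) = 100 * matches / (columns where at least one of the
    pair is non-gap); gap-gap columns are excluded from the denominator.
    Diagonal is 100 by definition.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    m = aln.matrix()
    n = aln.n
    out = np.full((n, n), 100.0)
    gap = m == GAP
    for i in range(n):
        for j in range(i + 1, n):
            denom_mask = ~(gap[i] & gap[j])
            denom = int(denom_mask.sum())
            if denom == 0:
                ident = 0.0
            else:
                matches = int(((m[i] == m[j]) & ~gap[i] & denom_mask).sum())
                ident = 100.0 * matches / denom
            out[i, j] = out[j, i] = ident
    return pd.DataFrame(out, index=list(aln.ids), columns=list(aln.ids))


def column_frequencies(aln: AlignmentSet) -> pd.DataFrame:
    """Per-column residue frequencies over non-gap characters (logo-ready).

    Rows are 1-based column positions; columns are the residues observed in
    the alignment.  Each row sums to 1; all-gap columns are all-NaN and
    flagged in the ``all_gap`` attribute-style column.
    """
    if aln.n < 1:
        raise ValueError("need at least 1 sequence")
    m = aln.matrix()
    residues = sorted(set(m.ravel()) - {GAP})
    freq = np.zeros((aln.length, len(residues)))
    all_gap = np.zeros(aln.length, dtype=bool)
    for col in range(aln.length):
        column = m[:, col]
        column = column[column != GAP]
        if column.size == 0:
            all_gap[col] = True
            freq[col] = np.nan
            continue
        for k, res in enumerate(residues):
            freq[col, k] = (column == res).sum() / column.size
    df = pd.DataFrame(freq, index=pd.RangeIndex(1, aln.length + 1, name="position"), columns=residues)
    df["all_gap"] = all_gap
    return df


def diversity_table(alignments: Mapping[str, AlignmentSet]) -> pd.DataFrame:
    """Per-locus diversity statistics as one tidy table (TSV-ready)."""
    rows = {name: tajimas_d(aln).to_series() for name, aln in alignments.items()}
    df = pd.DataFrame(rows).T
    df.index.name = "locus"
    return df
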