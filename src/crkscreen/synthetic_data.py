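"""Generators for every input class the dimer-screening pipeline consumes.

Structure prediction at family scale needs GPUs, and population sampling
needs genome downloads; neither belongs in a test suite.  This module
builds desk-scale stand-ins with *planted, recoverable ground truth*:

* two-chain coordinate fixtures with a controllable relative orientation
  (Standard / Flipped / FlippedShifted), interface separation and number of
  planted cross-chain contacts — pseudo-structures of CA/N/O traces, not
  physically realistic folds;
* PAE matrices with controllable intra-/inter-chain error levels;
* per-model ipTM/pTM score tables;
* neutral Kingman-coalescent nucleotide alignments under infinite sites;
* protein sequences with motifs planted at known positions;
* a pan-genome locus-retrieval emulation (one best hit per genome and
  locus) and expression tables.

Every generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqfeatures import AA20, RegionAnnotation
from .popgen import AlignmentSet
from .structmodel import (
    Atom,
    Chain,
    PaeMatrix,
    Residue,
    StructureModel,
    PAE_CEILING,
)

CA_SPACING = 3.8  # Å between consecutive CA atoms along the pseudo-chain axis
ORIENTATIONS = ("Standard", "Flipped", "FlippedShifted")

__all__ = [
    "DimerFixtureSpec",
    "PaeFixtureSpec",
    "CoalescentSpec",
    "make_dimer_fixture",
    "make_pae_fixture",
    "simulate_neutral_alignment",
    "plant_motif_sequence",
    "make_score_table",
    "make_disulfide_fixture",
    "make_locus_library",
    "make_pan_genome",
    "extract_locus_hits",
    "make_expression_table",
    "make_screen_cohort",
]


# ---------------------------------------------------------------------------
# dimer fixtures


@dataclass(frozen=True)
class DimerFixtureSpec:
    """Recipe for a two-chain pseudo-dimer with planted orientation.

    Each chain carries two rigid pseudo-domains ("DUF26-A" then "DUF26-B")
    of ``residues_per_domain`` CA positions at 3.8 Å spacing along the chain
    axis.  ``planted_contacts`` consecutive cross-chain residue pairs are
    brought to ``interface_separation`` Å (CA–CA) with backbone N/O atoms
    aimed so exactly those pairs satisfy the beta-ladder hydrogen-bond
    criterion; all other residues sit 4 Å further out.  Contacts pair the
    B domains for Standard/FlippedShifted and A with B for Flipped; the two
    chains' A->B axes are parallel for Standard, antiparallel otherwise.
    FlippedShifted additionally offsets the second chain along the axis
    (default: one domain length), which is what makes B:B contacts
    geometrically possible between antiparallel chains.

    The planted-contact contract (interface count per chain == contacts) is
    exact for separations in [4.4, 5.0] Å; tighter separations start to pull
    flanking residues inside a 5 Å cutoff.
    """

    orientation_label: str
    residues_per_domain: int
    interface_separation: float = 4.8
    planted_contacts: int = 6
    axial_shift: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation_label not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.residues_per_domain <= 0:
            raise ValueError("residues_per_domain must be positive")
        if not (0 <= self.planted_contacts <= self.residues_per_domain):
            raise ValueError("planted_contacts must be in [0, residues_per_domain]")
        if self.interface_separation <= 0:
            raise ValueError("interface_separation must be positive")


def _shift_steps(spec: DimerFixtureSpec) -> int:
    n, k = spec.residues_per_domain, spec.planted_contacts
    if spec.orientation_label != "FlippedShifted":
        return 0
    if spec.axial_shift is None:
        return n
    m = int(round(spec.axial_shift / CA_SPACING))
    if not (max(k, 1) <= m <= n):
        raise ValueError(
            f"axial_shift must map to {max(k, 1)}..{n} CA steps; got {m}"
        )
    return m


def planted_contact_pairs(spec: DimerFixtureSpec) -> List[Tuple[int, int]]:
    """The (chain-1 residue, chain-2 residue) pairs the fixture plants."""
    n, k = spec.residues_per_domain, spec.planted_contacts
    if k == 0:
        return []
    if spec.orientation_label == "Standard":
        start = n + 1 + (n - k) // 2  # centred in domain B
        return [(i, i) for i in range(start, start + k)]
    if spec.orientation_label == "Flipped":
        start = 1 + (n - k) // 2  # centred in domain A of chain 1
        return [(i, 2 * n - i + 1) for i in range(start, start + k)]
    m = _shift_steps(spec)
    return [(i, 2 * n - i + 1 + m) for i in range(n + 1, n + 1 + k)]


def make_dimer_fixture(
    spec: DimerFixtureSpec,
) -> Tuple[StructureModel, Dict[str, RegionAnnotation]]:
    """Build the pseudo-dimer and its per-chain domain annotations."""
    n = spec.residues_per_domain
    s = spec.interface_separation
    rng = np.random.default_rng(spec.seed)
    pairs = planted_contact_pairs(spec)
    contacts1 = {i for i, _ in pairs}
    contacts2 = {j for _, j in pairs}
    far = s + 4.0  # baseline separation for non-contact residues
    m = _shift_steps(spec)

    def chain_x(res: int, chain: int) -> float:
        if chain == 1 or spec.orientation_label == "Standard":
            base = (res - 1) * CA_SPACING
            return base if chain == 1 else base
        # antiparallel second chain, optionally shifted
        return (m + 2 * n - res) * CA_SPACING

    def build_chain(chain_id: str, which: int) -> Chain:
        residues = []
        for res in range(1, 2 * n + 1):
            x = chain_x(res, which)
            contact = res in (contacts1 if which == 1 else contacts2)
            if which == 1:
                y = 0.0
            else:
                y = s if contact else far
            ca = np.array([x, y, 0.0])
            atoms = {"CA": Atom("CA", ca)}
            # Backbone N/O placement: the hydrogen-bond donor/acceptor of a
            # planted pair face each other across the interface (O of chain 1
            # at y+1, N of chain 2 at y-1, so N-O = separation - 2 Å); all
            # other N/O atoms are tucked away from the partner chain so that
            # no unplanted residue strays inside a 5 Å interface cutoff for
            # separations >= 4.4 Å.
            if which == 1 and contact:
                atoms["O"] = Atom("O", ca + np.array([0.0, 1.0, 0.0]))
                atoms["N"] = Atom("N", ca + np.array([-1.2, 0.0, 0.0]))
            elif which == 2 and contact:
                atoms["N"] = Atom("N", ca + np.array([0.0, -1.0, 0.0]))
                atoms["O"] = Atom("O", ca + np.array([1.2, 1.0, 0.0]))
            elif which == 1:
                atoms["N"] = Atom("N", ca + np.array([-1.2, -1.0, 0.0]))
                atoms["O"] = Atom("O", ca + np.array([1.2, -1.0, 0.0]))
            else:
                atoms["N"] = Atom("N", ca + np.array([-1.2, 1.0, 0.0]))
                atoms["O"] = Atom("O", ca + np.array([1.2, 1.0, 0.0]))
            plddt = float(rng.uniform(80.0, 95.0))
            residues.append(Residue(index=res, name="ALA", atoms=atoms, bfactor=plddt))
        return Chain(chain_id, residues)

    model = StructureModel(
        chains=[build_chain("A", 1), build_chain("B", 2)],
        name=f"dimer_{spec.orientation_label}_{spec.seed}",
    )
    ann = {
        cid: RegionAnnotation(
            seq_id=cid, regions={"DUF26-A": (1, n), "DUF26-B": (n + 1, 2 * n)}
        )
        for cid in ("A", "B")
    }
    return model, ann


def make_disulfide_fixture(n_bonds: int, seed: int = 0) -> StructureModel:
    """A single chain of 2*n_bonds cysteines whose SG atoms pair off.

    Residues (2t-1, 2t) carry S-gamma atoms 2.05 Å apart (a vicinal
    disulfide); SG atoms of different pairs are > 2.5 Å apart.
    """
    if n_bonds < 1:
        raise ValueError("need at least one bond")
    rng = np.random.default_rng(seed)
    residues = []
    for res in range(1, 2 * n_bonds + 1):
        x = (res - 1) * CA_SPACING
        ca = np.array([x, 0.0, 0.0])
        atoms = {"CA": Atom("CA", ca)}
        if res % 2 == 1:
            atoms["SG"] = Atom("SG", np.array([x + 0.875, 1.5, 0.0]))
        else:
            atoms["SG"] = Atom("SG", np.array([x - CA_SPACING + 0.875 + 2.05, 1.5, 0.0]))
        residues.append(
            Residue(index=res, name="CYS", atoms=atoms, bfactor=float(rng.uniform(80, 95)))
        )
    return StructureModel(chains=[Chain("A", residues)], name=f"disulfide_{seed}")


# ---------------------------------------------------------------------------
# PAE fixtures


@dataclass(frozen=True)
class PaeFixtureSpec:
    n_chain1: int
    n_chain2: int
    intra_level: float = 3.0
    inter_level: float = 8.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chain1 <= 0 or self.n_chain2 <= 0:
            raise ValueError("chain lengths must be positive")
        if self.intra_level < 0 or self.inter_level < 0:
            raise ValueError("PAE levels must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_pae_fixture(spec: PaeFixtureSpec) -> PaeMatrix:
    """Block-structured PAE matrix: intra-chain diagonal blocks at
    ``intra_level``, cross-chain blocks at ``inter_level``, plus optional
    Gaussian noise, clipped to [0, 31.75] Å."""
    n1, n2 = spec.n_chain1, spec.n_chain2
    n = n1 + n2
    rng = np.random.default_rng(spec.seed)
    values = np.full((n, n), spec.intra_level, dtype=float)
    values[:n1, n1:] = spec.inter_level
    values[n1:, :n1] = spec.inter_level
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=(n, n))
    values = np.clip(values, 0.0, PAE_CEILING)
    return PaeMatrix(values=values, chain_lengths=(n1, n2))


# ---------------------------------------------------------------------------
# neutral coalescent alignments


@dataclass(frozen=True)
class CoalescentSpec:
    """Neutral Kingman coalescent under infinite sites.

    theta is the per-locus scaled mutation rate (4*N*mu summed over sites);
    E[pairwise differences] = theta and E[S] = theta * a1(n).
    """

    n_samples: int
    seq_length: int
    theta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


def simulate_neutral_alignment(spec: CoalescentSpec) -> AlignmentSet:
    """Simulate one locus under the standard neutral coalescent.

    Inter-coalescent times are Exponential(k(k-1)/2) in units of 2N
    generations; mutations are Poisson with mean (theta/2) * total branch
    length, each dropped on a branch with probability proportional to its
    length and assigned a fresh site (infinite sites: if the Poisson draw
    exceeds seq_length it is resampled).  Alleles are coded A (ancestral)
    and T (derived).
    """
    n = spec.n_samples
    rng = np.random.default_rng(spec.seed)

    # simulate the tree: parent pointers and branch lengths
    next_node = n
    active = list(range(n))
    parent: Dict[int, int] = {}
    blen: Dict[int, float] = {}
    node_time = {i: 0.0 for i in range(n)}
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for child in (a, b):
            parent[child] = next_node
            blen[child] = t - node_time[child]
        node_time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1

    branches = sorted(blen)  # every node except the root
    lengths = np.array([blen[b] for b in branches])
    total_length = float(lengths.sum())

    n_mut = rng.poisson(spec.theta / 2.0 * total_length) if spec.theta > 0 else 0
    while n_mut > spec.seq_length:  # infinite sites at finite length: resample
        n_mut = rng.poisson(spec.theta / 2.0 * total_length)

    # leaves below each branch
    children: Dict[int, List[int]] = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)

    def leaves_below(node: int) -> List[int]:
        if node < n:
            return [node]
        out: List[int] = []
        for c in children[node]:
            out.extend(leaves_below(c))
        return out

    aln = np.full((n, spec.seq_length), "A", dtype="U1")
    if n_mut > 0:
        probs = lengths / total_length
        hit_branches = rng.choice(len(branches), size=n_mut, p=probs)
        sites = rng.choice(spec.seq_length, size=n_mut, replace=False)
        for b_idx, site in zip(hit_branches, sites):
            for leaf in leaves_below(branches[b_idx]):
                aln[leaf, site] = "T"

    ids = tuple(f"hap{i + 1}" for i in range(n))
    rows = tuple("".join(aln[i]) for i in range(n))
    return AlignmentSet(ids=ids, rows=rows, alphabet="nucleotide")


# ---------------------------------------------------------------------------
# motif-bearing protein sequences


def plant_motif_sequence(
    length: int, motif_placements: Mapping[int, str], seed: int = 0
) -> str:
    """Background protein sequence with exact motifs at 1-based positions.

    Background residues exclude every letter appearing in a planted motif
    and additionally the scanner-relevant residues N, S, T and C, so no
    accidental sequon, cysteine motif or vicinal pair can arise: the
    planted positions are exactly the scanner hits.  Placements must be
    non-overlapping and in range.
    """
    for pos, motif in motif_placements.items():
        if not motif or any(c not in AA20 for c in motif.upper()):
            raise ValueError(f"motif {motif!r} outside the 20-letter alphabet")
        if pos < 1 or pos + len(motif) - 1 > length:
            raise ValueError(f"motif {motif!r} at {pos} out of range for length {length}")
    spans = sorted((pos, pos + len(m) - 1) for pos, m in motif_placements.items())
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("motif placements overlap")
    banned = {c for m in motif_placements.values() for c in m.upper()} | set("NSTC")
    background = [c for c in AA20 if c not in banned]
    if not background:
        raise ValueError("motifs exhaust the amino-acid alphabet")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(background, size=length))
    for pos, motif in motif_placements.items():
        seq[pos - 1 : pos - 1 + len(motif)] = list(motif.upper())
    return "".join(seq)


# ---------------------------------------------------------------------------
# score tables


def make_score_table(
    pairs: Sequence[Tuple[str, str]],
    per_pair_models: int = 5,
    score_ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    seed: int = 0,
    iptm_weight: float = 0.8,
) -> pd.DataFrame:
    """Per-model ipTM/pTM table: one row per (pair, model rank).

    The combined score is the usual multimer ranking confidence
    ``iptm_weight * ipTM + (1 - iptm_weight) * pTM``; all scores are
    clamped to [0, 1].
    """
    if not pairs:
        raise ValueError("empty pair list")
    if per_pair_models < 1:
        raise ValueError("per_pair_models must be >= 1")
    ranges = {"iptm": (0.2, 0.95), "ptm": (0.3, 0.95)}
    if score_ranges:
        ranges.update(score_ranges)
    rng = np.random.default_rng(seed)
    rows = []
    for id1, id2 in pairs:
        a, b = sorted((id1, id2))
        for rank in range(1, per_pair_models + 1):
            iptm = float(np.clip(rng.uniform(*ranges["iptm"]), 0.0, 1.0))
            ptm = float(np.clip(rng.uniform(*ranges["ptm"]), 0.0, 1.0))
            rows.append(
                {
                    "id1": a,
                    "id2": b,
                    "model_rank": rank,
                    "iptm": iptm,
                    "ptm": ptm,
                    "combined": iptm_weight * iptm + (1 - iptm_weight) * ptm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pan-genome retrieval emulation


def make_locus_library(n_loci: int, locus_length: int = 120, seed: int = 0) -> Dict[str, str]:
    """Random nucleotide loci with mutually distinct 20-mer prefixes."""
    if locus_length < 20:
        raise ValueError("locus_length must be >= 20")
    rng = np.random.default_rng(seed)
    loci: Dict[str, str] = {}
    prefixes = set()
    i = 0
    while len(loci) < n_loci:
        seq = "".join(rng.choice(list("ACGT"), size=locus_length))
        if seq[:20] in prefixes:
            continue
        prefixes.add(seq[:20])
        i += 1
        loci[f"locus{i:03d}"] = seq
    return loci


def make_pan_genome(
    loci: Mapping[str, str],
    n_genomes: int,
    spacer_length: int = 40,
    substitution_rate: float = 0.01,
    seed: int = 0,
) -> Dict[str, str]:
    """Synthetic genomes each containing one copy of every locus.

    Loci are concatenated in a per-genome shuffled order with random
    spacers; each copy may carry substitutions at ``substitution_rate``
    outside its first 20 bases (the retrieval seed region stays exact).
    """
    rng = np.random.default_rng(seed)
    nt = list("ACGT")
    genomes: Dict[str, str] = {}
    names = list(loci)
    for g in range(1, n_genomes + 1):
        order = list(names)
        rng.shuffle(order)
        parts = []
        for name in order:
            parts.append("".join(rng.choice(nt, size=spacer_length)))
            seq = list(loci[name])
            for k in range(20, len(seq)):
                if rng.random() < substitution_rate:
                    seq[k] = nt[int(rng.integers(4))]
            parts.append("".join(seq))
        parts.append("".join(rng.choice(nt, size=spacer_length)))
        genomes[f"ecotype{g:03d}"] = "".join(parts)
    return genomes


def extract_locus_hits(
    genomes: Mapping[str, str], loci: Mapping[str, str]
) -> pd.DataFrame:
    """Best-hit extraction: one row per (genome, locus) found.

    The first occurrence of the locus's 20-mer seed prefix anchors the hit;
    the locus-length substring starting there is extracted.  Emulates the
    count contract of a genome-wide best-hit search without an aligner.
    """
    rows = []
    for gname, genome in genomes.items():
        for lname, lseq in loci.items():
            pos = genome.find(lseq[:20])
            if pos < 0:
                continue
            rows.append(
                {
                    "genome": gname,
                    "locus": lname,
                    "position": pos + 1,
                    "sequence": genome[pos : pos + len(lseq)],
                }
            )
    return pd.DataFrame(rows, columns=["genome", "locus", "position", "sequence"])


# ---------------------------------------------------------------------------
# expression tables


def make_expression_table(
    node_ids: Sequence[str],
    conditions: Sequence[str] = ("seedling", "senescence", "flg22"),
    zero_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-negative expression values per node and condition; a seeded
    fraction of entries is exactly zero (not expressed)."""
    rng = np.random.default_rng(seed)
    data = {}
    for cond in conditions:
        vals = rng.gamma(shape=2.0, scale=5.0, size=len(node_ids))
        vals[rng.random(len(node_ids)) < zero_fraction] = 0.0
        data[cond] = vals
    df = pd.DataFrame(data, index=pd.Index(node_ids, name="id"))
    return df.reset_index()


# ---------------------------------------------------------------------------
# full screening cohort with planted ground truth


@dataclass(frozen=True)
class CohortManifest:
    """Ground truth planted by :func:`make_screen_cohort`."""

    pairs: Tuple[Tuple[str, str], ...]
    pass_pairs: Tuple[Tuple[str, str], ...]
    fail_confidence: Tuple[Tuple[str, str], ...]
    fail_interface: Tuple[Tuple[str, str], ...]
    orientations: Dict[Tuple[str, str], str]
    homodimer_pairs: Tuple[Tuple[str, str], ...]
    residues_per_domain: int

    @property
    def n_enumerated(self) -> int:
        return len(self.pairs)

    @property
    def n_confidence(self) -> int:
        return len(self.pass_pairs) + len(self.fail_interface)

    @property
    def n_retained(self) -> int:
        return len(self.pass_pairs)


def make_screen_cohort(
    out_dir,
    n_pass: int = 7,
    n_fail_confidence: int = 6,
    n_fail_interface: int = 3,
    n_homodimer_pass: int = 2,
    residues_per_domain: int = 8,
    per_pair_models: int = 5,
    seed: int = 0,
) -> CohortManifest:
    """Write a complete fixture cohort for the screening pipeline.

    Layout under ``out_dir``: ``models/{id1}__{id2}_rank{r}.pdb``,
    ``pae/{id1}__{id2}_rank{r}.json``, ``scores.tsv`` and
    ``annotations.tsv``.  Passing pairs get one clearly best model with
    combined score ~0.9, cross-chain PAE ~3 Å and 6 planted contacts;
    confidence failures get low scores or high cross-chain PAE;
    interface failures pass the confidence stage but plant only 2
    contacts.  ``n_homodimer_pass`` of the passing pairs are self-pairs.
    """
    from pathlib import Path

    from . import structmodel as sm

    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "pae").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_hetero_pass = n_pass - n_homodimer_pass
    if n_hetero_pass < 0:
        raise ValueError("n_homodimer_pass cannot exceed n_pass")
    n_ids = 2 * (n_hetero_pass + n_fail_confidence + n_fail_interface) + n_homodimer_pass
    ids = [f"CRK{i:02d}" for i in range(1, n_ids + 1)]
    it = iter(ids)

    pass_pairs: List[Tuple[str, str]] = []
    for _ in range(n_homodimer_pass):
        a = next(it)
        pass_pairs.append((a, a))
    for _ in range(n_hetero_pass):
        pass_pairs.append(tuple(sorted((next(it), next(it)))))
    fail_conf = [tuple(sorted((next(it), next(it)))) for _ in range(n_fail_confidence)]
    fail_iface = [tuple(sorted((next(it), next(it)))) for _ in range(n_fail_interface)]
    all_pairs = pass_pairs + fail_conf + fail_iface

    orientations: Dict[Tuple[str, str], str] = {}
    score_rows = []
    for idx, pair in enumerate(all_pairs):
        a, b = pair
        kind = (
            "pass"
            if pair in pass_pairs
            else ("fail_conf" if pair in fail_conf else "fail_iface")
        )
        orient = ORIENTATIONS[idx % 3]
        contacts = 2 if kind == "fail_iface" else 6
        orientations[pair] = orient
        best_rank = 1 + int(rng.integers(per_pair_models))
        for rank in range(1, per_pair_models + 1):
            if kind == "fail_conf":
                iptm = float(rng.uniform(0.3, 0.6))
                ptm = float(rng.uniform(0.3, 0.6))
                inter = float(rng.uniform(9.0, 14.0))
            elif rank == best_rank:
                iptm = float(rng.uniform(0.90, 0.96))
                ptm = float(rng.uniform(0.90, 0.96))
                inter = float(rng.uniform(2.5, 3.5))
            else:
                iptm = float(rng.uniform(0.60, 0.78))
                ptm = float(rng.uniform(0.60, 0.78))
                inter = float(rng.uniform(6.5, 9.0))
            combined = 0.8 * iptm + 0.2 * ptm
            score_rows.append(
                {"id1": a, "id2": b, "model_rank": rank, "iptm": iptm, "ptm": ptm,
                 "combined": combined}
            )
            spec = DimerFixtureSpec(
                orientation_label=orient,
                residues_per_domain=residues_per_domain,
                interface_separation=4.8,
                planted_contacts=contacts,
                seed=int(rng.integers(2**31 - 1)),
            )
            model, _ = make_dimer_fixture(spec)
            sm.write_structure(model, out / "models" / f"{a}__{b}_rank{rank}.pdb")
            pae = make_pae_fixture(
                PaeFixtureSpec(
                    n_chain1=2 * residues_per_domain,
                    n_chain2=2 * residues_per_domain,
                    intra_level=2.0,
                    inter_level=inter,
                    noise_sd=0.3,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            sm.write_pae_json(pae, out / "pae" / f"{a}__{b}_rank{rank}.json")

    pd.DataFrame(score_rows).to_csv(out / "scores.tsv", sep="\t", index=False)
    n = residues_per_domain
    pd.DataFrame(
        [
            {"chain": cid, "region": reg, "start": start, "end": end}
            for cid in ("A", "B")
            for reg, (start, end) in (("DUF26-A", (1, n)), ("DUF26-B", (n + 1, 2 * n)))
        ]
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)

    return CohortManifest(
        pairs=tuple(all_pairs),
        pass_pairs=tuple(pass_pairs),
        fail_confidence=tuple(fail_conf),
        fail_interface=tuple(fail_iface),
        orientations=orientations,
        homodimer_pairs=tuple(p for p in pass_pairs if p[0] == p[1]),
        residues_per_domain=residues_per_domain,
    )
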