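"""Geometry and confidence metrics on predicted two-chain coordinate models.

Readers for PDB/mmCIF coordinate models (pLDDT in the B-factor column) and
for predicted-aligned-error (PAE) matrices, plus the metrics the dimer
screen needs: per-chain/region pLDDT summaries, the cross-chain mean PAE
(iPAE), distance-based interface residues, disulfide detection from S-gamma
positions, cross-chain beta-ladder runs from main-chain N–O hydrogen-bond
distances, domain axes, relative-orientation classification
(Standard / Flipped / FlippedShifted) and Kabsch superposition RMSD.

gemmi backs the file parsing; everything downstream operates on the plain
in-memory :class:`StructureModel`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .seqfeatures import RegionAnnotation

logger = logging.getLogger(__name__)

PAE_CEILING = 31.75  # conventional ceiling of the PAE colour scale, Å

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "PaeMatrix",
    "OrientationCall",
    "read_structure",
    "write_structure",
    "read_pae",
    "plddt_summary",
    "confidence_class",
    "compute_ipae",
    "interface_residues",
    "detect_disulfides",
    "cross_chain_beta_ladder",
    "domain_axis",
    "classify_orientation",
    "kabsch_rmsd",
]


@dataclass
class Atom:
    name: str
    xyz: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    index: int  # 1-based sequence position
    name: str  # three-letter residue name
    atoms: Dict[str, Atom] = field(default_factory=dict)
    bfactor: Optional[float] = None  # pLDDT (0-100) in predicted models

    def atom_xyz(self, name: str) -> Optional[np.ndarray]:
        a = self.atoms.get(name)
        return None if a is None else a.xyz


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"residue indices not strictly increasing in chain {self.chain_id}")

    def __len__(self) -> int:
        return len(self.residues)

    def heavy_atoms(self) -> Tuple[np.ndarray, np.ndarray]:
        """(coords (m,3), residue index per atom) over all heavy atoms."""
        coords, ridx = [], []
        for r in self.residues:
            for a in r.atoms.values():
                coords.append(a.xyz)
                ridx.append(r.index)
        if not coords:
            return np.empty((0, 3)), np.empty((0,), dtype=int)
        return np.vstack(coords), np.asarray(ridx, dtype=int)

    def ca_coords(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        wanted = None if indices is None else set(indices)
        out = [
            r.atoms["CA"].xyz
            for r in self.residues
            if "CA" in r.atoms and (wanted is None or r.index in wanted)
        ]
        return np.vstack(out) if out else np.empty((0, 3))


@dataclass
class StructureModel:
    """A coordinate model: one or more chains of residues with heavy atoms."""

    chains: List[Chain]
    name: str = "model"

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("model must contain at least one chain")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id}")

    @property
    def has_plddt(self) -> bool:
        return all(
            r.bfactor is not None for c in self.chains for r in c.residues
        ) and any(r.bfactor for c in self.chains for r in c.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains = []
        for c in self.chains:
            residues = [
                Residue(
                    index=r.index,
                    name=r.name,
                    atoms={n: Atom(n, R @ a.xyz + t) for n, a in r.atoms.items()},
                    bfactor=r.bfactor,
                )
                for r in c.residues
            ]
            chains.append(Chain(c.chain_id, residues))
        return StructureModel(chains=chains, name=self.name)


def read_structure(path) -> StructureModel:
    """Read a PDB (or mmCIF) file into a StructureModel.

    The first model of a multi-model file is used (with a logged warning);
    altloc 'A'/blank is preferred; hydrogens are dropped.  B-factors are
    exposed per residue as pLDDT (the residue's CA B-factor, falling back
    to the mean over its atoms).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if len(st) > 1:
        logger.warning("%s has %d models; using the first", path, len(st))
    model = st[0]
    chains: List[Chain] = []
    for ch in model:
        residues: List[Residue] = []
        for res in ch:
            atoms: Dict[str, Atom] = {}
            bfs: List[float] = []
            for at in res:
                if at.is_hydrogen():
                    continue
                if at.altloc not in ("", "A", "\x00"):
                    continue
                atoms[at.name] = Atom(at.name, np.array([at.pos.x, at.pos.y, at.pos.z]))
                bfs.append(at.b_iso)
            if not atoms:
                continue
            ca = res.find_atom("CA", "A")
            b = float(ca.b_iso) if ca is not None else (sum(bfs) / len(bfs) if bfs else None)
            residues.append(Residue(index=res.seqid.num, name=res.name, atoms=atoms, bfactor=b))
        if residues:
            chains.append(Chain(ch.name, residues))
    if not chains or not any(len(c) for c in chains):
        raise ValueError(f"no atoms parsed from {path}")
    return StructureModel(chains=chains, name=str(path))


def write_structure(model: StructureModel, path) -> None:
    """Write a model to PDB via gemmi, pLDDT in the B-factor column."""
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model("1")
    for c in model.chains:
        gc = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.index, " ")
            for a in r.atoms.values():
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.name[:1])
                ga.pos = gemmi.Position(*a.xyz)
                ga.b_iso = 0.0 if r.bfactor is None else float(r.bfactor)
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# pLDDT


def confidence_class(plddt: float) -> str:
    """Confidence bracket of a pLDDT value.

    Brackets: very-high (90, 100], high (70, 90], low [50, 70],
    very-low [0, 50).  Exactly 70 falls in "low"'s closed upper bound?
    No — (70, 90] is high and [50, 70] is low, so 70 itself is "low";
    50 is "low"; 90 is "high".
    """
    if plddt > 90:
        return "very-high"
    if plddt > 70:
        return "high"
    if plddt >= 50:
        return "low"
    return "very-low"


def plddt_summary(
    model: StructureModel,
    regions: Optional[Mapping[str, RegionAnnotation]] = None,
) -> pd.DataFrame:
    """Mean pLDDT per chain (and per annotated region) with confidence class.

    ``regions`` maps chain id -> RegionAnnotation; rows are emitted for each
    whole chain and for every named region on it.
    """
    if not model.has_plddt:
        raise ValueError("model has no pLDDT (B-factor) values")
    rows = []
    for c in model.chains:
        vals = np.array([r.bfactor for r in c.residues], dtype=float)
        rows.append(
            {
                "chain": c.chain_id,
                "region": "all",
                "n_residues": len(vals),
                "mean_plddt": float(vals.mean()),
                "class": confidence_class(float(vals.mean())),
            }
        )
        ann = regions.get(c.chain_id) if regions else None
        if ann is not None:
            for name, (start, end) in ann.regions.items():
                sel = np.array(
                    [r.bfactor for r in c.residues if start <= r.index <= end], dtype=float
                )
                if sel.size == 0:
                    continue
                rows.append(
                    {
                        "chain": c.chain_id,
                        "region": name,
                        "n_residues": sel.size,
                        "mean_plddt": float(sel.mean()),
                        "class": confidence_class(float(sel.mean())),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PAE


@dataclass
class PaeMatrix:
    """Square predicted-aligned-error matrix (Å) with a two-chain partition."""

    values: np.ndarray
    chain_lengths: Tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n1, n2 = self.chain_lengths
        if self.values.shape != (n1 + n2, n1 + n2):
            raise ValueError(
                f"PAE shape {self.values.shape} does not match chain lengths {self.chain_lengths}"
            )
        if np.any(self.values < 0):
            raise ValueError("PAE entries must be non-negative")

    def cross_chain_blocks(self) -> Tuple[np.ndarray, np.ndarray]:
        n1, _ = self.chain_lengths
        return self.values[:n1, n1:], self.values[n1:, :n1]


def read_pae(path, chain_lengths: Tuple[int, int]) -> PaeMatrix:
    """Read a PAE matrix from JSON ("predicted_aligned_error" key, possibly
    wrapped in a one-element list) or a whitespace-delimited text matrix."""
    text = open(path).read()
    stripped = text.lstrip()
    if stripped.startswith("{") or stripped.startswith("["):
        obj = json.loads(text)
        if isinstance(obj, list):
            obj = obj[0]
        try:
            values = np.asarray(obj["predicted_aligned_error"], dtype=float)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"no 'predicted_aligned_error' key in {path}") from exc
    else:
        values = np.loadtxt(path)
    return PaeMatrix(values=values, chain_lengths=chain_lengths)


def write_pae_json(pae: PaeMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump({"predicted_aligned_error": pae.values.tolist()}, fh)


def compute_ipae(
    pae: PaeMatrix,
    mode: str = "chain",
    domain_annotations: Optional[Mapping[str, RegionAnnotation]] = None,
) -> float:
    """Interface PAE: mean expected error across the two cross-chain blocks.

    ``mode='chain'`` (default) averages every entry of the chain-1 x chain-2
    and chain-2 x chain-1 blocks.  ``mode='domain'`` averages only entries
    whose row and column both fall inside annotated DUF26 domains of the
    respective chains (still cross-chain) — the alternative reading of a
    per-domain average.
    """
    n1, n2 = pae.chain_lengths
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-size chain block")
    b12, b21 = pae.cross_chain_blocks()
    if mode == "chain":
        return float((b12.sum() + b21.sum()) / (b12.size + b21.size))
    if mode == "domain":
        if not domain_annotations or len(domain_annotations) < 2:
            raise ValueError("domain mode needs annotations for both chains")
        ids = list(domain_annotations)
        masks = []
        for cid, n in zip(ids[:2], (n1, n2)):
            m = np.zeros(n, dtype=bool)
            for start, end in domain_annotations[cid].regions.values():
                m[start - 1 : end] = True
            masks.append(m)
        sel12 = b12[np.ix_(masks[0], masks[1])]
        sel21 = b21[np.ix_(masks[1], masks[0])]
        return float((sel12.sum() + sel21.sum()) / (sel12.size + sel21.size))
    raise ValueError(f"unknown iPAE mode {mode!r}")


# ---------------------------------------------------------------------------
# interfaces, disulfides, ladders


def interface_residues(
    model: StructureModel, cutoff: float = 5.0
) -> Dict[str, Tuple[int, ...]]:
    """Residues of each chain with any heavy atom within ``cutoff`` Å of the
    other chain's heavy atoms.  Requires exactly two chains."""
    if len(model.chains) != 2:
        raise ValueError("interface_residues requires exactly 2 chains")
    c1, c2 = model.chains
    x1, r1 = c1.heavy_atoms()
    x2, r2 = c2.heavy_atoms()
    if x1.size == 0 or x2.size == 0:
        return {c1.chain_id: (), c2.chain_id: ()}
    d = np.linalg.norm(x1[:, None, :] - x2[None, :, :], axis=-1)
    close = d <= cutoff
    set1 = tuple(sorted(set(r1[close.any(axis=1)].tolist())))
    set2 = tuple(sorted(set(r2[close.any(axis=0)].tolist())))
    return {c1.chain_id: set1, c2.chain_id: set2}


def interface_counts(model: StructureModel, cutoff: float = 5.0) -> Tuple[int, int, int]:
    """(count chain 1, count chain 2, total) interface residues."""
    res = interface_residues(model, cutoff)
    (a, b) = (len(v) for v in res.values())
    return a, b, a + b


@dataclass(frozen=True)
class DisulfideBond:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    distance: float
    interchain: bool
    vicinal: bool  # sequentially adjacent cysteines on one chain


def detect_disulfides(model: StructureModel, sg_cutoff: float = 2.5) -> List[DisulfideBond]:
    """Pair cysteines whose S-gamma atoms lie within ``sg_cutoff`` Å.

    Greedy nearest-first pairing, ties broken by (chain, residue index);
    each cysteine joins at most one bond.  Cysteines lacking an SG atom
    fall back to CB with a relaxed cutoff (+2.0 Å).
    """
    cys = []  # (chain_id, res_index, xyz, used_fallback)
    for c in model.chains:
        for r in c.residues:
            if r.name != "CYS":
                continue
            xyz = r.atom_xyz("SG")
            fallback = False
            if xyz is None:
                xyz = r.atom_xyz("CB")
                fallback = True
            if xyz is not None:
                cys.append((c.chain_id, r.index, xyz, fallback))
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            ci, ri, xi, fi = cys[i]
            cj, rj, xj, fj = cys[j]
            if ci == cj and ri == rj:
                continue
            cut = sg_cutoff + (2.0 if (fi or fj) else 0.0)
            dist = float(np.linalg.norm(xi - xj))
            if dist <= cut:
                candidates.append((dist, (ci, ri), (cj, rj)))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used = set()
    bonds = []
    for dist, a, b in candidates:
        if a in used or b in used:
            continue
        used.add(a)
        used.add(b)
        bonds.append(
            DisulfideBond(
                chain_a=a[0],
                res_a=a[1],
                chain_b=b[0],
                res_b=b[1],
                distance=dist,
                interchain=a[0] != b[0],
                vicinal=a[0] == b[0] and abs(a[1] - b[1]) == 1,
            )
        )
    return bonds


@dataclass(frozen=True)
class LadderSegment:
    """A run of consecutive cross-chain backbone hydrogen-bonded residue pairs."""

    chain_a: str
    range_a: Tuple[int, int]
    chain_b: str
    range_b: Tuple[int, int]
    length: int


def cross_chain_beta_ladder(
    model: StructureModel, no_dist: float = 3.5, min_run: int = 3
) -> List[LadderSegment]:
    """Detect cross-chain beta-ladder runs from main-chain N–O distances.

    A residue pair (i on chain 1, j on chain 2) is hydrogen-bonded when
    either N_i–O_j or O_i–N_j is <= ``no_dist`` Å.  Bonded pairs are chained
    into runs where both i and j advance by one (in either direction on
    chain 2); only runs of length >= ``min_run`` are reported.
    """
    if len(model.chains) != 2:
        raise ValueError("requires exactly 2 chains")
    c1, c2 = model.chains

    def backbone(chain: Chain, name: str):
        idx, coords = [], []
        for r in chain.residues:
            xyz = r.atom_xyz(name)
            if xyz is not None:
                idx.append(r.index)
                coords.append(xyz)
        return idx, (np.vstack(coords) if coords else np.empty((0, 3)))

    n1i, n1 = backbone(c1, "N")
    o1i, o1 = backbone(c1, "O")
    n2i, n2 = backbone(c2, "N")
    o2i, o2 = backbone(c2, "O")
    if min(len(n1i), len(o1i), len(n2i), len(o2i)) == 0:
        logger.warning("missing backbone N/O atoms; ladder detection skipped")
        return []

    pairs = set()
    if n1.size and o2.size:
        d = np.linalg.norm(n1[:, None, :] - o2[None, :, :], axis=-1)
        for a, b in zip(*np.nonzero(d <= no_dist)):
            pairs.add((n1i[a], o2i[b]))
    if o1.size and n2.size:
        d = np.linalg.norm(o1[:, None, :] - n2[None, :, :], axis=-1)
        for a, b in zip(*np.nonzero(d <= no_dist)):
            pairs.add((o1i[a], n2i[b]))

    segments: List[LadderSegment] = []
    seen = set()
    for direction in (1, -1):
        for (i, j) in sorted(pairs):
            if (i - 1, j - direction) in pairs:
                continue  # not a run start in this direction
            run = []
            a, b = i, j
            while (a, b) in pairs:
                run.append((a, b))
                a, b = a + 1, b + direction
            if len(run) >= min_run:
                key = (run[0], run[-1])
                if key in seen or (key[1], key[0]) in seen:
                    continue
                seen.add(key)
                aa = [p[0] for p in run]
                bb = [p[1] for p in run]
                segments.append(
                    LadderSegment(
                        chain_a=c1.chain_id,
                        range_a=(min(aa), max(aa)),
                        chain_b=c2.chain_id,
                        range_b=(min(bb), max(bb)),
                        length=len(run),
                    )
                )
    segments.sort(key=lambda s: (s.range_a, s.range_b))
    # de-duplicate runs fully contained in a longer reported run
    kept: List[LadderSegment] = []
    for s in segments:
        contained = any(
            k.range_a[0] <= s.range_a[0] and s.range_a[1] <= k.range_a[1] and k.length > s.length
            for k in segments
        )
        if not contained:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# orientation


def domain_axis(model: StructureModel, chain_id: str, annotation: RegionAnnotation) -> np.ndarray:
    """Unit vector from the DUF26-A CA centroid to the DUF26-B CA centroid."""
    chain = model.chain(chain_id)
    try:
        a_start, a_end = annotation.regions["DUF26-A"]
        b_start, b_end = annotation.regions["DUF26-B"]
    except KeyError as exc:
        raise ValueError("annotation must define DUF26-A and DUF26-B") from exc
    ca_a = chain.ca_coords(range(a_start, a_end + 1))
    ca_b = chain.ca_coords(range(b_start, b_end + 1))
    if ca_a.size == 0 or ca_b.size == 0:
        raise ValueError(f"no CA atoms in annotated domains of chain {chain_id}")
    v = ca_b.mean(axis=0) - ca_a.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate axis: coincident domain centroids")
    return v / norm


@dataclass(frozen=True)
class OrientationCall:
    """Result of the relative-orientation decision rule for a dimer."""

    label: str  # Standard | Flipped | FlippedShifted | Unclassified
    dominant_pairing: Optional[str]  # "B:B", "A:B" or "A:A"
    axis_angle_deg: Optional[float]
    axial_offset: Optional[float]
    contact_counts: Dict[str, int] = field(default_factory=dict)
    reason: str = ""


def _domain_of(index: int, annotation: RegionAnnotation) -> Optional[str]:
    for name in ("DUF26-A", "DUF26-B"):
        start, end = annotation.regions[name]
        if start <= index <= end:
            return "A" if name.endswith("A") else "B"
    return None


def classify_orientation(
    model: StructureModel,
    annotations: Mapping[str, RegionAnnotation],
    cutoff: float = 5.0,
    parallel_angle_deg: float = 60.0,
    shift_frac: float = 0.5,
) -> OrientationCall:
    """Classify the relative orientation of a two-chain ectodomain dimer.

    Decision rule:

    1. tabulate cross-chain residue contacts (heavy-atom distance <=
       ``cutoff``) by domain pairing; dominant pairing is the argmax of
       {B:B, A:B (summed with B:A), A:A};
    2. theta = angle between the two chains' A->B domain axes;
    3. label Standard if dominant B:B and theta < ``parallel_angle_deg``;
       Flipped if dominant A:B; FlippedShifted if dominant B:B, theta >=
       180 - ``parallel_angle_deg`` and the axial offset of the chain
       centroids exceeds ``shift_frac`` x mean domain length; Unclassified
       otherwise (including dominant A:A or no contacts).
    """
    if len(model.chains) != 2:
        raise ValueError("requires exactly 2 chains")
    c1, c2 = model.chains
    ann1, ann2 = annotations[c1.chain_id], annotations[c2.chain_id]

    # contact pairs at residue level
    x1, r1 = c1.heavy_atoms()
    x2, r2 = c2.heavy_atoms()
    d = np.linalg.norm(x1[:, None, :] - x2[None, :, :], axis=-1)
    contact_pairs = {
        (int(r1[a]), int(r2[b])) for a, b in zip(*np.nonzero(d <= cutoff))
    }
    counts = {"B:B": 0, "A:B": 0, "A:A": 0}
    for i, j in contact_pairs:
        di, dj = _domain_of(i, ann1), _domain_of(j, ann2)
        if di is None or dj is None:
            continue
        if di == "B" and dj == "B":
            counts["B:B"] += 1
        elif di == "A" and dj == "A":
            counts["A:A"] += 1
        else:
            counts["A:B"] += 1
    total = sum(counts.values())
    if total == 0:
        return OrientationCall(
            label="Unclassified",
            dominant_pairing=None,
            axis_angle_deg=None,
            axial_offset=None,
            contact_counts=counts,
            reason="no cross-chain contacts",
        )
    dominant = max(counts, key=lambda k: (counts[k], k))

    axis1 = domain_axis(model, c1.chain_id, ann1)
    axis2 = domain_axis(model, c2.chain_id, ann2)
    cosang = float(np.clip(np.dot(axis1, axis2), -1.0, 1.0))
    theta = math.degrees(math.acos(cosang))

    cent1 = c1.ca_coords().mean(axis=0)
    cent2 = c2.ca_coords().mean(axis=0)
    axial_offset = abs(float(np.dot(cent2 - cent1, axis1)))

    def _domain_length(chain: Chain, ann: RegionAnnotation) -> float:
        a = chain.ca_coords(range(*_incl(ann.regions["DUF26-A"]))).mean(axis=0)
        b = chain.ca_coords(range(*_incl(ann.regions["DUF26-B"]))).mean(axis=0)
        return float(np.linalg.norm(b - a))

    dom_len = 0.5 * (_domain_length(c1, ann1) + _domain_length(c2, ann2))

    label = "Unclassified"
    reason = ""
    if dominant == "A:B":
        label = "Flipped"
    elif dominant == "B:B":
        if theta < parallel_angle_deg:
            label = "Standard"
        elif theta >= 180.0 - parallel_angle_deg and axial_offset > shift_frac * dom_len:
            label = "FlippedShifted"
        else:
            reason = "B:B contacts but axis geometry matches no class"
    else:
        reason = "dominant A:A pairing"
    return OrientationCall(
        label=label,
        dominant_pairing=dominant,
        axis_angle_deg=theta,
        axial_offset=axial_offset,
        contact_counts=counts,
        reason=reason,
    )


def _incl(interval: Tuple[int, int]) -> Tuple[int, int]:
    return interval[0], interval[1] + 1


# ---------------------------------------------------------------------------
# superposition


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after least-squares rigid superposition (Kabsch, proper rotation).

    Both inputs are (n, 3) arrays of paired coordinates, n >= 3.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate lists must have equal shapes")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need (n, 3) arrays with n >= 3")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    diff = Bc - Ac @ R.T
    return float(np.sqrt((diff**2).sum() / A.shape[0]))
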