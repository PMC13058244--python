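"""The dimer-screening pipeline.

Enumerate candidate pairs, pick the best of the five predicted models per
pair, apply the confidence cutoffs (combined ipTM/pTM score and cross-chain
iPAE), characterize interfaces, derive the adaptive interface-residue
cutoff (ceil of mean minus one sample SD over passing models), apply it,
classify orientations and summarize stage counts.

The combined score defaults to the standard multimer ranking confidence
0.8*ipTM + 0.2*pTM (range 0 to 1); a raw ipTM+pTM sum (range 0 to 2) is
available via ``combined_mode='sum'``.  Cutoff inequalities are strict
(score > cutoff, iPAE < cutoff) by default.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import structmodel as sm
from .seqfeatures import RegionAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "enumerate_pairs",
    "combined_score",
    "confidence_filter",
    "select_best_model",
    "adaptive_interface_cutoff",
    "interface_filter",
    "run_screen",
    "summarize_orientations",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and modes of the screening pipeline."""

    combined_score_cutoff: float = 0.8
    ipae_cutoff: float = 6.0  # Å
    models_per_pair: int = 5
    interface_distance: float = 5.0  # Å
    adaptive_cutoff_mode: str = "mean_minus_sd"  # or "fixed"
    fixed_interface_cutoff: Optional[int] = None
    include_self_pairs: bool = True
    combined_mode: str = "weighted"  # "weighted" (0.8/0.2) or "sum"
    interface_rule: str = "per_chain"  # or "total"
    inclusive_cutoffs: bool = False

    def __post_init__(self) -> None:
        if self.combined_score_cutoff <= 0 or self.ipae_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.models_per_pair < 1:
            raise ValueError("models_per_pair must be >= 1")
        if self.adaptive_cutoff_mode not in ("mean_minus_sd", "fixed"):
            raise ValueError("unknown adaptive_cutoff_mode")
        if self.adaptive_cutoff_mode == "fixed" and self.fixed_interface_cutoff is None:
            raise ValueError("fixed mode requires fixed_interface_cutoff")


def enumerate_pairs(ids: Sequence[str], include_self: bool = True) -> List[Tuple[str, str]]:
    """All unordered pairs in canonical (lexicographic) order.

    With self-pairs: n(n-1)/2 + n pairs (38 ids -> 741); without:
    n(n-1)/2 (40 ids -> 780).
    """
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    ordered = sorted(ids)
    pairs = []
    for i, a in enumerate(ordered):
        start = i if include_self else i + 1
        for b in ordered[start:]:
            pairs.append((a, b))
    return pairs


def combined_score(iptm: float, ptm: float, mode: str = "weighted") -> float:
    if mode == "weighted":
        return 0.8 * iptm + 0.2 * ptm
    if mode == "sum":
        return iptm + ptm
    raise ValueError(f"unknown combined mode {mode!r}")


def confidence_filter(
    combined: Optional[float], ipae: Optional[float], cfg: ScreenConfig
) -> Tuple[bool, str]:
    """Apply the confidence cutoffs; returns (pass, reason)."""
    if combined is None or ipae is None or not (math.isfinite(combined) and math.isfinite(ipae)):
        return False, "missing"
    if cfg.inclusive_cutoffs:
        score_ok = combined >= cfg.combined_score_cutoff
        ipae_ok = ipae <= cfg.ipae_cutoff
    else:
        score_ok = combined > cfg.combined_score_cutoff
        ipae_ok = ipae < cfg.ipae_cutoff
    if score_ok and ipae_ok:
        return True, "pass"
    reasons = []
    if not score_ok:
        reasons.append("combined_score")
    if not ipae_ok:
        reasons.append("ipae")
    return False, "+".join(reasons)


def select_best_model(models: pd.DataFrame, cfg: ScreenConfig) -> Optional[int]:
    """Choose the best model rank for one pair, or None if none pass.

    Among models passing the confidence filter, the highest combined score
    wins; ties break to lowest iPAE, then lowest model rank.
    """
    if models.empty:
        raise ValueError("need at least one model row")
    passing = []
    for _, row in models.iterrows():
        ok, _ = confidence_filter(row.get("combined"), row.get("ipae"), cfg)
        if ok:
            passing.append((-row["combined"], row["ipae"], int(row["model_rank"])))
    if not passing:
        return None
    passing.sort()
    return passing[0][2]


def adaptive_interface_cutoff(counts: Sequence[float]) -> Tuple[int, float, float]:
    """Interface-count cutoff: ceil(mean - 1 sample SD), with mean and SD.

    The worked case: mean 34, SD 5.5 -> ceil(28.5) = 29.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 counts")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    return int(math.ceil(mean - sd)), mean, sd


def interface_filter(
    count_a: int, count_b: int, cutoff: int, rule: str = "per_chain"
) -> bool:
    """Pass iff each chain has >= cutoff interface residues (default), or
    the complex total does (``rule='total'``)."""
    if rule == "per_chain":
        return count_a >= cutoff and count_b >= cutoff
    if rule == "total":
        return count_a + count_b >= cutoff
    raise ValueError(f"unknown interface rule {rule!r}")


def _read_annotations(path) -> Dict[str, RegionAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["chain"]), {})[str(row["region"])] = (
            int(row["start"]),
            int(row["end"]),
        )
    return {cid: RegionAnnotation(seq_id=cid, regions=regs) for cid, regs in out.items()}


def run_screen(
    models_dir,
    pae_dir,
    scores,
    annotations,
    cfg: ScreenConfig = ScreenConfig(),
) -> Tuple[pd.DataFrame, Dict]:
    """Run the full screen over a directory cohort.

    ``scores`` is a TSV path or DataFrame with columns id1, id2,
    model_rank, iptm, ptm (combined recomputed if absent); model and PAE
    files are expected as ``{id1}__{id2}_rank{r}.pdb`` under ``models_dir``
    and ``...rank{r}.json`` under ``pae_dir``.  ``annotations`` is a TSV
    path or mapping of chain id -> RegionAnnotation shared by all fixtures.

    Returns the per-pair record table (sorted by canonical pair id) and a
    summary dict with stage counts and the retained percentage.
    """
    models_dir, pae_dir = Path(models_dir), Path(pae_dir)
    table = pd.read_csv(scores, sep="\t") if not isinstance(scores, pd.DataFrame) else scores.copy()
    if "combined" not in table.columns:
        table["combined"] = [
            combined_score(r.iptm, r.ptm, cfg.combined_mode) for r in table.itertuples()
        ]
    ann = annotations if isinstance(annotations, Mapping) else _read_annotations(annotations)

    records: List[Dict] = []
    for (id1, id2), group in sorted(table.groupby(["id1", "id2"], sort=True)):
        a, b = sorted((str(id1), str(id2)))
        pair_id = f"{a}--{b}"
        group = group.copy()
        # iPAE per model from the PAE files
        ipaes, incomplete = {}, False
        for rank in group["model_rank"]:
            pae_path = pae_dir / f"{a}__{b}_rank{int(rank)}.json"
            if not pae_path.exists():
                incomplete = True
                continue
            # chain lengths from the matching model file
            model_path = models_dir / f"{a}__{b}_rank{int(rank)}.pdb"
            if not model_path.exists():
                incomplete = True
                continue
            model = sm.read_structure(model_path)
            if len(model.chains) != 2:
                raise ValueError(f"{model_path} is not a two-chain model")
            lengths = (len(model.chains[0]), len(model.chains[1]))
            ipaes[int(rank)] = sm.compute_ipae(sm.read_pae(pae_path, lengths))
        group["ipae"] = [ipaes.get(int(r), np.nan) for r in group["model_rank"]]

        best = select_best_model(group, cfg)
        rec: Dict = {
            "pair": pair_id,
            "id1": a,
            "id2": b,
            "is_homodimer": a == b,
            "chosen_rank": best,
            "passed_confidence": best is not None,
            "incomplete": incomplete,
        }
        if best is not None:
            row = group[group["model_rank"] == best].iloc[0]
            rec.update(
                iptm=float(row["iptm"]),
                ptm=float(row["ptm"]),
                combined=float(row["combined"]),
                ipae=float(row["ipae"]),
            )
            model = sm.read_structure(models_dir / f"{a}__{b}_rank{best}.pdb")
            ca, cb, _ = sm.interface_counts(model, cfg.interface_distance)
            rec.update(iface_a=ca, iface_b=cb)
            call = sm.classify_orientation(model, ann, cutoff=cfg.interface_distance)
            rec.update(orientation=call.label, dominant_pairing=call.dominant_pairing)
        else:
            rec.update(
                iptm=np.nan, ptm=np.nan, combined=np.nan, ipae=np.nan,
                iface_a=np.nan, iface_b=np.nan, orientation=None, dominant_pairing=None,
            )
        records.append(rec)

    df = pd.DataFrame(records).sort_values("pair").reset_index(drop=True)

    passing = df[df["passed_confidence"]]
    if cfg.adaptive_cutoff_mode == "fixed":
        cutoff, mean, sd = int(cfg.fixed_interface_cutoff), float("nan"), float("nan")
    else:
        pooled = list(passing["iface_a"]) + list(passing["iface_b"])
        if len(pooled) >= 2:
            cutoff, mean, sd = adaptive_interface_cutoff(pooled)
        else:
            cutoff, mean, sd = 0, float("nan"), float("nan")
    df["passed_interface"] = [
        bool(r.passed_confidence)
        and interface_filter(int(r.iface_a), int(r.iface_b), cutoff, cfg.interface_rule)
        if r.passed_confidence
        else False
        for r in df.itertuples()
    ]

    n_enum = len(df)
    n_conf = int(df["passed_confidence"].sum())
    n_kept = int(df["passed_interface"].sum())
    summary = {
        "n_enumerated": n_enum,
        "n_confidence_passed": n_conf,
        "n_interface_passed": n_kept,
        "retained_percent": int(math.floor(100.0 * n_kept / n_enum + 0.5)) if n_enum else 0,
        "interface_cutoff": cutoff,
        "interface_count_mean": mean,
        "interface_count_sd": sd,
        "config": {
            "combined_score_cutoff": cfg.combined_score_cutoff,
            "ipae_cutoff": cfg.ipae_cutoff,
            "interface_distance": cfg.interface_distance,
            "adaptive_cutoff_mode": cfg.adaptive_cutoff_mode,
            "combined_mode": cfg.combined_mode,
            "interface_rule": cfg.interface_rule,
        },
    }
    return df, summary


def summarize_orientations(
    records: pd.DataFrame, groups: Optional[Mapping[str, str]] = None
) -> Dict:
    """Orientation label fractions over classified retained records.

    With a member->group map, per-group tallies count every dimer containing
    a member of the group (a heterodimer spanning two groups counts toward
    both).
    """
    kept = records[records.get("passed_interface", True) & records["orientation"].notna()]
    kept = kept[kept["orientation"] != "Unclassified"]
    total = len(kept)
    fractions = {}
    if total:
        for label, count in kept["orientation"].value_counts().items():
            fractions[label] = {
                "count": int(count),
                "percent": int(math.floor(100.0 * count / total + 0.5)),
            }
    by_group: Dict[str, Dict[str, int]] = {}
    if groups is not None:
        for r in kept.itertuples():
            for g in {groups.get(r.id1, "unknown"), groups.get(r.id2, "unknown")}:
                by_group.setdefault(g, {}).setdefault(r.orientation, 0)
                by_group[g][r.orientation] += 1
    return {"n_classified": total, "fractions": fractions, "by_group": by_group}


def write_outputs(records: pd.DataFrame, summary: Dict, out_dir) -> None:
    """Write the record table, JSON summary, and retained-pair edge list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "screen_records.tsv", sep="\t", index=False)
    with open(out / "screen_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    kept = records[records["passed_interface"]]
    kept[["id1", "id2"]].to_csv(out / "retained_pairs.tsv", sep="\t", index=False)
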