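"""Per-drug cellular refinement on the three image-derived parameters.

For every drug, the quadruplicate embryos' means of (1) AChR cluster
count, (2) NMJ overlap percent, and (3) mean axon length are z-scored
against wild-type embryos with the same robust median/MAD convention as
the behavioral screen.  A parameter is "rescued" when its z exceeds the
threshold; a final hit must rescue the two NMJ parameters (1) and (2).
Group differences use a Kruskal-Wallis omnibus gate followed by pairwise
rank-sum tests with an explicit Holm step-down correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .behavior_scoring import _guarded_mad, mad
from .nmj_imaging import CellularMetrics

__all__ = [
    "CellularScore",
    "GroupComparison",
    "PARAMETERS",
    "cellular_z",
    "rescue_call",
    "group_compare",
    "holm_adjust",
    "hitmap",
]

#: the three scored parameters, in axis order (1), (2), (3)
PARAMETERS = ("n_achr_clusters", "overlap_percent", "mean_axon_length_um")


@dataclass(frozen=True)
class CellularScore:
    drug_id: str
    z3: tuple[float, float, float]
    rescue_flags: tuple[bool, bool, bool]
    final_hit: bool


def _values(metrics: Sequence[CellularMetrics], parameter: str) -> list[float]:
    out = []
    for m in metrics:
        v = getattr(m, parameter)
        if v is None:
            continue
        out.append(float(v))
    return out


def cellular_z(
    drug_metrics: Sequence[CellularMetrics],
    wt_metrics: Sequence[CellularMetrics],
    parameters: Sequence[str] = PARAMETERS,
) -> tuple[float, ...]:
    """z_p = (mean over the drug's embryos - median(WT)) / mad(WT) per parameter."""
    if len(wt_metrics) < 3:
        raise ValueError("need at least 3 wild-type embryos")
    if not drug_metrics:
        raise ValueError("no embryos for drug")
    zs = []
    for p in parameters:
        wt = _values(wt_metrics, p)
        dv = _values(drug_metrics, p)
        if not wt or not dv:
            raise ValueError(f"parameter {p}: missing values")
        z = (float(np.mean(dv)) - float(np.median(wt))) / _guarded_mad(wt)
        zs.append(float(z))
    return tuple(zs)


def rescue_call(
    z3: Sequence[float], z_threshold: float = -1.0
) -> tuple[tuple[bool, ...], bool]:
    """Flag each parameter rescued when z > threshold; final hit requires the
    two NMJ parameters (cluster count and overlap) both rescued."""
    if any(not np.isfinite(z) for z in z3):
        raise ValueError("z3 must be finite")
    flags = tuple(z > z_threshold for z in z3)
    return flags, bool(flags[0] and flags[1])


def score_drug(
    drug_id: str,
    drug_metrics: Sequence[CellularMetrics],
    wt_metrics: Sequence[CellularMetrics],
    z_threshold: float = -1.0,
) -> CellularScore:
    z3 = cellular_z(drug_metrics, wt_metrics)
    flags, final = rescue_call(z3, z_threshold)
    return CellularScore(drug_id=drug_id, z3=z3, rescue_flags=flags, final_hit=final)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, returned in the input order.

    Sort ascending; adjusted_i = max_{j<=i} min(1, (m-j+1) * p_(j)) with
    1-based j over the sorted order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):  # rank 0-based
        val = min(1.0, (m - rank) * p_values[idx])
        running = max(running, val)
        adjusted[idx] = running
    return adjusted


@dataclass
class GroupComparison:
    groups: dict[str, list[float]]
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[dict]  # pair, statistic, raw_p, holm_adjusted_p
    omnibus_alpha: float

    def to_json_dict(self) -> dict:
        return {
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "omnibus_alpha": self.omnibus_alpha,
            "group_sizes": {k: len(v) for k, v in self.groups.items()},
            "pairwise": self.pairwise,
        }


def group_compare(
    groups: Mapping[str, Sequence[float]],
    omnibus_alpha: float = 0.05,
    exact_max_n: int = 12,
) -> GroupComparison:
    """Kruskal-Wallis omnibus; pairwise Mann-Whitney + Holm when it passes.

    Rank-sum tests use exact enumeration for combined n <= ``exact_max_n``
    and the tie-corrected normal approximation otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {k: [float(x) for x in v] for k, v in groups.items()}
    for k, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")

    try:
        stat, p = stats.kruskal(*clean.values())
    except ValueError:
        # all values identical across groups
        stat, p = 0.0, 1.0

    pairwise: list[dict] = []
    if p <= omnibus_alpha:
        pairs = list(itertools.combinations(sorted(clean), 2))
        raw = []
        for a, b in pairs:
            xa, xb = clean[a], clean[b]
            n_comb = len(xa) + len(xb)
            ties = len(set(xa + xb)) < n_comb
            method = "exact" if (n_comb <= exact_max_n and not ties) else "asymptotic"
            u, praw = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            raw.append(float(praw))
            pairwise.append({"pair": [a, b], "statistic": float(u), "raw_p": float(praw)})
        for rec, adj in zip(pairwise, holm_adjust(raw)):
            rec["holm_adjusted_p"] = float(adj)

    return GroupComparison(
        groups=clean,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        omnibus_alpha=omnibus_alpha,
    )


def hitmap(scores: Sequence[CellularScore]) -> dict:
    """Rank drugs by rescued-parameter count then mean z; count the tiers."""
    rows = []
    for s in scores:
        n_rescued = sum(s.rescue_flags)
        rows.append(
            {
                "drug_id": s.drug_id,
                "z_clusters": s.z3[0],
                "z_overlap": s.z3[1],
                "z_axon_length": s.z3[2],
                "rescued_clusters": s.rescue_flags[0],
                "rescued_overlap": s.rescue_flags[1],
                "rescued_axon_length": s.rescue_flags[2],
                "n_rescued": n_rescued,
                "final_hit": s.final_hit,
                "mean_z": float(np.mean(s.z3)),
            }
        )
    rows.sort(key=lambda r: (-r["n_rescued"], -r["mean_z"], r["drug_id"]))
    counts = {
        "all_three": sum(1 for r in rows if r["n_rescued"] == 3),
        "two_incl_nmj": sum(
            1
            for r in rows
            if r["n_rescued"] == 2 and r["rescued_clusters"] and r["rescued_overlap"]
        ),
        "fewer": sum(
            1
            for r in rows
            if not (
                r["n_rescued"] == 3
                or (r["n_rescued"] == 2 and r["rescued_clusters"] and r["rescued_overlap"])
            )
        ),
        "final_hits": sum(1 for r in rows if r["final_hit"]),
    }
    return {"table": rows, "counts": counts}
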