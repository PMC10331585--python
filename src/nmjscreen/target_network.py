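"""Drug-target recurrence filtering.

Builds a bipartite drug->target graph restricted to the behavioral hits,
keeps only high-confidence target-target interactions, counts for each
target how many distinct hit drugs address it ("recurrence"), and
partitions the hits into favorites (targeting a recurrent protein),
unknowns (no annotated target), and the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "DrugTargetGraph",
    "RecurrenceReport",
    "build_graph",
    "target_recurrence",
    "select_hits",
    "export_network",
    "read_pairs_table",
    "read_edges_table",
]


@dataclass
class DrugTargetGraph:
    drug_target_pairs: frozenset[tuple[str, str]]
    target_edges: frozenset[tuple[str, str, float]]  # canonical order a < b
    hit_ids: frozenset[str]
    confidence_cutoff: float = 0.7

    @property
    def targets(self) -> set[str]:
        out = {t for _, t in self.drug_target_pairs}
        for a, b, _ in self.target_edges:
            out.add(a)
            out.add(b)
        return out


@dataclass
class RecurrenceReport:
    recurrence: dict[str, int]
    recurrent_targets: set[str]
    favorite_hits: set[str]
    unknown_hits: set[str]
    other_hits: set[str]
    components: list[set[str]]
    recurrence_cutoff: int

    def to_json_dict(self) -> dict:
        return {
            "recurrence": dict(sorted(self.recurrence.items())),
            "recurrent_targets": sorted(self.recurrent_targets),
            "favorite_hits": sorted(self.favorite_hits),
            "unknown_hits": sorted(self.unknown_hits),
            "other_hits": sorted(self.other_hits),
            "components": [sorted(c) for c in self.components],
            "recurrence_cutoff": self.recurrence_cutoff,
        }


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"drug_id", "target_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_edges_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"target_a", "target_b", "confidence"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def build_graph(
    pairs: pd.DataFrame,
    edges: pd.DataFrame,
    hits: Iterable[str],
    confidence_cutoff: float = 0.7,
) -> DrugTargetGraph:
    """Assemble the filtered graph.

    Keeps drug->target pairs whose drug is a hit; keeps target-target edges
    with confidence >= ``confidence_cutoff`` (inclusive, per the STRING
    "high confidence" convention).  Undirected duplicates collapse to one
    edge keeping the maximum confidence; self-edges are dropped.
    """
    hit_set = frozenset(hits)
    kept_pairs = frozenset(
        (str(d), str(t))
        for d, t in zip(pairs["drug_id"], pairs["target_id"])
        if str(d) in hit_set
    )

    best: dict[tuple[str, str], float] = {}
    for a, b, c in zip(edges["target_a"], edges["target_b"], edges["confidence"]):
        c = float(c)
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"confidence {c} outside [0,1] for edge ({a}, {b})")
        a, b = str(a), str(b)
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if c > best.get(key, -1.0):
            best[key] = c
    kept_edges = frozenset(
        (a, b, c) for (a, b), c in best.items() if c >= confidence_cutoff
    )
    return DrugTargetGraph(
        drug_target_pairs=kept_pairs,
        target_edges=kept_edges,
        hit_ids=hit_set,
        confidence_cutoff=confidence_cutoff,
    )


def target_recurrence(graph: DrugTargetGraph) -> dict[str, int]:
    """Number of distinct hit drugs addressing each target."""
    counts: dict[str, set[str]] = {}
    for d, t in graph.drug_target_pairs:
        counts.setdefault(t, set()).add(d)
    return {t: len(ds) for t, ds in counts.items()}


def select_hits(
    graph: DrugTargetGraph,
    recurrence: Mapping[str, int] | None = None,
    recurrence_cutoff: int = 3,
) -> RecurrenceReport:
    """Partition hits by recurrence.

    A target is recurrent when its recurrence >= ``recurrence_cutoff``
    (inclusive 3 by default); favorite hits address at least one recurrent
    target; unknown hits have no annotated target at all and are carried to
    the next filtering stage regardless of recurrence.
    """
    if recurrence is None:
        recurrence = target_recurrence(graph)
    recurrent = {t for t, n in recurrence.items() if n >= recurrence_cutoff}

    by_drug: dict[str, set[str]] = {d: set() for d in graph.hit_ids}
    for d, t in graph.drug_target_pairs:
        by_drug.setdefault(d, set()).add(t)
    favorites = {d for d, ts in by_drug.items() if ts & recurrent}
    unknowns = {d for d in graph.hit_ids if not by_drug.get(d)}
    others = set(graph.hit_ids) - favorites - unknowns

    g = nx.Graph()
    g.add_nodes_from(t for _, t in graph.drug_target_pairs)
    g.add_weighted_edges_from(graph.target_edges)
    components = [set(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), min(c)))

    return RecurrenceReport(
        recurrence=dict(recurrence),
        recurrent_targets=recurrent,
        favorite_hits=favorites,
        unknown_hits=unknowns,
        other_hits=others,
        components=components,
        recurrence_cutoff=recurrence_cutoff,
    )


def export_network(
    graph: DrugTargetGraph,
    report: RecurrenceReport,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write nodes.tsv / edges.tsv / report.json suitable for graph viewers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    comp_of: dict[str, int] = {}
    for i, comp in enumerate(report.components):
        for t in comp:
            comp_of[t] = i

    nodes = []
    drugs_in_graph = sorted({d for d, _ in graph.drug_target_pairs} | set(graph.hit_ids))
    for d in drugs_in_graph:
        nodes.append(
            {
                "node_id": d,
                "node_type": "drug",
                "recurrence": "",
                "component": "",
                "favorite": d in report.favorite_hits,
                "unknown": d in report.unknown_hits,
            }
        )
    for t in sorted(graph.targets):
        nodes.append(
            {
                "node_id": t,
                "node_type": "target",
                "recurrence": report.recurrence.get(t, 0),
                "component": comp_of.get(t, ""),
                "favorite": "",
                "unknown": "",
            }
        )
    nodes_df = pd.DataFrame(
        nodes, columns=["node_id", "node_type", "recurrence", "component", "favorite", "unknown"]
    )

    edge_rows = [
        {"source": d, "target": t, "edge_type": "drug-target", "confidence": ""}
        for d, t in sorted(graph.drug_target_pairs)
    ] + [
        {"source": a, "target": b, "edge_type": "target-target", "confidence": c}
        for a, b, c in sorted(graph.target_edges)
    ]
    edges_df = pd.DataFrame(edge_rows, columns=["source", "target", "edge_type", "confidence"])

    paths = {
        "nodes": out_dir / "nodes.tsv",
        "edges": out_dir / "edges.tsv",
        "report": out_dir / "report.json",
    }
    nodes_df.to_csv(paths["nodes"], sep="\t", index=False)
    edges_df.to_csv(paths["edges"], sep="\t", index=False)
    paths["report"].write_text(json.dumps(report.to_json_dict(), indent=2, sort_keys=True))
    return paths
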