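"""Pathway-membership annotation and crosstalk-point scoring.

A node's crosstalk score is its total degree minus its within-pathway
degree, where a neighbor counts as "within pathway" if it shares at least
one pathway label with the node (nodes may belong to several pathways).
A node with a non-zero score bridges otherwise separate signaling arms and
is a crosstalk point.  Computed on the undirected simple view of the
interaction network.
"""

from __future__ import annotations

from typing import Dict, Mapping, Set

import pandas as pd

from .network import InteractionNetwork

__all__ = [
    "crosstalk_scores",
    "crosstalk_points",
    "annotation_to_frame",
    "annotation_from_frame",
]


def crosstalk_scores(
    network: InteractionNetwork,
    annotation: Mapping[str, Set[str]],
    *,
    require_all_shared: bool = False,
) -> Dict[str, int]:
    """Crosstalk score per node: deg_total - deg_within.

    ``require_all_shared=False`` (default) counts a neighbor as
    within-pathway when it shares any label; the stricter alternative
    requires every label of the node to be shared.
    Raises if a non-isolated node lacks annotation.
    """
    g = network.undirected()
    missing = sorted(
        v for v in g.nodes if g.degree(v) > 0 and not annotation.get(v)
    )
    if missing:
        raise ValueError(f"unannotated non-isolated nodes: {missing}")
    scores: Dict[str, int] = {}
    for v in g.nodes:
        tags_v = set(annotation.get(v, set()))
        within = 0
        for w in g.neighbors(v):
            shared = tags_v & set(annotation.get(w, set()))
            ok = tags_v <= set(annotation.get(w, set())) if require_all_shared else bool(shared)
            if ok:
                within += 1
        scores[v] = g.degree(v) - within
    return scores


def crosstalk_points(
    network: InteractionNetwork, annotation: Mapping[str, Set[str]]
) -> Dict[str, int]:
    """Nodes with a non-zero crosstalk score, with their scores."""
    return {
        v: s for v, s in crosstalk_scores(network, annotation).items() if s > 0
    }


def annotation_to_frame(annotation: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Two-column long table (node, pathway), one row per membership."""
    rows = [
        {"node": node, "pathway": pw}
        for node in sorted(annotation)
        for pw in sorted(annotation[node])
    ]
    return pd.DataFrame(rows, columns=["node", "pathway"])


def annotation_from_frame(df: pd.DataFrame) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    for node, pw in zip(df["node"], df["pathway"]):
        out.setdefault(str(node), set()).add(str(pw))
    return out
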