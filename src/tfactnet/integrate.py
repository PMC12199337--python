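"""Logistic fusion of the expression-derived GRN with prior sources.

Every edge in the candidate universe gets

    W = 1 / (1 + exp(-(a0 + sum_i a_i * w_i)))

over its per-source weights, with missing sources contributing 0.  By
default the prior sources define the candidate TF-target universe and the
GRN only modulates weights (the integration exists to suppress the GRN's
false positives); edges seen only in the GRN can be admitted with
``grn_only_edges=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import WeightedEdgeList

__all__ = ["IntegrationConfig", "integrate_networks"]


@dataclass
class IntegrationConfig:
    a0: float = 0.0
    a: dict[str, float] = field(default_factory=dict)  # per-source, default 1
    max_target_num: int = 2000
    min_regulon_size: int = 10
    grn_only_edges: bool = False

    def __post_init__(self) -> None:
        if self.max_target_num < 1:
            raise ValueError("max_target_num must be >= 1")
        if self.min_regulon_size < 1:
            raise ValueError("min_regulon_size must be >= 1")

    def coef(self, source: str) -> float:
        return self.a.get(source, 1.0)


def integrate_networks(
    prior: dict[str, WeightedEdgeList],
    grn: WeightedEdgeList | None,
    cfg: IntegrationConfig | None = None,
    tfs: list[str] | None = None,
) -> WeightedEdgeList:
    """Fuse prior sources and the GRN into one weighted network.

    ``tfs`` optionally restricts the edge universe to listed regulators.
    Per TF at most ``cfg.max_target_num`` targets are kept, by descending
    integrated weight (ties broken on target id for determinism).
    """
    cfg = cfg or IntegrationConfig()
    universe: set[tuple[str, str]] = set()
    for net in prior.values():
        universe.update((r, t) for r, t, _ in net.edges)
    grn_map = grn.weight_map() if grn is not None else {}
    if cfg.grn_only_edges:
        universe.update(grn_map)
    if tfs is not None:
        allowed = set(tfs)
        universe = {(r, t) for r, t in universe if r in allowed}
    prior_maps = {name: net.weight_map() for name, net in prior.items()}

    by_tf: dict[str, list[tuple[str, float]]] = {}
    for r, t in universe:
        z = cfg.a0
        for name, wmap in prior_maps.items():
            w = wmap.get((r, t))
            if w is not None:
                z += cfg.coef(name) * w
        w = grn_map.get((r, t))
        if w is not None:
            z += cfg.coef("grn") * w
        by_tf.setdefault(r, []).append((t, float(1.0 / (1.0 + np.exp(-z)))))

    edges: list[tuple[str, str, float]] = []
    for r in sorted(by_tf):
        ranked = sorted(by_tf[r], key=lambda tw: (-tw[1], tw[0]))
        edges.extend((r, t, w) for t, w in ranked[: cfg.max_target_num])
    return WeightedEdgeList(edges)
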