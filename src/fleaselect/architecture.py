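"""Layer-graph census of standard and modified ResNet-50.

Builds a typed DAG of layer nodes (no weights, no training) so the inventory
and learnable-parameter count can be computed constructively:

- conv: k*k*in*out weights, bias-free (batch norm follows every conv)
- batchnorm: 2 learnable parameters per channel (scale + offset)
- fullyconnected: in*out weights + out biases
- everything else: 0

The standard graph uses bottleneck stages (3, 4, 6, 3) with one projection
conv+BN per stage and a 1000-way head, which yields 177 nodes and 25,557,032
learnable parameters. The modified graph uses (3, 4, 3, 3) bottleneck stages,
an 8-way head and no terminal classification node, yielding 146 nodes.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict

KINDS = {
    "input",
    "conv",
    "batchnorm",
    "relu",
    "maxpool",
    "avgpool",
    "addition",
    "fullyconnected",
    "softmax",
    "classification_output",
}

#: Per-stage (bottleneck width, output width) for width multiplier 1.0.
STAGE_WIDTHS = [(64, 256), (128, 512), (256, 1024), (512, 2048)]

STANDARD_STAGE_CONFIG = (3, 4, 6, 3)
MODIFIED_STAGE_CONFIG = (3, 4, 3, 3)


@dataclass
class LayerNode:
    name: str
    kind: str
    in_channels: int | None = None
    out_channels: int | None = None
    kernel: int | None = None
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind: {self.kind}")

    def n_parameters(self) -> int:
        if self.kind == "conv":
            if None in (self.kernel, self.in_channels, self.out_channels):
                raise ValueError(f"node {self.name}: conv shape metadata incomplete")
            return self.kernel * self.kernel * self.in_channels * self.out_channels
        if self.kind == "batchnorm":
            if self.out_channels is None:
                raise ValueError(f"node {self.name}: batchnorm channel count missing")
            return 2 * self.out_channels
        if self.kind == "fullyconnected":
            if None in (self.in_channels, self.out_channels):
                raise ValueError(f"node {self.name}: fc shape metadata incomplete")
            return self.in_channels * self.out_channels + self.out_channels
        return 0


@dataclass
class LayerGraph:
    nodes: list[LayerNode]
    edges: list[tuple[str, str]]
    stage_config: tuple[int, ...]
    width_multiplier: float = 1.0
    n_output_classes: int = 1000

    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def to_json(self, path) -> None:
        payload = {
            "stage_config": list(self.stage_config),
            "width_multiplier": self.width_multiplier,
            "n_output_classes": self.n_output_classes,
            "nodes": [asdict(n) for n in self.nodes],
            "edges": [list(e) for e in self.edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class _GraphBuilder:
    def __init__(self) -> None:
        self.nodes: list[LayerNode] = []
        self.edges: list[tuple[str, str]] = []
        self._counts: Counter = Counter()

    def add(self, kind: str, after: str | list[str] | None, **shape) -> str:
        self._counts[kind] += 1
        name = f"{kind}_{self._counts[kind]}"
        self.nodes.append(LayerNode(name=name, kind=kind, **shape))
        if after is not None:
            preds = [after] if isinstance(after, str) else after
            for p in preds:
                self.edges.append((p, name))
        return name


def _scaled(width: int, multiplier: float) -> int:
    return max(1, round(width * multiplier))


def _build_resnet(
    stage_config: tuple[int, ...],
    width_multiplier: float,
    n_output_classes: int,
    with_classification_node: bool,
) -> LayerGraph:
    b = _GraphBuilder()
    tip = b.add("input", None)
    stem_out = _scaled(64, width_multiplier)
    tip = b.add("conv", tip, in_channels=3, out_channels=stem_out, kernel=7, stride=2)
    tip = b.add("batchnorm", tip, out_channels=stem_out)
    tip = b.add("relu", tip)
    tip = b.add("maxpool", tip)

    in_ch = stem_out
    n_stages = len(stage_config)
    for stage, n_blocks in enumerate(stage_config):
        # Stage widths follow the canonical 4-stage ladder; extra stages
        # (non-faithful configs) reuse the last rung.
        base_w, base_out = STAGE_WIDTHS[min(stage, len(STAGE_WIDTHS) - 1)]
        w = _scaled(base_w, width_multiplier)
        out_ch = _scaled(base_out, width_multiplier)
        for block in range(n_blocks):
            shortcut = tip
            stride = 2 if (block == 0 and stage > 0) else 1
            tip = b.add("conv", tip, in_channels=in_ch, out_channels=w, kernel=1, stride=stride)
            tip = b.add("batchnorm", tip, out_channels=w)
            tip = b.add("relu", tip)
            tip = b.add("conv", tip, in_channels=w, out_channels=w, kernel=3, stride=1)
            tip = b.add("batchnorm", tip, out_channels=w)
            tip = b.add("relu", tip)
            tip = b.add("conv", tip, in_channels=w, out_channels=out_ch, kernel=1, stride=1)
            tip = b.add("batchnorm", tip, out_channels=out_ch)
            if block == 0:
                # Projection branch: one conv+BN per stage.
                proj = b.add(
                    "conv", shortcut, in_channels=in_ch, out_channels=out_ch, kernel=1, stride=stride
                )
                proj = b.add("batchnorm", proj, out_channels=out_ch)
                shortcut = proj
            tip = b.add("addition", [tip, shortcut])
            tip = b.add("relu", tip)
            in_ch = out_ch

    tip = b.add("avgpool", tip)
    tip = b.add(
        "fullyconnected", tip, in_channels=in_ch, out_channels=n_output_classes
    )
    tip = b.add("softmax", tip)
    if with_classification_node:
        tip = b.add("classification_output", tip)
    return LayerGraph(
        nodes=b.nodes,
        edges=b.edges,
        stage_config=tuple(stage_config),
        width_multiplier=width_multiplier,
        n_output_classes=n_output_classes,
    )


def build_standard_resnet50() -> LayerGraph:
    """Standard 50-layer bottleneck graph: 177 nodes, 1000-way head."""
    return _build_resnet(STANDARD_STAGE_CONFIG, 1.0, 1000, with_classification_node=True)


def build_modified_resnet50(
    stage_config: tuple[int, ...] = MODIFIED_STAGE_CONFIG,
    width_multiplier: float = 1.0,
    n_output_classes: int = 8,
) -> LayerGraph:
    """Reduced graph: 13 bottleneck blocks, 8-way head, no classification node."""
    stage_config = tuple(stage_config)
    if not 0.0 < width_multiplier <= 1.0:
        raise ValueError("width_multiplier must lie in (0, 1]")
    if sum(stage_config) != 13:
        warnings.warn(
            f"stage_config {stage_config} sums to {sum(stage_config)}, not 13; "
            "the resulting inventory is not the published one",
            UserWarning,
            stacklevel=2,
        )
    return _build_resnet(stage_config, width_multiplier, n_output_classes, with_classification_node=False)


def count_layers(graph: LayerGraph) -> dict[str, int]:
    """Exact node census by kind, plus a ``total`` entry."""
    counts = dict(Counter(n.kind for n in graph.nodes))
    counts["total"] = len(graph.nodes)
    return counts


def count_parameters(graph: LayerGraph) -> int:
    """Exact learnable-parameter count summed over nodes."""
    return sum(n.n_parameters() for n in graph.nodes)


def topological_order(graph: LayerGraph) -> list[str]:
    """Kahn topological sort; raises if the graph has a cycle."""
    indeg = {n.name: 0 for n in graph.nodes}
    succ: dict[str, list[str]] = {n.name: [] for n in graph.nodes}
    for src, dst in graph.edges:
        indeg[dst] += 1
        succ[src].append(dst)
    frontier = [n for n, d in indeg.items() if d == 0]
    order: list[str] = []
    while frontier:
        name = frontier.pop()
        order.append(name)
        for nxt in succ[name]:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                frontier.append(nxt)
    if len(order) != len(graph.nodes):
        raise ValueError("layer graph contains a cycle")
    return order
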