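"""Declarative layer graphs for the four 1D classification architectures.

A :class:`LayerGraph` is a small DAG of layer descriptors — enough to
materialize the network in any backend, to propagate shapes, and to count
trainable parameters — serializable to JSON.  Four builders are provided:

``alexnet1d``
    Three conv blocks (filters 32/64/128, kernel 3, each conv -> BN -> ReLU
    -> maxpool(2)), then flatten -> dropout(0.4) -> dense(128, ReLU) ->
    dense(n_classes, softmax).
``resnet1d``
    Stem conv(kernel 9, 24 filters) -> BN -> ReLU -> maxpool(3), three
    residual blocks (kernel 3; filters 32, 64, 128), global average
    pooling, dense softmax.
``mscnn``
    Three parallel branches with kernels 3/7/9 (each conv -> BN -> ReLU ->
    maxpool(2)), concatenated, then flatten -> dropout -> two dense layers.
``msresnet``
    The multi-scale front end (kernels 3/7/9, filters 16/32/64, pool 3)
    feeding the residual stack of ``resnet1d``, global average pooling and
    a dense softmax head.

A residual block's main path is conv -> BN -> ReLU -> conv; the shortcut is
a single kernel-1 conv projecting to the block's channel count; the merge
is elementwise addition followed by ReLU.  All convolutions use odd kernels
and 'same' padding, so lengths change only at pooling layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

from .exceptions import ConfigError

ARCHITECTURES = ("alexnet1d", "resnet1d", "mscnn", "msresnet")

LAYER_KINDS = (
    "input",
    "conv",
    "bn",
    "relu",
    "maxpool",
    "gap",
    "flatten",
    "dropout",
    "dense",
    "add",
    "concat",
)


@dataclass(frozen=True)
class LayerNode:
    id: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ConfigError(f"unknown layer kind {self.kind!r}")


@dataclass
class LayerGraph:
    """Architecture description: nodes, directed edges, input/output contract."""

    name: str
    input_length: int
    n_classes: int
    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)  # (src_id, dst_id)

    # -- graph algebra ----------------------------------------------------
    def node(self, node_id: str) -> LayerNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def predecessors(self, node_id: str) -> list:
        return [s for s, d in self.edges if d == node_id]

    def successors(self, node_id: str) -> list:
        return [d for s, d in self.edges if s == node_id]

    def topological_order(self) -> list:
        indeg = {n.id: 0 for n in self.nodes}
        for _, d in self.edges:
            indeg[d] += 1
        stack = sorted([i for i, k in indeg.items() if k == 0])
        order = []
        while stack:
            nid = stack.pop(0)
            order.append(nid)
            for d in self.successors(nid):
                indeg[d] -= 1
                if indeg[d] == 0:
                    stack.append(d)
        if len(order) != len(self.nodes):
            raise ConfigError(f"{self.name}: layer graph contains a cycle")
        return order

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate node ids")
        self.topological_order()
        sources = [n.id for n in self.nodes if not self.predecessors(n.id)]
        sinks = [n.id for n in self.nodes if not self.successors(n.id)]
        if len(sources) != 1 or self.node(sources[0]).kind != "input":
            raise ConfigError("graph must have exactly one input node")
        if len(sinks) != 1:
            raise ConfigError("graph must have exactly one output node")
        out = self.node(sinks[0])
        if out.kind != "dense" or out.params.get("units") != self.n_classes:
            raise ConfigError("output node must be a dense layer with units == n_classes")
        self.propagate_shapes()

    # -- shape propagation -------------------------------------------------
    def propagate_shapes(self) -> dict:
        """Return ``{node_id: (channels, length)}``; dense/flatten outputs use
        ``(features, None)``.  Raises on incompatible merges or non-positive
        intermediate lengths."""
        shapes: dict[str, tuple] = {}
        for nid in self.topological_order():
            node = self.node(nid)
            ins = [shapes[p] for p in self.predecessors(nid)]
            shapes[nid] = _infer_shape(self.name, node, ins, self.input_length)
        return shapes

    def count_parameters(self) -> int:
        """Total trainable scalars: conv kernels + biases, BN scale/shift,
        dense weights + biases."""
        shapes = self.propagate_shapes()
        total = 0
        for node in self.nodes:
            ins = [shapes[p] for p in self.predecessors(node.id)]
            if node.kind == "conv":
                cin = ins[0][0]
                k, cout = node.params["kernel_size"], node.params["n_filters"]
                total += k * cin * cout + cout
            elif node.kind == "bn":
                total += 2 * ins[0][0]
            elif node.kind == "dense":
                total += ins[0][0] * node.params["units"] + node.params["units"]
        return total

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "input_length": self.input_length,
            "n_classes": self.n_classes,
            "nodes": [{"id": n.id, "kind": n.kind, "params": n.params} for n in self.nodes],
            "edges": [list(e) for e in self.edges],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "LayerGraph":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text_or_path) as fh:
                text = fh.read()
        d = json.loads(text)
        g = cls(
            name=d["name"],
            input_length=d["input_length"],
            n_classes=d["n_classes"],
            nodes=[LayerNode(n["id"], n["kind"], n.get("params", {})) for n in d["nodes"]],
            edges=[tuple(e) for e in d["edges"]],
        )
        g.validate()
        return g


def _infer_shape(name: str, node: LayerNode, ins: list, input_length: int) -> tuple:
    kind = node.kind
    if kind == "input":
        return (1, input_length)
    if kind == "conv":
        c, ln = ins[0]
        if ln is None:
            raise ConfigError(f"{name}:{node.id}: conv after flatten/dense")
        if node.params["kernel_size"] % 2 == 0:
            raise ConfigError(f"{name}:{node.id}: kernel size must be odd for 'same' padding")
        return (node.params["n_filters"], ln)
    if kind in ("bn", "relu", "dropout"):
        return ins[0]
    if kind == "maxpool":
        c, ln = ins[0]
        p = node.params["pool_size"]
        out = ln // p
        if out < 1:
            raise ConfigError(f"{name}:{node.id}: length {ln} too short for pool({p})")
        return (c, out)
    if kind == "gap":
        c, _ = ins[0]
        return (c, 1)
    if kind == "flatten":
        c, ln = ins[0]
        return (c * (ln if ln else 1), None)
    if kind == "dense":
        return (node.params["units"], None)
    if kind == "add":
        if len(set(ins)) != 1:
            raise ConfigError(f"{name}:{node.id}: add inputs have mismatched shapes {ins}")
        return ins[0]
    if kind == "concat":
        lengths = {ln for _, ln in ins}
        if len(lengths) != 1:
            raise ConfigError(f"{name}:{node.id}: concat inputs have mismatched lengths {ins}")
        return (sum(c for c, _ in ins), lengths.pop())
    raise ConfigError(f"unknown kind {kind}")


# ---------------------------------------------------------------------------
# builders


class _Builder:
    """Helper accumulating nodes/edges with a running cursor."""

    def __init__(self, graph: LayerGraph):
        self.g = graph
        self.i = 0

    def add(self, kind: str, after, **params) -> str:
        nid = f"{kind}{self.i}"
        self.i += 1
        self.g.nodes.append(LayerNode(nid, kind, params))
        if after is not None:
            for a in [after] if isinstance(after, str) else after:
                self.g.edges.append((a, nid))
        return nid


def _check_input(input_length: int, n_classes: int, minimum: int) -> None:
    if input_length < minimum:
        raise ConfigError(f"input_length must be >= {minimum}, got {input_length}")
    if n_classes < 2:
        raise ConfigError(f"n_classes must be >= 2, got {n_classes}")


def build_alexnet1d(
    input_length: int, n_classes: int, *, dense_units: int = 128, dropout_rate: float = 0.4
) -> LayerGraph:
    """Plain 1D CNN: conv filters 32/64/128, kernel 3, pool 2, dropout 0.4."""
    _check_input(input_length, n_classes, 8)
    g = LayerGraph("alexnet1d", input_length, n_classes)
    b = _Builder(g)
    cur = b.add("input", None)
    for filters in (32, 64, 128):
        cur = b.add("conv", cur, kernel_size=3, n_filters=filters)
        cur = b.add("bn", cur)
        cur = b.add("relu", cur)
        cur = b.add("maxpool", cur, pool_size=2)
    cur = b.add("flatten", cur)
    cur = b.add("dropout", cur, rate=dropout_rate)
    cur = b.add("dense", cur, units=dense_units, activation="relu")
    cur = b.add("relu", cur)
    b.add("dense", cur, units=n_classes, activation="softmax")
    g.validate()
    return g


def _res_block(b: _Builder, cur: str, n_filters: int, kernel_size: int = 3) -> str:
    main = b.add("conv", cur, kernel_size=kernel_size, n_filters=n_filters)
    main = b.add("bn", main)
    main = b.add("relu", main)
    main = b.add("conv", main, kernel_size=kernel_size, n_filters=n_filters)
    short = b.add("conv", cur, kernel_size=1, n_filters=n_filters, shortcut=True)
    merged = b.add("add", [main, short])
    return b.add("relu", merged)


def build_resnet1d(
    input_length: int, n_classes: int, *, stem_kernel: int = 9, stem_filters: int = 24,
    stem_pool: int = 3, block_filters=(32, 64, 128), block_kernel: int = 3
) -> LayerGraph:
    """Residual 1D CNN: stem conv(9, 24) -> pool(3), blocks 32/64/128, GAP head."""
    _check_input(input_length, n_classes, 27)
    g = LayerGraph("resnet1d", input_length, n_classes)
    b = _Builder(g)
    cur = b.add("input", None)
    cur = b.add("conv", cur, kernel_size=stem_kernel, n_filters=stem_filters)
    cur = b.add("bn", cur)
    cur = b.add("relu", cur)
    cur = b.add("maxpool", cur, pool_size=stem_pool)
    for f in block_filters:
        cur = _res_block(b, cur, f, block_kernel)
    cur = b.add("gap", cur)
    cur = b.add("flatten", cur)
    b.add("dense", cur, units=n_classes, activation="softmax")
    g.validate()
    return g


def build_mscnn(
    input_length: int, n_classes: int, *, branch_kernels=(3, 7, 9), branch_filters: int = 32,
    pool_size: int = 2, dense_units: int = 128, dropout_rate: float = 0.4
) -> LayerGraph:
    """Multi-scale CNN: parallel branches with kernels 3/7/9, concatenated."""
    _check_input(input_length, n_classes, 9)
    g = LayerGraph("mscnn", input_length, n_classes)
    b = _Builder(g)
    inp = b.add("input", None)
    ends = []
    for k in branch_kernels:
        cur = b.add("conv", inp, kernel_size=k, n_filters=branch_filters)
        cur = b.add("bn", cur)
        cur = b.add("relu", cur)
        cur = b.add("maxpool", cur, pool_size=pool_size)
        ends.append(cur)
    cur = b.add("concat", ends)
    cur = b.add("flatten", cur)
    cur = b.add("dropout", cur, rate=dropout_rate)
    cur = b.add("dense", cur, units=dense_units, activation="relu")
    cur = b.add("relu", cur)
    b.add("dense", cur, units=n_classes, activation="softmax")
    g.validate()
    return g


def build_msresnet(
    input_length: int, n_classes: int, *, branch_kernels=(3, 7, 9), branch_filters=(16, 32, 64),
    branch_pool: int = 3, block_filters=(32, 64, 128), block_kernel: int = 3
) -> LayerGraph:
    """Multi-scale front end (kernels 3/7/9, filters 16/32/64) feeding the
    residual stack of :func:`build_resnet1d`."""
    _check_input(input_length, n_classes, 9)
    if len(set(branch_kernels)) != len(branch_kernels):
        raise ConfigError("branch kernel sizes must be pairwise distinct")
    g = LayerGraph("msresnet", input_length, n_classes)
    b = _Builder(g)
    inp = b.add("input", None)
    ends = []
    for k, f in zip(branch_kernels, branch_filters):
        cur = b.add("conv", inp, kernel_size=k, n_filters=f)
        cur = b.add("bn", cur)
        cur = b.add("relu", cur)
        cur = b.add("maxpool", cur, pool_size=branch_pool)
        ends.append(cur)
    cur = b.add("concat", ends)
    for f in block_filters:
        cur = _res_block(b, cur, f, block_kernel)
    cur = b.add("gap", cur)
    cur = b.add("flatten", cur)
    b.add("dense", cur, units=n_classes, activation="softmax")
    g.validate()
    return g


BUILDERS: dict[str, Callable[..., LayerGraph]] = {
    "alexnet1d": build_alexnet1d,
    "resnet1d": build_resnet1d,
    "mscnn": build_mscnn,
    "msresnet": build_msresnet,
}


def build(name: str, input_length: int, n_classes: int, **kwargs) -> LayerGraph:
    if name not in BUILDERS:
        raise ConfigError(f"unknown architecture {name!r}; choose from {ARCHITECTURES}")
    return BUILDERS[name](input_length, n_classes, **kwargs)
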