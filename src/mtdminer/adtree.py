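"""Alternating decision trees with additive margin scores.

The model is a rooted tree alternating between prediction nodes (each
carrying a real additive score) and threshold splitter nodes. An instance
simultaneously traverses every splitter attached to each prediction node it
reaches; its margin is the sum of all reached prediction scores, and the
sign of the margin is the class (margin 0 -> negative).

Training is real-valued boosting: each iteration exhaustively scans every
(existing prediction node, feature, threshold) triple and adds the rule
minimizing

    Z = 2 [ sqrt(W+(c1 ^ c2) W-(c1 ^ c2)) + sqrt(W+(c1 ^ ~c2) W-(c1 ^ ~c2)) ]
        + W(~c1)

where c1 is the precondition "instance reaches the node" and c2 the
predicate "x[f] <= threshold". Child scores are smoothed half-log-odds of
the class weights in each cell, and instance weights are multiplied by
exp(-y * r(x)) and renormalized after every addition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class PredictionNode:
    score: float
    splitters: list["SplitterNode"] = field(default_factory=list)
    index: int = 0  # creation order


@dataclass
class SplitterNode:
    feature_index: int
    threshold: float
    left: PredictionNode   # taken when x[feature] <= threshold
    right: PredictionNode  # taken when x[feature] > threshold
    order: int = 0         # 1-based rule addition order


@dataclass
class ADTreeModel:
    root: PredictionNode
    rules: list[tuple[PredictionNode, SplitterNode]]
    n_iterations: int
    n_features: int
    z_values: list[float] = field(default_factory=list)

    def prediction_nodes(self) -> list[PredictionNode]:
        out: list[PredictionNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            for sp in node.splitters:
                stack.extend([sp.left, sp.right])
        return sorted(out, key=lambda n: n.index)


def _reach_masks(model: ADTreeModel, X: np.ndarray) -> dict[int, np.ndarray]:
    """Boolean reach mask per prediction-node index for all rows of X."""
    masks = {model.root.index: np.ones(len(X), dtype=bool)}
    stack = [model.root]
    while stack:
        node = stack.pop()
        mask = masks[node.index]
        for sp in node.splitters:
            le = X[:, sp.feature_index] <= sp.threshold
            masks[sp.left.index] = mask & le
            masks[sp.right.index] = mask & ~le
            stack.extend([sp.left, sp.right])
    return masks


def predict_margin(model: ADTreeModel, X: np.ndarray) -> np.ndarray:
    """Sum of scores of all prediction nodes reached by each instance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise DataError(f"expected {model.n_features} features, "
                        f"got {X.shape[1]}")
    masks = _reach_masks(model, X)
    margins = np.zeros(len(X))
    for node in model.prediction_nodes():
        margins[masks[node.index]] += node.score
    return margins


def classify(model: ADTreeModel, X: np.ndarray) -> np.ndarray:
    """+1 where margin > 0, otherwise -1 (zero margin is negative)."""
    return np.where(predict_margin(model, X) > 0, 1, -1)


def _scan_node(vals: np.ndarray, wp: np.ndarray, wm: np.ndarray,
               outside: float):
    """Best (Z, threshold) for one (node, feature); None if no split exists.

    ``vals``/``wp``/``wm`` are the feature values and signed weights of the
    instances reaching the node; ``outside`` is W(~c1).
    """
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    cp = np.cumsum(wp[order])
    cm = np.cumsum(wm[order])
    cut = np.nonzero(sv[:-1] < sv[1:])[0]  # split after these positions
    if len(cut) == 0:
        return None
    wp_le, wm_le = cp[cut], cm[cut]
    wp_gt = cp[-1] - wp_le
    wm_gt = cm[-1] - wm_le
    z = 2.0 * (np.sqrt(wp_le * wm_le) + np.sqrt(wp_gt * wm_gt)) + outside
    best = int(np.argmin(z))  # ascending thresholds: first minimum wins ties
    thr = 0.5 * (sv[cut[best]] + sv[cut[best] + 1])
    return float(z[best]), float(thr)


def train_adtree(X: np.ndarray, y: np.ndarray, n_iterations: int = 6,
                 smoothing: float | None = None) -> ADTreeModel:
    """Boosted alternating decision tree.

    ``y`` may be {0,1} or {-1,+1}. ``smoothing`` defaults to 0.5/n. The
    returned model records the per-iteration normalizers ``z_values`` whose
    product upper-bounds the training error rate.

    The default of 6 rules yields a 19-node tree (1 + 3 per rule), i.e. a
    deliberately small, readable model; raise ``n_iterations`` for harder
    problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("X must be (n, d) with one label per row")
    if len(X) < 2:
        raise DataError("need at least 2 instances")
    if np.isnan(X).any():
        raise DataError("NaN feature values")
    ypm = np.where(y > 0, 1, -1).astype(float)
    if len(np.unique(ypm)) < 2:
        raise DataError("both classes must be present")
    n, d = X.shape
    eps = 0.5 / n if smoothing is None else smoothing

    w = np.full(n, 1.0 / n)
    pos = ypm > 0

    root_score = 0.5 * np.log(w[pos].sum() / w[~pos].sum())
    root = PredictionNode(score=root_score, index=0)
    model = ADTreeModel(root=root, rules=[], n_iterations=n_iterations,
                        n_features=d)
    w = w * np.exp(-ypm * root_score)
    model.z_values.append(float(w.sum()))
    w /= w.sum()

    # membership mask per prediction node, kept in sync with the tree
    masks: dict[int, np.ndarray] = {0: np.ones(n, dtype=bool)}
    nodes: list[PredictionNode] = [root]
    next_index = 1

    for it in range(n_iterations):
        best = None  # (z, feature, threshold, node_position)
        wp = np.where(pos, w, 0.0)
        wm = np.where(~pos, w, 0.0)
        for f in range(d):
            for ni, node in enumerate(nodes):
                mask = masks[node.index]
                if mask.sum() < 2:
                    continue
                outside = float(w[~mask].sum())
                res = _scan_node(X[mask, f], wp[mask], wm[mask], outside)
                if res is None:
                    continue
                z, thr = res
                key = (z, f, thr, ni)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        z_scan, f, thr, ni = best
        node = nodes[ni]
        mask = masks[node.index]
        le = mask & (X[:, f] <= thr)
        gt = mask & ~(X[:, f] <= thr)
        a = 0.5 * np.log((wp[le].sum() + eps) / (wm[le].sum() + eps))
        b = 0.5 * np.log((wp[gt].sum() + eps) / (wm[gt].sum() + eps))
        left = PredictionNode(score=float(a), index=next_index)
        right = PredictionNode(score=float(b), index=next_index + 1)
        next_index += 2
        splitter = SplitterNode(feature_index=f, threshold=thr,
                                left=left, right=right, order=it + 1)
        node.splitters.append(splitter)
        model.rules.append((node, splitter))
        nodes.extend([left, right])
        masks[left.index] = le
        masks[right.index] = gt

        contrib = np.zeros(n)
        contrib[le] = a
        contrib[gt] = b
        w = w * np.exp(-ypm * contrib)
        model.z_values.append(float(w.sum()))
        w /= w.sum()

    model.n_iterations = len(model.rules)
    return model


# ---------------------------------------------------------------------------
# export and persistence
# ---------------------------------------------------------------------------

def export_text(model: ADTreeModel, feature_names: list[str] | None = None) -> str:
    """Indented human-readable rendering with rule addition order."""
    names = feature_names or [f"f{i}" for i in range(model.n_features)]
    if len(names) != model.n_features:
        raise DataError("feature_names length mismatch")
    lines: list[str] = []

    def walk(node: PredictionNode, depth: int, tag: str) -> None:
        lines.append("  " * depth + f"{tag}score {node.score:+.4f}")
        for sp in node.splitters:
            lines.append("  " * (depth + 1)
                         + f"{names[sp.feature_index]}({sp.order}) "
                         f"<= {sp.threshold:g}?")
            walk(sp.left, depth + 2, "yes: ")
            walk(sp.right, depth + 2, "no:  ")

    walk(model.root, 0, "root ")
    return "\n".join(lines)


def _dot_quote(label: str) -> str:
    return '"' + label.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_dot(model: ADTreeModel, feature_names: list[str] | None = None) -> str:
    """Graphviz DOT rendering (prediction nodes ellipses, splitters boxes)."""
    names = feature_names or [f"f{i}" for i in range(model.n_features)]
    if len(names) != model.n_features:
        raise DataError("feature_names length mismatch")
    lines = ["digraph adtree {", "  node [fontsize=10];"]
    counter = [0]

    def pid(node: PredictionNode) -> str:
        return f"p{node.index}"

    def walk(node: PredictionNode) -> None:
        lines.append(f"  {pid(node)} [shape=ellipse, "
                     f"label={_dot_quote(f'{node.score:+.3f}')}];")
        for sp in node.splitters:
            counter[0] += 1
            sid = f"s{counter[0]}"
            label = f"{names[sp.feature_index]}({sp.order}) <= {sp.threshold:g}"
            lines.append(f"  {sid} [shape=box, label={_dot_quote(label)}];")
            lines.append(f"  {pid(node)} -> {sid};")
            lines.append(f"  {sid} -> {pid(sp.left)} [label={_dot_quote('y')}];")
            lines.append(f"  {sid} -> {pid(sp.right)} [label={_dot_quote('n')}];")
            walk(sp.left)
            walk(sp.right)

    walk(model.root)
    lines.append("}")
    return "\n".join(lines)


def _node_to_dict(node: PredictionNode) -> dict:
    return {
        "score": node.score,
        "index": node.index,
        "splitters": [
            {"feature_index": sp.feature_index, "threshold": sp.threshold,
             "order": sp.order, "left": _node_to_dict(sp.left),
             "right": _node_to_dict(sp.right)}
            for sp in node.splitters],
    }


def _node_from_dict(data: dict) -> PredictionNode:
    node = PredictionNode(score=data["score"], index=data["index"])
    for sp in data["splitters"]:
        node.splitters.append(SplitterNode(
            feature_index=sp["feature_index"], threshold=sp["threshold"],
            order=sp["order"], left=_node_from_dict(sp["left"]),
            right=_node_from_dict(sp["right"])))
    return node


def save_model(model: ADTreeModel, path) -> None:
    payload = {
        "format": "mtdminer-adtree-v1",
        "n_features": model.n_features,
        "n_iterations": model.n_iterations,
        "z_values": model.z_values,
        "root": _node_to_dict(model.root),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ADTreeModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "mtdminer-adtree-v1":
        raise DataError(f"{path!r}: not an ADtree model file")
    root = _node_from_dict(payload["root"])
    model = ADTreeModel(root=root, rules=[],
                        n_iterations=payload["n_iterations"],
                        n_features=payload["n_features"],
                        z_values=list(payload.get("z_values", [])))
    # rebuild rule list in addition order
    splitters: list[tuple[PredictionNode, SplitterNode]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        for sp in node.splitters:
            splitters.append((node, sp))
            stack.extend([sp.left, sp.right])
    model.rules = sorted(splitters, key=lambda t: t[1].order)
    return model
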