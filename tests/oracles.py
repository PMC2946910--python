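"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the CART oracle enumerates
every (variable, midpoint-threshold) split exhaustively, and the area oracles
work pairwise / by direct enumeration, so they can vouch for the optimized
implementations.
"""

import numpy as np


def pop_var(y):
    y = np.asarray(y, dtype=float)
    return float(((y - y.mean()) ** 2).mean())


def cart_oracle(X, y, min_split=2):
    """Fully grown CART regression tree by exhaustive search.

    Tie-break: lowest variable index, then lowest threshold (implemented by
    scanning variables and thresholds in ascending order and accepting only
    strictly better scores). Returns a nested dict.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    node = {"n": n, "var": pop_var(y), "value": float(y.mean())}
    if n < min_split or np.all(y == y[0]):
        node["leaf"] = True
        return node
    best = None
    for v in range(m):
        values = np.unique(X[:, v])
        for lo, hi in zip(values[:-1], values[1:]):
            t = 0.5 * (lo + hi)
            mask = X[:, v] <= t
            red = n * pop_var(y) - mask.sum() * pop_var(y[mask]) - (
                (~mask).sum() * pop_var(y[~mask])
            )
            if best is None or red > best[0]:
                best = (red, v, t, mask)
    if best is None:
        node["leaf"] = True
        return node
    red, v, t, mask = best
    node.update(
        leaf=False,
        feature=v,
        threshold=t,
        reduction=red,
        left=cart_oracle(X[mask], y[mask], min_split),
        right=cart_oracle(X[~mask], y[~mask], min_split),
    )
    return node


def oracle_importances(tree, m):
    imp = np.zeros(m)

    def walk(node):
        if node["leaf"]:
            return
        imp[node["feature"]] += node["reduction"]
        walk(node["left"])
        walk(node["right"])

    walk(tree)
    return imp


def oracle_predict(tree, X):
    out = np.empty(len(X))
    for i, row in enumerate(np.asarray(X, dtype=float)):
        node = tree
        while not node["leaf"]:
            node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
        out[i] = node["value"]
    return out


def pairwise_auroc(weights, labels):
    """O(P*N) concordance: ties in weight count 1/2."""
    weights = np.asarray(weights, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = weights[labels]
    neg = weights[~labels]
    total = 0.0
    for wp in pos:
        for wn in neg:
            if wp > wn:
                total += 1.0
            elif wp == wn:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumeration_aupr(labels):
    """Average precision by direct enumeration over the ordered labels."""
    labels = np.asarray(labels, dtype=bool)
    hits = 0
    precisions = []
    for rank, is_pos in enumerate(labels, start=1):
        if is_pos:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))
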