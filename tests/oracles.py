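"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (plain Python loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

import itertools
import math

from protacable import aa_tables

ALPHABET = aa_tables.CANONICAL_AA


def tpc_naive(seq):
    counts = {"".join(t): 0 for t in itertools.product(ALPHABET, repeat=3)}
    for i in range(len(seq) - 2):
        counts[seq[i:i + 3]] += 1
    return [counts[k] / (len(seq) - 2) for k in sorted(counts)]


def _group_code(groups):
    code = {}
    for gi, members in enumerate(groups.values()):
        for a in members:
            code[a] = gi
    return code, len(groups)


def grouped_triples_naive(seq, groups):
    code, n = _group_code(groups)
    counts = [0] * (n ** 3)
    for i in range(len(seq) - 2):
        a, b, c = code[seq[i]], code[seq[i + 1]], code[seq[i + 2]]
        counts[a * n * n + b * n + c] += 1
    return [c / (len(seq) - 2) for c in counts]


def ctdd_naive(seq):
    out = []
    L = len(seq)
    for groups in aa_tables.CTD_ATTRIBUTES.values():
        for members in groups:
            positions = [i + 1 for i, ch in enumerate(seq) if ch in members]
            if not positions:
                out.extend([0.0] * 5)
                continue
            n = len(positions)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = max(1, math.ceil(frac * n))
                out.append(100.0 * positions[k - 1] / L)
    return out


def geary_naive(seq, properties, n_lag):
    out = []
    L = len(seq)
    for scale in properties.values():
        vals = [scale[a] for a in ALPHABET]
        mean = sum(vals) / 20
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
        z = {a: (scale[a] - mean) / sd for a in ALPHABET}
        p = [z[a] for a in seq]
        pbar = sum(p) / L
        denom = sum((v - pbar) ** 2 for v in p) / (L - 1)
        for d in range(1, n_lag + 1):
            if denom < 1e-12:
                out.append(0.0)
                continue
            num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (2 * (L - d))
            out.append(num / denom)
    return out


def qsorder_naive(seq, matrices, n_lag, weight):
    out = []
    L = len(seq)
    idx = {a: i for i, a in enumerate(ALPHABET)}
    for dist in matrices.values():
        taus = []
        for d in range(1, n_lag + 1):
            taus.append(sum(dist[idx[seq[i]], idx[seq[i + d]]] ** 2
                            for i in range(L - d)))
        denom = L + weight * sum(taus)
        for a in ALPHABET:
            out.append(seq.count(a) / denom)
        for t in taus:
            out.append(weight * t / denom)
    return out


def roc_auc_naive(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_naive(scores, labels):
    """AP = sum_n (R_n - R_{n-1}) P_n over descending unique thresholds."""
    n_pos = sum(labels)
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp) if tp + fp else 0.0
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# ---------------------------------------------------------------------------
# Exhaustive-subset Shapley values on a fitted sklearn tree
# ---------------------------------------------------------------------------

def tree_conditional_expectation(tree, leaf_value, x, known, node=0):
    """E[f(x) | features in `known`], covers weighting unknown splits."""
    if tree.children_left[node] < 0:
        return leaf_value[node]
    f = tree.feature[node]
    left, right = tree.children_left[node], tree.children_right[node]
    if f in known:
        nxt = left if x[f] <= tree.threshold[node] else right
        return tree_conditional_expectation(tree, leaf_value, x, known, nxt)
    c = tree.weighted_n_node_samples
    return (
        c[left] * tree_conditional_expectation(tree, leaf_value, x, known, left)
        + c[right] * tree_conditional_expectation(tree, leaf_value, x, known, right)
    ) / c[node]


def exhaustive_tree_shap(tree, leaf_value, x, n_features):
    """Shapley values by explicit enumeration of all feature subsets."""
    used = sorted(set(int(f) for f in tree.feature if f >= 0))
    phi = [0.0] * n_features
    m = len(used)
    for i in used:
        others = [f for f in used if f != i]
        for k in range(m):
            for subset in itertools.combinations(others, k):
                w = (math.factorial(k) * math.factorial(m - k - 1)
                     / math.factorial(m))
                with_i = tree_conditional_expectation(
                    tree, leaf_value, x, set(subset) | {i})
                without = tree_conditional_expectation(
                    tree, leaf_value, x, set(subset))
                phi[i] += w * (with_i - without)
    return phi
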