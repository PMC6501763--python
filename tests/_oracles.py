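"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Mk oracle sums the
full joint likelihood over every internal-state assignment, interval
merging is done by painting a boolean mask, and random binary trees are
grown by naive joining.
"""

from __future__ import annotations

import itertools

import numpy as np

from ucekit.mkasr import CharacterData, mk_transition, read_newick


def enum_mk(tree, chars: CharacterData, alpha: float):
    """Exhaustive-enumeration Mk log-likelihood and marginals.

    Sums P(data, internal assignment) over all k^I assignments with a
    uniform root prior; marginals are the normalised per-node sums.
    Vectorised over assignments so trees with up to 8 internal nodes and
    k <= 4 stay fast.
    """
    k = chars.k
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    index = {id(n): i for i, n in enumerate(internals)}
    n_int = len(internals)
    assigns = np.array(list(itertools.product(range(k), repeat=n_int)), dtype=int)
    logw = np.full(len(assigns), -np.log(k))  # root prior
    for node in nodes:
        parent = node.parent_node
        if parent is None:
            continue
        P = mk_transition(k, alpha, node.edge.length or 0.0)
        ps = assigns[:, index[id(parent)]]
        if node.is_leaf():
            cs = np.full(len(assigns), chars.states[node.taxon.label])
        else:
            cs = assigns[:, index[id(node)]]
        logw = logw + np.log(P[ps, cs])
    w = np.exp(logw - logw.max())
    total = w.sum()
    marginals = {}
    for node in internals:
        col = assigns[:, index[id(node)]]
        m = np.array([w[col == s].sum() for s in range(k)]) / total
        marginals[id(node)] = m
    logL = np.log(total) + logw.max()
    return float(logL), marginals


def random_binary_tree(n_tips: int, rng: np.random.Generator, prefix: str = "t"):
    """Random rooted binary tree with uniform-ish branch lengths."""
    items = [f"{prefix}{i}:{rng.uniform(0.05, 1.5):.4f}" for i in range(n_tips)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b}):{rng.uniform(0.05, 1.5):.4f}")
    s = items[0]
    return read_newick(s[: s.rfind(":")] + ";")


def merge_intervals_oracle(spans, n: int):
    """Interval union by painting a mask over 1..n."""
    mask = np.zeros(n + 2, dtype=bool)
    for s, e in spans:
        mask[s : e + 1] = True
    out = []
    i = 1
    while i <= n:
        if mask[i]:
            j = i
            while j <= n and mask[j]:
                j += 1
            out.append((i, j - 1))
            i = j
        else:
            i += 1
    return out


def random_alignment(rng: np.random.Generator, n_taxa=8, n_cols=120, gap_p=0.05):
    """Random gappy DNA alignment with some conserved columns."""
    from ucekit.alignment import LocusAlignment

    base = rng.integers(0, 4, n_cols)
    arr = np.tile(base, (n_taxa, 1))
    noisy = rng.random((n_taxa, n_cols)) < rng.uniform(0.0, 0.8, n_cols)
    arr = np.where(noisy, rng.integers(0, 4, (n_taxa, n_cols)), arr)
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)[arr]
    gaps = rng.random((n_taxa, n_cols)) < gap_p
    chars = np.where(gaps, ord("-"), chars).astype(np.uint8)
    taxa = [f"s{i}" for i in range(n_taxa)]
    rows = {t: chars[i].tobytes().decode("ascii") for i, t in enumerate(taxa)}
    return LocusAlignment("rand", taxa, rows)
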