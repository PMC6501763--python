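"""One-parameter Markov k-state (Mk) model on a fixed rooted tree.

The Mk model (Lewis 2001) is a continuous-time Markov chain on k unordered
states with equal exchange rates; with rate alpha and branch length t the
transition probabilities have the closed form

    P(same)  = 1/k + (k-1)/k * exp(-k * alpha * t)
    P(other) = 1/k * (1 - exp(-k * alpha * t))

Likelihoods are computed with Felsenstein's pruning algorithm (per-node
scaling guards against underflow); ancestral states are marginal
("proportional likelihood") probabilities from an inside–outside pass,
normalised to sum to one at every internal node. The root prior is the
uniform distribution 1/k. Topologies are inputs, never inferred;
polytomies are rejected rather than resolved silently.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CharacterData",
    "MkResult",
    "read_newick",
    "write_newick",
    "mk_transition",
    "pruning_loglik",
    "fit_rate",
    "marginal_asr",
    "fit_mk",
    "read_traits",
    "write_asr_table",
]

RATE_BOUNDS = (1e-8, 100.0)


@dataclass
class CharacterData:
    """A single discrete character: taxon -> state index in 0..k-1."""

    states: dict[str, int]
    k: int
    state_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        bad = {t: s for t, s in self.states.items() if not 0 <= s < self.k}
        if bad:
            raise ValueError(f"state indices outside 0..{self.k - 1}: {bad}")
        if self.state_labels is None:
            self.state_labels = [str(i) for i in range(self.k)]


@dataclass
class MkResult:
    rate: float
    logL: float
    node_marginals: dict[str, np.ndarray]     # internal-node label -> k probs
    node_tipsets: dict[str, tuple[str, ...]]  # internal-node label -> tips below


# ---------------------------------------------------------------------------
# Newick IO with validation
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted, binary Newick tree with branch lengths.

    Polytomies, single-child roots, and missing branch lengths raise
    ``ValueError``.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    for node in tree.preorder_node_iter():
        nchild = len(node.child_nodes())
        if node is tree.seed_node:
            if nchild != 2:
                raise ValueError(f"root must have 2 children, found {nchild}")
        elif nchild not in (0, 2):
            raise ValueError(f"polytomy or unary node with {nchild} children")
        if node is not tree.seed_node and node.edge.length is None:
            raise ValueError("branch without a length")
        if node is not tree.seed_node and node.edge.length < 0:
            raise ValueError("negative branch length")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def _label_internals(tree: dendropy.Tree) -> None:
    """Assign stable postorder labels n0, n1, ... to unlabeled internals."""
    i = 0
    for node in tree.postorder_internal_node_iter():
        if node.label is None:
            node.label = f"n{i}"
        i += 1


# ---------------------------------------------------------------------------
# Model core
# ---------------------------------------------------------------------------

def mk_transition(k: int, alpha: float, t: float) -> np.ndarray:
    """Mk transition probability matrix for rate ``alpha`` and time ``t``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    e = np.exp(-k * alpha * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1.0) / k * e)
    return P


def _as_char_list(chars) -> list[CharacterData]:
    if isinstance(chars, CharacterData):
        return [chars]
    return list(chars)


def _check_tips(tree: dendropy.Tree, chars: CharacterData) -> None:
    missing = [
        lf.taxon.label
        for lf in tree.leaf_node_iter()
        if lf.taxon.label not in chars.states
    ]
    if missing:
        raise ValueError(f"tips without a character state: {missing}")


def _pruning_pass_multi(
    tree: dendropy.Tree, k: int, tip_states: dict[str, np.ndarray], alpha: float
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Post-order conditional likelihoods, vectorised over characters.

    ``tip_states[label]`` is an int array of per-character states.
    Returns (partials keyed by id(node), each (n_chars, k); per-character
    accumulated log scale)."""
    n_chars = len(next(iter(tip_states.values())))
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_chars)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros((n_chars, k))
            v[np.arange(n_chars), tip_states[node.taxon.label]] = 1.0
        else:
            v = np.ones((n_chars, k))
            for child in node.child_nodes():
                P = mk_transition(k, alpha, child.edge.length or 0.0)
                v = v * (partials[id(child)] @ P.T)
            m = v.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            v = v / m[:, None]
            logscale += np.log(m)
        partials[id(node)] = v
    return partials, logscale


def _pruning_pass(
    tree: dendropy.Tree, chars: CharacterData, alpha: float
) -> tuple[dict[int, np.ndarray], float]:
    """Single-character view of :func:`_pruning_pass_multi`."""
    tip_states = {t: np.array([s]) for t, s in chars.states.items()}
    partials, logscale = _pruning_pass_multi(tree, chars.k, tip_states, alpha)
    return {key: v[0] for key, v in partials.items()}, float(logscale[0])


def pruning_loglik(tree: dendropy.Tree, chars, alpha: float) -> float:
    """Log-likelihood of the character(s) under Mk with a uniform root
    prior; a list of characters is scored as an independent product."""
    char_list = _as_char_list(chars)
    k = char_list[0].k
    if any(ch.k != k for ch in char_list):
        raise ValueError("all characters must share the same state space")
    for ch in char_list:
        _check_tips(tree, ch)
    tip_states = {
        t: np.array([ch.states[t] for ch in char_list])
        for t in char_list[0].states
    }
    partials, logscale = _pruning_pass_multi(tree, k, tip_states, alpha)
    root = partials[id(tree.seed_node)]
    site = np.log(np.sum(root / k, axis=1)) + logscale
    return float(site.sum())


def fit_rate(tree: dendropy.Tree, chars) -> float:
    """Maximum-likelihood Mk rate by bounded 1-D optimisation.

    When every tip has the same state the likelihood is maximised at
    rate -> 0; the lower bound is returned with a warning.
    """
    char_list = _as_char_list(chars)
    for ch in char_list:
        _check_tips(tree, ch)
    observed = {s for ch in char_list for s in ch.states.values()}
    if len(observed) < 2:
        warnings.warn("character is invariant; rate is at the lower bound")
        return RATE_BOUNDS[0]
    # the profile can have a spurious high-rate plateau next to an interior
    # peak, so bracket the global optimum on a log grid before refining
    grid = np.geomspace(RATE_BOUNDS[0], RATE_BOUNDS[1], 40)
    lls = [pruning_loglik(tree, char_list, a) for a in grid]
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda a: -pruning_loglik(tree, char_list, a),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    best = float(res.x)
    if -res.fun < lls[i]:
        best = float(grid[i])
    return best


def marginal_asr(tree: dendropy.Tree, chars: CharacterData, alpha: float) -> MkResult:
    """Marginal (proportional-likelihood) ancestral states at every
    internal node, via one inside (pruning) and one outside pass."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    _check_tips(tree, chars)
    k = chars.k
    _label_internals(tree)
    partials, logscale = _pruning_pass(tree, chars, alpha)
    root = tree.seed_node
    logL = float(np.log(np.sum(partials[id(root)] / k)) + logscale)

    outside: dict[int, np.ndarray] = {id(root): np.full(k, 1.0 / k)}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        down = {
            id(c): mk_transition(k, alpha, c.edge.length or 0.0) @ partials[id(c)]
            for c in children
        }
        for child in children:
            msg = outside[id(node)].copy()
            for sib in children:
                if sib is not child:
                    msg = msg * down[id(sib)]
            P = mk_transition(k, alpha, child.edge.length or 0.0)
            v = P.T @ msg
            m = v.max()
            outside[id(child)] = v / m if m > 0 else v

    marginals: dict[str, np.ndarray] = {}
    tipsets: dict[str, tuple[str, ...]] = {}
    for node in tree.postorder_internal_node_iter():
        v = partials[id(node)] * outside[id(node)]
        marginals[node.label] = v / v.sum()
        tipsets[node.label] = tuple(
            sorted(lf.taxon.label for lf in node.leaf_iter())
        )
    return MkResult(rate=alpha, logL=logL, node_marginals=marginals, node_tipsets=tipsets)


def fit_mk(tree: dendropy.Tree, chars: CharacterData) -> MkResult:
    """Fit the rate, then reconstruct marginal ancestral states at the MLE."""
    alpha = fit_rate(tree, chars)
    return marginal_asr(tree, chars, alpha)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def read_traits(
    path: str | os.PathLike, k: int | None = None, state_labels: list[str] | None = None
) -> CharacterData:
    """Read a two-column TSV (taxon, state label or index).

    With ``state_labels`` given, states are looked up by label; otherwise
    labels are collected in sorted order (or taken as integer indices when
    every value parses as an integer).
    """
    pairs: list[tuple[str, str]] = []
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            taxon, state = line.split("\t")[:2]
            if taxon.lower() == "taxon":
                continue
            pairs.append((taxon, state))
    values = [s for _, s in pairs]
    if all(v.lstrip("-").isdigit() for v in values):
        states = {t: int(v) for t, v in pairs}
        kk = k or (max(states.values()) + 1)
        return CharacterData(states, max(kk, 2), state_labels)
    if state_labels is None:
        state_labels = sorted(set(values))
    index = {lab: i for i, lab in enumerate(state_labels)}
    states = {t: index[v] for t, v in pairs}
    return CharacterData(states, k or len(state_labels), state_labels)


def write_asr_table(result: MkResult, path: str | os.PathLike, labels: list[str] | None = None) -> None:
    """Write per-node proportional likelihoods (asr_nodes.tsv)."""
    k = len(next(iter(result.node_marginals.values())))
    labels = labels or [f"state{i}" for i in range(k)]
    with open(os.fspath(path), "w") as fh:
        fh.write("node\ttips\t" + "\t".join(labels) + "\n")
        for node in sorted(result.node_marginals):
            probs = result.node_marginals[node]
            tips = ",".join(result.node_tipsets[node])
            fh.write(node + "\t" + tips + "\t" + "\t".join(f"{p:.6f}" for p in probs) + "\n")
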