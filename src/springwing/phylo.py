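"""Discrete-trait ancestral-state reconstruction on a time-calibrated tree.

Flight-muscle type (synchronous vs asynchronous) is modelled as a
continuous-time Markov chain (Mk model) evolving along a rooted phylogeny
with branch lengths in millions of years.  The likelihood is computed by
Felsenstein pruning with per-branch transition probabilities from the
matrix exponential (closed form for two states); marginal node posteriors
follow from combining the partial likelihoods below and above each node
(the re-rooting formulation).  Wingless or unknown tips are coded as
ambiguous (all states allowed) by default.

The iterative node-constraining procedure asks for the probability that an
entire ancestor-to-descendant chain of internal nodes shares one state: at
each step the nodes already visited are clamped to that state, the next
node's marginal posterior is recorded, and the step probabilities multiply
into the joint (chain rule).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

__all__ = [
    "STATES",
    "TraitPhylogeny",
    "MkModel",
    "NodePosteriors",
    "read_newick",
    "read_traits",
    "mk_log_likelihood",
    "fit_rates",
    "marginal_ancestral_states",
    "constrained_path_probability",
    "simulate_trait_evolution",
]

#: Default two-state coding of flight-muscle type.
STATES = ("synchronous", "asynchronous")

#: Trait-table aliases mapping onto states or onto ambiguity.
_ALIASES = {
    "sync": 0, "synchronous": 0,
    "async": 1, "asynchronous": 1,
}
_AMBIGUOUS = {"wingless", "unknown", "ambiguous", "?", "na", ""}


class TraitPhylogeny:
    """Rooted tree with branch lengths, tip state sets and node ids.

    Tip assignments are boolean masks over the state space; an ambiguous
    tip allows every state.  Internal nodes receive stable identifiers
    ("N0", "N1", ... in preorder) unless the tree supplies labels.
    """

    def __init__(self, tree: dendropy.Tree, states: tuple = STATES):
        self.tree = tree
        self.states = tuple(states)
        self.n_states = len(self.states)
        self._index()
        # all tips ambiguous until traits are assigned
        self.tip_masks: dict[str, np.ndarray] = {
            label: np.ones(self.n_states, dtype=bool) for label in self.tip_labels
        }

    def _index(self) -> None:
        nodes = list(self.tree.preorder_node_iter())
        self.nodes = nodes
        self.node_ids: list[str] = []
        seen = set()
        counter = 0
        for nd in nodes:
            if nd.is_leaf():
                nid = nd.taxon.label if nd.taxon is not None else f"T{counter}"
            elif nd.label:
                nid = str(nd.label)
            else:
                nid = f"N{counter}"
            while nid in seen:
                nid = f"{nid}_dup"
            seen.add(nid)
            self.node_ids.append(nid)
            counter += 1
        self.id_to_index = {nid: i for i, nid in enumerate(self.node_ids)}
        self.parent = np.full(len(nodes), -1, dtype=int)
        pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.blen = np.zeros(len(nodes))
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = pos[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
                if self.blen[i] < 0:
                    raise ValueError(f"negative branch length at {self.node_ids[i]}")
        self.is_tip = np.array([nd.is_leaf() for nd in nodes])
        self.tip_labels = [
            nd.taxon.label if nd.taxon is not None else self.node_ids[i]
            for i, nd in enumerate(nodes) if nd.is_leaf()
        ]
        self.postorder = list(reversed(range(len(nodes))))  # preorder reversed

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def internal_ids(self) -> list[str]:
        return [self.node_ids[i] for i in range(len(self.nodes)) if not self.is_tip[i]]

    def set_tip_state(self, label: str, state) -> None:
        mask = np.zeros(self.n_states, dtype=bool)
        if state is None:
            mask[:] = True
        elif isinstance(state, (set, frozenset, list, tuple)):
            for s in state:
                mask[self.states.index(s) if isinstance(s, str) else s] = True
        elif isinstance(state, str):
            mask[self.states.index(state)] = True
        else:
            mask[int(state)] = True
        self.tip_masks[label] = mask

    def assign_traits(self, table: dict[str, str]) -> dict:
        """Attach a {species: state-string} table; returns a mismatch report.

        Tips absent from the table are coded ambiguous with a warning
        (mirroring unknown-muscle-type handling); table entries without a
        matching tip are reported.
        """
        tipset = set(self.tip_labels)
        unmatched_rows = [sp for sp in table if sp not in tipset]
        missing_tips = [tp for tp in self.tip_labels if tp not in table]
        for tip in self.tip_labels:
            if tip not in table:
                self.tip_masks[tip] = np.ones(self.n_states, dtype=bool)
                continue
            raw = str(table[tip]).strip().lower()
            if raw in _AMBIGUOUS:
                self.tip_masks[tip] = np.ones(self.n_states, dtype=bool)
            elif raw in _ALIASES and _ALIASES[raw] < self.n_states:
                mask = np.zeros(self.n_states, dtype=bool)
                mask[_ALIASES[raw]] = True
                self.tip_masks[tip] = mask
            elif raw in self.states:
                mask = np.zeros(self.n_states, dtype=bool)
                mask[self.states.index(raw)] = True
                self.tip_masks[tip] = mask
            else:
                raise ValueError(f"unrecognized state {table[tip]!r} for tip {tip!r}")
        if missing_tips:
            warnings.warn(
                f"{len(missing_tips)} tips absent from trait table coded "
                f"ambiguous: {missing_tips[:5]}...", stacklevel=2
            )
        return {"unmatched_rows": unmatched_rows, "missing_tips": missing_tips}

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_newick(source: str, states: tuple = STATES) -> TraitPhylogeny:
    """Parse a rooted Newick tree (text or path) into a TraitPhylogeny."""
    try:
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick input: {exc}") from exc
    return TraitPhylogeny(tree, states=states)


def read_traits(source) -> dict[str, str]:
    """Read a comma-separated (species, state) table into a dict."""
    import pandas as pd

    df = pd.read_csv(source if not isinstance(source, str) or "\n" not in source
                     else io.StringIO(source))
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    sp_col = "species" if "species" in cols else cols[0]
    st_col = "state" if "state" in cols else cols[1]
    return dict(zip(df[sp_col].astype(str), df[st_col].astype(str)))


@dataclass(frozen=True)
class MkModel:
    """Mk model of discrete character evolution.

    ``parameterization`` is "ER" (single rate) or "ARD" (one rate per
    ordered state pair); ``rates`` holds 1 or k(k-1) values (1/Myr).
    """

    n_states: int = 2
    parameterization: str = "ER"
    rates: tuple = (0.01,)
    root_prior: str = "flat"
    log_likelihood: float = float("nan")
    aic: float = float("nan")
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.parameterization not in ("ER", "ARD"):
            raise ValueError("parameterization must be 'ER' or 'ARD'")
        expected = 1 if self.parameterization == "ER" else self.n_states * (self.n_states - 1)
        if len(self.rates) != expected:
            raise ValueError(f"expected {expected} rates, got {len(self.rates)}")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be non-negative")
        if self.root_prior not in ("flat", "stationary"):
            raise ValueError("root_prior must be 'flat' or 'stationary'")

    @property
    def Q(self) -> np.ndarray:
        k = self.n_states
        Q = np.zeros((k, k))
        if self.parameterization == "ER":
            q = self.rates[0]
            Q[:] = q
        else:
            it = iter(self.rates)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = next(it)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary(self) -> np.ndarray:
        Q = self.Q
        if np.allclose(Q, 0.0):
            return np.full(self.n_states, 1.0 / self.n_states)
        # left null vector of Q
        w, v = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def prior(self) -> np.ndarray:
        if self.root_prior == "flat":
            return np.full(self.n_states, 1.0 / self.n_states)
        return self.stationary()

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); closed form for two states."""
        if self.n_states == 2:
            if self.parameterization == "ER":
                q01 = q10 = self.rates[0]
            else:
                q01, q10 = self.rates
            s = q01 + q10
            if s == 0.0 or t == 0.0:
                return np.eye(2)
            e = np.exp(-s * t)
            pi0, pi1 = q10 / s, q01 / s
            return np.array(
                [[pi0 + pi1 * e, pi1 * (1.0 - e)],
                 [pi0 * (1.0 - e), pi1 + pi0 * e]]
            )
        return expm(self.Q * t)


# ---------------------------------------------------------------------------
# Pruning


def _masks(phylo: TraitPhylogeny, constraints: dict | None) -> list:
    """Per-node allowed-state masks (tips from assignments, clamps on top)."""
    n = len(phylo.nodes)
    masks = [np.ones(phylo.n_states) for _ in range(n)]
    for i in range(n):
        if phylo.is_tip[i]:
            label = (phylo.nodes[i].taxon.label
                     if phylo.nodes[i].taxon is not None else phylo.node_ids[i])
            masks[i] = phylo.tip_masks[label].astype(float)
    if constraints:
        for nid, allowed in constraints.items():
            idx = phylo.id_to_index[nid]
            m = np.zeros(phylo.n_states)
            for s in allowed:
                m[phylo.states.index(s) if isinstance(s, str) else int(s)] = 1.0
            masks[idx] = masks[idx] * m
    return masks


def _down_partials(phylo, model, masks):
    """Post-order partial likelihoods D_v(s) with log-scaling.

    Returns (D, logscale) where the tree log-likelihood contribution of
    rescaling is accumulated in ``logscale``.
    """
    n = len(phylo.nodes)
    D = np.zeros((n, phylo.n_states))
    logscale = 0.0
    P_cache = {}
    for i in phylo.postorder:
        if phylo.is_tip[i]:
            D[i] = masks[i]
        else:
            part = np.ones(phylo.n_states)
            for c in phylo.children[i]:
                t = phylo.blen[c]
                P = P_cache.get(t)
                if P is None:
                    P = model.transition(t)
                    P_cache[t] = P
                part = part * (P @ D[c])
            D[i] = part * masks[i]
            mx = D[i].max()
            if mx > 0 and (mx < 1e-12 or mx > 1e12):
                D[i] /= mx
                logscale += np.log(mx)
    return D, logscale, P_cache


def mk_log_likelihood(
    phylo: TraitPhylogeny, model: MkModel, constraints: dict | None = None
) -> float:
    """Felsenstein-pruning log-likelihood of the tip data under the model.

    Ambiguous tips contribute partial likelihood 1 for every allowed state;
    ``constraints`` optionally clamps internal nodes to subsets of states.
    """
    masks = _masks(phylo, constraints)
    D, logscale, _ = _down_partials(phylo, model, masks)
    root = 0
    lik = float(model.prior() @ D[root])
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik) + logscale)


@dataclass
class NodePosteriors:
    """Marginal state posteriors per internal node."""

    node_ids: list
    probabilities: np.ndarray   # (n_nodes, n_states)
    states: tuple

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.probabilities[self.node_ids.index(node_id)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.probabilities,
                          columns=[f"P_{s}" for s in self.states])
        df.insert(0, "node_id", self.node_ids)
        return df


def marginal_ancestral_states(
    phylo: TraitPhylogeny, model: MkModel, constraints: dict | None = None
) -> NodePosteriors:
    """Marginal posterior state probabilities at every internal node.

    Combines the pruning partials below each node with the partials of the
    rest of the tree above it (re-rooting formulation); each node's vector
    sums to one.
    """
    masks = _masks(phylo, constraints)
    D, _, P_cache = _down_partials(phylo, model, masks)
    n = len(phylo.nodes)
    U = np.zeros((n, phylo.n_states))
    U[0] = model.prior()
    for i in range(n):          # preorder: parents before children
        if phylo.is_tip[i]:
            continue
        for c in phylo.children[i]:
            # contribution of everything above c, seen from c's states
            out = U[i] * masks[i] if i != 0 else U[0] * masks[0]
            for w in phylo.children[i]:
                if w == c:
                    continue
                Pw = P_cache.get(phylo.blen[w])
                if Pw is None:
                    Pw = model.transition(phylo.blen[w])
                out = out * (Pw @ D[w])
            Pc = P_cache.get(phylo.blen[c])
            if Pc is None:
                Pc = model.transition(phylo.blen[c])
            U[c] = out @ Pc
            mx = U[c].max()
            if mx > 0:
                U[c] /= mx
    ids, probs = [], []
    for i in range(n):
        if phylo.is_tip[i]:
            continue
        joint = U[i] * D[i]
        total = joint.sum()
        if total <= 0:
            raise ValueError(
                f"zero marginal likelihood at node {phylo.node_ids[i]} "
                "(inconsistent constraints?)"
            )
        ids.append(phylo.node_ids[i])
        probs.append(joint / total)
    return NodePosteriors(ids, np.asarray(probs), phylo.states)


def fit_rates(
    phylo: TraitPhylogeny, parameterization: str = "ER",
    root_prior: str = "flat", q0: float | None = None,
) -> MkModel:
    """Maximum-likelihood Mk rates with AIC.

    Optimizes log-rates with L-BFGS-B from a heuristic start (one expected
    change over the tree length); boundary solutions (rates pinned at the
    box edge) are flagged.
    """
    k = len(STATES) if phylo.n_states == 2 else phylo.n_states
    n_par = 1 if parameterization == "ER" else k * (k - 1)
    informative = sum(int(m.sum() == 1) for m in phylo.tip_masks.values())
    if informative < 2:
        raise ValueError("need at least 2 unambiguously coded tips")
    tl = max(phylo.total_branch_length, 1e-9)
    start = np.log(np.full(n_par, q0 if q0 is not None else 1.0 / tl))
    lo, hi = np.log(1e-9 / tl), np.log(1e5 / tl)

    def nll(logq):
        model = MkModel(k, parameterization, tuple(np.exp(logq)), root_prior)
        return -mk_log_likelihood(phylo, model)

    out = minimize(nll, start, method="L-BFGS-B",
                   bounds=[(lo, hi)] * n_par)
    rates = np.exp(out.x)
    # boundary: pinned at the box, or a degenerate solution with (nearly)
    # zero expected changes over the whole tree
    boundary = bool(
        np.any(out.x <= lo + 1e-6)
        or np.any(out.x >= hi - 1e-6)
        or np.any(rates * tl < 1e-3)
    )
    ll = -float(out.fun)
    return MkModel(k, parameterization, tuple(rates), root_prior,
                   log_likelihood=ll, aic=2.0 * n_par - 2.0 * ll,
                   boundary=boundary)


def constrained_path_probability(
    phylo: TraitPhylogeny, model: MkModel, node_path: list[str], state,
) -> tuple[float, list[float]]:
    """Joint probability that an ancestor-to-descendant node chain shares
    ``state``, by iterative clamping.

    Step i computes the marginal posterior of ``state`` at node i with
    nodes 1..i-1 clamped to ``state``; the returned product equals the
    joint posterior probability of the whole chain being in that state
    (chain rule).  Also returns the per-step factors.  The complement
    1 - product is the probability that at least one node on the chain was
    in another state.
    """
    s_idx = phylo.states.index(state) if isinstance(state, str) else int(state)
    idxs = [phylo.id_to_index[nid] for nid in node_path]
    for a, b in zip(idxs, idxs[1:]):
        # verify ancestor relation along the chain
        p = b
        ok = False
        while p != -1:
            p = phylo.parent[p]
            if p == a:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"{node_path[idxs.index(a)]} is not an ancestor of "
                f"{phylo.node_ids[b]}: path must be an ancestor chain"
            )
    factors: list[float] = []
    clamps: dict = {}
    for nid in node_path:
        post = marginal_ancestral_states(phylo, model, constraints=clamps or None)
        factors.append(float(post[nid][s_idx]))
        clamps[nid] = {s_idx}
    prod = float(np.prod(factors))
    return prod, factors


def simulate_trait_evolution(
    n_tips: int,
    model: MkModel,
    seed: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    tree_depth: float | None = None,
    states: tuple = STATES,
):
    """Simulate a birth-death tree and evolve a discrete trait along it.

    The root state is drawn from the model's root prior and each branch
    samples its endpoint state from the transition matrix.  Returns the
    TraitPhylogeny (tips assigned the simulated states) and the full truth
    mapping node_id -> state index.  Deterministic given ``seed``.
    """
    import random

    rng_tree = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate, death_rate, num_extant_tips=n_tips, rng=rng_tree
    )
    tree.seed_node.edge.length = 0.0
    if tree_depth is not None:
        depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        if depth > 0:
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    e.length *= tree_depth / depth
    phylo = TraitPhylogeny(tree, states=states)
    rng = np.random.default_rng(seed)
    truth: dict[str, int] = {}
    state_of: dict[int, int] = {}
    prior = model.prior()
    for i in range(len(phylo.nodes)):
        if phylo.parent[i] == -1:
            s = int(rng.choice(model.n_states, p=prior))
        else:
            P = model.transition(phylo.blen[i])
            s = int(rng.choice(model.n_states, p=P[state_of[phylo.parent[i]]]))
        state_of[i] = s
        truth[phylo.node_ids[i]] = s
    for i, tip in enumerate(phylo.nodes):
        if phylo.is_tip[i]:
            label = tip.taxon.label if tip.taxon is not None else phylo.node_ids[i]
            phylo.set_tip_state(label, state_of[i])
    return phylo, truth
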