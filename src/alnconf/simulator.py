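"""Indel-aware sequence evolution along a tree.

Evolves a root sequence down a rooted tree with branch lengths in expected
substitutions per site.  Substitutions follow a reversible amino-acid model
(LG by default, Poisson/uniform available for closed-form checks) with
among-site rate variation (continuous gamma + proportion of invariant
sites).  Insertions and deletions arrive as a Poisson process per branch;
lengths follow a truncated power law with the cap min(ceil(10% of the
current sequence length), 25).  The simulator emits the true alignment (the
complete indel history), the ungapped leaf sequences, per-site rates and an
event log.

Simplifications (documented): substitutions are applied over the full branch
before the branch's indels; residues inserted on a branch are drawn from the
equilibrium frequencies and do not further substitute on that branch; the
number of indel events on a branch is Poisson with mean (ins_rate +
del_rate) * branch_length * L, with L the sequence length at the top of the
branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from alnconf._lg import LG_FREQUENCIES, lg_exchangeability_matrix
from alnconf.guide_tree import Tree, TreeNode
from alnconf.msa import AA_ORDER, Msa, Sequence

DEFAULT_INDEL_RATE = 0.03  # events per substitution per site
DEFAULT_ZIPF_EXPONENT = 1.7


@dataclass(frozen=True)
class EvolModel:
    """Substitution + indel model parameters."""

    substitution_model: str = "LG"  # or "poisson"
    alpha: float = 1.0  # gamma shape for among-site rates
    pinv: float = 0.0  # proportion of invariant sites
    ins_rate: float = DEFAULT_INDEL_RATE
    del_rate: float = DEFAULT_INDEL_RATE
    zipf_exponent: float = DEFAULT_ZIPF_EXPONENT
    max_indel_cap: int = 25
    max_indel_frac: float = 0.10
    root_length: int = 100

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 <= self.pinv < 1:
            raise ValueError("pinv must be in [0, 1)")
        if self.ins_rate < 0 or self.del_rate < 0:
            raise ValueError("indel rates must be >= 0")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.substitution_model.lower() not in ("lg", "poisson"):
            raise ValueError(f"unknown substitution model {self.substitution_model!r}")

    def rate_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(Q, pi): rate matrix normalized to mean rate 1, and equilibrium."""
        if self.substitution_model.lower() == "lg":
            s = lg_exchangeability_matrix()
            pi = LG_FREQUENCIES.copy()
        else:
            s = np.ones((20, 20)) - np.eye(20)
            pi = np.full(20, 1 / 20)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale, pi


@dataclass(frozen=True)
class IndelEvent:
    branch: str  # name/id of the child node of the branch
    kind: str  # "insertion" | "deletion"
    position: int  # 0-based position in the node's sequence at event time
    length: int


@dataclass
class SimResult:
    true_msa: Msa
    sequences: list[Sequence]
    site_rates: np.ndarray  # root sites only
    events: list[IndelEvent]
    #: total columns ever created (root sites + inserted sites); columns
    #: surviving in no leaf are dropped from true_msa
    n_created_columns: int = 0

    @property
    def n_inserted_columns(self) -> int:
        return sum(e.length for e in self.events if e.kind == "insertion")


def sample_site_rates(
    alpha: float, pinv: float, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-site rate multipliers: 0 with probability pinv, else
    Gamma(alpha, mean 1)."""
    rates = rng.gamma(alpha, 1.0 / alpha, size=L)
    rates[rng.random(L) < pinv] = 0.0
    return rates


def _truncated_zipf(exponent: float, max_len: int, rng: np.random.Generator) -> int:
    if max_len <= 1:
        return 1
    lens = np.arange(1, max_len + 1)
    p = lens ** (-exponent)
    return int(rng.choice(lens, p=p / p.sum()))


class _Eig:
    """Spectral decomposition of a reversible rate matrix, giving transition
    probabilities P(t) for arbitrary per-site rate scalings in one matmul."""

    def __init__(self, q: np.ndarray, pi: np.ndarray) -> None:
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        self.w = w
        self.left = v / sq[:, None]  # row x of P uses v[x, :] / sqrt(pi_x)
        self.right = (v * sq[:, None]).T

    def rows(self, states: np.ndarray, t_rates: np.ndarray) -> np.ndarray:
        """P(t_rates[s])[states[s], :] for every site s, shape (L, 20)."""
        lam = np.exp(np.outer(t_rates, self.w))  # (L, 20)
        rows = self.left[states] * lam  # (L, 20) in eigenbasis
        p = rows @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def _sample_categorical_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(p.shape[0])
    cum = np.cumsum(p, axis=1)
    return (u[:, None] > cum).sum(axis=1).clip(max=p.shape[1] - 1)


def simulate(tree: Tree, model: EvolModel, rng: np.random.Generator) -> SimResult:
    """Evolve sequences along ``tree`` and return the true alignment.

    The root sequence (length ``model.root_length``) is drawn from the
    equilibrium frequencies; every site carries a rate multiplier drawn via
    :func:`sample_site_rates`.  Inserted sites receive fresh equilibrium
    residues and fresh rates.  Deterministic given the generator state.
    """
    q, pi = model.rate_matrix()
    eig = _Eig(q, pi)
    L0 = model.root_length

    root_states = rng.choice(20, size=L0, p=pi)
    root_rates = sample_site_rates(model.alpha, model.pinv, L0, rng)

    # master column order: every column ever created, in alignment order
    master: list[int] = list(range(L0))
    next_col = [L0]
    events: list[IndelEvent] = []
    leaf_sites: dict[str, tuple[list[int], list[int]]] = {}
    n_internal = [0]

    total_indel = model.ins_rate + model.del_rate

    def evolve_branch(
        cols: list[int], states: list[int], rates: list[int], node: TreeNode, name: str
    ) -> tuple[list[int], list[int], list[float]]:
        t = node.length
        states_arr = np.array(states, dtype=np.int64)
        rates_arr = np.array(rates, dtype=float)
        if t > 0 and states_arr.size:
            p = eig.rows(states_arr, t * rates_arr)
            states_arr = _sample_categorical_rows(p, rng)
        cols = list(cols)
        states = list(states_arr)
        rates = list(rates_arr)
        if total_indel > 0 and t > 0:
            n_events = rng.poisson(total_indel * t * len(cols))
            for _ in range(n_events):
                L = len(cols)
                if L == 0:
                    break
                max_len = min(int(np.ceil(model.max_indel_frac * L)), model.max_indel_cap)
                max_len = max(max_len, 1)
                is_ins = rng.random() < model.ins_rate / total_indel
                length = _truncated_zipf(model.zipf_exponent, max_len, rng)
                if is_ins:
                    pos = int(rng.integers(0, L + 1))  # slot, after pos-1
                    new_states = rng.choice(20, size=length, p=pi)
                    new_rates = sample_site_rates(model.alpha, model.pinv, length, rng)
                    new_cols = list(range(next_col[0], next_col[0] + length))
                    next_col[0] += length
                    if pos == 0:
                        mpos = master.index(cols[0])
                    else:
                        mpos = master.index(cols[pos - 1]) + 1
                    master[mpos:mpos] = new_cols
                    cols[pos:pos] = new_cols
                    states[pos:pos] = list(new_states)
                    rates[pos:pos] = list(new_rates)
                    events.append(IndelEvent(name, "insertion", pos, length))
                else:
                    pos = int(rng.integers(0, L))
                    end = min(pos + length, L)
                    if end - pos >= L:
                        continue  # refuse to delete the whole sequence
                    del cols[pos:end]
                    del states[pos:end]
                    del rates[pos:end]
                    events.append(IndelEvent(name, "deletion", pos, end - pos))
        return cols, states, rates

    def walk(node: TreeNode, cols: list[int], states: list[int], rates: list[float]) -> None:
        for child in node.children:
            if child.is_leaf:
                name = child.name
            else:
                n_internal[0] += 1
                name = f"internal_{n_internal[0]}"
            c, s, r = evolve_branch(cols, states, rates, child, name)
            if child.is_leaf:
                leaf_sites[child.name] = (c, s)
            else:
                walk(child, c, s, r)

    walk(tree.root, master[:L0], list(root_states), list(root_rates))

    leaf_names = tree.leaf_names()
    col_index = {c: k for k, c in enumerate(master)}
    used = np.zeros(len(master), dtype=bool)
    rows_codes = {}
    for name in leaf_names:
        cols, states = leaf_sites[name]
        idx = np.array([col_index[c] for c in cols], dtype=np.int64)
        used[idx] = True
        rows_codes[name] = (idx, np.array(states, dtype=np.int64))
    keep = np.flatnonzero(used)
    remap = -np.ones(len(master), dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    rows = []
    for name in leaf_names:
        idx, states = rows_codes[name]
        row = np.full(keep.size, "-", dtype="U1")
        row[remap[idx]] = [AA_ORDER[s] for s in states]
        rows.append("".join(row))
    true_msa = Msa(leaf_names, rows)
    sequences = true_msa.sequences()
    return SimResult(true_msa, sequences, root_rates, events, len(master))


def random_ultrametric_tree(
    n_taxa: int, depth: float, rng: np.random.Generator, prefix: str = "t"
) -> Tree:
    """Random binary ultrametric tree with root-to-tip path = ``depth``.

    Topology by uniform random sequential pair joining; internal node
    heights are sorted uniforms on (0, depth), the root forced to
    ``depth``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    heights = np.sort(rng.uniform(0, depth, size=n_taxa - 1))
    heights[-1] = depth
    nodes: list[tuple[TreeNode, float]] = [
        (TreeNode(f"{prefix}{i + 1}"), 0.0) for i in range(n_taxa)
    ]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        na.length = h - ha
        nb.length = h - hb
        parent = TreeNode(children=[na, nb])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, h))
    return Tree(nodes[0][0])
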