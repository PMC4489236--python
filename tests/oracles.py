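"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: alignment scoring by
exhaustive enumeration of all global alignments, column/pair scoring by
direct all-against-all comparison, and AUC via the Mann-Whitney U statistic.
"""

from __future__ import annotations

import itertools

import numpy as np

from alnconf.msa import Msa, column_keys, iter_all_pairs


def enumerate_alignment_score(
    s1: str,
    s2: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best score over *all* global alignments of two strings.

    Alignments are enumerated as move sequences (diagonal / gap-in-s2 /
    gap-in-s1); each complete alignment is scored from scratch: sum of
    match/mismatch over aligned pairs minus, for every maximal gap run of
    length g, gap_open + (g - 1) * gap_extend.
    """
    best = [-np.inf]

    def walk(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        if i == len(s1) and j == len(s2):
            best[0] = max(best[0], _score_alignment(cols, match, mismatch, gap_open, gap_extend))
            return
        if i < len(s1) and j < len(s2):
            walk(i + 1, j + 1, cols + [(s1[i], s2[j])])
        if i < len(s1):
            walk(i + 1, j, cols + [(s1[i], "-")])
        if j < len(s2):
            walk(i, j + 1, cols + [("-", s2[j])])

    walk(0, 0, [])
    return best[0]


def _score_alignment(cols, match, mismatch, gap_open, gap_extend) -> float:
    score = 0.0
    for row in (0, 1):
        run = 0
        for col in cols:
            if col[row] == "-":
                run += 1
            else:
                if run:
                    score -= gap_open + (run - 1) * gap_extend
                run = 0
        if run:
            score -= gap_open + (run - 1) * gap_extend
    for a, b in cols:
        if a != "-" and b != "-":
            score += match if a == b else mismatch
    return score


def count_gap_openings(msa: Msa) -> int:
    """Number of distinct gap runs over all rows of an alignment."""
    total = 0
    for row in msa.rows:
        in_gap = False
        for c in row:
            if c == "-" and not in_gap:
                total += 1
            in_gap = c == "-"
    return total


def brute_force_cs(ref: Msa, alternatives: list[Msa]) -> np.ndarray:
    """CS by comparing every reference column against every column of every
    alternative (no hashing)."""
    ref_keys = column_keys(ref)
    order = ref.ids
    counts = np.zeros(len(ref_keys))
    for alt in alternatives:
        perm = [alt.ids.index(i) for i in order]
        alt_keys = [tuple(k[p] for p in perm) for k in column_keys(alt)]
        for j, key in enumerate(ref_keys):
            if any(key == ak for ak in alt_keys):
                counts[j] += 1
    return counts / len(alternatives)


def brute_force_pair_scores(ref: Msa, alternatives: list[Msa]) -> dict:
    """Pair scores by materializing the full residue-pair set of every
    alternative."""
    ref_pairs = set(iter_all_pairs(ref))
    counts = {p: 0 for p in ref_pairs}
    for alt in alternatives:
        alt_pairs = set(iter_all_pairs(alt))
        for p in ref_pairs:
            if p in alt_pairs:
                counts[p] += 1
    return {p: c / len(alternatives) for p, c in counts.items()}


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the scaled Mann-Whitney U statistic (midpoint tie handling)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ranks = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def column_matches_truth_brute(inferred: Msa, truth: Msa, col: int) -> bool:
    """Label oracle: inferred column ``col`` is correct iff some truth column
    has the identical participating residue set and identical residue-pair
    set."""
    from alnconf.msa import column_pairs, keys_matrix, GAP

    km_i = keys_matrix(inferred)
    members_i = {
        (inferred.ids[r], int(km_i[r, col]))
        for r in range(inferred.n_sequences)
        if km_i[r, col] != GAP
    }
    pairs_i = column_pairs(inferred, col)
    km_t = keys_matrix(truth)
    for tc in range(truth.length):
        members_t = {
            (truth.ids[r], int(km_t[r, tc]))
            for r in range(truth.n_sequences)
            if km_t[r, tc] != GAP
        }
        if members_t == members_i and column_pairs(truth, tc) == pairs_i:
            return True
    return False


def random_tree_distances(
    n_taxa: int, rng: np.random.Generator
) -> tuple["np.ndarray", list[str], "object"]:
    """A random binary tree with positive branch lengths plus its additive
    leaf-to-leaf distance matrix."""
    from alnconf.guide_tree import Tree, TreeNode

    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(lb, length=float(rng.uniform(0.1, 1.0))) for lb in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 1.0))
        )
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = Tree(TreeNode(children=nodes))

    # path distances via root-to-leaf traversal
    paths: dict[str, list] = {}

    def walk(node, acc):
        if node.is_leaf:
            paths[node.name] = acc + [node]
        for c in node.children:
            walk(c, acc + [node])

    walk(tree.root, [])
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            pa, pb = paths[labels[a]], paths[labels[b]]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            dist = sum(n.length for n in pa[shared:]) + sum(
                n.length for n in pb[shared:]
            )
            d[a, b] = d[b, a] = dist
    return d, labels, tree
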