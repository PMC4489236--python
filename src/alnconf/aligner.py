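"""Internal progressive aligner: affine-gap profile–profile dynamic
programming with controllable head/tail orientation per merge.

Every ensemble member is produced by this aligner, so its determinism
matters: traceback uses a fixed state-preference order (match > delete >
insert), which makes the HEAD merge and the TAIL merge (both profiles
character-reversed, result un-reversed) land on opposite extreme co-optimal
solutions whenever the optimum is not unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence as TSequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from alnconf.msa import ALPHABET, GAP_CODE, Msa, Sequence, msa_from_encoded
from alnconf.guide_tree import Tree

HEAD = 0
TAIL = 1

_MATRIX_CACHE: dict[str, np.ndarray] = {}


def load_substitution_matrix(name_or_path: str) -> np.ndarray:
    """A 21x21 score matrix over ALPHABET (X row/column zeroed).

    ``name_or_path`` is a named matrix shipped with Biopython ("BLOSUM62",
    "PAM250", ...) or a path to a file in NCBI matrix text format.
    """
    key = str(name_or_path)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    if Path(key).is_file():
        raw = substitution_matrices.read(key)
    else:
        raw = substitution_matrices.load(key)
    mat = np.zeros((21, 21))
    for i, a in enumerate(ALPHABET[:20]):
        for j, b in enumerate(ALPHABET[:20]):
            mat[i, j] = raw[a, b]
    if not np.allclose(mat[:20, :20], mat[:20, :20].T):
        raise ValueError(f"substitution matrix {key!r} is not symmetric")
    # X is scored as unknown: 0 against everything
    _MATRIX_CACHE[key] = mat
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` / ``gap_extend`` are in *matrix-scale units*: the effective
    penalties are the given values multiplied by the mean diagonal of the
    substitution matrix.  This makes gap penalties comparable across matrices
    and keeps the conventional sampled range 1–3 meaningful as an absolute
    gap-open value (MAFFT-like convention, defaults 1.53 / 0.123).

    A gap run of length g costs ``open + (g - 1) * extend`` (effective
    units), scaled per column by the occupancy of the profile column aligned
    against the gap.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 1.53
    gap_extend: float = 0.123
    terminal_gap_policy: str = "penalized"  # or "free_ends"

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.terminal_gap_policy not in ("penalized", "free_ends"):
            raise ValueError(f"unknown terminal_gap_policy {self.terminal_gap_policy!r}")

    @property
    def matrix(self) -> np.ndarray:
        return load_substitution_matrix(self.matrix_name)

    @property
    def matrix_scale(self) -> float:
        return float(np.mean(np.diag(self.matrix)[:20]))

    @property
    def effective_open(self) -> float:
        return self.gap_open * self.matrix_scale

    @property
    def effective_extend(self) -> float:
        return self.gap_extend * self.matrix_scale

    def with_gap_open(self, gap_open: float) -> "ScoringScheme":
        return ScoringScheme(
            self.matrix_name, gap_open, self.gap_extend, self.terminal_gap_policy
        )


class Profile:
    """A (sub-)alignment treated as the alignable unit."""

    __slots__ = ("ids", "enc")

    def __init__(self, ids: TSequence[str], enc: np.ndarray) -> None:
        if len(ids) == 0 or enc.shape[1] == 0:
            raise ValueError("empty profile")
        self.ids = tuple(ids)
        self.enc = np.ascontiguousarray(enc, dtype=np.uint8)

    @classmethod
    def from_sequence(cls, seq: Sequence) -> "Profile":
        codes = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.uint8)
        for i, a in enumerate(ALPHABET):
            lut[ord(a)] = i
        return cls((seq.id,), lut[codes][None, :])

    @classmethod
    def from_msa(cls, msa: Msa) -> "Profile":
        return cls(msa.ids, msa.encoded())

    @property
    def n_rows(self) -> int:
        return self.enc.shape[0]

    @property
    def length(self) -> int:
        return self.enc.shape[1]

    def counts(self) -> np.ndarray:
        """Per-column residue counts, shape (length, 21); gaps excluded."""
        n, L = self.enc.shape
        cnt = np.zeros((L, 21))
        for code in range(21):
            cnt[:, code] = np.count_nonzero(self.enc == code, axis=0)
        return cnt

    def occupancy(self) -> np.ndarray:
        """Fraction of non-gap rows per column."""
        return np.count_nonzero(self.enc != GAP_CODE, axis=0) / self.n_rows

    def to_msa(self) -> Msa:
        return msa_from_encoded(self.ids, self.enc)


# ---------------------------------------------------------------------------
# DP kernel.  States: M (match), X (consume a column of A: gap inserted into
# B; "delete"), Y (consume a column of B: gap inserted into A; "insert").
# Tie preference everywhere: M > X > Y.

_NEG = -1e30


@njit(cache=True)
def _gotoh_kernel(S, occA, occB, go, ge, free_ends):  # pragma: no cover - numba
    L1, L2 = S.shape
    M = np.full((L1 + 1, L2 + 1), _NEG)
    X = np.full((L1 + 1, L2 + 1), _NEG)
    Y = np.full((L1 + 1, L2 + 1), _NEG)
    pM = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    pX = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    pY = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        if free_ends:
            X[i, 0] = 0.0
        elif i == 1:
            X[1, 0] = -go * occA[0]
            pX[1, 0] = 0
        else:
            X[i, 0] = X[i - 1, 0] - ge * occA[i - 1]
            pX[i, 0] = 1
    for j in range(1, L2 + 1):
        if free_ends:
            Y[0, j] = 0.0
        elif j == 1:
            Y[0, 1] = -go * occB[0]
            pY[0, 1] = 0
        else:
            Y[0, j] = Y[0, j - 1] - ge * occB[j - 1]
            pY[0, j] = 2
    for i in range(1, L1 + 1):
        oa = occA[i - 1]
        for j in range(1, L2 + 1):
            ob = occB[j - 1]
            # M: diagonal
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = src
            # X: A advances against a gap in B
            best = M[i - 1, j] - go * oa
            src = 0
            v = X[i - 1, j] - ge * oa
            if v > best:
                best = v
                src = 1
            v = Y[i - 1, j] - go * oa
            if v > best:
                best = v
                src = 2
            X[i, j] = best
            pX[i, j] = src
            # Y: B advances against a gap in A
            best = M[i, j - 1] - go * ob
            src = 0
            v = X[i, j - 1] - go * ob
            if v > best:
                best = v
                src = 1
            v = Y[i, j - 1] - ge * ob
            if v > best:
                best = v
                src = 2
            Y[i, j] = best
            pY[i, j] = src

    # choose the traceback start
    moves = np.empty(L1 + L2, dtype=np.uint8)
    nm = 0
    si, sj = L1, L2
    if free_ends:
        bi, bj, bstate, bscore = L1, L2, 0, _NEG
        for st in range(3):
            v = M[L1, L2] if st == 0 else (X[L1, L2] if st == 1 else Y[L1, L2])
            if v > bscore:
                bscore = v
                bi, bj, bstate = L1, L2, st
        for i in range(L1):
            for st in range(3):
                v = M[i, L2] if st == 0 else (X[i, L2] if st == 1 else Y[i, L2])
                if v > bscore:
                    bscore = v
                    bi, bj, bstate = i, L2, st
        for j in range(L2):
            for st in range(3):
                v = M[L1, j] if st == 0 else (X[L1, j] if st == 1 else Y[L1, j])
                if v > bscore:
                    bscore = v
                    bi, bj, bstate = L1, j, st
        # trailing free gaps
        for _ in range(L1 - bi):
            moves[nm] = 1
            nm += 1
        for _ in range(L2 - bj):
            moves[nm] = 2
            nm += 1
        si, sj, state, score = bi, bj, bstate, bscore
    else:
        score = M[L1, L2]
        state = 0
        if X[L1, L2] > score:
            score = X[L1, L2]
            state = 1
        if Y[L1, L2] > score:
            score = Y[L1, L2]
            state = 2

    i, j = si, sj
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                # boundary reached via a free-end pointer: remaining run is a gap
                state = 1 if i > 0 else 2
                continue
            moves[nm] = 0
            nm += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[nm] = 1
            nm += 1
            state = pX[i, j]
            i -= 1
        else:
            moves[nm] = 2
            nm += 1
            state = pY[i, j]
            j -= 1

    return score, moves[:nm][::-1].copy()


def profile_score_matrix(a: Profile, b: Profile, scheme: ScoringScheme) -> np.ndarray:
    """Column-against-column scores: mean substitution score over all cross
    row pairs; pairs involving a gap (or X) contribute 0 to the mean."""
    ca = a.counts()
    cb = b.counts()
    return (ca @ scheme.matrix @ cb.T) / (a.n_rows * b.n_rows)


def align_profiles(
    a: Profile,
    b: Profile,
    scheme: ScoringScheme,
    reversed: bool = False,
) -> tuple[Profile, float]:
    """Globally align two profiles with affine gaps (Gotoh, 3 states).

    Gap penalties are scaled by the occupancy (non-gap fraction) of the
    profile column aligned against the inserted gap.  With ``reversed``,
    both profiles are character-reversed before the DP and the merged result
    is un-reversed, yielding the opposite-extreme co-optimal alignment.

    Returns the merged profile (rows of ``a`` first) and the DP score.
    """
    common = set(a.ids) & set(b.ids)
    if common:
        raise ValueError(f"profiles share sequences: {sorted(common)}")
    S = profile_score_matrix(a, b, scheme)
    occA = a.occupancy()
    occB = b.occupancy()
    if reversed:
        S = S[::-1, ::-1].copy()
        occA = occA[::-1].copy()
        occB = occB[::-1].copy()
    score, moves = _gotoh_kernel(
        np.ascontiguousarray(S),
        np.ascontiguousarray(occA),
        np.ascontiguousarray(occB),
        scheme.effective_open,
        scheme.effective_extend,
        scheme.terminal_gap_policy == "free_ends",
    )
    if reversed:
        moves = moves[::-1]
    merged = _merge_by_moves(a, b, moves)
    return merged, float(score)


@njit(cache=True)
def _merge_kernel(encA, encB, moves, gap_code):  # pragma: no cover - numba
    nA, LA = encA.shape
    nB, LB = encB.shape
    L = moves.shape[0]
    out = np.empty((nA + nB, L), dtype=np.uint8)
    i = 0
    j = 0
    for k in range(L):
        mv = moves[k]
        if mv == 0:
            out[:nA, k] = encA[:, i]
            out[nA:, k] = encB[:, j]
            i += 1
            j += 1
        elif mv == 1:
            out[:nA, k] = encA[:, i]
            out[nA:, k] = gap_code
            i += 1
        else:
            out[:nA, k] = gap_code
            out[nA:, k] = encB[:, j]
            j += 1
    return out


def _merge_by_moves(a: Profile, b: Profile, moves: np.ndarray) -> Profile:
    out = _merge_kernel(a.enc, b.enc, moves, np.uint8(GAP_CODE))
    return Profile(a.ids + b.ids, out)


def pairwise_align(
    s1: Sequence, s2: Sequence, scheme: ScoringScheme, reversed: bool = False
) -> tuple[Msa, float]:
    """Convenience: global alignment of two sequences."""
    prof, score = align_profiles(
        Profile.from_sequence(s1), Profile.from_sequence(s2), scheme, reversed
    )
    return prof.to_msa(), score


def progressive_align(
    seqs: TSequence[Sequence],
    tree: Tree,
    scheme: ScoringScheme,
    orientation: TSequence[int] | None = None,
) -> Msa:
    """Align sequences progressively along a guide tree.

    Profiles are merged at the internal nodes in postorder; internal node k
    uses ``orientation[k]`` (HEAD or TAIL) for its merge.  The output row
    order is the input sequence order, which is the canonical order for
    column keys.  Fully deterministic given (seqs, tree, scheme,
    orientation).
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    leaf_names = set(tree.leaf_names())
    if leaf_names != set(ids):
        raise ValueError(
            "tree leaves do not match sequences: "
            f"only-in-tree={sorted(leaf_names - set(ids))}, "
            f"only-in-seqs={sorted(set(ids) - leaf_names)}"
        )
    n_internal = len(tree.internal_nodes())
    if orientation is None:
        orientation = [HEAD] * n_internal
    if len(orientation) != n_internal:
        raise ValueError(
            f"orientation length {len(orientation)} != #internal nodes {n_internal}"
        )
    by_id = {s.id: s for s in seqs}
    profiles: dict[int, Profile] = {}
    k = 0
    for node in tree.postorder():
        if node.is_leaf:
            profiles[id(node)] = Profile.from_sequence(by_id[node.name])
        else:
            left, right = (profiles.pop(id(c)) for c in node.children)
            merged, _ = align_profiles(left, right, scheme, reversed=bool(orientation[k]))
            profiles[id(node)] = merged
            k += 1
    final = profiles[id(tree.root)]
    order = [final.ids.index(i) for i in ids]
    return msa_from_encoded(ids, final.enc[order])
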