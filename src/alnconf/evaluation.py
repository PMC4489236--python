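"""Benchmarking of reliability scores against a known true alignment.

Columns of an inferred alignment are labeled correct iff their
column-identity key occurs among the truth's columns; the softer per-column
signal is the fraction of the column's residue pairs that are also aligned
in the truth.  Score vectors are then evaluated as binary predictors (ROC,
precision-recall) and against the pair fractions (Pearson r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence as TSequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from alnconf.msa import GAP, Msa, keys_matrix

logger = logging.getLogger(__name__)


@dataclass
class LabeledColumns:
    """Per-column truth labels for one inferred alignment.

    ``included`` marks columns that are evaluable: at least two residues
    (so pair evidence exists) and, when a core-block mask is given, at
    least two residues belonging to core truth columns.
    """

    labels: np.ndarray  # int {0,1}, per inferred column
    fractions: np.ndarray  # fraction of pairs aligned in truth; NaN if <2 residues
    included: np.ndarray  # bool
    n_excluded: int

    def __post_init__(self) -> None:
        ok = self.included & (self.labels == 1)
        frac_ok = np.isnan(self.fractions[ok]).sum() == 0 and np.all(
            self.fractions[ok] > 1 - 1e-12
        )
        if not frac_ok:
            raise AssertionError("label 1 implies pair fraction 1")


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class PrResult:
    recall: np.ndarray
    precision: np.ndarray
    auc: float


def label_columns(
    inferred: Msa, truth: Msa, core_mask: TSequence[bool] | None = None
) -> LabeledColumns:
    """Label inferred columns against the true alignment.

    label[j] = 1 iff inferred column j's identity key occurs among the
    truth's columns.  fraction[j] = share of column j's residue pairs that
    are aligned (share a column) in the truth; NaN for columns with fewer
    than two residues, which are excluded.  With ``core_mask`` (one flag per
    truth column) a column is evaluable only if at least two of its residues
    fall in core truth columns.
    """
    if set(inferred.ids) != set(truth.ids):
        raise ValueError("inferred and truth are over different sequence sets")
    ref_seqs = {s.id: s.residues for s in inferred.sequences()}
    truth_seqs = {s.id: s.residues for s in truth.sequences()}
    if ref_seqs != truth_seqs:
        raise ValueError("inferred and truth do not contain the same sequences")

    order = inferred.ids
    perm = [truth.ids.index(i) for i in order]
    km_inf = keys_matrix(inferred)
    km_tru = keys_matrix(truth)[perm]
    n, L = km_inf.shape

    truth_cols = {km_tru[:, j].tobytes(): j for j in range(km_tru.shape[1])}

    # truth partner maps: for each ordered sequence pair (i, j), ordinal of i
    # -> ordinal of j where aligned in truth, 0 otherwise
    partner: dict[tuple[int, int], np.ndarray] = {}
    lengths = [int((km_tru[i] != GAP).sum()) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            both = (km_tru[i] != GAP) & (km_tru[j] != GAP)
            m = np.zeros(lengths[i] + 1, dtype=np.int64)
            m[km_tru[i, both]] = km_tru[j, both]
            partner[(i, j)] = m

    # residue -> truth column index (for core-block masking)
    if core_mask is not None:
        core_mask = np.asarray(core_mask, dtype=bool)
        if core_mask.size != km_tru.shape[1]:
            raise ValueError("core mask length does not match truth columns")
        res_core: list[np.ndarray] = []
        for i in range(n):
            core_of = np.zeros(lengths[i] + 1, dtype=bool)
            nz = km_tru[i] != GAP
            core_of[km_tru[i, nz]] = core_mask[nz]
            res_core.append(core_of)

    labels = np.zeros(L, dtype=np.int64)
    fractions = np.full(L, np.nan)
    included = np.zeros(L, dtype=bool)
    for col in range(L):
        members = np.flatnonzero(km_inf[:, col] != GAP)
        if members.size >= 2:
            total = 0
            hit = 0
            for a in range(members.size):
                for b in range(a + 1, members.size):
                    i, j = int(members[a]), int(members[b])
                    total += 1
                    if partner[(i, j)][km_inf[i, col]] == km_inf[j, col]:
                        hit += 1
            fractions[col] = hit / total
            included[col] = True
            if core_mask is not None:
                n_core = sum(
                    1 for i in members if res_core[int(i)][km_inf[int(i), col]]
                )
                included[col] = n_core >= 2
        labels[col] = 1 if km_inf[:, col].tobytes() in truth_cols else 0
    n_excluded = int(L - included.sum())
    if n_excluded:
        logger.info("%d column(s) excluded from evaluation", n_excluded)
    return LabeledColumns(labels, fractions, included, n_excluded)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.all(np.isin(classes, [0, 1])):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError(
            "both classes must be present; AUC is undefined for single-class labels"
        )
    return labels


def roc(scores: TSequence[float], labels: TSequence[int]) -> RocResult:
    """ROC curve and AUC (trapezoid; ties grouped by threshold sweep)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return RocResult(fpr, tpr, float(_skm.auc(fpr, tpr)))


def pr(scores: TSequence[float], labels: TSequence[int]) -> PrResult:
    """Precision-recall curve; AUC by trapezoid over recall (no
    interpolation)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    # sklearn returns points from high threshold to low; sort by recall
    order = np.argsort(recall)
    r, p = recall[order], precision[order]
    return PrResult(r, p, float(np.trapezoid(p, r)))


def pearson_to_pair_fraction(
    scores: TSequence[float], fractions: TSequence[float]
) -> float:
    """Pearson correlation between scores and per-column pair fractions.

    Returns NaN (with a warning) when either vector is constant, rather
    than a silent 0.
    """
    scores = np.asarray(scores, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if scores.size != fractions.size:
        raise ValueError("length mismatch")
    if scores.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(scores) == 0 or np.ptp(fractions) == 0:
        logger.warning("constant input: Pearson correlation undefined (NaN)")
        return float("nan")
    return float(stats.pearsonr(scores, fractions).statistic)


# ---------------------------------------------------------------------------
# Benchmark harness


@dataclass
class BenchmarkResult:
    """Pooled benchmark over simulated replicates, one entry per mode."""

    auc_roc: dict[str, float]
    auc_pr: dict[str, float]
    pearson_pooled: dict[str, float]
    pearson_per_replicate: dict[str, list[float]]
    n_columns: int
    n_positive: int
    per_replicate_auc: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "pearson_pooled": self.pearson_pooled,
            "pearson_per_replicate": self.pearson_per_replicate,
            "n_columns": self.n_columns,
            "n_positive": self.n_positive,
        }


def run_benchmark(
    n_replicates: int = 30,
    n_taxa: int = 20,
    depth: float = 1.0,
    root_length: int = 200,
    modes: TSequence[str] = ("full", "tree", "gap", "hot"),
    budget: int = 100,
    seed: int = 0,
    alpha: float = 1.0,
    pinv: float = 0.0,
    progress: bool = False,
) -> BenchmarkResult:
    """Simulate replicates, score them with each ensemble mode at an equal
    budget, and evaluate the column scores against the true alignments.

    Columns are pooled over replicates for the ROC/PR/pooled-Pearson
    numbers; per-replicate Pearson r values are also reported.
    """
    from alnconf.perturb import (
        build_reference,
        component_mode_config,
        generate_alternatives,
    )
    from alnconf.scoring import column_score
    from alnconf.simulator import EvolModel, random_ultrametric_tree, simulate

    model = EvolModel(alpha=alpha, pinv=pinv, root_length=root_length)
    pooled_scores: dict[str, list[np.ndarray]] = {m: [] for m in modes}
    pooled_labels: list[np.ndarray] = []
    pooled_fracs: list[np.ndarray] = []
    per_rep_r: dict[str, list[float]] = {m: [] for m in modes}

    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        tree = random_ultrametric_tree(n_taxa, depth, rng)
        sim = simulate(tree, model, rng)
        ref = build_reference(sim.sequences)
        labeled = label_columns(ref, sim.true_msa)
        inc = labeled.included
        pooled_labels.append(labeled.labels[inc])
        pooled_fracs.append(labeled.fractions[inc])
        for mode in modes:
            cfg = component_mode_config(mode, budget, seed=seed * 1000 + rep)
            alts = generate_alternatives(sim.sequences, ref, cfg)
            cs = column_score(ref, alts)
            pooled_scores[mode].append(cs[inc])
            r = pearson_to_pair_fraction(cs[inc], labeled.fractions[inc])
            per_rep_r[mode].append(r)
        if progress:
            logger.info("replicate %d/%d done", rep + 1, n_replicates)

    labels = np.concatenate(pooled_labels)
    fracs = np.concatenate(pooled_fracs)
    auc_roc: dict[str, float] = {}
    auc_pr: dict[str, float] = {}
    pooled_r: dict[str, float] = {}
    for mode in modes:
        scores = np.concatenate(pooled_scores[mode])
        auc_roc[mode] = roc(scores, labels).auc
        auc_pr[mode] = pr(scores, labels).auc
        pooled_r[mode] = pearson_to_pair_fraction(scores, fracs)
    return BenchmarkResult(
        auc_roc=auc_roc,
        auc_pr=auc_pr,
        pearson_pooled=pooled_r,
        pearson_per_replicate=per_rep_r,
        n_columns=int(labels.size),
        n_positive=int(labels.sum()),
    )
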