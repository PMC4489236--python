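"""Ensemble generation: combine guide-tree bootstrap, per-tree gap-open
sampling, and co-optimal head/tail orientation sampling into a set of
alternative alignments of the same sequences.

Each perturbation component can also be toggled individually, which gives
single-component ensembles (tree-only, gap-only, co-optimal-only) for
ablation experiments at an equal ensemble budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as TSequence

import numpy as np

from alnconf.aligner import HEAD, ScoringScheme, pairwise_align, progressive_align
from alnconf.guide_tree import DistanceMatrix, Tree, bootstrap_msa, nj, p_distance
from alnconf.msa import Msa, Sequence, write_msa

logger = logging.getLogger(__name__)

TREE = "tree"
GAP = "gap"
HOT = "hot"
ALL_COMPONENTS = frozenset({TREE, GAP, HOT})

#: Conventional gap-open sampling ranges, in matrix-scale units.
GAP_OPEN_RANGES = {"mafft": (1.0, 3.0), "clustalw": (4.0, 16.0)}


@dataclass(frozen=True)
class PerturbConfig:
    """Recipe for one ensemble.

    With every component enabled, the ensemble holds ``n_trees *
    n_cooptimal`` members: each of ``n_trees`` bootstrap guide trees gets
    one gap-open value drawn uniformly from ``gap_open_range``, and
    ``n_cooptimal`` head/tail orientation vectors are sampled per
    (tree, gap-open) combination, the first always all-HEAD.
    """

    n_trees: int = 100
    n_cooptimal: int = 4
    gap_open_range: tuple[float, float] = GAP_OPEN_RANGES["mafft"]
    components: frozenset[str] = ALL_COMPONENTS
    seed: int = 0
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_cooptimal < 1:
            raise ValueError("n_trees and n_cooptimal must be >= 1")
        lo, hi = self.gap_open_range
        if lo > hi:
            raise ValueError("gap_open_range min exceeds max")
        unknown = set(self.components) - ALL_COMPONENTS
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        object.__setattr__(self, "components", frozenset(self.components))

    @property
    def n_alternatives(self) -> int:
        return self.n_trees * self.n_cooptimal


@dataclass(frozen=True)
class Provenance:
    """How one alternative was produced."""

    tree_index: int
    member_index: int
    gap_open: float
    orientation: tuple[int, ...]
    seed: int

    @property
    def orientation_bits(self) -> str:
        return "".join(str(b) for b in self.orientation)


@dataclass
class AlternativeSet:
    """A reference alignment plus its ensemble of alternatives."""

    base: Msa
    alternatives: list[Msa]
    provenance: list[Provenance]
    config: PerturbConfig

    def __post_init__(self) -> None:
        if len(self.alternatives) != len(self.provenance):
            raise ValueError("alternatives/provenance length mismatch")

    def __len__(self) -> int:
        return len(self.alternatives)

    def write(self, outdir: str | Path) -> None:
        """Write alternatives as gapped FASTA plus a TSV manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lines = ["file\ttree_idx\tmember_idx\tgap_open\torientation_bits\tseed"]
        for k, (alt, prov) in enumerate(zip(self.alternatives, self.provenance)):
            fname = f"alternative_{k:04d}.fasta"
            write_msa(alt, outdir / fname)
            lines.append(
                f"{fname}\t{prov.tree_index}\t{prov.member_index}\t"
                f"{prov.gap_open:.6f}\t{prov.orientation_bits}\t{prov.seed}"
            )
        (outdir / "manifest.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RNG streams.  Every random draw is keyed by (seed, tree index, member
# index[, purpose]) so the ensemble is reproducible member-by-member and
# independent of execution order.


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _bootstrap_rng(cfg: PerturbConfig, t: int) -> np.random.Generator:
    return _rng(cfg.seed, t, 0, 0)


def _gap_rng(cfg: PerturbConfig, t: int) -> np.random.Generator:
    return _rng(cfg.seed, t, 0, 1)


def _orientation_rng(cfg: PerturbConfig, t: int, k: int) -> np.random.Generator:
    return _rng(cfg.seed, t, k)


def preview_gap_opens(cfg: PerturbConfig, n: int | None = None) -> np.ndarray:
    """The gap-open values the ensemble generator will draw, one per tree.

    Replays exactly the per-tree RNG streams used by
    :func:`generate_alternatives`, without running any alignments.
    """
    n = cfg.n_trees if n is None else n
    lo, hi = cfg.gap_open_range
    return np.array(
        [_gap_rng(cfg, t).uniform(lo, hi) for t in range(1, n + 1)]
    )


def _sample_orientations(
    cfg: PerturbConfig, t: int, n_bits: int
) -> list[tuple[int, ...]]:
    """Orientation vectors for the members of tree ``t``.

    The first member is always all-HEAD; later members are drawn uniformly
    from the 2^n_bits vectors, kept distinct within the tree whenever the
    space is large enough, with duplicates allowed otherwise.
    """
    out: list[tuple[int, ...]] = [(HEAD,) * n_bits]
    force_distinct = 2**n_bits >= cfg.n_cooptimal
    seen = {out[0]}
    for k in range(2, cfg.n_cooptimal + 1):
        rng = _orientation_rng(cfg, t, k)
        for _ in range(10_000):
            cand = tuple(int(b) for b in rng.integers(0, 2, size=n_bits))
            if not force_distinct or cand not in seen:
                break
        seen.add(cand)
        out.append(cand)
    return out


# ---------------------------------------------------------------------------


def _all_pairs_distances(
    seqs: TSequence[Sequence], scheme: ScoringScheme
) -> DistanceMatrix:
    """p-distances from global pairwise alignments of every sequence pair."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_align(seqs[i], seqs[j], scheme)
            dij = p_distance(aln).d[0, 1]
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(tuple(s.id for s in seqs), d)


def build_reference(
    seqs: TSequence[Sequence], scheme: ScoringScheme | None = None
) -> Msa:
    """Build the reference alignment with default parameters.

    The guide tree is NJ on p-distances estimated from global pairwise
    alignments of all sequence pairs; the progressive merge uses the
    all-HEAD orientation.  Deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len(seqs) == 2:
        logger.warning("only 2 sequences: reliability scores will be trivial")
    scheme = scheme or ScoringScheme()
    tree = nj(_all_pairs_distances(seqs, scheme))
    return progressive_align(seqs, tree, scheme)


def generate_alternatives(
    seqs: TSequence[Sequence], base: Msa, config: PerturbConfig
) -> AlternativeSet:
    """Generate the perturbation ensemble for ``base``.

    Per tree t: bootstrap the base columns, estimate p-distances, build an
    NJ guide tree, and draw one gap-open value; then realign the original
    (ungapped) sequences once per sampled head/tail orientation.  Disabled
    components are pinned: tree off = the base's own NJ tree for every
    member, gap off = the scheme's default gap-open, co-optimal off =
    all-HEAD.  The base alignment itself is never counted as a member.
    """
    ids = tuple(s.id for s in seqs)
    if set(ids) != set(base.ids):
        raise ValueError("base alignment is not over the given sequences")
    n_bits = len(seqs) - 1
    base_tree: Tree | None = None
    if TREE not in config.components:
        base_tree = nj(p_distance(base))

    alternatives: list[Msa] = []
    provenance: list[Provenance] = []
    for t in range(1, config.n_trees + 1):
        if TREE in config.components:
            boot = bootstrap_msa(base, _bootstrap_rng(config, t))
            tree = nj(p_distance(boot))
        else:
            tree = base_tree
        if GAP in config.components:
            lo, hi = config.gap_open_range
            gap_open = float(_gap_rng(config, t).uniform(lo, hi))
        else:
            gap_open = config.scheme.gap_open
        scheme = config.scheme.with_gap_open(gap_open)
        if HOT in config.components:
            orientations = _sample_orientations(config, t, n_bits)
        else:
            orientations = [(HEAD,) * n_bits] * config.n_cooptimal
        for k, orient in enumerate(orientations, start=1):
            alt = progressive_align(seqs, tree, scheme, orient)
            alternatives.append(alt)
            provenance.append(
                Provenance(
                    tree_index=t,
                    member_index=k,
                    gap_open=gap_open,
                    orientation=orient,
                    seed=config.seed,
                )
            )
    return AlternativeSet(base, alternatives, provenance, config)


def component_mode_config(
    mode: str, budget: int, seed: int, scheme: ScoringScheme | None = None
) -> PerturbConfig:
    """Config for an ablation mode at a fixed ensemble budget.

    ``mode`` is "full" (tree+gap+co-optimal, budget split as budget/4 trees
    x 4 orientations) or one of "tree", "gap", "hot" (single component,
    one member per tree).
    """
    scheme = scheme or ScoringScheme()
    if mode == "full":
        if budget % 4:
            raise ValueError("full-mode budget must be divisible by 4")
        return PerturbConfig(
            n_trees=budget // 4, n_cooptimal=4, seed=seed, scheme=scheme
        )
    if mode in (TREE, GAP):
        return PerturbConfig(
            n_trees=budget,
            n_cooptimal=1,
            components=frozenset({mode}),
            seed=seed,
            scheme=scheme,
        )
    if mode == HOT:
        return PerturbConfig(
            n_trees=1,
            n_cooptimal=budget,
            components=frozenset({HOT}),
            seed=seed,
            scheme=scheme,
        )
    raise ValueError(f"unknown mode {mode!r}")
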