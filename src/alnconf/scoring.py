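"""Reliability scores of a reference alignment against an ensemble.

The column score (CS) of a reference column is the fraction of ensemble
members containing an identical column (same column-identity key: identical
gap pattern and residue ordinals).  Pair scores are the fraction of members
in which a residue pair shares a column; the sum-of-pairs column score (SPC)
averages pair scores within a column; residue and sequence scores average
over pairs and residues respectively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from alnconf.msa import GAP, Msa, X_CODE, keys_matrix, msa_from_encoded

logger = logging.getLogger(__name__)

Pair = tuple[tuple[str, int], tuple[str, int]]


@dataclass
class ScoreReport:
    """All reliability scores for one reference alignment."""

    cs: np.ndarray  # per-column, in [0, 1]
    spc: np.ndarray  # per-column, in [0, 1]
    pair_scores: dict[Pair, float]
    residue_scores: dict[tuple[str, int], float]
    sequence_scores: dict[str, float]
    n_alternatives: int
    #: columns with < 2 residues whose spc fell back to cs
    spc_fallback_columns: list[int] = field(default_factory=list)
    #: residues with no pairs whose score fell back to their column's cs
    residue_fallback: list[tuple[str, int]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_alternatives": self.n_alternatives,
            "n_columns": int(self.cs.size),
            "mean_cs": float(np.mean(self.cs)),
            "mean_spc": float(np.mean(self.spc)),
            "mean_sequence_score": float(np.mean(list(self.sequence_scores.values()))),
            "n_spc_fallback_columns": len(self.spc_fallback_columns),
            "n_residue_fallbacks": len(self.residue_fallback),
        }


def _check_same_sequences(ref: Msa, alts: Iterable[Msa]) -> None:
    ref_seqs = {s.id: s.residues for s in ref.sequences()}
    for k, alt in enumerate(alts):
        alt_seqs = {s.id: s.residues for s in alt.sequences()}
        if alt_seqs != ref_seqs:
            raise ValueError(f"alternative {k} is not over the reference's sequences")


def _alt_list(alts) -> list[Msa]:
    # accept AlternativeSet or a plain list of Msa
    return list(getattr(alts, "alternatives", alts))


def column_score(ref: Msa, alts) -> np.ndarray:
    """CS per reference column: frequency of the identical column among the
    alternatives (full column-identity key equality)."""
    alt_msas = _alt_list(alts)
    if not alt_msas:
        raise ValueError("empty ensemble")
    _check_same_sequences(ref, alt_msas)
    order = ref.ids
    ref_keys = keys_matrix(ref)
    counts = np.zeros(ref.length, dtype=np.int64)
    ref_bytes = [ref_keys[:, j].tobytes() for j in range(ref.length)]
    for alt in alt_msas:
        perm = [alt.ids.index(i) for i in order]
        km = keys_matrix(alt)[perm]
        present = {km[:, j].tobytes() for j in range(km.shape[1])}
        for j, kb in enumerate(ref_bytes):
            if kb in present:
                counts[j] += 1
    return counts / len(alt_msas)


def _pair_count_matrices(
    msas: list[Msa], order: tuple[str, ...], lengths: list[int]
) -> dict[tuple[int, int], np.ndarray]:
    """counts[(i, j)][oi, oj] = #alignments where residue oi of sequence i
    shares a column with residue oj of sequence j (ordinals 1-based)."""
    n = len(order)
    counts = {
        (i, j): np.zeros((lengths[i] + 1, lengths[j] + 1), dtype=np.int32)
        for i in range(n)
        for j in range(i + 1, n)
    }
    for msa in msas:
        perm = [msa.ids.index(i) for i in order]
        km = keys_matrix(msa)[perm]
        nongap = km != GAP
        for i in range(n):
            for j in range(i + 1, n):
                both = nongap[i] & nongap[j]
                counts[(i, j)][km[i, both], km[j, both]] += 1
    return counts


def pair_and_spc_scores(
    ref: Msa, alts
) -> tuple[dict[Pair, float], np.ndarray, list[int]]:
    """Pair scores and the SPC per column.

    Returns (pair_scores, spc, fallback_columns).  Columns with fewer than
    two residues have no pairs; their SPC falls back to the column score and
    they are listed in ``fallback_columns``.
    """
    alt_msas = _alt_list(alts)
    if not alt_msas:
        raise ValueError("empty ensemble")
    _check_same_sequences(ref, alt_msas)
    order = ref.ids
    lengths = [len(s.residues) for s in ref.sequences()]
    counts = _pair_count_matrices(alt_msas, order, lengths)
    n_alt = len(alt_msas)

    km = keys_matrix(ref)
    nongap = km != GAP
    pair_scores: dict[Pair, float] = {}
    spc = np.zeros(ref.length)
    fallback: list[int] = []
    cs_cache: np.ndarray | None = None
    for col in range(ref.length):
        members = np.flatnonzero(nongap[:, col])
        if members.size < 2:
            fallback.append(col)
            continue
        vals = []
        for a in range(members.size):
            for b in range(a + 1, members.size):
                i, j = int(members[a]), int(members[b])
                oi, oj = int(km[i, col]), int(km[j, col])
                score = counts[(i, j)][oi, oj] / n_alt
                pair_scores[((order[i], oi), (order[j], oj))] = float(score)
                vals.append(score)
        spc[col] = float(np.mean(vals))
    if fallback:
        cs_cache = column_score(ref, alt_msas)
        for col in fallback:
            spc[col] = cs_cache[col]
        logger.info(
            "%d column(s) with <2 residues: SPC fell back to CS", len(fallback)
        )
    return pair_scores, spc, fallback


def residue_and_sequence_scores(
    pair_scores: Mapping[Pair, float],
    ref: Msa,
    cs: np.ndarray | None = None,
) -> tuple[dict[tuple[str, int], float], dict[str, float], list[tuple[str, int]]]:
    """Residue score = mean pair score over the pairs containing the residue;
    sequence score = mean residue score over the sequence.

    Residues that appear in no pair (alone in their column) fall back to the
    CS of their column (requires ``cs``); they are returned in the third
    element.
    """
    sums: dict[tuple[str, int], float] = {}
    ns: dict[tuple[str, int], int] = {}
    for (ra, rb), score in pair_scores.items():
        for r in (ra, rb):
            sums[r] = sums.get(r, 0.0) + score
            ns[r] = ns.get(r, 0) + 1
    residue_scores: dict[tuple[str, int], float] = {}
    fallback: list[tuple[str, int]] = []
    km = keys_matrix(ref)
    for i, sid in enumerate(ref.ids):
        seq_len = int((km[i] != GAP).sum())
        for o in range(1, seq_len + 1):
            r = (sid, o)
            if r in sums:
                residue_scores[r] = sums[r] / ns[r]
            else:
                if cs is None:
                    raise ValueError(
                        f"residue {r} has no pairs and no column scores were given"
                    )
                col = int(np.flatnonzero(km[i] == o)[0])
                residue_scores[r] = float(cs[col])
                fallback.append(r)
    sequence_scores = {
        sid: float(
            np.mean(
                [residue_scores[(sid, o)] for o in range(1, int((km[i] != GAP).sum()) + 1)]
            )
        )
        for i, sid in enumerate(ref.ids)
    }
    return residue_scores, sequence_scores, fallback


def score_report(ref: Msa, alts) -> ScoreReport:
    """Compute the full reliability report for ``ref`` against an ensemble."""
    alt_msas = _alt_list(alts)
    cs = column_score(ref, alt_msas)
    pair_scores, spc, spc_fallback = pair_and_spc_scores(ref, alt_msas)
    residue_scores, sequence_scores, res_fallback = residue_and_sequence_scores(
        pair_scores, ref, cs
    )
    return ScoreReport(
        cs=cs,
        spc=spc,
        pair_scores=pair_scores,
        residue_scores=residue_scores,
        sequence_scores=sequence_scores,
        n_alternatives=len(alt_msas),
        spc_fallback_columns=spc_fallback,
        residue_fallback=res_fallback,
    )


def mask_msa(
    ref: Msa,
    report: ScoreReport,
    column_cutoff: float = 0.93,
    residue_cutoff: float = 0.6,
    mode: str = "remove_columns",
) -> Msa:
    """Filter the reference by its reliability scores.

    ``remove_columns`` drops columns with CS below ``column_cutoff``;
    ``mask_residues`` replaces residues scoring below ``residue_cutoff``
    with 'X'.  Columns emptied to all-gap are dropped (logged).
    """
    if not 0 <= column_cutoff <= 1 or not 0 <= residue_cutoff <= 1:
        raise ValueError("cutoffs must be in [0, 1]")
    if mode not in ("remove_columns", "mask_residues"):
        raise ValueError(f"unknown mode {mode!r}")
    enc = ref.encoded().copy()
    if mode == "remove_columns":
        keep = report.cs >= column_cutoff
        if not keep.any():
            raise ValueError("cutoff removes every column")
        return msa_from_encoded(ref.ids, enc[:, keep])
    km = keys_matrix(ref)
    for i, sid in enumerate(ref.ids):
        for col in range(ref.length):
            o = int(km[i, col])
            if o != GAP and report.residue_scores[(sid, o)] < residue_cutoff:
                enc[i, col] = X_CODE
    return msa_from_encoded(ref.ids, enc)


def write_report(report: ScoreReport, outdir: str | Path) -> None:
    """Write column/residue/sequence score TSVs plus a JSON summary.

    Column and residue coordinates are 1-based in all files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["column\tcs\tspc"]
    for j in range(report.cs.size):
        lines.append(f"{j + 1}\t{report.cs[j]:.6f}\t{report.spc[j]:.6f}")
    (outdir / "column_scores.tsv").write_text("\n".join(lines) + "\n")
    lines = ["sequence\tresidue\tscore"]
    for (sid, o), score in sorted(report.residue_scores.items()):
        lines.append(f"{sid}\t{o}\t{score:.6f}")
    (outdir / "residue_scores.tsv").write_text("\n".join(lines) + "\n")
    lines = ["sequence\tscore"]
    for sid, score in report.sequence_scores.items():
        lines.append(f"{sid}\t{score:.6f}")
    (outdir / "sequence_scores.tsv").write_text("\n".join(lines) + "\n")
    (outdir / "score_summary.json").write_text(
        json.dumps(report.summary(), indent=2) + "\n"
    )
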