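import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from alnconf.aligner import ScoringScheme
from alnconf.msa import AA_ORDER, Msa, Sequence

#: NCBI-format unit matrix: match +1, mismatch -1 (matrix scale = 1, so gap
#: penalties are taken at face value).
_UNIT_MATRIX = None


def make_unit_matrix_file(tmpdir: Path) -> Path:
    letters = list(AA_ORDER)
    lines = ["   " + "  ".join(letters)]
    for a in letters:
        row = [a] + [" 1" if a == b else "-1" for b in letters]
        lines.append(" ".join(row))
    path = tmpdir / "unit.mat"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def unit_matrix_path(tmp_path_factory) -> Path:
    return make_unit_matrix_file(tmp_path_factory.mktemp("matrices"))


@pytest.fixture(scope="session")
def unit_scheme(unit_matrix_path) -> ScoringScheme:
    """match 1, mismatch -1, gap open 2, gap extend 0.5."""
    return ScoringScheme(str(unit_matrix_path), gap_open=2.0, gap_extend=0.5)


def random_sequences(
    rng: np.random.Generator, n: int, length: int, alphabet: str = AA_ORDER
) -> list[Sequence]:
    lens = rng.integers(max(1, length - 3), length + 4, size=n)
    return [
        Sequence(
            f"s{i}",
            "".join(alphabet[c] for c in rng.integers(0, len(alphabet), size=lens[i])),
        )
        for i in range(n)
    ]


def random_msa(rng: np.random.Generator, n: int, length: int, gap_frac=0.2) -> Msa:
    """Random gapped MSA satisfying the invariants (no all-gap columns,
    no empty rows)."""
    while True:
        chars = rng.integers(0, 20, size=(n, length))
        gaps = rng.random((n, length)) < gap_frac
        # no all-gap columns, no all-gap rows
        if gaps.all(axis=0).any() or gaps.all(axis=1).any():
            continue
        rows = [
            "".join("-" if gaps[i, j] else AA_ORDER[chars[i, j]] for j in range(length))
            for i in range(n)
        ]
        return Msa([f"s{i}" for i in range(n)], rows)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests: 8 taxa, ~60 sites."""
    from alnconf.simulator import EvolModel, random_ultrametric_tree, simulate

    rng = np.random.default_rng(42)
    tree = random_ultrametric_tree(8, 0.8, rng)
    sim = simulate(tree, EvolModel(root_length=60), rng)
    return sim


@pytest.fixture(scope="session")
def small_ensemble(small_sim):
    """Reference + 10-member ensemble for the small simulated dataset."""
    from alnconf.perturb import PerturbConfig, build_reference, generate_alternatives

    ref = build_reference(small_sim.sequences)
    cfg = PerturbConfig(n_trees=5, n_cooptimal=2, seed=7)
    alts = generate_alternatives(small_sim.sequences, ref, cfg)
    return ref, alts
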