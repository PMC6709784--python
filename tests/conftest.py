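import numpy as np
import pytest

from pannlrome.models import CodonAlignment


BASES = "ACGT"


def random_alignment(rng: np.random.Generator, n: int, n_codons: int,
                     n_variable: int | None = None) -> CodonAlignment:
    """A random ungapped codon alignment with a controlled number of
    variable nucleotide columns (used to exercise the statistics)."""
    L = 3 * n_codons
    base = rng.choice(list(BASES), size=L)
    rows = np.tile(base, (n, 1))
    if n_variable is None:
        n_variable = int(rng.integers(0, L // 2))
    var_cols = rng.choice(L, size=min(n_variable, L), replace=False)
    for c in var_cols:
        alt = rng.choice([b for b in BASES if b != base[c]])
        carriers = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
        rows[carriers, c] = alt
    return CodonAlignment([f"s{i}" for i in range(n)],
                          ["".join(r) for r in rows])


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded synthetic pan-NLRome shared across tests."""
    from pannlrome.config import SimulationConfig
    from pannlrome.simulate import simulate_pannlrome
    cfg = SimulationConfig(
        n_accessions=12,
        og_spectrum=[(1.0, 4), (0.5, 5), (0.15, 5)],
        seed=101)
    return simulate_pannlrome(cfg)
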