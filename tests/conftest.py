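import numpy as np
import pandas as pd
import pytest

from dmicontinuum.synth import make_populations


def disjoint_pair_crosses(
    n_pairs: int,
    true_ri: float,
    rng: np.random.Generator,
    crosses_per_direction: int = 4,
    control_crosses: int = 4,
    p_control: float = 0.8,
    seeds_total: int = 15,
    seeds_tested: int = 5,
) -> pd.DataFrame:
    """Crossing table for ``n_pairs`` population pairs with no shared parents.

    Each pair contributes its own two intra-population controls plus
    reciprocal inter-population crosses, so per-pair RI estimates are
    mutually independent — the design the one-sample t-test assumes.  All
    populations are dune ecotype; pairs alternate clade scope.
    """
    p_hybrid = p_control * (1.0 - true_ri) / (1.0 + true_ri)
    rows = []
    for k in range(n_pairs):
        a, b = f"A{k}", f"B{k}"
        clade_b = "eastern" if k % 2 == 0 else "southeastern"
        for mother, father, p in (
            (a, a, p_control),
            (b, b, p_control),
            (a, b, p_hybrid),
            (b, a, p_hybrid),
        ):
            n_crosses = control_crosses if mother == father else crosses_per_direction
            for _ in range(n_crosses):
                rows.append(
                    {
                        "mother_pop": mother,
                        "father_pop": father,
                        "mother_ecotype": "D",
                        "father_ecotype": "D",
                        "mother_clade": "eastern" if mother.startswith("A") else clade_b,
                        "father_clade": "eastern" if father.startswith("A") else clade_b,
                        "seeds_fertilised": rng.binomial(seeds_total, p),
                        "seeds_total": seeds_total,
                        "seeds_germinated": rng.binomial(seeds_tested, p),
                        "seeds_tested": seeds_tested,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_cross_table() -> pd.DataFrame:
    """Two populations with exact proportions: controls 0.8 and 0.6, two
    inter-population crosses with proportions 0.3 and 0.4 (H = 0.35)."""

    def row(mother, father, fert, total):
        return {
            "mother_pop": mother,
            "father_pop": father,
            "mother_ecotype": "D",
            "father_ecotype": "D",
            "mother_clade": "eastern",
            "father_clade": "eastern",
            "seeds_fertilised": fert,
            "seeds_total": total,
            "seeds_germinated": 4,
            "seeds_tested": 5,
        }

    return pd.DataFrame(
        [
            row("P1", "P1", 16, 20),
            row("P2", "P2", 12, 20),
            row("P1", "P2", 6, 20),
            row("P1", "P2", 8, 20),
        ]
    )


@pytest.fixture
def pop_metadata() -> pd.DataFrame:
    return make_populations(2)
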