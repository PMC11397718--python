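import numpy as np
import pandas as pd
import pytest

from pollenstats import SimConfig, TraitTable, generate_study


def table_from_values(values: dict[str, dict[str, list[float]]],
                      ap: dict[str, float] | None = None) -> TraitTable:
    """Build a TraitTable from {taxon: {trait: [replicates...]}}."""
    rows = []
    for taxon, traits in values.items():
        for trait, reps in traits.items():
            for k, v in enumerate(reps, start=1):
                rows.append((taxon, k, trait, float(v)))
    df = pd.DataFrame(rows, columns=["taxon_id", "replicate", "trait", "value"])
    n = df.groupby(["taxon_id", "trait"])["replicate"].count().max()
    return TraitTable(df, aberrant_rate=ap, expected_replicates=int(n))


def random_table(rng: np.random.Generator, n_taxa: int = 6,
                 n_rep: int = 5, traits=("P", "E", "Eprime")) -> TraitTable:
    values = {}
    for i in range(n_taxa):
        values[f"t{i}"] = {
            t: rng.uniform(5.0, 50.0) * (1.0 + 0.2 * rng.standard_normal(n_rep))
            for t in traits
        }
    values = {
        tx: {t: np.abs(v) + 0.1 for t, v in d.items()}
        for tx, d in values.items()
    }
    return table_from_values(values)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across read-only tests."""
    return generate_study(SimConfig(n_species=10, n_cultivars=14,
                                    replicates=8, seed=11))
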