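import numpy as np
import pandas as pd
import pytest

from chemgenfit import diffit, synthpool as sp


@pytest.fixture(scope="session")
def small_catalog():
    return sp.generate_catalog(300, barcode_length=12, seed=11)


@pytest.fixture(scope="session")
def planted_dataset(small_catalog):
    """A small screen with strong planted effects, reused across modules."""
    compounds = ["c0", "c1", "c2", "c3"]
    cfg = sp.TruthConfig(effect_low=0.3, effect_high=0.5, dispersion=0.05)
    truth = sp.generate_truth(small_catalog, compounds, cfg, seed=12)
    design = sp.generate_design(compounds, n_replicates=3, seed=13)
    cm = sp.simulate_counts(small_catalog, design, truth,
                            depth=400_000, seed=14)
    return {"catalog": small_catalog, "truth": truth, "design": design,
            "counts": cm.counts, "cm": cm}


@pytest.fixture(scope="session")
def planted_fitness(planted_dataset):
    return diffit.fit_all(planted_dataset["counts"],
                          planted_dataset["design"])


def toy_fitness_table(flags: dict[str, dict[str, float]],
                      genes: list[str]) -> diffit.FitnessTable:
    """Build a FitnessTable directly from signed effects.

    ``flags[inhibitor][gene] = signed log2 effect``; listed genes are
    significant (p tiny), everything else is a clear null.
    """
    results = {}
    for inh, sig in flags.items():
        df = pd.DataFrame({"log2_effect": 0.0, "p_value": 1.0},
                          index=pd.Index(genes, name="gene"))
        for g, eff in sig.items():
            df.loc[g, "log2_effect"] = eff
            df.loc[g, "p_value"] = 1e-12
        results[inh] = df
    return diffit.build_fitness_table(results, fdr=0.05)
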