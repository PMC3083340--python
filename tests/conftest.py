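import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tfsarray as ta
from tfsarray.normalize import ErrorModelParams, combine_replicates, lowess_normalize
from tfsarray.tfs import classify_probes, collapse_redundant

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def quiet_design(**kw):
    """A small design with no flagged features, for exact-value tests."""
    defaults = dict(
        n_genes=200,
        n_redundant_genes=0,
        n_unannotated_probes=0,
        planted_patterns={},
        rate_saturated_both=0.0,
        rate_nonuniform=0.0,
        seed=3,
    )
    defaults.update(kw)
    return ta.SimulationDesign(**defaults)


def run_comparisons(sim, params=None):
    """Normalize and combine every comparison of a simulated experiment."""
    em = params or ErrorModelParams()
    return {
        k: combine_replicates([lowess_normalize(h, params=em) for h in tables], em)
        for k, tables in sim.hybridizations.items()
    }


@pytest.fixture(scope="session")
def default_run():
    """Full study-scale run: 2000 genes, 300 planted, defaults, fixed seed."""
    design = ta.default_design(n_genes=2000, n_planted=300, seed=1)
    sim = ta.simulate_experiment(design)
    results = run_comparisons(sim)
    per_probe = classify_probes(results)
    per_gene = collapse_redundant(per_probe)
    return {
        "design": design,
        "sim": sim,
        "results": results,
        "per_probe": per_probe,
        "per_gene": per_gene,
        "truth": sim.truth,
    }


@pytest.fixture(scope="session")
def null_run_6416():
    """One comparison of a fully null 6,416-probe simulation."""
    sim = ta.simulate_experiment(ta.null_design(n_genes=6416, seed=1))
    em = ErrorModelParams()
    norm = [lowess_normalize(h, params=em) for h in sim.hybridizations[1]]
    return combine_replicates(norm, em)
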