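import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tfekit as tk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.basicConfig(level=logging.WARNING)


@pytest.fixture(scope="session")
def small_config() -> tk.SimConfig:
    """A miniature study: quick to simulate, still exercises every path."""
    return tk.SimConfig(
        seed=3,
        n_chromosomes=2,
        chromosome_length=250_000,
        n_coding_genes=60,
        n_noncoding_genes=15,
        n_spikeins=20,
        samples_per_stage=3,
        n_markers_per_stage=2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> tk.SimBundle:
    return tk.simulate_study(small_config)


@pytest.fixture(scope="session")
def study():
    """The default-scale study with its full analysis, shared across tests.

    Returns a dict with the bundle, count matrix, size factors, normalized
    values, stage medians and consecutive-stage DE tables.
    """
    bundle = tk.simulate_study(tk.SimConfig(seed=11))
    matrix, unassigned = tk.quantify(bundle.events, bundle.sheet)
    factors = tk.spikein_size_factors(matrix)
    values = tk.log2_normalize(matrix, factors)
    medians = tk.stage_medians(values, bundle.sheet)
    de = tk.de_all_contrasts(matrix, factors, bundle.sheet)
    return {
        "bundle": bundle,
        "matrix": matrix,
        "unassigned": unassigned,
        "factors": factors,
        "values": values,
        "medians": medians,
        "de": de,
    }


def match_tfe(regions, gene_row, tol: int = 60):
    """TFE ids whose summit lies within ``tol`` bp of a true TSS, same
    chrom and strand."""
    sel = regions[
        (regions["chrom"] == gene_row["chrom"])
        & (regions["strand"] == gene_row["strand"])
        & ((regions["summit"] - gene_row["tss"]).abs() <= tol)
    ]
    return list(sel.index)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
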