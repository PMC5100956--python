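"""Shared fixtures.

The expensive fixtures (the 50-genome recovery batch and the split
simulations) are session-scoped so that the acceptance tests and the
module-level property tests draw on a single computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import neandsel as ns

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from neandsel.bootstrap import bootstrap_ci
from neandsel.model import ModelParams
from neandsel.synthetic import SyntheticGenomeConfig, generate_dataset
from neandsel.wfsim import SplitSimConfig, simulate_split

BATCH_SEED = 20_161_108  # fixed study seed for the recovery batch
N_RECOVERY_RUNS = 50


@pytest.fixture()
def toy_genome():
    """A small three-chromosome synthetic genome with zero-noise calls."""
    truth = ModelParams(p0=0.0338, s=4.12e-4, t=2000, mu=8.1e-5)
    cfg = SyntheticGenomeConfig(
        n_chromosomes=3, chrom_cm=30.0, truth=truth, noise="none", seed=7
    )
    gmap, exons, calls = generate_dataset(cfg)
    return gmap, exons, calls, truth


@dataclass
class RecoveryRun:
    truth: ModelParams
    p0_hat: float
    s_hat: float
    mu_hat: float
    mus_hat: float
    mus_ci: tuple
    covers: bool


def _one_recovery_run(rng: np.random.Generator) -> RecoveryRun:
    s_true = float(np.exp(rng.uniform(np.log(2e-4), np.log(8e-4))))
    mu_true = float(np.exp(rng.uniform(np.log(4e-5), np.log(1.6e-4))))
    p0_true = float(rng.uniform(0.030, 0.040))
    truth = ModelParams(p0=p0_true, s=s_true, t=2000, mu=mu_true)
    cfg = SyntheticGenomeConfig(truth=truth, noise="drift", seed=int(rng.integers(2**31)))
    gmap, exons, calls = generate_dataset(cfg)
    model = ns.LinkedSelectionModel().fit(calls, exons, gmap)
    ci = bootstrap_ci(
        model.block_sums_, n_boot=200, seed=int(rng.integers(2**31))
    ).ci["mus"]
    mus_true = s_true * mu_true
    return RecoveryRun(
        truth=truth,
        p0_hat=model.p0_,
        s_hat=model.s_,
        mu_hat=model.mu_,
        mus_hat=model.mus_,
        mus_ci=ci,
        covers=ci[0] <= mus_true <= ci[1],
    )


@pytest.fixture(scope="session")
def recovery_batch() -> list[RecoveryRun]:
    """Fifty full-scale synthetic genomes (22 chromosomes, ~50k SNPs, drift
    noise, truths near the published autosomal estimates), each fitted and
    bootstrapped at 200 replicates."""
    rng = np.random.default_rng(BATCH_SEED)
    return [_one_recovery_run(rng) for _ in range(N_RECOVERY_RUNS)]


@pytest.fixture(scope="session")
def split_sims() -> dict:
    """Split simulations at study scale: the default demography plus the two
    extreme recipient-bottleneck durations."""
    out = {}
    out["base"] = simulate_split(SplitSimConfig(n_sites=10000, seed=11))
    out["bottleneck_10"] = simulate_split(
        SplitSimConfig(n_sites=10000, bottleneck=(10, 1861), seed=12)
    )
    out["bottleneck_1000"] = simulate_split(
        SplitSimConfig(n_sites=10000, bottleneck=(1000, 1861), seed=13)
    )
    return out
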