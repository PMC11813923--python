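import numpy as np
import pandas as pd
import pytest

from megaenv.data import METDataset
from megaenv.simulate import default_simulation_params, simulate_met


@pytest.fixture(scope="session")
def study_params():
    """Study-style simulation parameters at a reduced collection size."""
    return default_simulation_params(n_genotypes=120, seed=11)


@pytest.fixture(scope="session")
def study_dataset(study_params):
    """One simulated nine-trial MET reused across read-only tests."""
    return simulate_met(study_params)


@pytest.fixture(scope="session")
def dtf_fit(study_dataset):
    from megaenv.mixed_models import fit_multitrial_lmm
    return fit_multitrial_lmm(study_dataset, "DTF")


def make_replicated_dataset(values: dict, trials, genotypes,
                            locations=None, noise_sd=0.0,
                            noise_rng=None) -> METDataset:
    """Small hand-built MET: every genotype twice per trial.

    ``values`` maps trait -> (genotype x trial) DataFrame of cell means;
    each replicate gets independent N(0, noise_sd) measurement noise so
    the residual variance stays identifiable.
    """
    locations = locations or {t: t[:-1] or t for t in trials}
    noise_rng = noise_rng or np.random.default_rng(0)
    rows = []
    for t in trials:
        for j, g in enumerate(genotypes):
            for rep in (1, 2):
                rows.append({"trial_id": t, "location": locations[t],
                             "year": 2018, "row": rep, "col": j + 1,
                             "genotype_id": g, "rep_class": "check"})
    frame = pd.DataFrame(rows)
    for trait, table in values.items():
        frame[trait] = [
            float(table.loc[r.genotype_id, r.trial_id])
            + noise_sd * noise_rng.standard_normal()
            for r in frame.itertuples()
        ]
    return METDataset(frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
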