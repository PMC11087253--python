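import numpy as np
import pandas as pd
import pytest

import mechamethyl as mm


@pytest.fixture(scope="session")
def small_design():
    return mm.StudyDesign(n_probes=2000, n_genes=200, seed=11)


@pytest.fixture(scope="session")
def annotation(small_design):
    return mm.generate_probe_annotation(small_design)


@pytest.fixture(scope="session")
def experiment(small_design, annotation):
    datasets, truth = mm.generate_methylation_experiment(
        small_design, mm.EffectSpec(), annotation
    )
    return datasets, truth


def make_dataset(beta, detp=None, condition=None, model="spherical"):
    """Small helper to wrap raw arrays into a MethylationDataset."""
    beta = pd.DataFrame(beta)
    beta.index = [f"p{i}" for i in range(beta.shape[0])]
    beta.columns = [f"s{i}" for i in range(beta.shape[1])]
    if detp is None:
        detp = pd.DataFrame(
            np.zeros(beta.shape), index=beta.index, columns=beta.columns
        )
    else:
        detp = pd.DataFrame(np.asarray(detp), index=beta.index, columns=beta.columns)
    if condition is None:
        half = beta.shape[1] // 2
        condition = ["loaded"] * half + ["control"] * (beta.shape[1] - half)
    samples = pd.DataFrame(
        {"model": model, "condition": condition}, index=beta.columns
    )
    samples.index.name = "sample_id"
    return mm.MethylationDataset(beta=beta, detp=detp, samples=samples, model_label=model)
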