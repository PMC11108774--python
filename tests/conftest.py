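import numpy as np
import pytest

from cytorigin.bagio import CATEGORIES, ClinicalCovariates
from cytorigin.mil_models import (FeatureBag, MILConfig, TrainConfig, build_model,
                                  train_mil)
from cytorigin.synthetic_data import BagSimConfig, gen_feature_bags

# architecture -> desk-scale training epochs (transformers converge faster here)
ARCH_EPOCHS = {"abmil": 30, "abmil_mb": 30, "transmil": 12, "transmil_cma": 12}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def covariates():
    return ClinicalCovariates(age=60, sex="female", site="ascites")


@pytest.fixture(scope="session")
def sim_bags():
    """Separable synthetic cohort: 200 bags, d=64, planted witness signal."""
    return gen_feature_bags(BagSimConfig(n_cases=200, d=64, seed=42))


def cases_for(sim, splits):
    out = []
    for split in splits:
        for cid in sim.split_ids(split):
            label = sim.labels[cid]
            if label.coarse is None:
                continue
            out.append((FeatureBag(sim.bags[cid], cid), sim.covariates[cid],
                        CATEGORIES.index(label.coarse)))
    return out


@pytest.fixture(scope="session")
def trained_models(sim_bags):
    """All four MIL heads trained on the shared synthetic cohort."""
    train = cases_for(sim_bags, ["train"])
    val = cases_for(sim_bags, ["val"])
    models = {}
    for arch, epochs in ARCH_EPOCHS.items():
        model = build_model(arch, MILConfig.tiny(d=64), seed=7)
        train_mil(model, train, val,
                  TrainConfig(epochs=epochs, select_from_epoch=epochs // 2), seed=7)
        models[arch] = model
    return models
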