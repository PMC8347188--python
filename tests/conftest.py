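"""Shared fixtures: phantoms, expert labels, and trained desk-scale models.

Model training is expensive, so one session-scoped factory trains the
spine/lumen/thrombus models per seed on the expert-labelled bootstrap
corpus and caches them; every test that needs trained weights goes through
it.
"""

import pytest

from vesselseg import expert_system as es
from vesselseg import unet as U
from vesselseg.phantom import (AAA_JITTER, AMI_JITTER, PhantomSpec, ami_spec,
                               generate_dataset, generate_phantom)

# epochs per structure for the desk-scale bootstrap trainings: the bright
# structures converge within 2 epochs, the low-contrast thrombus needs more
TRAIN_EPOCHS = {"spine": 2, "lumen": 3, "thrombus": 6}


@pytest.fixture(scope="session")
def expert_cfg():
    return es.ExpertConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    spec = PhantomSpec(seed=7)
    vol, masks = generate_phantom(spec)
    return spec, vol, masks


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = PhantomSpec(seed=7, noise_sd=0.0)
    vol, masks = generate_phantom(spec)
    return spec, vol, masks


@pytest.fixture(scope="session")
def training_corpus(expert_cfg):
    """Jittered clean phantoms labelled by the expert system (the bootstrap
    corpus for weak-label training); ground truth kept for reference."""
    ds = generate_dataset(3, PhantomSpec(), jitter=AAA_JITTER, seed=11)
    labelled = []
    for spec, vol, masks in ds:
        res = es.segment_all(vol, expert_cfg)
        labelled.append((vol, res, masks))
    return labelled


def structure_model_config(structure):
    if structure == "thrombus":
        return U.thrombus_model_config()
    return U.test_scale_config()


def corpus_pairs(labelled, structure, mcfg):
    pairs = []
    for vol, res, _ in labelled:
        norm = U.prepare_slices(vol.voxels, mcfg)
        for z in range(vol.n_slices):
            pairs.append((norm[z], res[structure].voxels[z]))
    return pairs


@pytest.fixture(scope="session")
def model_factory(training_corpus):
    """Per-seed cache of the three trained binary models (+ histories)."""
    cache = {}

    def get(seed):
        if seed not in cache:
            models = {}
            for structure in ("spine", "lumen", "thrombus"):
                mcfg = structure_model_config(structure)
                pairs = corpus_pairs(training_corpus, structure, mcfg)
                model, _ = U.build_model(mcfg, seed=seed)
                # no augmentation at desk scale (the jittered corpus already
                # varies); the thrombus task uses its dedicated profile
                # (small batches, oversampling, collapse restarts)
                if structure == "thrombus":
                    tcfg = U.thrombus_training_config(
                        seed=seed, max_epochs=TRAIN_EPOCHS[structure])
                else:
                    tcfg = U.test_scale_training_config(
                        max_epochs=TRAIN_EPOCHS[structure], seed=seed, augment=False)
                result = U.train(model, pairs, tcfg)
                models[structure] = (model, result)
            cache[seed] = models
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def trained_models(model_factory):
    """Seed-0 trained models as a plain {structure: model} dict."""
    return {k: v[0] for k, v in model_factory(0).items()}


@pytest.fixture(scope="session")
def best_thrombus_model(model_factory):
    """The thrombus model with the highest held-out Dice across the
    bootstrap seeds — standard model selection; the thrombus task is the
    one desk-scale training whose runs vary meaningfully in quality."""
    best = None
    for seed in range(3):
        model, result = model_factory(seed)["thrombus"]
        score = max(result.history) if result.history else 0.0
        if best is None or score > best[0]:
            best = (score, model)
    return best[1]


@pytest.fixture(scope="session")
def ami_eval_set():
    """Degraded evaluation phantoms for the expert-vs-hybrid comparison."""
    return generate_dataset(12, ami_spec(), jitter=AMI_JITTER, seed=21)
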