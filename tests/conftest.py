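import numpy as np
import pytest
from hypothesis import settings

import polyvoxel as pv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config():
    """Small but non-degenerate study: enough cases for 4:1 matching."""
    return pv.GeneratorConfig(
        n_subjects=420,
        n_voxels=120,
        n_pattern_voxels=30,
        homozygote_rate=0.10,
        heterozygote_rate=0.05,
        archetype_effect=2.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return pv.simulate_all(tiny_config)


@pytest.fixture(scope="session")
def labelled_subjects(tiny_study):
    matched = pv.match_controls(tiny_study.subjects, ratio=4, seed=11)
    return pv.split_samples(tiny_study.subjects, matched)


@pytest.fixture(scope="session")
def fitted_model(tiny_study, labelled_subjects):
    table_a = labelled_subjects[labelled_subjects["subsample"] == "A"]
    table_a = table_a.reset_index(drop=True)
    y = (table_a["genotype_class"] == "homozygote").to_numpy(int)
    images = tiny_study.t2w.select_subjects(table_a["subject_id"])
    return pv.fit_pvs(images, table_a, y, r=10, seed=11)


@pytest.fixture(scope="session")
def scored_b(tiny_study, labelled_subjects, fitted_model):
    """(table_b, pvs_b, latent_iron_b) for held-out checks."""
    sel = labelled_subjects["subsample"] == "B"
    table_b = labelled_subjects[sel].reset_index(drop=True)
    images_b = tiny_study.t2w.select_subjects(table_b["subject_id"])
    pvs_b = pv.score_images(fitted_model, images_b, table_b)
    latent_b = tiny_study.truth.latent_iron[np.asarray(sel)]
    return table_b, pvs_b, latent_b
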