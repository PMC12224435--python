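"""Shared fixtures: schemes, renderers, and desk-scale trained networks.

Network training is expensive, so trained models are session-scoped and
shared between the unit suite and the acceptance tests.  All randomness is
seeded; the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dmri_posterior import forward_model as fm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from dmri_posterior import odf_maps as om
from dmri_posterior.io_utils import RunConfig


@pytest.fixture(scope="session")
def scheme() -> fm.AcquisitionScheme:
    """HCP-style synthetic scheme: 90 directions × shells 1000/2000/3000."""
    return fm.hcp_like_scheme(90)


@pytest.fixture(scope="session")
def small_scheme() -> fm.AcquisitionScheme:
    """Cheaper scheme for brute-force comparisons."""
    return fm.hcp_like_scheme(30)


@pytest.fixture(scope="session")
def prior() -> fm.PriorSpec:
    return fm.PriorSpec()


@pytest.fixture(scope="session")
def renderer(scheme) -> om.MapRenderer:
    return om.MapRenderer(scheme)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(master_seed=1234)


@pytest.fixture(scope="session")
def trained_classifier(run_config):
    """Desk-scale classifier on the benchmark prior at SNR 3 (shared)."""
    from dmri_posterior.experiments import train_desk_classifier
    cfg = RunConfig(master_seed=run_config.master_seed,
                    classifier_train_per_class=1000, classifier_epochs=10)
    return train_desk_classifier(cfg)


@pytest.fixture(scope="session")
def trained_wellsep_classifier(run_config, renderer):
    """Classifier trained on the noiseless well-separated protocol:
    n=1 with FA ≥ 0.5, crossings ≥ 60° for n=2 and n=3."""
    import dmri_posterior.classifier as clf
    from dmri_posterior.experiments import (sample_high_fa_singles,
                                            well_separated_prior)
    from dmri_posterior import forward_model as fm

    prior_sep = well_separated_prior(60.0)
    per = 1000
    seed = run_config.master_seed + 501
    a1 = sample_high_fa_singles(per, seed)
    a2 = fm.sample_prior_alphas(prior_sep, 2, per,
                                np.random.default_rng(seed + 1))
    a3 = fm.sample_prior_alphas(prior_sep, 3, per,
                                np.random.default_rng(seed + 2))
    maps = np.concatenate([
        renderer.render_batch(
            fm.simulate_signals(a, prior_sep.w_fast, renderer.scheme))
        for a in (a1, a2, a3)])
    labels = np.repeat([1, 2, 3], per)
    cfg = clf.ClassifierConfig.desk(epochs=10, seed=seed + 3)
    return clf.train_classifier(clf.build_classifier(cfg), maps, labels, cfg)


@pytest.fixture(scope="session")
def trained_posterior_n1(run_config, prior, renderer):
    """Desk-scale single-fiber posterior network on noiseless data."""
    from dmri_posterior import posterior as pe
    cfg = pe.PosteriorNetConfig.desk(n_fibers=1, train_size=18_000,
                                     epochs=10, noise_sigma=0.0,
                                     seed=run_config.master_seed + 1)
    return pe.train_posterior(cfg, prior, renderer)
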