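"""Shared fixtures: one mid-sized synthetic atlas processed once per session."""

import warnings

import numpy as np
import pytest

from lungdyn import preprocess, synthetic, trajectory


@pytest.fixture(scope="session")
def atlas():
    return synthetic.make_atlas(synthetic.SimConfig(seed=1))


@pytest.fixture(scope="session")
def processed(atlas):
    """(qc_counts, expr, embedding, transform_model) for the session atlas."""
    qc = preprocess.qc_filter(atlas.counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, emb, model = preprocess.transform(qc)
    return qc, expr, emb, model


@pytest.fixture(scope="session")
def backbone(atlas, processed):
    """Trajectory model fitted on the planted-type subset of the atlas."""
    qc, expr, emb, _ = processed
    truth = qc.cell_meta["true_type"]
    traj_types = sorted({t for p in atlas.config.trajectory_spec.paths
                         for t in p})
    mask = truth.isin(traj_types).to_numpy()
    model = trajectory.infer_backbone(emb[mask], truth[mask].to_numpy(),
                                      "progenitor", cell_ids=qc.cell_ids[mask])
    return mask, model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
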