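"""VAE building blocks: losses, schedule, encode/decode, training, checkpoints.

The expensive trained-model behaviour (reconstruction accuracy on the
scaled-down study cohort) lives in test_acceptance.py; here everything runs
on a 114-vertex scaled-down LV shell.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomesh import mesh_core as mc
from cardiomesh import mesh_sampling as ms
from cardiomesh import mesh_vae as mv
from cardiomesh import synthetic_population as sp
from cardiomesh.errors import ConfigurationError, DimensionError


@pytest.fixture(scope="module")
def small_hier(small_template):
    return ms.build_hierarchy(small_template, n_levels=3, factor=3.0)


@pytest.fixture(scope="module")
def tiny_model(small_hier):
    stats = mc.StandardizationStats(
        mean=np.zeros((small_hier.levels[0].n_vertices, 3)),
        sd=np.ones((small_hier.levels[0].n_vertices, 3)),
    )
    cfg = mv.VAEConfig(latent_dim=4, cheb_order=3, n_levels=3, channels=(6, 6, 8), epochs=4, batch_size=4, seed=3)
    return mv.MeshVAEModel(small_hier, cfg, stats)


# ---------------------------------------------------------------------------
# Losses and schedule
# ---------------------------------------------------------------------------

def test_kl_zero_when_posterior_is_prior():
    assert mv.kl_divergence(mv.LatentCode(np.zeros(5), np.zeros(5))) == 0.0


def test_kl_unit_mean_closed_form():
    assert mv.kl_divergence(mv.LatentCode(np.array([1.0]), np.array([0.0]))) == pytest.approx(0.5)


def test_kl_matches_monte_carlo_oracle():
    rng = np.random.default_rng(17)
    n = 100_000
    for _ in range(5):
        mu = rng.normal(size=3)
        lv = rng.normal(scale=0.5, size=3)
        code = mv.LatentCode(mu, lv)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * rng.standard_normal((n, 3))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi) + lv).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        diffs = log_q - log_p
        mc_est = diffs.mean()
        se = diffs.std(ddof=1) / np.sqrt(n)
        assert abs(mv.kl_divergence(code) - mc_est) < 3 * se + 1e-12


def test_reconstruction_loss_identity_and_shift(small_template):
    assert mv.reconstruction_loss(small_template, small_template) == 0.0
    shifted = small_template.with_vertices(small_template.vertices + np.array([1.0, 0, 0]))
    assert mv.reconstruction_loss(small_template, shifted) == pytest.approx(1.0)


def test_reconstruction_loss_matches_explicit_sum():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(10, 3))
    y = rng.normal(size=(10, 3))
    brute = sum(np.sum((x[i] - y[i]) ** 2) for i in range(10)) / 10
    assert mv.reconstruction_loss(x, y) == pytest.approx(brute, rel=1e-12)


def test_beta_schedule_endpoints_and_midpoint():
    cfg = mv.VAEConfig(epochs=251)
    assert mv.beta_schedule(0, cfg) == pytest.approx(0.0001)
    assert mv.beta_schedule(250, cfg) == pytest.approx(0.001)
    assert mv.beta_schedule(125, cfg) == pytest.approx(0.00055)
    betas = [mv.beta_schedule(e, cfg) for e in range(251)]
    assert all(b2 >= b1 for b1, b2 in zip(betas, betas[1:]))


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        mv.VAEConfig(beta_start=0.01, beta_end=0.001)
    with pytest.raises(ConfigurationError):
        mv.VAEConfig(channels=(16, 16))


# ---------------------------------------------------------------------------
# Reparameterization
# ---------------------------------------------------------------------------

def test_reparameterize_collapses_to_mean_at_tiny_variance():
    code = mv.LatentCode(np.array([1.0, -2.0]), np.array([-60.0, -60.0]))
    z = mv.reparameterize(code, 1)
    np.testing.assert_allclose(z, code.mu, atol=1e-12)


def test_reparameterize_seed_reproducible():
    code = mv.LatentCode(np.zeros(4), np.zeros(4))
    np.testing.assert_array_equal(mv.reparameterize(code, 9), mv.reparameterize(code, 9))


def test_reparameterize_sample_mean_within_three_se():
    mu = np.array([0.7, -1.2])
    lv = np.array([0.3, -0.4])
    n = 100_000
    stacked = mv.LatentCode(np.tile(mu, (n, 1)), np.tile(lv, (n, 1)))
    draws = mv.reparameterize(stacked, 23)
    se = np.exp(0.5 * lv) / np.sqrt(n)
    assert (np.abs(draws.mean(axis=0) - mu) < 3 * se).all()


# ---------------------------------------------------------------------------
# Encode / decode
# ---------------------------------------------------------------------------

def test_encode_deterministic_and_injective(tiny_model, small_cohort):
    m0, m1 = small_cohort.ed.meshes[0], small_cohort.ed.meshes[1]
    a = mv.encode(tiny_model, m0)
    b = mv.encode(tiny_model, m0)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.log_var, b.log_var)
    assert np.isfinite(a.mu).all()
    c = mv.encode(tiny_model, m1)
    assert not np.allclose(a.mu, c.mu)


def test_decode_deterministic_preserves_connectivity(tiny_model):
    z = np.linspace(-1, 1, tiny_model.config.latent_dim)
    m1 = mv.decode(tiny_model, z)
    m2 = mv.decode(tiny_model, z)
    np.testing.assert_array_equal(m1.vertices, m2.vertices)
    np.testing.assert_array_equal(m1.faces, tiny_model.template.faces)
    assert m1.n_vertices == tiny_model.template.n_vertices


def test_encode_wrong_vertex_count_raises(tiny_model, tetra):
    with pytest.raises(DimensionError):
        mv.encode(tiny_model, tetra)


def test_decode_wrong_latent_length_raises(tiny_model):
    with pytest.raises(DimensionError):
        mv.decode(tiny_model, np.zeros(7))


def test_phase_tag_mismatch_rejected(small_hier, small_cohort):
    stats = mc.fit_standardization(small_cohort.ed)
    cfg = mv.VAEConfig(latent_dim=4, cheb_order=3, n_levels=3, channels=(6, 6, 8), epochs=2, seed=0)
    model = mv.MeshVAEModel(small_hier, cfg, stats, phase="ED")
    with pytest.raises(ConfigurationError):
        mv.encode(model, small_cohort.es.meshes[0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _overfit_setup(small_hier, n=8, seed=5):
    cfg = sp.CohortConfig(
        n_subjects=n, n_rings=6, n_circ=8, allow_nonstandard_resolution=True,
        misalignment_sd_mm=0.0, mace_prevalence=0.0, seed=seed,
    )
    cohort = sp.generate_cohort(cfg)
    ds = mc.MeshDataset(cohort.ed.meshes, cohort.ed.subject_ids)  # no split: train on all
    stats = mc.fit_standardization(ds.meshes)
    return ds, stats


def test_overfit_tiny_dataset_pure_autoencoder_limit(small_template):
    # With beta pinned tiny and enough capacity (shallow hierarchy, one
    # pooling step), an 8-mesh dataset is memorized: final reconstruction
    # loss < 1% of the initial one.
    hier = ms.build_hierarchy(small_template, n_levels=2, factor=3.0)
    ds, stats = _overfit_setup(hier)
    cfg = mv.VAEConfig(
        latent_dim=8, cheb_order=5, n_levels=2, channels=(16, 24),
        epochs=600, learning_rate=0.01, batch_size=8,
        beta_start=1e-9, beta_end=1e-8, seed=2,
    )
    model = mv.MeshVAEModel(hier, cfg, stats)
    hist = mv.train(model, ds, cfg)
    assert hist.reconstruction.iloc[-1] < 0.01 * hist.reconstruction.iloc[0]


def test_training_deterministic_same_seed(small_hier):
    ds, stats = _overfit_setup(small_hier)
    cfg = mv.VAEConfig(latent_dim=4, cheb_order=3, n_levels=3, channels=(6, 6, 8), epochs=5, batch_size=4, seed=11)
    h1 = mv.train(mv.MeshVAEModel(small_hier, cfg, stats), ds, cfg)
    h2 = mv.train(mv.MeshVAEModel(small_hier, cfg, stats), ds, cfg)
    np.testing.assert_array_equal(h1.total.to_numpy(), h2.total.to_numpy())


def test_history_loss_decomposition_identity(small_hier):
    ds, stats = _overfit_setup(small_hier)
    cfg = mv.VAEConfig(latent_dim=4, cheb_order=3, n_levels=3, channels=(6, 6, 8), epochs=6, batch_size=4, seed=1)
    hist = mv.train(mv.MeshVAEModel(small_hier, cfg, stats), ds, cfg)
    np.testing.assert_allclose(
        hist.total.to_numpy(),
        hist.reconstruction.to_numpy() + hist.beta.to_numpy() * hist.kl.to_numpy(),
        atol=1e-9,
    )


# ---------------------------------------------------------------------------
# Evaluation and checkpointing
# ---------------------------------------------------------------------------

def test_evaluate_reconstruction_hd_dominates_msd(tiny_model, small_cohort):
    table = mv.evaluate_reconstruction(tiny_model, small_cohort.ed, split="test")
    assert (table.hd_mm >= table.msd_mm - 1e-12).all()
    assert set(["subject_id", "phase", "msd_mm", "hd_mm"]).issubset(table.columns)


def test_checkpoint_round_trip(tmp_path, small_hier, small_cohort):
    ds = mc.MeshDataset(small_cohort.ed.meshes, small_cohort.ed.subject_ids)
    stats = mc.fit_standardization(ds.meshes)
    cfg = mv.VAEConfig(latent_dim=4, cheb_order=3, n_levels=3, channels=(6, 6, 8), epochs=3, batch_size=4, seed=8)
    model = mv.MeshVAEModel(small_hier, cfg, stats, phase="ED")
    mv.train(model, ds, cfg, checkpoint_path=tmp_path / "model.npz")
    back = mv.load_checkpoint(tmp_path / "model.npz")
    assert back.phase == "ED"
    assert back.config == model.config
    for p, q in zip(model.parameters(), back.parameters()):
        np.testing.assert_array_equal(p.value, q.value)
    mesh = ds.meshes[0]
    np.testing.assert_allclose(mv.encode(back, mesh).mu, mv.encode(model, mesh).mu, atol=1e-12)
    np.testing.assert_array_equal(back.history.total.to_numpy(), model.history.total.to_numpy())
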