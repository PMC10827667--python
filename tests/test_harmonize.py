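"""Empirical-Bayes and linear-model batch correction."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from lithopredict import simcohort
from lithopredict.harmonize import (
    CombatModel,
    apply_combat,
    batch_association,
    combat,
    fit_combat,
    log_normalize,
    residualize_batch,
)


def _sim_location_scale(seed, n_genes=300, n_per_batch=40, gamma_sd=1.0, scale=(1.0, 1.0)):
    """Direct draw from the additive-location / multiplicative-scale model."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(4, 10, n_genes)
    gamma = rng.normal(0, gamma_sd, n_genes)          # planted batch-2 offset
    delta = rng.uniform(*scale, n_genes)
    n = 2 * n_per_batch
    X = mu[:, None] + rng.normal(0, 1, (n_genes, n))
    X[:, n_per_batch:] *= delta[:, None] / 1.0
    X[:, n_per_batch:] += gamma[:, None]
    batches = np.array(["A"] * n_per_batch + ["B"] * n_per_batch)
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"s{j}" for j in range(n)])
    return df, batches, gamma, delta


def test_noiseless_two_batch_gene_collapses_to_grand_mean():
    X = pd.DataFrame([[4.0, 4.0, 8.0, 8.0]], index=["g"], columns=list("abcd"))
    out = combat(X, np.array(["b1", "b1", "b2", "b2"]))
    assert np.allclose(out.to_numpy(), 6.0, atol=1e-6)


def test_single_batch_correction_is_identity():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(5, 1, (20, 8)))
    out = combat(X, np.array(["b1"] * 8))
    assert np.allclose(out.to_numpy(), X.to_numpy(), atol=1e-8)


def test_singleton_batch_rejected():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(5, 5)))
    with pytest.raises(ValueError, match="singleton"):
        fit_combat(X, np.array(["a", "a", "a", "a", "b"]))


def test_location_estimates_recover_planted_offsets():
    X, batches, gamma, _ = _sim_location_scale(seed=1)
    model = fit_combat(X, batches)
    # de-standardize: per-gene batch difference on the original scale
    est = (model.gamma_star[1] - model.gamma_star[0]) * model.sigma
    err = np.abs(est - gamma)
    assert np.median(err) < 0.15
    assert np.corrcoef(est, gamma)[0, 1] > 0.95


def test_shrinkage_pulls_toward_prior_under_null():
    X, batches, _, _ = _sim_location_scale(seed=2, gamma_sd=0.0)
    model = fit_combat(X, batches)
    assert np.abs(model.gamma_star).mean() <= np.abs(model.gamma_hat).mean()


def test_equal_raw_scales_skip_scale_shrinkage():
    # every gene shares one residual pattern => identical delta_hat across genes
    base = np.array([0.5, -0.5, 1.0, -1.0, 0.3, -0.3, 0.8, -0.8])
    X = pd.DataFrame(
        np.stack([3.0 + base, 7.0 + base, 1.0 + base]),
        columns=list("abcdefgh"),
    )
    batches = np.array(["x"] * 4 + ["y"] * 4)
    model = fit_combat(X, batches)
    assert np.allclose(model.delta_sq_star, model.delta_sq_hat, rtol=1e-6)


def test_between_batch_differences_shrink_after_correction():
    X, batches, _, _ = _sim_location_scale(seed=3)
    out = combat(X, batches)

    def med_diff(m):
        a = m.loc[:, batches == "A"].mean(axis=1)
        b = m.loc[:, batches == "B"].mean(axis=1)
        return np.median(np.abs(a - b))

    assert med_diff(out) < 0.1 * med_diff(X)


def test_matches_reference_combat_implementation(tmp_path):
    """Independent oracle: Bioconductor sva::ComBat on the same fixture."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; reference oracle cannot run")
    X, batches, _, _ = _sim_location_scale(seed=7, n_genes=60, n_per_batch=12,
                                           scale=(0.7, 1.4))
    ours = combat(X, batches)
    xp = tmp_path / "X.tsv"
    bp = tmp_path / "batch.txt"
    op = tmp_path / "out.tsv"
    X.to_csv(xp, sep="\t")
    bp.write_text("\n".join(batches))
    script = tmp_path / "combat.R"
    script.write_text(
        "suppressMessages(library(sva))\n"
        f"X <- as.matrix(read.table('{xp}', header=TRUE, row.names=1, sep='\\t'))\n"
        f"batch <- scan('{bp}', what=character(), quiet=TRUE)\n"
        "out <- ComBat(dat=X, batch=batch, par.prior=TRUE, prior.plots=FALSE)\n"
        f"write.table(out, '{op}', sep='\\t', quote=FALSE)\n"
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(op, sep="\t", index_col=0)
    assert np.abs(ours.to_numpy() - ref.to_numpy()).max() < 1e-3


def test_apply_preserves_shape_and_order():
    X, batches, _, _ = _sim_location_scale(seed=4, n_genes=40, n_per_batch=10)
    model = fit_combat(X, batches)
    out = apply_combat(model, X, batches)
    assert list(out.index) == list(X.index)
    assert list(out.columns) == list(X.columns)
    with pytest.raises(ValueError, match="unknown batch"):
        apply_combat(model, X, np.array(["Z"] * X.shape[1]))


def test_parameter_recovery_on_simulated_cohort():
    """EB location estimates correlate with the generator's planted gamma."""
    cfg = simcohort.SimulationConfig(
        n_genes=400, n_marker_genes=0,
        group_sizes={"LR": 40, "NR": 40},
        biological_sigma=0.3, library_size_sigma=0.0, seed=31,
        batches=[
            simcohort.BatchSpec(batch_id="b1", cohort_id="c1",
                                location_shift_sigma=0.8,
                                sample_allocation={"LR": 20, "NR": 20}),
            simcohort.BatchSpec(batch_id="b2", cohort_id="c1",
                                location_shift_sigma=0.8,
                                sample_allocation={"LR": 20, "NR": 20}),
        ],
    )
    counts, meta, _, params = simcohort.generate_cohort(cfg, return_params=True)
    # planted per-gene batch offset difference, converted to the log2 scale
    # the correction operates on
    planted = (params["batch_gamma"]["b2"] - params["batch_gamma"]["b1"]) / np.log(2)
    X = log_normalize(counts)
    b = meta.set_index("sample_id").loc[X.columns, "batch"].to_numpy()
    model = fit_combat(
        X, b, covariates=meta.set_index("sample_id").loc[X.columns, "response"].to_numpy()
    )
    est = (model.gamma_star[1] - model.gamma_star[0]) * model.sigma
    r = np.corrcoef(est, planted)[0, 1]
    assert r > 0.8


# ---------------------------------------------------------------------------
# residualization


def test_residualize_two_constant_batches_meets_in_middle():
    X = pd.DataFrame([[1.0, 1.0, 5.0, 5.0]], index=["g"], columns=list("abcd"))
    out = residualize_batch(X, np.array(["x", "x", "y", "y"]))
    assert np.allclose(out.to_numpy(), 3.0)


def test_residualize_single_batch_is_identity():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(10, 6)))
    out = residualize_batch(X, np.array(["b"] * 6))
    assert np.allclose(out.to_numpy(), X.to_numpy())


def test_residualize_leaves_no_batch_signal_and_protects_groups():
    X, batches, _, _ = _sim_location_scale(seed=5, n_genes=100)
    rng = np.random.default_rng(5)
    groups = rng.permutation(np.array(["G1", "G2"] * 40))
    planted = np.zeros(100)
    planted[:10] = 2.0  # group effect on first 10 genes
    Xg = X + pd.DataFrame(
        np.outer(planted, (groups == "G2").astype(float)),
        index=X.index, columns=X.columns,
    )
    out = residualize_batch(Xg, batches, design=groups)
    # refit of batch contrasts on the output: coefficients vanish
    contrast = np.where(batches == "A", 1.0, -1.0)
    design = np.column_stack([np.ones_like(contrast), (groups == "G2").astype(float), contrast])
    beta, *_ = np.linalg.lstsq(design, out.to_numpy().T, rcond=None)
    assert np.abs(beta[-1]).max() < 1e-8

    def group_fc(m):
        return (m.loc[:, groups == "G2"].mean(axis=1) - m.loc[:, groups == "G1"].mean(axis=1))

    dev = np.abs(group_fc(out) - group_fc(Xg))
    assert np.median(dev) < 0.1


def test_residualize_rejects_confounded_design():
    X = pd.DataFrame(np.arange(8.0).reshape(2, 4))
    batches = np.array(["x", "x", "y", "y"])
    with pytest.raises(ValueError, match="confounded"):
        residualize_batch(X, batches, design=batches)


# ---------------------------------------------------------------------------
# batch association diagnostic


def test_batch_association_tracks_planted_shifts():
    X, batches, _, _ = _sim_location_scale(seed=6, gamma_sd=2.0)
    before = batch_association(X, batches)
    after = batch_association(combat(X, batches), batches)
    assert before > 0.5
    assert after < before


def test_batch_association_null_and_degenerate_cases():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(50, 60)))
    labels = rng.permutation(np.array(["a", "b", "c"] * 20))
    assert batch_association(X, labels) < 0.2
    const = pd.DataFrame(np.ones((5, 6)))
    assert batch_association(const, np.array(["a"] * 3 + ["b"] * 3)) == 0.0
    # two identically distributed batches: PC1 unrelated to labels
    X2 = pd.DataFrame(rng.normal(size=(50, 40)))
    assert batch_association(X2, np.array(["a"] * 20 + ["b"] * 20)) < 0.2
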