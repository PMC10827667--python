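"""Batch-effect removal on log-expression matrices.

Two corrections are provided, mirroring common transcriptomic practice:

* :class:`CombatModel` — the parametric empirical-Bayes location/scale
  adjustment (the ComBat model).  Per batch i and gene g, a location
  offset gamma_ig and a scale factor delta_ig are estimated on
  standardized data and shrunk across genes toward batch-level priors
  (normal prior for gamma, inverse-gamma for delta^2) before the data are
  centred and rescaled.  Used upstream of feature selection and
  classification.
* :func:`residualize_batch` — per-gene least-squares removal of batch
  contrasts (the limma ``removeBatchEffect`` approach), used for PCA and
  correlation diagnostics; an optional protected design keeps biological
  group differences out of the removed component.

Expression matrices are genes x samples pandas DataFrames of
log2(normalized count + 1) values (see :func:`log_normalize`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import size_factors

__all__ = [
    "log_normalize",
    "CombatModel",
    "BatchModel",
    "fit_combat",
    "apply_combat",
    "combat",
    "residualize_batch",
    "batch_association",
]

_VAR_FLOOR = 1e-8


def log_normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression matrix.

    ``factors`` defaults to median-of-ratios size factors computed from
    ``counts``.
    """
    if factors is None:
        factors = size_factors(counts)
    vals = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    return pd.DataFrame(np.log2(vals + 1.0), index=counts.index, columns=counts.columns)


def _dummy(labels: pd.Series | np.ndarray) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    mat = np.column_stack([(labels == lv).astype(float) for lv in levels])
    return mat, levels


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch parameters (results object).

    Attributes are arrays over genes (rows) and batches where applicable:
    ``alpha`` the per-gene grand mean (plus covariate fit stored per
    sample in ``mod_mean``), ``sigma`` the pooled per-gene residual sd,
    ``gamma_star``/``delta_sq_star`` the EB-shrunk location and squared
    scale per (batch, gene), and the per-batch hyperparameters of the
    normal / inverse-gamma priors.
    """

    gene_ids: list
    batch_ids: list
    alpha: np.ndarray                 # (G,)
    sigma: np.ndarray                 # (G,) pooled residual sd
    gamma_hat: np.ndarray             # (B, G) raw batch locations (standardized)
    delta_sq_hat: np.ndarray          # (B, G) raw batch variances
    gamma_star: np.ndarray            # (B, G) shrunk locations
    delta_sq_star: np.ndarray         # (B, G) shrunk variances
    gamma_bar: np.ndarray             # (B,) location prior means
    tau_bar_sq: np.ndarray            # (B,) location prior variances
    lambda_bar: np.ndarray            # (B,) scale prior shapes
    theta_bar: np.ndarray             # (B,) scale prior rates
    n_per_batch: np.ndarray           # (B,)
    mod_mean: pd.DataFrame | None = None   # (G, S) covariate contribution
    covariate_levels: list = field(default_factory=list)
    n_iter: np.ndarray | None = None  # (B,) fixed-point iterations used
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        """Per-batch hyperparameter table."""
        return pd.DataFrame(
            {
                "batch": self.batch_ids,
                "n_samples": self.n_per_batch,
                "location_prior_mean": self.gamma_bar,
                "location_prior_var": self.tau_bar_sq,
                "scale_prior_shape": self.lambda_bar,
                "scale_prior_rate": self.theta_bar,
                "mean_abs_gamma_star": np.abs(self.gamma_star).mean(axis=1),
                "mean_delta_sq_star": self.delta_sq_star.mean(axis=1),
            }
        ).set_index("batch")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "batch_ids": list(map(str, self.batch_ids)),
            "n_per_batch": self.n_per_batch.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau_bar_sq": self.tau_bar_sq.tolist(),
            "lambda_bar": self.lambda_bar.tolist(),
            "theta_bar": self.theta_bar.tolist(),
            "gene_ids": list(map(str, self.gene_ids)),
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_sq_star": self.delta_sq_star.tolist(),
            "converged": bool(self.converged),
        }
        Path(path).write_text(json.dumps(payload))


class CombatModel:
    """Empirical-Bayes location/scale batch-adjustment model.

    Parameters
    ----------
    X : genes x samples DataFrame of log expression.
    batches : per-sample batch labels (aligned with ``X`` columns).
    covariates : optional per-sample biological group labels to protect
        during standardization (e.g. diagnosis or response on training
        data).  Pass None when labels must not be used (held-out data).
    """

    def __init__(self, X: pd.DataFrame, batches, covariates=None,
                 conv_tol: float = 1e-4, max_iter: int = 100):
        self.X = X
        self.batches = np.asarray(batches)
        self.covariates = None if covariates is None else np.asarray(covariates)
        self.conv_tol = conv_tol
        self.max_iter = max_iter
        if len(self.batches) != X.shape[1]:
            raise ValueError("batch labels must align with samples")
        levels, counts = np.unique(self.batches, return_counts=True)
        if counts.min() < 2:
            bad = levels[counts.argmin()]
            raise ValueError(f"batch {bad!r} is a singleton; >= 2 samples required")
        if self.covariates is not None:
            # a covariate level wholly contained in one batch it alone occupies
            # makes batch and biology unseparable
            for lv in np.unique(self.covariates):
                b_of = np.unique(self.batches[self.covariates == lv])
                if len(b_of) == 1 and len(np.unique(self.covariates[self.batches == b_of[0]])) == 1:
                    raise ValueError(
                        f"covariate level {lv!r} confounded with batch {b_of[0]!r}"
                    )

    def fit(self) -> BatchModel:
        X = self.X.to_numpy(dtype=float)
        G, S = X.shape
        batch_mat, batch_levels = _dummy(self.batches)
        B = len(batch_levels)
        n_i = batch_mat.sum(axis=0)
        if B == 1:
            # degenerate but allowed: gamma = 0, delta = 1 by construction,
            # so applying the model is the identity
            sigma = np.sqrt(np.maximum(X.var(axis=1), _VAR_FLOOR))
            ones = np.ones((1, G))
            return BatchModel(
                gene_ids=list(self.X.index), batch_ids=batch_levels,
                alpha=X.mean(axis=1), sigma=sigma,
                gamma_hat=np.zeros((1, G)), delta_sq_hat=ones.copy(),
                gamma_star=np.zeros((1, G)), delta_sq_star=ones.copy(),
                gamma_bar=np.zeros(1), tau_bar_sq=np.zeros(1),
                lambda_bar=np.full(1, np.inf), theta_bar=np.full(1, np.nan),
                n_per_batch=n_i.astype(int), mod_mean=None,
                n_iter=np.zeros(1, dtype=int),
            )

        design_parts = [batch_mat]
        cov_levels: list = []
        if self.covariates is not None:
            cov_mat, cov_levels = _dummy(self.covariates)
            design_parts.append(cov_mat[:, 1:])  # drop reference level
        design = np.column_stack(design_parts)

        # (1) least squares; batch coefficients weighted-sum-to-zero give
        # the grand mean alpha
        beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (p, G)
        grand = (n_i / S) @ beta[:B]                          # (G,)
        mod_mean = np.zeros((G, S))
        if self.covariates is not None:
            mod_mean = (design[:, B:] @ beta[B:]).T
        stand_mean = grand[:, None] + mod_mean
        batch_mean = (design[:, :B] @ beta[:B]).T             # (G, S)
        resid = X - batch_mean - mod_mean
        var_pooled = (resid ** 2).mean(axis=1)                # ddof 0 over all samples
        # genes constant across *all* samples carry nothing to correct
        zero_var = X.var(axis=1) <= _VAR_FLOOR
        sigma = np.sqrt(np.maximum(var_pooled, _VAR_FLOOR))

        Z = (X - stand_mean) / sigma[:, None]

        gamma_hat = np.empty((B, G))
        delta_sq_hat = np.empty((B, G))
        gamma_star = np.empty((B, G))
        delta_sq_star = np.empty((B, G))
        gamma_bar = np.empty(B)
        tau_bar_sq = np.empty(B)
        lambda_bar = np.empty(B)
        theta_bar = np.empty(B)
        n_iter = np.zeros(B, dtype=int)
        converged = True
        for i, lv in enumerate(batch_levels):
            sel = self.batches == lv
            Zi = Z[:, sel]
            g_hat = Zi.mean(axis=1)
            d_hat = Zi.var(axis=1, ddof=1) if n_i[i] > 1 else np.ones(G)
            d_hat = np.maximum(d_hat, _VAR_FLOOR)
            gamma_hat[i] = g_hat
            delta_sq_hat[i] = d_hat
            gamma_bar[i] = g_hat.mean()
            tau_bar_sq[i] = g_hat.var(ddof=1) if G > 1 else 0.0
            m = d_hat.mean()
            v = d_hat.var(ddof=1) if G > 1 else 0.0
            if v <= 0:
                # degenerate prior: no information to shrink scale
                lambda_bar[i] = np.inf
                theta_bar[i] = np.nan
                g_star, d_star, it = self._fixed_point(
                    Zi, g_hat, d_hat, gamma_bar[i], tau_bar_sq[i], None, None, int(n_i[i])
                )
            else:
                lambda_bar[i] = m * m / v + 2.0
                theta_bar[i] = m * (lambda_bar[i] - 1.0)
                g_star, d_star, it = self._fixed_point(
                    Zi, g_hat, d_hat, gamma_bar[i], tau_bar_sq[i],
                    lambda_bar[i], theta_bar[i], int(n_i[i]),
                )
            gamma_star[i] = g_star
            delta_sq_star[i] = d_star
            n_iter[i] = it
            if it >= self.max_iter:
                converged = False

        # genes with no pooled variance pass through untouched
        if zero_var.any():
            gamma_star[:, zero_var] = 0.0
            delta_sq_star[:, zero_var] = 1.0

        return BatchModel(
            gene_ids=list(self.X.index),
            batch_ids=batch_levels,
            alpha=grand,
            sigma=sigma,
            gamma_hat=gamma_hat,
            delta_sq_hat=delta_sq_hat,
            gamma_star=gamma_star,
            delta_sq_star=delta_sq_star,
            gamma_bar=gamma_bar,
            tau_bar_sq=tau_bar_sq,
            lambda_bar=lambda_bar,
            theta_bar=theta_bar,
            n_per_batch=n_i.astype(int),
            mod_mean=pd.DataFrame(mod_mean, index=self.X.index, columns=self.X.columns),
            covariate_levels=cov_levels,
            n_iter=n_iter,
            converged=converged,
        )

    def _fixed_point(self, Zi, g_hat, d_hat, g_bar, tau_sq, lam, theta, n):
        """Iterate the EB posterior-mean updates for one batch."""
        g_star = g_hat.copy()
        d_star = d_hat.copy()
        if tau_sq <= 0:
            # all raw locations identical across genes: prior is a point mass
            g_star = np.full_like(g_hat, g_bar)
        if lam is None:
            # degenerate scale prior: keep raw variances, solve location only
            if tau_sq > 0:
                g_star = (n * tau_sq * g_hat + d_star * g_bar) / (n * tau_sq + d_star)
            return g_star, d_star, 0
        for it in range(1, self.max_iter + 1):
            if tau_sq > 0:
                g_new = (n * tau_sq * g_hat + d_star * g_bar) / (n * tau_sq + d_star)
            else:
                g_new = g_star
            sse = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * sse) / (n / 2.0 + lam - 1.0)
            d_new = np.maximum(d_new, _VAR_FLOOR)
            delta = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if delta < self.conv_tol:
                return g_star, d_star, it
        return g_star, d_star, self.max_iter


def fit_combat(X: pd.DataFrame, batches, covariates=None, **kw) -> BatchModel:
    """Fit the empirical-Bayes batch model (see :class:`CombatModel`)."""
    return CombatModel(X, batches, covariates, **kw).fit()


def apply_combat(model: BatchModel, X: pd.DataFrame, batches) -> pd.DataFrame:
    """Adjust ``X`` with a fitted :class:`BatchModel`.

    Samples must be (a subset of) those the model was fitted on when the
    fit protected covariates; gene order must match the fit.
    """
    batches = np.asarray(batches)
    if list(X.index) != list(model.gene_ids):
        raise ValueError("gene ids/order differ from the fitted model")
    unknown = set(np.unique(batches)) - set(model.batch_ids)
    if unknown:
        raise ValueError(f"unknown batch label {sorted(unknown)[0]!r}")
    vals = X.to_numpy(dtype=float)
    if model.mod_mean is not None and (model.mod_mean.to_numpy() != 0).any():
        missing = [c for c in X.columns if c not in model.mod_mean.columns]
        if missing:
            raise ValueError(
                f"sample {missing[0]!r} was not in the covariate-protected fit"
            )
        mod = model.mod_mean[X.columns].to_numpy()
    else:
        mod = np.zeros_like(vals)
    stand_mean = model.alpha[:, None] + mod
    Z = (vals - stand_mean) / model.sigma[:, None]
    out = np.empty_like(vals)
    for i, lv in enumerate(model.batch_ids):
        sel = batches == lv
        if not sel.any():
            continue
        adj = (Z[:, sel] - model.gamma_star[i][:, None]) / np.sqrt(
            model.delta_sq_star[i]
        )[:, None]
        out[:, sel] = adj * model.sigma[:, None] + stand_mean[:, sel]
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def combat(X: pd.DataFrame, batches, covariates=None, **kw) -> pd.DataFrame:
    """Fit-and-apply convenience wrapper."""
    model = fit_combat(X, batches, covariates, **kw)
    return apply_combat(model, X, batches)


def residualize_batch(X: pd.DataFrame, batches, design=None) -> pd.DataFrame:
    """Remove the batch component by per-gene least squares.

    Batch enters through sum-to-zero contrasts so the fitted intercept is
    the balanced grand mean; ``design`` (per-sample group labels) is
    protected — its fitted component is retained in the output.
    """
    batches = np.asarray(batches)
    levels = sorted(pd.unique(batches).tolist())
    if len(levels) < 2:
        return X.copy()
    # sum-to-zero coding: level i -> e_i (i < B-1), last level -> -1 vector
    B = len(levels)
    contrasts = np.zeros((len(batches), B - 1))
    for i, lv in enumerate(levels[:-1]):
        contrasts[batches == lv, i] = 1.0
    contrasts[batches == levels[-1], :] = -1.0
    parts = [np.ones((len(batches), 1))]
    if design is not None:
        dmat, _ = _dummy(design)
        parts.append(dmat[:, 1:])
    protected = np.column_stack(parts)
    full = np.column_stack([protected, contrasts])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        raise ValueError("batch contrasts confounded with the protected design")
    vals = X.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(full, vals.T, rcond=None)
    batch_part = (contrasts @ beta[protected.shape[1]:]).T
    return pd.DataFrame(vals - batch_part, index=X.index, columns=X.columns)


def batch_association(X: pd.DataFrame, batches) -> float:
    """R-squared of one-way ANOVA of sample PC1 scores on batch labels.

    0 means PC1 carries no batch signal; 1 means PC1 is fully explained by
    batch.  A constant matrix returns 0.
    """
    batches = np.asarray(batches)
    vals = X.to_numpy(dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    if not np.any(centered):
        return 0.0
    # PC1 scores of samples: leading right singular vector
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = s[0] * vt[0]
    total = ((scores - scores.mean()) ** 2).sum()
    if total <= 0:
        return 0.0
    between = 0.0
    for lv in pd.unique(batches):
        sel = scores[batches == lv]
        between += len(sel) * (sel.mean() - scores.mean()) ** 2
    return float(between / total)
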