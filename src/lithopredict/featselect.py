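"""Consensus biomarker-panel selection by exhaustive subset search.

Pipeline: (1) screen every gene with a two-sided Mann-Whitney U test and
keep the k = 20 smallest p-values; (2) enumerate every candidate subset up
to a size cap; (3) score each subset by the mean accuracy of an
L2-regularized logistic classifier over repeated stratified subject-level
50/50 splits; (4) keep subsets whose accuracy exceeds a gate (0.93 by
default); (5) rank genes by how often they appear in passing subsets and
take the top ``panel_size`` (7 for the lithium-response task, 5 for the
diagnosis task) as the consensus panel.

The subset scorer is a Newton/IRLS logistic regression vectorized across
subsets, so the full enumeration (137,979 subsets for k = 20, sizes 1-7)
stays tractable on one CPU.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import mwu_test

__all__ = [
    "ScreenResult",
    "SubsetSearchResult",
    "FeaturePanel",
    "mwu_screen",
    "enumerate_subsets",
    "score_subset",
    "search_subsets",
    "consensus_select",
    "select_features",
    "make_subject_splits",
]

_SD_FLOOR = 1e-12


class GateError(RuntimeError):
    """No subset passed the accuracy gate; lower ``accuracy_threshold``."""


@dataclass
class ScreenResult:
    gene_ids: list[str]          # retained genes, best first
    u_stats: pd.Series           # per retained gene
    p_values: pd.Series          # per retained gene
    k: int
    all_p_values: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids,
             "U": self.u_stats.loc[self.gene_ids].to_numpy(),
             "p_value": self.p_values.loc[self.gene_ids].to_numpy()}
        )


@dataclass
class SubsetSearchResult:
    subsets: list[tuple[tuple[str, ...], float]]
    accuracy_threshold: float
    passing_subsets: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    gene_frequency: dict[str, float] = field(default_factory=dict)


@dataclass
class FeaturePanel:
    gene_ids: list[str]
    panel_size: int
    screen_p_values: dict[str, float] = field(default_factory=dict)
    frequencies: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes": self.gene_ids,
            "panel_size": self.panel_size,
            "screen_p_values": self.screen_p_values,
            "consensus_frequencies": self.frequencies,
        }


def mwu_screen(X: pd.DataFrame, labels, k: int = 20) -> ScreenResult:
    """Keep the k genes with the smallest two-sided Mann-Whitney p-values.

    Ties on p are broken by larger absolute median group difference, then
    lexicographic gene id.
    """
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available genes")
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 label levels, got {levels}")
    m1 = labels == levels[0]
    m2 = labels == levels[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("need >= 2 samples per class")
    vals = X.to_numpy(dtype=float)
    n = X.shape[0]
    us = np.empty(n)
    ps = np.empty(n)
    meddiff = np.empty(n)
    for i in range(n):
        x1, x2 = vals[i, m1], vals[i, m2]
        us[i], ps[i] = mwu_test(x1, x2)
        meddiff[i] = abs(np.median(x2) - np.median(x1))
    order = sorted(range(n), key=lambda i: (ps[i], -meddiff[i], str(X.index[i])))
    retained = [str(X.index[i]) for i in order[:k]]
    return ScreenResult(
        gene_ids=retained,
        u_stats=pd.Series(us, index=X.index),
        p_values=pd.Series(ps, index=X.index),
        k=k,
        all_p_values=pd.Series(ps, index=X.index),
    )


def enumerate_subsets(candidates, min_size: int, max_size: int):
    """Yield every subset of each size in [min_size, max_size] exactly once,
    sizes ascending, members in candidate order within a size."""
    candidates = list(candidates)
    if not (1 <= min_size <= max_size <= len(candidates)):
        raise ValueError(
            f"need 1 <= min_size <= max_size <= {len(candidates)}, "
            f"got ({min_size}, {max_size})"
        )
    for size in range(min_size, max_size + 1):
        yield from itertools.combinations(candidates, size)


def n_subsets(n_candidates: int, min_size: int, max_size: int) -> int:
    return sum(math.comb(n_candidates, k) for k in range(min_size, max_size + 1))


# ---------------------------------------------------------------------------
# split machinery (shared with classify)


def make_subject_splits(
    y,
    subject_ids,
    n_splits: int,
    test_fraction: float,
    rng: np.random.Generator,
    max_attempts: int = 20,
):
    """Stratified subject-level train/test index splits.

    Subjects (not samples) are partitioned so replicates never straddle
    the split; stratification keeps class shares; a split missing a class
    on either side is resampled (up to ``max_attempts``).
    Returns a list of (train_sample_idx, test_sample_idx) arrays.
    """
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    subjects = pd.unique(subject_ids)
    subj_y = {}
    for s in subjects:
        lab = np.unique(y[subject_ids == s])
        if len(lab) != 1:
            raise ValueError(f"subject {s!r} has inconsistent labels")
        subj_y[s] = lab[0]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    splits = []
    for _ in range(n_splits):
        for _attempt in range(max_attempts):
            test_subjects: list = []
            for c in classes:
                cls_subj = np.array([s for s in subjects if subj_y[s] == c])
                n_test = int(round(len(cls_subj) * test_fraction))
                n_test = min(max(n_test, 1), len(cls_subj) - 1)
                test_subjects.extend(rng.choice(cls_subj, size=n_test, replace=False))
            test_mask = np.isin(subject_ids, test_subjects)
            tr, te = np.flatnonzero(~test_mask), np.flatnonzero(test_mask)
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                splits.append((tr, te))
                break
        else:
            raise RuntimeError("could not form a split with both classes present")
    return splits


# ---------------------------------------------------------------------------
# batched logistic scorer


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < _SD_FLOOR, 1.0, sd)  # constant feature: leave centred
    return (train - mu) / sd, (test - mu) / sd


def _logistic_fit_batch(
    X: np.ndarray, y: np.ndarray, l2: float = 1.0, max_iter: int = 30, tol: float = 1e-7
) -> np.ndarray:
    """L2-penalized logistic regression fit jointly for a batch of designs.

    X: (S, n, k) stack of design matrices (no intercept column; one is
    appended), y: (n,) in {0,1}.  The penalty ``l2`` applies to weights,
    not the intercept.  Returns coefficients (S, k+1), intercept last.
    """
    S, n, k = X.shape
    Xd = np.concatenate([X, np.ones((S, n, 1))], axis=2)
    beta = np.zeros((S, k + 1))
    pen = np.full(k + 1, l2)
    pen[-1] = 0.0
    eye = np.eye(k + 1)
    active = np.ones(S, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("snk,sk->sn", Xd, beta)
        eta = np.clip(eta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        grad = np.einsum("snk,sn->sk", Xd, y[None, :] - p) - pen * beta
        H = np.einsum("snk,sn,snj->skj", Xd, w, Xd) + pen[None, :, None] * eye
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        step = np.clip(step, -10.0, 10.0)
        beta = beta + np.where(active[:, None], step, 0.0)
        active = np.abs(step).max(axis=1) > tol
        if not active.any():
            break
    return beta


def _score_index_batch(
    Xfull: np.ndarray,
    y01: np.ndarray,
    subsets_idx: np.ndarray,
    splits,
    l2: float = 1.0,
) -> np.ndarray:
    """Mean split accuracy for each subset (rows of ``subsets_idx``)."""
    S = subsets_idx.shape[0]
    acc = np.zeros(S)
    for tr, te in splits:
        Xtr, Xte = _standardize(Xfull[tr], Xfull[te])
        ytr, yte = y01[tr], y01[te]
        Xtr_s = Xtr[:, subsets_idx].transpose(1, 0, 2)  # (S, n_tr, k)
        Xte_s = Xte[:, subsets_idx].transpose(1, 0, 2)
        beta = _logistic_fit_batch(Xtr_s, ytr, l2=l2)
        eta = np.einsum("snk,sk->sn", Xte_s, beta[:, :-1]) + beta[:, -1][:, None]
        pred = (eta > 0).astype(int)
        acc += (pred == yte[None, :]).mean(axis=1)
    return acc / len(splits)


def score_subset(
    X: pd.DataFrame,
    labels,
    subset,
    subject_ids=None,
    n_splits: int = 5,
    test_fraction: float = 0.5,
    seed: int = 0,
    l2: float = 1.0,
) -> float:
    """Mean accuracy of the logistic scorer for one gene subset.

    ``X`` is genes x samples; scoring uses ``n_splits`` stratified
    subject-level 50/50 splits (samples of one subject never straddle a
    split), features z-scored on the training half only.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    labels = np.asarray(labels)
    if subject_ids is None:
        subject_ids = np.asarray(X.columns)
    rng = np.random.default_rng(seed)
    splits = make_subject_splits(labels, subject_ids, n_splits, test_fraction, rng)
    levels = sorted(pd.unique(labels).tolist())
    y01 = (labels == levels[1]).astype(int)
    Xfull = X.loc[subset].to_numpy(dtype=float).T  # samples x genes
    idx = np.arange(len(subset))[None, :]
    return float(_score_index_batch(Xfull, y01, idx, splits, l2=l2)[0])


def search_subsets(
    X: pd.DataFrame,
    labels,
    candidates,
    min_size: int = 1,
    max_size: int = 7,
    accuracy_threshold: float = 0.93,
    subject_ids=None,
    n_splits: int = 5,
    test_fraction: float = 0.5,
    seed: int = 0,
) -> SubsetSearchResult:
    """Exhaustively score every candidate subset and gate by accuracy."""
    candidates = list(candidates)
    if not (1 <= min_size <= max_size <= len(candidates)):
        raise ValueError("invalid size bounds")
    labels = np.asarray(labels)
    if subject_ids is None:
        subject_ids = np.asarray(X.columns)
    rng = np.random.default_rng(seed)
    splits = make_subject_splits(labels, subject_ids, n_splits, test_fraction, rng)
    levels = sorted(pd.unique(labels).tolist())
    y01 = (labels == levels[1]).astype(int)
    Xfull = X.loc[candidates].to_numpy(dtype=float).T

    all_subsets: list[tuple[tuple[str, ...], float]] = []
    for size in range(min_size, max_size + 1):
        idx = np.array(list(itertools.combinations(range(len(candidates)), size)))
        scores = _score_index_batch(Xfull, y01, idx, splits)
        for row, sc in zip(idx, scores):
            all_subsets.append((tuple(candidates[i] for i in row), float(sc)))
    passing = [(s, sc) for s, sc in all_subsets if sc > accuracy_threshold]
    freq: dict[str, float] = {}
    if passing:
        counts: dict[str, int] = {}
        for s, _ in passing:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        freq = {g: c / len(passing) for g, c in counts.items()}
    return SubsetSearchResult(
        subsets=all_subsets,
        accuracy_threshold=accuracy_threshold,
        passing_subsets=passing,
        gene_frequency=freq,
    )


def consensus_select(
    search: SubsetSearchResult, panel_size: int, screen: ScreenResult
) -> FeaturePanel:
    """Top ``panel_size`` genes by frequency among passing subsets.

    Ties broken by smaller screen p-value, then lexicographic gene id.
    """
    if not search.passing_subsets:
        raise GateError(
            f"no subset exceeded accuracy {search.accuracy_threshold}; "
            "lower the accuracy threshold"
        )
    p = screen.p_values
    genes = sorted(
        search.gene_frequency,
        key=lambda g: (-search.gene_frequency[g], p.get(g, 1.0), g),
    )
    chosen = genes[:panel_size]
    return FeaturePanel(
        gene_ids=chosen,
        panel_size=panel_size,
        screen_p_values={g: float(p.get(g, np.nan)) for g in chosen},
        frequencies={g: search.gene_frequency[g] for g in chosen},
    )


def select_features(
    X: pd.DataFrame,
    labels,
    k: int = 20,
    min_size: int = 1,
    max_size: int = 7,
    accuracy_threshold: float = 0.93,
    panel_size: int = 7,
    subject_ids=None,
    n_splits: int = 5,
    test_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[FeaturePanel, ScreenResult, SubsetSearchResult]:
    """Screen -> exhaustive search -> gate -> consensus, end to end.

    Returns the panel plus the full screen and search results for audit.
    """
    screen = mwu_screen(X, labels, k=k)
    search = search_subsets(
        X,
        labels,
        screen.gene_ids,
        min_size=min_size,
        max_size=min(max_size, k),
        accuracy_threshold=accuracy_threshold,
        subject_ids=subject_ids,
        n_splits=n_splits,
        test_fraction=test_fraction,
        seed=seed,
    )
    panel = consensus_select(search, panel_size, screen)
    return panel, screen, search
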