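"""Cross-validated AUC evaluation, significance thresholds and cohort reports.

Implements the per-subject protocol: shuffle, split into k = 5 groups,
train a fresh model on 4 groups and score the held-out group, then report
the five fold AUCs with their mean and sample SD. Decoding significance is
judged against exact binomial chance-level thresholds, robustness by
re-running the identical protocol with the noisy (improbable) epochs
retained, and site effects with a rank-sum test.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet
from .metrics import auc
from . import cnn as cnn_mod
from . import svm as svm_mod

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partitioning


def kfold_split(n_items: int, k: int = 5, seed: int = 0) -> list:
    """Shuffle indices and split into k groups whose sizes differ by <= 1."""
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} groups")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n_items), k)


# ---------------------------------------------------------------------------
# significance thresholds


@dataclass(frozen=True)
class SignificanceThreshold:
    """Chance-level accuracy threshold from the exact binomial tail.

    ``critical_count`` is the smallest correct-trial count c* with
    P(X >= c* | n, p=0.5) < alpha; scores strictly above ``threshold_pct``
    ( = 100 (c*-1)/n ) are significant at level alpha.
    """

    n: int
    alpha: float
    critical_count: int
    threshold_pct: float


def significance_threshold(n: int, alpha: float) -> SignificanceThreshold:
    if n < 1 or not (0 < alpha < 1):
        raise ValueError("need n >= 1 and 0 < alpha < 1")
    tail = stats.binom.sf(np.arange(n + 1) - 1, n, 0.5)  # P(X >= c)
    below = np.nonzero(tail < alpha)[0]
    c_star = int(below[0]) if below.size else n + 1
    return SignificanceThreshold(n, alpha, c_star, 100.0 * (c_star - 1) / n)


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class CVSummary:
    """Per-fold AUCs plus their mean/SD for one subject-model-condition run."""

    fold_aucs: list
    mean_auc: float
    sd_auc: float
    subject_id: str = ""
    model: str = ""
    condition: str = "clean"
    seed: int = 0
    n_epochs: int = 0
    site: str = "A"
    pooled_auc: float | None = None


def _summarise(fold_aucs, **kw) -> CVSummary:
    fold_aucs = [float(a) for a in fold_aucs]
    sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    return CVSummary(fold_aucs, float(np.mean(fold_aucs)), sd, **kw)


def _cnn_fold_scores(Xtr, ytr, Xte, cnn_config, fold_seed):
    norm = cnn_mod.MinMaxSymmetric().fit(Xtr)
    cfg = replace(cnn_config, seed=fold_seed)
    model, _ = cnn_mod.train_cnn(
        norm.transform(Xtr), ytr, cfg, validation_split=0.0
    )
    return model.predict_proba(norm.transform(Xte))


def run_cv(
    model_kind,
    epoch_set: EpochSet,
    k: int = 5,
    seed: int = 0,
    condition: str = "clean",
    subject_id: str = "",
    site: str = "A",
    cnn_config: "cnn_mod.TrainConfig | None" = None,
    svm_config: "svm_mod.SVMConfig | None" = None,
    max_redraws: int = 50,
) -> CVSummary:
    """k-fold evaluation of one subject under one condition.

    ``model_kind`` is ``"cnn"``, ``"svm"``, or a factory ``f(seed) -> model``
    exposing ``fit(X, y)`` and ``predict_score(X)`` on raw epoch arrays.
    ``condition`` selects the clean view (reject mask applied) or
    ``"all_epochs"``. A shuffle that leaves a test fold single-class is
    re-drawn with a fresh seed (logged).
    """
    if condition not in ("clean", "all_epochs"):
        raise ValueError("condition must be 'clean' or 'all_epochs'")
    eps = epoch_set.clean() if condition == "clean" else epoch_set
    y = eps.labels_int
    if len(np.unique(y)) < 2:
        raise ValueError("epoch set must contain both classes")
    groups = None
    for attempt in range(max_redraws):
        cand = kfold_split(eps.n_epochs, k, seed + 100_000 * attempt)
        if all(len(np.unique(y[g])) == 2 for g in cand):
            groups = cand
            break
        logger.info("re-drawing folds (attempt %d): single-class test fold", attempt + 1)
    if groups is None:
        raise RuntimeError("could not draw folds with both classes in every test group")

    features = None
    if model_kind == "svm":
        features = svm_mod.bandpower_features(eps).values
    fold_aucs, pooled_scores, pooled_y = [], [], []
    for fold, test_idx in enumerate(groups):
        train_idx = np.concatenate([g for j, g in enumerate(groups) if j != fold])
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % 2**31)
        if model_kind == "svm":
            pipe = svm_mod.SVMPipeline(svm_config)
            pipe.fit(features[train_idx], y[train_idx])
            scores = pipe.predict_score(features[test_idx])
        elif model_kind == "cnn":
            scores = _cnn_fold_scores(
                eps.data[train_idx],
                y[train_idx],
                eps.data[test_idx],
                cnn_config or cnn_mod.TrainConfig(),
                fold_seed,
            )
        elif callable(model_kind):
            model = model_kind(fold_seed)
            model.fit(eps.data[train_idx], y[train_idx])
            scores = model.predict_score(eps.data[test_idx])
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        fold_aucs.append(auc(y[test_idx], scores))
        pooled_scores.append(np.asarray(scores))
        pooled_y.append(y[test_idx])
    summary = _summarise(
        fold_aucs,
        subject_id=subject_id,
        model=model_kind if isinstance(model_kind, str) else "custom",
        condition=condition,
        seed=seed,
        n_epochs=eps.n_epochs,
        site=site,
    )
    summary.pooled_auc = auc(np.concatenate(pooled_y), np.concatenate(pooled_scores))
    return summary


def robustness_experiment(
    epoch_set: EpochSet,
    model_kind,
    seed: int = 0,
    k: int = 5,
    subject_id: str = "",
    site: str = "A",
    cnn_config=None,
    svm_config=None,
) -> dict:
    """Evaluate one subject on clean epochs and on all epochs (noisy retained).

    Both runs use the same fold-drawing policy (same seed); returns the two
    summaries plus the AUC degradation (clean minus all-epochs).
    """
    if epoch_set.reject_mask is None:
        raise ValueError("epoch set has no reject mask; run preprocessing first")
    if epoch_set.clean().n_epochs == 0:
        raise ValueError("no clean epochs available")
    out = {}
    for condition in ("clean", "all_epochs"):
        out[condition] = run_cv(
            model_kind,
            epoch_set,
            k=k,
            seed=seed,
            condition=condition,
            subject_id=subject_id,
            site=site,
            cnn_config=cnn_config,
            svm_config=svm_config,
        )
    out["degradation"] = out["clean"].mean_auc - out["all_epochs"].mean_auc
    return out


# ---------------------------------------------------------------------------
# group comparison


def rank_sum_test(group_a, group_b) -> tuple:
    """Two-sided rank-sum (Mann-Whitney) test; returns (W, Z, p).

    W is the smaller group's rank sum. With >= 8 values per group the normal
    approximation with tie correction is used; otherwise the null
    distribution of the rank sum is enumerated exactly over all assignments
    of the observed (possibly tied) ranks.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if b.size < a.size:
        a, b = b, a  # a is now the smaller (or first of equal) group
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    n_s, n_l = a.size, b.size
    N = n_s + n_l
    W = float(ranks[:n_s].sum())
    mu = n_s * (N + 1) / 2.0
    if min(n_s, n_l) >= 8:
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
        var = n_s * n_l / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            return W, 0.0, 1.0
        z = (W - mu) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        return W, float(z), float(p)
    sums = np.array([ranks[list(c)].sum() for c in combinations(range(N), n_s)])
    p = float(np.mean(np.abs(sums - mu) >= abs(W - mu) - 1e-12))
    if var_exact := float(np.var(sums)):
        z = (W - mu) / np.sqrt(var_exact)
    else:
        z = 0.0
    return W, float(z), p


# ---------------------------------------------------------------------------
# cohort reporting


def cohort_report(
    summaries: list, alphas=(0.05, 1e-4), n_trials: int = 100
) -> tuple[pd.DataFrame, dict]:
    """Tabulate per-subject summaries and compute cohort statistics.

    Returns (table, stats): one row per CVSummary; stats holds cohort
    mean/SD of the per-subject mean AUCs per (model, condition), binomial
    significance thresholds at the requested alphas (for ``n_trials``
    trials), and - when two sites are present - a rank-sum comparison of
    per-subject AUCs between sites for each model/condition.
    """
    if not summaries:
        raise ValueError("no summaries to report")
    rows = [
        {
            "subject_id": s.subject_id,
            "model": s.model,
            "condition": s.condition,
            "site": s.site,
            "n_epochs": s.n_epochs,
            "fold_aucs": ";".join(f"{a:.6f}" for a in s.fold_aucs),
            "mean_auc": s.mean_auc,
            "sd_auc": s.sd_auc,
            "seed": s.seed,
        }
        for s in summaries
    ]
    table = pd.DataFrame(rows)
    stats_out: dict = {
        "thresholds": {
            alpha: significance_threshold(n_trials, alpha).threshold_pct for alpha in alphas
        },
        "groups": {},
        "site_comparison": {},
    }
    for (model, condition), grp in table.groupby(["model", "condition"]):
        key = f"{model}:{condition}"
        stats_out["groups"][key] = {
            "mean_auc": float(grp["mean_auc"].mean()),
            "sd_auc": float(grp["mean_auc"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "n_subjects": int(len(grp)),
        }
        sites = sorted(grp["site"].unique())
        if len(sites) == 2:
            a = grp.loc[grp["site"] == sites[0], "mean_auc"].to_numpy()
            b = grp.loc[grp["site"] == sites[1], "mean_auc"].to_numpy()
            W, Z, p = rank_sum_test(a, b)
            stats_out["site_comparison"][key] = {"W": W, "Z": Z, "p": p}
    return table, stats_out
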