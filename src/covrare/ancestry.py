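"""Ancestry inference: LD pruning, joint PCA with a labelled reference panel,
and vote-based super-population classification.

Pruning follows the classic sliding-window variance-inflation-factor scheme:
windows of 50 variants advancing by 5; within a window the variant with the
largest VIF (1/(1−R²) from regressing its genotype on the other window
variants) is removed, greedily, until all VIF ≤ 1.5 (r² ≈ 0.33).  Variants
with alt-allele frequency < 0.1 are excluded before pruning and PCA.

The cohort is combined with the reference panel and decomposed jointly (not
projected); each variant is standardized by mean 2p̂ and scale √(2p̂(1−p̂)).
A random forest trained on the reference samples' top-20 principal-component
scores, with super-population labels as outcomes, assigns each cohort sample
its highest-vote class; the EUR subset is the set of samples whose
highest-vote class is EUR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "PrunedSet",
    "PcaModel",
    "vif_to_r2",
    "af_filter",
    "ld_prune",
    "joint_pca",
    "classify_ancestry",
]

DEFAULT_WINDOW = 50
DEFAULT_STEP = 5
DEFAULT_VIF = 1.5
DEFAULT_N_PCS = 20
DEFAULT_RF_SEED = 1914
DEFAULT_RF_TREES = 500


def vif_to_r2(vif: float) -> float:
    """The r² implied by a variance-inflation-factor threshold: 1 − 1/VIF."""
    return 1.0 - 1.0 / vif


@dataclass
class PrunedSet:
    kept_indices: np.ndarray
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    vif_threshold: float = DEFAULT_VIF


@dataclass
class PcaModel:
    """Joint decomposition: loadings, per-sample scores, standardization."""

    scores_cohort: np.ndarray  # n_cohort × k
    scores_ref: np.ndarray  # n_ref × k
    loadings: np.ndarray  # k × m (on the kept variant set)
    means: np.ndarray  # 2·p̂ per kept variant
    scales: np.ndarray  # √(2p̂(1−p̂)) per kept variant
    kept: np.ndarray  # indices of variants kept (non-monomorphic)
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))


def af_filter(G: np.ndarray, min_af: float = 0.1) -> np.ndarray:
    """Indices of variants whose alt-allele frequency is ≥ min_af.

    The retention rule is on the alternate-allele frequency as such (not the
    folded minor-allele frequency).
    """
    with np.errstate(invalid="ignore"):
        af = np.nanmean(np.asarray(G, float), axis=0) / 2.0
    return np.where(af >= min_af)[0]


def _window_vifs(Gw: np.ndarray) -> np.ndarray:
    """VIF per column of a centered window matrix; inf for columns perfectly
    predicted by the others (or duplicated)."""
    X = Gw - Gw.mean(axis=0)
    sd = X.std(axis=0)
    live = sd > 0
    vif = np.ones(Gw.shape[1])
    if live.sum() < 2:
        return vif
    Xl = X[:, live] / sd[live]
    R = (Xl.T @ Xl) / Xl.shape[0]
    # guard against numerically singular correlation matrices
    try:
        inv = np.linalg.inv(R)
        diag = np.diag(inv)
        if np.any(diag < 1 - 1e-6):
            raise np.linalg.LinAlgError
        vif[live] = np.maximum(diag, 1.0)
    except np.linalg.LinAlgError:
        n = R.shape[0]
        out = np.empty(n)
        for k in range(n):
            r2 = _r2_against_others(Xl, k)
            out[k] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        vif[live] = out
    return vif


def _r2_against_others(X: np.ndarray, k: int) -> float:
    y = X[:, k]
    others = np.delete(X, k, axis=1)
    beta, *_ = np.linalg.lstsq(others, y, rcond=None)
    resid = y - others @ beta
    tot = float(y @ y)
    if tot == 0:
        return 0.0
    return max(0.0, 1.0 - float(resid @ resid) / tot)


def ld_prune(
    G: np.ndarray,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    vif_threshold: float = DEFAULT_VIF,
) -> PrunedSet:
    """Greedy sliding-window VIF pruning of a samples × variants matrix.

    Variants must already be position-sorted.  Within each window the variant
    with the largest VIF is removed (ties and exact duplicates resolved toward
    the later position) until all VIF ≤ threshold; windows advance by ``step``
    and the kept set is the union of survivors.  Deterministic for a given
    input order.
    """
    G = np.asarray(G, float)
    m = G.shape[1]
    removed = np.zeros(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, m)
        live = [j for j in range(start, stop) if not removed[j]]
        while len(live) >= 2:
            vifs = _window_vifs(G[:, live])
            worst = np.max(vifs)
            if worst <= vif_threshold:
                break
            # later position wins the tie-break for removal
            worst_local = max(k for k in range(len(live)) if vifs[k] == worst)
            removed[live[worst_local]] = True
            live.pop(worst_local)
        if stop >= m:
            break
        start += step
    return PrunedSet(np.where(~removed)[0], window, step, vif_threshold)


def joint_pca(
    cohort: np.ndarray,
    reference: np.ndarray,
    n_components: int = DEFAULT_N_PCS,
) -> PcaModel:
    """Joint PCA of cohort and reference genotypes on a shared variant set.

    Both matrices are samples × variants with matching columns.  Monomorphic
    variants after combination are dropped (logged).  Missing genotypes are
    mean-imputed before standardization.
    """
    C = np.asarray(cohort, float)
    R = np.asarray(reference, float)
    if C.shape[1] != R.shape[1]:
        raise ValueError("cohort and reference must share the variant set")
    X = np.vstack([C, R])
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, col_mean[None, :], X)
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("joint_pca: dropped %d monomorphic variants", n_dropped)
    X = X[:, keep]
    p = p[keep]
    means = 2.0 * p
    scales = np.sqrt(2.0 * p * (1.0 - p))
    Z = (X - means[None, :]) / scales[None, :]
    k = min(n_components, min(Z.shape) - 1, Z.shape[1])
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    evr = (S**2) / float((S**2).sum())
    return PcaModel(
        scores_cohort=scores[: C.shape[0]],
        scores_ref=scores[C.shape[0]:],
        loadings=Vt[:k],
        means=means,
        scales=scales,
        kept=np.where(keep)[0],
        explained_variance_ratio=evr[:k],
    )


def classify_ancestry(
    ref_scores: np.ndarray,
    ref_labels: np.ndarray,
    cohort_scores: np.ndarray,
    n_features: int = DEFAULT_N_PCS,
    n_trees: int = DEFAULT_RF_TREES,
    seed: int = DEFAULT_RF_SEED,
    abstain_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-forest vote classification of cohort samples.

    Trains on the reference samples' PC scores with super-population labels
    as outcomes and assigns each cohort sample its highest-vote class,
    returning (labels, vote fractions).  With ``abstain_threshold`` set,
    samples whose top vote fraction falls below it are labelled
    ``"unassigned"`` (off by default: the rule is simply highest vote).
    """
    ref_labels = np.asarray(ref_labels)
    if len(np.unique(ref_labels)) < 2:
        raise ValueError("need at least 2 reference classes")
    avail = min(n_features, ref_scores.shape[1], cohort_scores.shape[1])
    if avail < n_features:
        warnings.warn(
            f"only {avail} PCs available (< {n_features}); using {avail}",
            stacklevel=2,
        )
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(ref_scores[:, :avail], ref_labels)
    proba = rf.predict_proba(cohort_scores[:, :avail])
    top = np.argmax(proba, axis=1)
    labels = rf.classes_[top]
    votes = proba[np.arange(len(top)), top]
    if abstain_threshold is not None:
        labels = np.where(votes >= abstain_threshold, labels, "unassigned")
    return labels, votes
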