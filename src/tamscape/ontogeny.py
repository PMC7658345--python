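"""TAM ontogeny: bone-marrow-derived vs microglia-derived scoring.

Each cell gets two meta-gene scores — one for a BMDM marker signature, one
for a microglia signature.  Regional separability is quantified per
activation state by a radial-kernel SVM on the two scores (hyperparameters
tuned with 10-fold CV on a 70% training split, ROC/AUC on the held-out 30%),
and AUC differences between states are compared with DeLong's paired test.
Bulk samples from the five Ivy anatomic structures are mapped to
core/periphery and scored the same way for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .ingest import NormMatrix
from .scores import GeneSignature, metagene_score

IVY_REGION_MAP = {
    "leading edge": "periphery",
    "infiltrating tumour": "periphery",
    "cellular tumour": "core",
    "microvascular proliferation": "core",
    "pseudopalisading cells": "core",
}


@dataclass
class OntogenyScores:
    bmdm_score: np.ndarray
    mg_score: np.ndarray
    cell_ids: np.ndarray


@dataclass
class RocResult:
    auc: float
    curve: np.ndarray  # (n, 2) array of (fpr, tpr) from (0,0) to (1,1)
    scores: np.ndarray  # decision values for the evaluated cases
    truth: np.ndarray  # boolean, True = positive class


def ontogeny_scores(m: NormMatrix, bmdm_sig: GeneSignature, mg_sig: GeneSignature) -> OntogenyScores:
    return OntogenyScores(
        metagene_score(m, bmdm_sig).values,
        metagene_score(m, mg_sig).values,
        m.cell_ids,
    )


def _roc_from_scores(scores: np.ndarray, truth: np.ndarray) -> RocResult:
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    return RocResult(float(_trapezoid_auc(fpr, tpr)), np.column_stack([fpr, tpr]),
                     np.asarray(scores, float), truth.astype(bool))


def region_separability(
    scores: OntogenyScores,
    regions,
    states,
    train_frac: float = 0.7,
    folds: int = 10,
    seed: int = 0,
    cost_grid=(0.1, 1.0, 10.0),
    gamma_grid=(0.1, 1.0, 10.0),
    min_cells_per_region: int = 20,
) -> dict:
    """Per-activation-state ROC of region prediction from (bmdm, mg) scores.

    For each state, a radial-kernel SVM is fit on the two ontogeny scores
    with region as the target; cost and kernel width are tuned by
    ``folds``-fold CV on a stratified ``train_frac`` split and the ROC/AUC
    is computed from decision values on the remaining cells.  States with
    fewer than ``min_cells_per_region`` cells in either region are skipped
    with a warning.  "core" is the positive class.
    """
    regions = np.asarray(regions, dtype=object)
    states = np.asarray(states, dtype=object)
    X_all = np.column_stack([scores.bmdm_score, scores.mg_score])
    out: dict = {}
    for s in pd.unique(states):
        idx = states == s
        y = (regions[idx] == "core").astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"state {s!r} has a single region; skipped")
            continue
        if min(np.bincount(y)) < min_cells_per_region:
            warnings.warn(f"state {s!r} has < {min_cells_per_region} cells in a region; skipped")
            continue
        X = X_all[idx]
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=seed
        )
        cv = StratifiedKFold(n_splits=min(folds, int(np.bincount(y_tr).min())),
                             shuffle=True, random_state=seed)
        grid = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(cost_grid), "gamma": list(gamma_grid)},
            cv=cv,
            scoring="roc_auc",
        )
        grid.fit(X_tr, y_tr)
        dec = grid.best_estimator_.decision_function(X_te)
        out[s] = _roc_from_scores(dec, y_te.astype(bool))
    return out


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, cmp.mean()


def delong_test(r1: RocResult, r2: RocResult) -> float:
    """DeLong's two-sided test for equality of two correlated AUCs.

    Both ROC results must come from the same cases (identical truth
    vectors); the covariance of the paired AUC estimates is computed from
    the structural components.
    """
    t1, t2 = np.asarray(r1.truth, bool), np.asarray(r2.truth, bool)
    if t1.shape != t2.shape or not np.array_equal(t1, t2):
        raise ValueError("DeLong comparison requires identical case sets")
    if t1.all() or (~t1).all():
        raise ValueError("degenerate truth: need both positive and negative cases")
    v10_1, v01_1, a1 = _delong_components(np.asarray(r1.scores, float), t1)
    v10_2, v01_2, a2 = _delong_components(np.asarray(r2.scores, float), t1)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 1.0
    z = (a1 - a2) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def map_ivy_regions(labels) -> np.ndarray:
    """Map the five Ivy anatomic structures to core/periphery (case-insensitive)."""
    out = []
    for lab in np.asarray(labels, dtype=object):
        key = str(lab).strip().lower()
        key = key.replace("tumor", "tumour")
        if key.startswith("pseudopalisading"):
            key = "pseudopalisading cells"
        if key not in IVY_REGION_MAP:
            raise ValueError(
                f"unknown anatomic structure {lab!r}; accepted: {sorted(IVY_REGION_MAP)}"
            )
        out.append(IVY_REGION_MAP[key])
    return np.asarray(out, dtype=object)


def normalize_bulk(bulk: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) per sample; genes with zero counts across all samples dropped."""
    bulk = bulk.loc[bulk.sum(axis=1) > 0]
    cpm = bulk / bulk.sum(axis=0) * 1e6
    return np.log2(cpm + 1)


def bulk_validation(
    bulk: pd.DataFrame,
    bmdm_sig: GeneSignature,
    mg_sig: GeneSignature,
    structure_labels,
    normalized: bool = False,
) -> tuple:
    """Meta-gene ontogeny scores per bulk sample and region ROC.

    ``bulk`` is a genes x samples table of counts (or already-normalized
    values with ``normalized=True``); ``structure_labels`` uses the five Ivy
    names and is mapped to core/periphery.  The score ranked is
    bmdm - microglia; "core" is the positive class.
    """
    vals = bulk if normalized else normalize_bulk(bulk)
    regions = map_ivy_regions(structure_labels)
    nm = NormMatrix(
        vals.values, vals.index.values,
        pd.DataFrame({"region": regions}, index=vals.columns), ["lognorm"], 1e6,
    )
    bscore = metagene_score(nm, bmdm_sig).values
    mscore = metagene_score(nm, mg_sig).values
    truth = regions == "core"
    if truth.all() or (~truth).all():
        raise ValueError("need bulk samples from both regions")
    if truth.sum() == 1 or (~truth).sum() == 1:
        warnings.warn("a region has a single bulk sample; AUC is degenerate")
    roc = _roc_from_scores(bscore - mscore, truth)
    table = pd.DataFrame(
        {"bmdm_score": bscore, "mg_score": mscore, "region": regions},
        index=vals.columns,
    )
    return table, roc
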