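"""The low-luminal discriminant mini-classifier.

A compact linear discriminant model that flags LumE-low tumours directly from
a handful of gene expression values, without computing enrichment scores.
Training mirrors how such a panel is derived across heterogeneous cohorts:

1. label training samples LumE_low / non_LumE_low by luminal-score quartile;
2. restrict to genes measured in every dataset the model must serve;
3. drop the metagenes' own members (the classifier should generalise beyond
   the signature that defined the labels);
4. screen candidates by signed fold change (|sFC| > 1.25 by default);
5. forward stepwise selection of a fixed number of genes (10 by default),
   minimising Wilks' lambda at each step;
6. fit a two-class linear discriminant with pooled within-class covariance.

Coefficient signs follow the convention that a positive coefficient marks a
gene overexpressed in non-LumE_low samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .phenotype import BINARY_LOW, BINARY_NONLOW, quartile_stratify
from .ssgsea import ScoreMatrix

logger = logging.getLogger(__name__)

#: the published 10-gene discriminant panel (scoring-only convenience fixture)
PUBLISHED_TEN_GENES = [
    "AMACR", "ANXA3", "IDH1", "KLK3", "SLC13A3",
    "C3", "COL4A1", "CYP7A1", "MORF4L2", "RRM1",
]

RIDGE_CONDITION_LIMIT = 1e8


@dataclass
class DiscriminantModel:
    genes: list[str]  # selection order
    coefficients: list[float]
    threshold: float
    priors: tuple[float, float]  # (pi_low, pi_nonlow)
    training_accuracy: float
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["priors"] = list(self.priors)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["priors"] = tuple(payload["priors"])
        return cls(**payload)


@dataclass
class ClassifierReport:
    tp: int  # LumE_low called LumE_low
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def percent_correct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n


def common_genes(datasets: list[ExpressionMatrix]) -> list[str]:
    """Sorted intersection of the datasets' gene universes."""
    if not datasets:
        raise ValueError("need at least one dataset")
    universe = set(datasets[0].gene_ids)
    for d in datasets[1:]:
        universe &= set(d.gene_ids)
    if not universe:
        raise ValueError("datasets share no genes")
    return sorted(universe)


def signed_fold_change(mean_nonlow: np.ndarray, mean_low: np.ndarray) -> np.ndarray:
    """Signed ratio: r = nonlow/low if >= 1 else -low/nonlow."""
    r = mean_nonlow / mean_low
    return np.where(r >= 1, r, -1.0 / r)


def fold_change_filter(
    expr: ExpressionMatrix,
    labels: pd.Series,
    threshold: float = 1.25,
) -> list[str]:
    """Genes whose signed linear-scale fold change strictly exceeds the cut.

    Declared-log2 input is exponentiated first.  Genes with a non-positive
    group mean have no defined ratio and are dropped with a warning.
    """
    linear = expr.to_linear()
    labels = labels.reindex(linear.sample_ids)
    low_mask = (labels == BINARY_LOW).to_numpy()
    nonlow_mask = (labels == BINARY_NONLOW).to_numpy()
    if low_mask.sum() == 0 or nonlow_mask.sum() == 0:
        raise ValueError("both label groups must be non-empty")
    values = linear.values
    mean_low = values[:, low_mask].mean(axis=1)
    mean_nonlow = values[:, nonlow_mask].mean(axis=1)
    ok = (mean_low > 0) & (mean_nonlow > 0)
    if (~ok).any():
        logger.warning(
            "%d gene(s) dropped from fold-change screen (non-positive group mean)",
            int((~ok).sum()),
        )
    sfc = np.full(len(ok), np.nan)
    sfc[ok] = signed_fold_change(mean_nonlow[ok], mean_low[ok])
    keep = ok & (np.abs(sfc) > threshold)
    return [g for g, k in zip(linear.gene_ids, keep) if k]


def _class_matrices(expr: ExpressionMatrix, labels: pd.Series, genes: list[str]):
    labels = labels.reindex(expr.sample_ids)
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    x = expr.data.loc[genes].T.to_numpy(dtype=float)  # samples x genes
    y_low = (labels == BINARY_LOW).to_numpy()
    y_nonlow = (labels == BINARY_NONLOW).to_numpy()
    if not (y_low | y_nonlow).all():
        bad = labels[~(y_low | y_nonlow)].index.tolist()
        raise ValueError(f"samples with unknown binary label: {bad}")
    return x, y_low, y_nonlow


def _pooled_covariance(x: np.ndarray, y_low: np.ndarray, y_nonlow: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    xl, xn = x[y_low], x[y_nonlow]
    dl = xl - xl.mean(axis=0)
    dn = xn - xn.mean(axis=0)
    return (dl.T @ dl + dn.T @ dn) / (n - 2)


def lda_fit(
    expr: ExpressionMatrix,
    labels: pd.Series,
    genes: list[str],
    priors: tuple[float, float] | None = None,
) -> DiscriminantModel:
    """Two-class linear discriminant on the given genes.

    ``w = S_pooled^-1 (mu_nonlow - mu_low)``; a sample is called non-low when
    ``w.x > threshold`` with ``threshold = w.(mu_low + mu_nonlow)/2 +
    log(pi_low / pi_nonlow)``.  ``priors`` defaults to the training class
    frequencies.  When S_pooled is near-singular (condition number beyond
    1e8) a ridge ``lambda I`` with ``lambda = 1e-6 tr(S)/p`` is added.
    """
    x, y_low, y_nonlow = _class_matrices(expr, labels, genes)
    n_low, n_nonlow = int(y_low.sum()), int(y_nonlow.sum())
    if n_low < 2 or n_nonlow < 2:
        raise ValueError(f"need >=2 samples per class, got {n_low} low / {n_nonlow} non-low")
    if priors is None:
        priors = (n_low / x.shape[0], n_nonlow / x.shape[0])
    mu_low = x[y_low].mean(axis=0)
    mu_nonlow = x[y_nonlow].mean(axis=0)
    s = _pooled_covariance(x, y_low, y_nonlow)
    ridge = 0.0
    if np.linalg.cond(s) > RIDGE_CONDITION_LIMIT:
        ridge = 1e-6 * np.trace(s) / s.shape[0]
        if ridge == 0:
            ridge = 1e-6
        s = s + ridge * np.eye(s.shape[0])
        logger.warning("near-singular pooled covariance; ridge %.3g applied", ridge)
    w = np.linalg.solve(s, mu_nonlow - mu_low)
    threshold = float(w @ (mu_low + mu_nonlow) / 2 + np.log(priors[0] / priors[1]))
    model = DiscriminantModel(
        genes=list(genes),
        coefficients=[float(c) for c in w],
        threshold=threshold,
        priors=(float(priors[0]), float(priors[1])),
        training_accuracy=np.nan,
        params={"ridge": ridge},
    )
    preds = predict(model, expr)
    correct = (preds["label"].reindex(labels.index) == labels).mean()
    model.training_accuracy = float(100.0 * correct)
    return model


def wilks_lambda(x: np.ndarray, y_low: np.ndarray, y_nonlow: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for a two-group feature matrix."""
    xl, xn = x[y_low], x[y_nonlow]
    dl = xl - xl.mean(axis=0)
    dn = xn - xn.mean(axis=0)
    w_scatter = dl.T @ dl + dn.T @ dn
    dt = x - x.mean(axis=0)
    t_scatter = dt.T @ dt
    sign_t, logdet_t = np.linalg.slogdet(t_scatter)
    sign_w, logdet_w = np.linalg.slogdet(w_scatter)
    if sign_t <= 0:  # total scatter singular: feature set is degenerate
        return 1.0
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def forward_stepwise_select(
    expr: ExpressionMatrix,
    labels: pd.Series,
    candidates: list[str],
    n_features: int = 10,
) -> list[str]:
    """Greedy forward selection minimising Wilks' lambda at each step.

    The number of features is fixed (no p-to-enter stopping rule); ties are
    broken by gene id ascending.
    """
    if n_features > len(candidates):
        raise ValueError(
            f"n_features={n_features} exceeds the {len(candidates)} candidate gene(s)"
        )
    x_all, y_low, y_nonlow = _class_matrices(expr, labels, list(candidates))
    col = {g: i for i, g in enumerate(candidates)}
    selected: list[str] = []
    remaining = sorted(candidates)  # id-ascending order makes ties deterministic
    while len(selected) < n_features:
        best_gene, best_lambda = None, np.inf
        idx_sel = [col[g] for g in selected]
        for g in remaining:
            lam = wilks_lambda(x_all[:, idx_sel + [col[g]]], y_low, y_nonlow)
            if lam < best_lambda:
                best_gene, best_lambda = g, lam
        selected.append(best_gene)
        remaining.remove(best_gene)
    return selected


def train_mini_classifier(
    train: ExpressionMatrix,
    scores: ScoreMatrix,
    luminal_set: str,
    other_datasets: list[ExpressionMatrix] | None = None,
    exclude_genes: set[str] | None = None,
    fc_threshold: float = 1.25,
    n_features: int = 10,
    priors: tuple[float, float] | None = None,
) -> tuple[DiscriminantModel, ClassifierReport, pd.Series]:
    """Full training pipeline: labels -> gene screen -> stepwise -> LDA.

    ``scores`` must contain the luminal set's z-log2 row for the training
    samples.  ``exclude_genes`` (typically the metagene panel members) are
    removed from the candidate pool.  The discriminant itself is fit on
    log2-scale expression; the fold-change screen uses the linear scale.
    Returns (model, training report, binary labels used).
    """
    strat = quartile_stratify(scores.layer("zlog2").loc[luminal_set, train.sample_ids])
    labels = strat.binary
    pool = common_genes([train, *(other_datasets or [])])
    if exclude_genes:
        before = len(pool)
        pool = [g for g in pool if g not in exclude_genes]
        logger.info("excluded %d metagene member(s) from candidates", before - len(pool))
    screened = fold_change_filter(train.subset_genes(pool), labels, threshold=fc_threshold)
    logger.info("fold-change screen: %d / %d candidate gene(s) retained", len(screened), len(pool))
    if n_features > len(screened):
        raise ValueError(
            f"n_features={n_features} exceeds the {len(screened)} gene(s) "
            "surviving the fold-change screen"
        )
    train_log = train.to_log2(pseudocount=1.0)
    genes = forward_stepwise_select(train_log, labels, screened, n_features=n_features)
    model = lda_fit(train_log, labels, genes, priors=priors)
    model.params.update({"fc_threshold": fc_threshold, "n_features": n_features,
                         "luminal_set": luminal_set, "expression_layer": "log2",
                         "training_hash": _input_hash(train)})
    report = evaluate(predict(model, train_log)["label"], labels)
    return model, report, labels


def predict(model: DiscriminantModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample discriminant score and binary label.

    Every model gene must be present (no imputation); the supported fallback
    for a missing gene is retraining without it.  If the model records that
    it was fit on the log2 layer, declared-linear input is converted.
    """
    if model.params.get("expression_layer") == "log2":
        expr = expr.to_log2(pseudocount=1.0)
    missing = [g for g in model.genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"model gene(s) missing from expression matrix: {missing}")
    x = expr.data.loc[model.genes].T.to_numpy(dtype=float)
    score = x @ np.asarray(model.coefficients)
    label = np.where(score > model.threshold, BINARY_NONLOW, BINARY_LOW)
    return pd.DataFrame({"score": score, "label": label}, index=expr.sample_ids)


def evaluate(predictions: pd.Series, truth: pd.Series) -> ClassifierReport:
    """Confusion counts with LumE_low as the positive class."""
    truth = truth.reindex(predictions.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some predicted samples")
    pred_pos = predictions == BINARY_LOW
    true_pos = truth == BINARY_LOW
    return ClassifierReport(
        tp=int((pred_pos & true_pos).sum()),
        tn=int((~pred_pos & ~true_pos).sum()),
        fp=int((pred_pos & ~true_pos).sum()),
        fn=int((~pred_pos & true_pos).sum()),
    )


def _input_hash(expr: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update(",".join(expr.gene_ids).encode())
    h.update(",".join(expr.sample_ids).encode())
    h.update(np.ascontiguousarray(expr.values).tobytes())
    return h.hexdigest()[:16]
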