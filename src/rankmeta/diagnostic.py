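"""Hub-gene diagnostic panel: train/validation split, logistic model, ROC.

The panel classifier is a multivariate logistic regression on the
expression of the hub genes, fitted by iteratively reweighted least
squares with a small L2 ridge (default 1e-4) so that the fit converges
even under complete separation — with a handful of genes and a few dozen
samples, separation is the rule rather than the exception.  Features are
standardized to the training mean and standard deviation and the learned
transform is stored with the model.  Evaluation reports the confusion
counts at a probability cutoff (default 0.5), accuracy, sensitivity,
specificity, and the ROC AUC in its Mann-Whitney form (ties count 1/2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ClassifierModel",
    "EvalReport",
    "split_train_validation",
    "fit_logistic",
    "evaluate",
    "roc_auc",
]

POSITIVE = "case"


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; a larger ridge usually fixes this."""


def split_train_validation(
    sample_ids,
    labels=None,
    train_frac: float = 0.6,
    seed: int = 1234,
    strict: bool = False,
) -> tuple[list[str], list[str]]:
    """Random (unstratified) split into train and validation sample ids.

    The training size is round-half-up of ``train_frac * N``.  If
    ``labels`` are given and a class is absent from either part, a warning
    is emitted (an error under ``strict``).  Deterministic under ``seed``.
    """
    ids = list(sample_ids)
    if not 0.0 <= train_frac <= 1.0:
        raise ValueError(f"train_frac must be in [0, 1], got {train_frac}")
    n = len(ids)
    n_train = int(np.floor(train_frac * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    valid = [ids[i] for i in sorted(perm[n_train:])]
    if not valid:
        warnings.warn("validation split is empty", stacklevel=2)
    if labels is not None:
        lab = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
        classes = set(lab.loc[ids])
        for part, name in ((train, "train"), (valid, "validation")):
            missing = classes - set(lab.loc[part]) if part else classes
            if missing:
                msg = f"class(es) {sorted(missing)} absent from the {name} split"
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)
    return train, valid


@dataclass
class ClassifierModel:
    """Fitted logistic panel model with its standardization transform."""

    panel: list[str]
    coef: np.ndarray        # one log-odds coefficient per panel gene
    intercept: float
    ridge: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.panel):
            raise ValueError("coefficient count must equal panel size")
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite coefficients")

    def decision(self, expression: pd.DataFrame) -> pd.Series:
        """Linear predictor (log-odds of case) per sample; genes x samples input."""
        x = expression.loc[self.panel].to_numpy().T
        z = (x - self.feature_mean) / self.feature_sd
        return pd.Series(z @ self.coef + self.intercept, index=expression.columns)

    def predict_proba(self, expression: pd.DataFrame) -> pd.Series:
        """P(case) per sample."""
        return self.decision(expression).map(special.expit)

    def to_json(self, path) -> None:
        payload = {
            "panel": self.panel,
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "ridge": float(self.ridge),
            "feature_mean": [float(v) for v in self.feature_mean],
            "feature_sd": [float(v) for v in self.feature_sd],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            panel=list(payload["panel"]),
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
            ridge=float(payload["ridge"]),
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_sd=np.asarray(payload["feature_sd"], dtype=float),
        )


def fit_logistic(
    expression: pd.DataFrame,
    labels,
    ridge: float = 1e-4,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ClassifierModel:
    """Ridge-stabilized maximum-likelihood logistic regression (IRLS).

    ``expression`` is panel genes x training samples; ``labels`` maps each
    sample to 'case' or 'control'.  The intercept is unpenalized.  Raises
    :class:`ConvergenceError` if IRLS does not settle within ``max_iter``.
    """
    lab = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    lab = lab.loc[expression.columns]
    classes = set(lab)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes in training labels, got {sorted(classes)}")
    y = (lab == POSITIVE).to_numpy(dtype=float)

    x = expression.to_numpy().T  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    n, p = z.shape
    design = np.column_stack([np.ones(n), z])
    penalty = np.diag([0.0] + [ridge] * p)

    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = design @ beta
        prob = special.expit(eta)
        w = np.clip(prob * (1 - prob), 1e-10, None)
        # penalized Newton step on the log-likelihood
        grad = design.T @ (y - prob) - penalty @ beta
        hess = design.T @ (design * w[:, None]) + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                f"singular IRLS system; increase ridge (now {ridge})"
            ) from err
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations; increase ridge (now {ridge})"
        )

    return ClassifierModel(
        panel=list(expression.index),
        coef=beta[1:],
        intercept=float(beta[0]),
        ridge=ridge,
        feature_mean=mu,
        feature_sd=sd,
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form (ties count 1/2)."""
    s = np.asarray(list(scores), dtype=float)
    lab = np.asarray(list(labels))
    pos = s[lab == POSITIVE]
    neg = s[lab != POSITIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


@dataclass
class EvalReport:
    """Confusion counts and summary metrics on a validation set."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float

    def to_tsv(self, path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


def evaluate(
    model: ClassifierModel,
    expression: pd.DataFrame,
    labels,
    cutoff: float = 0.5,
) -> EvalReport:
    """Confusion counts at ``cutoff`` plus accuracy/sensitivity/specificity/AUC.

    Positives are cases.  With a single-class validation set the undefined
    rate (and the AUC) is reported as NaN with a warning.
    """
    if expression.shape[1] == 0:
        raise ValueError("validation set is empty")
    lab = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    lab = lab.loc[expression.columns]
    prob = model.predict_proba(expression)
    pred_pos = prob >= cutoff
    is_pos = (lab == POSITIVE).to_numpy()

    tp = int(np.sum(pred_pos & is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))

    accuracy = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    if (tp + fn) == 0 or (tn + fp) == 0:
        warnings.warn("single-class validation set: some rates are undefined", stacklevel=2)
        auc = float("nan")
    else:
        auc = roc_auc(prob, lab)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity, auc=auc,
    )
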