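"""Weighted log-enrichment regression (the count-based baseline).

cLE estimates are computed once per condition pair and used as regression
labels; each sequence's label is weighted by the inverse of twice its
asymptotic variance, ``w_i = 1/(2 sigma_i^2)``, so noisier labels pull less
on the fit. The multi-output generalization fits one regression output per
condition pair with the summed weighted squared-error loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import CountTable, compute_cle, compute_variance_weights
from .zoo import ModelConfig, SequenceModel, TrainConfig, build_model, train_model


@dataclass
class RegressionTrainingSet:
    """cLE labels and inverse-variance weights per modeled condition pair."""

    sequences: list
    labels: np.ndarray   # (M', n_pairs)
    weights: np.ndarray  # (M', n_pairs)
    pairs: list          # [(denominator, numerator), ...]
    pseudocount: float

    def __post_init__(self):
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if not (np.isfinite(self.labels).all() and np.isfinite(self.weights).all()):
            raise ValueError("labels and weights must be finite")
        if self.labels.shape != self.weights.shape:
            raise ValueError("labels and weights must have matching shapes")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")


def build_wler_training_set(table: CountTable, pairs=((0, 1),),
                            pseudocount: float = 1.0,
                            cap_weights: bool = False) -> RegressionTrainingSet:
    """Labels from cLE and weights from the asymptotic-variance formula."""
    labels, weights = [], []
    for denom, numer in pairs:
        est = compute_variance_weights(table, denominator=denom, numerator=numer,
                                       pseudocount=pseudocount,
                                       cap_weights=cap_weights)
        cle = compute_cle(table, denominator=denom, numerator=numer,
                          pseudocount=pseudocount)
        labels.append(cle.log_e)
        weights.append(est.weight)
    return RegressionTrainingSet(
        sequences=list(table.sequences),
        labels=np.column_stack(labels),
        weights=np.column_stack(weights),
        pairs=[tuple(p) for p in pairs],
        pseudocount=pseudocount,
    )


def wler_loss(predictions, labels, weights) -> float:
    """Weighted least-squares loss, summed over sequences and outputs."""
    f = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (np.isfinite(f).all() and np.isfinite(y).all() and np.isfinite(w).all()):
        raise ValueError("non-finite inputs to wler_loss")
    if f.shape != y.shape or y.shape != w.shape:
        raise ValueError("predictions, labels, weights must share a shape")
    return float(np.sum(w * (y - f) ** 2))


def fit_wler(training_set: RegressionTrainingSet,
             model_config: ModelConfig | None = None,
             train_config: TrainConfig | None = None, seed: int = 0,
             alphabet: str = "protein",
             normalize_weights: bool = True) -> SequenceModel:
    """Fit a regression model to the cLE labels under the shared recipe.

    Weights are normalized to mean 1 per pair (optimizer-scale stability
    only; the minimizer is unchanged). Batch losses are weight-normalized
    means so the recipe's learning rate is scale-free.
    """
    y = training_set.labels
    w = training_set.weights.copy()
    if normalize_weights:
        w /= w.mean(axis=0, keepdims=True)
    P = y.shape[1]
    if model_config is None:
        model_config = ModelConfig("linear-is", head="regression", n_outputs=P,
                                   seed=seed)
    if model_config.head != "regression" or model_config.n_outputs != P:
        raise ValueError(f"model_config must be a regression head with {P} outputs")
    seqs = training_set.sequences
    if model_config.family == "saturated":
        from .zoo import saturated_model
        model = saturated_model(seqs, "regression", P, model_config.seed)
    else:
        lengths = {len(s) for s in seqs}
        input_length = lengths.pop() if len(lengths) == 1 else None
        model = build_model(model_config, input_length=input_length,
                            alphabet=alphabet)

    def batch_loss_grad(out, rows):
        wi, yi = w[rows], y[rows]
        denom = wi.sum()
        resid = out - yi
        loss = float((wi * resid ** 2).sum() / denom)
        dout = 2.0 * wi * resid / denom
        return loss, denom, dout

    train_model(model, seqs, batch_loss_grad, train_config or TrainConfig(),
                seed=seed)
    return model
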