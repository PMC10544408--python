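"""Model-based enrichment: classifier-based density-ratio estimation.

A probabilistic classifier g is trained on raw reads to predict which
condition each read came from. For two conditions A (class 0) and B
(class 1), the density ratio between the library distributions is
estimated from the predicted class probabilities:

    d(x) = p^B(x) / p^A(x)  ~=  [g(x) / (1 - g(x))] * (N^A / N^B)

so ``log d`` is the population log-enrichment. With more than two
conditions the classifier is multi-class and any pair (or aggregate) of
conditions yields a log-density-ratio from the corresponding predicted
class probabilities.

The read-level logistic loss is equivalent to a grouped loss over unique
sequences weighted by read counts — sequences sequenced more often
contribute more, which is how MBE absorbs heteroscedastic sequencing noise
without an explicit weighting scheme. Under class imbalance each class's
term can be rescaled by ``max_j N^j / N^class`` so every condition has a
comparable impact on the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .counts import CountTable, ReadDataset, aggregate_reads
from .zoo import ModelConfig, SequenceModel, TrainConfig, build_model, train_model

PROB_EPS = 1e-7  # clamp for saturated predicted probabilities


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mbe_loss(logits, labels=None, counts=None, class_weighting: bool = False,
             class_totals=None) -> float:
    """The classification loss, in read-level or grouped-by-sequence form.

    1-D ``logits`` are binary scores ``g(x)`` (positive favors class 1/B):

    * with ``labels`` in {0,1} or {-1,+1}: the read-level logistic loss
      ``sum_i log(1 + exp(-y_i g_i))``;
    * with ``counts`` of shape (M', 2) (columns: class 0 = A, class 1 = B):
      the grouped form ``sum_i n_i^B log(1+exp(-g_i)) + n_i^A log(1+exp(g_i))``,
      which equals the read-level sum exactly.

    2-D ``logits`` (n, C) use the softmax generalization (categorical
    cross-entropy), again with integer ``labels`` or per-class ``counts``.

    ``class_weighting`` rescales class j's contribution by
    ``max_c N^c / N^j`` where the totals default to the column sums of
    ``counts`` (or may be passed via ``class_totals``).
    """
    logits = np.asarray(logits, dtype=float)
    if (labels is None) == (counts is None):
        raise ValueError("pass exactly one of labels / counts")
    if logits.ndim == 1:
        if counts is None:
            y = np.asarray(labels, dtype=float)
            bad = ~np.isin(y, (-1.0, 0.0, 1.0))
            if bad.any():
                raise ValueError(f"unknown binary label {y[bad][0]}")
            y = np.where(y == 0.0, -1.0, y)
            counts_m = np.zeros((len(y), 2))
            counts_m[y < 0, 0] = 1.0
            counts_m[y > 0, 1] = 1.0
        else:
            counts_m = np.asarray(counts, dtype=float)
            if counts_m.shape != (len(logits), 2):
                raise ValueError("binary grouped loss needs counts of shape (M', 2)")
        nA, nB = counts_m[:, 0], counts_m[:, 1]
        wA = wB = 1.0
        if class_weighting:
            NA, NB = (np.asarray(class_totals, dtype=float)
                      if class_totals is not None else counts_m.sum(axis=0))
            top = max(NA, NB)
            wA, wB = top / NA, top / NB
        return float(np.sum(wB * nB * np.logaddexp(0.0, -logits)
                            + wA * nA * np.logaddexp(0.0, logits)))
    # multi-class softmax path
    C = logits.shape[1]
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    if counts is None:
        y = np.asarray(labels)
        if ((y < 0) | (y >= C)).any():
            raise ValueError("label outside {0..k}")
        cnt = np.zeros_like(logits)
        cnt[np.arange(len(y)), y] = 1.0
    else:
        cnt = np.asarray(counts, dtype=float)
        if cnt.shape != logits.shape:
            raise ValueError("counts must match logits shape")
    w = np.ones(C)
    if class_weighting:
        totals = (np.asarray(class_totals, dtype=float)
                  if class_totals is not None else cnt.sum(axis=0))
        w = totals.max() / totals
    return float(-(w * cnt * logp).sum())


@dataclass
class DensityRatioModel:
    """A trained multi-class read classifier plus the class totals."""

    classifier: SequenceModel
    class_totals: np.ndarray
    class_weighting: bool

    @property
    def n_conditions(self) -> int:
        return self.classifier.config.n_outputs

    def predict_proba(self, seqs) -> np.ndarray:
        """Predicted class probabilities (n, k+1); rows sum to 1."""
        return _softmax(self.classifier.predict(seqs))

    def save(self, path: str):
        self.classifier.save(path, extra=dict(
            class_totals=[float(t) for t in self.class_totals],
            class_weighting=bool(self.class_weighting)))

    @classmethod
    def load(cls, path: str) -> "DensityRatioModel":
        model, extra = SequenceModel.load(path)
        return cls(model, np.asarray(extra["class_totals"]),
                   extra["class_weighting"])

    def predict_log_enrichment(self, seqs, numerator: int = 1,
                               denominator: int = 0,
                               prior_correction: bool = True) -> np.ndarray:
        """Vectorized :func:`log_density_ratio` over many sequences.

        The class-prior term log(N^den/N^num) corrects the probability
        ratio for unequal read depths. When the classifier was trained
        with class reweighting, its effective class priors are already
        balanced and the correction is identically zero.
        """
        p = _clamped(self.predict_proba(seqs))
        out = np.log(p[:, numerator]) - np.log(p[:, denominator])
        if prior_correction and not self.class_weighting:
            out = out + np.log(self.class_totals[denominator]
                               / self.class_totals[numerator])
        return out

    def predict_multiround(self, seqs, rounds=None) -> np.ndarray:
        """Mean of per-round pairwise LEs vs. the reference condition 0."""
        rounds = list(rounds) if rounds is not None else list(range(1, self.n_conditions))
        preds = [self.predict_log_enrichment(seqs, numerator=j) for j in rounds]
        return np.mean(preds, axis=0)


def _clamped(p: np.ndarray) -> np.ndarray:
    if (p <= PROB_EPS).any() or (p >= 1 - PROB_EPS).any():
        warnings.warn("saturated class probability clamped to eps=1e-7")
    return np.clip(p, PROB_EPS, 1 - PROB_EPS)


def fit_mbe(data, model_config: ModelConfig | None = None,
            train_config: TrainConfig | None = None,
            class_weighting: bool | None = None, seed: int = 0,
            alphabet: str | None = None) -> DensityRatioModel:
    """Train the MBE classifier on labeled reads (or a count table).

    Reads are grouped by unique sequence and the classifier is trained with
    the count-weighted grouped loss, which has exactly the same full-epoch
    gradient as read-level training. ``class_weighting=None`` turns the
    imbalance reweighting on automatically when class totals differ by more
    than 1%. Per-batch losses are normalized by the batch's (weighted) read
    count so the recipe's learning rate behaves like read-level mean-loss
    minibatching.
    """
    if isinstance(data, ReadDataset):
        table = aggregate_reads(data)
    elif isinstance(data, CountTable):
        table = data
    else:
        raise TypeError("data must be a ReadDataset or CountTable")
    C = table.n_conditions
    if C < 2 or (table.totals > 0).sum() < 2:
        raise ValueError("MBE needs reads from at least two conditions")
    totals = table.totals.astype(float)
    if class_weighting is None:
        class_weighting = bool(totals.max() > 1.01 * totals.min())
    class_w = totals.max() / totals if class_weighting else np.ones(C)

    alphabet = alphabet or table.alphabet
    if model_config is None:
        model_config = ModelConfig("fcn", hidden_units=100, head="classification",
                                   n_outputs=C, seed=seed)
    if model_config.head != "classification" or model_config.n_outputs != C:
        raise ValueError(
            f"model_config must have a classification head with {C} outputs")
    if model_config.family == "saturated":
        from .zoo import saturated_model
        model = saturated_model(table.sequences, "classification", C,
                                model_config.seed)
    else:
        lengths = {len(s) for s in table.sequences}
        input_length = lengths.pop() if len(lengths) == 1 else None
        model = build_model(model_config, input_length=input_length,
                            alphabet=alphabet)

    counts = table.counts.astype(float) * class_w  # per-row effective counts
    def batch_loss_grad(out, rows):
        a = counts[rows]
        denom = a.sum()
        p = _softmax(out)
        logp = np.log(np.clip(p, 1e-300, None))
        loss = -(a * logp).sum() / denom
        dout = (a.sum(axis=1, keepdims=True) * p - a) / denom
        return loss, denom, dout

    train_model(model, table.sequences, batch_loss_grad,
                train_config or TrainConfig(), seed=seed)
    return DensityRatioModel(model, table.totals.copy(), class_weighting)


def log_density_ratio(model: DensityRatioModel, x, numerator: int = 1,
                      denominator: int = 0, prior_correction: bool = True) -> float:
    """Log density ratio log[p^num(x)/p^den(x)] for one sequence.

    Returns ``log[p(l=num|x)/p(l=den|x)]`` plus, with ``prior_correction``,
    the class-prior term ``log(N^den/N^num)``.
    """
    if numerator == denominator:
        raise ValueError("numerator and denominator classes must differ")
    return float(model.predict_log_enrichment(
        [x], numerator=numerator, denominator=denominator,
        prior_correction=prior_correction)[0])


def log_density_ratio_aggregate(model: DensityRatioModel, x, numerator: int,
                                denominator_classes) -> float:
    """log of one class probability over a *sum* of other class probabilities."""
    S = sorted(set(int(j) for j in denominator_classes))
    if not S:
        raise ValueError("denominator class set is empty")
    if numerator in S:
        raise ValueError("numerator class cannot be in the denominator set")
    p = _clamped(model.predict_proba([x]))[0]
    return float(np.log(p[numerator]) - np.log(p[S].sum()))
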