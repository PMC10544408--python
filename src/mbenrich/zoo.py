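"""The shared architecture grid and training recipe.

Eleven architectures are available to both the regression (wLER) and
classification (MBE) heads:

* three linear models on ``is`` / ``neighbor`` / ``pairwise`` features,
* four two-hidden-layer fully-connected networks on IS features
  (100, 200, 500 or 1000 units per layer),
* four fully-convolutional networks on one-hot matrices (2, 4, 8 or 16
  window-5 / 100-filter residual conv blocks, skip connections summed into a
  global max pool) — the only family that accepts variable-length input.

The fixed training recipe: AMSGrad Adam, learning rate 1e-3, ten epochs, no
early stopping; Adam epsilon 1e-7 for linear/fully-connected models and 1e-4
with global-norm gradient clipping at 1 for the convolutional models.
Batches default to 1024 rows; variable-length inputs are bucketed by length
so no padding ever reaches a convolution.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .alphabets import resolve_alphabet
from .encoding import encode_batch, feature_dim
from .nnet import AMSGrad, Dense, ReLU, ResidualConvNet, Sequential

FCN_WIDTHS = (100, 200, 500, 1000)
CNN_DEPTHS = (2, 4, 8, 16)


@dataclass
class ModelConfig:
    """One point on the architecture grid.

    ``family`` is one of ``linear-is``, ``linear-neighbor``,
    ``linear-pairwise``, ``fcn`` (with ``hidden_units``), ``cnn`` (with
    ``conv_layers``), or ``saturated`` (indicator features; oracle use).
    """

    family: str
    hidden_units: int | None = None
    conv_layers: int | None = None
    head: str = "regression"
    n_outputs: int = 1
    seed: int = 0

    def __post_init__(self):
        legal = ("linear-is", "linear-neighbor", "linear-pairwise", "fcn", "cnn",
                 "saturated")
        if self.family not in legal:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "fcn" and self.hidden_units not in FCN_WIDTHS:
            raise ValueError(f"fcn hidden_units must be one of {FCN_WIDTHS}")
        if self.family == "cnn" and self.conv_layers not in CNN_DEPTHS:
            raise ValueError(f"cnn conv_layers must be one of {CNN_DEPTHS}")
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head == "classification" and self.n_outputs < 2:
            raise ValueError("classification head needs n_outputs >= 2")


def enumerate_architectures(head: str = "regression", n_outputs: int = 1,
                            seed: int = 0) -> list[ModelConfig]:
    """The eleven legal architecture configurations."""
    configs = [ModelConfig(f"linear-{s}", head=head, n_outputs=n_outputs, seed=seed)
               for s in ("is", "neighbor", "pairwise")]
    configs += [ModelConfig("fcn", hidden_units=h, head=head, n_outputs=n_outputs,
                            seed=seed) for h in FCN_WIDTHS]
    configs += [ModelConfig("cnn", conv_layers=d, head=head, n_outputs=n_outputs,
                            seed=seed) for d in CNN_DEPTHS]
    return configs


@dataclass
class TrainConfig:
    """The fixed optimization recipe; every field is overridable."""

    learning_rate: float = 1e-3
    epochs: int = 10
    epsilon: float | None = None  # None: 1e-7 linear/fcn, 1e-4 cnn
    gradient_clip: float | None = None  # None: no clip (linear/fcn), 1.0 cnn
    batch_size: int = 1024

    def resolved(self, family: str) -> "TrainConfig":
        eps = self.epsilon if self.epsilon is not None else (
            1e-4 if family == "cnn" else 1e-7)
        # gradient_clip: None = per-family default; 0 disables explicitly
        clip = self.gradient_clip
        if clip is None:
            clip = 1.0 if family == "cnn" else 0.0
        return TrainConfig(self.learning_rate, self.epochs, eps,
                           clip if clip > 0 else None, self.batch_size)


class SequenceModel:
    """An architecture bound to an alphabet, exposing sequence-level I/O."""

    def __init__(self, config: ModelConfig, net, scheme: str, alphabet: str,
                 input_length: int | None, indicator_index: dict | None = None):
        self.config = config
        self.net = net
        self.scheme = scheme
        self.alphabet = alphabet
        self.input_length = input_length
        self.indicator_index = indicator_index

    # -- encoding ---------------------------------------------------------
    def encode(self, seqs) -> np.ndarray:
        """Encode equal-length sequences into one design matrix/tensor."""
        seqs = list(seqs)
        if self.scheme == "indicator":
            X = np.zeros((len(seqs), len(self.indicator_index)), dtype=np.float32)
            for r, s in enumerate(seqs):
                try:
                    X[r, self.indicator_index[s]] = 1.0
                except KeyError:
                    raise KeyError(
                        f"sequence {s!r} not in the saturated model's support")
            return X
        if self.scheme == "onehot":
            A = len(resolve_alphabet(self.alphabet))
            X = encode_batch(seqs, "is", self.alphabet)
            return X.reshape(len(seqs), -1, A)
        if self.input_length is not None and len(seqs[0]) != self.input_length:
            raise ValueError(
                f"{self.config.family} model is fixed to length "
                f"{self.input_length}; got length {len(seqs[0])}")
        return encode_batch(seqs, self.scheme, self.alphabet)

    def length_groups(self, seqs):
        """Indices grouped by sequence length (trivial for fixed-length)."""
        groups: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            groups.setdefault(len(s), []).append(i)
        if len(groups) > 1 and self.config.family != "cnn":
            raise ValueError(
                f"{self.config.family} models require fixed-length input; "
                f"got lengths {sorted(groups)}")
        return groups

    # -- prediction -------------------------------------------------------
    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(X)

    def predict(self, seqs, batch_size: int = 4096) -> np.ndarray:
        """Model outputs (n, n_outputs) for a list of sequences."""
        seqs = list(seqs)
        out = np.zeros((len(seqs), self.config.n_outputs))
        for _, idx in sorted(self.length_groups(seqs).items()):
            for lo in range(0, len(idx), batch_size):
                chunk = idx[lo:lo + batch_size]
                X = self.encode([seqs[i] for i in chunk])
                out[chunk] = self.net.forward(X)
        return out

    # -- persistence ------------------------------------------------------
    def save(self, path: str, extra: dict | None = None):
        """Single-file checkpoint with the config (and any extras) embedded."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        meta = dict(config=asdict(self.config), scheme=self.scheme,
                    alphabet=self.alphabet, input_length=self.input_length,
                    indicator_seqs=(list(self.indicator_index)
                                    if self.indicator_index else None),
                    extra=extra or {})
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> tuple["SequenceModel", dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            config = ModelConfig(**meta["config"])
            if meta["indicator_seqs"] is not None:
                model = saturated_model(meta["indicator_seqs"], config.head,
                                        config.n_outputs, config.seed)
            else:
                model = build_model(config, input_length=meta["input_length"],
                                    alphabet=meta["alphabet"])
            for i, p in enumerate(model.net.params()):
                p.value[...] = z[f"p{i}"]
        return model, meta.get("extra", {})


def build_model(config: ModelConfig, input_length: int | None = None,
                alphabet: str = "protein") -> SequenceModel:
    """Instantiate an architecture for sequences of ``input_length`` residues.

    ``input_length=None`` declares variable-length input and is only legal
    for the convolutional family.
    """
    rng = np.random.default_rng(config.seed)
    A = len(resolve_alphabet(alphabet))
    if config.family == "cnn":
        net = ResidualConvNet(A, config.conv_layers, config.n_outputs, rng)
        return SequenceModel(config, net, "onehot", alphabet, None)
    if input_length is None:
        raise ValueError(f"{config.family} models need a fixed input_length")
    if config.family.startswith("linear-"):
        scheme = config.family.split("-", 1)[1]
        net = Sequential([Dense(feature_dim(scheme, input_length, A),
                                config.n_outputs, rng)])
        return SequenceModel(config, net, scheme, alphabet, input_length)
    if config.family == "fcn":
        h = config.hidden_units
        d = feature_dim("is", input_length, A)
        net = Sequential([Dense(d, h, rng, gain=np.sqrt(2.0)), ReLU(),
                          Dense(h, h, rng, gain=np.sqrt(2.0)), ReLU(),
                          Dense(h, config.n_outputs, rng)])
        return SequenceModel(config, net, "is", alphabet, input_length)
    raise ValueError(f"cannot build family {config.family!r} here")


def saturated_model(sequences, head: str = "regression", n_outputs: int = 1,
                    seed: int = 0) -> SequenceModel:
    """One free parameter per unique sequence: linear on indicator features.

    Its converged fit equals the closed-form minimizer of the loss, which
    makes it the oracle for both heads.
    """
    sequences = list(sequences)
    config = ModelConfig("saturated", head=head, n_outputs=n_outputs, seed=seed)
    rng = np.random.default_rng(seed)
    net = Sequential([Dense(len(sequences), n_outputs, rng)])
    index = {s: i for i, s in enumerate(sequences)}
    if len(index) != len(sequences):
        raise ValueError("saturated model requires unique sequences")
    return SequenceModel(config, net, "indicator", "n/a", None,
                         indicator_index=index)


def parameter_count(model: SequenceModel) -> int:
    return int(sum(p.value.size for p in model.net.params()))


def train_model(model: SequenceModel, seqs, batch_loss_grad, train_config=None,
                seed: int = 0) -> list[float]:
    """Run the fixed recipe; returns the per-epoch loss trace.

    ``batch_loss_grad(outputs, row_indices)`` must return
    ``(normalized_loss, weight, d_loss/d_outputs)`` where ``weight`` is the
    batch's share used to average epoch losses. Training order is a seeded
    shuffle each epoch; encoded inputs are cached per length bucket so the
    convolutional family never sees padding.
    """
    seqs = list(seqs)
    cfg = (train_config or TrainConfig()).resolved(model.config.family)
    opt = AMSGrad(model.net.params(), lr=cfg.learning_rate, eps=cfg.epsilon,
                  clip=cfg.gradient_clip)
    groups = sorted(model.length_groups(seqs).items())
    encoded = {L: model.encode([seqs[i] for i in idx]) for L, idx in groups}
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(cfg.epochs):
        batches = []
        for L, idx in groups:
            perm = rng.permutation(len(idx))
            for lo in range(0, len(idx), cfg.batch_size):
                batches.append((L, perm[lo:lo + cfg.batch_size]))
        rng.shuffle(batches)
        tot_loss = tot_w = 0.0
        group_index = dict(groups)
        for L, rows in batches:
            global_rows = [group_index[L][r] for r in rows]
            X = encoded[L][rows]
            out = model.net.forward(X)
            loss, w, dout = batch_loss_grad(out, np.asarray(global_rows))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss ({loss})")
            opt.zero_grad()
            model.net.backward(dout)
            opt.step()
            tot_loss += loss * w
            tot_w += w
        trace.append(tot_loss / max(tot_w, 1e-300))
    return trace
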