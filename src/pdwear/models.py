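"""Symptom-detection classifiers: random forest on features, CNN on raw clips.

The random forest (50 trees, out-of-bag error exposed, inverse-frequency
class weights) consumes the 56-feature representation; the CNN consumes
raw filtered clips (312 samples x 6 channels at the defaults) and learns
its representation end to end. Both output the probability that a clip
shows the symptom, are deterministic given their seed, and round-trip
through disk with a JSON sidecar describing spec, seed and input schema.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._nn import NumpyCNN

DEFAULT_INPUT_SAMPLES = 312
DEFAULT_INPUT_CHANNELS = 6


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of both classifier families.

    The CNN fields reproduce the reference architecture when left at their
    defaults (``paper_arch``): two conv blocks with kernels 32/16 samples,
    16/32 ReLU filters and max-pools of 4/6, then two 32-unit dense layers
    with dropout 0.5 and a 2-way softmax.
    """

    family: str = "random_forest"
    n_trees: int = 50
    kernel_sizes: tuple = (32, 16)
    filters: tuple = (16, 32)
    pool_sizes: tuple = (4, 6)
    dense: tuple = (32, 32)
    dropout: float = 0.5
    n_classes: int = 2
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (len(self.kernel_sizes) == len(self.filters) == len(self.pool_sizes)):
            raise ValueError("conv layer lists must have equal length")

    @property
    def paper_arch(self) -> bool:
        return (tuple(self.kernel_sizes), tuple(self.filters),
                tuple(self.pool_sizes), tuple(self.dense),
                self.dropout, self.n_classes) == ((32, 16), (16, 32), (4, 6),
                                                  (32, 32), 0.5, 2)


def _check_two_classes(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class; "
                         "a symptom detector needs both positive and negative clips")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")


class RandomForestModel:
    """Fitted RF wrapper: symptom probability out, OOB error exposed."""

    def __init__(self, clf: RandomForestClassifier, spec: ClassifierSpec):
        self.clf = clf
        self.spec = spec

    @property
    def n_trees(self) -> int:
        return len(self.clf.estimators_)

    @property
    def oob_error(self) -> float:
        return float(1.0 - self.clf.oob_score_)

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.clf.n_features_in_:
            raise ValueError(f"expected {self.clf.n_features_in_} features, "
                             f"got {X.shape[1]}")
        return self.clf.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.clf, path)
        sidecar = {"family": "random_forest", "spec": asdict(self.spec),
                   "n_features": int(self.clf.n_features_in_)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "RandomForestModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = ClassifierSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in sidecar["spec"].items()})
        return cls(joblib.load(path), spec)


def train_random_forest(X, labels, spec: ClassifierSpec | None = None
                        ) -> RandomForestModel:
    """Fit the feature-based detector: ``spec.n_trees`` trees (default 50,
    the value tuned by the out-of-bag error method), sqrt(p) features per
    split, balanced class weights, bootstrap OOB error estimate."""
    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees, max_features="sqrt", oob_score=True,
        class_weight="balanced" if spec.class_weighting else None,
        random_state=spec.seed, n_jobs=1, bootstrap=True)
    with warnings.catch_warnings():
        # at 50 trees a few samples may lack OOB predictions; the estimate
        # over the rest is still what we want
        warnings.filterwarnings("ignore", message=".*OOB.*")
        clf.fit(X, y)
    return RandomForestModel(clf, spec)


# ------------------------------------------------------------------ CNN side

@dataclass
class CNNArchitecture:
    """Layer-by-layer description with closed-form parameter counts."""

    layers: list = field(default_factory=list)
    total_params: int = 0
    input_samples: int = 0
    input_channels: int = 0

    @property
    def kernel_sizes(self):
        return [l["kernel"] for l in self.layers if l["type"] == "conv"]

    @property
    def filter_counts(self):
        return [l["filters"] for l in self.layers if l["type"] == "conv"]

    @property
    def pool_sizes(self):
        return [l["pool"] for l in self.layers if l["type"] == "maxpool"]

    @property
    def dense_widths(self):
        return [l["units"] for l in self.layers if l["type"] == "dense"]


def build_cnn(spec: ClassifierSpec | None = None,
              input_samples: int = DEFAULT_INPUT_SAMPLES,
              input_channels: int = DEFAULT_INPUT_CHANNELS) -> CNNArchitecture:
    """Describe the CNN for a given input shape and count its parameters.

    'same'-padded stride-1 convolutions keep the sequence length; each
    max-pool floors it by its pool size. Parameter counts are the usual
    closed forms (conv: K*Cin*Cout + Cout; dense: in*out + out).
    """
    spec = spec or ClassifierSpec(family="cnn")
    arch = CNNArchitecture(input_samples=input_samples,
                           input_channels=input_channels)
    L, C = input_samples, input_channels
    for k, f, p in zip(spec.kernel_sizes, spec.filters, spec.pool_sizes):
        arch.layers.append({"type": "conv", "kernel": int(k), "filters": int(f),
                            "activation": "relu", "out_length": L,
                            "params": int(k * C * f + f)})
        L, C = L // p, f
        if L < 1:
            raise ValueError("pooled sequence length collapsed below 1")
        arch.layers.append({"type": "maxpool", "pool": int(p),
                            "out_length": L, "params": 0})
    dim = L * C
    arch.layers.append({"type": "flatten", "out_dim": dim, "params": 0})
    for d in spec.dense:
        arch.layers.append({"type": "dense", "units": int(d), "activation": "relu",
                            "dropout": spec.dropout, "params": int(dim * d + d)})
        dim = d
    arch.layers.append({"type": "softmax", "units": spec.n_classes,
                        "params": int(dim * spec.n_classes + spec.n_classes)})
    arch.total_params = int(sum(l["params"] for l in arch.layers))
    return arch


class CNNModel:
    """Fitted CNN wrapper around :class:`~pdwear._nn.NumpyCNN`."""

    def __init__(self, net: NumpyCNN, spec: ClassifierSpec):
        self.net = net
        self.spec = spec

    @property
    def architecture(self) -> CNNArchitecture:
        return build_cnn(self.spec, self.net.input_samples, self.net.input_channels)

    def predict_proba(self, X) -> np.ndarray:
        return self.net.predict_proba(np.asarray(X, dtype=float))

    def predict_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        path = Path(path).with_suffix(".npz")
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.net.state_dict())
        sidecar = {"family": "cnn", "spec": asdict(self.spec),
                   "input_samples": self.net.input_samples,
                   "input_channels": self.net.input_channels}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "CNNModel":
        path = Path(path).with_suffix(".npz")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = ClassifierSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in sidecar["spec"].items()})
        net = NumpyCNN(sidecar["input_samples"], sidecar["input_channels"],
                       conv=list(zip(spec.kernel_sizes, spec.filters,
                                     spec.pool_sizes)),
                       dense=spec.dense, n_classes=spec.n_classes,
                       dropout=spec.dropout, seed=spec.seed)
        with np.load(path) as st:
            net.load_state_dict({k: st[k] for k in st.files})
        return cls(net, spec)


def train_cnn(clips, labels, spec: ClassifierSpec | None = None) -> CNNModel:
    """Fit the end-to-end detector on raw filtered clips (N, samples,
    channels). Class weights are inverse class frequencies when
    ``spec.class_weighting``; training is deterministic given ``spec.seed``."""
    spec = spec or ClassifierSpec(family="cnn")
    X = np.asarray(clips, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 3:
        raise ValueError(f"expected (N, samples, channels) clips, got {X.shape}")
    _check_two_classes(y)
    net = NumpyCNN(X.shape[1], X.shape[2],
                   conv=list(zip(spec.kernel_sizes, spec.filters, spec.pool_sizes)),
                   dense=spec.dense, n_classes=spec.n_classes,
                   dropout=spec.dropout, seed=spec.seed)
    cw = None
    if spec.class_weighting:
        counts = np.bincount(y, minlength=spec.n_classes)
        cw = {c: y.size / (spec.n_classes * counts[c])
              for c in range(spec.n_classes) if counts[c] > 0}
    net.fit(X, y, epochs=spec.epochs, batch_size=spec.batch_size,
            learning_rate=spec.learning_rate, class_weight=cw)
    return CNNModel(net, spec)


def predict_scores(model, examples) -> np.ndarray:
    """Probability of the symptom per example, in input order."""
    return model.predict_scores(examples)
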