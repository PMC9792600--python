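"""Base-learner architectures, feature projector, classifier and ensemble.

Three convolutional feature extractors from the EEG-decoding literature are
assembled into a multi-branch ensemble:

* **ShallowConvNet** — temporal convolution (band-pass analogue), spatial
  convolution over all electrodes, batch-norm, average pooling and a log
  activation (log-variance analogue of filter-bank CSP).
* **DeepConvNet** — a temporal/spatial block followed by three
  conv–max-pool blocks with ELU activations.
* **EEGNet** — a compact architecture with a length-preserving temporal
  convolution, a unit-max-norm depthwise spatial convolution and a
  separable convolution.

Each extractor maps a crop (channels x samples) to a flat feature vector.
The ensemble concatenates the extractor features, projects them through a
single 16-unit ELU dense layer (the contrastive embedding space) and
classifies with a dense softmax head.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn

__all__ = [
    "ExtractorSpec", "Extractor", "Projector", "BaseLearner", "EnsembleModel",
    "build_shallow", "build_deep", "build_eegnet", "build_extractor",
    "build_projector", "build_classifier", "concat_features",
    "tohoku_specs", "iia_specs", "tiny_specs", "base_learner_specs",
    "architecture_summary", "save_ensemble", "load_ensemble",
]

ARCHITECTURES = ("shallow", "deep", "eegnet")


@dataclass
class ExtractorSpec:
    """Architecture + hyperparameters of one feature extractor.

    Defaults correspond to a 16-channel, 128-sample input at 128 Hz; use the
    preset constructors for other geometries.
    """

    architecture: str
    n_channels: int
    n_samples: int
    dropout_p: float = 0.5
    # ShallowConvNet
    shallow_filters: int = 40
    shallow_kernel: int = 13
    shallow_pool: int = 35
    shallow_pool_stride: int = 7
    # square -> avg pool -> log mirrors the log-variance computation of
    # filter-bank CSP; the elu-log variant floors a large fraction of
    # pooled values at the log guard and trains poorly
    shallow_activation: str = "square-log"
    # DeepConvNet
    deep_filters: tuple = (25, 50, 100, 200)
    deep_kernel: int = 5
    deep_pool: int = 2
    # EEGNet
    eegnet_temporal_filters: int = 8
    eegnet_temporal_kernel: int = 64
    eegnet_depth_multiplier: int = 2
    eegnet_separable_kernel: int = 16
    eegnet_pools: tuple = (4, 8)

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("input geometry must be positive")


def tohoku_specs(n_channels: int = 16, n_samples: int = 128,
                 dropout_p: float = 0.5) -> list[ExtractorSpec]:
    """Extractor trio for the 16-channel, 128 Hz configuration."""
    base = dict(n_channels=n_channels, n_samples=n_samples,
                dropout_p=dropout_p)
    return [
        ExtractorSpec("shallow", shallow_kernel=13, shallow_pool=35,
                      shallow_pool_stride=7, **base),
        ExtractorSpec("deep", deep_kernel=5, deep_pool=2, **base),
        ExtractorSpec("eegnet", eegnet_temporal_kernel=64,
                      eegnet_separable_kernel=16, eegnet_pools=(4, 8), **base),
    ]


def iia_specs(n_channels: int = 22, n_samples: int = 1000,
              dropout_p: float = 0.5) -> list[ExtractorSpec]:
    """Extractor trio for the 22-channel, 250 Hz configuration."""
    base = dict(n_channels=n_channels, n_samples=n_samples,
                dropout_p=dropout_p)
    return [
        ExtractorSpec("shallow", shallow_kernel=25, shallow_pool=75,
                      shallow_pool_stride=15, **base),
        ExtractorSpec("deep", deep_kernel=10, deep_pool=3, **base),
        ExtractorSpec("eegnet", eegnet_temporal_kernel=128,
                      eegnet_separable_kernel=32, eegnet_pools=(8, 16), **base),
    ]


def tiny_specs(n_channels: int = 4, n_samples: int = 64,
               dropout_p: float = 0.25) -> list[ExtractorSpec]:
    """Scaled-down trio for fast experiments on small synthetic data.

    The narrow feature maps (tens of features rather than hundreds) tolerate
    far less dropout than the full-size architectures, hence the lighter
    default.
    """
    base = dict(n_channels=n_channels, n_samples=n_samples,
                dropout_p=dropout_p)
    return [
        ExtractorSpec("shallow", shallow_filters=8, shallow_kernel=7,
                      shallow_pool=9, shallow_pool_stride=3, **base),
        ExtractorSpec("deep", deep_filters=(8, 16, 32, 32), deep_kernel=3,
                      deep_pool=2, **base),
        # temporal kernel spans half a second at 64 Hz, as in the full-size
        # configurations (64 at 128 Hz, 128 at 250 Hz)
        ExtractorSpec("eegnet", eegnet_temporal_kernel=32,
                      eegnet_separable_kernel=8, eegnet_pools=(2, 4), **base),
    ]


def base_learner_specs(trio: list[ExtractorSpec],
                       count: int = 3) -> list[ExtractorSpec]:
    """Base-learner multiset for 2/3/4 learners: {shallow, deep},
    {shallow, deep, eegnet}, {shallow, deep, eegnet, shallow}."""
    shallow, deep, eegnet = trio
    if count == 2:
        return [shallow, deep]
    if count == 3:
        return [shallow, deep, eegnet]
    if count == 4:
        return [shallow, deep, eegnet, replace(shallow)]
    raise ValueError("base learner count must be 2, 3 or 4")


class Extractor:
    """A feature extractor: crop batch -> flat feature matrix."""

    def __init__(self, net: nn.Sequential, spec: ExtractorSpec, out_dim: int):
        self.net = net
        self.spec = spec
        self.out_dim = out_dim

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, channels, samples) -> (batch, out_dim)."""
        x = np.asarray(x)
        if x.ndim != 3 or x.shape[1] != self.spec.n_channels \
                or x.shape[2] != self.spec.n_samples:
            raise ValueError(
                f"{self.spec.architecture} extractor expects "
                f"(*, {self.spec.n_channels}, {self.spec.n_samples}), "
                f"got {x.shape}")
        return self.net.forward(x[:, None, :, :].astype(np.float32))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def params(self):
        return self.net.params()

    def set_training(self, flag: bool):
        self.net.set_training(flag)

    __call__ = forward


def _finish(layers: list, spec: ExtractorSpec, probe_shape: tuple) -> Extractor:
    net = nn.Sequential(*layers)
    net.set_training(False)
    probe = np.zeros((1, 1, spec.n_channels, spec.n_samples), dtype=np.float32)
    out = net.forward(probe)
    return Extractor(net, spec, out_dim=out.shape[1])


def build_shallow(spec: ExtractorSpec, seed: int = 0,
                  dtype=np.float32) -> Extractor:
    """Temporal conv -> spatial conv -> BN(+nonlinearity) -> avg pool ->
    log -> dropout -> flatten."""
    if spec.shallow_kernel > spec.n_samples:
        raise ValueError("temporal kernel exceeds input length")
    t_out = spec.n_samples - spec.shallow_kernel + 1
    if spec.shallow_pool > t_out:
        raise ValueError("pool size exceeds post-convolution length")
    rng = np.random.default_rng(seed)
    f = spec.shallow_filters
    layers = [
        nn.Conv2d(1, f, (1, spec.shallow_kernel), rng=rng, dtype=dtype),
        nn.Conv2d(f, f, (spec.n_channels, 1), bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm(f, dtype=dtype),
    ]
    if spec.shallow_activation == "elu-log":
        layers.append(nn.ELU())
    elif spec.shallow_activation == "square-log":
        layers.append(nn.Square())
    else:
        raise ValueError(f"unknown activation {spec.shallow_activation!r}")
    layers += [
        nn.AvgPool2d((1, spec.shallow_pool), (1, spec.shallow_pool_stride)),
        nn.LogClip(),
        nn.Dropout(spec.dropout_p, rng=rng),
        nn.Flatten(),
    ]
    return _finish(layers, spec, (1, spec.n_channels, spec.n_samples))


def build_deep(spec: ExtractorSpec, seed: int = 0,
               dtype=np.float32) -> Extractor:
    """Linear temporal/spatial block then three conv-max-pool blocks."""
    if spec.deep_kernel > spec.n_samples:
        raise ValueError("temporal kernel exceeds input length")
    rng = np.random.default_rng(seed)
    f0, f1, f2, f3 = spec.deep_filters
    p = spec.deep_pool
    layers: list = [
        nn.Conv2d(1, f0, (1, spec.deep_kernel), rng=rng, dtype=dtype),
        nn.Conv2d(f0, f0, (spec.n_channels, 1), bias=False, rng=rng,
                  dtype=dtype),
        nn.BatchNorm(f0, dtype=dtype),
        nn.ELU(),
        nn.MaxPool2d((1, p)),
        nn.Dropout(spec.dropout_p, rng=rng),
    ]
    prev = f0
    for f in (f1, f2, f3):
        layers += [
            nn.Conv2d(prev, f, (1, spec.deep_kernel), bias=False, rng=rng,
                      dtype=dtype),
            nn.BatchNorm(f, dtype=dtype),
            nn.ELU(),
            nn.MaxPool2d((1, p)),
            nn.Dropout(spec.dropout_p, rng=rng),
        ]
        prev = f
    layers.append(nn.Flatten())
    return _finish(layers, spec, (1, spec.n_channels, spec.n_samples))


def build_eegnet(spec: ExtractorSpec, seed: int = 0,
                 dtype=np.float32) -> Extractor:
    """Length-preserving temporal conv, unit-max-norm depthwise spatial
    conv, separable conv; average pooling between stages."""
    rng = np.random.default_rng(seed)
    f1 = spec.eegnet_temporal_filters
    d = spec.eegnet_depth_multiplier
    f2 = f1 * d
    p1, p2 = spec.eegnet_pools
    layers = [
        nn.Conv2d(1, f1, (1, spec.eegnet_temporal_kernel), padding="same",
                  bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm(f1, dtype=dtype),
        nn.ELU(),
        nn.Conv2d(f1, f2, (spec.n_channels, 1), groups=f1, bias=False,
                  max_norm=1.0, rng=rng, dtype=dtype),
        nn.BatchNorm(f2, dtype=dtype),
        nn.ELU(),
        nn.AvgPool2d((1, p1)),
        nn.Dropout(spec.dropout_p, rng=rng),
        # separable = depthwise temporal + pointwise 1x1
        nn.Conv2d(f2, f2, (1, spec.eegnet_separable_kernel), padding="same",
                  groups=f2, bias=False, rng=rng, dtype=dtype),
        nn.Conv2d(f2, f2, (1, 1), bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm(f2, dtype=dtype),
        nn.ELU(),
        nn.AvgPool2d((1, p2)),
        nn.Dropout(spec.dropout_p, rng=rng),
        nn.Flatten(),
    ]
    return _finish(layers, spec, (1, spec.n_channels, spec.n_samples))


_BUILDERS = {"shallow": build_shallow, "deep": build_deep,
             "eegnet": build_eegnet}


def build_extractor(spec: ExtractorSpec, seed: int = 0) -> Extractor:
    return _BUILDERS[spec.architecture](spec, seed=seed)


def concat_features(extractors: list[Extractor],
                    batch: np.ndarray) -> np.ndarray:
    """Per-crop concatenation of extractor features, in extractor order."""
    feats = []
    for i, ext in enumerate(extractors):
        try:
            feats.append(ext.forward(batch))
        except ValueError as exc:
            raise ValueError(f"extractor {i} "
                             f"({ext.spec.architecture}): {exc}") from exc
    return feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)


class Projector:
    """Dense in_dim -> 16 with ELU; optionally L2-normalized output.

    Normalized embeddings put the contrastive similarities on the unit
    sphere, which keeps the temperature scale meaningful across batches.
    """

    def __init__(self, in_dim: int, out_dim: int = 16, normalize: bool = True,
                 seed: int = 0, dtype=np.float32):
        if in_dim < 1:
            raise ValueError("in_dim must be >= 1")
        rng = np.random.default_rng(seed)
        self.dense = nn.Dense(in_dim, out_dim, rng=rng, dtype=dtype)
        self.elu = nn.ELU()
        self.normalize = normalize
        self.in_dim, self.out_dim = in_dim, out_dim
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.elu.forward(self.dense.forward(x.astype(np.float32)))
        if not self.normalize:
            self._cache = None
            return h
        norm = np.sqrt((h * h).sum(axis=1, keepdims=True))
        norm = np.maximum(norm, 1e-12)
        z = h / norm
        self._cache = (z, norm)
        return z

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is not None:
            z, norm = self._cache
            grad = (grad - z * (grad * z).sum(axis=1, keepdims=True)) / norm
        return self.dense.backward(self.elu.backward(grad))

    def params(self):
        return self.dense.params()

    def set_training(self, flag: bool):
        pass  # no stochastic layers

    __call__ = forward


def build_projector(in_dim: int, out_dim: int = 16, normalize: bool = True,
                    seed: int = 0) -> Projector:
    return Projector(in_dim, out_dim=out_dim, normalize=normalize, seed=seed)


class Classifier:
    """Dense -> softmax head producing class probabilities."""

    def __init__(self, in_dim: int, n_classes: int, seed: int = 0,
                 dtype=np.float32):
        if n_classes < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(seed)
        self.dense = nn.Dense(in_dim, n_classes, rng=rng, dtype=dtype)
        self.n_classes = n_classes

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.dense.forward(x.astype(np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        return self.dense.backward(grad_logits)

    def params(self):
        return self.dense.params()

    __call__ = forward


def build_classifier(n_classes: int, in_dim: int = 16,
                     seed: int = 0) -> Classifier:
    return Classifier(in_dim, n_classes, seed=seed)


class BaseLearner:
    """One extractor with its own softmax head (used during pretraining and
    by the weighted-voting ensemble)."""

    def __init__(self, extractor: Extractor, n_classes: int, seed: int = 0):
        self.extractor = extractor
        self.head = Classifier(extractor.out_dim, n_classes, seed=seed)
        self.n_classes = n_classes

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.extractor.forward(x)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.head.logits(self.features(x))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        self.extractor.set_training(False)
        outs = [nn.softmax(self.logits(x[i:i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def params(self):
        return self.extractor.params() + self.head.params()

    def set_training(self, flag: bool):
        self.extractor.set_training(flag)


class EnsembleModel:
    """Multi-branch ensemble: extractors -> concat -> (projector) -> head.

    With ``projector=None`` the head consumes the concatenated features
    directly (the plain feature-concatenation variant); otherwise the head
    consumes the 16-dimensional projected embedding.
    """

    def __init__(self, extractors: list[Extractor], n_classes: int,
                 use_projector: bool = True, normalize: bool = True,
                 projector_dim: int = 16, seed: int = 0):
        if len(extractors) < 1:
            raise ValueError("need at least one extractor")
        self.extractors = extractors
        self.concat_dim = sum(e.out_dim for e in extractors)
        if use_projector:
            self.projector: Projector | None = build_projector(
                self.concat_dim, out_dim=projector_dim, normalize=normalize,
                seed=seed + 101)
            head_in = projector_dim
        else:
            self.projector = None
            head_in = self.concat_dim
        self.head = Classifier(head_in, n_classes, seed=seed + 202)
        self.n_classes = n_classes
        self.voting_weights: np.ndarray | None = None

    # -- forward surfaces ---------------------------------------------------
    def concat(self, x: np.ndarray) -> np.ndarray:
        return concat_features(self.extractors, x)

    def embed(self, x: np.ndarray) -> np.ndarray:
        feats = self.concat(x)
        return self.projector.forward(feats) if self.projector else feats

    def embed_batched(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Batched :meth:`embed` — keeps convolution workspaces small."""
        self.set_training(False)
        return np.concatenate([self.embed(x[i:i + batch_size])
                               for i in range(0, len(x), batch_size)], axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        self.set_training(False)
        outs = [nn.softmax(self.head.logits(self.embed(x[i:i + batch_size])))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def params(self):
        out = []
        for e in self.extractors:
            out.extend(e.params())
        if self.projector:
            out.extend(self.projector.params())
        out.extend(self.head.params())
        return out

    def set_training(self, flag: bool):
        for e in self.extractors:
            e.set_training(flag)


# ---------------------------------------------------------------------------
# Introspection and checkpoints


def architecture_summary(extractor: Extractor) -> str:
    """Layer-by-layer output shapes, in the style of an architecture table."""
    spec = extractor.spec
    x = np.zeros((1, 1, spec.n_channels, spec.n_samples), dtype=np.float32)
    extractor.net.set_training(False)
    rows = [f"{'Layer':<14}{'Output dim':<22}",
            f"{'Input':<14}{str(x.shape[1:]):<22}"]
    for layer in extractor.net.layers:
        x = layer.forward(x)
        rows.append(f"{type(layer).__name__:<14}{str(tuple(x.shape[1:])):<22}")
    return "\n".join(rows)


def save_ensemble(path: str | os.PathLike, model: EnsembleModel) -> None:
    """Checkpoint: specs as JSON metadata + parameter arrays in one .npz."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    meta = {
        "specs": [asdict(e.spec) for e in model.extractors],
        "n_classes": model.n_classes,
        "use_projector": model.projector is not None,
        "normalize": model.projector.normalize if model.projector else True,
    }
    # running BN statistics are state, not Params
    stats = {}
    for ei, e in enumerate(model.extractors):
        for li, layer in enumerate(e.net.layers):
            if isinstance(layer, nn.BatchNorm):
                stats[f"rm{ei}_{li}"] = layer.running_mean
                stats[f"rv{ei}_{li}"] = layer.running_var
    if model.voting_weights is not None:
        arrays["voting_weights"] = model.voting_weights
    np.savez(os.fspath(path), meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays, **stats)


def load_ensemble(path: str | os.PathLike, seed: int = 0) -> EnsembleModel:
    with np.load(os.fspath(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        specs = [ExtractorSpec(**s) for s in meta["specs"]]
        for s in specs:
            s.deep_filters = tuple(s.deep_filters)
            s.eegnet_pools = tuple(s.eegnet_pools)
        extractors = [build_extractor(s, seed=seed + i)
                      for i, s in enumerate(specs)]
        model = EnsembleModel(extractors, meta["n_classes"],
                              use_projector=meta["use_projector"],
                              normalize=meta["normalize"], seed=seed)
        for i, p in enumerate(model.params()):
            p.data = z[f"p{i}"].copy()
        for ei, e in enumerate(model.extractors):
            for li, layer in enumerate(e.net.layers):
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean = z[f"rm{ei}_{li}"].copy()
                    layer.running_var = z[f"rv{ei}_{li}"].copy()
        if "voting_weights" in z:
            model.voting_weights = z["voting_weights"].copy()
    return model
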