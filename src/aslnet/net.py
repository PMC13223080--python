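"""3-D residual classifiers for perfusion volumes.

Two networks share one trunk design: a stem (7x7x7 conv, stride 2, group
norm, ReLU, 3x3x3 max-pool stride 2) followed by four residual stages whose
filter width doubles per stage and whose first blocks downsample (stride 2)
from stage 2 on.  A global-average-pooled, dropout-regularised softmax head
produces class probabilities.

* the grade network is a plain 3-class trunk;
* the survival network conditions the outputs of the last three stages on a
  clinical vector (age, sex, extent of resection) through feature-wise
  linear modulation (FiLM): a small MLP emits per-channel (gamma, beta)
  pairs and each conditioned stage output becomes ``gamma * x + beta``.
  gamma is parameterised as ``1 + delta`` with the MLP's output layer
  zero-initialised, so training starts at the identity modulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import (Conv3d, Dense, Dropout, GlobalAvgPool, GroupNorm,
                  MaxPool3d, ReLU, softmax)

__all__ = [
    "NetConfig", "MlpConfig", "FilmParams", "ClinicalVector", "Predictor",
    "build_grade_net", "build_os_net", "film_modulate", "encode_clinical",
    "spatial_trace", "DESK_PRESET", "FULL_PRESET",
]

EOR_LEVELS = ("GTR", "STR", "biopsy")
N_CLINICAL = 2 + len(EOR_LEVELS)  # age, sex, one-hot EOR


@dataclass(frozen=True)
class NetConfig:
    """Architecture description for one trunk."""

    blocks_per_stage: tuple[int, int, int, int] = (1, 1, 1, 1)
    init_filters: int = 8
    dropout_rate: float = 0.2
    bottleneck: bool = False
    norm_groups: int = 4
    n_classes: int = 3
    input_side: int = 70
    n_channels: int = 4
    stem_kernel: int = 7

    def __post_init__(self):
        if len(self.blocks_per_stage) != 4 or any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("blocks_per_stage must be 4 integers >= 1")
        if self.init_filters < 4:
            raise ValueError("init_filters must be >= 4")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for w in self.stage_widths:
            if w % self.norm_groups:
                raise ValueError(
                    f"norm_groups={self.norm_groups} does not divide stage width {w}")
            if self.bottleneck and (w // 4 == 0 or (w // 4) % self.norm_groups):
                raise ValueError(
                    f"norm_groups={self.norm_groups} does not divide bottleneck width {w // 4}")
        if self.init_filters % self.norm_groups:
            raise ValueError("norm_groups must divide init_filters (stem width)")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self.init_filters * 2 ** s for s in range(4))


DESK_PRESET = NetConfig(input_side=32, init_filters=8,
                        blocks_per_stage=(1, 1, 1, 1), norm_groups=4)
FULL_PRESET = NetConfig(input_side=70, init_filters=16,
                        blocks_per_stage=(2, 2, 2, 2), norm_groups=8)


@dataclass(frozen=True)
class MlpConfig:
    """Clinical-branch MLP: hidden layer sizes and dropout."""

    hidden: tuple[int, ...] = (16,)
    dropout: float = 0.2


@dataclass
class FilmParams:
    """One (gamma, beta) conditioning pair for a stage of channel width C."""

    gamma: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float32)
        self.beta = np.asarray(self.beta, dtype=np.float32)
        if self.gamma.shape != self.beta.shape:
            raise ValueError("gamma and beta must have matching shapes")


@dataclass(frozen=True)
class ClinicalVector:
    """Standardised clinical covariates for one patient."""

    age: float
    sex: int
    eor: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.isfinite([self.age, self.sex, *self.eor])):
            raise ValueError("clinical vector must be finite")
        if abs(sum(self.eor) - 1.0) > 1e-6:
            raise ValueError("eor one-hot must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.age, self.sex, *self.eor], dtype=np.float32)


def encode_clinical(df, age_mean: float, age_sd: float) -> np.ndarray:
    """Encode a clinical table into (N, 5) float32: z-age, sex, one-hot EOR."""
    out = np.zeros((len(df), N_CLINICAL), dtype=np.float32)
    out[:, 0] = (df["age"].to_numpy(dtype=float) - age_mean) / max(age_sd, 1e-8)
    out[:, 1] = df["sex"].to_numpy(dtype=float)
    eor = df["eor"].astype(str).to_numpy()
    for j, level in enumerate(EOR_LEVELS):
        out[:, 2 + j] = (eor == level)
    return out


def film_modulate(features: np.ndarray, params: FilmParams) -> np.ndarray:
    """Apply per-channel affine conditioning gamma * x + beta.

    ``features`` is channels-last; gamma/beta are either (C,) vectors shared
    across the batch or (N, C) sample-wise vectors.
    """
    g, b = params.gamma, params.beta
    c = features.shape[-1]
    if g.shape[-1] != c:
        raise ValueError(
            f"FiLM parameter length {g.shape[-1]} != channel width {c}")
    if g.ndim == 2:
        if g.shape[0] != features.shape[0]:
            raise ValueError("sample-wise FiLM batch mismatch")
        shape = (g.shape[0],) + (1,) * (features.ndim - 2) + (c,)
        g = g.reshape(shape)
        b = b.reshape(shape)
    return features * g + b


# ---------------------------------------------------------------------------
# residual blocks and trunks


class _ResBlock:
    """Basic (or bottleneck) residual block: branch + shortcut, post-add ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, groups: int,
                 bottleneck: bool, rng: np.random.Generator):
        if bottleneck:
            mid = c_out // 4
            self.branch = [
                Conv3d(c_in, mid, 1, 1, rng), GroupNorm(groups, mid), ReLU(),
                Conv3d(mid, mid, 3, stride, rng), GroupNorm(groups, mid), ReLU(),
                Conv3d(mid, c_out, 1, 1, rng), GroupNorm(groups, c_out),
            ]
        else:
            self.branch = [
                Conv3d(c_in, c_out, 3, stride, rng), GroupNorm(groups, c_out), ReLU(),
                Conv3d(c_out, c_out, 3, 1, rng), GroupNorm(groups, c_out),
            ]
        if stride != 1 or c_in != c_out:
            self.shortcut = [Conv3d(c_in, c_out, 1, stride, rng),
                             GroupNorm(groups, c_out)]
        else:
            self.shortcut = []

    def params(self):
        out = []
        for layer in self.branch + self.shortcut:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False, rng=None):
        h = x
        for layer in self.branch:
            h = layer.forward(h, train, rng)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, train, rng)
        pre = h + s
        self._relu_mask = pre > 0
        return np.where(self._relu_mask, pre, 0).astype(np.float32, copy=False)

    def backward(self, dout):
        dpre = np.where(self._relu_mask, dout, 0).astype(np.float32, copy=False)
        dh = dpre
        for layer in reversed(self.branch):
            dh = layer.backward(dh)
        ds = dpre
        for layer in reversed(self.shortcut):
            ds = layer.backward(ds)
        return dh + ds


class _Trunk:
    """Stem + four residual stages; exposes per-stage boundaries for FiLM."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        f = config.init_filters
        g = config.norm_groups
        self.stem = [
            Conv3d(config.n_channels, f, config.stem_kernel, 2, rng),
            GroupNorm(g, f), ReLU(), MaxPool3d(3, 2),
        ]
        self.stages: list[list[_ResBlock]] = []
        c_in = f
        for s, (n_blocks, width) in enumerate(
                zip(config.blocks_per_stage, config.stage_widths)):
            stage = []
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                stage.append(_ResBlock(c_in, width, stride, g,
                                       config.bottleneck, rng))
                c_in = width
            self.stages.append(stage)

    def params(self):
        out = []
        for layer in self.stem:
            out.extend(layer.params())
        for stage in self.stages:
            for block in stage:
                out.extend(block.params())
        return out

    def forward_stem(self, x, train, rng):
        for layer in self.stem:
            x = layer.forward(x, train, rng)
        return x

    def backward_stem(self, d, need_input: bool = True):
        for layer in reversed(self.stem):
            if isinstance(layer, Conv3d):
                d = layer.backward(d, need_input=need_input)
            else:
                d = layer.backward(d)
        return d

    def forward_stage(self, s, x, train, rng):
        for block in self.stages[s]:
            x = block.forward(x, train, rng)
        return x

    def backward_stage(self, s, d):
        for block in reversed(self.stages[s]):
            d = block.backward(d)
        return d


class _Head:
    def __init__(self, width: int, n_classes: int, dropout: float,
                 rng: np.random.Generator):
        self.gap = GlobalAvgPool()
        self.drop = Dropout(dropout)
        self.fc = Dense(width, n_classes, rng)

    def params(self):
        return self.fc.params()

    def forward(self, x, train, rng):
        h = self.gap.forward(x)
        h = self.drop.forward(h, train, rng)
        return self.fc.forward(h)

    def backward(self, dlogits):
        d = self.fc.backward(dlogits)
        d = self.drop.backward(d)
        return self.gap.backward(d)


class _FilmOp:
    """Sample-wise FiLM with gradient flow to both feature map and (dg, db)."""

    def forward(self, x, dg, db):
        self._x = x
        self._g = 1.0 + dg
        shape = (x.shape[0],) + (1,) * (x.ndim - 2) + (x.shape[-1],)
        return x * self._g.reshape(shape) + db.reshape(shape)

    def backward(self, dout):
        axes = tuple(range(1, dout.ndim - 1))
        ddg = (dout * self._x).sum(axis=axes)
        ddb = dout.sum(axis=axes)
        shape = (dout.shape[0],) + (1,) * (dout.ndim - 2) + (dout.shape[-1],)
        dx = dout * self._g.reshape(shape)
        self._x = None
        return dx, ddg, ddb


class GradeNet:
    """Plain image-only residual classifier."""

    uses_clinical = False

    def __init__(self, config: NetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.trunk = _Trunk(config, rng)
        self.head = _Head(config.stage_widths[-1], config.n_classes,
                          config.dropout_rate, rng)
        self._rng = np.random.default_rng(seed + 1)

    def params(self):
        return self.trunk.params() + self.head.params()

    def forward_logits(self, x, clinical=None, train=False):
        rng = self._rng if train else None
        h = self.trunk.forward_stem(x, train, rng)
        for s in range(4):
            h = self.trunk.forward_stage(s, h, train, rng)
        return self.head.forward(h, train, rng)

    def forward(self, x, clinical=None, train=False):
        return softmax(self.forward_logits(x, clinical, train))

    def backward(self, dlogits, need_input: bool = True):
        d = self.head.backward(dlogits)
        for s in reversed(range(4)):
            d = self.trunk.backward_stage(s, d)
        return self.trunk.backward_stem(d, need_input=need_input)


class OSNet:
    """FiLM-conditioned survival classifier.

    Clinical covariates enter ONLY through the (gamma, beta) pairs applied
    to the outputs of the last three residual stages.
    """

    uses_clinical = True
    conditioned_stages = (1, 2, 3)

    def __init__(self, config: NetConfig, mlp: MlpConfig = MlpConfig(),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.mlp_config = mlp
        self.trunk = _Trunk(config, rng)
        self.head = _Head(config.stage_widths[-1], config.n_classes,
                          config.dropout_rate, rng)
        self._film_widths = [config.stage_widths[s] for s in self.conditioned_stages]
        n_out = 2 * sum(self._film_widths)
        self.mlp: list = []
        n_in = N_CLINICAL
        for h in mlp.hidden:
            self.mlp += [Dense(n_in, h, rng), ReLU(), Dropout(mlp.dropout)]
            n_in = h
        # zero-initialised output layer -> training starts at identity FiLM
        self.mlp.append(Dense(n_in, n_out, rng, zero_init=True))
        self._film_ops = {s: _FilmOp() for s in self.conditioned_stages}
        self._rng = np.random.default_rng(seed + 1)

    def params(self):
        out = self.trunk.params() + self.head.params()
        for layer in self.mlp:
            out.extend(layer.params())
        return out

    def _film_vectors(self, clinical, train, rng):
        h = clinical
        for layer in self.mlp:
            h = layer.forward(h, train, rng)
        pairs = {}
        i = 0
        for s, w in zip(self.conditioned_stages, self._film_widths):
            pairs[s] = (h[:, i:i + w], h[:, i + w:i + 2 * w])
            i += 2 * w
        return pairs

    def forward_logits(self, x, clinical, train=False):
        if clinical is None:
            raise ValueError("survival network requires a clinical matrix")
        rng = self._rng if train else None
        pairs = self._film_vectors(clinical, train, rng)
        h = self.trunk.forward_stem(x, train, rng)
        for s in range(4):
            h = self.trunk.forward_stage(s, h, train, rng)
            if s in pairs:
                dg, db = pairs[s]
                h = self._film_ops[s].forward(h, dg, db)
        return self.head.forward(h, train, rng)

    def forward(self, x, clinical=None, train=False):
        return softmax(self.forward_logits(x, clinical, train))

    def backward(self, dlogits, need_input: bool = True):
        d = self.head.backward(dlogits)
        dfilm_parts = {}
        for s in reversed(range(4)):
            if s in self._film_ops:
                d, ddg, ddb = self._film_ops[s].backward(d)
                dfilm_parts[s] = (ddg, ddb)
            d = self.trunk.backward_stage(s, d)
        dx = self.trunk.backward_stem(d, need_input=need_input)
        n = dlogits.shape[0]
        dh = np.concatenate(
            [np.concatenate(dfilm_parts[s], axis=1) for s in self.conditioned_stages],
            axis=1).astype(np.float32)
        for layer in reversed(self.mlp):
            dh = layer.backward(dh)
        return dx


@dataclass
class Predictor:
    """A trained classifier: architecture description + parameter state."""

    net: GradeNet | OSNet
    task: str  # "grade" | "os"

    @property
    def config(self) -> NetConfig:
        return self.net.config

    def predict_proba(self, x: np.ndarray, clinical: np.ndarray | None = None,
                      batch_size: int = 8) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            clin = None if clinical is None else clinical[i:i + batch_size]
            out.append(self.net.forward(x[i:i + batch_size], clin, train=False))
        return np.concatenate(out, axis=0)

    def input_gradient(self, x: np.ndarray, target: int,
                       clinical: np.ndarray | None = None) -> np.ndarray:
        """d(probability of ``target``)/d(input voxels), evaluation mode."""
        x = np.asarray(x, dtype=np.float32)
        p = softmax(self.net.forward_logits(x, clinical, train=False))
        onehot = np.zeros_like(p)
        onehot[:, target] = 1.0
        dlogits = p[:, target:target + 1] * (onehot - p)
        return self.net.backward(dlogits.astype(np.float32))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.net.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.net.params(), state, strict=True):
            p.value[...] = v

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, *[p.value for p in self.net.params()])
        sidecar = {"task": self.task, "config": asdict(self.config)}
        if isinstance(self.net, OSNet):
            sidecar["clinical_mlp"] = asdict(self.net.mlp_config)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Predictor":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["blocks_per_stage"] = tuple(cfg["blocks_per_stage"])
        config = NetConfig(**cfg)
        if meta["task"] == "os":
            mlp = meta.get("clinical_mlp", {})
            mlp["hidden"] = tuple(mlp.get("hidden", (16,)))
            pred = build_os_net(config, MlpConfig(**mlp))
        else:
            pred = build_grade_net(config)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            pred.set_state([z[k] for k in z.files])
        return pred


def build_grade_net(config: NetConfig, seed: int = 0) -> Predictor:
    """3-class WHO-grade classifier (II / III / IV)."""
    if config.n_classes != 3:
        raise ValueError("grade network requires n_classes = 3")
    return Predictor(net=GradeNet(config, seed), task="grade")


def build_os_net(config: NetConfig, clinical_mlp: MlpConfig = MlpConfig(),
                 seed: int = 0) -> Predictor:
    """Binary 12-month survival classifier with clinical FiLM conditioning."""
    if config.n_classes != 2:
        raise ValueError("survival network requires n_classes = 2")
    return Predictor(net=OSNet(config, clinical_mlp, seed), task="os")


def spatial_trace(config: NetConfig) -> list[int]:
    """Spatial side length after stem conv, pool, and each stage."""
    side = config.input_side
    trace = []
    side = -(-side // 2)          # stem conv stride 2
    trace.append(side)
    side = -(-side // 2)          # max-pool stride 2
    trace.append(side)
    for s in range(4):
        if s > 0:
            side = -(-side // 2)  # first block of stages 2-4 strides
        trace.append(side)
    return trace
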