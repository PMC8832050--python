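"""The ECGNet architecture.

A 651 x 12 beat window (time-major, leads on the second axis, one value
channel) passes through:

1. a lead-stage squeeze-excitation over the 12-lead axis, producing one
   inspectable gate per lead — the model's lead attention;
2. three parallel branches, one per time-axis kernel length (3, 5, 7 by
   default).  Each branch is a stem convolution followed by pre-activation
   residual units (BN -> ReLU -> conv, twice, plus identity skip): one unit
   in Block1 and a repeated stack in Block2; then a branch-stage
   squeeze-excitation over the feature channels and global average pooling;
3. concatenation of the three branch vectors and a dense softmax head.

Every convolution is k x 1 along time with "same" padding and stride 1 — a
single kernel is shared across leads, so branch parameter counts do not
depend on the number of leads.  The forward pass exposes named handles for
the SE gates and each branch's last convolutional feature map, which the
attribution module consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["EcgNetConfig", "EcgNetModel", "build_ecgnet"]


@dataclass
class EcgNetConfig:
    n_classes: int = 11
    input_length: int = 651
    n_leads: int = 12
    branch_kernels: tuple = (3, 5, 7)
    base_filters: int = 32
    block2_repeats: int = 3
    se_reduction: int = 4
    lead_se_reduction: int = 4
    strict_shape: bool = True
    dtype: str = "float32"

    def validate(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.base_filters % self.se_reduction != 0:
            raise ValueError(
                f"se_reduction {self.se_reduction} must divide base_filters {self.base_filters}"
            )
        if self.n_leads % self.lead_se_reduction != 0:
            raise ValueError(
                f"lead_se_reduction {self.lead_se_reduction} must divide n_leads {self.n_leads}"
            )
        if not self.branch_kernels:
            raise ValueError("at least one branch kernel required")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "EcgNetConfig":
        d = dict(d)
        if "branch_kernels" in d:
            d["branch_kernels"] = tuple(d["branch_kernels"])
        return cls(**d)


class _ResidualUnit(nn.Layer):
    """Pre-activation residual unit: (BN -> ReLU -> conv) x 2 + skip."""

    def __init__(self, cin, cout, k, rng, dtype):
        self.bn1 = nn.BatchNorm(cin, dtype=dtype)
        self.conv1 = nn.ConvTime(cin, cout, k, rng, dtype)
        self.bn2 = nn.BatchNorm(cout, dtype=dtype)
        self.conv2 = nn.ConvTime(cout, cout, k, rng, dtype)
        # 1x1 projection only when the channel count changes
        self.proj = nn.ConvTime(cin, cout, 1, rng, dtype) if cin != cout else None

    def __call__(self, x, train):
        h = self.conv1(nn.relu(self.bn1(x, train)))
        h = self.conv2(nn.relu(self.bn2(h, train)))
        skip = self.proj(x) if self.proj is not None else x
        return nn.add(h, skip)


class _Branch(nn.Layer):
    """One kernel scale: stem conv -> Block1 -> Block2 -> SE -> global pool."""

    def __init__(self, kernel, cfg: EcgNetConfig, rng, dtype):
        f = cfg.base_filters
        self.stem = nn.ConvTime(1, f, kernel, rng, dtype)
        self.block1 = _ResidualUnit(f, f, kernel, rng, dtype)
        self.block2 = [_ResidualUnit(f, f, kernel, rng, dtype)
                       for _ in range(cfg.block2_repeats)]
        self.se = nn.SqueezeExcite(f, cfg.se_reduction, channel_axis=-1,
                                   rng=rng, dtype=dtype)

    def __call__(self, x, train):
        h = self.stem(x)
        h = self.block1(h, train)
        for unit in self.block2:
            h = unit(h, train)
        last_conv = h  # final residual feature map, pre-SE: Grad-CAM target
        h, gates = self.se(h)
        pooled = nn.mean(h, axes=(1, 2))  # global average pool over time and leads
        return pooled, gates, last_conv


class EcgNetModel:
    """Built ECGNet with named handles for attention and attribution."""

    def __init__(self, cfg: EcgNetConfig, rng: np.random.Generator | int | None = None):
        cfg.validate()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        dtype = cfg.np_dtype
        self.lead_se = nn.SqueezeExcite(cfg.n_leads, cfg.lead_se_reduction,
                                        channel_axis=2, rng=rng, dtype=dtype)
        self.branches = [_Branch(k, cfg, rng, dtype) for k in cfg.branch_kernels]
        fused = cfg.base_filters * len(cfg.branch_kernels)
        self.head = nn.Dense(fused, cfg.n_classes, rng, dtype)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[nn.Tensor]:
        params = self.lead_se.parameters()
        for br in self.branches:
            params.extend(br.parameters())
        params.extend(self.head.parameters())
        return params

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def branch_param_count(self) -> int:
        """Parameters in the convolutional branches only (no lead SE, no head)."""
        return int(sum(p.data.size for br in self.branches for p in br.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        state.extend(self._bn_state())
        return state

    def set_weights(self, state: list[np.ndarray]):
        params = self.parameters()
        for p, w in zip(params, state[: len(params)]):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()
        for bn, (rm, rv) in zip(self._bn_layers(),
                                zip(state[len(params)::2], state[len(params) + 1 :: 2])):
            bn.running_mean = rm.copy()
            bn.running_var = rv.copy()

    def _bn_layers(self):
        layers = []
        for br in self.branches:
            for unit in [br.block1, *br.block2]:
                layers.extend([unit.bn1, unit.bn2])
        return layers

    def _bn_state(self):
        state = []
        for bn in self._bn_layers():
            state.extend([bn.running_mean.copy(), bn.running_var.copy()])
        return state

    # -- forward ------------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.cfg.np_dtype)
        if X.ndim == 3:
            X = X[..., None]
        expected = (self.cfg.input_length, self.cfg.n_leads, 1)
        if X.shape[1:] != expected:
            if self.cfg.strict_shape:
                raise ValueError(f"input shape {X.shape[1:]} != expected {expected}")
        return X

    def forward(self, X: np.ndarray, train: bool = False):
        """Run the graph. Returns ``(logits, handles)``.

        ``handles`` maps names to live graph tensors: ``se_input`` (N x 12
        lead gates), ``se_scale{k}`` (N x F branch gates) and
        ``lastconv_scale{k}`` (N x T x L x F feature maps) per kernel k,
        plus ``input`` itself.
        """
        X = self._check_input(X)
        x = nn.Tensor(X)
        xw, lead_gates = self.lead_se(x)
        handles = {"input": x, "se_input": lead_gates}
        pooled = []
        for k, branch in zip(self.cfg.branch_kernels, self.branches):
            vec, gates, last_conv = branch(xw, train)
            handles[f"se_scale{k}"] = gates
            handles[f"lastconv_scale{k}"] = last_conv
            pooled.append(vec)
        logits = self.head(nn.concat(pooled, axis=1))
        return logits, handles

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = self._check_input(X)
        out = []
        for i in range(0, len(X), batch_size):
            logits, _ = self.forward(X[i : i + batch_size], train=False)
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(X, batch_size).argmax(axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path):
        """Architecture JSON + weights in an .npz next to it."""
        base = Path(path)
        base.parent.mkdir(parents=True, exist_ok=True)
        base.with_suffix(".json").write_text(json.dumps(self.cfg.to_dict(), indent=2))
        np.savez(base.with_suffix(".npz"),
                 **{f"w{i}": w for i, w in enumerate(self.get_weights())})

    @classmethod
    def load(cls, path) -> "EcgNetModel":
        base = Path(path)
        if base.suffix in {".json", ".npz"}:
            base = base.with_suffix("")
        cfg = EcgNetConfig.from_dict(json.loads(base.with_suffix(".json").read_text()))
        model = cls(cfg, rng=0)
        with np.load(base.with_suffix(".npz")) as npz:
            model.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
        return model

    def summary(self) -> str:
        cfg = self.cfg
        lines = [
            f"ECGNet: input {cfg.input_length} x {cfg.n_leads} x 1, "
            f"{cfg.n_classes} classes, {self.n_params} parameters",
            f"  lead-stage SE over {cfg.n_leads} leads (reduction {cfg.lead_se_reduction})",
        ]
        for k in cfg.branch_kernels:
            lines.append(
                f"  branch k={k}: stem conv {k}x1 -> Block1 (1 residual unit) -> "
                f"Block2 ({cfg.block2_repeats} units) -> SE (r={cfg.se_reduction}) -> avgpool"
            )
        fused = cfg.base_filters * len(cfg.branch_kernels)
        lines.append(f"  concat ({fused}) -> dense -> softmax({cfg.n_classes})")
        return "\n".join(lines)


def build_ecgnet(cfg: EcgNetConfig | None = None,
                 rng: np.random.Generator | int | None = None) -> EcgNetModel:
    """Construct an ECGNet from a config (defaults: 11-class localization)."""
    return EcgNetModel(cfg or EcgNetConfig(), rng)
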