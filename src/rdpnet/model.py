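"""The multi-scale residual dilated pyramid network.

Architecture, for a (batch, channels, T) input with T divisible by 4:

* **Residual convolution module (RCM)** — two residual blocks.  Each has
  a main path conv(k, stride 2) - BN - ReLU - conv(k, stride 1,
  dilation 2) - BN and a 1x1-conv (stride 2) + BN shortcut, summed and
  passed through ReLU, followed by dropout 0.3.  Block widths 64 and 128;
  temporal length halves per block (T -> T/4 overall).
* **Dilated convolution pyramid module (DCPM)** — five cascaded
  conv(k=5, stride 1) - BN - ReLU layers with dilations 1, 2, 4, 8, 16,
  length-preserving via symmetric padding, widening the receptive field
  to 125 samples without extra parameters per layer.
* **Feature fusion and enhancement module (FFEM)** — global max pooling
  and per-channel differential entropy of both the RCM output (branch
  pathway) and the DCPM output (main pathway); each 128-vector gets its
  own batch normalization and the four are concatenated into a 512-wide
  fused representation (256 without the entropy pathway).
* **Classifier** — BN - ReLU - dropout 0.5 - linear -> C logits.

Convolutions carry no bias (each is followed by batch normalization);
the final linear layer keeps its bias.  Under these conventions the
default single-channel five-class model has 568,581 trainable
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .entropy import EntropySpec, batched_entropy


class ConfigurationError(ValueError):
    """Inconsistent or invalid model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter, plus ablation switches.

    Defaults reproduce the published configuration: kernel size 5 in both
    convolutional modules, residual widths (64, 128), a 128-wide pyramid
    with dilations (1, 2, 4, 8, 16), dropout 0.3 after each residual
    block and 0.5 in the head.
    """

    in_channels: int = 1
    n_classes: int = 5
    rcm_kernel: int = 5
    dcpm_kernel: int = 5
    rcm_channels: tuple[int, int] = (64, 128)
    dcpm_channels: int = 128
    dcpm_dilations: tuple[int, ...] = (1, 2, 4, 8, 16)
    rcm_dropout: float = 0.3
    head_dropout: float = 0.5
    use_rcm: bool = True
    use_dcpm: bool = True
    use_entropy: bool = True
    entropy_spec: EntropySpec = field(default_factory=EntropySpec)

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.n_classes < 2:
            raise ConfigurationError("need >=1 input channel and >=2 classes")
        for k in (self.rcm_kernel, self.dcpm_kernel):
            if k < 3 or k % 2 == 0:
                raise ConfigurationError("kernel sizes must be odd and >= 3")
        d = self.dcpm_dilations
        if not d or any(x < 1 for x in d) or any(
                d[i] >= d[i + 1] for i in range(len(d) - 1)):
            raise ConfigurationError(
                "dilations must be strictly increasing positive integers")
        if not self.use_rcm and not self.use_dcpm:
            raise ConfigurationError(
                "at least one of the convolutional modules must be enabled")
        if self.use_rcm and self.use_dcpm and \
                self.rcm_channels[1] != self.dcpm_channels:
            raise ConfigurationError(
                "second residual width must equal the pyramid width")

    @property
    def fused_width(self) -> int:
        width = self.dcpm_channels if self.use_dcpm or not self.use_rcm \
            else self.rcm_channels[1]
        return (4 if self.use_entropy else 2) * width

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels, "n_classes": self.n_classes,
            "rcm_kernel": self.rcm_kernel, "dcpm_kernel": self.dcpm_kernel,
            "rcm_channels": list(self.rcm_channels),
            "dcpm_channels": self.dcpm_channels,
            "dcpm_dilations": list(self.dcpm_dilations),
            "rcm_dropout": self.rcm_dropout, "head_dropout": self.head_dropout,
            "use_rcm": self.use_rcm, "use_dcpm": self.use_dcpm,
            "use_entropy": self.use_entropy,
            "entropy_spec": self.entropy_spec.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["rcm_channels"] = tuple(d["rcm_channels"])
        d["dcpm_dilations"] = tuple(d["dcpm_dilations"])
        d["entropy_spec"] = EntropySpec.from_dict(d["entropy_spec"])
        return cls(**d)


@dataclass(frozen=True)
class LayerSpec:
    """Kernel/dilation/stride of one convolutional layer, for receptive
    field accounting."""

    kernel: int
    dilation: int = 1
    stride: int = 1

    def __post_init__(self) -> None:
        if min(self.kernel, self.dilation, self.stride) < 1:
            raise ValueError("layer spec entries must be >= 1")


def receptive_field(layers: list[LayerSpec]) -> int:
    """Receptive field of a cascade of stride-1 dilated convolutions:
    ``1 + sum((k_i - 1) * d_i)``."""
    if not layers:
        raise ValueError("need at least one layer")
    return 1 + sum((l.kernel - 1) * l.dilation for l in layers)


@dataclass
class FeatureBundle:
    """The four fusion inputs and their concatenation, batched (N, .)

    ``fused`` concatenates, in this fixed order, the batch-normalized
    (pooled_branch, pooled_main, entropy_branch, entropy_main); the two
    entropy parts are absent when the entropy pathway is disabled.
    """

    pooled_branch: np.ndarray
    pooled_main: np.ndarray
    entropy_branch: np.ndarray | None
    entropy_main: np.ndarray | None
    fused: np.ndarray


class ResBlock(nn.Module):
    """Residual block: strided main path plus 1x1 shortcut, ReLU merge."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        pad = kernel // 2
        self.conv1 = nn.Conv1d(in_channels, out_channels, kernel,
                               stride=2, padding=pad, rng=rng)
        self.bn1 = nn.BatchNorm(out_channels)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv1d(out_channels, out_channels, kernel,
                               stride=1, dilation=2, padding=2 * pad, rng=rng)
        self.bn2 = nn.BatchNorm(out_channels)
        self.sc_conv = nn.Conv1d(in_channels, out_channels, 1, stride=2, rng=rng)
        self.sc_bn = nn.BatchNorm(out_channels)
        self.relu_out = nn.ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        short = self.sc_bn.forward(self.sc_conv.forward(x))
        return self.relu_out.forward(main + short)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dx = self.sc_conv.backward(self.sc_bn.backward(d))
        dx += self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        return dx


class FFEM(nn.Module):
    """Dual-pathway fusion of pooled and entropy features.

    Max pooling captures the most salient activation per channel;
    differential entropy summarizes the statistical spread of each
    channel over time.  Four independent batch normalizations fix the
    scale mismatch between the feature types before concatenation.

    Non-differential entropy kinds (histogram/periodogram based) are
    supported for the sensitivity study; being piecewise constant in the
    feature values they contribute no gradient to the trunk.
    """

    def __init__(self, width: int, spec: EntropySpec, use_entropy: bool) -> None:
        super().__init__()
        self.width = width
        self.spec = spec
        self.use_entropy = use_entropy
        self.pool_branch = nn.GlobalMaxPool()
        self.pool_main = nn.GlobalMaxPool()
        self.bn_pb = nn.BatchNorm(width)
        self.bn_pm = nn.BatchNorm(width)
        if use_entropy:
            self.bn_eb = nn.BatchNorm(width)
            self.bn_em = nn.BatchNorm(width)
            if spec.kind == "differential":
                self.ent_branch = nn.DifferentialEntropyPool(spec.eps)
                self.ent_main = nn.DifferentialEntropyPool(spec.eps)
        self.bundle: FeatureBundle | None = None

    def _entropy(self, pool: "nn.DifferentialEntropyPool | None",
                 x: np.ndarray) -> np.ndarray:
        if self.spec.kind == "differential":
            return pool.forward(x)
        return batched_entropy(x, self.spec).astype(nn.DTYPE)

    def forward(self, branch: np.ndarray, main: np.ndarray) -> np.ndarray:
        if branch.shape[1] != self.width or main.shape[1] != self.width:
            raise ValueError(f"both pathways must have {self.width} channels")
        pb = self.bn_pb.forward(self.pool_branch.forward(branch))
        pm = self.bn_pm.forward(self.pool_main.forward(main))
        if self.use_entropy:
            if branch.shape[2] < 2:
                raise ValueError("entropy pathway needs >= 2 time samples")
            eb = self.bn_eb.forward(self._entropy(
                getattr(self, "ent_branch", None), branch))
            em = self.bn_em.forward(self._entropy(
                getattr(self, "ent_main", None), main))
            fused = np.concatenate([pb, pm, eb, em], axis=1)
            self.bundle = FeatureBundle(pb, pm, eb, em, fused)
        else:
            fused = np.concatenate([pb, pm], axis=1)
            self.bundle = FeatureBundle(pb, pm, None, None, fused)
        return fused

    def backward(self, dfused: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = self.width
        dbranch = self.pool_branch.backward(self.bn_pb.backward(dfused[:, :w]))
        dmain = self.pool_main.backward(self.bn_pm.backward(dfused[:, w:2 * w]))
        if self.use_entropy:
            deb = self.bn_eb.backward(dfused[:, 2 * w:3 * w])
            dem = self.bn_em.backward(dfused[:, 3 * w:])
            if self.spec.kind == "differential":
                dbranch += self.ent_branch.backward(deb)
                dmain += self.ent_main.backward(dem)
            # other kinds: piecewise-constant descriptors, zero gradient
        return dbranch, dmain


class RDPNet(nn.Module):
    """The full network; ablation flags excise individual modules.

    * ``use_rcm=False``: the input passes through a minimal adapter (1x1
      convolution to the pyramid width followed by stride-4 max pooling,
      preserving the T/4 temporal scale) and feeds the pyramid directly;
      the adapter output serves as the branch pathway.
    * ``use_dcpm=False``: both fusion pathways receive the RCM output.
    * ``use_entropy=False``: only the two pooled pathways are fused
      (width 256).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2 = cfg.rcm_channels
        width = cfg.dcpm_channels if cfg.use_dcpm or not cfg.use_rcm else c2
        if cfg.use_rcm:
            self.block1 = ResBlock(cfg.in_channels, c1, cfg.rcm_kernel, rng)
            self.drop1 = nn.Dropout(cfg.rcm_dropout)
            self.block2 = ResBlock(c1, width if not cfg.use_dcpm else c2,
                                   cfg.rcm_kernel, rng)
            self.drop2 = nn.Dropout(cfg.rcm_dropout)
        else:
            self.input_proj = nn.Conv1d(cfg.in_channels, width, 1, rng=rng)
            self.input_pool = nn.MaxPool1d(4)
        if cfg.use_dcpm:
            k, pad0 = cfg.dcpm_kernel, cfg.dcpm_kernel // 2
            self.pyramid = [
                _ConvBNReLU(width, width, k, dilation=d, padding=d * pad0,
                            rng=rng)
                for d in cfg.dcpm_dilations]
        self.ffem = FFEM(width, cfg.entropy_spec, cfg.use_entropy)
        self.head_bn = nn.BatchNorm(cfg.fused_width)
        self.head_relu = nn.ReLU()
        self.head_drop = nn.Dropout(cfg.head_dropout)
        self.fc = nn.Linear(cfg.fused_width, cfg.n_classes, rng=rng)
        self._stage: dict[str, np.ndarray] = {}

    # -- plumbing --------------------------------------------------------
    def set_rng(self, rng: np.random.Generator) -> None:
        """Point every dropout layer at one shared generator."""
        for m in self._all_modules():
            if isinstance(m, nn.Dropout):
                m.rng = rng

    def _all_modules(self) -> list[nn.Module]:
        out, stack = [], [self]
        while stack:
            m = stack.pop()
            out.append(m)
            stack.extend(m.children())
        return out

    # -- forward/backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (batch, {self.cfg.in_channels}, T) input")
        if self.cfg.use_rcm:
            h = self.drop1.forward(self.block1.forward(x))
            branch = self.drop2.forward(self.block2.forward(h))
        else:
            branch = self.input_pool.forward(self.input_proj.forward(x))
        self._stage["rcm"] = branch
        main = branch
        if self.cfg.use_dcpm:
            for layer in self.pyramid:
                main = layer.forward(main)
        self._stage["dcpm"] = main
        fused = self.ffem.forward(branch, main)
        self._stage["fused"] = fused
        h = self.head_drop.forward(self.head_relu.forward(
            self.head_bn.forward(fused)))
        return self.fc.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head_bn.backward(self.head_relu.backward(
            self.head_drop.backward(self.fc.backward(dlogits))))
        dbranch, dmain = self.ffem.backward(d)
        if self.cfg.use_dcpm:
            for layer in reversed(self.pyramid):
                dmain = layer.backward(dmain)
        dbranch = dbranch + dmain
        if self.cfg.use_rcm:
            self.block1.backward(self.drop1.backward(
                self.block2.backward(self.drop2.backward(dbranch))))
        else:
            self.input_proj.backward(self.input_pool.backward(dbranch))

    def features(self, stage: str) -> np.ndarray:
        """Per-segment feature vectors of the last forward pass.

        Convolutional stages (``rcm``, ``dcpm``) are max-pooled over
        time; ``fused`` returns the fusion vector itself.
        """
        if stage not in ("rcm", "dcpm", "fused"):
            raise ConfigurationError(f"unknown feature stage {stage!r}")
        fm = self._stage[stage]
        return fm if fm.ndim == 2 else fm.max(axis=2)


class _ConvBNReLU(nn.Module):
    def __init__(self, in_c: int, out_c: int, kernel: int, dilation: int,
                 padding: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = nn.Conv1d(in_c, out_c, kernel, dilation=dilation,
                              padding=padding, rng=rng)
        self.bn = nn.BatchNorm(out_c)
        self.relu = nn.ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


def build_model(cfg: ModelConfig, seed: int = 0) -> RDPNet:
    """Instantiate the network with seeded weight initialization."""
    return RDPNet(cfg, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalars: convolution and linear weights, the
    linear bias, and all normalization scale/shift parameters."""
    return sum(p.data.size for p in model.parameters())


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_proba(logits: np.ndarray) -> np.ndarray:
    return softmax(logits)


def _checkpoint_paths(path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    return path, path.with_suffix(".json")


def save_checkpoint(model: RDPNet, path: str | Path) -> None:
    """Write weights (npz) plus a JSON sidecar with the configuration."""
    weights, sidecar = _checkpoint_paths(path)
    with open(weights, "wb") as fh:
        np.savez(fh, **model.state_arrays())
    sidecar.write_text(json.dumps(model.cfg.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> RDPNet:
    """Rebuild a network from ``save_checkpoint`` output; the config
    round-trips losslessly through the JSON sidecar."""
    weights, sidecar = _checkpoint_paths(path)
    cfg = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    model = RDPNet(cfg)
    with np.load(weights) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    return model


def dcpm_layer_specs(cfg: ModelConfig) -> list[LayerSpec]:
    """The pyramid as a LayerSpec cascade (for receptive field reports)."""
    return [LayerSpec(kernel=cfg.dcpm_kernel, dilation=d)
            for d in cfg.dcpm_dilations]


def ablation_configs(cfg: ModelConfig) -> dict[str, ModelConfig]:
    """The published ablation sweep: full model and one module removed
    at a time."""
    return {
        "full": cfg,
        "wo_rcm": replace(cfg, use_rcm=False),
        "wo_dcpm": replace(cfg, use_dcpm=False),
        "wo_entropy": replace(cfg, use_entropy=False),
    }
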