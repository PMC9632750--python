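"""Fusion architectures over multiple convolutional branches.

Three strategies combine N backbone feature maps into one classifier:

* ``conv_reduce`` — branches with larger spatial maps pass through a
  'valid' 3x3 stride-1 convolution (channel count preserved) so all maps
  share the smallest spatial dims, then channel concatenation, CBAM,
  global average pooling and a dense softmax head;
* ``zero_pad`` — smaller maps are surrounded by rings of zeros up to the
  largest spatial dims, then the same concat/CBAM/GAP/dense head;
* ``dense_concat`` — classifier-level fusion: each branch keeps its own
  CBAM + GAP + dense feature vector and an auxiliary softmax head; the
  three feature vectors are concatenated into a merged softmax head, so
  the network exposes four outputs and trains on the sum of four losses.

Parallel elementwise fusion (``sum``/``mean``/``max``) is also provided
for branches with identical map geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backbones.tiny import BackboneSpec
from .nn import autodiff as ad
from .nn.autodiff import Var
from .nn.layers import CBAM, Conv2D, Dense, GlobalAvgPool, Module, ReLU

PARALLEL_MODES = ("sum", "mean", "max")
STRATEGIES = ("conv_reduce", "zero_pad", "dense_concat") + PARALLEL_MODES


# ---------------------------------------------------------------------------
# dimension arithmetic
# ---------------------------------------------------------------------------

@dataclass
class ConvDimSpec:
    """Output-size arithmetic of a convolution:
    ``out = (in - F + 2P) / S + 1`` per spatial dimension."""

    w_in: int
    h_in: int
    f: int
    p: int = 0
    s: int = 1
    w_out: int | None = None
    h_out: int | None = None


def conv_output_dims(spec: ConvDimSpec) -> ConvDimSpec:
    """Complete a :class:`ConvDimSpec`; non-integral sizes are hard errors."""
    done = {}
    for dim, size in (("w_out", spec.w_in), ("h_out", spec.h_in)):
        num = size - spec.f + 2 * spec.p
        if num % spec.s != 0:
            raise ValueError(
                f"{dim}: ({size} - {spec.f} + 2*{spec.p}) is not divisible "
                f"by stride {spec.s}")
        out = num // spec.s + 1
        if out <= 0:
            raise ValueError(f"{dim}: non-positive output size {out}")
        done[dim] = out
    return replace(spec, **done)


def fuse_parallel(maps: list[np.ndarray], mode: str) -> np.ndarray:
    """Elementwise combination of same-shape feature maps."""
    if mode not in PARALLEL_MODES:
        raise ValueError(f"mode must be one of {PARALLEL_MODES}")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(
            f"parallel fusion requires identical map shapes, got {shapes}")
    stack = np.stack(maps)
    if mode == "sum":
        return stack.sum(axis=0)
    if mode == "mean":
        return stack.mean(axis=0)
    return stack.max(axis=0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FusionConfig:
    """Declarative description of a fusion model."""

    strategy: str
    backbones: list[BackboneSpec]
    n_classes: int
    use_cbam: bool | list[bool] = True
    branch_dense_units: int = 256
    cbam_reduction: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; "
                             f"choose from {STRATEGIES}")
        if len(self.backbones) < 2:
            raise ValueError("fusion needs at least 2 backbones")
        if isinstance(self.use_cbam, (list, tuple)):
            if len(self.use_cbam) != len(self.backbones):
                raise ValueError("per-branch use_cbam list must match "
                                 "the number of backbones")

    def branch_cbam(self, i: int) -> bool:
        if isinstance(self.use_cbam, (list, tuple)):
            return bool(self.use_cbam[i])
        return bool(self.use_cbam)


@dataclass
class ForwardResult:
    """Outputs of one forward pass (autodiff nodes retained for saliency)."""

    logits: Var
    aux_logits: list[Var] = field(default_factory=list)
    branch_maps: dict[str, Var] = field(default_factory=dict)

    @property
    def probs(self) -> np.ndarray:
        return ad.softmax(self.logits.data)

    @property
    def aux_probs(self) -> list[np.ndarray]:
        return [ad.softmax(v.data) for v in self.aux_logits]


def _auto_reduction(channels: int, requested: int) -> int:
    """Largest divisor of ``channels`` not exceeding the requested ratio."""
    r = min(requested, channels)
    while channels % r != 0:
        r -= 1
    return r


class _Branch(Module):
    def __init__(self, spec: BackboneSpec, input_shape, cfg: FusionConfig,
                 use_cbam: bool, rng: np.random.Generator):
        self.name = spec.name
        self.backbone = spec.build(input_shape, rng)
        out_map = getattr(self.backbone, "out_map", spec.expected_map)
        if out_map is None:
            raise ValueError(
                f"backbone {spec.name!r} declares no output map geometry")
        if spec.expected_map is not None and tuple(out_map) != tuple(spec.expected_map):
            raise ValueError(
                f"backbone {spec.name!r} emits {out_map}, expected "
                f"{spec.expected_map}")
        self.out_map = tuple(out_map)
        c = self.out_map[2]
        self.cbam = (CBAM(c, _auto_reduction(c, cfg.cbam_reduction), rng=rng,
                          name=f"{spec.name}.cbam") if use_cbam else None)

    def __call__(self, x: Var) -> tuple[Var, Var]:
        """Return (backbone map, post-attention map)."""
        fmap = self.backbone(x)
        att = self.cbam(fmap) if self.cbam is not None else fmap
        return fmap, att


class FusionModel(Module):
    """A built fusion network; see the module docstring for the strategies."""

    def __init__(self, cfg: FusionConfig,
                 input_shape: tuple[int, int, int]):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        self.strategy = cfg.strategy
        per_branch_cbam = cfg.strategy == "dense_concat"
        self.branches = [
            _Branch(spec, input_shape, cfg,
                    use_cbam=cfg.branch_cbam(i) and per_branch_cbam, rng=rng)
            for i, spec in enumerate(cfg.backbones)]
        maps = [b.out_map for b in self.branches]
        self.reducers: list[Module | None] = [None] * len(maps)
        self.pad_rings = [0] * len(maps)

        if cfg.strategy in PARALLEL_MODES:
            if len(set(maps)) != 1:
                raise ValueError(
                    f"parallel fusion ({cfg.strategy}) requires identical "
                    f"branch map shapes, got {maps}")
            fused_c = maps[0][2]
        elif cfg.strategy == "conv_reduce":
            th = min(m[0] for m in maps)
            tw = min(m[1] for m in maps)
            for i, (h, w, c) in enumerate(maps):
                if (h, w) == (th, tw):
                    continue
                want = conv_output_dims(ConvDimSpec(w_in=w, h_in=h, f=3, p=0, s=1))
                if (want.h_out, want.w_out) != (th, tw):
                    raise ValueError(
                        f"branch {self.branches[i].name!r} map ({h},{w}) is "
                        f"not reconcilable to ({th},{tw}) by one 3x3 valid "
                        f"convolution; consider the zero_pad strategy")
                self.reducers[i] = Conv2D(c, c, 3, rng=rng,
                                          name=f"reduce{i}")
            fused_c = sum(m[2] for m in maps)
        elif cfg.strategy == "zero_pad":
            th = max(m[0] for m in maps)
            tw = max(m[1] for m in maps)
            for i, (h, w, c) in enumerate(maps):
                dh, dw = th - h, tw - w
                if dh != dw or dh % 2 != 0:
                    raise ValueError(
                        f"branch {self.branches[i].name!r} map ({h},{w}) "
                        f"cannot be ring-padded to ({th},{tw})")
                self.pad_rings[i] = dh // 2
            fused_c = sum(m[2] for m in maps)
        else:  # dense_concat
            fused_c = None

        n_cls = cfg.n_classes
        units = cfg.branch_dense_units
        if cfg.strategy == "dense_concat":
            self.branch_dense = [Dense(b.out_map[2], units, rng=rng,
                                       name=f"{b.name}.dense")
                                 for b in self.branches]
            self.aux_heads = [Dense(units, n_cls, rng=rng,
                                    name=f"{b.name}.aux")
                              for b in self.branches]
            self.merged_head = Dense(units * len(self.branches), n_cls,
                                     rng=rng, name="merged")
            self.fused_cbam = None
        else:
            want_cbam = (any(cfg.use_cbam)
                         if isinstance(cfg.use_cbam, (list, tuple))
                         else bool(cfg.use_cbam))
            self.fused_cbam = (CBAM(fused_c,
                                    _auto_reduction(fused_c, cfg.cbam_reduction),
                                    rng=rng, name="fused.cbam")
                               if want_cbam else None)
            self.fused_dense = Dense(fused_c, units, rng=rng, name="fused.dense")
            self.head = Dense(units, n_cls, rng=rng, name="head")
        self.gap = GlobalAvgPool()

    # -- parameter groups -------------------------------------------------
    def backbone_params(self):
        out = []
        for b in self.branches:
            out.extend(b.backbone.params())
        return out

    def head_params(self):
        backbone = {id(p) for p in self.backbone_params()}
        return [p for p in self.params() if id(p) not in backbone]

    def freeze_backbones(self) -> None:
        for p in self.backbone_params():
            p.trainable = False

    def unfreeze_all(self) -> None:
        for p in self.params():
            p.trainable = True

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray | Var) -> ForwardResult:
        if not isinstance(x, Var):
            x = Var(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 3:
            x = ad.reshape(x, (1,) + x.data.shape)
        branch_maps: dict[str, Var] = {}
        fmaps, atts = [], []
        for b in self.branches:
            fmap, att = b(x)
            branch_maps[b.name] = att
            fmaps.append(fmap)
            atts.append(att)

        if self.strategy == "dense_concat":
            feats, aux = [], []
            for att, dense, head in zip(atts, self.branch_dense, self.aux_heads):
                f = ad.relu(dense(self.gap(att)))
                feats.append(f)
                aux.append(head(f))
            logits = self.merged_head(ad.concat(feats, axis=-1))
            return ForwardResult(logits=logits, aux_logits=aux,
                                 branch_maps=branch_maps)

        if self.strategy in PARALLEL_MODES:
            fused = atts[0]
            rest = atts[1:]
            if self.strategy == "max":
                for m in rest:
                    fused = ad.maximum(fused, m)
            else:
                for m in rest:
                    fused = ad.add(fused, m)
                if self.strategy == "mean":
                    fused = ad.scale(fused, 1.0 / len(atts))
        else:
            aligned = []
            for i, att in enumerate(atts):
                if self.reducers[i] is not None:
                    att = self.reducers[i](att)
                if self.pad_rings[i]:
                    att = ad.pad2d(att, self.pad_rings[i])
                aligned.append(att)
            fused = ad.concat(aligned, axis=-1)
        branch_maps["merged"] = fused
        if self.fused_cbam is not None:
            fused = self.fused_cbam(fused)
        z = ad.relu(self.fused_dense(self.gap(fused)))
        return ForwardResult(logits=self.head(z), branch_maps=branch_maps)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self.forward(x[i:i + batch_size]).probs
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    @property
    def n_outputs(self) -> int:
        return 1 + (len(self.branches) if self.strategy == "dense_concat" else 0)

    def summary(self) -> str:
        lines = [f"FusionModel(strategy={self.strategy}, "
                 f"input={self.input_shape}, n_classes={self.cfg.n_classes})"]
        for b in self.branches:
            cb = "+CBAM" if b.cbam is not None else ""
            lines.append(f"  branch {b.name}: map {b.out_map}{cb}")
        lines.append(f"  outputs: {self.n_outputs}")
        lines.append(f"  parameters: {sum(p.data.size for p in self.params())}")
        return "\n".join(lines)


def build_branch(spec: BackboneSpec, cfg: FusionConfig,
                 input_shape: tuple[int, int, int],
                 rng: np.random.Generator | None = None) -> _Branch:
    """One backbone -> CBAM -> (GAP/dense handled by the parent model)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return _Branch(spec, input_shape, cfg, use_cbam=True, rng=rng)


def _build(strategy: str, cfg: FusionConfig, input_shape) -> FusionModel:
    cfg = replace(cfg, strategy=strategy)
    return FusionModel(cfg, input_shape)


def save_model(model: FusionModel, path) -> None:
    """Serialize a fusion model (config recipe + parameter arrays) to .npz.

    Only models whose backbones carry a serializable descriptor (the tiny
    trainable backbones do) can be saved.
    """
    import json

    descs = []
    for spec in model.cfg.backbones:
        if spec.descriptor is None:
            raise ValueError(f"backbone {spec.name!r} is not serializable")
        descs.append(spec.descriptor)
    meta = {
        "strategy": model.cfg.strategy,
        "n_classes": model.cfg.n_classes,
        "use_cbam": model.cfg.use_cbam,
        "branch_dense_units": model.cfg.branch_dense_units,
        "cbam_reduction": model.cfg.cbam_reduction,
        "seed": model.cfg.seed,
        "input_shape": list(model.input_shape),
        "backbones": descs,
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> FusionModel:
    import json

    from .backbones.tiny import tiny_backbone

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        specs = [tiny_backbone(d["seed"], tuple(d["out_map"]),
                               width=d["width"], name=d["name"])
                 for d in meta["backbones"]]
        cfg = FusionConfig(strategy=meta["strategy"], backbones=specs,
                           n_classes=meta["n_classes"],
                           use_cbam=meta["use_cbam"],
                           branch_dense_units=meta["branch_dense_units"],
                           cbam_reduction=meta["cbam_reduction"],
                           seed=meta["seed"])
        model = FusionModel(cfg, tuple(meta["input_shape"]))
        for i, p in enumerate(model.params()):
            saved = data[f"p{i}"]
            if saved.shape != p.data.shape:
                raise ValueError("checkpoint does not match the rebuilt model")
            p.data = saved.astype(np.float32)
    return model


def build_fusion_conv_reduce(cfg: FusionConfig, input_shape) -> FusionModel:
    return _build("conv_reduce", cfg, input_shape)


def build_fusion_zero_pad(cfg: FusionConfig, input_shape) -> FusionModel:
    return _build("zero_pad", cfg, input_shape)


def build_fusion_dense_concat(cfg: FusionConfig, input_shape) -> FusionModel:
    return _build("dense_concat", cfg, input_shape)
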