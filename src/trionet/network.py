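"""Trio genotyping networks: One-to-One, Trio-to-One and Trio-to-Trio variants.

All models share a convolutional trunk (conv -> residual blocks -> spatial
pyramid pooling -> dense) over pileup feature tensors and end in per-sample
softmax heads over the 21 genotype classes.  The Trio-to-Trio architecture
consumes the trio-stacked tensor (three samples' read rows concatenated per
channel in family order child, parent1, parent2) and emits all three samples'
genotype distributions from one model; Trio-to-One consumes the stacked
tensor but predicts a single member; One-to-One sees only one sample's block.

Trio-to-Trio comes in four shapes differing in where the computation splits
into per-sample branches:

* shape A — one shared trunk and shared dense layer; only the final dense
  layer is divided into three heads (the default).
* shape B — shared trunk; three fully separate dense stacks.
* shape C — the trunk is applied per sample with shared weights; features
  are concatenated before a shared dense layer and a divided final layer.
* shape D — like A but with an extra shared residual block before the split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genotype_space import N_GENOTYPES
from .losses import softmax
from .nn import Conv2d, Dense, Layer, Param, PyramidPool, ReLU, ResBlock, Sequential

__all__ = [
    "ModelConfig",
    "NetworkModel",
    "TrioPrediction",
    "build_model",
    "predict",
    "load_model",
    "TRIO_SAMPLES",
]

TRIO_SAMPLES = ("child", "parent1", "parent2")

#: class counts of the optional auxiliary heads
AUX_HEAD_SIZES = {"zygosity": 3, "indel_length_1": 33, "indel_length_2": 33}


class ShapeMismatchError(ValueError):
    """Input tensor shape incompatible with the model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and capacity knobs.

    ``heads`` always contains genotype21; auxiliary tasks (zygosity and the
    two INDEL-length heads) may be enabled per sample but are off by default.
    """

    architecture: str = "trio_to_trio"
    shape: str = "A"
    channels: int = 16
    n_res_blocks: int = 1
    kernel: int = 3
    pool_bins: tuple[int, ...] = (1, 2, 4)
    dense_width: int = 128
    heads: tuple[str, ...] = ("genotype21",)
    l2_weight: float = 0.0
    output_sample: str = "child"  # trio_to_one only

    def __post_init__(self) -> None:
        if self.architecture not in ("one_to_one", "trio_to_one", "trio_to_trio"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "trio_to_trio" and self.shape not in "ABCD":
            raise ValueError(f"unknown trio_to_trio shape {self.shape!r}")
        if "genotype21" not in self.heads:
            raise ValueError("the genotype21 head is mandatory")
        for h in self.heads:
            if h != "genotype21" and h not in AUX_HEAD_SIZES:
                raise ValueError(f"unknown head {h!r}")


@dataclass
class TrioPrediction:
    """Per-sample genotype distributions for a batch of candidate sites."""

    p_child: np.ndarray
    p_parent1: np.ndarray
    p_parent2: np.ndarray
    aux: dict = field(default_factory=dict)
    site_ids: np.ndarray | None = None

    def sample(self, name: str) -> np.ndarray:
        return {"child": self.p_child, "parent1": self.p_parent1, "parent2": self.p_parent2}[name]


def _build_trunk(cfg: ModelConfig, c_in: int, n_res: int, rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = [Conv2d(c_in, cfg.channels, cfg.kernel, rng), ReLU()]
    layers += [ResBlock(cfg.channels, cfg.kernel, rng) for _ in range(n_res)]
    layers.append(PyramidPool(cfg.pool_bins))
    return Sequential(*layers)


def _head_sizes(cfg: ModelConfig) -> dict[str, int]:
    return {
        h: (N_GENOTYPES if h == "genotype21" else AUX_HEAD_SIZES[h]) for h in cfg.heads
    }


class NetworkModel:
    """A built network: shared feature stages plus per-sample task heads.

    ``forward_logits`` caches activations for ``backward``; inference goes
    through :meth:`predict_probs`, which is deterministic for fixed weights.
    """

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int, int], seed: int = 0):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = config
        c_in, window, width = self.input_shape
        if c_in != 8:
            raise ShapeMismatchError(f"expected 8 feature channels, got {c_in}")
        if cfg.architecture != "one_to_one" and width % 3 != 0:
            raise ShapeMismatchError(
                f"trio architectures need a trio-stacked depth axis divisible by 3, got {width}"
            )

        spp = cfg.channels * sum(b * b for b in cfg.pool_bins)
        sizes = _head_sizes(cfg)
        self.out_samples = (
            TRIO_SAMPLES
            if cfg.architecture == "trio_to_trio"
            else ((cfg.output_sample,) if cfg.architecture == "trio_to_one" else ("sample",))
        )
        n_res = cfg.n_res_blocks + (1 if cfg.architecture == "trio_to_trio" and cfg.shape == "D" else 0)
        self._per_sample_trunk = cfg.architecture == "trio_to_trio" and cfg.shape == "C"

        self.trunk = _build_trunk(cfg, c_in, n_res, rng)
        if cfg.architecture == "trio_to_trio" and cfg.shape == "B":
            self.neck: Sequential | None = None
            self.heads = {
                s: {
                    t: Sequential(Dense(spp, cfg.dense_width, rng), ReLU(), Dense(cfg.dense_width, n, rng))
                    for t, n in sizes.items()
                }
                for s in self.out_samples
            }
        else:
            neck_in = spp * (3 if self._per_sample_trunk else 1)
            self.neck = Sequential(Dense(neck_in, cfg.dense_width, rng), ReLU())
            self.heads = {
                s: {t: Dense(cfg.dense_width, n, rng) for t, n in sizes.items()}
                for s in self.out_samples
            }

    # -- parameters -----------------------------------------------------------

    @property
    def params(self) -> list[Param]:
        out = list(self.trunk.params)
        if self.neck is not None:
            out += self.neck.params
        for s in self.out_samples:
            for head in self.heads[s].values():
                out += head.params
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def l2_term(self) -> float:
        if not self.config.l2_weight:
            return 0.0
        return float(
            self.config.l2_weight * sum((p.value**2).sum() for p in self.params if p.value.ndim > 1)
        )

    # -- forward / backward ---------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or tuple(x.shape[1:]) != self.input_shape:
            raise ShapeMismatchError(
                f"model expects (B, {', '.join(map(str, self.input_shape))}), got {x.shape}"
            )

    def forward_logits(self, x: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Training-mode forward; caches activations for :meth:`backward`."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=self.trunk.params[0].value.dtype)
        if self._per_sample_trunk:
            d = self.input_shape[2] // 3
            feats = [self.trunk.forward(x[:, :, :, s * d : (s + 1) * d]) for s in range(3)]
            feat = np.concatenate(feats, axis=1)
        else:
            feat = self.trunk.forward(x)
        if self.neck is not None:
            feat = self.neck.forward(feat)
        return {
            s: {t: head.forward(feat) for t, head in self.heads[s].items()}
            for s in self.out_samples
        }

    def backward(self, dlogits: dict[str, dict[str, np.ndarray]]) -> None:
        """Accumulate parameter gradients from per-head logit gradients."""
        dfeat: np.ndarray | None = None
        for s in self.out_samples:
            for t, head in self.heads[s].items():
                if t not in dlogits.get(s, {}):
                    continue
                d = head.backward(dlogits[s][t])
                dfeat = d if dfeat is None else dfeat + d
        if dfeat is None:
            return
        if self.neck is not None:
            dfeat = self.neck.backward(dfeat)
        if self._per_sample_trunk:
            spp = dfeat.shape[1] // 3
            for s in reversed(range(3)):  # LIFO order of the cached forwards
                self.trunk.backward(dfeat[:, s * spp : (s + 1) * spp])
        else:
            self.trunk.backward(dfeat)

    def predict_probs(self, x: np.ndarray, batch_size: int = 512) -> dict[str, dict[str, np.ndarray]]:
        """Inference: softmax distributions per sample and task."""
        self._check_input(x)
        chunks: list[dict[str, dict[str, np.ndarray]]] = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[lo : lo + batch_size])
            self._drop_caches()
            chunks.append(
                {s: {t: softmax(z) for t, z in per.items()} for s, per in logits.items()}
            )
        return {
            s: {t: np.concatenate([c[s][t] for c in chunks]) for t in chunks[0][s]}
            for s in chunks[0]
        }

    def _drop_caches(self) -> None:
        def clear(layer: Layer) -> None:
            layer._stack.clear()
            for sub in getattr(layer, "layers", []):
                clear(sub)
            for name in ("conv1", "conv2", "relu", "out_relu"):
                if hasattr(layer, name):
                    clear(getattr(layer, name))

        clear(self.trunk)
        if self.neck is not None:
            clear(self.neck)
        for s in self.out_samples:
            for head in self.heads[s].values():
                clear(head)

    # -- checkpointing --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weight container (.npz) with a JSON config sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params)}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    def copy(self) -> "NetworkModel":
        clone = NetworkModel(self.config, self.input_shape, self.seed)
        for dst, src in zip(clone.params, self.params):
            dst.value[...] = src.value
        return clone


def load_model(path: str | Path) -> NetworkModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_d = meta["config"]
    for key in ("pool_bins", "heads"):
        cfg_d[key] = tuple(cfg_d[key])
    model = NetworkModel(ModelConfig(**cfg_d), tuple(meta["input_shape"]), meta["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.params):
            p.value[...] = data[f"p{i}"]
    return model


def build_model(config: ModelConfig, input_shape: tuple[int, int, int], seed: int = 0) -> NetworkModel:
    """Construct a network for tensors of ``input_shape`` = (channels, window, depth).

    For trio architectures the depth axis is the trio-stacked one (three
    samples concatenated); for one_to_one it is a single sample's block.
    """
    return NetworkModel(config, input_shape, seed)


def predict(model: NetworkModel, tensors: np.ndarray, site_ids: np.ndarray | None = None) -> TrioPrediction:
    """Run inference and package the three genotype distributions.

    For single-output architectures the predicted sample's distribution is
    placed in its slot and the other slots are None.
    """
    probs = model.predict_probs(np.asarray(tensors))
    aux = {
        s: {t: p for t, p in per.items() if t != "genotype21"}
        for s, per in probs.items()
        if any(t != "genotype21" for t in per)
    }
    if model.config.architecture == "trio_to_trio":
        return TrioPrediction(
            p_child=probs["child"]["genotype21"],
            p_parent1=probs["parent1"]["genotype21"],
            p_parent2=probs["parent2"]["genotype21"],
            aux=aux,
            site_ids=site_ids,
        )
    (name,) = model.out_samples
    dist = probs[name]["genotype21"]
    slots = {"child": None, "parent1": None, "parent2": None}
    slots[name if name in slots else "child"] = dist
    return TrioPrediction(
        p_child=slots["child"],
        p_parent1=slots["parent1"],
        p_parent2=slots["parent2"],
        aux=aux,
        site_ids=site_ids,
    )
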