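"""Attention-based kinase-ligand affinity regressor and its six variants.

Every variant is assembled from five blocks: a convolution block and an input
attention block extract a feature vector per input branch, the branch vectors
are concatenated, an output attention block reweights the joint
representation, and a dense output block emits a single bioactivity value
(log10 nM).

Branches:

* **kinase** — for aligned-sequence modes, same-padded 1-D convolutions over
  alignment positions (one filter bank per kernel size), a position-wise
  multi-head self-attention layer, and mean pooling; for the identifier mode
  the length-1 "sequence" makes convolution vacuous, so a dense embedding of
  the catalog one-hot is used instead.
* **compound blocks** (PCPP, MCFP, MGFP, and 3CED when enabled) — a dense
  encoder with a learned sigmoid gating vector (feature attention).

Variants: ``1-*`` identifier, ``2-*`` active-site slice, ``3-*`` full
alignment; ``*-2`` adds the 3CED branch, ``*-1`` omits it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .nn import Parameter, Tensor

VARIANT_IDS = ("1-1", "1-2", "2-1", "2-2", "3-1", "3-2")
_KINASE_MODES = {"1": "identifier", "2": "active_site", "3": "full_alignment"}

#: 2D compound block lengths, fixed by the descriptor pipeline.
BLOCK_2D_LENGTHS = {"PCPP": 208, "MCFP": 167, "MGFP": 1792}


@dataclass(frozen=True)
class VariantSpec:
    """One of the six fixed input-representation variants."""

    variant_id: str

    def __post_init__(self) -> None:
        if self.variant_id not in VARIANT_IDS:
            raise ValueError(f"unknown variant {self.variant_id!r}; expected one of {VARIANT_IDS}")

    @property
    def kinase_mode(self) -> str:
        return _KINASE_MODES[self.variant_id[0]]

    @property
    def use_3ced(self) -> bool:
        return self.variant_id.endswith("2")

    @property
    def compound_blocks(self) -> tuple[str, ...]:
        return ("PCPP", "MCFP", "MGFP", "3CED") if self.use_3ced else ("PCPP", "MCFP", "MGFP")


@dataclass
class PredictorConfig:
    """Hyperparameters and input shapes of a predictor."""

    variant: VariantSpec
    kinase_length: int  # alignment width, active-site length, or catalog size
    kinase_channels: int  # 21 for sequence modes, catalog size for identifier
    ced_dim: int = 3348
    conv_channels: int = 64
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    attention_heads: int = 4
    embed_dim: int = 128
    head_dims: tuple[int, ...] = (256, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.variant, str):
            self.variant = VariantSpec(self.variant)
        for name in ("conv_channels", "attention_heads", "embed_dim", "kinase_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.embed_dim % self.attention_heads:
            raise ValueError("attention heads must divide the embedding width")
        if self.variant.kinase_mode == "identifier" and self.kinase_length != 1:
            raise ValueError("identifier variants take kinase input of length 1")

    @property
    def block_lengths(self) -> dict[str, int]:
        out = dict(BLOCK_2D_LENGTHS)
        if self.variant.use_3ced:
            out["3CED"] = self.ced_dim
        return out

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant.variant_id
        return d

    @classmethod
    def from_manifest(cls, d: Mapping) -> "PredictorConfig":
        d = dict(d)
        d["variant"] = VariantSpec(d["variant"])
        d["kernel_sizes"] = tuple(d["kernel_sizes"])
        d["head_dims"] = tuple(d["head_dims"])
        return cls(**d)


class ShapeError(ValueError):
    """Raised when an input does not match the predictor's contract."""


class Predictor:
    """A built model: parameter collection plus a deterministic forward pass."""

    def __init__(self, config: PredictorConfig):
        self.config = config
        self.params: dict[str, Parameter] = {}
        self._build(np.random.default_rng(config.seed))

    # -- construction ----------------------------------------------------------
    def _param(self, name: str, array: np.ndarray) -> Parameter:
        p = Parameter(array)
        self.params[name] = p
        return p

    def _dense(self, rng, name: str, n_in: int, n_out: int) -> None:
        self._param(f"{name}.W", nn.glorot(rng, (n_in, n_out)))
        self._param(f"{name}.b", np.zeros(n_out, dtype=np.float32))

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        E = cfg.embed_dim
        if cfg.variant.kinase_mode == "identifier":
            self._dense(rng, "kin.embed", cfg.kinase_channels, E)
        else:
            for k in cfg.kernel_sizes:
                self._param(
                    f"kin.conv{k}.W", nn.glorot(rng, (k, cfg.kinase_channels, cfg.conv_channels))
                )
                self._param(f"kin.conv{k}.b", np.zeros(cfg.conv_channels, dtype=np.float32))
            conv_out = cfg.conv_channels * len(cfg.kernel_sizes)
            self._dense(rng, "kin.proj", conv_out, E)
            for w in ("q", "k", "v", "o"):
                self._dense(rng, f"kin.attn.{w}", E, E)
            self._dense(rng, "kin.out", E, E)
        for name, length in cfg.block_lengths.items():
            self._dense(rng, f"cmp.{name}.enc", length, E)
            self._dense(rng, f"cmp.{name}.gate", length, E)
        joint = E * (1 + len(cfg.variant.compound_blocks))
        self._dense(rng, "out.attn", joint, joint)
        widths = [joint, *cfg.head_dims, 1]
        for i, (a, b) in enumerate(zip(widths, widths[1:])):
            self._dense(rng, f"head.{i}", a, b)
        self.n_head_layers = len(widths) - 1

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward ----------------------------------------------------------------
    def _apply_dense(self, name: str, x: Tensor) -> Tensor:
        return nn.matmul(x, self.params[f"{name}.W"]) + self.params[f"{name}.b"]

    def _kinase_branch(self, kinase_inputs: Tensor) -> Tensor:
        """(n_kinases, L, C) one-hots -> (n_kinases, embed) vectors."""
        cfg = self.config
        if cfg.variant.kinase_mode == "identifier":
            flat = nn.reshape(kinase_inputs, (kinase_inputs.shape[0], cfg.kinase_channels))
            return nn.relu(self._apply_dense("kin.embed", flat))
        conv_outs = [
            nn.conv1d_same(
                kinase_inputs, self.params[f"kin.conv{k}.W"], self.params[f"kin.conv{k}.b"]
            )
            for k in cfg.kernel_sizes
        ]
        h = nn.relu(nn.concat(conv_outs, axis=-1))
        h = nn.relu(self._apply_dense("kin.proj", h))  # (n, L, E)
        h = self._self_attention(h)
        pooled = nn.t_mean(h, axis=1)  # (n, E)
        return nn.relu(self._apply_dense("kin.out", pooled))

    def _self_attention(self, x: Tensor) -> Tensor:
        """Position-wise multi-head self-attention, (n, L, E) -> (n, L, E)."""
        cfg = self.config
        n, L, E = x.shape
        h, dh = cfg.attention_heads, E // cfg.attention_heads

        def split_heads(t: Tensor) -> Tensor:
            t = nn.reshape(t, (n, L, h, dh))
            return nn.transpose(t, (0, 2, 1, 3))  # (n, h, L, dh)

        q = split_heads(self._apply_dense("kin.attn.q", x))
        k = split_heads(self._apply_dense("kin.attn.k", x))
        v = split_heads(self._apply_dense("kin.attn.v", x))
        scores = nn.mul(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))), 1.0 / math.sqrt(dh))
        attn = nn.softmax(scores, axis=-1)
        ctx = nn.matmul(attn, v)  # (n, h, L, dh)
        ctx = nn.reshape(nn.transpose(ctx, (0, 2, 1, 3)), (n, L, E))
        return self._apply_dense("kin.attn.o", ctx)

    def _compound_branch(self, name: str, x: Tensor) -> Tensor:
        enc = nn.relu(self._apply_dense(f"cmp.{name}.enc", x))
        gate = nn.sigmoid(self._apply_dense(f"cmp.{name}.gate", x))
        return nn.mul(gate, enc)

    def check_inputs(
        self, kinase_inputs: np.ndarray, kinase_index: np.ndarray, blocks: Mapping[str, np.ndarray]
    ) -> None:
        cfg = self.config
        expected = (cfg.kinase_length, cfg.kinase_channels)
        if tuple(kinase_inputs.shape[1:]) != expected:
            raise ShapeError(
                f"kinase branch expects (*, {expected[0]}, {expected[1]}), "
                f"got {tuple(kinase_inputs.shape)}"
            )
        want = set(cfg.variant.compound_blocks)
        got = set(blocks)
        if want != got:
            raise ShapeError(
                f"compound blocks mismatch for variant {cfg.variant.variant_id}: "
                f"expected {sorted(want)}, got {sorted(got)}"
            )
        n = len(kinase_index)
        for name, arr in blocks.items():
            exp_len = cfg.block_lengths[name]
            if arr.shape != (n, exp_len):
                raise ShapeError(
                    f"block {name} expects shape ({n}, {exp_len}), got {arr.shape}"
                )
        if np.any(kinase_index < 0) or np.any(kinase_index >= kinase_inputs.shape[0]):
            raise ShapeError("kinase_index out of range")

    def forward(
        self,
        kinase_inputs,
        kinase_index,
        blocks: Mapping[str, Tensor | np.ndarray],
    ) -> Tensor:
        """Batched forward pass returning a (batch,) bioactivity tensor.

        ``kinase_inputs`` holds one one-hot stack per *unique* kinase;
        ``kinase_index`` maps each batch row to its kinase, so the kinase
        branch runs once per kinase instead of once per record.
        """
        kin = nn.as_tensor(np.asarray(kinase_inputs, dtype=np.float32))
        idx = np.asarray(kinase_index, dtype=np.int64)
        block_t = {k: nn.as_tensor(np.asarray(v, dtype=np.float32)) for k, v in blocks.items()}
        self.check_inputs(kin.data, idx, {k: v.data for k, v in block_t.items()})
        kin_vec = nn.take_rows(self._kinase_branch(kin), idx)  # (B, E)
        branches = [kin_vec]
        for name in self.config.variant.compound_blocks:
            branches.append(self._compound_branch(name, block_t[name]))
        z = nn.concat(branches, axis=-1)
        z = nn.mul(z, nn.sigmoid(self._apply_dense("out.attn", z)))
        for i in range(self.n_head_layers):
            z = self._apply_dense(f"head.{i}", z)
            if i < self.n_head_layers - 1:
                z = nn.relu(z)
        return nn.reshape(z, (z.shape[0],))

    def predict(
        self,
        kinase_inputs,
        kinase_index,
        blocks: Mapping[str, np.ndarray],
        batch_size: int = 2048,
    ) -> np.ndarray:
        """Forward pass without gradients, chunked over the batch."""
        idx = np.asarray(kinase_index, dtype=np.int64)
        out = np.empty(len(idx), dtype=np.float64)
        for start in range(0, len(idx), batch_size):
            sl = slice(start, start + batch_size)
            chunk = {k: np.asarray(v)[sl] for k, v in blocks.items()}
            out[sl] = self.forward(kinase_inputs, idx[sl], chunk).data
        return out

    # -- state ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("parameter names do not match this predictor")
        for k, p in self.params.items():
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {k}")
            p.data = np.asarray(state[k], dtype=np.float32)

    def save(self, directory: str | os.PathLike) -> None:
        """Write weights (npz) plus a JSON config manifest."""
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.state_dict())
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(self.config.to_manifest(), fh, indent=2)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "Predictor":
        """Load a checkpoint; refuses weights against a mismatched manifest."""
        with open(os.path.join(directory, "manifest.json")) as fh:
            config = PredictorConfig.from_manifest(json.load(fh))
        pred = cls(config)
        with np.load(os.path.join(directory, "weights.npz")) as data:
            state = {k: data[k] for k in data.files}
        pred.load_state_dict(state)
        return pred


def build_predictor(config: PredictorConfig) -> Predictor:
    """Construct a predictor for a variant; seeded, deterministic weights."""
    return Predictor(config)
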