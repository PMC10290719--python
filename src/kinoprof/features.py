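"""Assembly of model-ready feature bundles from activity records.

A :class:`FeatureBundle` holds one kinase encoding stack per *unique* kinase,
a per-record index into that stack, and the per-record compound descriptor
blocks.  Compound descriptors are computed once per unique canonical SMILES
and broadcast to records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .curation import ActivityRecord
from .descriptors2d import feature_block_2d
from .kinases import ActiveSiteMap, KinaseCatalog
from .models import VariantSpec
from .pharm3d import SignatureSpace, build_signature_space, compute_3ced, generate_conformers


@dataclass
class FeatureBundle:
    """Featurized kinase-ligand pairs ready for the regressor."""

    kinase_inputs: np.ndarray  # (n_unique_kinases, L, C)
    kinase_index: np.ndarray  # (n_records,)
    blocks: dict[str, np.ndarray]  # name -> (n_records, length)
    y: np.ndarray | None
    kinase_ids: list[str]
    smiles: list[str]

    def __len__(self) -> int:
        return len(self.kinase_index)

    def subset(self, indices) -> "FeatureBundle":
        idx = np.asarray(indices)
        if idx.dtype != bool:
            idx = idx.astype(np.int64)
        return FeatureBundle(
            kinase_inputs=self.kinase_inputs,
            kinase_index=self.kinase_index[idx],
            blocks={k: v[idx] for k, v in self.blocks.items()},
            y=None if self.y is None else self.y[idx],
            kinase_ids=[self.kinase_ids[i] for i in idx],
            smiles=[self.smiles[i] for i in idx],
        )

    def with_blocks(self, blocks: dict[str, np.ndarray]) -> "FeatureBundle":
        return replace(self, blocks=blocks)


def featurize_records(
    records: Sequence[ActivityRecord],
    catalog: KinaseCatalog,
    variant: VariantSpec | str,
    site_map: ActiveSiteMap | None = None,
    space: SignatureSpace | None = None,
    max_conformers: int = 16,
    seed: int = 7,
    compound_cache: Mapping[str, dict[str, np.ndarray]] | None = None,
) -> FeatureBundle:
    """Build the feature bundle a variant expects from curated records.

    ``compound_cache`` may carry precomputed per-SMILES blocks (as produced by
    :func:`featurize_compounds`) to avoid recomputation across variants.
    """
    variant = VariantSpec(variant) if isinstance(variant, str) else variant
    kinase_inputs = catalog.encode_all(variant.kinase_mode, site_map=site_map).astype(np.float32)
    kinase_index = np.array([catalog.index(r.kinase_id) for r in records], dtype=np.int64)
    smiles = [r.compound_smiles for r in records]
    cache = dict(compound_cache or {})
    missing = sorted(set(smiles) - set(cache))
    if missing:
        cache.update(
            featurize_compounds(
                missing,
                space=space,
                with_3ced=variant.use_3ced,
                max_conformers=max_conformers,
                seed=seed,
            )
        )
    blocks: dict[str, np.ndarray] = {}
    for name in variant.compound_blocks:
        blocks[name] = np.stack([cache[s][name] for s in smiles]).astype(np.float32)
    y = np.array([r.bioactivity for r in records], dtype=np.float64)
    return FeatureBundle(
        kinase_inputs=kinase_inputs,
        kinase_index=kinase_index,
        blocks=blocks,
        y=y,
        kinase_ids=[r.kinase_id for r in records],
        smiles=smiles,
    )


def featurize_compounds(
    smiles_list: Iterable[str],
    space: SignatureSpace | None = None,
    with_3ced: bool = True,
    max_conformers: int = 16,
    seed: int = 7,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-SMILES descriptor blocks, keyed by the input SMILES string."""
    out: dict[str, dict[str, np.ndarray]] = {}
    if with_3ced:
        space = space or build_signature_space()
    for smi in smiles_list:
        vec = feature_block_2d(smi)
        entry = {name: vec.block(name).astype(np.float32) for name in vec.block_names}
        if with_3ced:
            ens = generate_conformers(smi, max_n=max_conformers, seed=seed)
            entry["3CED"] = compute_3ced(ens, space).values.astype(np.float32)
        out[smi] = entry
    return out


class FeatureScaler:
    """Per-feature standardisation of the real-valued descriptor blocks.

    Binary fingerprint blocks (MCFP, MGFP) are left untouched; PCPP and 3CED
    are standardised to zero mean and unit variance using statistics from the
    fitted (training) rows only.  Kinase one-hots are never scaled.
    """

    SCALED_BLOCKS = ("PCPP", "3CED")

    def __init__(self) -> None:
        self.stats_: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def fit(self, bundle: FeatureBundle, indices=None) -> "FeatureScaler":
        self.stats_ = {}
        for name in self.SCALED_BLOCKS:
            if name not in bundle.blocks:
                continue
            x = bundle.blocks[name]
            if indices is not None:
                x = x[np.asarray(indices)]
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            self.stats_[name] = (mu.astype(np.float32), sd.astype(np.float32))
        return self

    def transform(self, bundle: FeatureBundle) -> FeatureBundle:
        if not self.stats_ and any(b in bundle.blocks for b in self.SCALED_BLOCKS):
            raise RuntimeError("FeatureScaler used before fit")
        blocks = dict(bundle.blocks)
        for name, (mu, sd) in self.stats_.items():
            blocks[name] = (bundle.blocks[name] - mu) / sd
        return bundle.with_blocks(blocks)

    def save(self, path) -> None:
        arrays = {}
        for name, (mu, sd) in self.stats_.items():
            arrays[f"{name}.mean"] = mu
            arrays[f"{name}.sd"] = sd
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FeatureScaler":
        scaler = cls()
        with np.load(path) as data:
            names = {k.rsplit(".", 1)[0] for k in data.files}
            for name in names:
                scaler.stats_[name] = (data[f"{name}.mean"], data[f"{name}.sd"])
        return scaler
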