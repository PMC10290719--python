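"""Desk-scale synthetic inputs: aligned kinase catalogs with group structure,
a compound library, and bioactivities with planted group selectivity.

The generator emulates the statistical structure of large kinome bioactivity
collections without mimicking real phylogeny or chemotypes: kinase groups
share a consensus domain sequence that differs from other groups at
informative alignment columns (including group-specific gap columns), group
members add per-column substitution noise, and bioactivity of a pair is

    baseline + kinase offset + compound descriptor signal
    + group effect (selective compounds only) + Gaussian noise,

all on the log10(nM) scale.  A selective compound is ``effect_size`` log
units more potent against its assigned group.  The compound descriptor
signal is a fixed sparse linear function of named physicochemical
descriptors (z-scored over the sampled library), so models have learnable
compound-side structure.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .curation import ActivityRecord, MeasurementType
from .descriptors2d import canonicalize, compute_pcpp, PCPP_NAMES
from .kinases import ActiveSiteMap, KinaseCatalog, KinaseEntry

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: kinase-group style labels used for synthetic catalogs
_GROUP_LABELS = ("TYR", "CMGC", "AGC", "CAMK", "STE", "CK1", "TKL", "NEK")

#: sparse linear compound signal: descriptor name -> weight (applied to
#: z-scores over the sampled library, then rescaled to descriptor_effect_sd)
COMPOUND_SIGNAL_WEIGHTS = {
    "MolLogP": 0.5,
    "TPSA": 0.4,
    "NumRotatableBonds": -0.3,
}


@dataclass
class SimConfig:
    n_kinases: int = 40
    alignment_width: int = 200
    n_groups: int = 5
    n_compounds: int = 125
    selective_fraction: float = 0.4
    effect_size: float = 2.0  # log10 units of added potency on the target group
    noise_sd: float = 0.3  # log10 units
    baseline: float = 4.0  # log10 nM (10 uM, weak)
    kinase_sd: float = 0.3  # per-kinase offset scale, log10 units
    descriptor_effect_sd: float = 0.7  # scale of the compound signal, log10 units
    substitution_rate: float = 0.05
    informative_fraction: float = 0.3
    gap_columns_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_kinases:
            raise ValueError("n_groups must not exceed n_kinases")
        if self.n_groups > len(_GROUP_LABELS):
            raise ValueError(f"at most {len(_GROUP_LABELS)} groups supported")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.alignment_width < 29:
            raise ValueError("alignment width must support a 29-column active-site map")
        if not 0 <= self.selective_fraction <= 1:
            raise ValueError("selective_fraction must lie in [0, 1]")


def simulate_catalog(config: SimConfig) -> tuple[KinaseCatalog, ActiveSiteMap]:
    """Group-structured aligned kinase catalog plus a 29-column site map.

    Each group owns a consensus sequence differing from the base at the
    informative columns and carrying gaps at group-specific columns; members
    add substitution noise, so within-group identity exceeds between-group
    identity.  The active-site map covers 29 of the informative columns.
    """
    rng = np.random.default_rng(config.seed)
    W = config.alignment_width
    base = rng.integers(0, 20, size=W)
    n_info = max(29, int(config.informative_fraction * W))
    reserved_gaps = config.n_groups * config.gap_columns_per_group
    cols = rng.permutation(W)
    gap_cols = cols[:reserved_gaps].reshape(config.n_groups, config.gap_columns_per_group)
    info_cols = np.sort(cols[reserved_gaps : reserved_gaps + n_info])

    group_names = list(_GROUP_LABELS[: config.n_groups])
    consensi = []
    for g in range(config.n_groups):
        cons = base.copy()
        # group-specific residues at informative columns
        cons[info_cols] = (base[info_cols] + rng.integers(1, 20, size=n_info)) % 20
        consensi.append(cons)

    # round-robin group membership keeps group sizes balanced
    entries = []
    for i in range(config.n_kinases):
        g = i % config.n_groups
        seq = consensi[g].copy()
        mutate = rng.random(W) < config.substitution_rate
        seq[mutate] = (seq[mutate] + rng.integers(1, 20, size=int(mutate.sum()))) % 20
        chars = [_AA20[a] for a in seq]
        for c in gap_cols[g]:
            chars[c] = "-"
        entries.append(
            KinaseEntry(
                kinase_id=f"KIN{i + 1:03d}",
                group=group_names[g],
                aligned_seq="".join(chars),
            )
        )
    site_cols = np.sort(rng.choice(info_cols, size=29, replace=False))
    return KinaseCatalog(entries), ActiveSiteMap(tuple(int(c) for c in site_cols))


def library_smiles() -> list[str]:
    """The committed synthetic compound library (canonical SMILES)."""
    text = resources.files("kinoprof.data").joinpath("compound_library.smi").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def sample_compounds(n: int, seed: int = 0) -> list[str]:
    """Seeded sample of n distinct canonical SMILES from the library."""
    lib = library_smiles()
    if n > len(lib):
        raise ValueError(f"requested {n} compounds but the library holds {len(lib)}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(lib))[:n]
    return [canonicalize(lib[i]).canonical_smiles for i in idx]


@dataclass
class SyntheticDataset:
    """Simulated records plus the planted ground truth."""

    records: list[ActivityRecord]
    planted_group: dict[str, str | None]  # compound -> assigned group (None if non-selective)
    compound_signal: dict[str, float]
    kinase_offset: dict[str, float]
    config: SimConfig


def _compound_signal(compounds: Sequence[str], sd: float) -> dict[str, float]:
    names = list(COMPOUND_SIGNAL_WEIGHTS)
    idx = [PCPP_NAMES.index(n) for n in names]
    mat = np.array([compute_pcpp(c)[idx] for c in compounds], dtype=np.float64)
    mu, sigma = mat.mean(axis=0), mat.std(axis=0)
    sigma[sigma == 0] = 1.0
    z = (mat - mu) / sigma
    raw = z @ np.array([COMPOUND_SIGNAL_WEIGHTS[n] for n in names])
    s = raw.std()
    if s > 0:
        raw = raw * (sd / s)
    return dict(zip(compounds, raw))


def simulate_bioactivity(
    catalog: KinaseCatalog,
    compounds: Sequence[str],
    config: SimConfig,
) -> SyntheticDataset:
    """Simulate one IC50 record per kinase-compound pair.

    Selective compounds (the first ``selective_fraction`` share, assigned to
    groups round-robin) are ``effect_size`` log units more potent against
    their group.  Records are emitted as IC50 values in nM whose log10 equals
    the simulated bioactivity.
    """
    if not compounds:
        raise ValueError("no compounds given")
    rng = np.random.default_rng(config.seed + 1)
    groups = sorted(set(e.group for e in catalog.entries))
    n_selective = int(round(config.selective_fraction * len(compounds)))
    planted: dict[str, str | None] = {}
    for i, c in enumerate(compounds):
        planted[c] = groups[i % len(groups)] if i < n_selective else None
    signal = _compound_signal(compounds, config.descriptor_effect_sd)
    kin_off = {
        e.kinase_id: float(rng.normal(0.0, config.kinase_sd)) for e in catalog.entries
    }
    records = []
    for c in compounds:
        for e in catalog.entries:
            b = config.baseline + kin_off[e.kinase_id] + signal[c]
            if planted[c] is not None and e.group == planted[c]:
                b -= config.effect_size
            if config.noise_sd > 0:
                b += float(rng.normal(0.0, config.noise_sd))
            records.append(
                ActivityRecord.from_bioactivity(
                    kinase_id=e.kinase_id,
                    compound_smiles=c,
                    bioactivity=b,
                    measurement_type=MeasurementType.IC50,
                    source="synthetic",
                )
            )
    return SyntheticDataset(
        records=records,
        planted_group=planted,
        compound_signal=signal,
        kinase_offset=kin_off,
        config=config,
    )


def simulate_dataset(config: SimConfig | None = None):
    """Catalog, site map, compounds and records in one call."""
    config = config or SimConfig()
    catalog, site_map = simulate_catalog(config)
    compounds = sample_compounds(config.n_compounds, seed=config.seed + 2)
    data = simulate_bioactivity(catalog, compounds, config)
    return catalog, site_map, compounds, data
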