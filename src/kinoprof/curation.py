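"""Parsing, filtering, unit normalisation, deduplication and splitting of
kinase-ligand activity tables.

Bioactivity is defined throughout as log10 of a potency measurement (IC50 or
Ki) expressed in nM, so 1 uM maps to exactly 3.0 and lower values mean more
potent compounds.  Only IC50 and Ki measurements are retained; rows lacking a
kinase identifier, a parseable structure, or a usable value are dropped and
logged with a machine-readable reason.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd


class MeasurementType(str, Enum):
    IC50 = "IC50"
    KI = "Ki"


#: multiplicative factors converting a unit to nM (case-insensitive lookup)
UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,  # micro sign
    "μm": 1e3,  # greek mu
    "mm": 1e6,
    "m": 1e9,
}


class TableFormatError(ValueError):
    """Raised when an activity table's header does not match the column map."""


def to_bioactivity(value: float, unit: str = "nM") -> float:
    """log10 of a potency value after conversion to nM.

    >>> to_bioactivity(1, "uM")
    3.0
    """
    key = str(unit).strip().lower()
    if key not in UNIT_TO_NM:
        raise ValueError(f"unknown unit {unit!r}; expected one of nM/uM/mM/M")
    value = float(value)
    if not value > 0:
        raise ValueError(f"potency value must be positive, got {value}")
    return math.log10(value * UNIT_TO_NM[key])


def from_bioactivity(bioactivity: float) -> float:
    """Inverse of :func:`to_bioactivity`: potency in nM."""
    return 10.0 ** float(bioactivity)


@dataclass(frozen=True)
class ActivityRecord:
    """One kinase-ligand measurement on the log10(nM) scale."""

    kinase_id: str
    compound_smiles: str
    measurement_type: MeasurementType
    value_nM: float
    bioactivity: float
    source: str = ""
    n_merged: int = 1

    def __post_init__(self) -> None:
        if self.value_nM <= 0:
            raise ValueError("value_nM must be positive")
        if abs(self.bioactivity - math.log10(self.value_nM)) > 1e-9:
            raise ValueError(
                "bioactivity inconsistent with value_nM: "
                f"{self.bioactivity} vs log10({self.value_nM})"
            )
        if not isinstance(self.measurement_type, MeasurementType):
            object.__setattr__(
                self, "measurement_type", MeasurementType(self.measurement_type)
            )

    @classmethod
    def from_bioactivity(
        cls,
        kinase_id: str,
        compound_smiles: str,
        bioactivity: float,
        measurement_type: MeasurementType = MeasurementType.IC50,
        source: str = "",
        n_merged: int = 1,
    ) -> "ActivityRecord":
        return cls(
            kinase_id=kinase_id,
            compound_smiles=compound_smiles,
            measurement_type=measurement_type,
            value_nM=from_bioactivity(bioactivity),
            bioactivity=float(bioactivity),
            source=source,
            n_merged=n_merged,
        )


@dataclass(frozen=True)
class Rejection:
    """A dropped input row and the reason it was dropped."""

    row_index: int
    reason: str
    detail: str = ""


@dataclass
class SplitDataset:
    train: list
    test: list
    split_kind: str  # random_fold | strict_kinase | strict_compound

    def __post_init__(self) -> None:
        pairs_train = {(r.kinase_id, r.compound_smiles) for r in self.train}
        pairs_test = {(r.kinase_id, r.compound_smiles) for r in self.test}
        if pairs_train & pairs_test:
            raise ValueError("train and test share identical kinase-compound pairs")
        if self.split_kind == "strict_kinase":
            shared = {r.kinase_id for r in self.train} & {r.kinase_id for r in self.test}
            if shared:
                raise ValueError(f"kinases appear on both sides of a strict split: {shared}")
        elif self.split_kind == "strict_compound":
            shared = {r.compound_smiles for r in self.train} & {
                r.compound_smiles for r in self.test
            }
            if shared:
                raise ValueError(f"compounds appear on both sides of a strict split: {shared}")


_DEFAULT_COLUMNS = {
    "kinase": "kinase_id",
    "smiles": "smiles",
    "type": "measurement_type",
    "value": "value",
    "unit": "unit",
}


def parse_activity_table(
    stream,
    column_map: Mapping[str, str] | None = None,
    source: str = "",
    canonicalize_smiles: bool = True,
    sep: str | None = None,
) -> tuple[list[ActivityRecord], list[Rejection]]:
    """Parse a CSV/TSV activity export into records plus a rejection log.

    ``column_map`` maps the roles ``kinase``, ``smiles``, ``type``, ``value``,
    ``unit`` to the header names of the input table.  Rows missing a kinase
    id, structure or value, with a measurement type other than IC50/Ki, with a
    non-positive value, or with an unknown unit token are rejected and logged.
    ``|accepted| + |rejected|`` always equals the number of parsed rows.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(stream, sep=sep, engine="python")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise TableFormatError(f"activity table lacks columns {missing}; header={list(df.columns)}")

    if canonicalize_smiles:
        from .descriptors2d import MoleculeParseError, canonicalize

    records: list[ActivityRecord] = []
    rejections: list[Rejection] = []
    for idx, row in df.iterrows():
        kinase = row[colmap["kinase"]]
        smiles = row[colmap["smiles"]]
        mtype = row[colmap["type"]]
        value = row[colmap["value"]]
        unit = row[colmap["unit"]]
        if pd.isna(kinase) or str(kinase).strip() == "":
            rejections.append(Rejection(idx, "missing kinase"))
            continue
        if pd.isna(smiles) or str(smiles).strip() == "":
            rejections.append(Rejection(idx, "missing smiles"))
            continue
        if pd.isna(value) or str(value).strip() == "":
            rejections.append(Rejection(idx, "missing bioactivity"))
            continue
        mkey = str(mtype).strip().lower()
        if mkey not in ("ic50", "ki"):
            rejections.append(Rejection(idx, "measurement type", str(mtype)))
            continue
        try:
            value = float(value)
        except (TypeError, ValueError):
            rejections.append(Rejection(idx, "missing bioactivity", str(value)))
            continue
        try:
            bioactivity = to_bioactivity(value, str(unit))
        except ValueError as exc:
            reason = "unit" if "unit" in str(exc) else "nonpositive value"
            rejections.append(Rejection(idx, reason, str(unit) if reason == "unit" else str(value)))
            continue
        smiles = str(smiles).strip()
        if canonicalize_smiles:
            try:
                smiles = canonicalize(smiles).canonical_smiles
            except MoleculeParseError:
                rejections.append(Rejection(idx, "invalid smiles", smiles))
                continue
        records.append(
            ActivityRecord(
                kinase_id=str(kinase).strip(),
                compound_smiles=smiles,
                measurement_type=MeasurementType.IC50 if mkey == "ic50" else MeasurementType.KI,
                value_nM=value * UNIT_TO_NM[str(unit).strip().lower()],
                bioactivity=bioactivity,
                source=source,
            )
        )
    return records, rejections


def deduplicate_pairs(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse repeated (kinase, compound) measurements to their mean.

    The mean is taken on the log10(nM) bioactivity scale.  Output is sorted by
    (kinase_id, smiles) so the result is independent of input order.
    """
    groups: dict[tuple[str, str], list[ActivityRecord]] = {}
    for rec in records:
        groups.setdefault((rec.kinase_id, rec.compound_smiles), []).append(rec)
    out = []
    for (kinase, smiles), grp in sorted(groups.items()):
        if len(grp) == 1 and grp[0].n_merged == 1:
            out.append(grp[0])
            continue
        n = sum(g.n_merged for g in grp)
        mean_b = sum(g.bioactivity * g.n_merged for g in grp) / n
        sources = sorted({g.source for g in grp if g.source})
        out.append(
            ActivityRecord.from_bioactivity(
                kinase_id=kinase,
                compound_smiles=smiles,
                bioactivity=mean_b,
                measurement_type=grp[0].measurement_type,
                source="+".join(sources),
                n_merged=n,
            )
        )
    return out


def strict_split(
    records: Sequence[ActivityRecord],
    holdout_kinases: Iterable[str] | None = None,
    holdout_compounds: Iterable[str] | None = None,
) -> SplitDataset:
    """Hold out every record touching the given kinases (or compounds).

    Exactly one of ``holdout_kinases`` / ``holdout_compounds`` must be given.
    Holdout entities absent from the records trigger a warning; an empty
    training side raises.
    """
    if (holdout_kinases is None) == (holdout_compounds is None):
        raise ValueError("give exactly one of holdout_kinases or holdout_compounds")
    if holdout_kinases is not None:
        holdout = set(holdout_kinases)
        key = lambda r: r.kinase_id
        kind = "strict_kinase"
    else:
        holdout = set(holdout_compounds)
        key = lambda r: r.compound_smiles
        kind = "strict_compound"
    if not holdout:
        raise ValueError("holdout set is empty")
    present = {key(r) for r in records}
    absent = holdout - present
    if absent:
        warnings.warn(f"holdout entities absent from records: {sorted(absent)}")
    test = [r for r in records if key(r) in holdout]
    train = [r for r in records if key(r) not in holdout]
    if not train:
        raise ValueError("strict split leaves an empty training set")
    return SplitDataset(train=train, test=test, split_kind=kind)


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kinase_id": r.kinase_id,
                "smiles": r.compound_smiles,
                "bioactivity": r.bioactivity,
                "n_merged": r.n_merged,
                "source": r.source,
            }
            for r in records
        ]
    )


def write_table(records: Iterable[ActivityRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_table(path) -> list[ActivityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ActivityRecord.from_bioactivity(
            kinase_id=row.kinase_id,
            compound_smiles=row.smiles,
            bioactivity=row.bioactivity,
            source=getattr(row, "source", "") if not pd.isna(getattr(row, "source", "")) else "",
            n_merged=int(getattr(row, "n_merged", 1)),
        )
        for row in df.itertuples()
    ]


def write_rejections(rejections: Iterable[Rejection], path) -> None:
    pd.DataFrame(
        [{"row_index": r.row_index, "reason": r.reason, "detail": r.detail} for r in rejections],
        columns=["row_index", "reason", "detail"],
    ).to_csv(path, sep="\t", index=False)
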