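"""Kinase catalog and one-hot encodings over a structure-aligned kinase MSA.

Three encodings of a kinase are supported: a catalog-index one-hot
(*identifier*), the one-hot of the active-site columns of its aligned domain
sequence, and the one-hot of the full aligned sequence.  Sequence channels are
the 20 standard amino acids in alphabetical one-letter order followed by the
gap symbol ``-`` (21 channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

#: 20 standard amino acids (alphabetical one-letter codes) then the gap symbol.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
N_CHANNELS = len(AA_ALPHABET)  # 21
_CHANNEL_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
GAP = "-"


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or duplicate identifiers."""


@dataclass(frozen=True)
class KinaseEntry:
    kinase_id: str
    group: str
    aligned_seq: str


@dataclass
class KinaseCatalog:
    """Ordered kinase entries with equal-width aligned domain sequences.

    Entry order is stable and defines the identifier one-hot indices.
    """

    entries: list[KinaseEntry]
    alignment_width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("catalog must contain at least one kinase")
        widths = {len(e.aligned_seq) for e in self.entries}
        if len(widths) != 1:
            raise AlignmentFormatError(f"ragged alignment: sequence widths {sorted(widths)}")
        self.alignment_width = widths.pop()
        ids = [e.kinase_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate kinase ids: {dupes}")
        bad = {c for e in self.entries for c in e.aligned_seq} - set(AA_ALPHABET)
        if bad:
            raise AlignmentFormatError(f"non-standard characters in alignment: {sorted(bad)}")
        self._index = {e.kinase_id: i for i, e in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kinase_id: str) -> bool:
        return kinase_id in self._index

    def index(self, kinase_id: str) -> int:
        try:
            return self._index[kinase_id]
        except KeyError:
            raise KeyError(f"kinase {kinase_id!r} not in catalog") from None

    def entry(self, kinase_id: str) -> KinaseEntry:
        return self.entries[self.index(kinase_id)]

    @property
    def kinase_ids(self) -> list[str]:
        return [e.kinase_id for e in self.entries]

    @property
    def groups(self) -> dict[str, str]:
        return {e.kinase_id: e.group for e in self.entries}

    def encode_all(self, mode: str, site_map: "ActiveSiteMap | None" = None) -> np.ndarray:
        """Stack the chosen encoding for every catalog entry.

        Returns (n, 1, n) for ``identifier``, (n, |sites|, 21) for
        ``active_site`` and (n, width, 21) for ``full_alignment``.
        """
        if mode == "identifier":
            return np.eye(len(self), dtype=np.uint8)[:, None, :]
        if mode == "active_site":
            if site_map is None:
                raise ValueError("active_site mode needs an ActiveSiteMap")
            return np.stack(
                [encode_active_site(e.aligned_seq, site_map) for e in self.entries]
            )
        if mode == "full_alignment":
            return np.stack([encode_sequence(e.aligned_seq) for e in self.entries])
        raise ValueError(f"unknown kinase encoding mode {mode!r}")


@dataclass(frozen=True)
class ActiveSiteMap:
    """Ordered 0-based alignment columns forming the active-site slice."""

    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = tuple(int(c) for c in self.columns)
        object.__setattr__(self, "columns", cols)
        if not cols:
            raise ValueError("active-site map is empty")
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("active-site columns must be strictly increasing")
        if cols[0] < 0:
            raise ValueError("active-site columns must be nonnegative")

    def __len__(self) -> int:
        return len(self.columns)

    def validate_for(self, alignment_width: int) -> None:
        if self.columns[-1] >= alignment_width:
            raise IndexError(
                f"active-site column {self.columns[-1]} out of range "
                f"for alignment width {alignment_width}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ActiveSiteMap":
        """Load a YAML list of 1-based column numbers."""
        with open(path) as fh:
            cols = yaml.safe_load(fh)
        return cls(tuple(int(c) - 1 for c in cols))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump([c + 1 for c in self.columns], fh)


def read_alignment(
    stream, group_map: Mapping[str, str] | None = None
) -> KinaseCatalog:
    """Read an aligned FASTA into a catalog, preserving input order.

    Headers (up to the first whitespace) are the kinase ids; groups come from
    ``group_map`` where present, else ``"unknown"``.
    """
    seqs = list(SeqIO.parse(stream, "fasta"))
    if not seqs:
        raise AlignmentFormatError("no sequences in alignment")
    group_map = dict(group_map or {})
    entries = [
        KinaseEntry(
            kinase_id=rec.id,
            group=group_map.get(rec.id, "unknown"),
            aligned_seq=str(rec.seq).upper(),
        )
        for rec in seqs
    ]
    return KinaseCatalog(entries)


def write_alignment(catalog: KinaseCatalog, path) -> None:
    with open(path, "w") as fh:
        for e in catalog.entries:
            fh.write(f">{e.kinase_id}\n{e.aligned_seq}\n")


def read_group_map(path) -> dict[str, str]:
    """TSV with columns (kinase_id, group), no header required."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["kinase_id", "group"])
    return dict(zip(df.kinase_id.astype(str), df.group.astype(str)))


def write_group_map(groups: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for k, g in groups.items():
            fh.write(f"{k}\t{g}\n")


def encode_identifier(kinase_id: str, catalog: KinaseCatalog) -> np.ndarray:
    """(1, |catalog|) one-hot at the catalog index of the kinase."""
    out = np.zeros((1, len(catalog)), dtype=np.uint8)
    out[0, catalog.index(kinase_id)] = 1
    return out


def encode_sequence(aligned_seq: str, strict: bool = True) -> np.ndarray:
    """(L, 21) one-hot of an aligned sequence.

    In strict mode any character outside the 21-letter alphabet raises; in
    lenient mode it is mapped to the gap channel with a warning.
    """
    seq = aligned_seq.upper()
    bad = sorted({c for c in seq if c not in _CHANNEL_INDEX})
    if bad:
        if strict:
            raise ValueError(f"characters outside the 21-letter alphabet: {bad}")
        import warnings

        warnings.warn(f"mapping non-standard characters to gap: {bad}")
        seq = "".join(c if c in _CHANNEL_INDEX else GAP for c in seq)
    idx = np.fromiter((_CHANNEL_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    out = np.zeros((len(seq), N_CHANNELS), dtype=np.uint8)
    out[np.arange(len(seq)), idx] = 1
    return out


def decode_sequence(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != N_CHANNELS:
        raise ValueError(f"expected (L, {N_CHANNELS}) matrix, got {matrix.shape}")
    if not np.all(matrix.sum(axis=1) == 1):
        raise ValueError("matrix rows are not one-hot")
    return "".join(AA_ALPHABET[i] for i in matrix.argmax(axis=1))


def encode_active_site(aligned_seq: str, site_map: ActiveSiteMap, strict: bool = True) -> np.ndarray:
    """(|site_map|, 21) one-hot of the selected alignment columns."""
    site_map.validate_for(len(aligned_seq))
    sub = "".join(aligned_seq[c] for c in site_map.columns)
    return encode_sequence(sub, strict=strict)
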