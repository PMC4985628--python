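"""Species abundance distributions and OTU-table I/O.

A :class:`CommunitySample` is one community's species abundance distribution
(SAD): the vector of per-species read counts ``n_i`` together with the totals
``J`` (individuals/reads) and ``S`` (species/OTUs) and the abundance-class
multiplicities ``phi[a]`` (number of species observed exactly ``a`` times).
These are the sufficient statistics of both sampling formulas implemented in
:mod:`neutralsad.ewens` and :mod:`neutralsad.etienne`.

An :class:`OTUTable` is a samples x OTUs count matrix with per-sample
metadata (subject, body site, body location, 16S region). Two on-disk
dialects are supported:

* ``wide``  — first column sample id, remaining columns OTU ids.
* ``shared`` — mothur ``.shared`` layout: ``label``, ``Group``, ``numOtus``,
  then OTU count columns; ``Group`` is the sample id.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .sites import canonical_site, location_for_site

__all__ = [
    "CommunitySample",
    "OTUTable",
    "OTUTableFormatError",
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "sample_to_sad",
]

METADATA_COLUMNS = ("sample_id", "subject_id", "body_site", "body_location", "region")

_SHARED_BOOKKEEPING = ("label", "Group", "numOtus")


class OTUTableFormatError(ValueError):
    """A file does not conform to the declared OTU-table dialect."""


class ValidationError(ValueError):
    """Data violate an invariant (negative counts, empty community, ...)."""


@dataclasses.dataclass(frozen=True)
class CommunitySample:
    """One sample's species abundance distribution.

    Attributes
    ----------
    sample_id:
        Opaque identifier of the community sample.
    abundances:
        Per-species read counts ``n_i``, sorted non-increasing, all >= 1.
    J:
        Total number of individuals (reads), ``sum(n_i)``.
    S:
        Number of species (OTUs) present.
    phi:
        Abundance-class multiplicities: ``phi[a]`` species have abundance
        exactly ``a``. ``sum(phi.values()) == S`` and
        ``sum(a * phi[a]) == J``.
    """

    sample_id: str
    abundances: tuple[int, ...]
    J: int
    S: int
    phi: Mapping[int, int]

    @classmethod
    def from_counts(
        cls, counts: Iterable[int], sample_id: str = "sample"
    ) -> "CommunitySample":
        """Build a SAD from raw (possibly zero-padded, unsorted) counts.

        Zero counts are dropped: the sampling formulas are defined over the
        species actually present. Negative or non-integer counts raise
        :class:`ValidationError`.
        """
        arr = np.asarray(list(counts))
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValidationError(
                    f"sample {sample_id!r}: non-integer abundance in {arr!r}"
                )
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValidationError(f"sample {sample_id!r}: negative abundance")
        arr = arr[arr > 0]
        if arr.size == 0:
            raise ValidationError(f"sample {sample_id!r}: empty community (all zeros)")
        arr = np.sort(arr)[::-1]
        values, mult = np.unique(arr, return_counts=True)
        phi = {int(a): int(c) for a, c in zip(values, mult)}
        return cls(
            sample_id=str(sample_id),
            abundances=tuple(int(n) for n in arr),
            J=int(arr.sum()),
            S=int(arr.size),
            phi=phi,
        )

    def __post_init__(self) -> None:
        if self.S != len(self.abundances):
            raise ValidationError("S does not match number of abundances")
        if any(n < 1 for n in self.abundances):
            raise ValidationError("abundances must all be >= 1")
        if any(a < b for a, b in zip(self.abundances, self.abundances[1:])):
            raise ValidationError("abundances must be non-increasing")
        if self.J != sum(self.abundances):
            raise ValidationError("J does not match sum of abundances")
        if sum(self.phi.values()) != self.S or (
            sum(a * c for a, c in self.phi.items()) != self.J
        ):
            raise ValidationError("phi inconsistent with abundances")

    @property
    def max_abundance(self) -> int:
        return self.abundances[0]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=np.int64)


class OTUTable:
    """Samples x OTUs integer count matrix with per-sample metadata.

    ``counts`` is a dense non-negative integer DataFrame indexed by sample id
    with OTU ids as columns. ``metadata`` is indexed by sample id with columns
    ``subject_id``, ``body_site``, ``body_location``, ``region``; rows are kept
    aligned with ``counts``. The body_location column, when absent, is derived
    from body_site through the site vocabulary.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame | None = None):
        counts = counts.copy()
        bad = counts.columns[~counts.dtypes.map(lambda d: np.issubdtype(d, np.integer))]
        for col in bad:
            as_float = pd.to_numeric(counts[col], errors="raise")
            if not np.all(as_float == np.floor(as_float)):
                row = counts.index[as_float != np.floor(as_float)][0]
                raise ValidationError(
                    f"non-integer count at sample {row!r}, OTU {col!r}"
                )
            counts[col] = as_float.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            rows, cols = np.nonzero(counts.to_numpy() < 0)
            raise ValidationError(
                "negative count at sample "
                f"{counts.index[rows[0]]!r}, OTU {counts.columns[cols[0]]!r}"
            )
        counts.index = counts.index.astype(str)
        self.counts = counts.astype(np.int64)

        if metadata is None:
            metadata = pd.DataFrame(index=self.counts.index)
        else:
            metadata = metadata.copy()
            if "sample_id" in metadata.columns:
                metadata = metadata.set_index("sample_id")
            metadata.index = metadata.index.astype(str)
            missing = set(self.counts.index) - set(metadata.index)
            extra = set(metadata.index) - set(self.counts.index)
            if missing or extra:
                raise ValidationError(
                    f"metadata/counts sample mismatch: missing={sorted(missing)[:5]} "
                    f"extra={sorted(extra)[:5]}"
                )
        for col in ("subject_id", "body_site", "region"):
            if col not in metadata.columns:
                metadata[col] = "unknown"
        metadata["body_site"] = metadata["body_site"].map(canonical_site)
        if "body_location" not in metadata.columns:
            metadata["body_location"] = metadata["body_site"].map(location_for_site)
        else:
            unset = metadata["body_location"].isna()
            metadata.loc[unset, "body_location"] = metadata.loc[
                unset, "body_site"
            ].map(location_for_site)
        self.metadata = metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata[
            list(METADATA_COLUMNS[1:])
        ].equals(other.metadata[list(METADATA_COLUMNS[1:])])

    def __repr__(self) -> str:
        return f"OTUTable({self.n_samples} samples x {self.n_otus} OTUs)"


def sample_to_sad(table: OTUTable, sample_id: str) -> CommunitySample:
    """Extract one sample's SAD from an OTU table.

    Zero-count OTUs are dropped; ties in abundance are broken by OTU id so the
    rank order (and any rank-abundance export) is deterministic.
    """
    sample_id = str(sample_id)
    if sample_id not in table.counts.index:
        raise KeyError(f"sample {sample_id!r} not in table")
    row = table.counts.loc[sample_id]
    # sort by (-count, otu_id) for a deterministic rank order
    row = row[row > 0]
    if row.empty:
        raise ValidationError(f"sample {sample_id!r}: empty community (all zeros)")
    row = row.sort_index().sort_values(ascending=False, kind="stable")
    return CommunitySample.from_counts(row.to_numpy(), sample_id=sample_id)


def read_otu_table(
    path: str | Path,
    dialect: str = "wide",
    metadata: str | Path | pd.DataFrame | None = None,
) -> OTUTable:
    """Read an OTU count table in the ``wide`` or ``shared`` dialect.

    Parameters
    ----------
    path:
        TSV file to read.
    dialect:
        ``"wide"`` (first column sample id, remaining columns OTU ids) or
        ``"shared"`` (mothur layout with label/Group/numOtus bookkeeping
        columns, which are consumed and validated but not stored as OTUs).
    metadata:
        Optional sample-metadata TSV path or DataFrame with columns
        ``sample_id, subject_id, body_site, body_location, region``.
    """
    path = Path(path)
    if dialect not in ("wide", "shared"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.size < 2:
        raise OTUTableFormatError(f"{path}: expected a tab-separated header row")
    if dialect == "shared":
        for col in _SHARED_BOOKKEEPING:
            if col not in df.columns:
                raise OTUTableFormatError(
                    f"{path}: shared dialect requires column {col!r}"
                )
        otu_cols = [c for c in df.columns if c not in _SHARED_BOOKKEEPING]
        n_declared = pd.to_numeric(df["numOtus"], errors="coerce")
        if n_declared.isna().any() or (n_declared != len(otu_cols)).any():
            raise OTUTableFormatError(
                f"{path}: numOtus column disagrees with the {len(otu_cols)} "
                "OTU columns present"
            )
        counts = df[otu_cols].copy()
        counts.index = df["Group"].astype(str)
    else:
        counts = df.set_index(df.columns[0])
    counts = _coerce_counts(counts, path)
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)
    return OTUTable(counts, metadata)


def _coerce_counts(counts: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in counts.columns:
        num = pd.to_numeric(counts[col], errors="coerce")
        if num.isna().any():
            row = counts.index[num.isna()][0]
            raise ValidationError(
                f"{path}: non-numeric count at sample {row!r}, column {col!r}"
            )
        if not np.all(num == np.floor(num)):
            row = counts.index[num != np.floor(num)][0]
            raise ValidationError(
                f"{path}: non-integer count at sample {row!r}, column {col!r}"
            )
        if (num < 0).any():
            row = counts.index[num < 0][0]
            raise ValidationError(
                f"{path}: negative count at sample {row!r}, column {col!r}"
            )
        out[col] = num.astype(np.int64)
    return pd.DataFrame(out, index=counts.index)


def write_otu_table(table: OTUTable, path: str | Path, dialect: str = "wide") -> None:
    """Write ``table`` to ``path`` in the chosen dialect (inverse of
    :func:`read_otu_table` on counts)."""
    path = Path(path)
    if dialect == "wide":
        out = table.counts.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")
    elif dialect == "shared":
        out = table.counts.copy()
        out.insert(0, "label", "0.03")
        out.insert(1, "Group", out.index)
        out.insert(2, "numOtus", table.n_otus)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id",) if c not in df.columns]
    if missing:
        raise OTUTableFormatError(f"{path}: metadata lacks column(s) {missing}")
    return df


def write_metadata(table: OTUTable, path: str | Path) -> None:
    md = table.metadata.copy()
    md.insert(0, "sample_id", md.index)
    md[list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)
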