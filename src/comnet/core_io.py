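"""Tabular containers and I/O for taxon-by-sample community data.

The universal input is a count table: taxa as rows, samples as columns,
non-negative integer read counts (the common OTU/ASV table layout). A
metadata table maps samples to categorical factors (compartment, host,
soil, ...). All matrices in this package are taxa-as-rows; the invariant
is asserted at construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "SampleMetadata",
    "AbundanceTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "align",
    "relative_abundance",
    "write_distance_matrix",
    "read_distance_matrix",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dups))}")


@dataclass
class CountTable:
    """Integer taxon x sample abundance matrix.

    Parameters
    ----------
    taxa : list of str
        Row identifiers (ASV/OTU/taxon IDs), unique.
    samples : list of str
        Column identifiers (sample IDs), unique.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer read counts.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        self.samples = [str(s) for s in self.samples]
        _check_unique(self.taxa, "taxon")
        _check_unique(self.samples, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxa[i]!r}, sample {self.samples[j]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    def select_taxa(self, keep: list[str]) -> "CountTable":
        """Subset to `keep` (in given order); unknown IDs raise KeyError."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        rows = [idx[t] for t in keep]
        return CountTable(list(keep), list(self.samples), self.counts[rows])

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = {s: i for i, s in enumerate(self.samples)}
        cols = [idx[s] for s in keep]
        return CountTable(list(self.taxa), list(keep), self.counts[:, cols])


@dataclass
class SampleMetadata:
    """Per-sample categorical factors.

    `factors` maps factor name -> list of levels aligned with `samples`.
    """

    samples: list[str]
    factors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        _check_unique(self.samples, "sample")
        n = len(self.samples)
        for name, levels in self.factors.items():
            if len(levels) != n:
                raise ValueError(
                    f"factor {name!r} has {len(levels)} levels for {n} samples"
                )
            if any(l is None or str(l) == "" for l in levels):
                raise ValueError(f"factor {name!r} has empty levels")
            self.factors[name] = [str(l) for l in levels]

    def levels(self, factor: str, samples: list[str] | None = None) -> list[str]:
        """Levels of `factor` for the given sample order (default: all)."""
        if factor not in self.factors:
            raise KeyError(f"unknown factor {factor!r}")
        if samples is None:
            return list(self.factors[factor])
        pos = {s: i for i, s in enumerate(self.samples)}
        return [self.factors[factor][pos[s]] for s in samples]

    def select_samples(self, keep: list[str]) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return SampleMetadata(
            list(keep), {f: [v[i] for i in idx] for f, v in self.factors.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.factors, index=self.samples)


@dataclass
class AbundanceTable:
    """Relative abundances: columns sum to 1."""

    taxa: list[str]
    samples: list[str]
    ra: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        self.samples = [str(s) for s in self.samples]
        _check_unique(self.taxa, "taxon")
        _check_unique(self.samples, "sample")
        ra = np.asarray(self.ra, dtype=float)
        if ra.shape != (len(self.taxa), len(self.samples)):
            raise ValueError("ra shape does not match ID lists")
        if ra.size:
            if ra.min() < 0 or ra.max() > 1 + 1e-9:
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = ra.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.samples[int(np.argmax(np.abs(sums - 1)))]
                raise ValueError(f"column sums must be 1 (sample {bad!r})")
        self.ra = ra

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ra, index=self.taxa, columns=self.samples)


def read_count_table(path, fmt: str = "tsv") -> CountTable:
    """Read a taxon x sample count table.

    TSV dialect: tab-separated, header row of sample IDs, first column of
    taxon IDs, UTF-8.
    """
    if fmt == "biom":
        raise NotImplementedError("BIOM input is not supported; convert to TSV")
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")  # pandas would silently mangle dupes
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, encoding="utf-8")
    if df.columns.size == 0:
        raise ValueError(f"{path}: no sample columns found (malformed header?)")
    _check_unique(list(df.columns), "sample")
    _check_unique(list(df.index), "taxon")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna().to_numpy().argmax()]
            raise ValueError(f"non-numeric count at taxon {row!r}, sample {col!r}")
        df[col] = vals
    return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="#ID", encoding="utf-8")


def read_metadata(path, factors: list[str] | None = None) -> SampleMetadata:
    """Read a metadata TSV: first column sample IDs, remaining columns factors."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")
    _check_unique(list(df.index), "sample")
    cols = list(df.columns) if factors is None else factors
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing factor columns: {missing}")
    return SampleMetadata(
        list(df.index.astype(str)),
        {c: list(df[c].astype(str)) for c in cols},
    )


def align(count: CountTable, meta: SampleMetadata) -> tuple[CountTable, SampleMetadata]:
    """Restrict count table and metadata to their shared samples.

    Order follows the count table. Dropped samples are logged.
    """
    shared = [s for s in count.samples if s in set(meta.samples)]
    if not shared:
        raise ValueError("count table and metadata share no sample IDs")
    dropped = sorted((set(count.samples) | set(meta.samples)) - set(shared))
    if dropped:
        logger.warning("align: dropping %d unshared samples: %s", len(dropped), dropped)
    return count.select_samples(shared), meta.select_samples(shared)


def relative_abundance(count: CountTable) -> AbundanceTable:
    """Close each sample column to relative abundances (column sum 1)."""
    sums = count.counts.sum(axis=0)
    if (sums == 0).any():
        bad = count.samples[int(np.argmax(sums == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return AbundanceTable(list(count.taxa), list(count.samples), count.counts / sums)


def write_distance_matrix(labels: list[str], d: np.ndarray, path) -> None:
    pd.DataFrame(d, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="#ID", encoding="utf-8"
    )


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    return list(df.index.astype(str)), df.to_numpy(dtype=float)
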