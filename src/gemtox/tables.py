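"""OTU count tables, covariate metadata and reference genus lists.

Implements the data-preparation steps applied before model fitting: parsing
tab-separated OTU-by-site tables, the low-abundance filter (an OTU is kept
only if its total count over all sites *exceeds* the threshold), and jittering
of tied covariate values so every modelled site carries a distinct stressor
level (absolute value taken for uncontaminated sites so jittered zeros stay
nonnegative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "OTUCountTable",
    "CovariateVector",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "filter_low_abundance",
    "jitter_ties",
    "read_reference_genera",
]


class ParseError(ValueError):
    """Raised when an input file violates the expected tabular layout."""


@dataclass(frozen=True)
class OTUCountTable:
    """Integer abundance matrix, OTUs (rows) by sites (columns).

    Attributes
    ----------
    counts : (n_otus, n_sites) nonnegative integer array
    otu_ids : OTU labels, unique
    site_ids : site labels, unique
    genera : optional per-OTU genus annotation; None entries mean the OTU
        was not classified to genus level.
    """

    counts: np.ndarray
    otu_ids: tuple[str, ...]
    site_ids: tuple[str, ...]
    genera: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D OTU x site matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if len(self.otu_ids) != counts.shape[0]:
            raise ValueError("otu_ids length does not match counts rows")
        if len(self.site_ids) != counts.shape[1]:
            raise ValueError("site_ids length does not match counts columns")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicated otu_id")
        if self.genera is not None and len(self.genera) != counts.shape[0]:
            raise ValueError("genera length does not match counts rows")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    @property
    def otu_totals(self) -> np.ndarray:
        """Total abundance of each OTU over all sites."""
        return self.counts.sum(axis=1)

    @property
    def site_totals(self) -> np.ndarray:
        """Sequencing depth of each site."""
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> np.ndarray:
        """Per-site relative abundances (columns sum to 1)."""
        totals = self.site_totals.astype(float)
        if (totals == 0).any():
            raise ValueError("site with zero total count")
        return self.counts / totals

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.site_ids))
        df.insert(0, "otu_id", list(self.otu_ids))
        genera = self.genera if self.genera is not None else [""] * self.n_otus
        df.insert(1, "genus", ["" if g is None else g for g in genera])
        return df


@dataclass(frozen=True)
class CovariateVector:
    """Per-site contaminant concentrations, raw and after tie-breaking jitter.

    ``raw`` keeps the measured values (ties and exact zeros allowed) and is
    used to define the uncontaminated baseline group; ``jittered`` holds the
    pairwise-distinct values used for model fitting, or None before
    :func:`jitter_ties` has been applied.
    """

    raw: np.ndarray
    site_ids: tuple[str, ...]
    jittered: np.ndarray | None = None
    jitter_sd: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        if raw.ndim != 1:
            raise ValueError("raw covariates must be 1-D")
        if not np.all(np.isfinite(raw)) or (raw < 0).any():
            raise ValueError("covariates must be finite and nonnegative")
        object.__setattr__(self, "raw", raw)
        if len(self.site_ids) != raw.size:
            raise ValueError("site_ids length does not match covariates")
        if self.jittered is not None:
            jit = np.asarray(self.jittered, dtype=float)
            if jit.shape != raw.shape:
                raise ValueError("jittered and raw must have equal length")
            if len(np.unique(jit)) != jit.size:
                raise ValueError("jittered values must be pairwise distinct")
            object.__setattr__(self, "jittered", jit)

    @property
    def values(self) -> np.ndarray:
        """Model-ready covariates: jittered when available, raw otherwise."""
        return self.raw if self.jittered is None else self.jittered

    @property
    def baseline_mask(self) -> np.ndarray:
        """True for uncontaminated sites (raw value exactly zero)."""
        return self.raw == 0.0

    def subset(self, index: Sequence[int]) -> "CovariateVector":
        index = list(index)
        return CovariateVector(
            raw=self.raw[index],
            site_ids=tuple(self.site_ids[i] for i in index),
            jittered=None if self.jittered is None else self.jittered[index],
            jitter_sd=self.jitter_sd,
            seed=self.seed,
        )


def read_otu_table(path: str | Path, transpose: bool = False) -> OTUCountTable:
    """Read a tab-separated OTU table.

    Expected layout: header ``otu_id<TAB>genus<TAB><site ids...>``, one row
    per OTU with integer counts (the ``genus`` column is optional).  With
    ``transpose=True`` a mothur-shared-style orientation (rows = sites) is
    accepted and transposed on read.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names="otu_id")
    if df.columns[0] != "otu_id":
        raise ParseError(f"{path}: first column must be 'otu_id', got {df.columns[0]!r}")
    has_genus = len(df.columns) > 1 and df.columns[1] == "genus"
    site_cols = list(df.columns[(2 if has_genus else 1):])
    if not site_cols:
        raise ParseError(f"{path}: no site columns found")
    counts = np.empty((len(df), len(site_cols)), dtype=np.int64)
    for r, (_, row) in enumerate(df.iterrows()):
        for c, col in enumerate(site_cols):
            cell = str(row[col]).strip()
            try:
                value = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer count {cell!r} at line {r + 2}, column {col!r}"
                ) from None
            if value < 0:
                raise ParseError(f"{path}: negative count at line {r + 2}, column {col!r}")
            counts[r, c] = value
    otu_ids = tuple(df["otu_id"].tolist())
    if len(set(otu_ids)) != len(otu_ids):
        dupes = df["otu_id"][df["otu_id"].duplicated()].iloc[0]
        line = int(df.index[df["otu_id"] == dupes][1]) + 2
        raise ParseError(f"{path}: duplicated otu_id {dupes!r} at line {line}")
    genera = None
    if has_genus:
        genera = tuple(g if g != "" else None for g in df["genus"].tolist())
    return OTUCountTable(counts=counts, otu_ids=otu_ids,
                         site_ids=tuple(site_cols), genera=genera)


def write_otu_table(table: OTUCountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> CovariateVector:
    """Read per-site metadata with columns ``site_id`` and ``tph_mg_per_kg``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("site_id", "tph_mg_per_kg"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return CovariateVector(
        raw=df["tph_mg_per_kg"].to_numpy(dtype=float),
        site_ids=tuple(str(s) for s in df["site_id"]),
    )


def write_metadata(cov: CovariateVector, path: str | Path) -> None:
    df = pd.DataFrame({"site_id": list(cov.site_ids), "tph_mg_per_kg": cov.raw})
    if cov.jittered is not None:
        df["tph_jittered"] = cov.jittered
    df.to_csv(path, sep="\t", index=False)


def filter_low_abundance(table: OTUCountTable, threshold: int = 10) -> OTUCountTable:
    """Keep only OTUs whose total abundance over all sites strictly exceeds
    ``threshold`` (default 10).  Row order is preserved; retained counts are
    unchanged.  Idempotent."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    keep = table.otu_totals > threshold
    if not keep.any():
        raise ValueError(
            f"abundance filter (> {threshold}) removed every OTU; table is empty"
        )
    idx = np.flatnonzero(keep)
    return OTUCountTable(
        counts=table.counts[idx],
        otu_ids=tuple(table.otu_ids[i] for i in idx),
        site_ids=table.site_ids,
        genera=None if table.genera is None else tuple(table.genera[i] for i in idx),
    )


def jitter_ties(cov: CovariateVector, jitter_sd: float = 1.0,
                seed: int = 0, max_tries: int = 1000) -> CovariateVector:
    """Break covariate ties with Gaussian noise of standard deviation
    ``jitter_sd`` (mg/kg).

    Every raw value receives independent N(0, jitter_sd^2) noise; for raw
    zeros the absolute value of the perturbed value is taken so baseline
    sites stay nonnegative.  On the (measure-zero) event of a collision the
    noise is redrawn.
    """
    if jitter_sd <= 0:
        raise ValueError("jitter_sd must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        jittered = cov.raw + rng.normal(0.0, jitter_sd, size=cov.raw.size)
        jittered[cov.raw == 0.0] = np.abs(jittered[cov.raw == 0.0])
        if len(np.unique(jittered)) == jittered.size:
            return replace(cov, jittered=jittered, jitter_sd=jitter_sd, seed=seed)
    raise RuntimeError("could not break covariate ties; increase jitter_sd")


def read_reference_genera(path: str | Path) -> set[str]:
    """Read a plain-text genus list (one genus per line) into a case-folded,
    deduplicated set.  An empty file yields an empty set with a warning."""
    lines = Path(path).read_text().splitlines()
    genera = {line.strip().casefold() for line in lines if line.strip()}
    if not genera:
        warnings.warn(f"reference genus list {path} is empty", stacklevel=2)
    return genera
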