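"""Reading, collapsing, filtering and writing taxon abundance tables.

The central object is :class:`AbundanceTable`: a taxa x samples matrix of
non-negative abundances (counts or relative abundances) whose columns are
time-ordered samples, optionally carrying a semicolon-delimited taxonomy
string per taxon (``k__...;p__...;c__...;o__...;f__...;g__...``) in the
Greengenes/QIIME convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "collapse_to_rank",
    "filter_features",
    "RANK_PREFIXES",
]

#: taxonomic ranks in Greengenes prefix order
RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
_RANK_ORDER = list(RANK_PREFIXES)


@dataclass
class AbundanceTable:
    """Taxa x time-ordered-samples abundance matrix.

    Parameters
    ----------
    taxon_ids
        Unique row identifiers (OTU ids or collapsed rank strings).
    sample_ids
        Unique column identifiers, in temporal order.
    values
        ``(n_taxa, n_samples)`` array of finite, non-negative numbers.
    taxonomy
        Optional per-taxon semicolon-delimited rank string.
    sample_times
        Optional monotone non-decreasing timestamps, one per sample.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    taxonomy: list[str] | None = None
    sample_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D taxa x samples array")
        n_taxa, n_samples = self.values.shape
        if n_taxa != len(self.taxon_ids):
            raise ValueError(
                f"{len(self.taxon_ids)} taxon ids for {n_taxa} rows"
            )
        if n_samples != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        dup = _duplicates(self.taxon_ids)
        if dup:
            raise ValueError(f"duplicate taxon ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance values must be finite")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be non-negative")
        if self.taxonomy is not None and len(self.taxonomy) != n_taxa:
            raise ValueError("taxonomy length does not match taxon count")
        if self.sample_times is not None:
            times = np.asarray(self.sample_times, dtype=float)
            if times.shape != (n_samples,):
                raise ValueError("sample_times length does not match samples")
            if np.any(np.diff(times) < 0):
                raise ValueError("sample_times must be non-decreasing")
            self.sample_times = times

    # -- conveniences ------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.taxon_ids, columns=self.sample_ids
        )
        df.index.name = "#OTU ID"
        if self.taxonomy is not None:
            df = df.assign(taxonomy=self.taxonomy)
        return df

    def select_taxa(self, keep: Sequence[int]) -> "AbundanceTable":
        keep = list(keep)
        return AbundanceTable(
            taxon_ids=[self.taxon_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            values=self.values[keep, :],
            taxonomy=(
                [self.taxonomy[i] for i in keep] if self.taxonomy else None
            ),
            sample_times=self.sample_times,
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup


def read_abundance_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a taxa x samples TSV (plain or BIOM-style TSV export).

    First column holds taxon ids, remaining columns are samples in temporal
    order; an optional trailing ``taxonomy`` column carries rank strings.
    A leading ``# Constructed from biom file`` comment line is tolerated.
    """
    path = Path(path)
    if format not in ("tsv", "biom-tsv"):
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=_biom_header(path))
    df = df.set_index(df.columns[0])
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str).tolist()
        df = df.drop(columns=["taxonomy"])
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 samples in the table")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric abundance cell in {path}: {exc}") from exc
    return AbundanceTable(
        taxon_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
        taxonomy=taxonomy,
    )


def _biom_header(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("# Constructed from biom file") else 0


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the table in the same TSV dialect `read_abundance_table` accepts."""
    table.to_frame().to_csv(path, sep="\t")


def _truncate_taxonomy(tax: str, rank: str) -> str | None:
    """Taxonomy string truncated at `rank`, or None if unassigned there."""
    depth = _RANK_ORDER.index(rank)
    parts = [p.strip() for p in tax.split(";")]
    if len(parts) <= depth:
        return None
    label = parts[depth]
    prefix = RANK_PREFIXES[rank]
    # empty label ("g__") or bare prefix means unassigned at this rank
    if label in ("", prefix) or label == prefix.rstrip("_") + "__":
        return None
    return ";".join(parts[: depth + 1])


def collapse_to_rank(table: AbundanceTable, rank: str = "genus") -> AbundanceTable:
    """Sum rows sharing the same taxonomy prefix up to `rank`.

    Taxa with an empty or missing label at the rank are pooled into a single
    ``unassigned at <rank>`` row so per-sample mass is conserved.
    """
    if table.taxonomy is None:
        raise ValueError("collapse requires taxonomy for all taxa")
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}; one of {_RANK_ORDER}")
    unassigned = f"unassigned at {rank}"
    groups: dict[str, np.ndarray] = {}
    for i, tax in enumerate(table.taxonomy):
        key = _truncate_taxonomy(tax, rank) or unassigned
        if key in groups:
            groups[key] = groups[key] + table.values[i]
        else:
            groups[key] = table.values[i].copy()
    taxon_ids = list(groups)
    return AbundanceTable(
        taxon_ids=taxon_ids,
        sample_ids=list(table.sample_ids),
        values=np.vstack([groups[k] for k in taxon_ids]),
        taxonomy=list(taxon_ids),
        sample_times=table.sample_times,
    )


def filter_features(
    table: AbundanceTable,
    min_total: float = 10,
    min_prevalence: int = 5,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Drop low-abundance, low-prevalence taxa.

    A taxon is removed when its total across samples is strictly below
    ``min_total`` OR it is non-zero in strictly fewer than ``min_prevalence``
    samples; taxa sitting exactly on either boundary are retained.

    Returns the filtered table and a log DataFrame of removed taxa with
    their totals and prevalences.
    """
    totals = table.values.sum(axis=1)
    prevalence = (table.values > 0).sum(axis=1)
    removed = (totals < min_total) | (prevalence < min_prevalence)
    log = pd.DataFrame(
        {
            "taxon": np.asarray(table.taxon_ids, dtype=object)[removed],
            "total": totals[removed],
            "prevalence": prevalence[removed],
        }
    )
    keep = np.flatnonzero(~removed)
    if keep.size == 0:
        raise ValueError(
            "filter removed all taxa; lower min_total/min_prevalence"
        )
    return table.select_taxa(keep), log
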