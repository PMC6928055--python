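"""Abundance tables, sample metadata and the standard preprocessing steps.

The central container is :class:`AbundanceTable`: a feature-by-sample matrix
of 16S read counts (or relative abundances) with optional ranked taxonomy per
feature.  Everything downstream -- diversity, enterotyping, core scoring,
effect sizes, networks, classification -- consumes this container.

Preprocessing mirrors the conventions of amplicon pipelines:

* ``rarefy`` -- subsample every sample without replacement to a common depth
  (multivariate hypergeometric), removing sequencing-depth bias.
* ``filter_sparse`` -- drop features whose total count is below a fraction of
  the grand total of reads (default 0.002%), a standard denoising step.
* ``prevalence_filter`` -- keep features non-zero in at least a fraction of
  samples (default 51%, i.e. non-zero median), optionally enforced within
  every declared sample group.
* ``collapse`` -- cumulate feature abundances at a higher taxonomic rank.

File formats are plain TSV: feature id in the first column, one column per
sample, an optional trailing ``taxonomy`` column with ranks separated by
``;`` and ``#`` comment lines.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

TAXONOMY_COLUMN = "taxonomy"

__all__ = [
    "RANKS",
    "AbundanceTable",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "rarefy",
    "filter_sparse",
    "to_relative",
    "collapse",
    "prevalence_filter",
]


@dataclass
class AbundanceTable:
    """Feature x sample abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with features as rows (unique ids) and samples as columns
        (unique ids).  Non-negative.
    kind:
        ``"counts"`` for integer read counts, ``"relative"`` for proportions
        (every column sums to 1 within 1e-8).
    taxonomy:
        Optional map ``feature_id -> tuple of rank names`` ordered from
        domain down to species; shorter lineages are allowed.
    """

    data: pd.DataFrame
    kind: str = "counts"
    taxonomy: dict[str, tuple[str, ...]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic protocol -------------------------------------------------
    def validate(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            f, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative abundance at feature "
                f"{self.data.index[f]!r}, sample {self.data.columns[s]!r}"
            )
        if self.kind == "relative":
            sums = vals.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-8)
            if bad.size:
                raise ValueError(
                    f"relative table columns must sum to 1; offending sample "
                    f"{self.data.columns[bad[0]]!r} sums to {sums[bad[0]]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        """Matrix of abundances, features x samples."""
        return self.data.to_numpy(dtype=float)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        return replace(self, data=self.data[list(sample_ids)])

    def select_features(self, feature_ids) -> "AbundanceTable":
        """Subset to the given features.

        A relative table is renormalized (closure of the subcomposition) so
        the column-sums-to-1 invariant still holds.
        """
        sub = self.data.loc[list(feature_ids)]
        if self.kind == "relative":
            sums = sub.sum(axis=0)
            if (sums == 0).any():
                raise ValueError("feature subset leaves an all-zero sample")
            sub = sub / sums
        tax = None
        if self.taxonomy is not None:
            tax = {f: self.taxonomy[f] for f in sub.index if f in self.taxonomy}
        return replace(self, data=sub, taxonomy=tax)


# -- I/O -----------------------------------------------------------------


def read_abundance(path, kind: str = "counts") -> AbundanceTable:
    """Read an abundance TSV.

    Expected layout: a header line (first cell is a feature-id column label,
    remaining cells are sample ids, optionally ending with a ``taxonomy``
    column), then one row per feature.  Lines starting with ``#`` are
    comments.  Errors name the offending line.
    """
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                if len(cells) != len(header):
                    raise ValueError(
                        f"{path}: line {lineno}: expected {len(header)} columns, "
                        f"got {len(cells)}"
                    )
                rows.append((lineno, cells))
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")

    has_tax = header[-1].lower() in (TAXONOMY_COLUMN, "lineage")
    sample_ids = header[1 : -1 if has_tax else len(header)]
    feature_ids: list[str] = []
    taxonomy: dict[str, tuple[str, ...]] = {}
    matrix: list[list[float]] = []
    for lineno, cells in rows:
        fid = cells[0]
        feature_ids.append(fid)
        stop = -1 if has_tax else len(cells)
        try:
            vals = [float(c) for c in cells[1:stop]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        for j, v in enumerate(vals):
            if v < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative value for feature {fid!r}, "
                    f"sample {sample_ids[j]!r}"
                )
        matrix.append(vals)
        if has_tax and cells[-1]:
            taxonomy[fid] = tuple(t.strip() for t in cells[-1].split(";") if t.strip())

    data = pd.DataFrame(matrix, index=feature_ids, columns=sample_ids)
    if kind == "counts":
        arr = data.to_numpy()
        if np.allclose(arr, np.round(arr)):
            data = data.round().astype(np.int64)
    return AbundanceTable(data=data, kind=kind, taxonomy=taxonomy or None)


def write_abundance(table: AbundanceTable, path) -> None:
    """Write an abundance TSV (round-trips exactly for integer counts)."""
    with open(path, "wt", encoding="utf-8") as fh:
        cols = ["feature_id", *table.sample_ids]
        if table.taxonomy is not None:
            cols.append(TAXONOMY_COLUMN)
        fh.write("\t".join(cols) + "\n")
        for fid, row in table.data.iterrows():
            cells = [str(fid)]
            for v in row.to_numpy():
                cells.append(str(int(v)) if float(v).is_integer() else repr(float(v)))
            if table.taxonomy is not None:
                cells.append(";".join(table.taxonomy.get(fid, ())))
            fh.write("\t".join(cells) + "\n")


METADATA_COLUMNS = ("cohort", "region", "sex", "diet", "age", "bmi")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def validate_metadata(meta: pd.DataFrame, table: AbundanceTable | None = None) -> list[str]:
    """Check a sample-metadata table; returns a list of issues (empty = ok).

    Missing age/BMI values are permitted; non-positive ones are flagged, and
    every sample of the companion abundance table must be annotated.
    """
    issues: list[str] = []
    if meta.index.has_duplicates:
        issues.append("duplicate sample ids in metadata")
    if table is not None:
        missing = set(table.sample_ids) - set(meta.index)
        if missing:
            issues.append(f"samples missing from metadata: {sorted(missing)}")
    for col in ("age", "bmi"):
        if col in meta.columns:
            vals = pd.to_numeric(meta[col], errors="coerce")
            bad = meta.index[(vals <= 0) & vals.notna()]
            if len(bad):
                issues.append(f"non-positive {col} for samples: {list(bad)}")
    return issues


# -- preprocessing -------------------------------------------------------


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # substream keyed by sample id so results survive column reordering
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(sample_id).encode())])
    )


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth=None`` uses the minimum column sum (the shallowest sample), the
    usual rarefaction policy.  Each sample's draw is multivariate
    hypergeometric, with a per-sample random substream derived from ``seed``
    and the sample id, so the result is reproducible and independent of
    column order.
    """
    if table.kind != "counts":
        raise ValueError("rarefy requires a counts table")
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    shallow = np.flatnonzero(totals < depth)
    if shallow.size:
        raise ValueError(
            f"sample {table.sample_ids[shallow[0]]!r} has only "
            f"{totals[shallow[0]]} reads (< depth {depth})"
        )
    out = np.empty_like(counts)
    for j, sid in enumerate(table.sample_ids):
        if totals[j] == depth:
            out[:, j] = counts[:, j]
        else:
            rng = _sample_rng(seed, sid)
            out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    data = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return replace(table, data=data)


def filter_sparse(
    table: AbundanceTable, min_total_fraction: float = 0.00002
) -> tuple[AbundanceTable, list[str]]:
    """Drop sparse features: total count < ``min_total_fraction`` x grand total.

    The default 0.00002 is the 0.002%-of-all-reads denoising rule.  Returns
    the filtered table and the list of dropped feature ids.
    """
    if table.kind != "counts":
        raise ValueError("filter_sparse requires a counts table")
    totals = table.data.sum(axis=1)
    threshold = float(min_total_fraction) * float(totals.sum())
    keep = totals >= threshold
    dropped = list(table.data.index[~keep])
    return table.select_features(table.data.index[keep]), dropped


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample to proportions summing to 1."""
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        empty = sums.index[sums == 0][0]
        raise ValueError(f"sample {empty!r} has zero total abundance")
    data = table.data.astype(float).div(sums, axis=1)
    return replace(table, data=data, kind="relative")


def collapse(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Cumulate feature abundances at a higher taxonomic rank.

    Features sharing the lineage prefix down to ``rank`` are summed into one
    row named after that lineage's last taxon.  Features lacking the rank are
    pooled under ``"unclassified"``.
    """
    if table.taxonomy is None:
        raise ValueError("collapse requires taxonomy")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    groups: dict[str, tuple[str, ...]] = {}
    labels: list[str] = []
    for fid in table.feature_ids:
        lineage = table.taxonomy.get(fid, ())
        if len(lineage) > level:
            prefix = tuple(lineage[: level + 1])
            name = prefix[-1]
        else:
            prefix = ("unclassified",)
            name = "unclassified"
        groups[name] = prefix
        labels.append(name)
    data = table.data.groupby(pd.Index(labels, name=rank), sort=False).sum()
    # float relative tables can drift by machine eps when regrouped
    return AbundanceTable(data=data, kind=table.kind, taxonomy=dict(groups))


def prevalence_filter(
    table: AbundanceTable,
    min_nonzero_fraction: float = 0.51,
    groups: pd.Series | None = None,
) -> AbundanceTable:
    """Keep features non-zero in >= ``min_nonzero_fraction`` of samples.

    With ``groups`` (a sample -> group mapping) the rule is enforced within
    EVERY group: a feature is kept only if it clears the fraction in each
    group separately.  The default 0.51 keeps features with a non-zero
    median in every group.
    """
    vals = table.values()
    nonzero = vals > 0
    if groups is None:
        keep = nonzero.mean(axis=1) >= min_nonzero_fraction
    else:
        groups = groups.reindex(table.sample_ids)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])
            raise ValueError(f"samples missing a group label: {missing}")
        keep = np.ones(table.n_features, dtype=bool)
        for g in groups.unique():
            idx = np.flatnonzero((groups == g).to_numpy())
            keep &= nonzero[:, idx].mean(axis=1) >= min_nonzero_fraction
    return table.select_features(table.data.index[keep])
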