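"""Feature tables, cohort metadata, and the standard pre-processing steps.

Tables are held samples-as-rows internally. Readers accept either
orientation via an explicit flag; nothing is auto-guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "CohortMetadata",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "to_relative",
    "prevalence_filter",
]

_ROW_SUM_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Samples x taxa non-negative abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa.
    kind : {"counts", "relative"}
        ``relative`` rows must sum to 1 (within 1e-9).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        vals = self.data.to_numpy(dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 2:
            raise ValueError("table needs at least 1 sample and 2 taxa")
        if not np.all(np.isfinite(vals)):
            raise ValueError("table contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("abundances must be non-negative")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers")
        if self.kind == "relative":
            rs = vals.sum(axis=1)
            if np.any(np.abs(rs - 1.0) > _ROW_SUM_TOL):
                raise ValueError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortMetadata:
    """Per-sample phenotype: group label and hepatic fat content (HFC, %).

    ``hfc_change`` is followup minus baseline in percentage points of liver
    fat; it is computed from the two HFC columns when not supplied.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"group", "hfc_baseline", "hfc_followup"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        self.data = self.data.astype(
            {c: float for c in ("hfc_baseline", "hfc_followup", "hfc_change") if c in self.data.columns}
        )
        if "hfc_change" not in self.data.columns:
            self.data = self.data.assign(
                hfc_change=self.data["hfc_followup"] - self.data["hfc_baseline"]
            )
        for col in ("hfc_baseline", "hfc_followup", "hfc_change"):
            v = self.data[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(v) & ~np.isnan(v)):
                raise ValueError(f"{col} contains non-finite values")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def hfc_change(self) -> pd.Series:
        return self.data["hfc_change"]

    def aligned_to(self, table: AbundanceTable) -> "CohortMetadata":
        """Reindex to the table's samples, erroring on any missing sample."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing}")
        return CohortMetadata(self.data.loc[table.sample_ids].copy())


# ---------------------------------------------------------------------------
# readers / writers


def read_table(
    path,
    format: str = "tsv",
    orientation: str = "samples_as_rows",
    kind: str | None = None,
) -> AbundanceTable:
    """Read a feature table from TSV or BIOM v2.1 (HDF5).

    ``orientation`` applies to TSV only ("samples_as_rows" or
    "taxa_as_rows"); BIOM stores observations (taxa) as rows by convention
    and is transposed on read. ``kind`` overrides the integer-based
    counts/relative detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "taxa_as_rows":
            df = df.T
        elif orientation != "samples_as_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
    elif format == "biom":
        df = _read_biom(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    df = df.astype(float)
    if kind is None:
        vals = df.to_numpy()
        kind = "counts" if np.allclose(vals, np.round(vals)) else "relative"
    return AbundanceTable(df, kind=kind)


def write_table(table: AbundanceTable, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = table.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom(path: Path) -> pd.DataFrame:
    """BIOM v2.1 HDF5 layout: CSR matrix under observation/matrix with
    observations (taxa) as rows."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        g = f["observation/matrix"]
        mat = csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(obs_ids), len(samp_ids)),
        )
    return pd.DataFrame(mat.toarray().T, index=samp_ids, columns=obs_ids)


def _write_biom(table: AbundanceTable, path: Path) -> None:
    import datetime

    import h5py
    from scipy.sparse import csc_matrix, csr_matrix

    dense = table.values.T  # observations x samples
    obs_csr = csr_matrix(dense)
    samp_csc = csc_matrix(dense)
    n_obs, n_samp = dense.shape
    str_dt = "S{}".format(max(1, max(len(str(t)) for t in table.taxon_ids + table.sample_ids)))
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = (2, 1)
        f.attrs["generated-by"] = "sparccnet"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = (n_obs, n_samp)
        f.attrs["nnz"] = int(obs_csr.nnz)
        f.create_dataset("observation/ids", data=np.array([str(t) for t in table.taxon_ids], dtype=str_dt))
        f.create_dataset("sample/ids", data=np.array([str(s) for s in table.sample_ids], dtype=str_dt))
        f.create_dataset("observation/matrix/data", data=obs_csr.data.astype(float))
        f.create_dataset("observation/matrix/indices", data=obs_csr.indices.astype(np.int64))
        f.create_dataset("observation/matrix/indptr", data=obs_csr.indptr.astype(np.int64))
        f.create_dataset("sample/matrix/data", data=samp_csc.data.astype(float))
        f.create_dataset("sample/matrix/indices", data=samp_csc.indices.astype(np.int64))
        f.create_dataset("sample/matrix/indptr", data=samp_csc.indptr.astype(np.int64))
        for grp in ("observation", "sample"):
            for sub in ("metadata", "group-metadata"):
                f.create_group(f"{grp}/{sub}")


def read_metadata(path) -> CohortMetadata:
    """Read a metadata TSV with columns sample_id, group, hfc_baseline,
    hfc_followup (hfc_change optional, recomputed if absent)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# preprocessing


def to_relative(table: AbundanceTable, pseudocount: float = 0.5) -> AbundanceTable:
    """Add a pseudocount and renormalise each sample to relative abundance.

    The pseudocount replaces zeros before the log-ratio transforms; 0.5 on
    counts is the conventional choice. Pass 0 to renormalise an already
    positive table unchanged.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = table.values + pseudocount
    rs = vals.sum(axis=1)
    if np.any(rs <= 0):
        bad = [table.sample_ids[i] for i in np.flatnonzero(rs <= 0)]
        raise ValueError(f"samples with zero total abundance: {bad}")
    rel = vals / rs[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        kind="relative",
    )


def prevalence_filter(table: AbundanceTable, min_prevalence: float = 0.2) -> AbundanceTable:
    """Keep taxa with strictly positive abundance in at least
    ceil(min_prevalence * S) samples (column order preserved).

    Prevalence is evaluated on the table as given, before any pseudocount.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    S = table.n_samples
    need = int(np.ceil(min_prevalence * S))
    present = (table.values > 0).sum(axis=0)
    keep = present >= need
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 taxa pass prevalence {min_prevalence:g}; correlation undefined"
        )
    return AbundanceTable(table.data.loc[:, keep], kind=table.kind)
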