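"""Domain types and I/O for multi-omics matrices and clinical tables.

The in-memory convention is rows = samples everywhere; files written
columns-are-samples can be read with ``orientation="columns"``. All
matrices are dense float64 with unique, ordered sample and feature IDs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "ClinicalTable",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_clinical_table",
    "standardize",
    "align_dataset",
    "write_labels",
]


def _check_unique(ids, kind: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = seen.get(x, 0) + 1
    if dups:
        raise ValueError(f"duplicate {kind} IDs: {sorted(set(dups))}")


@dataclasses.dataclass
class OmicsMatrix:
    """One omics view: an N samples x D features real matrix with IDs."""

    name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"{self.name}: values must be 2-D")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{self.name}: {len(self.sample_ids)} sample IDs for {n} rows"
            )
        if len(self.feature_ids) != d:
            raise ValueError(
                f"{self.name}: {len(self.feature_ids)} feature IDs for {d} columns"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def reorder(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Return a copy with rows re-indexed to `sample_ids` (all must exist)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"{self.name}: samples not present: {missing}")
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(
            self.name, list(sample_ids), list(self.feature_ids), self.values[idx]
        )


@dataclasses.dataclass
class MultiOmicsDataset:
    """Aligned genomics views plus a partially observed protein matrix.

    ``protein.values`` has a row for every sample; rows where
    ``protein_mask`` is False are placeholders (zeros) that never enter
    the translation loss.
    """

    views: list[OmicsMatrix]
    protein: OmicsMatrix
    protein_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("at least one genomics view is required")
        ids = self.views[0].sample_ids
        for v in self.views[1:]:
            if v.sample_ids != ids:
                raise ValueError(
                    f"view {v.name!r} sample order differs from {self.views[0].name!r}"
                )
        if self.protein.sample_ids != ids:
            raise ValueError("protein matrix sample order differs from views")
        self.protein_mask = np.asarray(self.protein_mask, dtype=bool)
        if self.protein_mask.shape != (len(ids),):
            raise ValueError("protein_mask length must equal the sample count")

    @property
    def sample_ids(self) -> list[str]:
        return self.views[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_observed(self) -> int:
        """Number of samples with observed protein data (training samples)."""
        return int(self.protein_mask.sum())


@dataclasses.dataclass
class ClinicalTable:
    """Survival outcome plus typed clinical covariates for a sample set."""

    sample_ids: list[str]
    survival_time: np.ndarray
    event: np.ndarray
    parameters: pd.DataFrame
    types: dict[str, str]  # column -> "discrete" | "continuous"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.survival_time = np.asarray(self.survival_time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.sample_ids)
        if self.survival_time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("survival_time and event must have one entry per sample")
        if np.any(self.survival_time < 0):
            raise ValueError("survival_time must be nonnegative")
        if len(self.parameters) != n:
            raise ValueError("parameters must have one row per sample")
        for col in self.parameters.columns:
            if self.types.get(col) not in ("discrete", "continuous"):
                raise ValueError(f"parameter {col!r} missing a discrete/continuous tag")

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(
            list(sample_ids),
            self.survival_time[idx],
            self.event[idx],
            self.parameters.iloc[idx].reset_index(drop=True),
            dict(self.types),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_omics_matrix(
    path,
    name: str | None = None,
    orientation: str = "rows",
    drop_missing: bool = False,
) -> OmicsMatrix:
    """Read a delimited omics matrix (TSV by default, CSV by extension).

    Parameters
    ----------
    orientation : "rows" if file rows are samples, "columns" if file
        columns are samples (the matrix is transposed on read).
    drop_missing : if True, features (columns) containing missing values
        are dropped, then any samples still containing missing values;
        if False, missing values are an error.
    """
    if orientation not in ("rows", "columns"):
        raise ValueError("orientation must be 'rows' or 'columns'")
    df = _read_delimited(path)
    if orientation == "columns":
        df = df.T
    for ids, kind in ((df.index, "sample"), (df.columns, "feature")):
        dupes = ids[ids.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"{path}: duplicate {kind} IDs: {dupes}")
    num = df.apply(pd.to_numeric, errors="coerce")
    # non-numeric cells: present in the raw frame but NaN after coercion
    raw_nan = df.isna()
    coerced_nan = num.isna() & ~raw_nan
    if coerced_nan.to_numpy().any():
        r, c = np.argwhere(coerced_nan.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iloc[r, c]!r} at sample "
            f"{df.index[r]!r}, feature {df.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        if drop_missing:
            trimmed = num.dropna(axis=1, how="any")
            num = trimmed if trimmed.shape[1] > 0 else num.dropna(axis=0, how="any")
            num = num.dropna(axis=0, how="any")
            if num.size == 0:
                raise ValueError(f"{path}: no complete rows/columns remain")
        else:
            r, c = np.argwhere(num.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at sample {num.index[r]!r}, "
                f"feature {num.columns[c]!r} (use drop_missing=True to drop)"
            )
    # numpy's parser is correctly rounded; pandas to_numeric can be 1 ulp off
    exact = df.loc[num.index, num.columns].astype(np.float64)
    return OmicsMatrix(
        name or Path(path).stem,
        list(num.index),
        list(num.columns),
        exact.to_numpy(),
    )


def write_omics_matrix(m: OmicsMatrix, path, orientation: str = "rows") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = m.to_frame()
    if orientation == "columns":
        df = df.T
    df.to_csv(path, sep=sep, index_label="id")


def read_clinical_table(
    path,
    discrete_threshold: int = 10,
    type_overrides: dict[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time, event, covariates...

    Non-numeric covariates are tagged discrete; numeric covariates with at
    most `discrete_threshold` distinct values are discrete, otherwise
    continuous. `type_overrides` forces a tag per column.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = ["sample_id", "time", "event"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    times = pd.to_numeric(df["time"], errors="raise").to_numpy()
    events = pd.to_numeric(df["event"], errors="raise").to_numpy().astype(bool)
    params = df.drop(columns=required)
    types: dict[str, str] = {}
    overrides = type_overrides or {}
    out = {}
    for col in params.columns:
        numeric = pd.to_numeric(params[col], errors="coerce")
        if numeric.notna().all():
            n_distinct = numeric.nunique()
            types[col] = "discrete" if n_distinct <= discrete_threshold else "continuous"
            out[col] = numeric
        else:
            types[col] = "discrete"
            out[col] = params[col]
        if col in overrides:
            types[col] = overrides[col]
    return ClinicalTable(
        list(df["sample_id"]),
        times,
        events,
        pd.DataFrame(out) if out else pd.DataFrame(index=range(len(df))),
        types,
    )


def write_labels(sample_ids, labels, path) -> None:
    """Write cluster labels as `sample_id<TAB>cluster`, clusters from 1."""
    pd.DataFrame({"sample_id": list(sample_ids), "cluster": np.asarray(labels)}).to_csv(
        Path(path), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Per-feature z-score (sample SD, ddof=1); constant columns map to zero."""
    x = m.values
    if not np.isfinite(x).all():
        raise ValueError(f"{m.name}: non-finite values; clean before standardizing")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return OmicsMatrix(m.name, list(m.sample_ids), list(m.feature_ids), out)


def align_dataset(
    views: list[OmicsMatrix],
    protein: OmicsMatrix,
    clinical: ClinicalTable | None = None,
) -> tuple[MultiOmicsDataset, ClinicalTable | None]:
    """Align genomics views and a partially observed protein matrix.

    All views must cover the same sample universe (every cohort sample has
    every genomics type); the protein matrix may cover a subset. The
    canonical sample order is the first view's order. Protein rows for
    unobserved samples are zero placeholders with mask False.
    """
    if not views:
        raise ValueError("no genomics views given")
    universe = list(views[0].sample_ids)
    uset = set(universe)
    for v in views[1:]:
        vset = set(v.sample_ids)
        if vset != uset:
            missing = sorted(uset - vset)
            extra = sorted(vset - uset)
            raise ValueError(
                f"view {v.name!r} does not cover the sample universe "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
    stray = sorted(set(protein.sample_ids) - uset)
    if stray:
        raise ValueError(f"protein samples not in the genomics universe: {stray[:5]}")
    if not set(protein.sample_ids):
        raise ValueError("protein matrix has no samples")
    aligned_views = [v.reorder(universe) for v in views]
    ppos = {s: i for i, s in enumerate(protein.sample_ids)}
    mask = np.array([s in ppos for s in universe], dtype=bool)
    if not mask.any():
        raise ValueError("empty intersection between protein and genomics samples")
    pvals = np.zeros((len(universe), protein.n_features))
    for i, s in enumerate(universe):
        if s in ppos:
            pvals[i] = protein.values[ppos[s]]
    aligned_protein = OmicsMatrix(
        protein.name, universe, list(protein.feature_ids), pvals
    )
    dataset = MultiOmicsDataset(aligned_views, aligned_protein, mask)
    aligned_clinical = None
    if clinical is not None:
        cset = set(clinical.sample_ids)
        missing = sorted(uset - cset)
        if missing:
            raise ValueError(f"clinical table missing samples: {missing[:5]}")
        aligned_clinical = clinical.subset(universe)
    return dataset, aligned_clinical
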