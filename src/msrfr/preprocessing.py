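"""Expression-matrix ingestion and preprocessing.

The pipeline for raw miRNA/mRNA quantifications (counts or FPKM-like
values) is: presence filter on raw values, log2(v + pseudocount),
cross-cohort alignment of samples and features, and per-cohort column
standardization.  The regression model downstream assumes every column
of every matrix has zero mean and unit sample standard deviation.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "ExpressionMatrix",
    "ClinicalTable",
    "MultitaskDataset",
    "read_expression_matrix",
    "read_clinical_table",
    "filter_low_expression",
    "log2_transform",
    "standardize_columns",
    "align_cohorts",
    "preprocess_cohorts",
]


class Stage(str, enum.Enum):
    """Processing stage of an expression matrix."""

    RAW = "raw"
    LOG2 = "log2"
    STANDARDIZED = "standardized"


@dataclass
class ExpressionMatrix:
    """A samples x features expression matrix with identifier metadata.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by sample identifiers, columns by feature
        identifiers.  Non-negative at stage ``raw``; unitless after
        standardization.
    stage : Stage
        Where in the preprocessing pipeline this matrix sits.
    """

    values: pd.DataFrame
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [
                (str(idx[i]), str(cols[j]))
                for i, j in zip(*np.where(self.values.map(_non_numeric)))
            ]
            raise ValueError(f"non-numeric cells at (sample, feature): {bad[:10]}")
        if self.stage is Stage.RAW and np.nanmin(arr, initial=0.0) < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at raw stage: sample {idx[i]!r}, feature {cols[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _non_numeric(x) -> bool:
    try:
        float(x)
        return False
    except (TypeError, ValueError):
        return True


@dataclass
class ClinicalTable:
    """Per-patient time-to-event data.

    ``time_days`` is days to death (event=1) or days to last follow-up
    (event=0, censored).
    """

    table: pd.DataFrame  # columns: patient_id, time_days, event

    REQUIRED = ("patient_id", "time_days", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        t = self.table
        if t["patient_id"].duplicated().any():
            dups = t.loc[t["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValueError(f"duplicate patients in clinical table: {dups}")
        if (t["time_days"] <= 0).any():
            raise ValueError("clinical times must be positive")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    def lookup(self, patient_ids) -> pd.DataFrame:
        """Rows for ``patient_ids`` in that order; unmatched ids are fatal."""
        indexed = self.table.set_index("patient_id")
        orphans = [p for p in patient_ids if p not in indexed.index]
        if orphans:
            raise KeyError(f"patients without clinical rows: {orphans}")
        return indexed.loc[list(patient_ids)].reset_index()


@dataclass
class MultitaskDataset:
    """K cohorts of matched, standardized miRNA (X) and mRNA (Y) matrices.

    All cohorts share one miRNA vocabulary (length D) and one mRNA
    vocabulary (length T); within a cohort X and Y cover the same
    samples in the same order.
    """

    cohort_names: list[str]
    X: list[ExpressionMatrix] = field(repr=False)
    Y: list[ExpressionMatrix] = field(repr=False)

    def __post_init__(self) -> None:
        if not (len(self.cohort_names) == len(self.X) == len(self.Y)):
            raise ValueError("cohort_names, X and Y must have equal length")
        mirnas = self.X[0].feature_ids
        mrnas = self.Y[0].feature_ids
        for name, x, y in zip(self.cohort_names, self.X, self.Y):
            if x.sample_ids != y.sample_ids:
                raise ValueError(f"cohort {name}: X/Y sample ids differ")
            if x.feature_ids != mirnas:
                raise ValueError(f"cohort {name}: miRNA features differ across cohorts")
            if y.feature_ids != mrnas:
                raise ValueError(f"cohort {name}: mRNA features differ across cohorts")

    @property
    def K(self) -> int:
        return len(self.cohort_names)

    @property
    def D(self) -> int:
        return self.X[0].n_features

    @property
    def T(self) -> int:
        return self.Y[0].n_features

    @property
    def n_samples(self) -> list[int]:
        return [x.n_samples for x in self.X]

    @property
    def mirna_ids(self) -> list[str]:
        return self.X[0].feature_ids

    @property
    def mrna_ids(self) -> list[str]:
        return self.Y[0].feature_ids

    def X_arrays(self) -> list[np.ndarray]:
        return [x.to_numpy() for x in self.X]

    def Y_arrays(self) -> list[np.ndarray]:
        return [y.to_numpy() for y in self.Y]

    # -- serialization ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write one TSV per matrix plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        hasher = hashlib.sha256()
        for name, x, y in zip(self.cohort_names, self.X, self.Y):
            for prefix, m in (("X", x), ("Y", y)):
                path = directory / f"{prefix}_{name}.tsv"
                m.values.to_csv(path, sep="\t", float_format="%.10g")
                hasher.update(path.read_bytes())
        manifest = {
            "cohort_names": self.cohort_names,
            "n_samples": self.n_samples,
            "n_mirnas": self.D,
            "n_mrnas": self.T,
            "stage": self.X[0].stage.value,
            "sha256": hasher.hexdigest(),
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "MultitaskDataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        names = manifest["cohort_names"]
        stage = Stage(manifest["stage"])
        X = [
            ExpressionMatrix(
                pd.read_csv(directory / f"X_{n}.tsv", sep="\t", index_col=0), stage
            )
            for n in names
        ]
        Y = [
            ExpressionMatrix(
                pd.read_csv(directory / f"Y_{n}.tsv", sep="\t", index_col=0), stage
            )
            for n in names
        ]
        return cls(names, X, Y)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    stage: Stage | str = Stage.RAW,
) -> ExpressionMatrix:
    """Read a delimited expression table (TSV/CSV by extension).

    The file must carry one header row and one identifier column.
    ``orientation`` says what the file's rows are; the returned matrix
    is always samples x features.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate identifiers in header: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "features_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, Stage(stage))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df["patient_id"] = df["patient_id"].astype(str)
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def filter_low_expression(
    m: ExpressionMatrix, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop features expressed (value > 0) in less than ``min_fraction`` of samples.

    A feature is kept when its expressed fraction is >= ``min_fraction``
    (the discard rule is "expressed in less than 50% of the tumors"), so
    exactly-at-threshold features survive.  Idempotent.
    """
    if m.stage is not Stage.RAW:
        raise ValueError("presence filtering is defined on raw values")
    frac = (m.values.to_numpy() > 0).mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError("no features pass the expression filter")
    return ExpressionMatrix(m.values.loc[:, keep], Stage.RAW)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """v -> log2(v + pseudocount).  With the default pseudocount, 0 maps to 0."""
    if m.stage is not Stage.RAW:
        raise ValueError("log2 transform expects raw values")
    if pseudocount <= 0 and (m.values.to_numpy() == 0).any():
        raise ValueError("pseudocount <= 0 with zero values present")
    return ExpressionMatrix(np.log2(m.values + pseudocount), Stage.LOG2)


def standardize_columns(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each column and scale to unit sample standard deviation (ddof=1).

    Zero-variance columns cannot be scaled and are removed with a warning.
    """
    if m.stage is Stage.RAW:
        raise ValueError("standardize after the log2 transform")
    vals = m.values
    sd = vals.std(axis=0, ddof=1)
    constant = (sd == 0) | sd.isna()
    if constant.any():
        dropped = list(vals.columns[constant])
        warnings.warn(
            f"removed {len(dropped)} zero-variance feature(s): {dropped[:5]}...",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("standardize_columns removed zero-variance features: %s", dropped)
        vals = vals.loc[:, ~constant]
        sd = sd[~constant]
    out = (vals - vals.mean(axis=0)) / sd
    return ExpressionMatrix(out, Stage.STANDARDIZED)


def align_cohorts(
    miRNA: list[ExpressionMatrix],
    mRNA: list[ExpressionMatrix],
    names: list[str],
) -> MultitaskDataset:
    """Restrict cohorts to matched samples and shared features, then standardize.

    Per cohort, samples are cut to the intersection of the miRNA and
    mRNA sample ids (order of first appearance in the miRNA matrix);
    features are cut to the intersection across all cohorts, separately
    for miRNAs and mRNAs, in the first cohort's order.  Standardization
    is (re)applied after every restriction so the model's zero-mean /
    unit-variance assumption holds exactly; features constant in any
    cohort are dropped everywhere to keep vocabularies identical.
    """
    if not (len(miRNA) == len(mRNA) == len(names)):
        raise ValueError("need one miRNA and one mRNA matrix per cohort")

    shared_mirnas = _ordered_intersection([m.feature_ids for m in miRNA])
    shared_mrnas = _ordered_intersection([m.feature_ids for m in mRNA])
    if not shared_mirnas or not shared_mrnas:
        raise ValueError("empty feature intersection across cohorts")

    Xs, Ys = [], []
    for name, x, y in zip(names, miRNA, mRNA):
        samples = [s for s in x.sample_ids if s in set(y.sample_ids)]
        if not samples:
            raise ValueError(f"cohort {name}: no samples with both profiles")
        Xs.append(x.values.loc[samples, shared_mirnas])
        Ys.append(y.values.loc[samples, shared_mrnas])

    # drop features constant in any cohort, then standardize per cohort
    for frames in (Xs, Ys):
        bad = set()
        for df in frames:
            sd = df.std(axis=0, ddof=1)
            bad |= set(df.columns[(sd == 0) | sd.isna()])
        if bad:
            warnings.warn(
                f"removed {len(bad)} feature(s) constant in at least one cohort",
                UserWarning,
                stacklevel=2,
            )
            for i, df in enumerate(frames):
                frames[i] = df.drop(columns=list(bad))
        if frames[0].shape[1] == 0:
            raise ValueError("no variable features left after alignment")

    stage = miRNA[0].stage
    X = [
        standardize_columns(ExpressionMatrix(df, stage if stage is not Stage.RAW else Stage.LOG2))
        for df in Xs
    ]
    Y = [
        standardize_columns(ExpressionMatrix(df, stage if stage is not Stage.RAW else Stage.LOG2))
        for df in Ys
    ]
    return MultitaskDataset(list(names), X, Y)


def _ordered_intersection(lists: list[list[str]]) -> list[str]:
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [f for f in lists[0] if f in common]


def preprocess_cohorts(
    miRNA_raw: list[ExpressionMatrix],
    mRNA_raw: list[ExpressionMatrix],
    names: list[str],
    min_fraction: float = 0.5,
    pseudocount: float = 1.0,
) -> MultitaskDataset:
    """Full pipeline: presence filter -> log2 -> align -> standardize."""
    miRNA = [log2_transform(filter_low_expression(m, min_fraction), pseudocount) for m in miRNA_raw]
    mRNA = [log2_transform(filter_low_expression(m, min_fraction), pseudocount) for m in mRNA_raw]
    return align_cohorts(miRNA, mRNA, names)
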