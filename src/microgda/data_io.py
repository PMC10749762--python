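"""Reading, writing and normalizing species-level relative-abundance tables.

Profiles are samples x species tables of compositional (relative) abundances,
as produced by MetaPhlAn- or mOTU-style taxonomic profilers, accompanied by
per-sample metadata (disease/health label and cohort of origin). Features are
log10-transformed with a pseudocount and z-scored with statistics estimated on
the *training* samples only; the same frozen statistics are applied to test
samples so that no test information enters normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: label encoding: health/control = 0, disease/case = 1, unlabeled = NaN
HEALTH, DISEASE = 0, 1
_LABEL_TO_CODE = {"health": 0.0, "disease": 1.0, "unknown": np.nan}
_CODE_TO_LABEL = {0.0: "health", 1.0: "disease"}


@dataclass
class AbundanceMatrix:
    """Samples x taxa relative-abundance table with per-sample annotations.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    taxa : list of str
        Unique species names, one per column of ``values``.
    values : ndarray of shape (n_samples, n_taxa)
        Non-negative relative abundances.
    cohort : list of str, optional
        Study/cohort label per sample.
    label : ndarray of shape (n_samples,), optional
        Disease status per sample: 1.0 disease, 0.0 health, NaN unlabeled.
    """

    sample_ids: list[str]
    taxa: list[str]
    values: np.ndarray
    cohort: list[str] | None = None
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x taxa matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.taxa) != p:
            raise ValueError(f"{len(self.taxa)} taxa for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxa)) != p:
            raise ValueError("duplicate taxon names")
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")
        if self.cohort is not None and len(self.cohort) != n:
            raise ValueError("cohort length does not match sample count")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=float)
            if self.label.shape != (n,):
                raise ValueError("label length does not match sample count")
            ok = np.isnan(self.label) | np.isin(self.label, [0.0, 1.0])
            if not np.all(ok):
                raise ValueError("labels must be 0 (health), 1 (disease) or NaN")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def labeled_mask(self) -> np.ndarray:
        if self.label is None:
            return np.zeros(self.n_samples, dtype=bool)
        return ~np.isnan(self.label)

    def subset(self, row_idx: np.ndarray) -> "AbundanceMatrix":
        """Row subset / reordering by integer index."""
        row_idx = np.asarray(row_idx)
        return AbundanceMatrix(
            sample_ids=[self.sample_ids[i] for i in row_idx],
            taxa=list(self.taxa),
            values=self.values[row_idx],
            cohort=None if self.cohort is None else [self.cohort[i] for i in row_idx],
            label=None if self.label is None else self.label[row_idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxa)


@dataclass
class NormalizationStats:
    """Frozen per-taxon normalization statistics estimated on training data."""

    mean: np.ndarray
    std: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape or self.mean.ndim != 1:
            raise ValueError("mean and std must be 1-D and of equal length")
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def save(self, path: str | Path) -> None:
        """Write a plain-text key-value table (taxon index, mean, std)."""
        with open(path, "w") as fh:
            fh.write(f"#pseudocount\t{float(self.pseudocount)!r}\n")
            fh.write("index\tmean\tstd\n")
            for i, (m, s) in enumerate(zip(self.mean, self.std)):
                fh.write(f"{i}\t{float(m)!r}\t{float(s)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationStats":
        with open(path) as fh:
            first = fh.readline().strip().split("\t")
            if first[0] != "#pseudocount":
                raise ValueError("not a NormalizationStats file")
            pc = float(first[1])
            fh.readline()  # header
            means, stds = [], []
            for line in fh:
                _, m, s = line.rstrip("\n").split("\t")
                means.append(float(m))
                stds.append(float(s))
        return cls(np.array(means), np.array(stds), pc)


def read_abundance_table(
    path: str | Path, orientation: str = "samples-in-rows"
) -> AbundanceMatrix:
    """Read a tab-separated abundance table.

    ``orientation`` selects whether rows are samples (``samples-in-rows``) or
    taxa (``samples-in-columns``); the returned matrix always has samples in
    rows. Duplicate identifiers, negative values and non-numeric cells are
    hard errors.
    """
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    columns = header[1:]
    if len(set(columns)) != len(columns):  # pandas silently mangles duplicates
        raise ValueError(f"duplicate column identifier in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate row identifier in {path}")
    if orientation == "samples-in-columns":
        df = df.T
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row(s) {list(bad)}"
            ) from exc
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    return AbundanceMatrix(
        sample_ids=[str(s) for s in df.index],
        taxa=[str(t) for t in df.columns],
        values=values,
    )


def write_abundance_table(
    m: AbundanceMatrix, path: str | Path, orientation: str = "samples-in-rows"
) -> None:
    """Write a matrix as TSV; inverse of :func:`read_abundance_table`."""
    df = m.to_frame()
    if orientation == "samples-in-columns":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: columns sample_id, label (disease/health/unknown), cohort."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "label", "cohort"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["label"]) - set(_LABEL_TO_CODE)
    if bad:
        raise ValueError(f"unknown label values: {sorted(bad)}")
    return meta


def write_metadata(m: AbundanceMatrix, path: str | Path) -> None:
    labels = []
    for i in range(m.n_samples):
        code = np.nan if m.label is None else m.label[i]
        labels.append("unknown" if np.isnan(code) else _CODE_TO_LABEL[code])
    pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "label": labels,
            "cohort": m.cohort if m.cohort is not None else ["NA"] * m.n_samples,
        }
    ).to_csv(path, sep="\t", index=False)


def attach_metadata(m: AbundanceMatrix, meta: pd.DataFrame) -> AbundanceMatrix:
    """Attach labels and cohort ids from a metadata frame (by sample_id)."""
    meta = meta.set_index("sample_id")
    missing = [s for s in m.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing samples: {missing[:5]}")
    label = np.array([_LABEL_TO_CODE[meta.loc[s, "label"]] for s in m.sample_ids])
    cohort = [str(meta.loc[s, "cohort"]) for s in m.sample_ids]
    return AbundanceMatrix(m.sample_ids, m.taxa, m.values, cohort=cohort, label=label)


def align_features(
    train: AbundanceMatrix, test: AbundanceMatrix
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Put two matrices on a shared, lexicographically sorted taxon union.

    Taxa absent from one matrix are zero-filled there (a taxon not reported by
    a profiler is taken as not detected). Sample order is preserved.
    """
    if train.n_samples == 0 or test.n_samples == 0:
        raise ValueError("cannot align empty matrices")
    union = sorted(set(train.taxa) | set(test.taxa))
    if not union:
        raise ValueError("empty taxon union")
    shared = set(train.taxa) & set(test.taxa)
    if not shared:
        logger.warning(
            "train and test share no taxa; aligned matrices are disjoint blocks"
        )

    def _expand(m: AbundanceMatrix) -> AbundanceMatrix:
        out = np.zeros((m.n_samples, len(union)))
        col = {t: j for j, t in enumerate(m.taxa)}
        for j, t in enumerate(union):
            if t in col:
                out[:, j] = m.values[:, col[t]]
        return AbundanceMatrix(
            list(m.sample_ids), union, out, cohort=m.cohort, label=m.label
        )

    return _expand(train), _expand(test)


def concat_samples(matrices: list[AbundanceMatrix]) -> AbundanceMatrix:
    """Stack matrices sample-wise; all must share an identical taxon list."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    taxa = matrices[0].taxa
    for m in matrices[1:]:
        if m.taxa != taxa:
            raise ValueError("taxon lists differ; align_features first")
    return AbundanceMatrix(
        sample_ids=[s for m in matrices for s in m.sample_ids],
        taxa=list(taxa),
        values=np.vstack([m.values for m in matrices]),
        cohort=(
            None
            if any(m.cohort is None for m in matrices)
            else [c for m in matrices for c in m.cohort]
        ),
        label=(
            None
            if any(m.label is None for m in matrices)
            else np.concatenate([m.label for m in matrices])
        ),
    )


def log10_transform(m: AbundanceMatrix | np.ndarray, pseudocount: float = 1e-5) -> np.ndarray:
    """log10(value + pseudocount), applied to every cell.

    The pseudocount is added to all cells (not only zeros) so the transform is
    strictly monotone in the raw abundance.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = m.values if isinstance(m, AbundanceMatrix) else np.asarray(m, dtype=float)
    return np.log10(values + pseudocount)


def zscore_fit(train_logged: np.ndarray, pseudocount: float = 1e-5) -> NormalizationStats:
    """Per-taxon mean and *population* standard deviation of training features."""
    train_logged = np.asarray(train_logged, dtype=float)
    if train_logged.shape[0] < 2:
        raise ValueError("need at least 2 training samples to fit z-score stats")
    return NormalizationStats(
        mean=train_logged.mean(axis=0),
        std=train_logged.std(axis=0, ddof=0),
        pseudocount=pseudocount,
    )


def zscore_apply(m_logged: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """(x - mean) / std with frozen training stats; zero-variance taxa map to 0."""
    m_logged = np.asarray(m_logged, dtype=float)
    if m_logged.shape[1] != stats.mean.shape[0]:
        raise ValueError(
            f"matrix has {m_logged.shape[1]} taxa, stats have {stats.mean.shape[0]}"
        )
    zero = stats.std == 0
    if np.any(zero):
        logger.warning(
            "%d zero-variance taxa normalized to 0 (column indices %s ...)",
            int(zero.sum()),
            np.flatnonzero(zero)[:10].tolist(),
        )
    safe_std = np.where(zero, 1.0, stats.std)
    out = (m_logged - stats.mean) / safe_std
    out[:, zero] = 0.0
    return out


def normalize_fit_apply(
    train: AbundanceMatrix, test: AbundanceMatrix, pseudocount: float = 1e-5
) -> tuple[np.ndarray, np.ndarray, NormalizationStats]:
    """Convenience: log10 + z-score both sets with stats fitted on train only."""
    logged_tr = log10_transform(train, pseudocount)
    stats = zscore_fit(logged_tr, pseudocount)
    x_tr = zscore_apply(logged_tr, stats)
    x_te = zscore_apply(log10_transform(test, pseudocount), stats)
    return x_tr, x_te, stats
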