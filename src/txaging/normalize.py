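"""Count-matrix containers, library-size normalization, and expression filters.

The analysis operates on a feature x sample matrix of non-negative integer
read counts. Two normalized scales are used downstream:

* ``log2(CPM)`` (counts per million) feeds the per-gene linear models; the
  low-expression filter on this scale keeps features with at least
  ``min_samples`` values at or above a log2(CPM) threshold.
* rounded ``CPB`` (counts per billion) feeds the negative-binomial models,
  which need integer responses; rounding at the CPB scale (rather than CPM)
  keeps the relative rounding error small.

Both filter thresholds (log2CPM >= -3; CPB >= 125) are the same physical
cut: 10 reads out of an 80-million-read library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_counts_tsv",
    "read_samples_tsv",
    "read_feature_map_tsv",
    "to_cpm",
    "to_cpb",
    "to_tpm",
    "drop_unexpressed",
    "filter_min_samples",
    "nb_exclusion_filter",
]

#: log2(CPM) value that compares below every finite threshold (a zero count
#: with pseudo-count 0).  ``-inf`` fails every ``>=`` filter by construction.
LOG2CPM_ZERO_SENTINEL = -np.inf


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with sample ids as columns.
    biotype
        Optional per-feature biotype annotation (e.g. ``protein_coding``).
    library_size
        Total aligned reads per sample.  Defaults to the column sums of
        ``counts`` (the total is not recoverable from a filtered table, so
        an externally measured value can be supplied).
    """

    counts: pd.DataFrame
    biotype: pd.Series | None = None
    library_size: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(float)
        else:
            self.library_size = pd.Series(self.library_size, dtype=float).reindex(
                self.counts.columns
            )
            if self.library_size.isna().any():
                raise ValueError("library_size missing for some samples")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class NormalizedMatrix:
    """Normalized expression values with an explicit unit tag."""

    values: pd.DataFrame
    unit: str  # CPM | log2CPM | CPB | CPB_rounded | TPM | log2TPM1
    pseudo: float = 0.0

    _UNITS = {"CPM", "log2CPM", "CPB", "CPB_rounded", "TPM", "log2TPM1"}

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# readers


def read_counts_tsv(path, biotype_col: str | None = None) -> CountMatrix:
    """Read a tab-separated feature x sample count table.

    The first column holds feature ids; an optional ``biotype_col`` is
    split off into the biotype annotation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    biotype = None
    if biotype_col is not None and biotype_col in df.columns:
        biotype = df.pop(biotype_col)
    return CountMatrix(counts=df, biotype=biotype)


def read_samples_tsv(path) -> pd.DataFrame:
    """Read sample metadata (columns: sample_id, age, sex[, group])."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("sample_id")
    if "age" not in df.columns or "sex" not in df.columns:
        raise ValueError("sample table needs 'age' and 'sex' columns")
    return df


def read_feature_map_tsv(path) -> pd.Series:
    """Read a two-column child->parent map (e.g. transcript_id, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("feature map needs two columns")
    return df.set_index(df.columns[0])[df.columns[1]]


# ---------------------------------------------------------------------------
# transforms


def _check_library(cm: CountMatrix) -> pd.Series:
    lib = cm.library_size
    bad = lib[lib <= 0]
    if len(bad):
        raise ValueError(f"zero/negative library size for samples: {list(bad.index)}")
    return lib


def to_cpm(cm: CountMatrix, log2: bool = False, pseudo: float = 0.0) -> NormalizedMatrix:
    """Counts per million, optionally log2-transformed.

    With ``pseudo=0`` a zero count maps to ``-inf`` on the log2 scale, which
    fails every ``>=`` threshold — the behaviour the -3 filter relies on.
    """
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    lib = _check_library(cm)
    cpm = cm.counts.div(lib, axis=1) * 1e6
    if not log2:
        return NormalizedMatrix(cpm, unit="CPM", pseudo=0.0)
    with np.errstate(divide="ignore"):
        vals = np.log2(cpm + pseudo)
    return NormalizedMatrix(vals, unit="log2CPM", pseudo=pseudo)


def to_cpb(cm: CountMatrix, rounded: bool = True) -> NormalizedMatrix:
    """Counts per billion; by default rounded half-up to integers.

    Half-up rounding (``floor(x + 0.5)``) makes the integerization rule
    explicit: 87.5 -> 88.
    """
    lib = _check_library(cm)
    cpb = cm.counts.div(lib, axis=1) * 1e9
    if not rounded:
        return NormalizedMatrix(cpb, unit="CPB")
    return NormalizedMatrix(np.floor(cpb + 0.5).astype(np.int64), unit="CPB_rounded")


def to_tpm(
    cm: CountMatrix, effective_lengths: pd.Series, log2: bool = True
) -> NormalizedMatrix:
    """Transcripts per million from counts and effective lengths.

    TPM divides each count by its feature's effective length, then scales
    each sample so the length-normalized values sum to 1e6.  With
    ``log2=True`` returns log2(TPM + 1).
    """
    lens = pd.Series(effective_lengths, dtype=float).reindex(cm.feature_ids)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("effective length missing or non-positive for some features")
    rate = cm.counts.div(lens, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    if not log2:
        return NormalizedMatrix(tpm, unit="TPM")
    return NormalizedMatrix(np.log2(tpm + 1.0), unit="log2TPM1", pseudo=1.0)


# ---------------------------------------------------------------------------
# filters


def drop_unexpressed(cm: CountMatrix) -> tuple[CountMatrix, int]:
    """Remove features with zero counts in every sample.

    Returns the reduced matrix and the number of removed features.  Library
    sizes are preserved (removing all-zero rows cannot change column sums,
    and an externally supplied total should survive filtering).
    """
    expressed = (cm.counts > 0).any(axis=1)
    n_removed = int((~expressed).sum())
    kept = cm.counts.loc[expressed]
    biotype = cm.biotype.loc[expressed] if cm.biotype is not None else None
    return CountMatrix(kept, biotype=biotype, library_size=cm.library_size), n_removed


def filter_min_samples(
    nm: NormalizedMatrix, threshold: float, min_samples: int = 10
) -> pd.Series:
    """Boolean mask: feature passes iff >= ``min_samples`` values are >= threshold.

    Defaults used in the pipeline: ``threshold=-3, min_samples=10`` on
    log2CPM; ``threshold=125, min_samples=10`` on rounded CPB.
    """
    n = nm.values.shape[1]
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds n_samples={n}")
    return (nm.values >= threshold).sum(axis=1) >= min_samples


def nb_exclusion_filter(
    cpb: NormalizedMatrix, max_zero_samples: int = 50, median_floor: float = 630
) -> tuple[pd.Series, pd.Series]:
    """Exclusions specific to the negative-binomial branch.

    A feature is excluded when its rounded CPB is zero in more than
    ``max_zero_samples`` samples (too many zeros to support a count model)
    or when its median CPB falls below ``median_floor`` (expression too low
    for a stable fit).  Returns ``(keep_mask, reasons)`` where ``reasons``
    labels each excluded feature with ``"excess zeros"`` or ``"low median"``
    (excess zeros takes precedence).
    """
    if cpb.unit != "CPB_rounded":
        raise ValueError("nb_exclusion_filter expects rounded CPB input")
    vals = cpb.values
    n_zero = (vals == 0).sum(axis=1)
    med = vals.median(axis=1)
    excess = n_zero > max_zero_samples
    low = (~excess) & (med < median_floor)
    reasons = pd.Series("", index=vals.index, dtype=object)
    reasons[excess] = "excess zeros"
    reasons[low] = "low median"
    keep = ~(excess | low)
    return keep, reasons[~keep]
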