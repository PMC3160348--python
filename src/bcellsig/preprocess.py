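"""Normalization, expression filtering and qPCR relative quantities."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    ConfigurationError,
    ExpressionMatrix,
    FormatError,
    SampleAnnotation,
)

__all__ = [
    "quantile_normalize",
    "filter_expressed",
    "FilterResult",
    "log2_transform",
    "CtTable",
    "delta_delta_ct",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 4.0

FILTER_RULES = ("group_mean", "overall_mean", "max", "median")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize the value distribution across samples.

    Every sample's sorted value vector is replaced by the across-sample
    mean of sorted vectors; ties within a sample receive the mean of
    the reference values over their rank span (average ranks).
    """
    if matrix.n_samples < 2:
        raise ConfigurationError("quantile normalization needs at least 2 samples")
    X = matrix.values.to_numpy(float)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(X.shape[0], dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.gene_symbols,
    )


@dataclass
class FilterResult:
    """Outcome of the expression filter."""

    matrix: ExpressionMatrix
    n_input: int
    n_retained: int
    threshold: float
    rule: str

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0


def filter_expressed(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    rule: str = "group_mean",
) -> FilterResult:
    """Drop probes that are unexpressed in both groups.

    Under the default ``group_mean`` rule a probe is retained iff its
    mean log2 value reaches the threshold in at least one group
    (equivalently: dropped iff below threshold in both controls and
    patients).  Alternative rules: ``overall_mean``, ``max`` (any
    sample), ``median`` (overall median).
    """
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    if rule not in FILTER_RULES:
        raise ConfigurationError(f"unknown filter rule {rule!r}; use one of {FILTER_RULES}")
    X = matrix.values
    if rule == "group_mean":
        if annotation is None:
            raise ConfigurationError("group_mean rule needs a sample annotation")
        annotation.check_matches(matrix)
        keep = pd.Series(False, index=X.index)
        for group_samples in (annotation.controls, annotation.patients):
            cols = [s for s in group_samples if s in X.columns]
            if cols:
                keep |= X[cols].mean(axis=1) >= threshold
    elif rule == "overall_mean":
        keep = X.mean(axis=1) >= threshold
    elif rule == "max":
        keep = X.max(axis=1) >= threshold
    else:  # median
        keep = X.median(axis=1) >= threshold
    retained = matrix.subset_probes(keep.to_numpy())
    if retained.n_probes == 0:
        warnings.warn("expression filter removed every probe")
    return FilterResult(
        matrix=retained,
        n_input=matrix.n_probes,
        n_retained=retained.n_probes,
        threshold=threshold,
        rule=rule,
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Apply log2(x + offset) for matrices supplied on the linear scale."""
    X = matrix.values.to_numpy(float)
    if (X + offset <= 0).any():
        raise ConfigurationError("log2 transform undefined: values <= -offset present")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(X + offset), index=matrix.values.index, columns=matrix.values.columns
        ),
        matrix.gene_symbols,
    )


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements with a designated calibrator sample.

    ``rows`` needs columns sample_id, gene, ct_target, ct_reference;
    the reference is the endogenous control (e.g. 18S rRNA).
    """

    rows: pd.DataFrame
    calibrator_sample_id: str

    REQUIRED = ("sample_id", "gene", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise FormatError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.rows[["ct_target", "ct_reference"]].to_numpy(float)
        if not np.isfinite(ct).all():
            raise FormatError("non-finite Ct values")
        if self.calibrator_sample_id not in set(self.rows["sample_id"]):
            raise FormatError(
                f"calibrator sample {self.calibrator_sample_id!r} absent from table"
            )

    @classmethod
    def read(cls, path, calibrator_sample_id: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), calibrator_sample_id)


def delta_delta_ct(ct: CtTable) -> pd.DataFrame:
    """Relative expression by the comparative Ct method.

    Per sample and gene: dCt = Ct_target - Ct_reference; ddCt =
    dCt_sample - dCt_calibrator; relative quantity = 2**(-ddCt).  The
    calibrator's relative quantity is exactly 1 for every gene.
    """
    df = ct.rows.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out = []
    for gene, sub in df.groupby("gene", sort=True):
        cal = sub[sub["sample_id"] == ct.calibrator_sample_id]
        if cal.empty:
            raise FormatError(f"no calibrator row for gene {gene!r}")
        cal_dct = float(cal["delta_ct"].iloc[0])
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - cal_dct
        sub["relative_quantity"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)[
        ["sample_id", "gene", "delta_ct", "delta_delta_ct", "relative_quantity"]
    ]
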