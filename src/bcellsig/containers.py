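"""Core in-memory containers shared across the pipeline.

An :class:`ExpressionMatrix` holds log2-scale probe-set intensities
(probes x samples) together with an optional probe -> gene-symbol
annotation.  A :class:`SampleAnnotation` carries the binary
control/patient label plus any clinical covariates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
PATIENT = "patient"
GROUPS = (CONTROL, PATIENT)


class FormatError(ValueError):
    """An input file violates its declared layout."""


class ConfigurationError(ValueError):
    """Simulation or pipeline parameters are inconsistent."""


@dataclass
class ExpressionMatrix:
    """Probe-set x sample matrix of log2 intensities.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns.
        No missing values are allowed; probe ids must be unique.
    gene_symbols
        Per-probe gene symbol, aligned to ``values.index``.  Empty
        string for probes without an annotation.  Multiple probes may
        map to the same symbol.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise FormatError(f"duplicate probe ids: {dup}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(vals).all():
            raise FormatError("expression matrix contains missing/non-finite values")
        self.values = self.values.astype(float)
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=self.values.index, dtype=object)
        else:
            self.gene_symbols = (
                pd.Series(self.gene_symbols)
                .reindex(self.values.index)
                .fillna("")
                .astype(str)
            )

    # -- convenience accessors -------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes: Sequence | np.ndarray) -> "ExpressionMatrix":
        """Return a matrix restricted to ``probes`` (ids or boolean mask)."""
        if isinstance(probes, (np.ndarray, pd.Series)) and getattr(probes, "dtype", None) == bool:
            sub = self.values.loc[np.asarray(probes)]
        else:
            sub = self.values.loc[list(probes)]
        return ExpressionMatrix(sub, self.gene_symbols.reindex(sub.index))

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.gene_symbols)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.gene_symbols.copy())


@dataclass
class SampleAnnotation:
    """Per-sample group label (control/patient) plus clinical fields.

    ``table`` is indexed by sample id and must contain a ``group``
    column taking values in ``{"control", "patient"}``.  Any further
    columns (age, sex, SLEDAI, ...) ride along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise FormatError("annotation table must have a 'group' column")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in annotation")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")

    @classmethod
    def from_groups(cls, groups: dict[str, str]) -> "SampleAnnotation":
        return cls(pd.DataFrame({"group": pd.Series(groups, dtype=object)}))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def controls(self) -> list[str]:
        return list(self.table.index[self.table["group"] == CONTROL])

    @property
    def patients(self) -> list[str]:
        return list(self.table.index[self.table["group"] == PATIENT])

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def for_samples(self, samples: Iterable[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(samples)].copy())

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples without annotation: {sorted(missing)[:5]}")
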