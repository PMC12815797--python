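"""Core containers shared across the pipeline stages.

An :class:`OmicsLayer` is one named sample-by-feature matrix (mRNA, miRNA,
methylation, protein, ...) together with the metadata the preprocessing
stage needs: which value domain the entries live in and whether the layer
has already been min–max normalized.  A :class:`MultiOmicsDataset` is a
list of layers that share one sample index in one order, plus an
append-only provenance log of the processing steps applied so far.

Matrices are held as :class:`pandas.DataFrame` objects (rows = samples,
columns = features); missing entries are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALUE_DOMAINS = ("continuous", "unit_interval", "nonneg_continuous")


@dataclass
class OmicsLayer:
    name: str
    values: pd.DataFrame  # rows = samples, columns = features, NaN = missing
    value_domain: str = "continuous"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.value_domain not in VALUE_DOMAINS:
            raise ValueError(
                f"unknown value_domain {self.value_domain!r}; "
                f"expected one of {VALUE_DOMAINS}"
            )
        if self.values.index.has_duplicates:
            raise ValueError(f"layer {self.name!r}: duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError(f"layer {self.name!r}: duplicate feature ids")

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

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame, **kwargs) -> "OmicsLayer":
        """Copy of this layer with a new matrix (and optional field overrides)."""
        return replace(self, values=values, **kwargs)


@dataclass
class MultiOmicsDataset:
    layers: list[OmicsLayer]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("dataset needs at least one layer")
        ref = self.layers[0].sample_ids
        for layer in self.layers[1:]:
            if layer.sample_ids != ref:
                raise ValueError(
                    f"layer {layer.name!r} does not share the sample index of "
                    f"layer {self.layers[0].name!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.layers[0].n_samples

    def layer(self, name: str) -> OmicsLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(f"no layer named {name!r}")

    def log(self, message: str) -> None:
        self.provenance.append(message)


def check_finite(matrix: np.ndarray | pd.DataFrame, what: str = "matrix") -> None:
    arr = np.asarray(matrix, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} contains non-finite values (NaN or inf)")
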