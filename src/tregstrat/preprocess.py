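"""Per-layer preprocessing: sample intersection, missingness QC, KNN
imputation, min–max normalization, top-variance feature selection, and
concatenation of the layers into one joint matrix.

The canonical sample order after intersection is the lexicographic sort
of the common sample ids, which makes the result independent of input
file order.  KNN imputation works in sample space: a missing entry
(sample *s*, feature *f*) is replaced by the mean of *f* over the *k*
samples nearest to *s* by Euclidean distance computed on the features
observed in both samples, skipping candidate neighbors that are missing
*f* themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MultiOmicsDataset, OmicsLayer


@dataclass
class PreprocessConfig:
    max_missing_frac: float = 0.2
    knn_k: int = 5
    # retained feature counts per layer (capped at availability by the driver)
    retain: dict[str, int] = field(
        default_factory=lambda: {
            "mRNA": 2000,
            "miRNA": 482,
            "methylation": 2000,
            "protein": 217,
        }
    )
    # which layers get min-max scaling; methylation keeps native beta values
    # and protein arrives pre-normalized, so both default to "none"
    normalize: dict[str, str] = field(
        default_factory=lambda: {
            "mRNA": "minmax",
            "miRNA": "minmax",
            "methylation": "none",
            "protein": "none",
        }
    )
    normalize_then_select: bool = True

    def validate(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if any(v < 1 for v in self.retain.values()):
            raise ValueError("retain counts must be >= 1")
        for name, mode in self.normalize.items():
            if mode not in ("minmax", "none"):
                raise ValueError(f"layer {name!r}: unknown normalize mode {mode!r}")


def intersect_samples(layers: list[OmicsLayer]) -> MultiOmicsDataset:
    """Restrict every layer to the common samples, sorted lexicographically."""
    if not layers:
        raise ValueError("need at least one layer")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        nxt = common & set(layer.sample_ids)
        if not nxt:
            raise ValueError(
                f"no common samples between layer {layers[0].name!r} "
                f"(as intersected so far) and layer {layer.name!r}"
            )
        common = nxt
    order = sorted(common)
    new_layers = [lyr.with_values(lyr.values.loc[order]) for lyr in layers]
    ds = MultiOmicsDataset(layers=new_layers)
    ds.log(f"intersect_samples: {len(order)} common samples")
    return ds


def filter_features_by_missing(
    layer: OmicsLayer, max_missing_frac: float
) -> OmicsLayer:
    """Drop features whose missing fraction exceeds the threshold (inclusive keep)."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = layer.values.isna().mean(axis=0)
    keep = frac[frac <= max_missing_frac].index
    if len(keep) == 0:
        raise ValueError(
            f"layer {layer.name!r}: every feature exceeds missing fraction "
            f"{max_missing_frac}; raise the threshold or inspect the data"
        )
    return layer.with_values(layer.values[keep])


def knn_impute(layer: OmicsLayer, k: int = 5) -> OmicsLayer:
    """Sample-space KNN imputation (see module docstring for the metric)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = layer.values.to_numpy(dtype=float, copy=True)
    obs = ~np.isnan(X)
    if layer.n_missing() == 0:
        return layer
    if not obs.any(axis=1).all():
        bad = int(np.argmin(obs.any(axis=1)))
        raise ValueError(
            f"layer {layer.name!r}: sample {layer.sample_ids[bad]!r} has no "
            "observed features; cannot impute"
        )
    if not obs.any(axis=0).all():
        bad = int(np.argmin(obs.any(axis=0)))
        raise ValueError(
            f"layer {layer.name!r}: feature {layer.feature_ids[bad]!r} has no "
            "observed values; filter it out before imputing"
        )

    # pairwise squared distance over features observed in BOTH samples:
    # d2_st = sum_f obs_s obs_t (x_sf - x_tf)^2
    X0 = np.where(obs, X, 0.0)
    M = obs.astype(float)
    sq = X0**2
    d2 = sq @ M.T + M @ sq.T - 2.0 * (X0 @ X0.T)
    np.maximum(d2, 0.0, out=d2)

    out = X.copy()
    missing_rows = np.where(~obs.all(axis=1))[0]
    n = X.shape[0]
    for s in missing_rows:
        dist = d2[s].copy()
        dist[s] = np.inf
        for f in np.where(~obs[s])[0]:
            cand = np.where(obs[:, f])[0]
            cand = cand[cand != s]
            # stable tie-break by sample order
            nearest = cand[np.argsort(dist[cand], kind="stable")[:k]]
            out[s, f] = X[nearest, f].mean()
    assert not np.isnan(out).any()
    return layer.with_values(
        pd.DataFrame(out, index=layer.values.index, columns=layer.values.columns)
    )


def minmax_normalize(layer: OmicsLayer) -> OmicsLayer:
    """Per-feature rescale to [0, 1]; constant features map to 0."""
    X = layer.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            f"layer {layer.name!r} has missing entries; impute before normalizing"
        )
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng_safe = np.where(rng > 0, rng, 1.0)
    scaled = (X - lo) / rng_safe
    return layer.with_values(
        pd.DataFrame(scaled, index=layer.values.index, columns=layer.values.columns),
        normalized=True,
    )


def select_top_variance(layer: OmicsLayer, n: int) -> OmicsLayer:
    """Keep the n highest-variance features, preserving original column order."""
    if n > layer.n_features:
        raise ValueError(
            f"layer {layer.name!r}: requested {n} features but only "
            f"{layer.n_features} available"
        )
    X = layer.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(f"layer {layer.name!r} has missing entries; impute first")
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    # stable sort on -variance keeps original order among ties
    top = np.sort(np.argsort(-var, kind="stable")[:n])
    return layer.with_values(layer.values.iloc[:, top])


def concatenate_layers(dataset: MultiOmicsDataset) -> pd.DataFrame:
    """Column-wise concatenation; feature ids become '<layer>:<feature>'."""
    ref = dataset.layers[0].sample_ids
    blocks = []
    for layer in dataset.layers:
        if layer.sample_ids != ref:
            raise ValueError(
                f"layer {layer.name!r} sample order differs from layer "
                f"{dataset.layers[0].name!r}; intersect_samples first"
            )
        if layer.n_missing():
            raise ValueError(f"layer {layer.name!r} still has missing entries")
        block = layer.values.copy()
        block.columns = [f"{layer.name}:{c}" for c in block.columns]
        blocks.append(block)
    return pd.concat(blocks, axis=1)


def preprocess_dataset(
    layers: list[OmicsLayer] | MultiOmicsDataset,
    config: PreprocessConfig | None = None,
) -> tuple[MultiOmicsDataset, pd.DataFrame]:
    """Full preprocessing driver: intersect -> filter -> impute -> normalize
    -> select -> concatenate.  Returns the processed dataset and the joint
    matrix."""
    config = config or PreprocessConfig()
    config.validate()
    if isinstance(layers, MultiOmicsDataset):
        provenance = list(layers.provenance)
        layers = layers.layers
    else:
        provenance = []
    ds = intersect_samples(list(layers))
    ds.provenance = provenance + ds.provenance

    processed = []
    for layer in ds.layers:
        before = layer.n_features
        layer = filter_features_by_missing(layer, config.max_missing_frac)
        dropped = before - layer.n_features
        if layer.n_missing():
            layer = knn_impute(layer, k=config.knn_k)
        mode = config.normalize.get(layer.name, "minmax")

        def _select(lyr: OmicsLayer) -> OmicsLayer:
            want = config.retain.get(lyr.name, lyr.n_features)
            if want > lyr.n_features:
                warnings.warn(
                    f"layer {lyr.name!r}: requested {want} features, only "
                    f"{lyr.n_features} available; keeping all",
                    stacklevel=3,
                )
                want = lyr.n_features
            return select_top_variance(lyr, want)

        if config.normalize_then_select:
            if mode == "minmax":
                layer = minmax_normalize(layer)
            layer = _select(layer)
        else:
            layer = _select(layer)
            if mode == "minmax":
                layer = minmax_normalize(layer)
        ds.log(
            f"layer {layer.name}: dropped {dropped} high-missing features, "
            f"retained {layer.n_features}, normalize={mode}"
        )
        processed.append(layer)

    out = MultiOmicsDataset(layers=processed, provenance=ds.provenance)
    joint = concatenate_layers(out)
    out.log(f"joint matrix: {joint.shape[0]} samples x {joint.shape[1]} features")
    return out, joint
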