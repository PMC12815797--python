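"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices travel as TSV with samples in rows (first column = sample id,
header = feature ids); an ``orientation`` flag accepts genes-by-samples
files as produced by most expression portals.  Gene sets use the GMT
convention (name, description, then one gene per tab).  Tumor-growth
studies are long-format CSV with one row per animal per day.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import MultiOmicsDataset, OmicsLayer


# ---------------------------------------------------------------- matrices

def read_matrix(
    path: str | Path,
    sep: str = "\t",
    orientation: str = "samples_by_features",
) -> pd.DataFrame:
    """Read a matrix TSV/CSV into a samples-by-features DataFrame.

    ``orientation='features_by_samples'`` transposes on read.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="sample_id")


def read_layer(
    path: str | Path,
    name: str,
    value_domain: str = "continuous",
    sep: str = "\t",
    orientation: str = "samples_by_features",
) -> OmicsLayer:
    return OmicsLayer(
        name=name,
        values=read_matrix(path, sep=sep, orientation=orientation),
        value_domain=value_domain,
    )


def write_dataset(dataset: MultiOmicsDataset, outdir: str | Path) -> dict:
    """Write each layer as TSV plus a manifest JSON; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"layers": [], "provenance": dataset.provenance}
    for layer in dataset.layers:
        fname = f"{layer.name}.tsv"
        write_matrix(layer.values, outdir / fname)
        manifest["layers"].append(
            {
                "name": layer.name,
                "file": fname,
                "n_samples": layer.n_samples,
                "n_features": layer.n_features,
                "value_domain": layer.value_domain,
                "normalized": layer.normalized,
                "n_missing": layer.n_missing(),
            }
        )
    with open(outdir / "dataset_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: [genes]} (description column dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            name, _desc, *genes = parts
            genes = [g.strip().upper() for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ----------------------------------------------------------- growth studies

def read_growth_csv(path: str | Path) -> pd.DataFrame:
    """Load a long-format growth study.

    Expects columns ``animal, arm, day`` plus either ``volume_mm3`` or
    caliper columns ``length_mm, width_mm`` (volumes are then derived with
    the standard L*W^2/2 formula).
    """
    df = pd.read_csv(path)
    required = {"animal", "arm", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV missing columns: {sorted(missing)}")
    if "volume_mm3" not in df.columns:
        if not {"length_mm", "width_mm"} <= set(df.columns):
            raise ValueError(
                "growth CSV needs volume_mm3 or length_mm+width_mm columns"
            )
        from .efficacy import tumor_volume

        df["volume_mm3"] = [
            tumor_volume(l, w) for l, w in zip(df["length_mm"], df["width_mm"])
        ]
    return df[["animal", "arm", "day", "volume_mm3"]].copy()


def write_growth_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ------------------------------------------------------------------- JSON

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2)


def _jsonify(obj):
    """Recursively coerce numpy scalars/arrays (incl. dict keys) to JSON types."""
    import numpy as np

    if isinstance(obj, dict):
        return {_jsonify(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
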