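"""Synthetic multi-omics and tumor-growth generators with planted ground truth.

Every downstream stage of the pipeline is exercised against data produced
here, so the generators are deliberately simple and fully seeded:

* **Multi-omics**: ``n_clusters`` latent sample groups shared across all
  layers.  A random subset of each layer's features ("informative"
  features) carries the cluster signal as additive per-cluster mean
  shifts; one designated cluster additionally over-expresses a 9-gene
  regulatory T cell (Treg) signature, a 6-gene T-cell exhaustion panel
  and two small immune gene sets in the mRNA layer.  Values are then
  pushed through a monotone transform into each layer's value domain
  (log-normal for counts-like layers, logistic for methylation-style
  beta values) and missing entries are injected uniformly at random.

* **Tumor growth**: per-animal exponential growth
  ``V(t) = V0 * exp(rate * effect * t) * noise`` with multiplicative
  log-normal measurement noise and arm-specific rate multipliers, on the
  caliper schedule days 0, 2, 4, 7, 9, 11, 14.  Animals are block
  randomized to arms by baseline volume.

Identical config (including seed) always yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MultiOmicsDataset, OmicsLayer

# Nine-gene Treg signature: core identity markers, immunosuppressive
# cytokines, and Treg-recruitment chemokines.
TREG_GENES = (
    "FOXP3", "CCR8", "IL2RA", "TGFB1", "IL10",
    "CCL1", "CCL22", "CCL17", "CXCL12",
)

# T-cell exhaustion marker panel.
EXHAUSTION_MARKERS = ("PDCD1", "CTLA4", "LAG3", "TIGIT", "TOX", "ENTPD1")

# Small immune programs planted alongside the Treg signature so that
# ORA / immune-score selection criteria have something to detect.
IMMUNE_SET_SIZES = {"IMMUNE_RESPONSE": 25, "CYTOKINE_SIGNALING": 25}


@dataclass
class SyntheticOmicsConfig:
    n_samples: int = 300
    n_clusters: int = 3
    layer_specs: list[tuple[str, int, str]] = field(
        default_factory=lambda: [
            ("mRNA", 500, "nonneg_continuous"),
            ("miRNA", 150, "nonneg_continuous"),
            ("methylation", 400, "unit_interval"),
            ("protein", 120, "continuous"),
        ]
    )
    cluster_sep: float = 3.0        # per-feature cluster mean scale, SD units
    frac_informative: float = 0.2   # fraction of features carrying cluster signal
    treg_cluster: int = 0           # cluster index receiving the Treg spike
    treg_effect: float = 2.0        # additive SD-unit shift on signature genes
    spike_intensity_cv: float = 0.3  # per-sample variation of the spike strength
    spike_exhaustion: bool = True   # co-spike the exhaustion panel
    mirror_treg_in_protein: bool = False
    background_corr: float = 0.0    # shared latent background factor weight
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_samples < self.n_clusters:
            raise ValueError("n_samples must be >= n_clusters")
        if not 0.0 <= self.frac_informative <= 1.0:
            raise ValueError("frac_informative must lie in [0, 1]")
        if not 0 <= self.treg_cluster < self.n_clusters:
            raise ValueError("treg_cluster must index an existing cluster")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.background_corr < 1.0:
            raise ValueError("background_corr must lie in [0, 1)")
        from .datatypes import VALUE_DOMAINS

        for name, n_features, domain in self.layer_specs:
            if domain not in VALUE_DOMAINS:
                raise ValueError(f"layer {name!r}: unknown value_domain {domain!r}")
            if n_features < 1:
                raise ValueError(f"layer {name!r}: n_features must be >= 1")


@dataclass
class SyntheticTruth:
    labels: np.ndarray                       # per-sample true cluster index
    informative_features: dict[str, list[str]]  # per layer
    treg_genes: list[str]
    exhaustion_markers: list[str]
    immune_sets: dict[str, list[str]]
    treg_cluster: int


def _mrna_feature_names(n_features: int) -> list[str]:
    """mRNA feature ids: real signature symbols first, filler genes after."""
    named = list(TREG_GENES) + list(EXHAUSTION_MARKERS)
    for set_name, size in IMMUNE_SET_SIZES.items():
        prefix = "IMM" if set_name == "IMMUNE_RESPONSE" else "CYT"
        named += [f"{prefix}{i:03d}" for i in range(size)]
    if n_features < len(named):
        raise ValueError(
            f"mRNA layer needs at least {len(named)} features to hold the "
            "planted signature genes"
        )
    filler = [f"GENE{i:05d}" for i in range(n_features - len(named))]
    return named + filler


def immune_set_genes() -> dict[str, list[str]]:
    out = {}
    for set_name, size in IMMUNE_SET_SIZES.items():
        prefix = "IMM" if set_name == "IMMUNE_RESPONSE" else "CYT"
        out[set_name] = [f"{prefix}{i:03d}" for i in range(size)]
    return out


def _to_domain(x: np.ndarray, domain: str) -> np.ndarray:
    if domain == "continuous":
        return x
    if domain == "nonneg_continuous":
        # log-normal: positive, right-skewed, counts-like
        return np.exp(0.5 * x)
    if domain == "unit_interval":
        # logistic squash: beta-value-like, stays in (0, 1)
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown value_domain {domain!r}")


def generate_multiomics(
    config: SyntheticOmicsConfig,
) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Generate a multi-layer dataset with planted cluster and Treg structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_samples
    labels = rng.permutation(np.arange(n) % config.n_clusters)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    treg_mask = labels == config.treg_cluster
    immune_sets = immune_set_genes()

    shared = rng.standard_normal(n)  # optional cross-layer background factor

    layers: list[OmicsLayer] = []
    informative: dict[str, list[str]] = {}
    for name, n_features, domain in config.layer_specs:
        if name == "mRNA":
            feature_ids = _mrna_feature_names(n_features)
            n_reserved = (
                len(TREG_GENES) + len(EXHAUSTION_MARKERS)
                + sum(IMMUNE_SET_SIZES.values())
            )
        else:
            feature_ids = [f"{name}_{i:04d}" for i in range(n_features)]
            n_reserved = 0

        z = rng.standard_normal((n, n_features))
        if config.background_corr > 0:
            c = config.background_corr
            z = np.sqrt(1 - c) * z + np.sqrt(c) * shared[:, None]

        # additive cluster-mean design on a random non-signature subset
        n_info = int(round(config.frac_informative * n_features))
        candidates = np.arange(n_reserved, n_features)
        n_info = min(n_info, candidates.size)
        info_idx = np.sort(rng.choice(candidates, size=n_info, replace=False))
        if n_info:
            centers = config.cluster_sep * rng.standard_normal(
                (config.n_clusters, n_info)
            )
            z[:, info_idx] += centers[labels]
        informative[name] = [feature_ids[j] for j in info_idx]

        if name == "mRNA" and config.treg_effect != 0:
            spiked = list(TREG_GENES)
            if config.spike_exhaustion:
                spiked += list(EXHAUSTION_MARKERS)
            for genes in immune_sets.values():
                spiked += genes
            cols = [feature_ids.index(g) for g in spiked]
            # per-sample spike intensity (lognormal, mean 1): Treg burden
            # varies between tumors, which couples the signature genes and
            # the exhaustion panel within the spiked cluster
            cv = config.spike_intensity_cv
            if cv > 0:
                s = np.sqrt(np.log1p(cv**2))
                intensity = np.exp(rng.normal(-0.5 * s**2, s, int(treg_mask.sum())))
            else:
                intensity = np.ones(int(treg_mask.sum()))
            z[np.ix_(treg_mask, cols)] += config.treg_effect * intensity[:, None]

        if name == "protein" and config.mirror_treg_in_protein and config.treg_effect != 0:
            n_mirror = min(len(TREG_GENES), n_features)
            z[treg_mask, :n_mirror] += config.treg_effect

        values = pd.DataFrame(
            _to_domain(z, domain), index=sample_ids, columns=feature_ids
        )
        layer = OmicsLayer(name=name, values=values, value_domain=domain)
        if config.missing_rate > 0:
            layer = inject_missing(
                layer, config.missing_rate, seed=int(rng.integers(2**31))
            )
        layers.append(layer)

    dataset = MultiOmicsDataset(
        layers=layers,
        provenance=[
            f"synthetic: n={n}, K={config.n_clusters}, sep={config.cluster_sep}, "
            f"treg_cluster={config.treg_cluster}, treg_effect={config.treg_effect}, "
            f"missing_rate={config.missing_rate}, seed={config.seed}"
        ],
    )
    truth = SyntheticTruth(
        labels=labels,
        informative_features=informative,
        treg_genes=list(TREG_GENES),
        exhaustion_markers=list(EXHAUSTION_MARKERS),
        immune_sets=immune_sets,
        treg_cluster=config.treg_cluster,
    )
    return dataset, truth


def inject_missing(layer: OmicsLayer, rate: float, seed: int) -> OmicsLayer:
    """Set exactly ``round(rate * n_entries)`` entries to NaN, reproducibly."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return layer
    rng = np.random.default_rng(seed)
    arr = layer.values.to_numpy(dtype=float, copy=True)
    n_entries = arr.size
    n_missing = int(round(rate * n_entries))
    flat = rng.choice(n_entries, size=n_missing, replace=False)
    arr.flat[flat] = np.nan
    return layer.with_values(
        pd.DataFrame(arr, index=layer.values.index, columns=layer.values.columns)
    )


def make_ranked_expression(
    n_genes: int,
    set_position: str = "top",
    seed: int = 0,
    set_size: int = 10,
) -> tuple[pd.Series, "object"]:
    """Fixture generator: a ranked gene list with a gene set planted at an extreme.

    Returns a descending-sorted :class:`pandas.Series` (index = gene id,
    value = ranking score) and a :class:`~tregstrat.characterize.GeneSet`.
    """
    from .characterize import GeneSet

    if not 1 <= set_size <= n_genes:
        raise ValueError("need n_genes >= set_size >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    scores = np.linspace(3.0, -3.0, n_genes)  # strictly decreasing, symmetric
    if set_position == "top":
        members = genes[:set_size]
    elif set_position == "bottom":
        members = genes[-set_size:]
    elif set_position == "random":
        members = [genes[i] for i in rng.choice(n_genes, set_size, replace=False)]
    else:
        raise ValueError(f"unknown set_position {set_position!r}")
    ranked = pd.Series(scores, index=genes, name="synthetic_rank")
    return ranked, GeneSet(name="PLANTED", genes=list(members))


# ------------------------------------------------------------ tumor growth

@dataclass
class GrowthSimConfig:
    """Exponential tumor-growth study emulating a 4-arm syngeneic design.

    The default arm effects are back-calculated from the reported day-14
    tumor growth inhibition of each arm in the motivating preclinical
    study (control ~1860 mm3 from a ~96 mm3 baseline implies a growth
    rate of ~0.211/day; monotherapies near-inactive, combination ~25%
    inhibition).
    """

    arms: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("control", 1.0),
            ("IPG7236", 1.051),
            ("antiPDL1", 0.999),
            ("combo", 0.907),
        ]
    )
    n_per_arm: int = 5
    v0_mean: float = 96.45
    v0_sd: float = 12.93
    growth_rate: float = 0.2114     # 1/day
    noise_cv: float = 0.10          # multiplicative lognormal CV
    days: tuple[int, ...] = (0, 2, 4, 7, 9, 11, 14)
    seed: int = 0

    def validate(self) -> None:
        if self.v0_mean <= 0:
            raise ValueError("v0_mean must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        days = list(self.days)
        if any(d < 0 for d in days) or sorted(set(days)) != days:
            raise ValueError("days must be nonnegative and strictly increasing")
        names = [a for a, _ in self.arms]
        effects = dict(self.arms)
        if "control" not in names or effects["control"] != 1.0:
            raise ValueError("arms must include 'control' with effect 1.0")


def generate_growth_study(config: GrowthSimConfig) -> pd.DataFrame:
    """Simulate per-animal volume trajectories; long-format DataFrame.

    Animals are block randomized: baselines are sorted and arms permuted
    within consecutive blocks of ``len(arms)`` animals, mimicking
    baseline-size block designs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_arms = len(config.arms)
    n_total = n_arms * config.n_per_arm

    baselines = np.abs(rng.normal(config.v0_mean, config.v0_sd, size=n_total))
    order = np.argsort(baselines)[::-1]
    arm_of = np.empty(n_total, dtype=int)
    for b in range(config.n_per_arm):
        block = order[b * n_arms : (b + 1) * n_arms]
        arm_of[block] = rng.permutation(n_arms)

    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    else:
        sigma = 0.0

    records = []
    days = np.asarray(config.days, dtype=float)
    for i in range(n_total):
        arm_name, effect = config.arms[arm_of[i]]
        v = baselines[i] * np.exp(config.growth_rate * effect * days)
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=days.size))
            v = v * noise
        for d, vol in zip(config.days, v):
            records.append((f"M{i:03d}", arm_name, int(d), float(vol)))
    return pd.DataFrame(records, columns=["animal", "arm", "day", "volume_mm3"])
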