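"""Synthetic fingerprint/potency data with planted activity cliffs.

The generator emulates the statistical structure that the SAR/SVR analysis
assumes in real compound data sets:

* clusters of structural analogs — each cluster shares a core of on-bits and
  every member adds a few private bits, so within-cluster Tanimoto similarity
  is high (roughly ``core / (core + 2 * private)``) and between-cluster
  similarity is low;
* smooth potency variation inside most clusters — a linear gradient over the
  member index plus Gaussian noise, both with amplitude tied to
  ``within_cluster_spread`` so that as the spread goes to zero the set
  becomes perfectly continuous;
* a controllable fraction of *activity-cliff* compounds: cluster members
  whose potency is boosted by ``cliff_magnitude`` pKi units, creating pairs
  above the similarity threshold with large potency gaps.

Cliff compounds are selected in a cluster-interleaved, seeded order and
boosted incrementally, so for a fixed seed the raw discontinuity score is
monotone non-decreasing in ``cliff_fraction`` and two configs differing only
in ``cliff_fraction`` share the identical underlying compounds.

All sampling consumes a single ``numpy`` Generator keyed by the seed, in a
fixed documented order (cluster cores, cluster base potencies, per-compound
private bits, potency noise, cliff ordering), so the same seed reproduces the
same data set bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_io import CompoundRecord, DataSet, FingerprintScheme
from .errors import ConfigError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic compound data set.

    Defaults model an ECFP4-like regime: universe 1024 bits, 40 shared core
    bits and 8 private bits per compound give within-cluster Tc ≈ 0.71,
    comfortably above the 0.56 qualifying threshold; pKi spans [5, 10] with
    0.3 pKi of smooth within-cluster variation, and cliff compounds gain
    3 pKi units (an activity cliff of three orders of magnitude in K_i).
    """

    n_compounds: int = 100
    n_clusters: int = 8
    universe: int = 1024
    core_bits: int = 40
    private_bits: int = 8
    potency_range: tuple[float, float] = (5.0, 10.0)
    within_cluster_spread: float = 0.3
    cliff_fraction: float = 0.0
    cliff_magnitude: float = 3.0
    tc_threshold: float = 0.56
    seed: int = 0

    def __post_init__(self):
        if self.core_bits + self.private_bits > self.universe:
            raise ConfigError("core_bits + private_bits exceeds the universe")
        if not 0.0 <= self.cliff_fraction <= 1.0:
            raise ConfigError("cliff_fraction must be in [0, 1]")
        if not self.potency_range[0] < self.potency_range[1]:
            raise ConfigError("potency_range must satisfy low < high")
        if self.n_compounds < 1 or self.n_clusters < 1:
            raise ConfigError("n_compounds and n_clusters must be >= 1")
        if self.n_clusters > self.n_compounds:
            raise ConfigError("more clusters than compounds")
        if self.within_cluster_spread < 0:
            raise ConfigError("within_cluster_spread must be >= 0")


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of the multi-set reference panel used for normalization."""

    n_sets: int = 120
    size_range: tuple[int, int] = (100, 140)
    cliff_fraction_range: tuple[float, float] = (0.0, 0.15)
    spread_range: tuple[float, float] = (0.15, 0.45)
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 2:
            raise ConfigError("a reference panel needs n_sets >= 2")
        if self.size_range[0] < 2 or self.size_range[0] > self.size_range[1]:
            raise ConfigError("bad size_range")


def _cluster_cores(rng: np.random.Generator, cfg: SyntheticConfig) -> list[np.ndarray]:
    # Disjoint cores when the universe allows it (low between-cluster Tc);
    # otherwise independently sampled cores.
    if cfg.n_clusters * cfg.core_bits <= cfg.universe:
        perm = rng.permutation(cfg.universe)
        return [
            perm[k * cfg.core_bits : (k + 1) * cfg.core_bits]
            for k in range(cfg.n_clusters)
        ]
    return [
        rng.choice(cfg.universe, size=cfg.core_bits, replace=False)
        for _ in range(cfg.n_clusters)
    ]


def _cliff_order(rng: np.random.Generator, members: list[list[int]]) -> list[int]:
    """Cluster-interleaved seeded order of cliff-eligible compounds.

    Only clusters with >= 2 members are eligible (a cliff needs a similar
    partner); within each eligible cluster member order is shuffled, then
    clusters are visited round-robin in shuffled order.
    """
    eligible = [m for m in members if len(m) >= 2]
    queues = [list(rng.permutation(m)) for m in eligible]
    if queues:
        queues = [queues[k] for k in rng.permutation(len(queues))]
    order: list[int] = []
    while any(queues):
        for q in queues:
            if q:
                order.append(int(q.pop(0)))
    return order


def generate_dataset(config: SyntheticConfig) -> DataSet:
    """Generate one synthetic data set; same config => bit-identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    low, high = cfg.potency_range

    cores = _cluster_cores(rng, cfg)
    cluster_of = np.arange(cfg.n_compounds) % cfg.n_clusters
    members: list[list[int]] = [
        list(np.flatnonzero(cluster_of == k)) for k in range(cfg.n_clusters)
    ]

    # Cluster base potencies, kept clear of the range ends so the smooth
    # variation rarely clips.
    margin = min(cfg.within_cluster_spread, (high - low) / 4)
    bases = rng.uniform(low + margin, high - margin, size=cfg.n_clusters)

    fingerprints: list[frozenset[int]] = []
    for i in range(cfg.n_compounds):
        core = cores[cluster_of[i]]
        outside = np.setdiff1d(np.arange(cfg.universe), core, assume_unique=False)
        private = rng.choice(outside, size=cfg.private_bits, replace=False)
        fingerprints.append(frozenset(int(b) for b in core) | frozenset(int(b) for b in private))

    potencies = np.empty(cfg.n_compounds)
    for k, mem in enumerate(members):
        m = len(mem)
        # linear gradient spanning +-spread across the cluster, plus noise
        grad = (
            np.linspace(-cfg.within_cluster_spread, cfg.within_cluster_spread, m)
            if m > 1
            else np.zeros(1)
        )
        noise = rng.normal(0.0, cfg.within_cluster_spread, size=m)
        potencies[mem] = bases[k] + grad + noise
    potencies = np.clip(potencies, low, high)

    n_cliffs = math.ceil(cfg.cliff_fraction * cfg.n_compounds)
    order = _cliff_order(rng, members)
    for idx in order[:n_cliffs]:
        potencies[idx] = min(potencies[idx] + cfg.cliff_magnitude, high + 2.0)

    scheme = FingerprintScheme("synthetic", cfg.universe, cfg.tc_threshold)
    records = [
        CompoundRecord(f"CPD{i:05d}", fingerprints[i], float(potencies[i]))
        for i in range(cfg.n_compounds)
    ]
    return DataSet(target_id=f"synthetic-seed{cfg.seed}", scheme=scheme, records=records)


def generate_reference_panel(config: PanelConfig) -> list[DataSet]:
    """Generate the reference panel of independent synthetic data sets.

    Set sizes, cliff fractions, and within-cluster spreads are sampled per
    set from the configured ranges, so panel raw scores have genuine spread
    (a prerequisite for Z-normalization). Deterministic under the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_sets)
    panel = []
    for i in range(cfg.n_sets):
        n = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
        cf = float(rng.uniform(*cfg.cliff_fraction_range))
        spread = float(rng.uniform(*cfg.spread_range))
        set_cfg = SyntheticConfig(
            n_compounds=n,
            n_clusters=max(4, n // 12),
            cliff_fraction=cf,
            within_cluster_spread=spread,
            seed=int(child_seeds[i]),
        )
        ds = generate_dataset(set_cfg)
        ds.target_id = f"panel-{i:03d}"
        panel.append(ds)
    return panel


def with_cliff_fraction(config: SyntheticConfig, cliff_fraction: float) -> SyntheticConfig:
    """Same underlying compounds, different planted-cliff fraction."""
    return replace(config, cliff_fraction=cliff_fraction)
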