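"""Synthetic multi-treatment OTU datasets with known planted structure.

The generator emulates a greenhouse stress experiment profiled by 16S
amplicon sequencing: four treatment groups (control plus three stressors),
eight plants per group, and library depths around the rarefaction depth
used for community analysis.  Latent ("basis") OTU abundances are
log-normal; planted effects multiply basis means by ``2**(+-effect_log2)``
— in all three stress groups for "core" OTUs, in exactly one group for
treatment-specific OTUs.  Planted inter-OTU associations are encoded as
correlations of the multivariate-normal log-basis.  Observed counts are a
multinomial draw of each sample's depth from its normalized basis, so the
data are compositional by construction.

Every stochastic draw descends from one root seed through named
substreams, so a downstream test can regenerate any piece independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skbio import TreeNode

from .io import OtuTable

STRESS_TREATMENTS = ("copper", "drought", "shade")

# fixed lineage pool, assigned round-robin, covering the phyla that dominate
# plant root communities; nested ranks exercise taxonomy summaries
_TAXONOMY_POOL = (
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; g__Rhizobium",
    "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Burkholderiales; g__Burkholderia",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Xanthomonadales; g__Luteimonas",
    "k__Bacteria; p__Proteobacteria; c__Deltaproteobacteria; o__Myxococcales; g__Sorangium",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; g__Streptomyces",
    "k__Bacteria; p__Bacteroidetes; c__Sphingobacteriia; o__Sphingobacteriales; g__Niabella",
    "k__Bacteria; p__Bacteroidetes; c__Cytophagia; o__Cytophagales; g__Spirosoma",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; g__Paenibacillus",
    "k__Bacteria; p__Verrucomicrobia; c__Verrucomicrobiae; o__Verrucomicrobiales; g__Luteolibacter",
)

# substream indices off the root SeedSequence
_STREAMS = {"basis": 0, "depths": 1, "counts": 2, "tree": 3, "omics": 4}


class ConfigError(ValueError):
    """A SimConfig field violates its invariant."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the emulated design: 8 plants per treatment, four
    treatments (control + copper/drought/shade), per-sample sequencing
    depth drawn uniformly between the 19,000-read rarefaction depth and
    60,000 reads, and a planted effect of 1.5 log2 units on latent
    abundances.
    """

    n_otus: int = 50
    samples_per_group: int = 8
    treatments: tuple[str, ...] = ("control", "copper", "drought", "shade")
    depth_range: tuple[int, int] = (19_000, 60_000)
    n_core_up: int = 5
    n_core_down: int = 5
    n_specific_per_treatment: int = 3
    effect_log2: float = 1.5
    n_corr_pairs: int = 3
    corr_strength: float = 0.8
    basis_log_mean_sd: float = 1.0
    basis_log_sd: float = 0.5
    planted_log_mean_offset: float = -1.5
    compartment: str = "root"
    seed: int = 0

    def validate(self) -> None:
        if self.n_otus < 2:
            raise ConfigError("n_otus must be >= 2")
        if self.samples_per_group < 1:
            raise ConfigError("samples_per_group must be positive")
        if len(self.treatments) < 1 or self.treatments[0] != "control":
            raise ConfigError("treatments must start with 'control'")
        n_stress = len(self.treatments) - 1
        if min(self.n_core_up, self.n_core_down, self.n_specific_per_treatment,
               self.n_corr_pairs) < 0:
            raise ConfigError("effect-set sizes must be nonnegative")
        n_planted = (self.n_core_up + self.n_core_down
                     + n_stress * self.n_specific_per_treatment)
        if n_planted > self.n_otus:
            raise ConfigError(
                f"n_core_up + n_core_down + {n_stress}*n_specific_per_treatment "
                f"= {n_planted} exceeds n_otus = {self.n_otus}")
        if not (-1.0 < self.corr_strength < 1.0):
            raise ConfigError("corr_strength must lie strictly inside (-1, 1)")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ConfigError("depth_range must satisfy 0 < low <= high")
        if self.basis_log_sd <= 0 or self.basis_log_mean_sd < 0:
            raise ConfigError("basis log-sd parameters must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth record of every planted effect."""

    core_up: set[str] = field(default_factory=set)
    core_down: set[str] = field(default_factory=set)
    specific: dict[str, dict[str, int]] = field(default_factory=dict)
    corr_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    omics_links: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    @property
    def core(self) -> set[str]:
        return self.core_up | self.core_down

    def direction_of(self, otu: str, treatment: str) -> int:
        """Planted sign of the latent shift of `otu` under `treatment` (0 = none)."""
        if otu in self.core_up:
            return 1
        if otu in self.core_down:
            return -1
        return self.specific.get(treatment, {}).get(otu, 0)

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["core_up"] = sorted(self.core_up)
        doc["core_down"] = sorted(self.core_down)
        doc["corr_pairs"] = [list(t) for t in self.corr_pairs]
        doc["omics_links"] = [list(t) for t in self.omics_links]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


def _correlation_matrix(n: int, pairs: list[tuple[int, int]], rho: float) -> np.ndarray:
    corr = np.eye(n)
    for i, j in pairs:
        corr[i, j] = corr[j, i] = rho
    return corr


def simulate_dataset(config: SimConfig) -> tuple[OtuTable, TreeNode, SyntheticTruth]:
    """Generate (OtuTable, tree, truth) under `config`.

    Column sums equal the drawn per-sample depths exactly; planted shifts
    act on basis means before normalization, so fold-changes are on latent
    abundances and the induced compositional distortion of the remaining
    OTUs is part of the simulation.
    """
    config.validate()
    otu_ids = [f"OTU_{i:04d}" for i in range(config.n_otus)]
    stress = list(config.treatments[1:])

    # assign planted roles to the first OTUs (ids carry no information)
    cursor = 0
    core_up = otu_ids[cursor:cursor + config.n_core_up]
    cursor += config.n_core_up
    core_down = otu_ids[cursor:cursor + config.n_core_down]
    cursor += config.n_core_down
    specific: dict[str, dict[str, int]] = {t: {} for t in stress}
    for k, t in enumerate(stress):
        ids = otu_ids[cursor:cursor + config.n_specific_per_treatment]
        cursor += config.n_specific_per_treatment
        # alternate planted direction so both signs are exercised
        specific[t] = {o: (1 if i % 2 == 0 else -1) for i, o in enumerate(ids)}

    # planted basis correlations among the remaining, effect-free OTUs when
    # possible (keeps the two kinds of planted structure separable)
    free = list(range(cursor, config.n_otus))
    if len(free) < 2 * config.n_corr_pairs:
        free = list(range(config.n_otus))
    pair_idx = [(free[2 * k], free[2 * k + 1]) for k in range(config.n_corr_pairs)]

    rng_basis = _rng(config.seed, "basis")
    base_log_mean = rng_basis.normal(0.0, config.basis_log_mean_sd, config.n_otus)
    # responsive taxa in the emulated study are individually minor members:
    # collectively they carry on the order of 10-15% of the community, not a
    # dominant share.  Planted OTUs are therefore drawn from a lower basis
    # mean, which also keeps the compositional distortion of unplanted OTUs
    # small.  planted_log_mean_offset = -1.5 realizes roughly that share for
    # the default design.
    planted_rows = [otu_ids.index(o) for o in (*core_up, *core_down)]
    planted_rows += [otu_ids.index(o) for t in stress for o in specific[t]]
    base_log_mean[planted_rows] += config.planted_log_mean_offset
    corr = _correlation_matrix(config.n_otus, pair_idx, config.corr_strength)
    chol = np.linalg.cholesky(corr)

    n_groups = len(config.treatments)
    n_samples = n_groups * config.samples_per_group
    sample_ids, sample_treatment = [], []
    for t in config.treatments:
        for r in range(config.samples_per_group):
            sample_ids.append(f"{t}_{r + 1:02d}")
            sample_treatment.append(t)

    # per-treatment shift of the log-basis mean
    ln2 = np.log(2.0)
    shift = {t: np.zeros(config.n_otus) for t in config.treatments}
    for t in stress:
        for o in core_up:
            shift[t][otu_ids.index(o)] = config.effect_log2 * ln2
        for o in core_down:
            shift[t][otu_ids.index(o)] = -config.effect_log2 * ln2
        for o, sgn in specific[t].items():
            shift[t][otu_ids.index(o)] = sgn * config.effect_log2 * ln2

    z = rng_basis.standard_normal((n_samples, config.n_otus)) @ chol.T
    log_basis = np.empty((n_samples, config.n_otus))
    for s in range(n_samples):
        log_basis[s] = (base_log_mean + shift[sample_treatment[s]]
                        + config.basis_log_sd * z[s])
    basis = np.exp(log_basis)
    fractions = basis / basis.sum(axis=1, keepdims=True)

    rng_depth = _rng(config.seed, "depths")
    depths = rng_depth.integers(config.depth_range[0], config.depth_range[1] + 1,
                                size=n_samples)
    rng_counts = _rng(config.seed, "counts")
    counts = np.empty((config.n_otus, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng_counts.multinomial(depths[s], fractions[s])

    taxonomy = {o: _TAXONOMY_POOL[i % len(_TAXONOMY_POOL)]
                for i, o in enumerate(otu_ids)}
    metadata = {s: {"treatment": t, "compartment": config.compartment}
                for s, t in zip(sample_ids, sample_treatment)}
    table = OtuTable(counts, otu_ids, sample_ids, taxonomy, metadata)

    tree = simulate_tree(otu_ids, seed=config.seed)
    truth = SyntheticTruth(
        core_up=set(core_up), core_down=set(core_down), specific=specific,
        corr_pairs=[(otu_ids[i], otu_ids[j], config.corr_strength)
                    for i, j in pair_idx],
        seed=config.seed)
    return table, tree, truth


def simulate_tree(otu_ids: list[str], seed: int) -> TreeNode:
    """Random rooted bifurcating tree over `otu_ids`.

    Built by repeated random joins (a coalescent-style topology);
    branch lengths are exponential(1) draws, strictly positive.
    """
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTU ids to build a tree")
    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError("OTU ids must be unique")
    rng = _rng(seed, "tree")
    nodes = [TreeNode(name=o) for o in otu_ids]
    for node in nodes:
        node.length = float(rng.exponential(1.0)) + 1e-9
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.exponential(1.0)) + 1e-9
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    root.length = None
    return root


def simulate_linked_omics(table: OtuTable, n_features: int,
                          links: list[tuple[str, str, float]],
                          noise_sd: float, seed: int,
                          ) -> tuple[np.ndarray, list[str], SyntheticTruth]:
    """Feature matrix (n_features x n_samples) with planted linear links.

    Each link ``(feature_id, otu_id, slope)`` sets that feature to
    ``slope * clr(otu) + N(0, noise_sd)``, where clr is the centered
    log-ratio of the per-sample relative abundances (pseudocount 1 on
    counts).  Features without a link are pure standard-normal noise.
    Feature ids are ``F_0000 .. F_{n-1}``; link feature ids must be drawn
    from that range.
    """
    feature_ids = [f"F_{k:04d}" for k in range(n_features)]
    fid_index = {f: k for k, f in enumerate(feature_ids)}
    for fid, otu, _ in links:
        if otu not in table.otu_ids:
            raise ValueError(f"unknown OTU id {otu!r} in links")
        if fid not in fid_index:
            raise ValueError(f"feature id {fid!r} outside F_0000..F_{n_features - 1:04d}")
    rng = _rng(seed, "omics")
    X = rng.standard_normal((n_features, table.n_samples))
    clr = clr_transform(table)
    otu_row = {o: i for i, o in enumerate(table.otu_ids)}
    for fid, otu, slope in links:
        noise = rng.standard_normal(table.n_samples) * noise_sd
        X[fid_index[fid]] = slope * clr[otu_row[otu]] + noise
    truth = SyntheticTruth(omics_links=[tuple(l) for l in links], seed=seed)
    return X, feature_ids, truth


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio of per-sample fractions, pseudocount on counts."""
    frac = (table.counts + pseudocount)
    frac = frac / frac.sum(axis=0, keepdims=True)
    logf = np.log(frac)
    return logf - logf.mean(axis=0, keepdims=True)
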