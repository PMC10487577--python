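"""Ground-truthed synthetic data: hierarchically structured spectra and
co-evolved 16S-like sequences.

The generator realises the sharing structure that whole-cell fingerprints
of related bacteria show: a genus has a set of conserved peaks present in
every member species, each species adds its own peaks, strains of one
species share the species peak set and differ mainly in relative
intensity, and replicates of one strain differ by measurement noise
(intensity scatter, occasional peak dropout, small m/z jitter, sparse
low-intensity baseline peaks).  Peaks are never shared across genera.
16S-like sequences evolve by a Jukes-Cantor process along the same
species hierarchy, so spectral groupings and sequence phylogeny have one
common truth to recover.

Every draw flows from the config seed; the same config yields the same
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .phylo import Alignment
from .spectra import RawSpectrum, StrainManifest

__all__ = [
    "SimConfig",
    "TruthHierarchy",
    "SimulatedDataset",
    "simulate_hierarchy",
    "simulate_spectra",
    "simulate_sequences",
    "simulate_dataset",
    "default_survey_preset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``species_per_genus`` is an int (uniform) or one count per genus;
    ``strains_per_species`` is an int or one count per species (flattened
    genus by genus).  Intensities are in arbitrary units, m/z in Da,
    branch lengths in substitutions/site.
    """

    n_genera: int = 4
    species_per_genus: int | tuple[int, ...] = (13, 4, 3, 2)
    strains_per_species: int | tuple[int, ...] = (
        # 40 + 10 + 6 + 5 = 61 strains over 22 species
        4, 4, 4, 4, 3, 3, 3, 3, 3, 3, 2, 2, 2,
        3, 3, 2, 2,
        2, 2, 2,
        3, 2,
    )
    replicates: int = 3
    n_genus_peaks: int = 12
    n_species_peaks: int = 18
    intensity_log_mean: float = float(np.log(1500.0))  # lognormal of peak base intensity
    intensity_log_sigma: float = 0.8
    strain_multiplier_sigma: float = 0.3  # lognormal sigma of per-strain peak multipliers
    replicate_sigma: float = 0.25  # lognormal sigma of replicate intensity scatter
    peak_dropout: float = 0.05  # per-peak missing probability per replicate
    mz_jitter: float = 0.3  # Da, uniform +-jitter
    noise_density: float = 0.002  # expected baseline peaks per grid point
    noise_intensity_scale: float = 30.0  # exponential scale of baseline intensities
    mz_min: float = 2000.0
    mz_max: float = 20000.0
    sequence_length: int = 1200
    branch_length_scale: float = 1.0
    strain_branch_length: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.peak_dropout,):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mz_jitter < 0 or self.noise_density < 0:
            raise ValueError("jitter and noise density must be >= 0")
        if len(self.species_counts()) != self.n_genera:
            raise ValueError("species_per_genus length must equal n_genera")
        n_species = sum(self.species_counts())
        if len(self.strain_counts()) != n_species:
            raise ValueError(
                f"strains_per_species must give one count per species ({n_species})"
            )

    def species_counts(self) -> tuple[int, ...]:
        if isinstance(self.species_per_genus, int):
            return (self.species_per_genus,) * self.n_genera
        return tuple(self.species_per_genus)

    def strain_counts(self) -> tuple[int, ...]:
        n_species = sum(self.species_counts())
        if isinstance(self.strains_per_species, int):
            return (self.strains_per_species,) * n_species
        return tuple(self.strains_per_species)


def default_survey_preset(seed: int = 0, replicates: int = 3, **overrides) -> SimConfig:
    """The package's reference study design: 4 genera, 22 species, 61
    strains (one dominant genus of 40 strains), 2-20 kDa grid."""
    return SimConfig(seed=seed, replicates=replicates, **overrides)


@dataclass
class TruthHierarchy:
    """Genus > species > strain structure with peak sets and the true tree."""

    genera: list[str]
    species_of_genus: dict[str, list[str]]
    strains_of_species: dict[str, list[str]]
    replicates: int
    species_tree: dendropy.Tree  # rooted, leaves = species, genera monophyletic
    genus_peaks: dict[str, np.ndarray]  # m/z, Da
    species_peaks: dict[str, np.ndarray]  # genus peaks + species-specific peaks
    base_intensity: dict[str, np.ndarray]  # per species, aligned to species_peaks
    strain_multiplier: dict[str, np.ndarray]  # per strain, aligned to its species' peaks
    seed: int = 0

    @property
    def species(self) -> list[str]:
        return [s for g in self.genera for s in self.species_of_genus[g]]

    @property
    def strains(self) -> list[str]:
        return [t for s in self.species for t in self.strains_of_species[s]]

    def genus_of_species(self, species: str) -> str:
        for g, ss in self.species_of_genus.items():
            if species in ss:
                return g
        raise KeyError(species)

    def manifest(self) -> StrainManifest:
        records = []
        for g in self.genera:
            for s in self.species_of_genus[g]:
                for t in self.strains_of_species[s]:
                    records.append((t, s, g))
        return StrainManifest.from_records(records)

    def true_tree_newick(self) -> str:
        return self.species_tree.as_string(schema="newick", suppress_rooting=True).strip()


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_bifurcation(
    leaves: Sequence[dendropy.Node], rng: np.random.Generator
) -> dendropy.Node:
    if len(leaves) == 1:
        return leaves[0]
    order = rng.permutation(len(leaves))
    split = int(rng.integers(1, len(leaves)))
    left = [leaves[i] for i in order[:split]]
    right = [leaves[i] for i in order[split:]]
    node = dendropy.Node()
    node.add_child(_random_bifurcation(left, rng))
    node.add_child(_random_bifurcation(right, rng))
    return node


def simulate_hierarchy(cfg: SimConfig) -> TruthHierarchy:
    rng = _rng(cfg.seed, 0)
    species_counts = cfg.species_counts()
    strain_counts = cfg.strain_counts()

    genera = [f"G{g + 1}" for g in range(cfg.n_genera)]
    species_of_genus: dict[str, list[str]] = {}
    strains_of_species: dict[str, list[str]] = {}
    idx = 0
    for g, genus in enumerate(genera):
        species_of_genus[genus] = [f"{genus}S{s + 1:02d}" for s in range(species_counts[g])]
        for species in species_of_genus[genus]:
            strains_of_species[species] = [
                f"{species}T{t + 1:02d}" for t in range(strain_counts[idx])
            ]
            idx += 1
    all_species = [s for g in genera for s in species_of_genus[g]]

    # Disjoint peak positions: candidates spaced 10 Da so jitter cannot
    # merge peaks of different origin.
    margin = 50.0
    candidates = np.arange(cfg.mz_min + margin, cfg.mz_max - margin + 1e-9, 10.0)
    n_needed = cfg.n_genera * cfg.n_genus_peaks + len(all_species) * cfg.n_species_peaks
    if n_needed > candidates.size:
        raise ValueError(
            f"requested {n_needed} distinct peaks but the grid holds only {candidates.size}"
        )
    drawn = rng.choice(candidates, size=n_needed, replace=False)
    pos = iter(drawn)

    genus_peaks = {
        g: np.sort(np.array([next(pos) for _ in range(cfg.n_genus_peaks)])) for g in genera
    }
    species_peaks: dict[str, np.ndarray] = {}
    base_intensity: dict[str, np.ndarray] = {}
    strain_multiplier: dict[str, np.ndarray] = {}
    for genus in genera:
        for species in species_of_genus[genus]:
            own = np.array([next(pos) for _ in range(cfg.n_species_peaks)])
            peaks = np.sort(np.concatenate([genus_peaks[genus], own]))
            species_peaks[species] = peaks
            base_intensity[species] = rng.lognormal(
                cfg.intensity_log_mean, cfg.intensity_log_sigma, size=peaks.size
            )
            for strain in strains_of_species[species]:
                strain_multiplier[strain] = rng.lognormal(
                    0.0, cfg.strain_multiplier_sigma, size=peaks.size
                )

    tree = _simulate_species_tree(genera, species_of_genus, cfg, rng)
    return TruthHierarchy(
        genera=genera,
        species_of_genus=species_of_genus,
        strains_of_species=strains_of_species,
        replicates=cfg.replicates,
        species_tree=tree,
        genus_peaks=genus_peaks,
        species_peaks=species_peaks,
        base_intensity=base_intensity,
        strain_multiplier=strain_multiplier,
        seed=cfg.seed,
    )


def _simulate_species_tree(
    genera: list[str],
    species_of_genus: dict[str, list[str]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Rooted species tree with genera monophyletic by construction.

    Genus stems are long (0.08-0.12 subs/site before scaling) relative to
    within-genus edges (0.005-0.03), mirroring the deep inter-genus vs
    shallow inter-species divergence of 16S."""
    scale = cfg.branch_length_scale
    labels = [s for g in genera for s in species_of_genus[g]]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = dendropy.Node()
    for genus in genera:
        leaves = []
        for sp in species_of_genus[genus]:
            leaf = dendropy.Node(taxon=taxa.get_taxon(sp))
            leaf.edge.length = float(rng.uniform(0.01, 0.03)) * scale
            leaves.append(leaf)
        sub = _random_bifurcation(leaves, rng)
        for node in sub.preorder_iter():
            if node.edge.length is None and node is not sub:
                node.edge.length = float(rng.uniform(0.005, 0.015)) * scale
        sub.edge.length = float(rng.uniform(0.08, 0.12)) * scale
        root.add_child(sub)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def simulate_spectra(
    h: TruthHierarchy, cfg: SimConfig
) -> tuple[list[RawSpectrum], StrainManifest]:
    """One raw peak list per strain x replicate."""
    rng = _rng(cfg.seed, 1)
    n_grid = int(round(cfg.mz_max - cfg.mz_min)) + 1
    spectra: list[RawSpectrum] = []
    for species in h.species:
        peaks = h.species_peaks[species]
        base = h.base_intensity[species]
        for strain in h.strains_of_species[species]:
            mult = h.strain_multiplier[strain]
            for rep in range(1, cfg.replicates + 1):
                keep = rng.random(peaks.size) >= cfg.peak_dropout
                mz = peaks[keep] + (
                    rng.uniform(-cfg.mz_jitter, cfg.mz_jitter, keep.sum())
                    if cfg.mz_jitter > 0
                    else 0.0
                )
                intensity = (
                    base[keep]
                    * mult[keep]
                    * rng.lognormal(0.0, cfg.replicate_sigma, keep.sum())
                )
                n_noise = rng.poisson(cfg.noise_density * n_grid)
                if n_noise:
                    mz = np.concatenate(
                        [mz, rng.uniform(cfg.mz_min, cfg.mz_max, n_noise)]
                    )
                    intensity = np.concatenate(
                        [intensity, rng.exponential(cfg.noise_intensity_scale, n_noise)]
                    )
                mz = np.round(mz, 1)
                uniq, inverse = np.unique(mz, return_inverse=True)
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, intensity)
                spectra.append(
                    RawSpectrum(uniq, summed, strain_id=strain, replicate_id=f"r{rep}")
                )
    return spectra, h.manifest()


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor: substitute each site with probability
    p = 3/4 (1 - exp(-4d/3)); a substituted site moves to one of the
    other three bases uniformly."""
    if d <= 0:
        return seq.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    hit = rng.random(seq.size) < p
    out = seq.copy()
    out[hit] = (out[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


def simulate_sequences(h: TruthHierarchy, cfg: SimConfig) -> tuple[Alignment, str]:
    """Alignment of strain sequences plus the true species tree (Newick).

    The root sequence is uniform-random; species sequences evolve along
    the true tree and each strain adds a short private branch.  No indels,
    so the output is aligned by construction.
    """
    if cfg.sequence_length < 100:
        raise ValueError("sequence_length must be >= 100")
    rng = _rng(cfg.seed, 2)
    L = cfg.sequence_length
    root_seq = rng.integers(0, 4, L, dtype=np.int64)
    node_seq: dict = {h.species_tree.seed_node: root_seq}
    species_seq: dict[str, np.ndarray] = {}
    for node in h.species_tree.preorder_node_iter():
        if node.parent_node is not None:
            node_seq[node] = _evolve(
                node_seq[node.parent_node], node.edge.length or 0.0, rng
            )
        if node.is_leaf():
            species_seq[node.taxon.label] = node_seq[node]

    ids, seqs = [], []
    strain_d = cfg.strain_branch_length * cfg.branch_length_scale
    for species in h.species:
        for strain in h.strains_of_species[species]:
            ids.append(strain)
            seq = _evolve(species_seq[species], strain_d, rng)
            seqs.append(_BASES[seq].tobytes().decode())
    return Alignment(ids, seqs), h.true_tree_newick()


@dataclass
class SimulatedDataset:
    config: SimConfig
    hierarchy: TruthHierarchy
    spectra: list[RawSpectrum]
    manifest: StrainManifest
    alignment: Alignment
    true_tree_newick: str
    truth: dict = field(default_factory=dict)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Hierarchy + spectra + sequences in one seeded call."""
    h = simulate_hierarchy(cfg)
    spectra, manifest = simulate_spectra(h, cfg)
    alignment, newick = simulate_sequences(h, cfg)
    truth = {
        "genera": h.genera,
        "species": {g: h.species_of_genus[g] for g in h.genera},
        "strains": {s: h.strains_of_species[s] for s in h.species},
        "seed": cfg.seed,
    }
    return SimulatedDataset(cfg, h, spectra, manifest, alignment, newick, truth)
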