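"""Synthetic pan-genome generator.

Emulates the statistical structure the downstream analysis assumes: a set
of bacterial strains sharing a fixed core genome, dispensable gene families
carried probabilistically, strain-unique genes, and K planted trait
clusters — groups of families that co-occur exactly in the strains able to
grow on a given carbohydrate.  Protein sequences within a family derive
from one ancestral sequence mutated along a species tree, and are emitted
already aligned (equal length, substitutions only), so p-distances and
percent identities are exact without running an aligner.

Randomness is organised as one seeded child stream per output in a fixed,
documented order (see :func:`spawn_streams`), so any single output can be
regenerated without replaying the others and tests can replay individual
draws (e.g. phenotype-noise flips) independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PlantedCluster",
    "SyntheticTruth",
    "ConfigurationError",
    "DEFAULT_CARBOHYDRATES",
    "EXCLUSION_VOCABULARY",
    "CONTROL_CARBOHYDRATE",
    "GROWTH_TIMEPOINTS",
    "spawn_streams",
    "simulate_pangenome",
    "simulate_growth_curves",
    "phenotype_flip_mask",
    "presence_absence_from_genomes",
]

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: carbohydrates assigned to planted trait clusters, in planting order
DEFAULT_CARBOHYDRATES = (
    "xylooligosaccharides",
    "arabinan",
    "arabinoxylan",
    "galactan",
    "fucosyllactose",
)

#: the always-grows positive control emitted with every growth-curve table
CONTROL_CARBOHYDRATE = "lactose"

GROWTH_TIMEPOINTS = (0, 6, 9, 12, 24)

#: annotations that the gene-trait-matching stage is expected to exclude
EXCLUSION_VOCABULARY = (
    "IS3 family transposase",
    "prophage protein",
    "phage tail fiber protein",
    "integrase",
    "type I restriction-modification system methyltransferase",
    "restriction endonuclease",
    "CRISPR-associated protein Cas1",
    "mobile element protein",
)

_CORE_FUNCTIONS = (
    "DNA polymerase III subunit",
    "30S ribosomal protein",
    "50S ribosomal protein",
    "elongation factor Tu",
    "ATP synthase subunit",
    "DNA gyrase subunit",
    "chaperonin GroEL",
    "RNA polymerase subunit",
    "aminoacyl-tRNA synthetase",
    "cell division protein FtsZ",
)

_DISPENSABLE_FUNCTIONS = (
    "hypothetical protein",
    "ABC transporter ATP-binding protein",
    "glycosyltransferase",
    "sugar permease",
    "MFS transporter",
    "cell surface protein",
    "sortase-dependent pilin",
    "exopolysaccharide biosynthesis protein",
    "two-component system response regulator",
)

_CLUSTER_FUNCTIONS = {
    "xylooligosaccharides": (
        "beta-1,4-xylosidase",
        "ABC transporter permease",
        "lactose ABC transporter substrate-binding protein",
        "LacI family transcriptional regulator",
        "alpha-L-arabinofuranosidase",
        "galactoside O-acetyltransferase",
    ),
    "arabinan": (
        "endo-1,4-beta-xylanase",
        "beta-xylosidase",
        "endo-1,4-beta-xylanase II",
        "arabinan endo-1,5-alpha-L-arabinosidase",
    ),
    "arabinoxylan": (
        "exo-alpha-L-arabinofuranosidase II",
        "beta-xylosidase",
        "alpha-arabinofuranosidase I",
        "ABC transporter permease protein",
        "LacI family transcriptional regulator",
    ),
    "galactan": (
        "glycosyl hydrolase family 53 endogalactanase",
        "beta-galactosidase",
        "solute-binding protein of ABC transporter system",
        "transcriptional regulator LacI family",
    ),
    "fucosyllactose": (
        "alpha-1,3/4-fucosidase",
        "fucose isomerase",
        "ABC transporter substrate binding component",
        "LacI family transcriptional regulator",
        "glycosyl hydrolase family 95 protein",
    ),
}

_GENERIC_CLUSTER_FUNCTIONS = (
    "carbohydrate hydrolase",
    "sugar ABC transporter permease",
    "sugar ABC transporter substrate-binding protein",
    "LacI family transcriptional regulator",
    "carbohydrate kinase",
)

#: fixed order of the per-output child streams spawned from the seed
STREAM_NAMES = (
    "tree",
    "ancestors",
    "carriage",
    "planted",
    "unique",
    "annotations",
    "phenotype_noise",
    "growth",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic pan-genome.

    Defaults describe a 20-strain species with a 400-family core, 600
    dispensable families (a handful of which form the planted trait
    clusters), a modest number of strain-unique genes, noiseless phenotype
    calls and a small optical-density measurement noise.
    """

    n_strains: int = 20
    core_size: int = 400
    n_dispensable: int = 600
    occurrence_prob_range: tuple[float, float] = (0.15, 0.85)
    unique_per_strain_range: tuple[int, int] = (0, 25)
    n_trait_clusters: int = 4
    cluster_size_range: tuple[int, int] = (4, 10)
    carrier_fraction: float = 0.5
    phenotype_noise: float = 0.0
    protein_length: int = 200
    divergence_within_family: float = 0.25
    divergence_between_families: float = 0.60
    exclusion_annotation_fraction: float = 0.10
    od_noise_sd: float = 0.02
    growth_od12_range: tuple[float, float] = (0.6, 1.1)
    nogrowth_od12_range: tuple[float, float] = (0.05, 0.2)
    outgroup: str = "OUTG"
    seed: int = 0

    # identity thresholds the clustering stage will apply; the simulator
    # guarantees margins of +5 (within-family) and -10 (between-family)
    # percentage points around this value.
    clustering_identity_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ConfigurationError("n_strains must be >= 2")
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ConfigurationError("carrier_fraction must be in (0, 1)")
        if not 0.0 <= self.phenotype_noise < 1.0:
            raise ConfigurationError("phenotype_noise must be in [0, 1)")
        lo, hi = self.occurrence_prob_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                "occurrence_prob_range must lie strictly inside (0, 1)"
            )
        if self.growth_od12_range[0] <= 0.4:
            raise ConfigurationError("growth_od12_range minimum must exceed 0.4")
        if self.nogrowth_od12_range[1] >= 0.3:
            raise ConfigurationError("nogrowth_od12_range maximum must be below 0.3")
        if self.cluster_size_range[0] < 1 or (
            self.cluster_size_range[0] > self.cluster_size_range[1]
        ):
            raise ConfigurationError("cluster_size_range must be a nondecreasing pair >= 1")
        if self.cluster_size_range[1] > self.n_dispensable:
            raise ConfigurationError(
                f"cluster_size_range {self.cluster_size_range} exceeds "
                f"n_dispensable={self.n_dispensable}"
            )
        if self.n_trait_clusters * self.cluster_size_range[1] > self.n_dispensable:
            raise ConfigurationError(
                "planted clusters cannot exceed the dispensable family pool: "
                f"{self.n_trait_clusters} clusters x up to "
                f"{self.cluster_size_range[1]} families > {self.n_dispensable}"
            )
        # within-family identity must stay >= threshold + 5 points:
        # maximum expected pairwise p-distance equals divergence_within_family
        max_pdist = self.divergence_within_family
        floor = (self.clustering_identity_threshold + 5.0) / 100.0
        if 1.0 - max_pdist < floor + 0.05:  # 5-point stochastic buffer
            raise ConfigurationError(
                f"divergence_within_family={self.divergence_within_family} would "
                f"push within-family identity towards "
                f"{100 * (1 - max_pdist):.0f}%, below the required "
                f"{100 * floor:.0f}% (clustering threshold + 5-point margin); "
                "lower the divergence or the clustering threshold"
            )
        # between-family ancestors must sit >= 10 points below the threshold
        min_floor = 1.0 - (self.clustering_identity_threshold - 10.0) / 100.0
        if self.divergence_between_families < min_floor:
            raise ConfigurationError(
                f"divergence_between_families={self.divergence_between_families} "
                f"allows ancestral identities above "
                f"{self.clustering_identity_threshold - 10:.0f}% "
                "(clustering threshold - 10-point margin)"
            )

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(f"S{i:02d}" for i in range(1, self.n_strains + 1))

    @property
    def taxa(self) -> tuple[str, ...]:
        """All genomes in the species tree: strains plus the outgroup."""
        return self.strains + (self.outgroup,)


@dataclass(frozen=True)
class PlantedCluster:
    families: frozenset[str]
    carriers: frozenset[str]
    carbohydrate: str


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    family_membership: dict[str, set[str]]
    planted_clusters: dict[str, PlantedCluster]
    species_tree: str  # rooted Newick over strains + outgroup
    true_phenotypes: dict[str, dict[str, int]]  # carbohydrate -> strain -> {0,1}

    def to_json(self) -> str:
        payload = {
            "family_membership": {
                f: sorted(s) for f, s in sorted(self.family_membership.items())
            },
            "planted_clusters": {
                cid: {
                    "families": sorted(pc.families),
                    "carriers": sorted(pc.carriers),
                    "carbohydrate": pc.carbohydrate,
                }
                for cid, pc in sorted(self.planted_clusters.items())
            },
            "species_tree": self.species_tree,
            "true_phenotypes": {
                carb: dict(sorted(calls.items()))
                for carb, calls in sorted(self.true_phenotypes.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            family_membership={f: set(s) for f, s in d["family_membership"].items()},
            planted_clusters={
                cid: PlantedCluster(
                    families=frozenset(pc["families"]),
                    carriers=frozenset(pc["carriers"]),
                    carbohydrate=pc["carbohydrate"],
                )
                for cid, pc in d["planted_clusters"].items()
            },
            species_tree=d["species_tree"],
            true_phenotypes={
                carb: {s: int(v) for s, v in calls.items()}
                for carb, calls in d["true_phenotypes"].items()
            },
        )


def spawn_streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Per-output RNG streams spawned from the seed in ``STREAM_NAMES`` order."""
    children = np.random.SeedSequence(config.seed).spawn(len(STREAM_NAMES))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(STREAM_NAMES, children)
    }


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children", "length")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.children: list[_Node] = []
        self.length = length

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"

    def leaves(self) -> Iterator["_Node"]:
        if not self.children:
            yield self
        for c in self.children:
            yield from c.leaves()

    def depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: _Node, d: float) -> None:
            d += node.length
            if not node.children:
                out[node.label] = d
            for c in node.children:
                walk(c, d)

        walk(self, -self.length)
        return out


def _simulate_species_tree(config: SimulationConfig, rng: np.random.Generator) -> _Node:
    """Random rooted binary tree over the strains, outgroup attached at the root.

    Edge lengths are drawn uniform(0.4, 0.6) and then globally rescaled so
    the maximum leaf-to-leaf path equals ``divergence_within_family`` — the
    per-edge length is interpreted directly as the per-site substitution
    probability, so this caps expected within-family divergence.
    """
    nodes = [_Node(label=s, length=float(rng.uniform(0.4, 0.6)))
             for s in config.strains]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _Node(length=float(rng.uniform(0.4, 0.6)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    ingroup = nodes[0]
    out = _Node(label=config.outgroup, length=float(rng.uniform(0.5, 0.7)))
    root = _Node(length=0.0)
    root.children = [ingroup, out]

    depths = root.depths()
    vals = sorted(depths.values())
    max_path = vals[-1] + vals[-2]  # upper bound on leaf-to-leaf path via root
    scale = config.divergence_within_family / max_path

    def rescale(node: _Node) -> None:
        node.length *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    return root


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_proteins(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    idx = rng.integers(0, len(AMINO_ACIDS), size=(n, length))
    return AMINO_ACIDS[idx]


def _enforce_between_family_floor(
    ancestors: np.ndarray,
    rng: np.random.Generator,
    max_identity: float,
    max_rounds: int = 20,
) -> np.ndarray:
    """Regenerate ancestral sequences until all pairs are dissimilar enough.

    ``max_identity`` is the fraction of identical sites allowed between any
    two ancestral family sequences.  Random 20-letter proteins essentially
    never violate a 40% ceiling, but the floor is enforced, not assumed.
    """
    n, length = ancestors.shape
    for _ in range(max_rounds):
        bad: set[int] = set()
        block = 128
        for i0 in range(0, n, block):
            sub = ancestors[i0 : i0 + block]
            eq = (sub[:, None, :] == ancestors[None, :, :]).mean(axis=2)
            ii, jj = np.nonzero(eq > max_identity)
            for a, b in zip(ii, jj):
                gi = i0 + a
                if gi < b:
                    bad.add(int(b))
        if not bad:
            return ancestors
        idx = sorted(bad)
        ancestors[idx] = _random_proteins(rng, len(idx), length)
    raise ConfigurationError(
        "could not satisfy the between-family dissimilarity floor "
        f"(max identity {max_identity:.2f}) after {max_rounds} rounds; "
        "increase protein_length or relax divergence_between_families"
    )


def _evolve_family(
    ancestor: np.ndarray,
    tree: _Node,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Mutate the ancestral sequence along the tree; returns leaf sequences.

    Each site substitutes on an edge with probability equal to the edge
    length (clipped to 0.75), to one of the 19 other residues chosen
    uniformly.
    """
    out: dict[str, np.ndarray] = {}

    def walk(node: _Node, seq: np.ndarray) -> None:
        p = min(node.length, 0.75)
        if p > 0:
            mask = rng.random(seq.shape[0]) < p
            k = int(mask.sum())
            if k:
                seq = seq.copy()
                shifts = rng.integers(1, len(AMINO_ACIDS), size=k)
                current = np.searchsorted(AMINO_ACIDS, seq[mask])
                seq[mask] = AMINO_ACIDS[(current + shifts) % len(AMINO_ACIDS)]
        if not node.children:
            out[node.label] = seq
        for c in node.children:
            walk(c, seq)

    walk(tree, ancestor)
    return out


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def _carbohydrate_labels(k: int) -> list[str]:
    labels = list(DEFAULT_CARBOHYDRATES[:k])
    for extra in range(len(labels), k):
        labels.append(f"carbohydrate{extra + 1:02d}")
    return labels


def simulate_pangenome(
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, str]], dict[str, str], SyntheticTruth]:
    """Generate genomes, annotations and ground truth.

    Returns ``(genomes, annotations, truth)`` where ``genomes`` maps each
    genome id (strains plus outgroup) to ``{gene_id: protein sequence}``,
    ``annotations`` maps gene id to a free-text function, and ``truth``
    records family carriage, planted clusters, the species tree and the
    noiseless phenotypes.  Gene ids are ``<strain>|<family>|<serial>`` so
    presence/absence is recoverable from the FASTA alone.  Identical
    configs (same seed) give byte-identical outputs.
    """
    streams = spawn_streams(config)
    tree = _simulate_species_tree(config, streams["tree"])
    strains = list(config.strains)
    n = config.n_strains
    carb_labels = _carbohydrate_labels(config.n_trait_clusters)

    # --- planted trait clusters -------------------------------------------
    rng_p = streams["planted"]
    planted: dict[str, PlantedCluster] = {}
    planted_family_ids: list[str] = []
    seen_carrier_sets: set[frozenset[str]] = set()
    n_carriers = max(1, min(n - 1, round(config.carrier_fraction * n)))
    for ci, carb in enumerate(carb_labels, start=1):
        size = int(rng_p.integers(config.cluster_size_range[0],
                                  config.cluster_size_range[1] + 1))
        for _ in range(1000):
            carriers = frozenset(
                strains[i] for i in rng_p.choice(n, size=n_carriers, replace=False)
            )
            if carriers not in seen_carrier_sets:
                break
        else:  # pragma: no cover - would need pathological configs
            raise ConfigurationError("could not draw distinct carrier sets")
        seen_carrier_sets.add(carriers)
        fams = [f"P{ci:02d}_{k:02d}" for k in range(1, size + 1)]
        planted_family_ids.extend(fams)
        planted[f"cluster{ci:02d}"] = PlantedCluster(
            families=frozenset(fams), carriers=carriers, carbohydrate=carb
        )

    # --- carriage ----------------------------------------------------------
    rng_c = streams["carriage"]
    membership: dict[str, set[str]] = {}
    core_ids = [f"C{i:04d}" for i in range(1, config.core_size + 1)]
    for fid in core_ids:
        membership[fid] = set(config.taxa)  # core: all strains + outgroup

    n_random_disp = config.n_dispensable - len(planted_family_ids)
    disp_ids = [f"D{i:04d}" for i in range(1, n_random_disp + 1)]
    lo, hi = config.occurrence_prob_range
    for fid in disp_ids:
        p = float(rng_c.uniform(lo, hi))
        while True:
            carried = {s for s in strains if rng_c.random() < p}
            if 1 <= len(carried) <= n - 1:  # strictly dispensable
                break
        membership[fid] = carried

    for pc in planted.values():
        for fid in sorted(pc.families):
            membership[fid] = set(pc.carriers)

    # --- unique genes ------------------------------------------------------
    rng_u = streams["unique"]
    ulo, uhi = config.unique_per_strain_range
    unique_ids: list[str] = []
    for s in strains:
        n_unique = int(rng_u.integers(ulo, uhi + 1))
        for k in range(1, n_unique + 1):
            fid = f"U{s}_{k:03d}"
            membership[fid] = {s}
            unique_ids.append(fid)

    # --- sequences ---------------------------------------------------------
    rng_a = streams["ancestors"]
    family_ids = sorted(membership)
    ancestors = _random_proteins(rng_a, len(family_ids), config.protein_length)
    ancestors = _enforce_between_family_floor(
        ancestors, rng_a, max_identity=1.0 - config.divergence_between_families
    )
    genomes: dict[str, dict[str, str]] = {t: {} for t in config.taxa}
    for row, fid in enumerate(family_ids):
        leaf_seqs = _evolve_family(ancestors[row], tree, rng_a)
        for strain in sorted(membership[fid]):
            gene_id = f"{strain}|{fid}|0"
            genomes[strain][gene_id] = leaf_seqs[strain].tobytes().decode("ascii")

    # --- annotations -------------------------------------------------------
    rng_ann = streams["annotations"]
    family_function: dict[str, str] = {}
    for i, fid in enumerate(core_ids):
        family_function[fid] = f"{_CORE_FUNCTIONS[i % len(_CORE_FUNCTIONS)]} {i + 1}"
    for fid in disp_ids:
        if rng_ann.random() < config.exclusion_annotation_fraction:
            family_function[fid] = str(rng_ann.choice(EXCLUSION_VOCABULARY))
        else:
            family_function[fid] = str(rng_ann.choice(_DISPENSABLE_FUNCTIONS))
    for pc in planted.values():
        vocab = _CLUSTER_FUNCTIONS.get(pc.carbohydrate, _GENERIC_CLUSTER_FUNCTIONS)
        for k, fid in enumerate(sorted(pc.families)):
            family_function[fid] = vocab[k % len(vocab)]
    for fid in unique_ids:
        family_function[fid] = "hypothetical protein"

    annotations = {
        gene_id: family_function[gene_id.split("|")[1]]
        for strain in config.taxa
        for gene_id in sorted(genomes[strain])
    }

    # --- phenotypes --------------------------------------------------------
    true_phenotypes = {
        pc.carbohydrate: {s: int(s in pc.carriers) for s in strains}
        for pc in planted.values()
    }

    truth = SyntheticTruth(
        family_membership=membership,
        planted_clusters=planted,
        species_tree=tree.newick() + ";",
        true_phenotypes=true_phenotypes,
    )
    return genomes, annotations, truth


def phenotype_flip_mask(
    config: SimulationConfig, carbohydrates: list[str], strains: list[str]
) -> dict[str, dict[str, bool]]:
    """Replay the phenotype-noise stream: which (carb, strain) calls flip.

    Draw order: carbohydrates sorted, strains sorted within each, one
    uniform draw per pair; a call flips when the draw falls below
    ``phenotype_noise``.  The positive-control carbohydrate is never
    flipped and takes no draw.
    """
    rng = spawn_streams(config)["phenotype_noise"]
    flips: dict[str, dict[str, bool]] = {}
    for carb in sorted(carbohydrates):
        flips[carb] = {}
        for s in sorted(strains):
            flips[carb][s] = bool(rng.random() < config.phenotype_noise)
    return flips


# fraction of the 12-h OD reached at each timepoint, growers / non-growers
_GROWER_PROFILE = {0: 0.08, 6: 0.35, 9: 0.70, 12: 1.00, 24: 1.12}
_NONGROWER_PROFILE = {0: 0.60, 6: 0.80, 9: 0.90, 12: 1.00, 24: 1.00}


def simulate_growth_curves(
    truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """OD600 time series per (strain, carbohydrate) in long format.

    Growers follow a monotone logistic-like rise whose 12-h OD is drawn
    from ``growth_od12_range``; non-growers stay within
    ``nogrowth_od12_range``.  Gaussian noise (sd ``od_noise_sd``) is added
    and truncated at 0.  Phenotype noise flips the grower/non-grower call
    before curve generation (assay noise and biological noise stay
    separable).  A lactose column with all-grower calls is always emitted
    as the positive control.
    """
    strains = sorted({s for calls in truth.true_phenotypes.values() for s in calls})
    carbs = sorted(truth.true_phenotypes)
    flips = phenotype_flip_mask(config, carbs, strains)
    rng = spawn_streams(config)["growth"]

    rows: list[tuple[str, str, int, float]] = []
    for carb in carbs + [CONTROL_CARBOHYDRATE]:
        for s in strains:
            if carb == CONTROL_CARBOHYDRATE:
                grows = True
            else:
                grows = bool(truth.true_phenotypes[carb][s]) ^ flips[carb][s]
            lo, hi = (
                config.growth_od12_range if grows else config.nogrowth_od12_range
            )
            od12 = float(rng.uniform(lo, hi))
            profile = _GROWER_PROFILE if grows else _NONGROWER_PROFILE
            for t in GROWTH_TIMEPOINTS:
                od = od12 * profile[t]
                if config.od_noise_sd > 0:
                    od += float(rng.normal(0.0, config.od_noise_sd))
                rows.append((s, carb, t, max(od, 0.0)))
    return pd.DataFrame(rows, columns=["strain", "carbohydrate", "time_h", "od600"])


def presence_absence_from_genomes(
    genomes: dict[str, dict[str, str]],
    genome_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Reconstruct the family x genome count matrix from emitted gene ids."""
    if genome_ids is None:
        genome_ids = sorted(genomes)
    counts: dict[str, dict[str, int]] = {}
    for g in genome_ids:
        for gene_id in genomes[g]:
            fid = gene_id.split("|")[1]
            counts.setdefault(fid, {})[g] = counts.setdefault(fid, {}).get(g, 0) + 1
    mat = pd.DataFrame(
        0, index=sorted(counts), columns=list(genome_ids), dtype=int
    )
    for fid, per in counts.items():
        for g, c in per.items():
            mat.at[fid, g] = c
    return mat
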