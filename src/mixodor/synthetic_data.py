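"""Synthetic mixture datasets with planted, recoverable structure.

The generator emulates the shape of a GC-MS + RATA study of spirit samples:
a pool of volatile molecules, N samples in two origin-type classes, each
sample carrying 100-200 detected molecules with positive relative peak areas,
and a panel of assessors producing sparse integer rate-all-that-apply
ratings (at most five nonzero descriptors per sample each).

Structure is planted so every pipeline stage has something real to recover:

* per type, ``exclusive_per_type`` molecules occur in every sample of that
  type and never in the other — the mechanism that makes origin-type
  classification separable and gives influence differences a known sign;
* each descriptor owns a disjoint set of *driver* molecules; a sample's
  latent intensity for a descriptor is a monotone function of how many of its
  drivers were detected;
* descriptors are split into type-affine groups: drivers of a type-affine
  descriptor are strongly tilted toward samples of that type, so descriptor
  profiles differ between types and an origin-aware model beats frequency
  guessing;
* panelists rate the latent top-five descriptors with integer jitter, and
  with probability ``noise_rate`` a rated descriptor is swapped for a random
  other one — the knob that moves inter-panelist agreement from perfect
  (0.0) to chance (1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_features import ConfigError, MoleculeRecord
from .labels import LabelSet, RataTable, sum_rata, top5_labels

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "MixtureSample",
    "SyntheticDataset",
    "STUDY_DESCRIPTORS",
    "generate_pool",
    "generate_mixtures",
    "generate_panel",
    "generate_dataset",
]

# Default descriptor vocabulary: the 17 attributes used by the whisky panel
# whose data shapes this package's defaults.
STUDY_DESCRIPTORS = [
    "apple-like",
    "butter-like",
    "caramel-like",
    "coconut-like",
    "flowery",
    "fruity",
    "honey-like",
    "honeydew-melon-like",
    "orange-like",
    "peach-like",
    "pear-like",
    "phenolic",
    "smoky",
    "solvent-like",
    "spicy-clove-like",
    "vanilla-like",
    "woody",
]

TYPE_NAMES = ["american", "scotch"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the study shape."""

    n_samples: int = 16
    n_type_classes: int = 2
    pool_size: int = 240
    molecules_per_sample: tuple[int, int] = (100, 200)
    n_descriptors: int = 17
    n_panelists: int = 11
    exclusive_per_type: int = 2
    drivers_per_descriptor: int = 3
    noise_rate: float = 0.3
    rating_max: int = 10
    seed: int = 0
    # inclusion-weight tilt for drivers of type-affine descriptors
    affine_weight: float = 4.0
    disfavored_weight: float = 0.25

    def __post_init__(self) -> None:
        if min(
            self.n_samples,
            self.n_type_classes,
            self.pool_size,
            self.n_descriptors,
            self.n_panelists,
            self.exclusive_per_type,
            self.drivers_per_descriptor,
            self.rating_max,
        ) < 1:
            raise ConfigError("all synthetic counts must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        lo, hi = self.molecules_per_sample
        if not 1 <= lo <= hi:
            raise ConfigError(f"invalid molecules_per_sample range {self.molecules_per_sample}")
        needed = (
            self.exclusive_per_type * self.n_type_classes
            + self.drivers_per_descriptor * self.n_descriptors
        )
        if self.pool_size < needed:
            raise ConfigError(
                f"pool_size {self.pool_size} too small for {needed} planted molecules"
            )
        if hi > self.pool_size:
            raise ConfigError("molecules_per_sample upper bound exceeds pool_size")

    def descriptors(self) -> list[str]:
        if self.n_descriptors == len(STUDY_DESCRIPTORS):
            return list(STUDY_DESCRIPTORS)
        return [f"desc_{i:02d}" for i in range(self.n_descriptors)]

    def type_names(self) -> list[str]:
        if self.n_type_classes == 2:
            return list(TYPE_NAMES)
        return [f"type_{i}" for i in range(self.n_type_classes)]


@dataclass
class MixtureSample:
    """One synthetic mixture: detected molecules plus its latent odor profile."""

    sample_id: str
    type_label: str
    molecules: list[MoleculeRecord]
    latent: dict[str, int]

    def molecule_ids(self) -> set[str]:
        return {m.molecule_id for m in self.molecules}


@dataclass
class GroundTruth:
    """The planted structure a successful pipeline should recover."""

    type_labels: dict[str, str]
    exclusive: dict[str, list[str]]  # type -> molecule ids
    drivers: dict[str, list[str]]  # descriptor -> molecule ids
    descriptor_affinity: dict[str, str | None]  # descriptor -> type or None
    latent: dict[tuple[str, str], int]  # (sample, descriptor) -> intensity


@dataclass
class SyntheticDataset:
    """A complete generated study: pool, mixtures, panel, and derived labels."""

    config: SyntheticConfig
    pool: list[MoleculeRecord]
    samples: list[MixtureSample]
    truth: GroundTruth
    rata: RataTable
    descriptors: list[str]
    label_sets: list[LabelSet]

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def label_set_for(self, sample_id: str) -> LabelSet:
        return next(ls for ls in self.label_sets if ls.sample_id == sample_id)


def _homolog_smiles(max_chain: int) -> list[str]:
    """A combinatorial vocabulary of typical spirit volatiles.

    Homologous series (alcohols, aldehydes, acids, ketones, esters of several
    alcohols) plus named phenols, terpenoids, lactones and furans.
    """
    chains = [("C" * n) for n in range(1, max_chain + 1)]
    smiles: list[str] = []
    for n in range(2, max_chain + 1):
        c = "C" * n
        smiles.append(c)  # n-alkane
        smiles.append(c + "O")  # 1-alcohol
        smiles.append(c + "=O" if n == 1 else "C" * (n - 1) + "C=O")  # aldehyde
        smiles.append(c + "(=O)O")  # carboxylic acid
    for n in range(3, max_chain + 1):
        smiles.append("CC(=O)" + "C" * (n - 2))  # 2-ketone
        smiles.append("CC(C)" + "C" * max(n - 3, 0) + "O")  # branched alcohol
    for alcohol in ["C", "CC", "CCC", "CCCC", "CC(C)C"]:
        for n in range(2, max_chain + 1):
            smiles.append("C" * (n - 1) + "C(=O)O" + alcohol)  # esters
    smiles += [
        "Oc1ccccc1",  # phenol
        "Cc1ccc(O)cc1",  # p-cresol
        "COc1ccccc1O",  # guaiacol
        "CCc1ccc(O)cc1",  # 4-ethylphenol
        "COc1cc(C=O)ccc1O",  # vanillin
        "COc1cc(CC=C)ccc1O",  # eugenol
        "CC1CCC(C(C)C)C(O)C1",  # menthol
        "CC(C)=CCCC(C)CCO",  # citronellol
        "CC(C)=CCCC(C)=CCO",  # geraniol
        "CC(C)=CCCC(C)(O)C=C",  # linalool
        "CC1=CCC(CC1)C(C)=C",  # limonene
        "O=C1CCCO1",  # gamma-butyrolactone
        "CCCCCC1CCC(=O)O1",  # gamma-decalactone core
        "CCCCC1CCC(=O)O1",
        "CCCC1CCC(=O)O1",
        "O=Cc1ccco1",  # furfural
        "Cc1ccc(C=O)o1",  # 5-methylfurfural
        "OCC1CCCO1",
        "CC(O)C1CCCO1",
        "CSC",  # dimethyl sulfide
        "CCSC",
        "OCC(O)C",  # propylene glycol
        "OCCO",
    ]
    return smiles


def generate_pool(config: SyntheticConfig) -> list[MoleculeRecord]:
    """Draw ``pool_size`` unique molecules from the homolog vocabulary.

    Deterministic per seed; different seeds draw different subsets.  The
    vocabulary is extended with longer-chain homologs on demand so any
    reasonable pool size is satisfiable.
    """
    max_chain = 12
    records: dict[str, str] = {}
    while True:
        records = {}
        for smi in _homolog_smiles(max_chain):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            records.setdefault(canonical, smi)
        if len(records) >= config.pool_size + 10 or max_chain > 40:
            break
        max_chain += 4
    if len(records) < config.pool_size:
        raise ConfigError(
            f"pool_size {config.pool_size} exceeds the {len(records)}-molecule vocabulary"
        )
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x01])
    canonicals = sorted(records)
    chosen = sorted(rng.choice(len(canonicals), size=config.pool_size, replace=False))
    pool = []
    for rank, idx in enumerate(chosen):
        canonical = canonicals[idx]
        pool.append(
            MoleculeRecord(
                molecule_id=f"mol_{rank:03d}",
                smiles=records[canonical],
                canonical_smiles=canonical,
            )
        )
    return pool


def generate_mixtures(
    config: SyntheticConfig, pool: list[MoleculeRecord] | None = None
) -> tuple[list[MixtureSample], GroundTruth]:
    """Generate per-sample molecule sets and the latent descriptor profiles."""
    if pool is None:
        pool = generate_pool(config)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x02])
    descriptors = config.descriptors()
    types = config.type_names()
    pool_ids = [m.molecule_id for m in pool]
    by_id = {m.molecule_id: m for m in pool}

    # plant exclusives and descriptor drivers on disjoint molecule sets
    shuffled = list(rng.permutation(pool_ids))
    exclusive: dict[str, list[str]] = {}
    for t in types:
        exclusive[t] = sorted(shuffled.pop() for _ in range(config.exclusive_per_type))
    drivers: dict[str, list[str]] = {}
    for d in descriptors:
        drivers[d] = sorted(shuffled.pop() for _ in range(config.drivers_per_descriptor))

    # type affinity: a third of descriptors per type (2-class case), rest neutral
    affinity: dict[str, str | None] = {d: None for d in descriptors}
    perm = list(rng.permutation(descriptors))
    n_affine = max(1, len(descriptors) // 3)
    for t in types:
        for d in perm[:n_affine]:
            affinity[d] = t
        perm = perm[n_affine:]

    driver_of = {m: d for d, mols in drivers.items() for m in mols}
    # class sizes mirror the 9:7 split of a 16-sample two-origin study
    counts = [
        int(round(config.n_samples * (1.0 / config.n_type_classes)))
        for _ in range(config.n_type_classes - 1)
    ]
    if config.n_type_classes == 2:
        counts = [config.n_samples - int(round(config.n_samples * 9 / 16))]
    counts.append(config.n_samples - sum(counts))
    type_of_sample: list[str] = []
    for t, c in zip(types, counts):
        type_of_sample += [t] * c

    samples: list[MixtureSample] = []
    latent_all: dict[tuple[str, str], int] = {}
    type_labels: dict[str, str] = {}
    lo, hi = config.molecules_per_sample
    for i in range(config.n_samples):
        sid = f"sample_{i:02d}"
        t = type_of_sample[i]
        type_labels[sid] = t
        forbidden = {m for tt, mols in exclusive.items() if tt != t for m in mols}
        own = list(exclusive[t])
        eligible = [m for m in pool_ids if m not in forbidden and m not in own]
        weights = np.ones(len(eligible))
        for j, m in enumerate(eligible):
            d = driver_of.get(m)
            if d is not None and affinity[d] is not None:
                weights[j] = (
                    config.affine_weight if affinity[d] == t else config.disfavored_weight
                )
        m_count = int(rng.integers(lo, hi + 1))
        n_draw = min(m_count - len(own), len(eligible))
        drawn = rng.choice(len(eligible), size=n_draw, replace=False, p=weights / weights.sum())
        mol_ids = sorted(own + [eligible[j] for j in drawn])
        areas = rng.lognormal(mean=0.0, sigma=1.0, size=len(mol_ids))
        molecules = [
            replace(by_id[m], peak_area=float(a)) for m, a in zip(mol_ids, areas)
        ]
        present = set(mol_ids)
        latent = {}
        for d in descriptors:
            v = 1 + 2 * sum(1 for m in drivers[d] if m in present)
            latent[d] = int(min(v, config.rating_max))
            latent_all[(sid, d)] = latent[d]
        samples.append(
            MixtureSample(sample_id=sid, type_label=t, molecules=molecules, latent=latent)
        )

    truth = GroundTruth(
        type_labels=type_labels,
        exclusive=exclusive,
        drivers=drivers,
        descriptor_affinity=affinity,
        latent=latent_all,
    )
    return samples, truth


def generate_panel(
    samples: Sequence[MixtureSample], truth: GroundTruth, config: SyntheticConfig
) -> RataTable:
    """Simulate sparse RATA ratings from the latent descriptor profiles.

    Each panelist rates the sample's five highest latent descriptors (shared
    deterministic tie order) with intensity = latent value plus integer jitter
    in {-1, 0, +1}, clipped to [1, rating_max].  With probability
    ``noise_rate`` a rated descriptor is swapped for a uniformly drawn
    currently-unrated descriptor, keeping at most five nonzero ratings.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x03])
    descriptors = config.descriptors()
    panelists = [f"panelist_{i:02d}" for i in range(config.n_panelists)]
    ratings: dict[tuple[str, str, str], int] = {}
    for p in panelists:
        for s in samples:
            ordered = sorted(descriptors, key=lambda d: (-s.latent[d], d))
            chosen = ordered[:5]
            scored = {
                d: int(np.clip(s.latent[d] + int(rng.integers(-1, 2)), 1, config.rating_max))
                for d in chosen
            }
            swap_out = [d for d in scored if rng.random() < config.noise_rate]
            rated = {d: r for d, r in scored.items() if d not in swap_out}
            for d in swap_out:
                # replacement drawn uniformly from descriptors other than the
                # swapped one and not already in the final set; at full noise
                # the rated set is therefore (near-)uniform over descriptors
                options = [x for x in descriptors if x != d and x not in rated]
                if options:
                    rated[options[int(rng.integers(len(options)))]] = scored[d]
            for d, r in rated.items():
                ratings[(p, s.sample_id, d)] = r
    return RataTable(
        panelists=panelists,
        samples=[s.sample_id for s in samples],
        descriptors=list(descriptors),
        ratings=ratings,
    )


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate pool, mixtures, panel, and the seeded consensus label sets."""
    config = config or SyntheticConfig()
    pool = generate_pool(config)
    samples, truth = generate_mixtures(config, pool)
    rata = generate_panel(samples, truth, config)
    consensus = sum_rata(rata)
    label_sets = [
        top5_labels(consensus, s.sample_id, seed=config.seed) for s in samples
    ]
    return SyntheticDataset(
        config=config,
        pool=pool,
        samples=samples,
        truth=truth,
        rata=rata,
        descriptors=config.descriptors(),
        label_sets=label_sets,
    )
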