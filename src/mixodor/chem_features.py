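"""Substructural featurization of molecule pools.

The feature space is built from a reference pool of molecules by computing the
maximum common substructure (MCS) of every unordered pair.  Each surviving MCS
becomes a SMARTS substructure pattern; a molecule is then described by its
*applicability* to each pattern — either the number of distinct substructure
matches (``match_count``) or, if the pattern matches at all, the pattern's
heavy-atom count (``overlap_length``).  Stacking the applicability vectors of
the molecules detected in a mixture yields the input representation consumed
by the CNN, and the pattern vocabulary doubles as an interpretable feature set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFMCS

RDLogger.DisableLog("rdApp.*")

ApplicabilityMode = Literal["match_count", "overlap_length"]

__all__ = [
    "MoleculeRecord",
    "SubstructurePattern",
    "ApplicabilityMatrix",
    "canonicalize_molecule",
    "pairwise_mcs",
    "applicability_value",
    "build_applicability_matrix",
]


class InputError(ValueError):
    """Raised for malformed user inputs (bad SMILES, duplicate ids, ...)."""


class ConfigError(ValueError):
    """Raised for invalid configuration values (unknown modes, variants, ...)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One detected volatile compound.

    Parameters
    ----------
    molecule_id:
        Stable identifier (e.g. a compound name or library key).
    smiles:
        The structure text as provided.
    canonical_smiles:
        RDKit-canonical SMILES; two spellings of the same molecule share it.
    peak_area:
        Optional relative GC peak area (ratio to an internal standard), > 0.
    """

    molecule_id: str
    smiles: str
    canonical_smiles: str
    peak_area: float | None = None

    def __post_init__(self) -> None:
        if self.peak_area is not None and not self.peak_area > 0:
            raise InputError(
                f"peak_area for {self.molecule_id!r} must be > 0, got {self.peak_area}"
            )

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class SubstructurePattern:
    """A substructure query extracted as the MCS of a reference-pool pair."""

    pattern_id: str
    smarts: str
    atom_count: int
    source_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.atom_count < 1:
            raise InputError(f"atom_count must be >= 1, got {self.atom_count}")

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise InputError(f"pattern {self.pattern_id!r}: unparsable SMARTS {self.smarts!r}")
        return q


@dataclass
class ApplicabilityMatrix:
    """Molecules x substructure-patterns matrix of non-negative weights.

    ``values[i, j]`` is 0 exactly when pattern ``j`` has no substructure match
    in molecule ``i``.
    """

    molecule_ids: list[str]
    pattern_ids: list[str]
    values: np.ndarray
    mode: ApplicabilityMode

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.pattern_ids)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.molecule_ids)}, {len(self.pattern_ids)})"
            )
        if (self.values < 0).any():
            raise InputError("applicability values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, molecule_id: str) -> np.ndarray:
        return self.values[self.molecule_ids.index(molecule_id)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.pattern_ids)


def canonicalize_molecule(
    smiles: str, molecule_id: str | None = None, peak_area: float | None = None
) -> MoleculeRecord:
    """Parse a SMILES string and return a record with its canonical form.

    Raises :class:`InputError` naming the offending string if the SMILES does
    not parse.  Canonicalization is idempotent.
    """
    if not smiles or not smiles.strip():
        raise InputError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        molecule_id=molecule_id if molecule_id is not None else canonical,
        smiles=smiles,
        canonical_smiles=canonical,
        peak_area=peak_area,
    )


def _canonical_smarts(smarts: str) -> str:
    """Round-trip a SMARTS through RDKit to get a stable deduplication key."""
    q = Chem.MolFromSmarts(smarts)
    if q is None:  # pragma: no cover - rdFMCS output always parses
        return smarts
    return Chem.MolToSmarts(q)


def pairwise_mcs(
    reference_pool: Sequence[MoleculeRecord],
    min_atoms: int = 2,
    timeout: int = 1,
    deduplicate: bool = True,
) -> list[SubstructurePattern]:
    """Extract substructure patterns as pairwise MCS over a reference pool.

    One MCS is computed per unordered pair (n*(n-1)/2 comparisons).  Atoms are
    compared by element and bonds by bond order; only connected substructures
    are considered and the objective is the atom count.  Results with fewer
    than ``min_atoms`` atoms are discarded; duplicates (identical canonical
    SMARTS) are merged when ``deduplicate`` is set.  Output order is
    deterministic: atom count descending, then SMARTS lexicographic.

    ``timeout`` (seconds, per pair) bounds each MCS search; on timeout the
    best result found so far is kept.
    """
    if len(reference_pool) < 2:
        raise InputError(f"reference pool needs >= 2 molecules, got {len(reference_pool)}")
    if min_atoms < 1:
        raise ConfigError(f"min_atoms must be >= 1, got {min_atoms}")

    mols = [(rec, rec.mol()) for rec in reference_pool]
    for rec, mol in mols:
        if mol is None:
            raise InputError(f"molecule {rec.molecule_id!r} has invalid structure")

    raw: list[tuple[str, int, tuple[str, str]]] = []
    for (rec_a, mol_a), (rec_b, mol_b) in itertools.combinations(mols, 2):
        result = rdFMCS.FindMCS(
            [mol_a, mol_b],
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            maximizeBonds=False,
            ringMatchesRingOnly=False,
            completeRingsOnly=False,
            matchValences=False,
            timeout=timeout,
        )
        if result.numAtoms < min_atoms or not result.smartsString:
            continue
        raw.append(
            (
                _canonical_smarts(result.smartsString),
                result.numAtoms,
                (rec_a.molecule_id, rec_b.molecule_id),
            )
        )

    if deduplicate:
        seen: dict[str, tuple[int, tuple[str, str]]] = {}
        for smarts, n_atoms, pair in raw:
            if smarts not in seen:
                seen[smarts] = (n_atoms, pair)
        entries = [(s, n, p) for s, (n, p) in seen.items()]
    else:
        entries = raw

    entries.sort(key=lambda e: (-e[1], e[0]))
    return [
        SubstructurePattern(
            pattern_id=f"mcs_{i:04d}", smarts=smarts, atom_count=n_atoms, source_pair=pair
        )
        for i, (smarts, n_atoms, pair) in enumerate(entries)
    ]


def applicability_value(
    molecule: MoleculeRecord | Chem.Mol,
    pattern: SubstructurePattern,
    mode: ApplicabilityMode = "match_count",
    _query: Chem.Mol | None = None,
) -> float:
    """Relevance of one substructure pattern for one molecule.

    ``match_count`` counts distinct substructure matches; ``overlap_length``
    returns the pattern's atom count if it matches at all, else 0.  Both modes
    return 0 exactly when the pattern is absent from the molecule.
    """
    if mode not in ("match_count", "overlap_length"):
        raise ConfigError(f"unknown applicability mode: {mode!r}")
    mol = molecule.mol() if isinstance(molecule, MoleculeRecord) else molecule
    query = _query if _query is not None else pattern.query()
    if mode == "match_count":
        return float(len(mol.GetSubstructMatches(query, uniquify=True)))
    return float(pattern.atom_count) if mol.HasSubstructMatch(query) else 0.0


def build_applicability_matrix(
    train_molecules: Sequence[MoleculeRecord],
    patterns: Sequence[SubstructurePattern],
    mode: ApplicabilityMode = "match_count",
) -> ApplicabilityMatrix:
    """Applicability of every pattern (columns) for every molecule (rows)."""
    ids = [m.molecule_id for m in train_molecules]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate molecule ids in training set")
    canon = [m.canonical_smiles for m in train_molecules]
    if len(set(canon)) != len(canon):
        raise InputError("duplicate molecules (identical canonical SMILES) in training set")

    mols = [m.mol() for m in train_molecules]
    queries = [p.query() for p in patterns]
    values = np.zeros((len(mols), len(patterns)), dtype=float)
    for j, (pattern, query) in enumerate(zip(patterns, queries)):
        for i, mol in enumerate(mols):
            values[i, j] = applicability_value(mol, pattern, mode, _query=query)
    return ApplicabilityMatrix(
        molecule_ids=ids,
        pattern_ids=[p.pattern_id for p in patterns],
        values=values,
        mode=mode,
    )
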