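"""Synthetic SMILES fixtures with known shingle statistics.

Two generators make the whole pipeline testable without any external
corpus:

* a *reference corpus* generator that replicates scaffolds at chosen
  multiplicities, so every shingle unique to a scaffold ends up in the
  frequency table with exactly that multiplicity (and shared shingles
  with the sum over sharing scaffolds);

* a *query set* generator that emits random molecules from homologous
  families (linear/branched alkanes, alcohols/ethers, amines, small
  substituted aromatics) over a configurable heavy-atom range.  The
  families overlap the default reference scaffolds in their substructure
  vocabulary to different degrees, producing a broad spread of scores
  and of (HAC, stereocenter, heteroatom) triplet bins.

All randomness flows from explicit seeds in the specs; the generators
use no global RNG state and are byte-deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from rdkit import Chem

from .shingles import parse_molecule

#: Default reference scaffolds: homologous series of alkanes, alcohols,
#: ethers, amines and methylated aromatics, so that query molecules from
#: the same families share many shingles with the reference.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC", "CCCCCC",
    "CCO", "CCCO", "CC(C)O", "CCCCO", "CCOC", "CCOCC",
    "CCN", "CCCN", "CC(C)N", "CCNCC", "CCCCN",
    "c1ccccc1", "Cc1ccccc1", "Cc1ccccc1C", "Cc1ccc(C)cc1",
    "c1ccncc1", "Cc1ccncc1", "c1ccoc1", "c1ccsc1",
    "OCc1ccccc1", "NCc1ccccc1", "CC(O)CN", "OCCN", "OCCO",
)


class FixtureSpecError(ValueError):
    """A fixture spec contains an invalid scaffold or weights."""


@dataclass
class CorpusSpec:
    """Reference corpus: scaffolds replicated at fixed multiplicities."""

    scaffolds: Sequence[tuple[str, int]]
    shuffle_seed: int = 0

    def validate(self) -> None:
        for smiles, mult in self.scaffolds:
            if mult < 1:
                raise FixtureSpecError(f"multiplicity {mult} < 1 for {smiles!r}")
            if Chem.MolFromSmiles(smiles) is None:
                raise FixtureSpecError(f"invalid scaffold SMILES: {smiles!r}")

    @property
    def total(self) -> int:
        return sum(m for _, m in self.scaffolds)


@dataclass
class QuerySpec:
    """Random query set drawn from weighted generator families."""

    n_molecules: int = 1000
    seed: int = 0
    hac_range: tuple[int, int] = (3, 17)
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "alkane": 1.0,
            "oxy": 1.0,       # alcohols and ethers
            "amine": 1.0,
            "aromatic": 1.0,
        }
    )

    def validate(self) -> None:
        if self.n_molecules < 0:
            raise FixtureSpecError("n_molecules must be >= 0")
        if any(w < 0 for w in self.weights.values()) or sum(self.weights.values()) <= 0:
            raise FixtureSpecError("weights must be >= 0 with positive sum")
        lo, hi = self.hac_range
        if not 1 <= lo <= hi:
            raise FixtureSpecError("invalid hac_range")


def generate_reference_corpus(spec: CorpusSpec) -> list[str]:
    """Emit each scaffold exactly ``multiplicity`` times, order shuffled."""
    spec.validate()
    lines: list[str] = []
    for smiles, mult in spec.scaffolds:
        lines.extend([smiles] * mult)
    random.Random(spec.shuffle_seed).shuffle(lines)
    return lines


def _random_skeleton(rng: random.Random, n_heavy: int, hetero: Sequence[tuple[int, int]]) -> str:
    """Random acyclic molecule of ``n_heavy`` atoms as SMILES.

    Grows a random attachment tree of carbons, then substitutes some
    positions with heteroatoms drawn from ``hetero`` (atomic number,
    max valence) where the tree degree allows it.  Valid by
    construction.
    """
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(6))
    degrees = [0]
    for _ in range(n_heavy - 1):
        candidates = [i for i, d in enumerate(degrees) if d < 4]
        parent = rng.choice(candidates)
        idx = mol.AddAtom(Chem.Atom(6))
        degrees.append(1)
        degrees[parent] += 1
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
    for atomic_num, max_valence in hetero:
        candidates = [i for i, d in enumerate(degrees) if d <= max_valence]
        if not candidates:
            continue
        pick = rng.choice(candidates)
        mol.GetAtomWithIdx(pick).SetAtomicNum(atomic_num)
        degrees[pick] = 5  # never substitute the same position twice
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


_AROMATIC_CORES = ("c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1")
_SUBSTITUENTS = ("C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "CO", "CN")


def _random_aromatic(rng: random.Random, hac_max: int) -> str:
    """Aromatic core with random substituents, capped at ``hac_max`` atoms."""
    core = Chem.MolFromSmiles(rng.choice(_AROMATIC_CORES))
    mol = Chem.RWMol(core)
    open_sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetTotalNumHs() > 0
    ]
    rng.shuffle(open_sites)
    for site in open_sites:
        if rng.random() < 0.5:
            continue
        sub = Chem.MolFromSmiles(rng.choice(_SUBSTITUENTS))
        if mol.GetNumAtoms() + sub.GetNumAtoms() > hac_max:
            break
        offset = mol.GetNumAtoms()
        mol.InsertMol(sub)
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
        atom = mol.GetAtomWithIdx(site)
        if atom.GetNumExplicitHs() > 0:  # e.g. pyrrole [nH]
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _generate_one(rng: random.Random, family: str, hac_range: tuple[int, int]) -> str:
    lo, hi = hac_range
    n = rng.randint(max(lo, 2), hi)
    if family == "alkane":
        return _random_skeleton(rng, n, [])
    if family == "oxy":
        n_het = rng.randint(1, max(1, n // 4))
        return _random_skeleton(rng, n, [(8, 2)] * n_het)
    if family == "amine":
        n_het = rng.randint(1, max(1, n // 5))
        return _random_skeleton(rng, n, [(7, 3)] * n_het)
    if family == "aromatic":
        return _random_aromatic(rng, hi)
    raise FixtureSpecError(f"unknown generator family: {family!r}")


def generate_query_set(spec: QuerySpec) -> list[str]:
    """Emit ``n_molecules`` lines of ``SMILES<TAB>Qxxxxxx``, seeded."""
    spec.validate()
    rng = random.Random(spec.seed)
    families = sorted(spec.weights)
    weights = [spec.weights[f] for f in families]
    lines = []
    for i in range(spec.n_molecules):
        family = rng.choices(families, weights=weights)[0]
        smiles = _generate_one(rng, family, spec.hac_range)
        lines.append(f"{smiles}\tQ{i:06d}")
    return lines


def iter_records(lines: Sequence[str]) -> Iterator:
    """Parse fixture lines into molecule records (all are parseable)."""
    for i, line in enumerate(lines):
        parts = line.split("\t")
        smiles = parts[0].split()[0]
        id = parts[1] if len(parts) > 1 else str(i + 1)
        yield parse_molecule(smiles, id)
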