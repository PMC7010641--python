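"""Shared fixtures and the independent ball-enumeration oracle.

The oracle re-derives atom environments from the topological distance
matrix (a bond lies at BFS depth 1 + the distance of its nearer endpoint
from the root; the radius-r ball is every bond at depth <= r, emitted
only when some bond sits at depth exactly r).  It shares nothing with
the package's extraction path except the final fragment writer.
"""

from __future__ import annotations

import random

import pytest
from rdkit import Chem

from clscore.fixtures import QuerySpec, generate_query_set
from clscore.shingles import parse_molecule


def oracle_shingle_texts(mol: Chem.Mol, min_radius: int = 1, max_radius: int = 3) -> set[str]:
    """Brute-force ball enumeration via the distance matrix."""
    dm = Chem.GetDistanceMatrix(mol)
    out: set[str] = set()
    for root in range(mol.GetNumAtoms()):
        depth = {}
        for bond in mol.GetBonds():
            d1, d2 = dm[root][bond.GetBeginAtomIdx()], dm[root][bond.GetEndAtomIdx()]
            if d1 >= 1e6 or d2 >= 1e6:  # other component
                continue
            depth[bond.GetIdx()] = 1 + int(min(d1, d2))
        for radius in range(min_radius, max_radius + 1):
            if not any(d == radius for d in depth.values()):
                continue
            bonds = [i for i, d in depth.items() if d <= radius]
            amap: dict[int, int] = {}
            submol = Chem.PathToSubmol(mol, bonds, atomMap=amap)
            out.add(Chem.MolToSmiles(submol, rootedAtAtom=amap[root], canonical=True))
    return out


def random_molecule_smiles(n: int, seed: int, hac_range=(2, 12)) -> list[str]:
    """Deterministic pool of diverse parseable SMILES for property tests."""
    lines = generate_query_set(QuerySpec(n_molecules=n, seed=seed, hac_range=hac_range))
    return [line.split("\t")[0] for line in lines]


def random_renderings(smiles: str, n: int, seed: int) -> list[str]:
    """Alternative SMILES renderings of one molecule (seeded random walks)."""
    mol = Chem.MolFromSmiles(smiles)
    return list(Chem.MolToRandomSmilesVect(mol, n, randomSeed=seed))


@pytest.fixture(scope="session")
def molecule_pool() -> list[str]:
    return random_molecule_smiles(60, seed=11)


@pytest.fixture
def ethanol_record():
    return parse_molecule("CCO", "ethanol")
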