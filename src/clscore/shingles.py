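"""Circular-substructure (shingle) extraction from SMILES.

A *shingle* is the connected fragment induced by all bonds within ``r``
bonds of a root atom, serialized as a canonical SMILES string written
starting at the root, with aromatic atoms in lowercase aromatic form and
all stereochemistry discarded.  Shingles of radii 1-3 (diameters up to
six bonds) are the atom environments underlying ECFP-style fingerprints;
here the fragment strings themselves are kept verbatim, never hashed.

Canonical-form stability
------------------------
Rooted canonical SMILES of a *fragment* (which may contain aromatic atoms
outside a complete ring and therefore cannot be sanitized on its own) is
not invariant to the parent molecule's atom numbering.  The engine
therefore round-trips every input through its canonical stereo-free
SMILES before extraction, which pins a deterministic atom order and makes
the extracted shingle set independent of how the input SMILES was
written.  This convention, together with the toolkit version and
aromaticity model, is recorded in :data:`CANONICALIZATION_TAG`; frequency
tables built under one tag must only be queried with molecules parsed
under the same tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, TextIO, Union

import rdkit
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.error")

#: Provenance marker for shingle strings: toolkit version, aromaticity
#: model, stereo handling and atom-order convention.  Tables and queries
#: must share this tag.
CANONICALIZATION_TAG = (
    f"rdkit-{rdkit.__version__}|default-aromaticity|stereo-stripped|canonical-order-roundtrip"
)

#: SMILES standardizer applied before parsing, or None.  Hook for users
#: who normalize protonation states etc. with external tooling.
Standardizer = Callable[[str], str]


class ParseError(ValueError):
    """A SMILES record could not be parsed.

    Carries the offending input so stream processors can log and skip.
    """

    def __init__(self, smiles: str, id: str = ""):
        self.smiles = smiles
        self.id = id
        super().__init__(f"unparseable SMILES{f' (id={id})' if id else ''}: {smiles!r}")


@dataclass(frozen=True)
class Shingle:
    """One circular substructure: canonical rooted fragment string + radius."""

    text: str
    radius: int


@dataclass
class MoleculeRecord:
    """A parsed molecule with its input rendering and identifier.

    ``mol`` holds the stereo-stripped, canonically renumbered RDKit
    molecule actually used for extraction; ``smiles`` keeps the input
    text verbatim so filtered streams can re-emit original lines.
    """

    smiles: str
    id: str
    mol: Chem.Mol = field(repr=False)
    hac: int
    canonicalization_tag: str = CANONICALIZATION_TAG


def parse_molecule(
    smiles: str,
    id: str = "",
    standardizer: Optional[Standardizer] = None,
) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Aromaticity is perceived under RDKit's default model; stereochemistry
    is discarded; the molecule is renumbered into canonical atom order
    (see module docstring).  Raises :class:`ParseError` on invalid input.
    """
    if not smiles or not smiles.strip():
        raise ParseError(smiles, id)
    text = standardizer(smiles) if standardizer is not None else smiles
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ParseError(smiles, id)
    Chem.RemoveStereochemistry(mol)
    # Round-trip through the canonical SMILES string: its atom order is a
    # pure function of the molecular graph, unlike canonical-rank
    # renumbering whose tie-breaking leaks the input order.
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical output always re-parses
        raise ParseError(smiles, id)
    return MoleculeRecord(smiles=smiles, id=id, mol=mol, hac=mol.GetNumHeavyAtoms())


def extract_shingles(
    mol: Union[MoleculeRecord, Chem.Mol],
    min_radius: int = 1,
    max_radius: int = 3,
) -> set[Shingle]:
    """Extract the unique set of shingles of radii ``min_radius..max_radius``.

    For every atom and radius, the environment is the set of bonds within
    that many BFS steps of the root; environments that do not extend to
    the full requested radius are not emitted (their fragments already
    appear at their true radius).  Multi-fragment inputs are processed
    per component implicitly (environments never cross components) and
    pooled uniquely.
    """
    if not 1 <= min_radius <= max_radius:
        raise ValueError("require 1 <= min_radius <= max_radius")
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    out: set[Shingle] = set()
    for atom_idx in range(rdmol.GetNumAtoms()):
        for radius in range(min_radius, max_radius + 1):
            bonds = AllChem.FindAtomEnvironmentOfRadiusN(rdmol, radius, atom_idx)
            if not bonds:
                break  # deeper environments cannot exist either
            amap: dict[int, int] = {}
            submol = Chem.PathToSubmol(rdmol, bonds, atomMap=amap)
            text = Chem.MolToSmiles(submol, rootedAtAtom=amap[atom_idx], canonical=True)
            out.add(Shingle(text=text, radius=radius))
    return out


def shingle_texts(
    mol: Union[MoleculeRecord, Chem.Mol],
    min_radius: int = 1,
    max_radius: int = 3,
) -> set[str]:
    """Unique shingle strings only (radius collapsed), as counted in tables."""
    return {s.text for s in extract_shingles(mol, min_radius, max_radius)}


def iter_smiles_lines(lines: Iterable[str]) -> Iterator[tuple[str, str, int]]:
    """Yield ``(smiles, id, line_number)`` from a SMILES stream.

    One record per line, ``SMILES[<whitespace>ID]``; lines beginning with
    '#' and blank lines are ignored.  The id defaults to the 1-based line
    number when absent.
    """
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        id = parts[1].strip() if len(parts) > 1 else str(lineno)
        yield smiles, id, lineno


def read_smiles_file(
    source: Union[str, TextIO],
    standardizer: Optional[Standardizer] = None,
    strict: bool = False,
    on_error: Optional[Callable[[ParseError], None]] = None,
) -> Iterator[MoleculeRecord]:
    """Stream :class:`MoleculeRecord` objects from a SMILES file or handle.

    Unparseable lines raise in ``strict`` mode; otherwise they are
    reported to ``on_error`` (if given) and skipped.
    """
    if isinstance(source, str):
        with open(source) as fh:
            yield from read_smiles_file(fh, standardizer, strict, on_error)
        return
    for smiles, id, _ in iter_smiles_lines(source):
        try:
            yield parse_molecule(smiles, id, standardizer)
        except ParseError as err:
            if strict:
                raise
            if on_error is not None:
                on_error(err)
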