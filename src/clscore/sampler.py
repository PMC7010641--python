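"""Property-triplet binning and uniform (even) sampling across bins.

Molecules are stratified by the triplet (heavy atom count, stereocenter
class, heteroatom class), with the high tails merged: stereocenter
counts >= 5 collapse into one class, heteroatom counts >= 8 into
another.  Even sampling then draws the same number of molecules from
every bin that can afford it: bins smaller than the running per-bin
quota are taken whole, and the quota is recomputed over the remaining
bins until it stabilizes.  The result is a subset spread evenly across
molecular size, stereochemical complexity and polarity instead of
mirroring the exponential skew of enumerated chemical space.
"""

from __future__ import annotations

import math
import os
import random
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

from rdkit import Chem

from .shingles import MoleculeRecord

STEREO_MERGE_DEFAULT = 5
HETERO_MERGE_DEFAULT = 8


class PropertyTriplet(NamedTuple):
    """(HAC, stereocenter class, heteroatom class) bin key after merging."""

    hac: int
    stereo_class: int
    hetero_class: int


@dataclass
class BinCensus:
    """Occupancy of every non-empty triplet bin."""

    counts: dict[PropertyTriplet, int] = field(default_factory=dict)
    parse_failures: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class BinAllocation:
    """Per-bin draw quotas produced by :func:`allocate_uniform`."""

    quotas: dict[PropertyTriplet, int]
    target: int

    @property
    def total(self) -> int:
        return sum(self.quotas.values())


class AllocationError(ValueError):
    """Allocation inconsistent with the census/stream it is applied to."""


def compute_triplet(
    mol: Union[MoleculeRecord, Chem.Mol],
    stereo_merge: int = STEREO_MERGE_DEFAULT,
    hetero_merge: int = HETERO_MERGE_DEFAULT,
    assigned_only: bool = False,
) -> PropertyTriplet:
    """Bin key for one molecule.

    Stereocenters are *potential* tetrahedral centers (assigned plus
    unassigned) under symmetry-aware perception, since enumerated
    collections carry mostly unassigned centers; ``assigned_only``
    restricts to centers with specified configuration.  Heteroatoms are
    heavy atoms that are not carbon.
    """
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    if assigned_only and isinstance(mol, MoleculeRecord):
        # the engine strips stereochemistry at parse time; recover the
        # assigned centers from the original input rendering
        reparsed = Chem.MolFromSmiles(mol.smiles)
        if reparsed is not None:
            rdmol = reparsed
    hac = rdmol.GetNumHeavyAtoms()
    hetero = sum(1 for a in rdmol.GetAtoms() if a.GetAtomicNum() != 6)
    centers = Chem.FindMolChiralCenters(
        rdmol, includeUnassigned=not assigned_only, useLegacyImplementation=False
    )
    stereo = len(centers)
    return PropertyTriplet(
        hac=hac,
        stereo_class=min(stereo, stereo_merge),
        hetero_class=min(hetero, hetero_merge),
    )


def census_stream(
    records: Iterable[MoleculeRecord],
    stereo_merge: int = STEREO_MERGE_DEFAULT,
    hetero_merge: int = HETERO_MERGE_DEFAULT,
    assigned_only: bool = False,
    spill_dir: Optional[str] = None,
) -> BinCensus:
    """Single-pass exact bin census over a record stream.

    With ``spill_dir`` set, each record's input line (``smiles<TAB>id``)
    is appended to its bin's file, so later phases can restart from disk
    without re-streaming the input.
    """
    census = BinCensus()
    handles: dict[PropertyTriplet, object] = {}
    if spill_dir is not None:
        os.makedirs(spill_dir, exist_ok=True)
    try:
        for record in records:
            key = compute_triplet(record, stereo_merge, hetero_merge, assigned_only)
            census.counts[key] = census.counts.get(key, 0) + 1
            if spill_dir is not None:
                fh = handles.get(key)
                if fh is None:
                    fh = open(os.path.join(spill_dir, spill_filename(key)), "a")
                    handles[key] = fh
                fh.write(f"{record.smiles}\t{record.id}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return census


def spill_filename(key: PropertyTriplet) -> str:
    return f"bin_{key.hac}_{key.stereo_class}_{key.hetero_class}.smi"


def allocate_uniform(census: BinCensus, target: int) -> BinAllocation:
    """Iterative even allocation of ``target`` draws across bins.

    Bins are processed in ascending size order.  Repeatedly, the
    remaining target is divided by the number of remaining bins; every
    bin no larger than that quota is taken whole and subtracted from the
    target.  Once the smallest remaining bin exceeds the quota, every
    remaining bin receives floor(quota), and quotas are topped up by one
    per bin in ascending-size order (ties by lexicographic key) until the
    allocation sums to min(target, total).
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    quotas: dict[PropertyTriplet, int] = {k: 0 for k in census.counts}
    remaining = sorted(census.counts, key=lambda k: (census.counts[k], k))
    remaining_target = min(target, census.total)
    while remaining:
        quota = remaining_target / len(remaining)
        exhausted = [k for k in remaining if census.counts[k] <= quota]
        if not exhausted:
            break
        for k in exhausted:
            quotas[k] = census.counts[k]
            remaining_target -= census.counts[k]
        remaining = [k for k in remaining if k not in set(exhausted)]
    if remaining:
        base = math.floor(remaining_target / len(remaining))
        for k in remaining:
            quotas[k] = base
        shortfall = remaining_target - base * len(remaining)
        for k in remaining[:shortfall]:
            quotas[k] += 1
    return BinAllocation(quotas=quotas, target=target)


def _bin_rng(seed: int, key: PropertyTriplet) -> random.Random:
    """Seeded per-bin RNG, stable across runs and platforms."""
    token = f"{seed}|{key.hac},{key.stereo_class},{key.hetero_class}"
    return random.Random(zlib.crc32(token.encode()) & 0x7FFFFFFF)


def _reservoir(lines: Iterable[str], quota: int, rng: random.Random) -> list[str]:
    """Uniform sample without replacement via Algorithm R."""
    kept: list[str] = []
    for i, line in enumerate(lines):
        if i < quota:
            kept.append(line)
        else:
            j = rng.randint(0, i)
            if j < quota:
                kept[j] = line
    return kept


def draw_sample(
    source: Union[str, Iterable[tuple[PropertyTriplet, str]]],
    allocation: BinAllocation,
    seed: int,
    census: Optional[BinCensus] = None,
) -> Iterator[str]:
    """Draw the allocated sample, yielding ``smiles<TAB>id`` lines.

    ``source`` is either a spill directory written by
    :func:`census_stream` or an iterable of ``(bin key, line)`` pairs.
    Per bin, exactly ``quotas[b]`` lines are drawn uniformly without
    replacement by seeded reservoir sampling; the per-bin seed is derived
    from ``(seed, bin key)`` so repeat runs are byte-identical.  Output
    order: bins in lexicographic key order, records in draw order.
    Raises :class:`AllocationError` when a bin holds fewer lines than its
    quota (allocation and source are out of sync).
    """
    per_bin: dict[PropertyTriplet, list[str]] = {}
    if isinstance(source, str):
        for key, quota in allocation.quotas.items():
            if quota == 0:
                continue
            path = os.path.join(source, spill_filename(key))
            if not os.path.exists(path):
                raise AllocationError(f"spill file missing for bin {key}")
            with open(path) as fh:
                lines = (line.rstrip("\n") for line in fh if line.strip())
                per_bin[key] = _reservoir(lines, quota, _bin_rng(seed, key))
    else:
        # streaming single pass: one reservoir per bin; the RNG is only
        # consumed once a bin overflows its quota, exactly as in
        # _reservoir, so spill-dir and streaming draws are byte-identical
        rngs: dict[PropertyTriplet, random.Random] = {}
        counts: dict[PropertyTriplet, int] = {}
        for key, line in source:
            quota = allocation.quotas.get(key, 0)
            i = counts.get(key, 0)
            counts[key] = i + 1
            if quota == 0:
                continue
            bucket = per_bin.setdefault(key, [])
            if i < quota:
                bucket.append(line)
            else:
                rng = rngs.setdefault(key, _bin_rng(seed, key))
                j = rng.randint(0, i)
                if j < quota:
                    bucket[j] = line
    for key, quota in allocation.quotas.items():
        got = len(per_bin.get(key, [])) if quota > 0 else 0
        if quota > 0 and got < quota:
            raise AllocationError(f"bin {key}: quota {quota} but only {got} records")
    for key in sorted(allocation.quotas):
        if allocation.quotas[key] > 0:
            yield from per_bin[key]
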