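"""Scikit-learn style estimators wrapping the functional core.

``CLScorer`` is fit/transform-shaped: ``fit`` tabulates shingle
frequencies over a reference corpus, ``score_samples`` computes the
likeness score of query molecules against the fitted table.
``UniformBinSampler`` is fit/sample-shaped: ``fit`` takes the bin
census and computes per-bin quotas, ``sample`` draws the stratified
subset.  Both compose with sklearn pipelines and model selection via
``get_params`` / ``set_params``.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import sampler as _sampler
from . import scoring as _scoring
from . import table as _table
from .shingles import MoleculeRecord, ParseError, Standardizer, parse_molecule


def _as_records(X: Iterable, standardizer=None, strict: bool = True):
    """Accept SMILES strings or MoleculeRecords; parse as needed."""
    for item in X:
        if isinstance(item, MoleculeRecord):
            yield item
        else:
            try:
                yield parse_molecule(str(item), standardizer=standardizer)
            except ParseError:
                if strict:
                    raise
                yield None


class CLScorer(BaseEstimator):
    """Substructure-frequency likeness scorer.

    Parameters
    ----------
    min_count : int, default 100
        Minimum number of reference molecules a shingle must occur in to
        be stored (rarer shingles are dropped from the table).
    min_radius, max_radius : int, defaults 1 and 3
        Bond radii of the circular substructures.
    dedupe : bool, default False
        Drop exact structural duplicates from the reference corpus
        before counting.
    standardizer : callable or None
        Optional SMILES -> SMILES hook applied before parsing.

    Attributes
    ----------
    table_ : ShingleFrequencyTable
        The fitted shingle frequency table.
    n_features_in_ : int
        Number of reference molecules seen during fit.
    """

    def __init__(
        self,
        min_count: int = 100,
        min_radius: int = 1,
        max_radius: int = 3,
        dedupe: bool = False,
        standardizer: Optional[Standardizer] = None,
    ):
        self.min_count = min_count
        self.min_radius = min_radius
        self.max_radius = max_radius
        self.dedupe = dedupe
        self.standardizer = standardizer

    def fit(self, X: Iterable, y=None) -> "CLScorer":
        """Tabulate shingle frequencies over reference SMILES/records."""
        self.table_ = _table.build_reference(
            X,
            min_count=self.min_count,
            min_radius=self.min_radius,
            max_radius=self.max_radius,
            dedupe=self.dedupe,
            standardizer=self.standardizer,
        )
        self.n_features_in_ = self.table_.n_molecules
        return self

    @classmethod
    def from_table(cls, table: _table.ShingleFrequencyTable) -> "CLScorer":
        """Build a fitted scorer around an existing (e.g. loaded) table."""
        est = cls(
            min_count=table.min_count,
            min_radius=table.min_radius,
            max_radius=table.max_radius,
        )
        est.table_ = table
        est.n_features_in_ = table.n_molecules
        return est

    def score_samples(self, X: Iterable) -> np.ndarray:
        """Likeness score per query molecule (NaN for unparseable input)."""
        check_is_fitted(self, "table_")
        out = []
        for record in _as_records(X, self.standardizer, strict=False):
            if record is None:
                out.append(np.nan)
            else:
                out.append(_scoring.score_molecule(record, self.table_).clscore)
        return np.asarray(out, dtype=float)

    def transform(self, X: Iterable) -> pd.DataFrame:
        """Full per-molecule breakdowns as a DataFrame."""
        check_is_fitted(self, "table_")
        rows = []
        for record in _as_records(X, self.standardizer, strict=False):
            if record is None:
                rows.append((None, None, np.nan, np.nan, np.nan, np.nan))
                continue
            b = _scoring.score_molecule(record, self.table_)
            rows.append((record.smiles, record.id, b.clscore, b.n_shingles, b.n_matched, b.log_sum))
        return pd.DataFrame(
            rows, columns=["smiles", "id", "clscore", "n_shingles", "n_matched", "log_sum"]
        )

    def predict(self, X: Iterable) -> np.ndarray:
        return self.score_samples(X)


class UniformBinSampler(BaseEstimator):
    """Stratified even sampler over property-triplet bins.

    ``fit`` computes the bin census of the input and the per-bin quotas
    for ``target`` total draws; ``sample`` draws the subset with seeded
    per-bin reservoir sampling (byte-identical across repeat runs).
    """

    def __init__(
        self,
        target: int = 10_000_000,
        seed: int = 0,
        stereo_merge: int = _sampler.STEREO_MERGE_DEFAULT,
        hetero_merge: int = _sampler.HETERO_MERGE_DEFAULT,
        assigned_only: bool = False,
    ):
        self.target = target
        self.seed = seed
        self.stereo_merge = stereo_merge
        self.hetero_merge = hetero_merge
        self.assigned_only = assigned_only

    def fit(self, X: Iterable, y=None) -> "UniformBinSampler":
        records = _as_records(X)
        self.census_ = _sampler.census_stream(
            records, self.stereo_merge, self.hetero_merge, self.assigned_only
        )
        self.allocation_ = _sampler.allocate_uniform(self.census_, self.target)
        return self

    def sample(self, X: Iterable) -> list[str]:
        """Draw the allocated subset from ``X`` (same population as fit)."""
        check_is_fitted(self, "allocation_")

        def keyed():
            for record in _as_records(X):
                key = _sampler.compute_triplet(
                    record, self.stereo_merge, self.hetero_merge, self.assigned_only
                )
                yield key, f"{record.smiles}\t{record.id}"

        return list(_sampler.draw_sample(keyed(), self.allocation_, self.seed))

    def fit_sample(self, X: Sequence) -> list[str]:
        return self.fit(X).sample(X)
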