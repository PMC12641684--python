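"""Named per-case feature matrices shared across extractor families."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureBlock:
    """A cases x features matrix with unique, ordered feature names.

    ``family`` identifies the extractor ({shape, firstorder, glcm, glrlm,
    filtered, radiomics, latent, reduced}); ``case_ids`` align rows across
    blocks when assembling classifier inputs.
    """

    names: list
    matrix: np.ndarray
    family: str
    case_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("name count does not match matrix columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        if self.case_ids and len(self.case_ids) != self.matrix.shape[0]:
            raise ValueError("case_ids length does not match rows")

    @classmethod
    def single_row(cls, names, values, family: str, case_id: str | None = None):
        ids = [case_id] if case_id is not None else []
        return cls(names=list(names), matrix=np.asarray(values, dtype=np.float64)[None, :],
                   family=family, case_ids=ids)

    @property
    def n_cases(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, case_ids) -> "FeatureBlock":
        """Row-subset by case id, preserving the requested order."""
        index = {c: i for i, c in enumerate(self.case_ids)}
        rows = [index[c] for c in case_ids]
        return FeatureBlock(names=list(self.names), matrix=self.matrix[rows],
                            family=self.family, case_ids=list(case_ids))

    def to_frame(self) -> pd.DataFrame:
        idx = self.case_ids if self.case_ids else None
        return pd.DataFrame(self.matrix, columns=self.names, index=idx)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "case_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, family: str) -> "FeatureBlock":
        df = pd.read_csv(path, index_col=0)
        return cls(names=list(df.columns), matrix=df.to_numpy(),
                   family=family, case_ids=[str(i) for i in df.index])


def concat_blocks(blocks, family: str = "combined") -> FeatureBlock:
    """Column-concatenate blocks sharing an identical case ordering."""
    ids = blocks[0].case_ids
    for b in blocks[1:]:
        if b.case_ids != ids:
            raise ValueError("case sets/ordering differ across blocks")
    names = [n for b in blocks for n in b.names]
    matrix = np.hstack([b.matrix for b in blocks])
    return FeatureBlock(names=names, matrix=matrix, family=family, case_ids=list(ids))
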