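"""Assignment of predictor columns to named sets (genes)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSetMap:
    """Maps named sets (genes) to predictor column indices.

    A SNP may belong to several sets (overlapping genes); the column index
    is then repeated in each set's entry.  SNPs assigned to no set are simply
    absent from ``columns``.
    """

    snp_ids: list[str]
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.columns = {k: np.asarray(v, dtype=np.intp) for k, v in self.columns.items()}
        p = len(self.snp_ids)
        for name, idx in self.columns.items():
            if idx.size == 0:
                raise ValueError(f"set {name!r} is empty")
            if idx.min() < 0 or idx.max() >= p:
                raise ValueError(f"set {name!r} references columns outside 0..{p - 1}")

    @property
    def set_ids(self) -> list[str]:
        return list(self.columns)

    @property
    def n_sets(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns.items())

    def __getitem__(self, set_id: str) -> np.ndarray:
        return self.columns[set_id]

    @classmethod
    def from_sizes(cls, set_sizes, snp_ids=None, set_ids=None) -> "GeneSetMap":
        """Contiguous blocks of the given sizes, named set1..setG by default."""
        set_sizes = [int(s) for s in set_sizes]
        if any(s <= 0 for s in set_sizes):
            raise ValueError("set sizes must be positive")
        p = sum(set_sizes)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(p)]
        if set_ids is None:
            set_ids = [f"set{g + 1}" for g in range(len(set_sizes))]
        cols, start = {}, 0
        for name, size in zip(set_ids, set_sizes):
            cols[name] = np.arange(start, start + size)
            start += size
        return cls(snp_ids=list(snp_ids), columns=cols)

    @classmethod
    def from_table(cls, table: pd.DataFrame, snp_ids: list[str]) -> "GeneSetMap":
        """Build from a two-column (snp_id, set_id) table.

        SNPs listed under several sets are duplicated into each; table rows
        whose snp_id is not among ``snp_ids`` are ignored by the caller's
        bookkeeping (see :func:`nlhsim.io.read_set_map`).
        """
        pos = {s: i for i, s in enumerate(snp_ids)}
        cols: dict[str, list[int]] = {}
        for snp, gene in zip(table.iloc[:, 0], table.iloc[:, 1]):
            if snp in pos:
                cols.setdefault(str(gene), []).append(pos[snp])
        if not cols:
            raise ValueError("set map assigns no known SNP to any set")
        return cls(snp_ids=list(snp_ids), columns={k: np.unique(v) for k, v in cols.items()})

    def to_table(self) -> pd.DataFrame:
        rows = [(self.snp_ids[i], name) for name, idx in self.columns.items() for i in idx]
        return pd.DataFrame(rows, columns=["snp_id", "set_id"])

    def restrict(self, kept_columns) -> "GeneSetMap":
        """Project the map onto a subset of columns (e.g. post-screening).

        Column indices are renumbered to positions within ``kept_columns``;
        sets losing all their SNPs are dropped.
        """
        kept_columns = np.asarray(kept_columns, dtype=np.intp)
        new_pos = {int(c): i for i, c in enumerate(kept_columns)}
        cols = {}
        for name, idx in self.columns.items():
            sub = [new_pos[int(i)] for i in idx if int(i) in new_pos]
            if sub:
                cols[name] = np.asarray(sub, dtype=np.intp)
        if not cols:
            raise ValueError("no set survives the column restriction")
        return GeneSetMap(
            snp_ids=[self.snp_ids[int(c)] for c in kept_columns], columns=cols
        )
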