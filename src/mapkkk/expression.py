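"""FPKM expression matrices with tissue/condition/replicate sample structure.

The container wraps a genes x samples :class:`pandas.DataFrame` whose column
names encode the sample design as ``tissue_condition_rep`` (for example
``leaf_drought_1``).  Tissues are typically ``leaf``, ``stem`` and ``root``
and conditions ``drought`` and ``control``, but any labels without
underscores are accepted.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SAMPLE_RE = re.compile(r"^(?P<tissue>[^_]+)_(?P<condition>[^_]+)_(?P<rep>\d+)$")


def parse_sample_name(name: str) -> tuple[str, str, int]:
    """Split a ``tissue_condition_rep`` column name into its parts."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(
            f"sample column {name!r} does not match 'tissue_condition_rep'"
        )
    return m["tissue"], m["condition"], int(m["rep"])


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM table with parsed sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id; columns named ``tissue_condition_rep``.
        All entries must be non-negative FPKM values.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        meta = [parse_sample_name(c) for c in self.values.columns]
        self.samples = pd.DataFrame(
            meta, columns=["tissue", "condition", "rep"], index=self.values.columns
        )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.samples["tissue"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def replicate_columns(self, tissue: str, condition: str) -> list[str]:
        sel = (self.samples["tissue"] == tissue) & (
            self.samples["condition"] == condition
        )
        return list(self.samples.index[sel])

    def replicate_values(self, gene: str, tissue: str, condition: str) -> np.ndarray:
        cols = self.replicate_columns(tissue, condition)
        return self.values.loc[gene, cols].to_numpy(dtype=float)

    def condition_means(self) -> pd.DataFrame:
        """Average replicates, returning genes x ``tissue_condition`` means.

        For the standard three-tissue, two-condition design this yields the
        six observation columns used by the expression filter and the
        co-expression network.
        """
        out = {}
        for tissue, condition in itertools.product(self.tissues, self.conditions):
            cols = self.replicate_columns(tissue, condition)
            if cols:
                out[f"{tissue}_{condition}"] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out, index=self.values.index)

    def subset(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy())

    # ------------------------------------------------------------------ io
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)
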