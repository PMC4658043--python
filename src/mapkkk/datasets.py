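"""Bundled reference data: the maize drought qPCR panel.

Relative expression (qRT-PCR, drought vs well-watered, delta-delta Ct with
the zSSIIb reference gene) of eight maize MAPKKK genes across eight inbred
lines, together with the lines' fresh- and dry-biomass drought tolerance
indices.  X178 is the most drought-tolerant line in the panel and E28 the
most sensitive.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mapkkk").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)


def load_drought_panel() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(lines x genes relative expression, lines x {fresh, dry} DTI)."""
    return _load("drought_panel_expression.tsv"), _load("drought_panel_dti.tsv")
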