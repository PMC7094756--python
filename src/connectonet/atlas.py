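"""The shipped region-label table (AAL2 cerebrum, 94 parcels)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["aal2_labels", "aal2_table"]


def aal2_table() -> pd.DataFrame:
    """Two-column table (1-based index, region name), 47 per hemisphere."""
    with resources.files("connectonet.data").joinpath("aal2_labels.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def aal2_labels() -> list[str]:
    """The 94 AAL2 region names in atlas order."""
    return aal2_table()["name"].tolist()
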