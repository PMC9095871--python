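"""Bundled published summary tables for the rodent lineage.

These are the printed inputs of the rate and connection arithmetic:
per-branch EBR counts and branch times, rearrangement counts by type,
and per-ancestor syntenic-association connection counts.  They let the
rate table, rearrangement totals, EBR age partition and LRI-synteny
connection fractions be recomputed without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_rodent_branches", "load_lri_connection_counts", "RODENT_TREE_DEPTH_MY",
           "MYODONTA_SPLIT", "RODENT_CHAIN"]

RODENT_TREE_DEPTH_MY = 73.0  # age of the rodent root ancestor
MYODONTA_SPLIT = "Myodonta"
RODENT_CHAIN = (
    "Rodentia",
    "Mouse Clade + Ctenohystricia",
    "Mouse Clade",
    "Myodonta",
    "Muroidea",
    "Eumuroidea",
    "Muridae",
    "Mouse",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("grr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", na_values=["NA"])


def load_rodent_branches() -> pd.DataFrame:
    """Per-branch EBR counts, branch times (My) and rearrangement counts,
    ordered root -> mouse; root branch has no event counts."""
    df = _read("rodent_branches.tsv")
    return df.set_index("branch").loc[list(RODENT_CHAIN)].reset_index()


def load_lri_connection_counts() -> pd.DataFrame:
    """Ancestral syntenic associations per ancestor and how many are
    connected by round-spermatid LRIs."""
    return _read("lri_synteny_counts.tsv")
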