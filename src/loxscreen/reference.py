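"""Packaged reference data: the 50 lowest-rate loxP variants.

The fixture lists, for each variant right RBE, its substitution count
relative to the wild type and its measured cleavage rate between loxP
sites (%), i.e. the share of excision events that used the loxP pair in
competition with lox2272.  It doubles as a realistic truth table for
the simulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import RbeVariant
from .simulate import TruthRecord


def load_reference_variants() -> pd.DataFrame:
    """The packaged 50-variant table: right_rbe, n_substitutions, cleavage_rate_pct."""
    path = resources.files("loxscreen") / "data" / "table1_variants.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def reference_truth(
    n_molecules: int = 2000, p_noncleavage: float = 0.035
) -> list[TruthRecord]:
    """Truth records assigning each reference variant its measured rate."""
    df = load_reference_variants()
    return [
        TruthRecord(
            variant=RbeVariant(row.right_rbe),
            p_noncleavage=p_noncleavage,
            p_loxP_given_cleaved=row.cleavage_rate_pct / 100.0,
            n_molecules=n_molecules,
        )
        for row in df.itertuples()
    ]
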