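"""Bundled reference tables.

``table1.csv`` holds the published strain-pair shape comparisons used to
evaluate the ΔIDD regression: 21 rows (20 training, 1 held-out test), each
with the model-predicted and the observed change in intracellular diameter
deviation between two strains differing by a single genetic change.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_table1() -> pd.DataFrame:
    """Load the strain-comparison table (predicted and observed ΔIDD).

    Columns: ``strain1``, ``strain2``, ``predicted_didd``,
    ``observed_didd``, ``split`` ("training" or "testing").
    """
    with resources.files("curvedcell.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    expected = {"strain1", "strain2", "predicted_didd", "observed_didd", "split"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"table1 fixture is malformed: missing {sorted(missing)}")
    return df


def table1_r_squared(include_test: bool = False) -> float:
    """Squared Pearson correlation between predicted and observed ΔIDD."""
    from .model import r_squared

    df = load_table1()
    if not include_test:
        df = df[df["split"] == "training"]
    return r_squared(df["predicted_didd"], df["observed_didd"])
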