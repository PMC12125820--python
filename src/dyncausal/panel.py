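"""Long-format longitudinal panel container.

A panel holds one row per (individual, wave) with a set of health
variables, an optional binary outcome column, and per-variable kind
metadata (``continuous``, ``binary`` or ``categorical``).  Missing cells
are represented as NaN (continuous / binary) or pandas NA (categorical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COL = "id"
WAVE_COL = "wave"
OUTCOME_COL = "stroke"

VALID_KINDS = ("continuous", "binary", "categorical")


@dataclass
class PanelDataset:
    """Long-format panel: one row per individual per wave.

    Parameters
    ----------
    frame
        DataFrame with columns ``id``, ``wave``, one column per variable
        and optionally an outcome column ``stroke``.
    kinds
        Mapping variable name -> kind in {continuous, binary, categorical}.
        Every variable column in ``frame`` must be declared here.
    """

    frame: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return [c for c in self.frame.columns if c in self.kinds]

    @property
    def has_outcome(self) -> bool:
        return OUTCOME_COL in self.frame.columns

    @property
    def n_individuals(self) -> int:
        return self.frame[ID_COL].nunique()

    @property
    def n_waves(self) -> int:
        return int(self.frame[WAVE_COL].max()) + 1

    def missing_fraction(self) -> pd.Series:
        """Per-variable fraction of missing cells over all rows."""
        return self.frame[self.variables].isna().mean()

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.frame.copy(), dict(self.kinds))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        cols = set(self.frame.columns)
        for required in (ID_COL, WAVE_COL):
            if required not in cols:
                raise ValueError(f"panel frame lacks required column {required!r}")
        unknown = [k for k, v in self.kinds.items() if v not in VALID_KINDS]
        if unknown:
            raise ValueError(f"invalid variable kinds for {unknown}")
        missing_meta = [
            c
            for c in self.frame.columns
            if c not in (ID_COL, WAVE_COL, OUTCOME_COL) and c not in self.kinds
        ]
        if missing_meta:
            raise ValueError(f"variables without kind metadata: {missing_meta}")
        if self.frame.duplicated([ID_COL, WAVE_COL]).any():
            raise ValueError("duplicate (id, wave) pairs in panel")
        # waves strictly increasing within individual (frame sorted or not)
        waves = self.frame.sort_values([ID_COL, WAVE_COL])[[ID_COL, WAVE_COL]]
        diffs = waves.groupby(ID_COL, sort=False)[WAVE_COL].diff().dropna()
        if (diffs <= 0).any():
            raise ValueError("waves must be strictly increasing within individual")
        if self.has_outcome:
            y = self.frame[OUTCOME_COL].dropna()
            if not y.isin([0, 1]).all():
                raise ValueError("outcome must be binary where present")

    def sorted(self) -> "PanelDataset":
        """Return a copy with rows ordered by (id, wave)."""
        out = self.frame.sort_values([ID_COL, WAVE_COL], kind="mergesort")
        return PanelDataset(out.reset_index(drop=True), dict(self.kinds))
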