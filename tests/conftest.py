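import numpy as np
import pandas as pd
import pytest

import dyncausal as dc
from dyncausal.panel import PanelDataset


def edge_f1(found: set, truth: set) -> float:
    tp = len(found & truth)
    fp = len(found - truth)
    fn = len(truth - found)
    return 2 * tp / (2 * tp + fp + fn) if tp else 0.0


def make_panel(values: dict[str, list], n_waves: int, kinds: dict[str, str], outcome=None):
    """Small panel from per-individual wave series: values[var] is a list of
    per-individual lists, one value per wave."""
    n_ind = len(next(iter(values.values())))
    rows = {
        "id": np.repeat(np.arange(n_ind), n_waves),
        "wave": np.tile(np.arange(n_waves), n_ind),
    }
    for var, series in values.items():
        rows[var] = np.concatenate([np.asarray(s, dtype=object) for s in series])
    frame = pd.DataFrame(rows)
    for var, kind in kinds.items():
        if kind != "categorical":
            frame[var] = frame[var].astype(float)
    if outcome is not None:
        frame["stroke"] = np.asarray(outcome, dtype=float)
    return PanelDataset(frame, kinds)


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed default cohort (n=2000) shared across structure tests."""
    cfg = dc.default_config(n_individuals=2000, seed=1, calibrate=False)
    cfg.missing_rates = {}
    panel, graph = dc.generate_panel(cfg)
    clean = dc.PanelPreprocessor().fit(panel).transform(panel)
    fm = dc.TemporalFeatures().fit(clean).transform(clean)
    return {"config": cfg, "panel": panel, "graph": graph, "features": fm}


@pytest.fixture(scope="session")
def white_noise_panel():
    """Three mutually independent white-noise variables, 500 individuals."""
    variables = [dc.VariableSpec(n, "continuous") for n in ("x", "y", "z")]
    cfg = dc.SynthConfig(n_individuals=500, variables=variables, autoregression=0.0, seed=42)
    panel, _ = dc.generate_panel(cfg)
    return panel
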