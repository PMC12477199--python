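"""Shared setup for the analysis drivers: the seed-17 synthetic study,
semi-quantified and half-minimum filled, plus the results directory."""

from pathlib import Path

from vola.quantify import semi_quantify
from vola.synth import SynthConfig, generate_dataset
from vola.tables import fill_missing_half_min

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 17


def load_study(seed: int = SEED):
    """Deterministic default study: (dataset, concentration table)."""
    ds = generate_dataset(SynthConfig(seed=seed))
    ct = fill_missing_half_min(semi_quantify(ds.features, ds.is_params))
    return ds, ct
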