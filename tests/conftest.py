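import numpy as np
import pandas as pd
import pytest

from phenostab.synthdata import AsymmetryModel, DesignConfig, TraitModel, generate_experiment


def leaf_frame(readings, individual_id="plant1"):
    """Build a leaf table from {leaf_index: {side: [replicate readings]}}."""
    rows = []
    for leaf_index, sides in readings.items():
        for side, widths in sides.items():
            for rep, width in enumerate(widths, start=1):
                rows.append(
                    {
                        "individual_id": individual_id,
                        "leaf_index": leaf_index,
                        "side": side,
                        "replicate": rep,
                        "width": width,
                    }
                )
    return pd.DataFrame(rows)


def leaves_from_sides(right, left, m=2, sigma_me=0.0, rng=None,
                      individual_id="plant1"):
    """Leaf table with m replicate readings around given true side widths."""
    right = np.asarray(right, float)
    left = np.asarray(left, float)
    rng = rng or np.random.default_rng(0)
    frames = []
    for side, widths in (("right", right), ("left", left)):
        for rep in range(m):
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": individual_id,
                        "leaf_index": np.arange(1, widths.size + 1),
                        "side": side,
                        "replicate": rep + 1,
                        "width": widths + rng.normal(0, sigma_me, widths.size)
                        if sigma_me
                        else widths,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete synthetic experiment (2 species, fast)."""
    design = DesignConfig(
        species_labels=["spA", "spB"],
        reps_late=6,
        reps_first_harvest=8,
        leaves_min=4,
        leaves_max=6,
        rng_seed=42,
    )
    return generate_experiment(design, AsymmetryModel(), TraitModel())
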