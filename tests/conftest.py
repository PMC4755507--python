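import numpy as np
import pandas as pd
import pytest

from kinaray.layout import make_layout
from kinaray.synthetic import (
    ImageRenderSpec,
    SimulationDesign,
    render_array_image,
    simulate_intensity_matrix,
    simulate_truth,
)


def make_samples(cell_types=("Treg", "Teff"), times=(0, 5, 15, 60), reps=3):
    """Sample sheet for a full factorial design, one slide per condition."""
    rows = []
    for cell in cell_types:
        for t in times:
            for r in range(1, reps + 1):
                rows.append({
                    "sample_id": f"{cell}_t{t}_r{r}", "cell_type": cell,
                    "time_min": t, "replicate": r, "slide_id": f"{cell}_t{t}",
                })
    return pd.DataFrame(rows)


@pytest.fixture
def samples_24():
    return make_samples()


@pytest.fixture
def noise_free_matrix():
    """Complete, noise-free matrix with a +1 log2 effect on SUB0001-0005."""
    design = SimulationDesign(n_substrates=40, effect_fraction=0.0,
                              noise_sd=0.0, missing_rate=0.0,
                              rep_effect_sd=0.2, seed=42)
    truth = simulate_truth(design)
    effect = truth.cell_effect.copy()
    effect[:5] = 1.0
    truth = type(truth)(truth.substrate_ids, truth.baseline,
                        truth.time_offsets, effect, truth.rep_offsets,
                        np.arange(40) < 5)
    return simulate_intensity_matrix(truth, design), truth, design


@pytest.fixture(scope="session")
def rendered_slide():
    """A small single-block rendered array with planted offset and 8%
    irregular spots; shared across image tests (read-only)."""
    layout = make_layout(96, n_controls=4, n_blocks=1)
    rng = np.random.default_rng(7)
    values = 2.0 ** rng.uniform(8.0, 12.0, layout.n_spots)
    spec = ImageRenderSpec(irregular_fraction=0.08, grid_offset_px=(3, -2),
                           seed=7)
    image, truth = render_array_image(values, layout, spec)
    return image, truth, layout, values
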