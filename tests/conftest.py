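import numpy as np
import pytest

from ecgpaper import ecg_source, paper_render
from ecgpaper._nn import DenoiserSpec
from ecgpaper.cleanup import make_toy_grid_pairs, train_denoiser


@pytest.fixture(scope="session")
def ecg_record():
    return ecg_source.synthesize_ecg(12, 250.0, 10.0, 72.0, seed=3)


@pytest.fixture(scope="session")
def render_spec():
    return paper_render.RenderSpec()


@pytest.fixture(scope="session")
def page(ecg_record, render_spec):
    """A full rendered 3x4+strip page with ground truth (grid on)."""
    return paper_render.render_ecg(ecg_record, render_spec)


@pytest.fixture(scope="session")
def desk_denoiser():
    """Desk-scale trained denoiser plus its held-out evaluation patches."""
    ys, xs = make_toy_grid_pairs(2000, seed=0)
    y_tr, x_tr = ys[:1600], xs[:1600]
    y_ho, x_ho = ys[1600:], xs[1600:]
    model = train_denoiser((y_tr, x_tr), DenoiserSpec.desk())
    gridded = np.sum((y_ho - x_ho) ** 2, axis=(1, 2)) > 0
    return {
        "model": model,
        "held_gridded": (y_ho[gridded], x_ho[gridded]),
        "held_clean": x_ho[~gridded],
    }
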