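import numpy as np
import pytest

from porehr.media import generate_medium


@pytest.fixture(scope="session")
def small_medium():
    """1.2 cm x 0.9 cm medium at 10 px/lambda_c: fast, still granular."""
    return generate_medium(
        1e-3, 0.5, width=0.012, height=0.009, pixels_per_lambda_c=10, seed=3
    )


@pytest.fixture(scope="session")
def paper_medium():
    """Full-size 3 cm x 2.25 cm reference chip at 20 px/lambda_c."""
    return generate_medium(1e-3, 0.5, seed=1)


@pytest.fixture(scope="session")
def toy_medium():
    """30x30 px medium for brute-force oracle comparisons."""
    rng = np.random.default_rng(11)
    raster = (rng.random((30, 30)) < 0.35).astype(np.uint8)
    raster[0, ::3] = 0  # guarantee pore entries at the top
    raster[-1, ::4] = 0  # and outlets at the bottom
    from porehr.media import MediumImage

    return MediumImage(raster=raster, pixel_size=1e-4, achieved_porosity=float((raster == 0).mean()))
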