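import numpy as np
import pytest

from ngahic.segment import extract_nucleus_records, segment_nuclei
from ngahic.simulate import SpotSimParams, generate_spot_image
from ngahic.stains import color_deconvolve


@pytest.fixture(scope="session")
def spot_fixture():
    """A mid-size synthetic spot with well-separated nuclei, plus its ground
    truth: the shared raw material for segmentation/feature tests."""
    params = SpotSimParams(
        n_nuclei=50,
        canvas=512,
        clustering=0.0,
        orientation_kappa=1.0,
        seed=3,
    )
    image, mask, truth = generate_spot_image(params)
    return {"params": params, "image": image, "mask": mask, "truth": truth}


@pytest.fixture(scope="session")
def segmented_spot(spot_fixture):
    """Deconvolved, segmented records for the shared spot."""
    image = spot_fixture["image"]
    hema, _, _ = color_deconvolve(image.pixels)
    mask = segment_nuclei(hema)
    records = extract_nucleus_records(mask, image)
    return {"image": image, "hema": hema, "mask": mask, "records": records}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
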