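import math

import numpy as np
import pytest

from rarecell import gating, imaging, synth


@pytest.fixture(scope="session")
def default_slide():
    """One rendered slide at default study conditions, with truth."""
    spec = synth.SlideSpec(seed=3)
    slide, truth = synth.generate_slide(spec)
    return spec, slide, truth


@pytest.fixture(scope="session")
def segmented_slide(default_slide):
    """Slide plus segmentation products: records, background, labels."""
    spec, slide, truth = default_slide
    cfg = imaging.SegmentationConfig()
    cell_mask = imaging.build_cell_mask(slide, cfg)
    dapi_mask = imaging.segment_channel(slide["DAPI"], cfg)
    records = imaging.extract_cells(slide, cell_mask, dapi_mask, cfg)
    background = imaging.estimate_background(slide, cell_mask)
    labels = gating.immunophenotype(records, gating.GateConfig(), background)
    return spec, slide, truth, records, background, labels


def match_to_truth(records, truth):
    """Map each truth cell to the detected record at its centroid (or None)."""
    pairs = []
    for t in truth:
        hit = None
        for r in records:
            d = math.hypot(t.centroid[0] - r.centroid[0], t.centroid[1] - r.centroid[1])
            if d < 10.0:
                hit = r
                break
        pairs.append((t, hit))
    return pairs


@pytest.fixture(scope="session")
def flat_disk_slide():
    """Noise-free slide with a single bright disk, for analytic checks."""
    img = np.full((200, 200), 100.0)
    rr, cc = np.mgrid[0:200, 0:200]
    disk = (rr - 100) ** 2 + (cc - 100) ** 2 <= 30**2
    img[disk] = 1000.0
    return img, disk
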