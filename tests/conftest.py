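import numpy as np
import pytest

from shapedx import Condition, Genotype, composition_preset, render_field
from shapedx.imaging import CellRegion
from shapedx.shape_features import measure_cell

SMALL_FIELD = (700, 900)


@pytest.fixture(scope="session")
def scd_low_field():
    """A small slow-deoxygenation SCD field with per-cell truth."""
    preset = composition_preset(Genotype.SCD, Condition.C_LOW)
    return render_field(preset, 60, 7, field_shape=SMALL_FIELD)


@pytest.fixture(scope="session")
def healthy_field():
    preset = composition_preset(Genotype.HEALTHY, Condition.NONE)
    return render_field(preset, 60, 11, field_shape=SMALL_FIELD)


@pytest.fixture(scope="session")
def rasterize_and_measure():
    """Rasterize a centred polygon at 6 px/um and measure its descriptors."""

    def _measure(poly: np.ndarray):
        from skimage.draw import polygon as draw_polygon

        p = poly - poly.min(axis=0) + 4.0
        h = int(np.ceil(p[:, 1].max())) + 8
        w = int(np.ceil(p[:, 0].max())) + 8
        rr, cc = draw_polygon(p[:, 1], p[:, 0], shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        region = CellRegion(
            cell_id=1, mask=mask, offset=(0, 0), area_px=int(mask.sum()), touches_border=False
        )
        return measure_cell(region, pixel_scale=6.0)

    return _measure
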