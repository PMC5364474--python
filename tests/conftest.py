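import numpy as np
import pytest

from thermoseal import GridTransform, ThermalRaster


@pytest.fixture
def make_raster():
    """Factory for small test rasters: values -> ThermalRaster (gsd 0.08 m)."""

    def _make(values, gsd=0.08, origin=(0.0, None), nodata=-9999.0, crs=32620):
        values = np.asarray(values, dtype=float)
        ox, oy = origin
        if oy is None:
            oy = values.shape[0] * gsd  # origin at NW corner, grid ends at y=0
        return ThermalRaster(values, GridTransform(ox, oy, gsd), crs, nodata=nodata)

    return _make
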