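"""Small grid helpers shared by the geometry modules.

All in-memory volumes are indexed ``(z, y, x)``:

* ``z`` — longitudinal axis, increasing feet → head (inferior → superior),
* ``y`` — dorsoventral axis, increasing posterior → anterior,
* ``x`` — horizontal axis, increasing right → left... i.e. the RAS "L" grows.

``spacing_mm`` is always stored in ``(x, y, z)`` order to match how voxel
sizes are quoted for axial acquisitions (in-plane pair first, slice
thickness last).
"""

from __future__ import annotations

import numpy as np

#: tag recorded on every volume; geometry code refuses anything else
CANONICAL_AXES = "zyx(SI,PA,RL)"


def spacing_zyx(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Return spacing as an array in array-index order ``(z, y, x)``."""
    sx, sy, sz = spacing_mm
    return np.array([sz, sy, sx], dtype=float)


def nearest_index(coord: float) -> int:
    """Nearest integer index with ties broken toward the smaller index.

    Used for mid-plane selection: a center of mass exactly between two
    slices picks the inferior / posterior / right one.
    """
    return int(np.ceil(coord - 0.5))
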