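"""Weight-free geometric lung segmentation.

A classical pipeline that exploits the basic contrast of proton-density
thoracic images — bright body, dark air-filled lungs — so the quantification
pipeline can run without any trained model file:

1. body candidate = voxels above the global mean intensity, largest 3D
   connected component kept;
2. lung candidates = low-intensity cavities enclosed by the body;
3. components reaching the superior volume face are discarded as airway;
4. the two largest remaining components are kept and closed morphologically
   (1-voxel ball);
5. right/left is assigned by component centroid column (axis 2 runs
   subject-right -> subject-left); ties break toward right.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from ..volumes import LungSegmentation, Volume

__all__ = ["segment_lungs_classical"]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def segment_lungs_classical(volume: Volume) -> LungSegmentation:
    """Segment both lungs from a thoracic volume by cavity detection.

    Raises ``ValueError("lungs not found")`` when fewer than two enclosed
    cavities exist (e.g. a uniform volume).
    """
    data = volume.data
    body = _largest_component(data > data.mean())

    interior = ndimage.binary_fill_holes(body)
    cavities = interior & ~body

    lab, n = ndimage.label(cavities)
    if n > 0:
        # drop anything connected to the superior volume face (airway/trachea)
        airway_ids = set(np.unique(lab[:, 0, :])) - {0}
        for i in airway_ids:
            lab[lab == i] = 0
        ids, sizes = np.unique(lab[lab > 0], return_counts=True)
    else:
        ids, sizes = np.array([]), np.array([])
    if len(ids) < 2:
        raise ValueError("lungs not found")

    order = np.argsort(sizes)[::-1]
    keep = ids[order[:2]]
    comps = [ndimage.binary_closing(lab == i, structure=ball(1)) for i in keep]

    # centroid column decides laterality; low column = subject right
    cols = [ndimage.center_of_mass(c)[2] for c in comps]
    if cols[0] <= cols[1]:
        right, left = comps
    else:
        left, right = comps
    # closing may have produced a voxel of overlap at the midline
    left = left & ~right
    return LungSegmentation(right, left, volume.spacing)
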