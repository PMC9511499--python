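"""Concentric-disk cell phantoms for ring-quantification fixtures.

Pixel centers sit at integer coordinates; a disk of radius r is the inclusive
set of pixels whose center lies within Euclidean distance r of the cell
center. The phantom is deterministic: two renders with identical arguments
are identical arrays.
"""

from __future__ import annotations

import numpy as np


def render_cell_image(
    nucleus_radius: float,
    cell_radius: float,
    nuclear_intensity: float,
    cytoplasm_intensity: float,
    background: float = 0.0,
    image_size: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a centered two-disk cell phantom and its nuclear mask.

    The nucleus disk carries ``nuclear_intensity``, the cytoplasmic annulus
    (nucleus_radius < d <= cell_radius) carries ``cytoplasm_intensity`` and
    everything else is ``background``. The cytoplasm must leave room for the
    standard 2-px gap + 15-px sampling ring (cell_radius > nucleus_radius +
    17) and the whole cell must fit inside the image.
    """
    if cell_radius <= nucleus_radius + 17:
        raise ValueError(
            "cell_radius must exceed nucleus_radius + 17 so the 2-px gap and "
            "15-px ring fit inside the cytoplasm"
        )
    center = (image_size - 1) / 2.0
    if center - cell_radius < 1 or center + cell_radius > image_size - 2:
        raise ValueError("cell clips the image border; enlarge image_size")

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dist = np.hypot(yy - center, xx - center)
    nuclear_mask = dist <= nucleus_radius
    cyto = (dist > nucleus_radius) & (dist <= cell_radius)
    image = np.full((image_size, image_size), float(background))
    image[nuclear_mask] = nuclear_intensity
    image[cyto] = cytoplasm_intensity
    return image, nuclear_mask
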