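"""Reference colors and the normalized yellow-intensity score.

The screen's readout is the color of the redox dye AHDS_red, which fades
from orange-yellow to clear as it is oxidized.  A well's RGB color ``C`` is
reduced to a single scalar by projecting it, relative to the white
reference ``W0``, onto the direction of the most saturated yellow seen in
the assay, ``Y0``::

    y = (C - W0) . (Y0 - W0) / |Y0 - W0|^2

which is 1 for a fully yellow (reduced) well and 0 for a clear (fully
oxidized) one.  Off-axis colors (stains, condensation) can fall slightly
outside [0, 1]; the value is deliberately not clipped so such wells remain
visible to QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceColors",
    "DEFAULT_REFERENCES",
    "yellow_intensity",
    "display_color",
]


@dataclass(frozen=True)
class ReferenceColors:
    """White and saturated-yellow reference colors for the assay.

    ``Y0_prime = Y0 - W0`` is the yellow direction in white-referenced
    color space; its squared norm normalizes the projection.
    """

    Y0: tuple[float, float, float] = (225.0, 153.0, 0.0)
    W0: tuple[float, float, float] = (255.0, 255.0, 255.0)

    @property
    def Y0_prime(self) -> np.ndarray:
        return np.asarray(self.Y0, dtype=float) - np.asarray(self.W0, dtype=float)

    @property
    def norm_sq(self) -> float:
        v = self.Y0_prime
        return float(v @ v)


DEFAULT_REFERENCES = ReferenceColors()


def yellow_intensity(C, refs: ReferenceColors = DEFAULT_REFERENCES):
    """Normalized yellow intensity of an RGB color (or array of colors).

    Parameters
    ----------
    C : array-like, shape (..., 3)
        8-bit RGB color(s); channels in [0, 255].
    refs : ReferenceColors
        White and yellow references.

    Returns
    -------
    float or ndarray
        ``(C - W0) . (Y0 - W0) / |Y0 - W0|^2``, unclipped.
    """
    C = np.asarray(C, dtype=float)
    if C.shape[-1] != 3:
        raise ValueError("color must have 3 channels (RGB)")
    C_prime = C - np.asarray(refs.W0, dtype=float)
    y = C_prime @ refs.Y0_prime / refs.norm_sq
    return float(y) if y.ndim == 0 else y


def display_color(y, refs: ReferenceColors = DEFAULT_REFERENCES) -> np.ndarray:
    """Reconstruct the display color on the white-yellow segment for ``y``.

    Inverse of :func:`yellow_intensity` for colors on the segment:
    ``W0 + y * (Y0 - W0)``.  Returned as float RGB; not clipped.
    """
    y = np.asarray(y, dtype=float)
    return np.asarray(refs.W0, dtype=float) + y[..., None] * refs.Y0_prime
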