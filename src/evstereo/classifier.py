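"""Grey-level classification of candidate MVB-like vesicle profiles.

A candidate vesicle inside an MCMV is called *MVB-like* when three
criteria hold simultaneously:

1. its measured major axis exceeds 200 nm (strictly);
2. the grey-value distributions inside and outside the candidate are
   clearly separated;
3. the inside is lighter (more electron-lucent) than the outside.

"Clear separation of two peaks" is operationalised as Ashman's D on the
mask statistics, ``D = sqrt(2)·|μ_in − μ_out| / sqrt(σ_in² + σ_out²)``,
with the classical resolvability bound D ≥ 2 as default threshold.  This
is bin-width-independent, unlike literal peak finding on a binned
histogram.  Grey convention: higher value = lighter; pass ``inverted=True``
for raw acquisitions with the opposite polarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InvalidInputError

#: Minimum pixels per mask for trustworthy statistics ("many pixels
#: inside and outside").
MIN_MASK_PIXELS = 50


@dataclass
class PatchROI:
    """A grey-scale patch with annotator masks and calibration.

    ``pixels`` is a 2-D 8-bit-scale grey array; ``inside_mask`` and
    ``outside_mask`` are disjoint boolean arrays of the same shape, each
    covering at least :data:`MIN_MASK_PIXELS` pixels; ``nm_per_px`` is the
    pixel calibration.
    """

    pixels: np.ndarray
    inside_mask: np.ndarray
    outside_mask: np.ndarray
    nm_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        self.outside_mask = np.asarray(self.outside_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise InvalidInputError("pixels must be a 2-D array")
        if (self.inside_mask.shape != self.pixels.shape
                or self.outside_mask.shape != self.pixels.shape):
            raise InvalidInputError("masks must be congruent with pixels")
        if np.any(self.inside_mask & self.outside_mask):
            raise InvalidInputError("inside and outside masks must be disjoint")
        for name, m in (("inside", self.inside_mask),
                        ("outside", self.outside_mask)):
            if int(m.sum()) < MIN_MASK_PIXELS:
                raise InvalidInputError(
                    f"{name} mask has {int(m.sum())} px "
                    f"(< {MIN_MASK_PIXELS} required)")
        if not self.nm_per_px > 0:
            raise InvalidInputError("nm_per_px must be positive")


@dataclass(frozen=True)
class ClassifierParams:
    """Tunables of the MVB-like call: size floor (nm) and separation bound."""

    min_diameter: float = 200.0
    separation_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not self.min_diameter > 0:
            raise InvalidInputError("min_diameter must be positive")
        if not self.separation_threshold > 0:
            raise InvalidInputError("separation_threshold must be positive")


@dataclass(frozen=True)
class SeparationResult:
    separated: bool
    D: float
    lighter_inside: bool
    inside_mean: float
    outside_mean: float
    inside_sd: float
    outside_sd: float


@dataclass(frozen=True)
class Decision:
    """Outcome of the MVB-like call with all features kept for audit."""

    mvb_like: bool
    features: dict = field(default_factory=dict)


def histogram_separation(
    patch: PatchROI,
    threshold: float = 2.0,
    inverted: bool = False,
) -> SeparationResult:
    """Score inside/outside grey-level separation on a patch.

    Computes Ashman's D from the mask means and standard deviations.  When
    both masks have zero variance and identical means D is defined as 0;
    zero variance with distinct means yields D = inf (perfect separation).
    ``lighter_inside`` compares means under the higher-is-lighter
    convention, flipped when ``inverted``.
    """
    pix = patch.pixels.astype(float)
    mu_in = float(pix[patch.inside_mask].mean())
    mu_out = float(pix[patch.outside_mask].mean())
    sd_in = float(pix[patch.inside_mask].std(ddof=1))
    sd_out = float(pix[patch.outside_mask].std(ddof=1))
    denom = math.hypot(sd_in, sd_out)
    diff = abs(mu_in - mu_out)
    if denom == 0.0:
        D = 0.0 if diff == 0.0 else math.inf
    else:
        D = math.sqrt(2.0) * diff / denom
    lighter = mu_in > mu_out
    if inverted:
        lighter = mu_in < mu_out
    return SeparationResult(separated=D >= threshold, D=D,
                            lighter_inside=lighter,
                            inside_mean=mu_in, outside_mean=mu_out,
                            inside_sd=sd_in, outside_sd=sd_out)


def classify_mvb_like(
    patch: PatchROI,
    major_axis_nm: float,
    params: Optional[ClassifierParams] = None,
    inverted: bool = False,
) -> Decision:
    """Call a candidate vesicle MVB-like from its patch and measured size.

    ``major_axis_nm`` is the major axis measured on the micrograph at the
    same calibration as the patch; the size rule is strict (> min_diameter).
    The decision is true only when size, separation and lighter-inside all
    hold; every feature is reported in :attr:`Decision.features`.
    """
    if params is None:
        params = ClassifierParams()
    if major_axis_nm < 0:
        raise InvalidInputError(
            f"major_axis_nm must be >= 0, got {major_axis_nm}")
    sep = histogram_separation(patch, params.separation_threshold, inverted)
    size_ok = major_axis_nm > params.min_diameter
    decision = bool(size_ok and sep.separated and sep.lighter_inside)
    return Decision(
        mvb_like=decision,
        features={
            "major_axis_nm": major_axis_nm,
            "size_ok": size_ok,
            "inside_mean": sep.inside_mean,
            "outside_mean": sep.outside_mean,
            "separation_D": sep.D,
            "separated": sep.separated,
            "lighter_inside": sep.lighter_inside,
        },
    )


# ---------------------------------------------------------------------------
# TIFF I/O — patches travel as an 8-bit grey TIFF plus two mask TIFFs
# ---------------------------------------------------------------------------

def save_patch(patch: PatchROI, prefix) -> None:
    """Write ``<prefix>.tif``, ``<prefix>_inside.tif``, ``<prefix>_outside.tif``."""
    import tifffile

    prefix = Path(prefix)
    tifffile.imwrite(prefix.with_suffix(".tif"),
                     patch.pixels.astype(np.uint8),
                     resolution=(1.0 / patch.nm_per_px, 1.0 / patch.nm_per_px))
    tifffile.imwrite(prefix.parent / (prefix.name + "_inside.tif"),
                     patch.inside_mask.astype(np.uint8) * 255)
    tifffile.imwrite(prefix.parent / (prefix.name + "_outside.tif"),
                     patch.outside_mask.astype(np.uint8) * 255)


def load_patch(prefix, nm_per_px: float) -> PatchROI:
    """Read a patch previously written by :func:`save_patch`."""
    import tifffile

    prefix = Path(prefix)
    pixels = tifffile.imread(prefix.with_suffix(".tif"))
    inside = tifffile.imread(prefix.parent / (prefix.name + "_inside.tif")) > 0
    outside = tifffile.imread(prefix.parent / (prefix.name + "_outside.tif")) > 0
    return PatchROI(pixels=pixels, inside_mask=inside,
                    outside_mask=outside, nm_per_px=nm_per_px)
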