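"""End-to-end automated cell counting: enhance → indicator → watershed →
mask → count.

This chains the stage modules with mutually consistent defaults derived
from a single physical scale, the expected cell diameter.  Each stage
remains independently usable; the pipeline only wires them together and
collects intermediate products for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelVolume, Mask, Volume
from .enhance import EnhanceParams, anisotropic_diffusion, membrane_indicator
from .mask import MaskParams, primordium_mask
from .quant import CountParams, CountResult, count_cells
from .segment import SegmentParams, segment_cells

__all__ = ["PipelineResult", "count_pipeline", "default_min_volume"]


@dataclass(frozen=True)
class PipelineResult:
    count: int
    labels: LabelVolume
    mask: Mask
    indicator: Volume
    count_result: CountResult


def default_min_volume(cell_diameter: float) -> float:
    """Minimum surviving segment volume: 10% of the expected cell volume."""
    return 0.1 * (np.pi / 6.0) * cell_diameter**3


def count_pipeline(
    v: Volume,
    cell_diameter: float = 7.0,
    membrane_width: float = 1.0,
    enhance_params: EnhanceParams | None = None,
    segment_params: SegmentParams | None = None,
    mask_params: MaskParams | None = None,
    count_params: CountParams | None = None,
) -> PipelineResult:
    """Count cells in one membrane-channel stack.

    Scale defaults: the Hessian scale is 1.2 × the membrane width, mask
    smoothing is half a cell diameter, and the fragment-size floor is 10%
    of the expected cell volume.  Any stage's parameters can be overridden.
    """
    if enhance_params is None:
        enhance_params = EnhanceParams(sigma_hessian=max(1.2 * membrane_width,
                                                         max(v.spacing)))
    if segment_params is None:
        segment_params = SegmentParams(min_volume=default_min_volume(cell_diameter))
    if mask_params is None:
        mask_params = MaskParams(sigma_mask=0.5 * cell_diameter)
    count_params = count_params or CountParams()

    enhanced = anisotropic_diffusion(v, enhance_params)
    indicator = membrane_indicator(enhanced, enhance_params.sigma_hessian)
    labels = segment_cells(indicator, segment_params)
    msk = primordium_mask(v, mask_params)
    cr = count_cells(labels, msk, count_params)
    return PipelineResult(cr.count, labels, msk, indicator, cr)
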