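"""Treatment outcome scoring: target/organ-at-risk masks, dose-volume
histograms, generalized equivalent uniform dose and the Lyman normal-tissue
complication probability.

The target volume (TV) is the set of pixels holding cancer cells at
treatment start, dilated by two pixels; the organ at risk (OAR) is its
complement.  Both masks and the complication endpoint parameters are fixed
for the whole treatment.  The Lyman model maps the OAR's gEUD through a
normal CDF:

    NTCP = Phi( (gEUD - TD50) / (m * TD50) ).

Two volume-weighting conventions are provided for gEUD (see :func:`geud`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp, ndtr

from .sim import SimGrid


@dataclass(frozen=True)
class LKBParams:
    """Lyman complication-model parameters for one organ/endpoint."""

    td50: float     # Gy, uniform dose giving 50% complication probability
    m: float        # slope of the dose-response curve
    n: float        # volume-effect parameter (small n -> hotspot dominated)

    def __post_init__(self) -> None:
        if self.td50 <= 0 or self.m <= 0 or self.n <= 0:
            raise ValueError("td50, m and n must all be > 0")


#: per-site complication endpoints: rectal bleeding, xerostomia, pneumonitis
LKB_DEFAULTS: dict[str, LKBParams] = {
    "rectum": LKBParams(80.10, 0.150, 0.15),
    "head_and_neck": LKBParams(40.28, 0.408, 0.01),
    "lung": LKBParams(29.88, 0.400, 0.15),
}


def lkb_params(site: str) -> LKBParams:
    try:
        return LKB_DEFAULTS[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(LKB_DEFAULTS)}") from None


@dataclass(frozen=True)
class RegionMasks:
    """Binary target-volume / organ-at-risk partition of the grid."""

    tv: np.ndarray
    oar: np.ndarray


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram.

    ``volume_fraction[i]`` is the fraction of the region receiving at least
    ``bin_edges[i]`` Gy; it starts at 1 for edge 0 and is non-increasing.
    """

    bin_edges: np.ndarray       # Gy
    volume_fraction: np.ndarray


def compute_masks(grid: SimGrid, dilation_px: int = 2) -> RegionMasks:
    """Build the TV/OAR masks from the tumor occupancy at treatment start.

    The cancer-occupancy mask is dilated by ``dilation_px`` iterations of a
    3x3 square structuring element (Chebyshev radius ``dilation_px``); the
    OAR is the logical complement.
    """
    occ = grid.cancer_mask()
    if not occ.any():
        raise ValueError("no cancer-occupied pixel: cannot define a target volume")
    tv = ndimage.binary_dilation(occ, structure=np.ones((3, 3), dtype=bool),
                                 iterations=dilation_px) if dilation_px else occ
    return RegionMasks(tv=tv, oar=~tv)


def cumulative_dvh(dose: np.ndarray, mask: np.ndarray, bin_width: float = 0.5) -> DVH:
    """Cumulative DVH of the masked pixels of a per-pixel dose map."""
    if not mask.any():
        raise ValueError("empty mask: DVH undefined")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(dose, dtype=np.float64)[mask]
    top = float(values.max())
    n_edges = int(np.floor(top / bin_width + 1e-9)) + 2
    edges = np.arange(n_edges) * bin_width
    # fraction receiving >= each edge
    frac = 1.0 - np.searchsorted(np.sort(values), edges, side="left") / values.size
    frac[0] = 1.0
    return DVH(bin_edges=edges, volume_fraction=frac)


def geud(dvh: DVH, n: float, weighting: str = "differential") -> float:
    """Generalized equivalent uniform dose of a cumulative DVH,

        gEUD = ( sum_i V_i * D_i^(1/n) )^n ,

    evaluated in log space (1/n can exceed 100 for hotspot-dominated organs).

    ``weighting`` selects what V_i means:

    - ``"differential"``: V_i is the fraction of volume in dose bin i
      (first difference of the cumulative curve).  The textbook gEUD: a
      volume-weighted power mean, equal to D for a uniform dose and to the
      mean dose at n = 1.
    - ``"cumulative"``: V_i is the cumulative ordinate itself (fraction
      receiving at least D_i), summed over all histogram bins.  This is the
      convention the treatment-assessment pipeline reports (see
      docs/methods.md); it grows with the histogram resolution and can
      exceed the maximum dose.
    """
    if n <= 0:
        raise ValueError("volume-effect parameter n must be > 0")
    edges = np.asarray(dvh.bin_edges, dtype=np.float64)
    cum = np.asarray(dvh.volume_fraction, dtype=np.float64)
    if weighting == "differential":
        v = cum - np.concatenate([cum[1:], [0.0]])
    elif weighting == "cumulative":
        v = cum.copy()
    else:
        raise ValueError("weighting must be 'differential' or 'cumulative'")
    keep = (v > 0) & (edges > 0)
    if not keep.any():
        return 0.0
    log_terms = np.log(v[keep]) + np.log(edges[keep]) / n
    return float(np.exp(n * logsumexp(log_terms)))


def ntcp(geud_value: float, lkb: LKBParams) -> float:
    """Lyman complication probability: the standard normal CDF at
    tau = (gEUD - TD50) / (m * TD50).  Exactly 0.5 at gEUD = TD50."""
    if geud_value < 0:
        raise ValueError("geud_value must be >= 0")
    tau = (geud_value - lkb.td50) / (lkb.m * lkb.td50)
    return float(ndtr(tau))


def ntcp_from_dose(dose: np.ndarray, mask: np.ndarray, lkb: LKBParams,
                   bin_width: float = 0.5, weighting: str = "cumulative") -> tuple[float, float, DVH]:
    """Convenience pipeline: cumulative dose map -> OAR DVH -> gEUD -> NTCP.

    Returns (ntcp, geud, dvh).  Defaults to the reported-KPI weighting.
    """
    dvh = cumulative_dvh(dose, mask, bin_width)
    g = geud(dvh, lkb.n, weighting=weighting)
    return ntcp(g, lkb), g, dvh
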