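"""Radiation response: linear-quadratic survival with an oxygen-modifying
factor, the beam dose profile, and stochastic per-cell kill.

Survival after a fraction of dose D follows the oxygen-modified
linear-quadratic model

    SF(D) = exp[ gamma_r * ( -alpha * OMF * D - beta * (OMF * D)^2 ) ],

where OMF in (0, 1] scales the effective dose down under hypoxia, bounded
below by the reciprocal of the maximum oxygen enhancement ratio.  Each cell
is killed independently with probability 1 - SF at its local dose and
oxygenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RadbioConfig
from .sim import CANCER, SimGrid


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic coefficients for one tissue type."""

    alpha: float        # Gy^-1
    beta: float         # Gy^-2
    gamma_r: float = 1.0  # dimensionless radiosensitivity scaling

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma_r <= 0:
            raise ValueError("gamma_r must be > 0")


@dataclass(frozen=True)
class SiteParams:
    """Tumor and normal-tissue LQ parameters for one anatomical site."""

    site: str
    tumor: LQParams
    normal: LQParams

    def with_tumor(self, alpha: float, beta: float) -> "SiteParams":
        """Copy with substituted tumor radiosensitivity (robustness sweeps)."""
        return SiteParams(
            site=self.site,
            tumor=LQParams(alpha, beta, self.tumor.gamma_r),
            normal=self.normal,
        )


#: default per-site LQ parameters; tumors follow an alpha/beta ratio near 10
#: (early-responding tissue), normal tissue near 3 (late-responding).
SITE_DEFAULTS: dict[str, SiteParams] = {
    "rectum": SiteParams("rectum", LQParams(0.315, 0.0662), LQParams(0.0484, 0.0124)),
    "head_and_neck": SiteParams("head_and_neck", LQParams(0.330, 0.029), LQParams(0.0341, 0.0114)),
    "lung": SiteParams("lung", LQParams(0.325, 0.0325), LQParams(0.0637, 0.0168)),
}


def site_params(site: str) -> SiteParams:
    try:
        return SITE_DEFAULTS[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_DEFAULTS)}") from None


@dataclass(frozen=True)
class DoseProfile:
    """A planned beam: flat at the nominal dose over the target disc, Gaussian
    penumbra beyond.  ``shape`` is the unit-dose per-pixel map; multiply by a
    fraction's nominal dose to get that fraction's dose map."""

    center: tuple[float, float]     # (row, col), may be fractional
    nominal_dose: float             # Gy
    flat_radius: float              # px
    sigma: float                    # penumbra scale, px
    shape: np.ndarray = field(repr=False, default=None)

    @property
    def dose_map(self) -> np.ndarray:
        return self.nominal_dose * self.shape


def omf(oxygen_level: float | np.ndarray, config: RadbioConfig) -> float | np.ndarray:
    """Oxygen-modifying factor of the per-cell oxygen availability (mL/cell).

    A saturating rational curve: 1 for well-oxygenated cells, falling to
    1/OER_max under anoxia, with half effect at ``config.omf_halfsat``:

        OMF(p) = (OER_max * p + K) / (p + K) / OER_max.
    """
    p = np.asarray(oxygen_level, dtype=np.float64)
    out = (config.oer_max * p + config.omf_halfsat) / (p + config.omf_halfsat) / config.oer_max
    return float(out) if np.isscalar(oxygen_level) else out


def survival_fraction(dose: float | np.ndarray, lq: LQParams,
                      omf_value: float | np.ndarray = 1.0) -> float | np.ndarray:
    """Oxygen-modified LQ surviving fraction; 1 at zero dose, in (0, 1]."""
    d_eff = np.asarray(omf_value) * np.asarray(dose, dtype=np.float64)
    sf = np.exp(lq.gamma_r * (-lq.alpha * d_eff - lq.beta * d_eff ** 2))
    return float(sf) if sf.ndim == 0 else sf


def build_dose_profile(grid: SimGrid, nominal_dose: float,
                       config: RadbioConfig | None = None) -> DoseProfile:
    """Plan the beam from the current tumor geometry.

    The beam is centered on the cancer-cell centroid and delivers the nominal
    dose over a disc that covers every cancer-occupied pixel plus
    ``beam_margin``, with a Gaussian shoulder of scale ``beam_sigma`` beyond.
    Deterministic given the grid.  The treatment environment plans the field
    once, at treatment start, and keeps it fixed for the course (the flat
    disc then covers the full initial tumor extent).
    """
    if config is None:
        config = RadbioConfig()
    if nominal_dose < 0:
        raise ValueError("nominal_dose must be >= 0")
    g = grid.size
    cancer_pos = grid.pos[grid.kind == CANCER]
    if cancer_pos.size == 0:
        raise ValueError("cannot target a beam: no cancer cells on the grid")
    rows = cancer_pos // g
    cols = cancer_pos % g
    center = (float(rows.mean()), float(cols.mean()))
    r_max = float(np.hypot(rows - center[0], cols - center[1]).max())
    r0 = r_max + config.beam_margin

    rr, cc = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    dist = np.hypot(rr - center[0], cc - center[1])
    shape = np.where(
        dist <= r0, 1.0,
        np.exp(-0.5 * ((dist - r0) / config.beam_sigma) ** 2),
    )
    return DoseProfile(center=center, nominal_dose=float(nominal_dose),
                       flat_radius=r0, sigma=config.beam_sigma, shape=shape)


def irradiate(grid: SimGrid, dose_map: np.ndarray, site: SiteParams,
              rng: np.random.Generator | None = None,
              config: RadbioConfig | None = None,
              dose_accum: np.ndarray | None = None) -> tuple[int, int]:
    """Deliver one fraction: kill each cell stochastically and record dose.

    Every alive cell receives the dose of its pixel; its survival probability
    combines its tissue's LQ parameters with the oxygen-modifying factor of
    its pixel's per-cell oxygen share.  A uniform variate above SF kills the
    cell.  Survivors suffer radiation-induced mitotic delay: their cycle
    clock is set back in proportion to the linear-quadratic log-kill they
    sustained (``arrest_hours_per_damage`` hours per unit of
    alpha*D_eff + beta*D_eff^2; sublethal damage arrests progression
    through the cycle).  If
    ``dose_accum`` is given, ``dose_map`` is added to it (the cumulative
    per-pixel record the dose-volume analysis uses).

    Returns (killed_healthy, killed_cancer).
    """
    if config is None:
        config = RadbioConfig()
    if rng is None:
        rng = grid.rng
    if dose_map.shape != (grid.size, grid.size):
        raise ValueError("dose_map shape does not match the grid")
    if dose_accum is not None:
        dose_accum += dose_map

    n = grid.n_cells
    if n == 0:
        return 0, 0
    pos = grid.pos
    dens = np.bincount(pos, minlength=grid.size * grid.size)
    share_oxy = grid.oxygen.reshape(-1) / np.maximum(dens, 1)
    omf_cell = omf(share_oxy[pos], config)
    d = dose_map.reshape(-1)[pos]

    is_cancer = grid.kind == CANCER
    alpha = np.where(is_cancer, site.tumor.alpha, site.normal.alpha)
    beta = np.where(is_cancer, site.tumor.beta, site.normal.beta)
    gamma_r = np.where(is_cancer, site.tumor.gamma_r, site.normal.gamma_r)
    d_eff = omf_cell * d
    damage = alpha * d_eff + beta * d_eff ** 2
    sf = np.exp(-gamma_r * damage)
    killed = rng.random(n) > sf
    killed_healthy = int(np.count_nonzero(killed & ~is_cancer))
    killed_cancer = int(np.count_nonzero(killed & is_cancer))
    if killed.any():
        grid.remove(killed)
        damage = damage[~killed]
    if config.arrest_hours_per_damage > 0 and grid.n_cells:
        delay = np.rint(config.arrest_hours_per_damage * damage).astype(np.int64)
        grid.phase_clock -= delay
    return killed_healthy, killed_cancer
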