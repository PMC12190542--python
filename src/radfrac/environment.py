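"""The treatment episode environment: tumor growth to the treatment
threshold, daily dose delivery, and outcome bookkeeping.

A :class:`TreatmentEnv` wires the growth model, the beam and the outcome
masks into the decision process the agent (or a fixed baseline schedule)
interacts with: one ``step`` delivers a fraction and advances 24 hours of
tissue dynamics, checking the endpoint hourly.  The target/organ-at-risk
masks and the beam geometry are planned once, at treatment start, and held
fixed for the episode, like a clinical treatment plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import OutcomeConfig, RadbioConfig, SimConfig
from .outcome import LKBParams, RegionMasks, compute_masks, lkb_params, ntcp_from_dose
from .radbio import DoseProfile, SiteParams, build_dose_profile, irradiate, site_params
from .sim import (
    EndpointState, SimGrid, check_endpoint, count_cells, grow_to_threshold,
    init_grid, step_hour,
)


@dataclass
class StepResult:
    """What the agent observes after one decision.

    ``killed_*`` are the observable net count decreases over the decision
    window (clamped at zero): the agent's state is the cell counts, so the
    cells lost between two decisions are what it can attribute to the chosen
    dose.  ``radiation_killed_*`` are the raw radiation-kill tallies of the
    fraction itself.
    """

    healthy: int
    cancer: int
    killed_healthy: int          # net healthy loss over the window
    killed_cancer: int           # net cancer loss over the window
    radiation_killed_healthy: int
    radiation_killed_cancer: int
    done: bool
    endpoint: str


class GrowthPool:
    """A reservoir of independently grown treatment-start grids.

    Growing a tumor to the treatment threshold dominates episode cost, so
    training samples starting states from a pre-grown pool; each draw gets a
    fresh random stream so treatment stochasticity stays independent across
    episodes.  Evaluation runs should grow fresh replicates instead.
    """

    def __init__(self, sim_config: SimConfig, size: int, base_seed: int = 0):
        self.grids: list[SimGrid] = []
        seed = base_seed
        attempts = 0
        while len(self.grids) < size:
            if attempts > 10 * size + 20:
                raise RuntimeError("too many degenerate growth replicates for the pool")
            attempts += 1
            try:
                grid = grow_to_threshold(init_grid(sim_config, seed=seed), sim_config)
            except Exception:
                seed += 1
                continue
            self.grids.append(grid)
            seed += 1

    def sample(self, seed: int) -> SimGrid:
        rng = np.random.default_rng(seed)
        grid = self.grids[int(rng.integers(len(self.grids)))].copy()
        grid.rng = np.random.default_rng(rng.integers(2 ** 31))
        return grid


class TreatmentEnv:
    """Episodic radiotherapy environment over the lattice tumor model."""

    def __init__(self, sim_config: SimConfig | None = None,
                 site: SiteParams | str = "rectum",
                 radbio_config: RadbioConfig | None = None,
                 outcome_config: OutcomeConfig | None = None,
                 lkb: LKBParams | None = None,
                 pool: GrowthPool | None = None,
                 max_growth_retries: int = 5):
        self.sim_config = sim_config or SimConfig()
        self.site = site_params(site) if isinstance(site, str) else site
        self.radbio_config = radbio_config or RadbioConfig()
        self.outcome_config = outcome_config or OutcomeConfig()
        self.lkb = lkb or lkb_params(self.site.site)
        self.pool = pool
        self.max_growth_retries = max_growth_retries
        self.grid: SimGrid | None = None
        self.masks: RegionMasks | None = None
        self.beam: DoseProfile | None = None
        self.dose_accum: np.ndarray | None = None
        self.fraction_doses: list[float] = []
        self.count_trace: list[tuple[int, int]] = []
        self.endpoint: EndpointState = EndpointState.ONGOING

    # ------------------------------------------------------------------
    def reset(self, seed: int) -> tuple[int, int]:
        """Grow (or draw) a treatment-start grid and plan masks and beam.

        Degenerate growth replicates (tumor die-out before the threshold)
        are retried on consecutive derived seeds.
        """
        if self.pool is not None:
            self.grid = self.pool.sample(seed)
        else:
            last_err: Exception | None = None
            for attempt in range(self.max_growth_retries):
                try:
                    self.grid = grow_to_threshold(
                        init_grid(self.sim_config, seed=seed + 1_000_003 * attempt),
                        self.sim_config)
                    break
                except Exception as err:   # degenerate replicate
                    last_err = err
            else:
                raise RuntimeError(
                    f"growth failed {self.max_growth_retries} times") from last_err
        self.masks = compute_masks(self.grid)
        self.beam = build_dose_profile(self.grid, 1.0, self.radbio_config)
        g = self.grid.size
        self.dose_accum = np.zeros((g, g))
        self.fraction_doses = []
        self.count_trace = [count_cells(self.grid)]
        self.endpoint = EndpointState.ONGOING
        return count_cells(self.grid)

    @property
    def clock(self) -> int:
        return self.grid.clock if self.grid is not None else 0

    def step(self, dose: float) -> StepResult:
        """Deliver one fraction, then simulate a 24 h window with hourly
        endpoint checks (the window ends early at an endpoint)."""
        if self.grid is None:
            raise RuntimeError("call reset() before step()")
        if self.endpoint is not EndpointState.ONGOING:
            raise RuntimeError("episode already ended")
        # the plan is frozen at treatment start (like the masks): the flat
        # field covers the full initial tumor extent, so every cancer cell
        # stays inside the field for the whole course
        h_before, c_before = count_cells(self.grid)
        kh, kc = irradiate(self.grid, dose * self.beam.shape, self.site,
                           rng=self.grid.rng, config=self.radbio_config,
                           dose_accum=self.dose_accum)
        self.fraction_doses.append(float(dose))
        ep = check_endpoint(self.grid, self.sim_config)
        hours = 0
        while ep is EndpointState.ONGOING and hours < 24:
            step_hour(self.grid, self.sim_config)
            hours += 1
            ep = check_endpoint(self.grid, self.sim_config)
        self.endpoint = ep if ep is not EndpointState.ONGOING else EndpointState.ONGOING
        healthy, cancer = count_cells(self.grid)
        self.count_trace.append((healthy, cancer))
        return StepResult(
            healthy=healthy, cancer=cancer,
            killed_healthy=max(0, h_before - healthy),
            killed_cancer=max(0, c_before - cancer),
            radiation_killed_healthy=kh, radiation_killed_cancer=kc,
            done=ep is not EndpointState.ONGOING,
            endpoint=ep.value,
        )

    def remaining_time(self) -> int:
        return self.sim_config.max_hours - self.clock

    def outcome(self) -> tuple[float, float]:
        """(NTCP, gEUD) of the organ at risk from the accumulated dose."""
        ntcp_value, geud_value, _ = ntcp_from_dose(
            self.dose_accum, self.masks.oar, self.lkb,
            bin_width=self.outcome_config.dvh_bin_width,
            weighting=self.outcome_config.geud_weighting)
        return ntcp_value, geud_value


def make_env_factory(sim_config: SimConfig | None = None,
                     site: SiteParams | str = "rectum",
                     radbio_config: RadbioConfig | None = None,
                     outcome_config: OutcomeConfig | None = None,
                     lkb: LKBParams | None = None,
                     pool_size: int = 0, pool_seed: int = 0):
    """Build an ``env_factory(seed)`` for training or evaluation.

    With ``pool_size > 0`` a shared :class:`GrowthPool` is grown once and
    every environment draws starting states from it.
    """
    sim_config = sim_config or SimConfig()
    pool = GrowthPool(sim_config, pool_size, pool_seed) if pool_size else None

    def factory(seed: int) -> TreatmentEnv:
        return TreatmentEnv(sim_config=sim_config, site=site,
                            radbio_config=radbio_config,
                            outcome_config=outcome_config, lkb=lkb, pool=pool)

    return factory
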