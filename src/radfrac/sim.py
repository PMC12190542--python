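"""Lattice cellular-automaton model of avascular tumor growth.

The tissue is a square lattice.  Each pixel carries a glucose store (mg), an
oxygen store (mL) and any number of biological cells; healthy and cancer
cells may share a pixel.  Scattered nutrient-source pixels are replenished
every hour and a nearest-neighbour mixing step diffuses both fields.  Cells
progress through the mitotic cycle G1 (11 h) -> S (8 h) -> G2 (4 h) ->
M (1 h), dividing after mitosis; cells whose per-cell share of the local
nutrient store falls below a quiescence threshold arrest reversibly, and
cells below a critical threshold starve.

All per-cell state is held in flat numpy arrays (structure-of-arrays) so an
hourly step is a fixed sequence of vectorized operations; a grid holds its
own random generator so trajectories are exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import SimConfig

# cell-cycle phases and their durations in hours
G1, S, G2, M = 0, 1, 2, 3
PHASE_HOURS = np.array([11, 8, 4, 1], dtype=np.int64)
PHASE_NAMES = ("G1", "S", "G2", "M")
CYCLE_HOURS = int(PHASE_HOURS.sum())  # 24

HEALTHY, CANCER = 0, 1


class EndpointState(str, Enum):
    ONGOING = "ongoing"
    SUCCESS = "success"    # no cancer cell remains
    FAILURE = "failure"    # healthy population collapsed
    TIMEOUT = "timeout"    # treatment time limit exceeded


class DegenerateReplicateError(RuntimeError):
    """Raised when the growth phase cannot reach the treatment threshold."""


@dataclass
class StepStats:
    """Per-hour bookkeeping of population changes (division and starvation)."""

    births: int = 0
    starved_healthy: int = 0
    starved_cancer: int = 0


@dataclass
class Cell:
    """Scalar view of one cell, used at API edges and in tests.

    ``phase`` is one of G1/S/G2/M or ``"quiescent"`` for an arrested cell.
    """

    kind: str                   # "healthy" | "cancer"
    phase: str
    phase_clock: int
    glucose_efficiency: float   # mg/cell/h
    oxygen_efficiency: float    # mL/cell/h
    alive: bool = True


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws, redrawn until strictly positive (rates are physical)."""
    x = rng.normal(mean, sd, n)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x <= 0
    return x


class SimGrid:
    """The full simulation state: fields, cells, sources and the clock."""

    __slots__ = (
        "size", "pos", "kind", "phase", "phase_clock", "quiescent",
        "glu_eff", "oxy_eff", "glucose", "oxygen", "sources",
        "clock", "growth_hours", "rng", "last_stats", "_nbr",
    )

    def __init__(self, size: int, sources: np.ndarray, glucose: np.ndarray,
                 oxygen: np.ndarray, rng: np.random.Generator):
        self.size = int(size)
        n0 = 0
        self.pos = np.empty(n0, dtype=np.int64)        # flat pixel index
        self.kind = np.empty(n0, dtype=np.int8)        # HEALTHY / CANCER
        self.phase = np.empty(n0, dtype=np.int8)       # G1/S/G2/M
        self.phase_clock = np.empty(n0, dtype=np.int64)
        self.quiescent = np.empty(n0, dtype=bool)
        self.glu_eff = np.empty(n0, dtype=np.float64)
        self.oxy_eff = np.empty(n0, dtype=np.float64)
        self.glucose = glucose                          # (size, size) mg
        self.oxygen = oxygen                            # (size, size) mL
        self.sources = sources                          # flat indices
        self.clock = 0
        self.growth_hours = 0
        self.rng = rng
        self.last_stats = StepStats()
        self._nbr = _neighbor_table(self.size)

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.pos.size

    @property
    def density(self) -> np.ndarray:
        """Per-pixel count of alive cells (recomputed, hence always exact)."""
        d = np.bincount(self.pos, minlength=self.size * self.size)
        return d.reshape(self.size, self.size)

    @property
    def healthy_count(self) -> int:
        return int(np.count_nonzero(self.kind == HEALTHY))

    @property
    def cancer_count(self) -> int:
        return int(np.count_nonzero(self.kind == CANCER))

    def cancer_mask(self) -> np.ndarray:
        """Boolean (size, size) mask of pixels holding at least one cancer cell."""
        occ = np.zeros(self.size * self.size, dtype=bool)
        occ[self.pos[self.kind == CANCER]] = True
        return occ.reshape(self.size, self.size)

    def cell(self, i: int) -> Cell:
        return Cell(
            kind="cancer" if self.kind[i] == CANCER else "healthy",
            phase="quiescent" if self.quiescent[i] else PHASE_NAMES[self.phase[i]],
            phase_clock=int(self.phase_clock[i]),
            glucose_efficiency=float(self.glu_eff[i]),
            oxygen_efficiency=float(self.oxy_eff[i]),
        )

    def add_cell(self, row: int, col: int, kind: str = "healthy",
                 phase: str = "G1", phase_clock: int = 0,
                 glucose_efficiency: float | None = None,
                 oxygen_efficiency: float | None = None) -> None:
        """Append one cell (test/setup helper)."""
        quiescent = phase == "quiescent"
        p = 0 if quiescent else PHASE_NAMES.index(phase)
        self.pos = np.append(self.pos, row * self.size + col)
        self.kind = np.append(self.kind, CANCER if kind == "cancer" else HEALTHY)
        self.phase = np.append(self.phase, np.int8(p))
        self.phase_clock = np.append(self.phase_clock, phase_clock)
        self.quiescent = np.append(self.quiescent, quiescent)
        self.glu_eff = np.append(self.glu_eff, glucose_efficiency or 3.6e-8)
        self.oxy_eff = np.append(self.oxy_eff, oxygen_efficiency or 2.16e-8)

    def remove(self, dead: np.ndarray) -> None:
        """Drop the cells flagged True in ``dead``."""
        keep = ~dead
        self.pos = self.pos[keep]
        self.kind = self.kind[keep]
        self.phase = self.phase[keep]
        self.phase_clock = self.phase_clock[keep]
        self.quiescent = self.quiescent[keep]
        self.glu_eff = self.glu_eff[keep]
        self.oxy_eff = self.oxy_eff[keep]

    def copy(self) -> "SimGrid":
        new = SimGrid.__new__(SimGrid)
        new.size = self.size
        for name in ("pos", "kind", "phase", "phase_clock", "quiescent",
                     "glu_eff", "oxy_eff"):
            setattr(new, name, getattr(self, name).copy())
        new.glucose = self.glucose.copy()
        new.oxygen = self.oxygen.copy()
        new.sources = self.sources.copy()
        new.clock = self.clock
        new.growth_hours = self.growth_hours
        new.rng = np.random.default_rng()
        new.rng.bit_generator.state = self.rng.bit_generator.state
        new.last_stats = StepStats()
        new._nbr = self._nbr
        return new


_NBR_CACHE: dict[int, np.ndarray] = {}


def _neighbor_table(size: int) -> np.ndarray:
    """(size^2, 4) von-Neumann neighbour flat indices, -1 off-grid."""
    if size in _NBR_CACHE:
        return _NBR_CACHE[size]
    idx = np.arange(size * size)
    r, c = idx // size, idx % size
    nbr = np.full((size * size, 4), -1, dtype=np.int64)
    nbr[r > 0, 0] = idx[r > 0] - size
    nbr[r < size - 1, 1] = idx[r < size - 1] + size
    nbr[c > 0, 2] = idx[c > 0] - 1
    nbr[c < size - 1, 3] = idx[c < size - 1] + 1
    _NBR_CACHE[size] = nbr
    return nbr


def init_grid(config: SimConfig, seed: int | None = None) -> SimGrid:
    """Build the initial tissue: healthy cells scattered uniformly at random,
    the seeding cancer cell(s) at the central pixel, uniform nutrient fields
    and randomly placed sources.

    Healthy cells start at a uniformly random position within the 24 h cycle
    (an established tissue is asynchronous); the cancer founder starts at the
    beginning of G1.  Identical seeds give bit-identical grids.
    """
    if seed is None:
        seed = config.rng_seed
    g = config.grid_size
    capacity = g * g * (config.density_cap or g * g)
    if config.n_healthy_init + config.n_cancer_init > capacity:
        raise ValueError(
            f"initial population {config.n_healthy_init + config.n_cancer_init} "
            f"exceeds grid capacity {capacity}"
        )
    rng = np.random.default_rng(seed)
    sources = rng.choice(g * g, size=config.n_sources, replace=False).astype(np.int64)
    glucose = np.full((g, g), config.glucose_init, dtype=np.float64)
    oxygen = np.full((g, g), config.oxygen_init, dtype=np.float64)
    grid = SimGrid(g, sources, glucose, oxygen, rng)

    nh, nc = config.n_healthy_init, config.n_cancer_init
    n = nh + nc
    center = (g // 2) * g + (g // 2)
    grid.pos = np.concatenate([
        rng.integers(0, g * g, size=nh), np.full(nc, center),
    ]).astype(np.int64)
    grid.kind = np.concatenate([
        np.full(nh, HEALTHY, dtype=np.int8), np.full(nc, CANCER, dtype=np.int8),
    ])
    # asynchronous healthy tissue: uniform position along the 24 h cycle
    offsets = rng.integers(0, CYCLE_HOURS, size=nh)
    cum = np.cumsum(PHASE_HOURS)
    phase_h = np.searchsorted(cum, offsets, side="right").astype(np.int8)
    clock_h = offsets - np.concatenate(([0], cum[:-1]))[phase_h]
    grid.phase = np.concatenate([phase_h, np.zeros(nc, dtype=np.int8)])
    grid.phase_clock = np.concatenate([clock_h, np.zeros(nc, dtype=np.int64)])
    grid.quiescent = np.zeros(n, dtype=bool)
    grid.glu_eff = np.concatenate([
        _positive_normal(rng, config.glucose_absorb_healthy_mean,
                         config.glucose_absorb_healthy_sd, nh),
        _positive_normal(rng, config.glucose_absorb_cancer_mean,
                         config.glucose_absorb_cancer_sd, nc),
    ])
    grid.oxy_eff = _positive_normal(
        rng, config.oxygen_consume_mean, config.oxygen_consume_sd, n)
    return grid


def _diffuse(field: np.ndarray, fraction: float) -> None:
    """One explicit step of 4-neighbour averaging with zero-flux edges."""
    if fraction == 0.0:
        return
    p = np.pad(field, 1, mode="edge")
    nb = 0.25 * (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:])
    field += fraction * (nb - field)


def step_hour(grid: SimGrid, config: SimConfig) -> SimGrid:
    """Advance the tissue by one hour, in a fixed sub-step order:
    replenish -> diffuse -> consume -> starvation/quiescence -> cycle/divide.

    The grid is modified in place and returned; ``grid.last_stats`` holds the
    hour's division and starvation tallies.
    """
    g2 = grid.size * grid.size
    rng = grid.rng
    stats = StepStats()

    # 1) replenish at sources, 2) diffuse
    flat_glu = grid.glucose.reshape(-1)
    flat_oxy = grid.oxygen.reshape(-1)
    np.add.at(flat_glu, grid.sources, config.source_glucose_rate)
    np.add.at(flat_oxy, grid.sources, config.source_oxygen_rate)
    _diffuse(grid.glucose, config.diffusion_fraction)
    _diffuse(grid.oxygen, config.diffusion_fraction)

    n = grid.n_cells
    if n:
        pos = grid.pos
        dens = np.bincount(pos, minlength=g2)

        # per-cell share of the pre-consumption pixel store
        safe = np.maximum(dens, 1)
        share_glu_px = flat_glu[:g2] / safe
        share_oxy_px = flat_oxy[:g2] / safe
        # sustainable headcount per pixel at the critical thresholds
        allowed = np.minimum(
            np.floor(flat_glu[:g2] / config.critical_glucose),
            np.floor(flat_oxy[:g2] / config.critical_oxygen),
        ).astype(np.int64)

        # 3) consumption: each cell demands its own efficiency (reduced when
        # quiescent); an under-stocked pixel is split pro rata by demand,
        # which subtracting min(store, demand) implements exactly.
        w = np.where(grid.quiescent, config.quiescent_consumption_factor, 1.0)
        dem_g = np.bincount(pos, weights=grid.glu_eff * w, minlength=g2)
        dem_o = np.bincount(pos, weights=grid.oxy_eff * w, minlength=g2)
        flat_glu[:g2] -= np.minimum(flat_glu[:g2], dem_g)
        flat_oxy[:g2] -= np.minimum(flat_oxy[:g2], dem_o)

        # 4) starvation: pixels holding more cells than the store can sustain
        # lose the excess; competition favors avid consumers, so the cells
        # with the lowest glucose uptake starve first (cancer cells, drawing
        # more, displace healthy cells at contested pixels)
        if np.any(dens > allowed):
            order = np.lexsort((-grid.glu_eff, pos))
            ps = pos[order]
            newgrp = np.empty(n, dtype=bool)
            newgrp[0] = True
            np.not_equal(ps[1:], ps[:-1], out=newgrp[1:])
            starts = np.flatnonzero(newgrp)
            grp = np.cumsum(newgrp) - 1
            rank = np.arange(n) - starts[grp]
            die_sorted = rank >= allowed[ps]
            die = np.empty(n, dtype=bool)
            die[order] = die_sorted
            if die.any():
                stats.starved_healthy = int(np.count_nonzero(die & (grid.kind == HEALTHY)))
                stats.starved_cancer = int(np.count_nonzero(die & (grid.kind == CANCER)))
                grid.remove(die)
                pos = grid.pos
                n = grid.n_cells

    if n:
        # quiescence: arrest below the quiescence thresholds, wake above them
        sg = share_glu_px[pos]
        so = share_oxy_px[pos]
        grid.quiescent = (
            (sg < config.effective_quiescent_glucose)
            | (so < config.effective_quiescent_oxygen)
        )

        # 5) cycle progression and mitosis
        active = ~grid.quiescent
        grid.phase_clock[active] += 1
        done = active & (grid.phase_clock >= PHASE_HOURS[grid.phase])
        dividing = done & (grid.phase == M)
        advancing = done & ~dividing
        grid.phase[advancing] += 1
        grid.phase_clock[advancing] = 0
        grid.phase[dividing] = G1
        grid.phase_clock[dividing] = 0

        k = int(np.count_nonzero(dividing))
        if k:
            pp = grid.pos[dividing]
            # contact inhibition: normal tissue stops dividing at low local
            # density, cancer keeps going up to its own (higher) cap
            big = np.iinfo(np.int64).max
            cancer_cap = config.density_cap if config.density_cap is not None else big
            healthy_cap = (config.healthy_density_cap
                           if config.healthy_density_cap is not None else big)
            cap = np.where(grid.kind[dividing] == CANCER, cancer_cap, healthy_cap)
            dens2 = np.bincount(grid.pos, minlength=g2)
            if cancer_cap == big and healthy_cap == big:
                dpos = pp
                ok = np.ones(k, dtype=bool)
            else:
                same_ok = dens2[pp] < cap
                nb = grid._nbr[pp]                       # (k, 4)
                nd = np.where(nb >= 0, dens2[np.maximum(nb, 0)], big)
                # random tie-break: jitter < 1 cannot reorder distinct counts
                j = np.argmin(nd + rng.random((k, 4)), axis=1)
                rows = np.arange(k)
                spill_ok = nd[rows, j] < cap
                dpos = np.where(same_ok, pp, nb[rows, j])
                ok = same_ok | spill_ok
                # synchronized cohorts can target one pixel en masse in the
                # same hour; cap concurrent placements to the free slots
                dkind_all = grid.kind[dividing]
                for ckind, kcap in ((HEALTHY, healthy_cap), (CANCER, cancer_cap)):
                    if kcap == big:
                        continue
                    sel = ok & (dkind_all == ckind)
                    idx = np.flatnonzero(sel)
                    if idx.size < 2:
                        continue
                    tgt = dpos[idx]
                    order = np.argsort(tgt, kind="stable")
                    ts = tgt[order]
                    first = np.empty(ts.size, dtype=bool)
                    first[0] = True
                    np.not_equal(ts[1:], ts[:-1], out=first[1:])
                    starts = np.flatnonzero(first)
                    rank = np.arange(ts.size) - starts[np.cumsum(first) - 1]
                    slots = kcap - dens2[ts]
                    ok[idx[order[rank >= slots]]] = False
            dpos = dpos[ok]
            dkind = grid.kind[dividing][ok]
            m = dpos.size
            if m:
                stats.births = m
                nh = int(np.count_nonzero(dkind == HEALTHY))
                glu_eff = np.empty(m)
                if nh:
                    glu_eff[dkind == HEALTHY] = _positive_normal(
                        rng, config.glucose_absorb_healthy_mean,
                        config.glucose_absorb_healthy_sd, nh)
                if m - nh:
                    glu_eff[dkind == CANCER] = _positive_normal(
                        rng, config.glucose_absorb_cancer_mean,
                        config.glucose_absorb_cancer_sd, m - nh)
                grid.pos = np.concatenate([grid.pos, dpos])
                grid.kind = np.concatenate([grid.kind, dkind])
                grid.phase = np.concatenate([grid.phase, np.zeros(m, dtype=np.int8)])
                grid.phase_clock = np.concatenate([grid.phase_clock, np.zeros(m, dtype=np.int64)])
                grid.quiescent = np.concatenate([grid.quiescent, np.zeros(m, dtype=bool)])
                grid.glu_eff = np.concatenate([grid.glu_eff, glu_eff])
                grid.oxy_eff = np.concatenate([
                    grid.oxy_eff,
                    _positive_normal(rng, config.oxygen_consume_mean,
                                     config.oxygen_consume_sd, m),
                ])

    grid.clock += 1
    grid.last_stats = stats
    return grid


def save_snapshot(grid: SimGrid, prefix: str) -> list[str]:
    """Export the grid's layers as plain-text arrays for inspection.

    Writes ``<prefix>_density.txt``, ``<prefix>_glucose.txt`` and
    ``<prefix>_oxygen.txt`` (whitespace-separated, loadable with
    ``numpy.loadtxt``) and returns the paths.
    """
    paths = []
    for name, layer in (("density", grid.density.astype(float)),
                        ("glucose", grid.glucose), ("oxygen", grid.oxygen)):
        path = f"{prefix}_{name}.txt"
        np.savetxt(path, layer, fmt="%.6e",
                   header=f"{name} layer at clock={grid.clock} h")
        paths.append(path)
    return paths


def count_cells(grid: SimGrid) -> tuple[int, int]:
    """Exact (healthy, cancer) tallies of alive cells."""
    return grid.healthy_count, grid.cancer_count


def check_endpoint(grid: SimGrid, config: SimConfig) -> EndpointState:
    """Classify the treatment state.

    Eradication takes precedence (a tumor-free grid is a success however few
    healthy cells remain); the clock is treatment time in hours.
    """
    healthy, cancer = count_cells(grid)
    if cancer == 0:
        return EndpointState.SUCCESS
    if healthy < config.min_healthy:
        return EndpointState.FAILURE
    if grid.clock > config.max_hours:
        return EndpointState.TIMEOUT
    return EndpointState.ONGOING


def grow_to_threshold(grid: SimGrid, config: SimConfig) -> SimGrid:
    """Run the untreated growth phase until the cancer population first
    reaches the treatment threshold.

    On return the treatment clock is reset to zero and the growth duration is
    kept in ``grid.growth_hours``.  Raises :class:`DegenerateReplicateError`
    if the tumor dies out, the healthy population collapses, or the safety
    time cap is hit first.
    """
    while grid.cancer_count < config.cancer_threshold:
        if grid.clock > 0 and grid.cancer_count == 0:
            raise DegenerateReplicateError("tumor died out before the treatment threshold")
        if grid.healthy_count < config.min_healthy:
            raise DegenerateReplicateError("healthy population collapsed during growth")
        if grid.clock >= config.max_growth_hours:
            raise DegenerateReplicateError(
                f"cancer population did not reach {config.cancer_threshold} "
                f"within {config.max_growth_hours} h"
            )
        step_hour(grid, config)
    grid.growth_hours = grid.clock
    grid.clock = 0
    return grid
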