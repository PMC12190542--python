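"""Configuration objects for the tumor-growth environment and the SARSA agent.

Every tunable of the model lives in one of the frozen-default dataclasses
below.  The cell-biology constants (initial populations, nutrient levels,
per-cell consumption distributions, survival thresholds) describe a 50x50
avascular tumor microenvironment; the transport constants (source
replenishment, diffusion fraction, crowding cap) are the model's own
calibration knobs and are documented in docs/methods.md.

Configs round-trip through YAML via :func:`load_config` / :func:`save_config`,
with unknown keys rejected and errors reported by field path.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

logger = logging.getLogger(__name__)

_warned_threshold_order = False


@dataclass
class SimConfig:
    """Parameters of the lattice tumor-growth model.

    Units: glucose in mg, oxygen in mL, rates per cell per hour,
    thresholds per cell (share of the pixel store).
    """

    grid_size: int = 50
    n_healthy_init: int = 1000
    n_cancer_init: int = 1
    n_sources: int = 100
    glucose_init: float = 1e-6          # mg per pixel at t=0
    oxygen_init: float = 1e-6           # mL per pixel at t=0

    # per-cell metabolic efficiency distributions (normal, redrawn positive)
    glucose_absorb_healthy_mean: float = 3.6e-8   # mg/cell/h
    glucose_absorb_healthy_sd: float = 1.2e-8
    glucose_absorb_cancer_mean: float = 5.4e-8
    glucose_absorb_cancer_sd: float = 1.8e-8
    oxygen_consume_mean: float = 2.16e-8          # mL/cell/h, both cell kinds
    oxygen_consume_sd: float = 0.72e-8

    # survival / quiescence thresholds on the per-cell share of the pixel store
    critical_oxygen: float = 3.88e-8    # mL/cell: below -> death
    critical_glucose: float = 6.48e-8   # mg/cell: below -> death
    quiescent_oxygen: float = 10.37e-8  # mL/cell: below -> cycle arrest
    quiescent_glucose: float = 1.728e-8  # mg/cell (inverted vs critical; see methods)

    # episode bookkeeping
    cancer_threshold: int = 9000        # cancer count that triggers treatment
    max_hours: int = 1200               # treatment time limit (50 days)
    min_healthy: int = 10               # below this the treatment has failed
    max_growth_hours: int = 4000        # safety cap for the growth phase

    # nutrient transport and crowding (calibrated, see docs/methods.md)
    source_glucose_rate: float = 6.0e-6   # mg/source/h replenished
    source_oxygen_rate: float = 3.6e-6    # mL/source/h replenished
    diffusion_fraction: float = 0.6       # per-hour 4-neighbour mixing fraction
    density_cap: int | None = 40          # max cells per pixel for cancer division
    healthy_density_cap: int | None = 2   # contact inhibition of normal tissue
    quiescent_consumption_factor: float = 0.9   # quiescent cells' reduced uptake

    rng_seed: int = 0

    def __post_init__(self) -> None:
        global _warned_threshold_order
        if self.grid_size < 3:
            raise ValueError("grid_size must be >= 3")
        for name in (
            "n_healthy_init", "n_cancer_init", "n_sources", "glucose_init",
            "oxygen_init", "critical_oxygen", "critical_glucose",
            "quiescent_oxygen", "quiescent_glucose", "cancer_threshold",
            "max_hours", "min_healthy", "source_glucose_rate",
            "source_oxygen_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for mean_name, sd_name in (
            ("glucose_absorb_healthy_mean", "glucose_absorb_healthy_sd"),
            ("glucose_absorb_cancer_mean", "glucose_absorb_cancer_sd"),
            ("oxygen_consume_mean", "oxygen_consume_sd"),
        ):
            mean, sd = getattr(self, mean_name), getattr(self, sd_name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{mean_name} must be > 0 and {sd_name} >= 0")
            if sd >= mean:
                raise ValueError(
                    f"{sd_name} ({sd}) must be smaller than {mean_name} ({mean})"
                )
        if not 0.0 <= self.diffusion_fraction <= 1.0:
            raise ValueError("diffusion_fraction must lie in [0, 1]")
        if self.n_sources > self.grid_size ** 2:
            raise ValueError("more nutrient sources than pixels")
        if self.density_cap is not None and self.density_cap < 1:
            raise ValueError("density_cap must be >= 1 (or None to disable)")
        if self.healthy_density_cap is not None and self.healthy_density_cap < 1:
            raise ValueError("healthy_density_cap must be >= 1 (or None to disable)")
        if not 0.0 <= self.quiescent_consumption_factor <= 1.0:
            raise ValueError("quiescent_consumption_factor must lie in [0, 1]")
        if (
            self.quiescent_glucose < self.critical_glucose
            or self.quiescent_oxygen < self.critical_oxygen
        ) and not _warned_threshold_order:
            logger.warning(
                "quiescence threshold below critical threshold for at least one "
                "nutrient; the effective quiescence level is "
                "max(quiescent, critical) so the quiescent band stays reachable"
            )
            _warned_threshold_order = True

    # effective thresholds used by the stepper (quiescent band never below death)
    @property
    def effective_quiescent_glucose(self) -> float:
        return max(self.quiescent_glucose, self.critical_glucose)

    @property
    def effective_quiescent_oxygen(self) -> float:
        return max(self.quiescent_oxygen, self.critical_oxygen)


@dataclass
class RadbioConfig:
    """Dose-delivery geometry and oxygen-effect parameters.

    The beam is a flat field at the nominal dose covering the tumor plus a
    margin, with a Gaussian penumbra beyond; the oxygen-modifying factor is a
    saturating Michaelis-Menten-type curve bounded by the maximum oxygen
    enhancement ratio.
    """

    oer_max: float = 3.0            # maximum oxygen enhancement ratio
    omf_halfsat: float = 5.5e-7     # oxygen share (mL/cell) of half-maximal effect
    beam_margin: float = 0.25       # flat-field margin beyond tumor extent (px)
    beam_sigma: float = 4.2         # penumbra falloff scale (px)
    # radiation-induced cycle arrest, hours per unit of LQ log-kill
    # (alpha*D_eff + beta*D_eff^2) suffered by the surviving cell
    arrest_hours_per_damage: float = 13.0

    def __post_init__(self) -> None:
        if self.oer_max < 1.0:
            raise ValueError("oer_max must be >= 1")
        if self.omf_halfsat <= 0:
            raise ValueError("omf_halfsat must be > 0")
        if self.beam_sigma <= 0:
            raise ValueError("beam_sigma must be > 0")
        if self.beam_margin < 0:
            raise ValueError("beam_margin must be >= 0")
        if self.arrest_hours_per_damage < 0:
            raise ValueError("arrest_hours_per_damage must be >= 0")


@dataclass
class OutcomeConfig:
    """DVH resolution and the volume-weighting convention used for gEUD."""

    dvh_bin_width: float = 0.27     # Gy
    geud_weighting: str = "cumulative"  # "cumulative" (reported KPIs) or "differential"

    def __post_init__(self) -> None:
        if self.dvh_bin_width <= 0:
            raise ValueError("dvh_bin_width must be > 0")
        if self.geud_weighting not in ("cumulative", "differential"):
            raise ValueError("geud_weighting must be 'cumulative' or 'differential'")


def _default_cancer_edges() -> tuple:
    return (1, 11, 101, 501) + tuple(range(1001, 20002, 1000))


@dataclass
class StateBinning:
    """Discretization of (healthy count, cancer count) into a tabular state.

    Healthy counts are binned in fixed-width steps; cancer counts on a
    near-logarithmic grid with a dedicated bin for zero (tumor eradicated),
    fine resolution at small counts and 1000-wide steps above 1000.
    """

    healthy_bin_width: int = 500
    n_healthy_bins: int = 25
    cancer_edges: tuple = field(default_factory=_default_cancer_edges)

    def __post_init__(self) -> None:
        if self.healthy_bin_width < 1 or self.n_healthy_bins < 2:
            raise ValueError("invalid healthy-count binning")
        edges = tuple(self.cancer_edges)
        if list(edges) != sorted(set(edges)) or edges[0] < 1:
            raise ValueError("cancer_edges must be strictly increasing and >= 1")
        self.cancer_edges = edges

    @property
    def n_cancer_bins(self) -> int:
        return len(self.cancer_edges) + 1


@dataclass
class SarsaConfig:
    """Hyperparameters of the tabular on-policy temporal-difference agent."""

    eta: float = 0.1                # learning rate
    gamma: float = 0.99             # discount factor
    epsilon_start: float = 1.0
    epsilon_final: float = 0.05
    epsilon_decay_fraction: float = 0.7  # fraction of episodes spent decaying
    n_episodes: int = 3000
    actions: tuple = (1.0, 2.0, 3.0, 4.0)   # daily dose choices (Gy)
    decision_interval: int = 24     # hours between decisions
    binning: StateBinning = field(default_factory=StateBinning)
    pool_size: int = 16             # pre-grown starting grids reused in training
    # optional training-episode horizon in fractions; evaluation rollouts are
    # never capped (the 1200 h clinical limit applies there)
    max_fractions_train: int | None = None
    # terminal outcome reward: +success_reward on eradication, -failure_penalty
    # on healthy-tissue collapse, 0 on timeout.  Unit scale puts the episode
    # return on the [0, 1] scale; without it the per-step kill reward makes
    # indefinitely "farming" a regrowing tumor the optimal policy (see
    # docs/methods.md).
    success_reward: float = 1.0
    failure_penalty: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must lie in (0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        for name in ("epsilon_start", "epsilon_final"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.epsilon_decay_fraction <= 1.0:
            raise ValueError("epsilon_decay_fraction must lie in (0, 1]")
        if self.n_episodes < 0:
            raise ValueError("n_episodes must be >= 0")
        if len(self.actions) == 0 or any(a <= 0 for a in self.actions):
            raise ValueError("actions must be positive doses")
        self.actions = tuple(float(a) for a in self.actions)
        if self.decision_interval < 1:
            raise ValueError("decision_interval must be >= 1")
        if isinstance(self.binning, dict):
            self.binning = StateBinning(**self.binning)


@dataclass
class ExperimentConfig:
    """Top-level run descriptor consumed by the command-line interface."""

    site: str = "rectum"
    kind: str = "baseline"          # train | baseline | evaluate | sweep | retrain | nutrient
    replicates: int = 100
    seed: int = 0
    output_dir: str = "results"
    baseline_fraction_dose: float | None = None  # None -> per-site default
    sim: SimConfig = field(default_factory=SimConfig)
    radbio: RadbioConfig = field(default_factory=RadbioConfig)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    sarsa: SarsaConfig = field(default_factory=SarsaConfig)
    alpha_tumor: float | None = None    # optional LQ overrides
    beta_tumor: float | None = None
    sweep_pairs: list = field(default_factory=list)      # [(alpha, beta), ...]
    nutrient_multipliers: list = field(default_factory=lambda: [0.8, 1.0, 1.2])

    _KINDS = ("train", "baseline", "evaluate", "sweep", "retrain", "nutrient")

    def __post_init__(self) -> None:
        from .radbio import SITE_DEFAULTS  # deferred: avoid import cycle

        if self.site not in SITE_DEFAULTS:
            raise ValueError(
                f"unknown site {self.site!r}; expected one of {sorted(SITE_DEFAULTS)}"
            )
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("alpha_tumor", "beta_tumor"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        for sub, cls in (
            ("sim", SimConfig), ("radbio", RadbioConfig),
            ("outcome", OutcomeConfig), ("sarsa", SarsaConfig),
        ):
            if isinstance(getattr(self, sub), dict):
                setattr(self, sub, _from_mapping(cls, getattr(self, sub), sub))
        self.sweep_pairs = [tuple(float(x) for x in p) for p in self.sweep_pairs]


# ---------------------------------------------------------------------------
# YAML round-trip helpers


def _from_mapping(cls: type, data: dict, path: str = "") -> Any:
    """Build a dataclass from a nested mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"{path or cls.__name__}: unknown key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        sub_cls = _DATACLASS_FIELDS.get((cls, key))
        if sub_cls is not None and isinstance(value, dict):
            kwargs[key] = _from_mapping(sub_cls, value, f"{path}.{key}" if path else key)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path or cls.__name__}: {exc}") from exc


_DATACLASS_FIELDS = {
    (SarsaConfig, "binning"): StateBinning,
    (ExperimentConfig, "sim"): SimConfig,
    (ExperimentConfig, "radbio"): RadbioConfig,
    (ExperimentConfig, "outcome"): OutcomeConfig,
    (ExperimentConfig, "sarsa"): SarsaConfig,
}


def to_mapping(cfg: Any) -> dict:
    """Serialize any config dataclass to plain mappings/lists/scalars."""
    out = dataclasses.asdict(cfg)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    return _clean(out)


def load_config(path: str, cls: type = ExperimentConfig) -> Any:
    """Load and validate a config from a YAML file.

    An empty file yields the all-defaults config. Unknown keys and invalid
    values are rejected with the offending field path in the message.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return _from_mapping(cls, data)


def save_config(cfg: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_mapping(cfg), fh, sort_keys=False)
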