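"""Treatment arms, KPI aggregation and robustness studies.

The baseline arm delivers one conventional fraction per day until an
endpoint; the learned arm rolls out a greedy policy from a trained Q-table.
Both are scored with the same key performance indicators over replicate
simulations: success rate, organ-at-risk complication probability (with its
mean +/- 3 sigma band), total dose, fraction count and duration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import QTable, greedy_policy, train_agent
from .config import OutcomeConfig, RadbioConfig, SarsaConfig, SimConfig
from .environment import TreatmentEnv, make_env_factory
from .outcome import LKBParams, lkb_params
from .radbio import SiteParams, site_params
from .sim import EndpointState

#: conventional daily fraction sizes per site (Gy); the rectum schedule uses
#: a slightly smaller conventional fraction than the 2 Gy head-and-neck and
#: lung schedules.
BASELINE_FRACTION_DOSE: dict[str, float] = {
    "rectum": 1.8,
    "head_and_neck": 2.0,
    "lung": 2.0,
}


@dataclass
class TreatmentRecord:
    """One replicate's full treatment trace and outcome."""

    seed: int
    site: str
    doses: list[float]
    endpoint: str
    ntcp: float                 # probability in [0, 1]
    geud: float                 # Gy
    healthy_start: int
    cancer_start: int
    growth_hours: int
    count_trace: list = field(default_factory=list, repr=False)

    @property
    def n_fractions(self) -> int:
        return len(self.doses)

    @property
    def total_dose(self) -> float:
        return float(np.sum(self.doses)) if self.doses else 0.0

    @property
    def duration(self) -> float:
        """Daily schedule: 24 h per delivered fraction."""
        return 24.0 * self.n_fractions

    @property
    def success(self) -> bool:
        return self.endpoint == EndpointState.SUCCESS.value


@dataclass
class KPIReport:
    """Replicate-averaged key performance indicators."""

    site: str
    arm: str
    n_replicates: int
    sr: float                   # % of replicates reaching eradication
    mean_ntcp: float            # %
    ntcp_ci: tuple[float, float]  # [mu - 3 sigma, mu + 3 sigma], %
    mean_dose: float            # Gy
    mean_fractions: float
    mean_duration: float        # h
    dose_trace_mean: list = field(default_factory=list)
    dose_trace_sd: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "site": self.site, "arm": self.arm, "n_replicates": self.n_replicates,
            "sr_percent": self.sr, "mean_ntcp_percent": self.mean_ntcp,
            "ntcp_ci_percent": list(self.ntcp_ci), "mean_dose_gy": self.mean_dose,
            "mean_fractions": self.mean_fractions, "mean_duration_h": self.mean_duration,
        }


@dataclass
class SweepSpec:
    """A grid of tumor LQ parameters to stress an agent against."""

    site: str
    pairs: list                  # [(alpha_tumor, beta_tumor), ...]
    replicates: int = 100
    nutrient_multipliers: list = field(default_factory=list)


def run_treatment(env: TreatmentEnv, policy, seed: int) -> TreatmentRecord:
    """Run one full episode under ``policy(healthy, cancer, k) -> dose``.

    Fractions are delivered daily until an endpoint; a replicate whose next
    window would exceed the treatment time limit stops as a timeout.
    """
    healthy, cancer = env.reset(seed)
    healthy_start, cancer_start = healthy, cancer
    k = 0
    endpoint = EndpointState.TIMEOUT.value
    while True:
        if cancer == 0:   # nothing to treat (also covers a tumor-free reset)
            endpoint = EndpointState.SUCCESS.value
            break
        if env.remaining_time() < 24:
            endpoint = EndpointState.TIMEOUT.value
            break
        res = env.step(policy(healthy, cancer, k))
        healthy, cancer = res.healthy, res.cancer
        k += 1
        if res.done:
            endpoint = res.endpoint
            break
    if env.fraction_doses:
        ntcp_value, geud_value = env.outcome()
    else:
        ntcp_value, geud_value = 0.0, 0.0
    return TreatmentRecord(
        seed=seed, site=env.site.site, doses=list(env.fraction_doses),
        endpoint=endpoint, ntcp=ntcp_value, geud=geud_value,
        healthy_start=healthy_start, cancer_start=cancer_start,
        growth_hours=env.grid.growth_hours, count_trace=list(env.count_trace),
    )


def aggregate_kpis(records: list[TreatmentRecord], site: str = "",
                   arm: str = "") -> KPIReport:
    """Average the KPIs over replicates.

    The complication band is mean +/- 3 sample standard deviations (the
    99.7% normal band, reported as the treatment's 99% confidence interval).
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    site = site or records[0].site
    ntcps = np.array([r.ntcp for r in records]) * 100.0
    mu = float(ntcps.mean())
    sd = float(ntcps.std(ddof=1)) if len(records) > 1 else 0.0
    max_k = max(r.n_fractions for r in records)
    trace_mean, trace_sd = [], []
    for k in range(max_k):
        dk = [r.doses[k] for r in records if r.n_fractions > k]
        trace_mean.append(float(np.mean(dk)))
        trace_sd.append(float(np.std(dk)))
    return KPIReport(
        site=site, arm=arm, n_replicates=len(records),
        sr=100.0 * np.mean([r.success for r in records]),
        mean_ntcp=mu, ntcp_ci=(mu - 3 * sd, mu + 3 * sd),
        mean_dose=float(np.mean([r.total_dose for r in records])),
        mean_fractions=float(np.mean([r.n_fractions for r in records])),
        mean_duration=float(np.mean([r.duration for r in records])),
        dose_trace_mean=trace_mean, dose_trace_sd=trace_sd,
    )


def _replicate_seeds(base_seed: int, n: int) -> list[int]:
    return [int(base_seed) + i for i in range(n)]


def run_baseline(site: SiteParams | str, n_replicates: int = 100,
                 fraction_dose: float | None = None, seed: int = 0,
                 sim_config: SimConfig | None = None,
                 radbio_config: RadbioConfig | None = None,
                 outcome_config: OutcomeConfig | None = None,
                 lkb: LKBParams | None = None,
                 return_records: bool = False):
    """Conventional daily schedule: a fixed fraction every 24 h until an
    endpoint.  Defaults to the site's conventional fraction size."""
    sp = site_params(site) if isinstance(site, str) else site
    if fraction_dose is None:
        fraction_dose = BASELINE_FRACTION_DOSE[sp.site]
    if fraction_dose <= 0:
        raise ValueError("fraction_dose must be > 0")
    records = []
    for s in _replicate_seeds(seed, n_replicates):
        env = TreatmentEnv(sim_config=sim_config, site=sp,
                           radbio_config=radbio_config,
                           outcome_config=outcome_config, lkb=lkb)
        records.append(run_treatment(env, lambda h, c, k: fraction_dose, s))
    report = aggregate_kpis(records, site=sp.site, arm="baseline")
    return (report, records) if return_records else report


def run_rl_arm(q: QTable, site: SiteParams | str, n_replicates: int = 100,
               seed: int = 0, sarsa_config: SarsaConfig | None = None,
               sim_config: SimConfig | None = None,
               radbio_config: RadbioConfig | None = None,
               outcome_config: OutcomeConfig | None = None,
               lkb: LKBParams | None = None,
               return_records: bool = False):
    """Greedy rollouts of a trained table over fresh replicates."""
    sp = site_params(site) if isinstance(site, str) else site
    cfg = sarsa_config or SarsaConfig()
    records = []
    for s in _replicate_seeds(seed, n_replicates):
        env = TreatmentEnv(sim_config=sim_config, site=sp,
                           radbio_config=radbio_config,
                           outcome_config=outcome_config, lkb=lkb)
        policy = greedy_policy(q, cfg.binning, cfg.actions,
                               np.random.default_rng(s + 777_000_001))
        records.append(run_treatment(env, policy, s))
    report = aggregate_kpis(records, site=sp.site, arm="rl")
    return (report, records) if return_records else report


def robustness_sweep(q: QTable, spec: SweepSpec, seed: int = 0,
                     sarsa_config: SarsaConfig | None = None,
                     sim_config: SimConfig | None = None,
                     radbio_config: RadbioConfig | None = None,
                     outcome_config: OutcomeConfig | None = None) -> pd.DataFrame:
    """Evaluate a frozen agent against off-training tumor radiosensitivity.

    One row per (alpha, beta) pair; ``robust`` flags pairs the agent still
    eradicates in every replicate.
    """
    base = site_params(spec.site)
    rows = []
    for alpha, beta in spec.pairs:
        sp = base.with_tumor(alpha, beta)
        report = run_rl_arm(q, sp, n_replicates=spec.replicates, seed=seed,
                            sarsa_config=sarsa_config, sim_config=sim_config,
                            radbio_config=radbio_config,
                            outcome_config=outcome_config,
                            lkb=lkb_params(spec.site))
        rows.append({
            "site": spec.site, "alpha_tumor": alpha, "beta_tumor": beta,
            "sr_percent": report.sr, "mean_ntcp_percent": report.mean_ntcp,
            "mean_dose_gy": report.mean_dose,
            "mean_fractions": report.mean_fractions,
            "mean_duration_h": report.mean_duration,
            "robust": report.sr >= 100.0,
        })
    return pd.DataFrame(rows)


def retrain_and_compare(spec: SweepSpec, sarsa_config: SarsaConfig,
                        q_frozen: QTable | None = None, seed: int = 0,
                        sim_config: SimConfig | None = None,
                        radbio_config: RadbioConfig | None = None,
                        outcome_config: OutcomeConfig | None = None) -> pd.DataFrame:
    """Train a fresh agent inside each off-nominal environment and put its
    KPIs side by side with the frozen agent's sweep."""
    base = site_params(spec.site)
    if q_frozen is None:
        factory = make_env_factory(sim_config=sim_config, site=base,
                                   radbio_config=radbio_config,
                                   outcome_config=outcome_config,
                                   pool_size=sarsa_config.pool_size,
                                   pool_seed=sarsa_config.rng_seed)
        q_frozen, _ = train_agent(factory, sarsa_config)
    frozen = robustness_sweep(q_frozen, spec, seed=seed,
                              sarsa_config=sarsa_config, sim_config=sim_config,
                              radbio_config=radbio_config,
                              outcome_config=outcome_config)
    rows = []
    for alpha, beta in spec.pairs:
        sp = base.with_tumor(alpha, beta)
        factory = make_env_factory(sim_config=sim_config, site=sp,
                                   radbio_config=radbio_config,
                                   outcome_config=outcome_config,
                                   pool_size=sarsa_config.pool_size,
                                   pool_seed=sarsa_config.rng_seed + 97)
        q_new, _ = train_agent(factory, sarsa_config)
        report = run_rl_arm(q_new, sp, n_replicates=spec.replicates, seed=seed,
                            sarsa_config=sarsa_config, sim_config=sim_config,
                            radbio_config=radbio_config,
                            outcome_config=outcome_config,
                            lkb=lkb_params(spec.site))
        rows.append({
            "site": spec.site, "alpha_tumor": alpha, "beta_tumor": beta,
            "sr_percent": report.sr, "mean_ntcp_percent": report.mean_ntcp,
            "mean_dose_gy": report.mean_dose,
            "mean_fractions": report.mean_fractions,
            "mean_duration_h": report.mean_duration,
        })
    retrained = pd.DataFrame(rows)
    return frozen.merge(retrained, on=["site", "alpha_tumor", "beta_tumor"],
                        suffixes=("_frozen", "_retrained"))


def nutrient_sensitivity(q: QTable, multipliers: list[float], site: str = "rectum",
                         n_replicates: int = 100, seed: int = 0,
                         sarsa_config: SarsaConfig | None = None,
                         sim_config: SimConfig | None = None,
                         radbio_config: RadbioConfig | None = None,
                         outcome_config: OutcomeConfig | None = None) -> pd.DataFrame:
    """Re-evaluate a frozen agent with the cancer cells' nutrient-consumption
    means scaled by each multiplier."""
    base = sim_config or SimConfig()
    rows = []
    for mult in multipliers:
        if mult <= 0:
            raise ValueError("nutrient multipliers must be > 0")
        scaled = dataclasses.replace(
            base,
            glucose_absorb_cancer_mean=base.glucose_absorb_cancer_mean * mult,
            glucose_absorb_cancer_sd=base.glucose_absorb_cancer_sd * mult,
        )
        report = run_rl_arm(q, site, n_replicates=n_replicates, seed=seed,
                            sarsa_config=sarsa_config, sim_config=scaled,
                            radbio_config=radbio_config,
                            outcome_config=outcome_config)
        rows.append({
            "multiplier": mult, "sr_percent": report.sr,
            "mean_ntcp_percent": report.mean_ntcp,
            "mean_dose_gy": report.mean_dose,
            "mean_fractions": report.mean_fractions,
        })
    return pd.DataFrame(rows)


def records_to_dataframe(records: list[TreatmentRecord]) -> pd.DataFrame:
    """Tidy per-replicate table (one row per replicate)."""
    return pd.DataFrame([
        {
            "seed": r.seed, "site": r.site, "endpoint": r.endpoint,
            "success": r.success, "n_fractions": r.n_fractions,
            "total_dose_gy": r.total_dose, "duration_h": r.duration,
            "ntcp": r.ntcp, "geud_gy": r.geud,
            "healthy_start": r.healthy_start, "cancer_start": r.cancer_start,
            "growth_hours": r.growth_hours,
            "first_dose_gy": r.doses[0] if r.doses else np.nan,
        }
        for r in records
    ])
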