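"""Scenario presets and parameter sweeps with outcome-map aggregation.

Each preset pins the parameters of one computational experiment (the
figure-style scenarios): single-pathogen runs, (r, c_r) and (beta_f, c_r)
outcome maps, and the recombination time courses.  Sweep resolution is not
part of the scenario definition; region maps are qualitative, so a coarse
"smoke" grid probes the same region topology as the full-resolution one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evolution import (
    EventSchedule,
    EvolutionTrace,
    OutcomeRecord,
    run_evolution,
    summarize_outcome,
)
from .integrate import IntegratorConfig, equilibrate
from .model import ModelParams, QGrid, SystemState
from .recombination import FourGenotypeState, RecombParams, run_recombination

__all__ = [
    "SweepSpec",
    "OutcomeMap",
    "run_sweep",
    "export_outcomes",
    "BASE_PARAMS",
    "SCENARIOS",
    "sweep_scenario",
    "run_scenario_names",
    "fig5_params",
    "fig5_initial_state",
]

#: Shared parameter core of the figure experiments.
BASE_PARAMS = ModelParams(b=1.5, mu=0.2, gamma=0.01, beta_e=1.0, theta=0.5)

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


@dataclass(frozen=True)
class SweepSpec:
    """Two-axis parameter sweep over independent evolutionary runs."""

    axis1_name: str
    axis1_values: tuple
    axis2_name: str
    axis2_values: tuple
    params: ModelParams
    schedule: EventSchedule

    def __post_init__(self):
        object.__setattr__(self, "axis1_values", tuple(float(v) for v in self.axis1_values))
        object.__setattr__(self, "axis2_values", tuple(float(v) for v in self.axis2_values))
        for name, values in (
            (self.axis1_name, self.axis1_values),
            (self.axis2_name, self.axis2_values),
        ):
            if name not in _PARAM_FIELDS:
                raise ValueError(f"unknown sweep axis {name!r}; must be a ModelParams field")
            if len(values) == 0:
                raise ValueError(f"sweep axis {name!r} has no values")

    def cells(self):
        for v1 in self.axis1_values:
            for v2 in self.axis2_values:
                yield v1, v2

    def cell_params(self, v1: float, v2: float) -> ModelParams:
        return replace(self.params, **{self.axis1_name: v1, self.axis2_name: v2})


@dataclass
class OutcomeMap:
    """Grid of outcome records keyed by (axis1 value, axis2 value)."""

    spec: SweepSpec
    records: dict
    errors: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v1, v2 in self.spec.cells():
            key = (v1, v2)
            row = {self.spec.axis1_name: v1, self.spec.axis2_name: v2}
            rec = self.records.get(key)
            if rec is None:
                row.update(
                    specific_fate="error",
                    q_S_mode=None, q_S_mean=None, q_R_mode=None, q_R_mean=None,
                    endemic_persists=None, foreign_persists=None, stability=None,
                    error=str(self.errors.get(key, "missing")),
                )
            else:
                row.update(
                    specific_fate=rec.specific_fate.value,
                    q_S_mode=rec.q_S_mode,
                    q_S_mean=rec.q_S_mean,
                    q_R_mode=rec.q_R_mode,
                    q_R_mean=rec.q_R_mean,
                    endemic_persists=rec.endemic_persists,
                    foreign_persists=rec.foreign_persists,
                    stability=rec.stability.value if rec.stability else None,
                    error="",
                )
            rows.append(row)
        return pd.DataFrame(rows)


def run_sweep(spec: SweepSpec, grid: QGrid | None = None,
              config: IntegratorConfig | None = None,
              progress: bool = False) -> OutcomeMap:
    """Run one independent evolution per cell (deterministic, order-free)."""
    grid = grid or QGrid.default()
    config = config or IntegratorConfig()
    records: dict = {}
    errors: dict = {}
    cells = list(spec.cells())
    iterator = cells
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(cells, desc="sweep")
        except ImportError:
            pass
    for v1, v2 in iterator:
        try:
            trace = run_evolution(spec.cell_params(v1, v2), grid, spec.schedule, config)
            records[(v1, v2)] = summarize_outcome(trace)
        except Exception as exc:  # per-cell failures must not kill the sweep
            errors[(v1, v2)] = exc
    return OutcomeMap(spec, records, errors)


def export_outcomes(outcome_map: OutcomeMap, path) -> None:
    """Write one CSV row per cell in deterministic order (axis1 outer)."""
    outcome_map.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _axis(lo: float, hi: float, n: int) -> tuple:
    return tuple(np.round(np.linspace(lo, hi, n), 10))


def fig1a_spec(resolution: int = 26) -> SweepSpec:
    """Fate of the R allele with general resistance fixed at q = 0."""
    total = 40
    return SweepSpec(
        "r", _axis(0.0, 1.0, resolution),
        "c_r", _axis(0.0, 0.5, resolution),
        BASE_PARAMS,
        EventSchedule(total_iterations=total, introduce_R_at=5,
                      freeze_general_until=total),
    )


def fig1b_schedule(iterations: int = 60) -> EventSchedule:
    """General resistance evolving alone with the endemic pathogen."""
    return EventSchedule(total_iterations=iterations)


def fig1cd_spec(resolution: int = 26) -> SweepSpec:
    """R introduced after general resistance equilibrated (general first)."""
    return SweepSpec(
        "r", _axis(0.0, 1.0, resolution),
        "c_r", _axis(0.0, 0.5, resolution),
        BASE_PARAMS,
        EventSchedule(total_iterations=100, introduce_R_at=50),
    )


def specific_first_spec(resolution: int = 26) -> SweepSpec:
    """Specific resistance equilibrates before q is allowed to mutate."""
    return SweepSpec(
        "r", _axis(0.0, 1.0, resolution),
        "c_r", _axis(0.0, 0.5, resolution),
        BASE_PARAMS,
        EventSchedule(total_iterations=100, introduce_R_at=0,
                      freeze_general_until=50),
    )


def fig2_spec(resolution: int = 26) -> SweepSpec:
    """Two-pathogen outcome map at beta_f = 0.6."""
    return SweepSpec(
        "r", _axis(0.0, 1.0, resolution),
        "c_r", _axis(0.0, 0.5, resolution),
        replace(BASE_PARAMS, beta_f=0.6),
        EventSchedule(total_iterations=150, introduce_R_at=50, introduce_If_at=100),
    )


def fig3_setup() -> tuple[ModelParams, EventSchedule]:
    """Point run producing S/R polymorphism with intermediate q in S only."""
    params = replace(BASE_PARAMS, r=0.85, c_r=0.325, beta_f=0.6)
    return params, EventSchedule(total_iterations=150, introduce_R_at=50,
                                 introduce_If_at=100)


def fig4_spec(resolution: int = 26) -> SweepSpec:
    """Foreign transmission x cost sweep at fixed r = 0.8."""
    return SweepSpec(
        "beta_f", _axis(0.0, 1.0, resolution),
        "c_r", _axis(0.0, 0.5, resolution),
        replace(BASE_PARAMS, r=0.8),
        EventSchedule(total_iterations=150, introduce_R_at=50, introduce_If_at=100),
    )


def fig5_params(p: float) -> RecombParams:
    """Recombination presets: two-allele q locus at the evolved strengths.

    The endemic transmission rate is 0.75 here: it is the value consistent
    with the evolved strength q+ = 0.091 (cost 0.0465) of the source
    adaptive-dynamics equilibrium, and it satisfies the foreign-persistence
    condition beta_f > (1 - r) beta_e at r = 0.2 that the coexistence state
    requires.
    """
    base = ModelParams(b=1.5, mu=0.2, gamma=0.001, beta_e=0.75, beta_f=0.7,
                       r=0.2, c_r=0.1, theta=0.5)
    return RecombParams(base=base, p=p, q_plus=0.091, q_minus=0.0)


def fig5_initial_state(rp: RecombParams,
                       config: IntegratorConfig | None = None,
                       burn_in: float = 20000.0) -> FourGenotypeState:
    """Initial abundances on the clonal (p = 0) attractor.

    The recombination scenarios start from the equilibrium reached by the
    adaptive-dynamics model (Q+S and Q-R coexisting with both pathogens);
    that state is regenerated here by burning in the p = 0 four-genotype
    system from a low-density seed of the same genotypes.
    """
    config = config or IntegratorConfig()
    clonal = replace(rp, p=0.0)
    state = FourGenotypeState(np.array([1.0, 0.0, 0.0, 1.0]), I_e=1.0, I_f=1.0)
    traj, _ = run_recombination(state, clonal, config, t_end=burn_in,
                                record_every=burn_in)
    return FourGenotypeState(traj.D[-1].copy(), float(traj.I_e[-1]), float(traj.I_f[-1]))


#: Registry used by the CLI; values are (kind, factory) pairs.
SCENARIOS = {
    "fig1a": ("sweep", fig1a_spec),
    "fig1b": ("run", fig1b_schedule),
    "fig1c": ("sweep", fig1cd_spec),
    "fig1d": ("sweep", fig1cd_spec),
    "fig1_specific_first": ("sweep", specific_first_spec),
    "fig2": ("sweep", fig2_spec),
    "fig3": ("run", fig3_setup),
    "fig4": ("sweep", fig4_spec),
    "fig5_p0": ("recomb", lambda: fig5_params(0.0)),
    "fig5_p005": ("recomb", lambda: fig5_params(0.005)),
    "fig5_p05": ("recomb", lambda: fig5_params(0.05)),
}


def sweep_scenario(name: str, resolution: int = 26) -> SweepSpec:
    kind, factory = SCENARIOS[name]
    if kind != "sweep":
        raise ValueError(f"scenario {name!r} is not a sweep")
    return factory(resolution)


def run_scenario_names() -> list[str]:
    return sorted(SCENARIOS)
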