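"""Synthetic proliferation-plate data with known ground truth.

Emulates a 72-h viability assay on 96-well plates: an untreated-control
column anchoring the normalization, single-agent dose series at fractions
and multiples of the true IC50, and constant-ratio two-drug combinations.
Each agent's response follows a median-effect curve with known (Dm, m);
combinations are generated under a constant-combination-index mechanism so
that the analysis pipeline has an exactly recoverable ground truth; well
signals carry multiplicative Gaussian noise, as plate-reader absorbance
noise is approximately proportional to signal.

The generator writes the same long-format well records the IO module
consumes, plus a manifest of generating parameters for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .combination import DEFAULT_MULTIPLIERS, ConstantRatioDesign
from .errors import DomainError
from .median_effect import MedianEffectModel, dose_for_fa

#: Baseline control-well signal in arbitrary optical-density units.
BASELINE_SIGNAL = 1.0

#: Columns of the long-format well table, shared with io_reporting.
WELL_COLUMNS = (
    "experiment_id", "agent_a", "dose_a", "agent_b", "dose_b",
    "replicate", "signal", "is_control",
)

__all__ = [
    "AgentSpec",
    "InteractionSpec",
    "PlateConfig",
    "simulate_single_agent",
    "simulate_combination",
    "generate_study",
    "solve_constant_ci_fa",
    "WELL_COLUMNS",
    "BASELINE_SIGNAL",
]


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth median-effect parameters of one agent.

    ``denticity_class`` labels chelator arms whose metal complexes are
    modeled as relabeled agents ('hexadentate', 'tridentate' or 'none').
    """

    agent_id: str
    true_dm: float
    true_m: float
    denticity_class: str = "none"

    def __post_init__(self) -> None:
        if self.true_dm <= 0:
            raise DomainError("true_dm must be > 0")
        if self.true_m <= 0:
            raise DomainError("true_m must be > 0")

    @property
    def model(self) -> MedianEffectModel:
        return MedianEffectModel(dm=self.true_dm, m=self.true_m)


@dataclass(frozen=True)
class InteractionSpec:
    """Target constant combination index for one agent pair.

    ``ci_star`` may instead be a callable ``fa -> CI*(fa)`` to generate
    dose-varying interactions (e.g. U-shaped Fa-CI profiles); a constant
    is the default mechanism because it makes CI exactly recoverable.
    """

    agent_a: str
    agent_b: str
    ci_star: float | Callable[[float], float] = 1.0

    def __post_init__(self) -> None:
        if not callable(self.ci_star) and self.ci_star <= 0:
            raise DomainError("ci_star must be > 0")

    def ci_at(self, fa: float) -> float:
        return float(self.ci_star(fa)) if callable(self.ci_star) \
            else float(self.ci_star)


@dataclass(frozen=True)
class PlateConfig:
    """Replication and noise structure of the simulated study.

    Defaults mirror a typical plate workflow: four independent
    experiments, triplicate wells per dose, eight untreated control wells
    per experiment, and 5% multiplicative signal noise.
    """

    n_experiments: int = 4
    replicates_per_dose: int = 3
    noise_sd: float = 0.05
    control_wells: int = 8
    seed: int = 0
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    #: SD (natural-log scale) of optional log-normal jitter on each
    #: agent's true Dm across experiments, emulating inter-experiment
    #: biological variability; 0 disables it.
    dm_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise DomainError("n_experiments must be >= 1")
        if self.replicates_per_dose < 1 or self.control_wells < 1:
            raise DomainError("replicates and control wells must be >= 1")
        if self.noise_sd < 0 or self.dm_jitter_sd < 0:
            raise DomainError("noise_sd and dm_jitter_sd must be >= 0")
        object.__setattr__(self, "multipliers", tuple(self.multipliers))

    def experiment_rngs(self) -> list[np.random.Generator]:
        """One independent RNG stream per experiment, all fixed by seed."""
        seq = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s)
                for s in seq.spawn(self.n_experiments)]


def _jittered_model(spec: AgentSpec, exp_index: int,
                    plate: PlateConfig) -> MedianEffectModel:
    """Per-experiment response model with optional log-normal Dm jitter.

    The jitter stream is keyed on (seed, agent id, experiment), so the
    same agent sees the same jittered Dm in its single-agent arm and in
    every combination arm of the same experiment, while administered
    doses stay anchored at the nominal Dm (dosing is fixed by design;
    biology varies).
    """
    if plate.dm_jitter_sd == 0:
        return spec.model
    import zlib
    key = (plate.seed, zlib.crc32(spec.agent_id.encode()), exp_index)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    dm = spec.true_dm * float(np.exp(rng.normal(0.0, plate.dm_jitter_sd)))
    return MedianEffectModel(dm=dm, m=spec.true_m)


def _noisy_signal(fu: float, rng: np.random.Generator,
                  noise_sd: float, size: int) -> np.ndarray:
    """Raw well signals: baseline x fu x (1 + eps), truncated at 0."""
    eps = rng.normal(0.0, noise_sd, size=size) if noise_sd > 0 \
        else np.zeros(size)
    return np.maximum(BASELINE_SIGNAL * fu * (1.0 + eps), 0.0)


def _control_rows(exp_id: str, rng, plate: PlateConfig) -> list[dict]:
    sig = _noisy_signal(1.0, rng, plate.noise_sd, plate.control_wells)
    return [
        dict(experiment_id=exp_id, agent_a="", dose_a=0.0, agent_b="",
             dose_b=0.0, replicate=i + 1, signal=float(s), is_control=True)
        for i, s in enumerate(sig)
    ]


def _experiment_ids(plate: PlateConfig) -> list[str]:
    return [f"exp{i + 1}" for i in range(plate.n_experiments)]


def simulate_single_agent(
    spec: AgentSpec, plate: PlateConfig, include_controls: bool = True
) -> pd.DataFrame:
    """Simulate one agent's dose series across all experiments.

    Doses are the design multipliers times the agent's true Dm.  Each well
    signal is ``baseline * fu(dose) * (1 + eps)`` with
    ``eps ~ Normal(0, noise_sd)``; control wells sit at dose 0 with
    fu = 1.  Deterministic under a fixed seed.
    """
    rows: list[dict] = []
    for k, (exp_id, rng) in enumerate(zip(_experiment_ids(plate),
                                          plate.experiment_rngs())):
        model = _jittered_model(spec, k, plate)
        if include_controls:
            rows.extend(_control_rows(exp_id, rng, plate))
        for mult in plate.multipliers:
            dose = mult * spec.true_dm
            fu = 1.0 - 1.0 / (1.0 + (model.dm / dose) ** model.m)
            sig = _noisy_signal(fu, rng, plate.noise_sd,
                                plate.replicates_per_dose)
            rows.extend(
                dict(experiment_id=exp_id, agent_a=spec.agent_id,
                     dose_a=float(dose), agent_b="", dose_b=0.0,
                     replicate=i + 1, signal=float(s), is_control=False)
                for i, s in enumerate(sig)
            )
    return pd.DataFrame(rows, columns=list(WELL_COLUMNS))


def solve_constant_ci_fa(
    design: ConstantRatioDesign,
    model_a: MedianEffectModel,
    model_b: MedianEffectModel,
    total_dose: float,
    ci_star: float,
    tol: float = 1e-12,
) -> tuple[float, bool]:
    """Effect level fa at which the given total dose meets CI = ci_star.

    Solves ``rho_a*D/dxa(fa) + rho_b*D/dxb(fa) = ci_star`` for fa by
    Brent's method.  The left side is strictly decreasing in fa (both
    iso-effective doses increase with fa), so the root is unique when it
    exists.  Returns ``(fa, clamped)``; when the dose lies outside the
    achievable effect range the fa is clamped to the search bracket edge
    and flagged.
    """
    dose_a, dose_b = design.split_total(total_dose)

    def excess(fa: float) -> float:
        return (dose_a / dose_for_fa(model_a, fa)
                + dose_b / dose_for_fa(model_b, fa)) - ci_star

    lo, hi = 1e-9, 1.0 - 1e-9
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo < 0:        # even a vanishing effect needs more dose
        return lo, True
    if f_hi > 0:        # dose exceeds what a near-total effect requires
        return hi, True
    fa = brentq(excess, lo, hi, xtol=tol)
    return float(fa), False


def simulate_combination(
    spec_a: AgentSpec,
    spec_b: AgentSpec,
    interaction: InteractionSpec,
    plate: PlateConfig,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Simulate a constant-ratio combination arm across all experiments.

    The design is anchored at the true IC50s; at each level the generated
    fraction affected is the unique solution of the CI equation at the
    target ``ci_star`` (see :func:`solve_constant_ci_fa`), after which
    noise is applied exactly as for single agents.  For a callable
    ``ci_star`` the equation is solved with the level-dependent target via
    a fixed point on fa (iterated bisection).
    """
    design = ConstantRatioDesign(
        agent_a=spec_a.agent_id, agent_b=spec_b.agent_id,
        ic50_a=spec_a.true_dm, ic50_b=spec_b.true_dm,
        multipliers=plate.multipliers,
    )
    rows: list[dict] = []
    for k, (exp_id, rng) in enumerate(zip(_experiment_ids(plate),
                                          plate.experiment_rngs())):
        model_a = _jittered_model(spec_a, k, plate)
        model_b = _jittered_model(spec_b, k, plate)
        # advance the stream identically to the single-agent arm so that
        # combination wells are independent of control wells
        if include_controls:
            rows.extend(_control_rows(exp_id, rng, plate))
        for mult in plate.multipliers:
            dose_a, dose_b = design.doses_at(mult)
            total = dose_a + dose_b
            if callable(interaction.ci_star):
                fa, clamped = _solve_varying_ci(design, model_a, model_b,
                                                total, interaction)
            else:
                fa, clamped = solve_constant_ci_fa(
                    design, model_a, model_b, total, interaction.ci_at(0.5))
            if clamped:
                import logging
                logging.getLogger(__name__).warning(
                    "dose level %gx outside achievable effect range for "
                    "%s+%s; fa clamped to %g", mult, spec_a.agent_id,
                    spec_b.agent_id, fa)
            fu = 1.0 - fa
            sig = _noisy_signal(fu, rng, plate.noise_sd,
                                plate.replicates_per_dose)
            rows.extend(
                dict(experiment_id=exp_id, agent_a=spec_a.agent_id,
                     dose_a=float(dose_a), agent_b=spec_b.agent_id,
                     dose_b=float(dose_b), replicate=i + 1,
                     signal=float(s), is_control=False)
                for i, s in enumerate(sig)
            )
    return pd.DataFrame(rows, columns=list(WELL_COLUMNS))


def _solve_varying_ci(design, model_a, model_b, total_dose,
                      interaction: InteractionSpec,
                      max_iter: int = 200) -> tuple[float, bool]:
    """Solve CI(fa) = ci_star(fa) for a dose-varying target by bisection.

    Assumes ci_star(fa) varies slowly enough that
    CI(fa) - ci_star(fa) still changes sign exactly once on (0, 1).
    """
    dose_a, dose_b = design.split_total(total_dose)

    def excess(fa: float) -> float:
        return (dose_a / dose_for_fa(model_a, fa)
                + dose_b / dose_for_fa(model_b, fa)) - interaction.ci_at(fa)

    lo, hi = 1e-9, 1.0 - 1e-9
    if excess(lo) < 0:
        return lo, True
    if excess(hi) > 0:
        return hi, True
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi), False


@dataclass(frozen=True)
class SyntheticStudy:
    """All arms of a generated study plus the ground-truth manifest."""

    wells: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def generate_study(
    panel: list[AgentSpec],
    pairs: list[InteractionSpec],
    plate: PlateConfig,
) -> SyntheticStudy:
    """Generate a complete study: every single agent plus every pair.

    Controls are emitted once per experiment (shared by all arms of that
    experiment, matching a plate normalized against its own untreated
    column).  The manifest records every generating parameter keyed by
    agent or pair, for parameter-recovery tests.
    """
    ids = [s.agent_id for s in panel]
    if len(set(ids)) != len(ids):
        raise DomainError(f"duplicate agent ids in panel: {ids}")
    by_id = {s.agent_id: s for s in panel}
    for p in pairs:
        missing = {p.agent_a, p.agent_b} - set(by_id)
        if missing:
            raise DomainError(f"pair references unknown agents: {missing}")

    frames: list[pd.DataFrame] = []
    control_rng = np.random.default_rng(
        np.random.SeedSequence(plate.seed).spawn(plate.n_experiments + 1)[-1])
    ctrl_rows: list[dict] = []
    for exp_id in _experiment_ids(plate):
        ctrl_rows.extend(_control_rows(exp_id, control_rng, plate))
    frames.append(pd.DataFrame(ctrl_rows, columns=list(WELL_COLUMNS)))

    for spec in panel:
        frames.append(simulate_single_agent(spec, plate,
                                            include_controls=False))
    for p in pairs:
        frames.append(simulate_combination(by_id[p.agent_a], by_id[p.agent_b],
                                           p, plate, include_controls=False))

    manifest = {
        "seed": plate.seed,
        "n_experiments": plate.n_experiments,
        "noise_sd": plate.noise_sd,
        "dm_jitter_sd": plate.dm_jitter_sd,
        "multipliers": list(plate.multipliers),
        "agents": {
            s.agent_id: {"true_dm": s.true_dm, "true_m": s.true_m,
                         "denticity_class": s.denticity_class}
            for s in panel
        },
        "pairs": {
            f"{p.agent_a}+{p.agent_b}": {
                "ci_star": ("callable" if callable(p.ci_star)
                            else float(p.ci_star)),
            }
            for p in pairs
        },
    }
    wells = pd.concat(frames, ignore_index=True)
    return SyntheticStudy(wells=wells, manifest=manifest)


#: Example agent panel with IC50s on the scale of a chelator study
#: (micromolar for the hydrophilic/lipophilic chelators, nanomolar for the
#: thiosemicarbazone); slopes are assumptions, not measured values.
EXAMPLE_PANEL = (
    AgentSpec("DFO", true_dm=16.902, true_m=1.5,
              denticity_class="hexadentate"),
    AgentSpec("SIH", true_dm=14.004, true_m=1.5,
              denticity_class="tridentate"),
    AgentSpec("NHAPI", true_dm=19.137, true_m=1.5,
              denticity_class="tridentate"),
    AgentSpec("Dp44mT", true_dm=0.004, true_m=2.0,
              denticity_class="tridentate"),
)
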