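"""Two-drug interaction analysis under Loewe additivity.

The combination index (CI) for doses (Da, Db) given together that produce
fraction affected fa is

    CI = Da / Dxa + Db / Dxb

where Dxa and Dxb are the single-agent iso-effective doses at the same fa,
obtained by inverting each agent's median-effect model.  CI = 1 is Loewe
additivity (a drug is additive with itself), CI < 1 synergism, CI > 1
antagonism.  The two-term (mutually exclusive) form of the equation is
used; there is no third interaction term.

The constant-ratio design fixes the two drugs' dose ratio at the ratio of
their IC50s while the total dose is scaled through fractions and multiples
of IC50 (default 1/8, 1/4, 1/2, 1, 2, 4).  Treating the mixture as a
single agent in total dose gives a median-effect model of its own, from
which the Fa-CI profile — CI as a function of effect level — is simulated
on a dense fa grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import DomainError, UndefinedCIError
from .median_effect import (
    DoseResponseDataset,
    MedianEffectModel,
    dose_for_fa,
    fit_median_effect,
)

DEFAULT_MULTIPLIERS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

DEFAULT_FA_GRID = tuple(np.round(np.arange(0.01, 1.0, 0.01), 10))

__all__ = [
    "ConstantRatioDesign",
    "CombinationMeasurement",
    "CIResult",
    "FaCIProfile",
    "CIClassification",
    "CI_SCALE",
    "combination_index",
    "fit_mixture",
    "fa_ci_curve",
    "ci_at_design_point",
    "classify_ci",
    "aggregate",
    "design_dose_series",
    "metal_complex_ratio",
    "DEFAULT_MULTIPLIERS",
    "DEFAULT_FA_GRID",
]


@dataclass(frozen=True)
class ConstantRatioDesign:
    """Fixed-ratio two-drug design anchored at the agents' IC50s.

    At every level k the administered doses are
    ``(multiplier_k * ic50_a, multiplier_k * ic50_b)``, so the dose ratio
    is constant and each drug's dose fraction of the total is
    ``rho_a = ic50_a / (ic50_a + ic50_b)`` and ``rho_b = 1 - rho_a``.
    """

    agent_a: str
    agent_b: str
    ic50_a: float
    ic50_b: float
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS

    def __post_init__(self) -> None:
        if self.ic50_a <= 0 or self.ic50_b <= 0:
            raise DomainError("IC50 anchors must be > 0")
        object.__setattr__(self, "multipliers", tuple(self.multipliers))
        if any(mult <= 0 for mult in self.multipliers):
            raise DomainError("design multipliers must be > 0")

    @property
    def rho_a(self) -> float:
        return self.ic50_a / (self.ic50_a + self.ic50_b)

    @property
    def rho_b(self) -> float:
        return 1.0 - self.rho_a

    def doses_at(self, multiplier: float) -> tuple[float, float]:
        """Component doses (dose_a, dose_b) at one design level."""
        if multiplier <= 0:
            raise DomainError("multiplier must be > 0")
        return multiplier * self.ic50_a, multiplier * self.ic50_b

    def split_total(self, total_dose: float) -> tuple[float, float]:
        """Split a total dose onto the constant ratio."""
        return self.rho_a * total_dose, self.rho_b * total_dose


@dataclass(frozen=True)
class CombinationMeasurement:
    """Observed effect of one co-administered dose pair."""

    dose_a: float
    dose_b: float
    fa_observed: float

    def __post_init__(self) -> None:
        if self.dose_a <= 0 or self.dose_b <= 0:
            raise DomainError("combination doses must be > 0")
        if not 0.0 <= self.fa_observed <= 1.0:
            raise DomainError("fa_observed must be in [0, 1]")


@dataclass(frozen=True)
class CIResult:
    """Combination index with its components.

    ``ci = dose_a / dxa + dose_b / dxb`` where (dxa, dxb) are the
    single-agent iso-effective doses at effect level ``fa``.
    """

    ci: float
    fa: float
    dose_a: float
    dose_b: float
    dxa: float
    dxb: float


@dataclass(frozen=True)
class FaCIProfile:
    """CI indexed by effect level for one constant-ratio combination."""

    fa_grid: tuple[float, ...]
    ci_values: tuple[float, ...]
    mixture_model: MedianEffectModel
    design: ConstantRatioDesign

    def __post_init__(self) -> None:
        object.__setattr__(self, "fa_grid", tuple(self.fa_grid))
        object.__setattr__(self, "ci_values", tuple(self.ci_values))
        if len(self.fa_grid) != len(self.ci_values):
            raise DomainError("fa_grid and ci_values lengths differ")


@dataclass(frozen=True)
class CIClassification:
    """Verbal interaction category with its CI interval.

    ``lower``/``upper`` are the interval bounds; ``lower_closed`` /
    ``upper_closed`` record which ends are included.
    """

    label: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool

    def contains(self, ci: float) -> bool:
        above = ci > self.lower or (self.lower_closed and ci == self.lower)
        below = ci < self.upper or (self.upper_closed and ci == self.upper)
        return above and below


def _build_scale() -> tuple[CIClassification, ...]:
    # Bands closed on the side nearer CI = 1, open away from it, so the
    # printed boundaries (0.9, 1.1, ...) resolve to a single label and the
    # bands partition (0, inf).
    return (
        CIClassification("very strong synergism", 0.0, 0.1, False, False),
        CIClassification("strong synergism", 0.1, 0.3, True, False),
        CIClassification("synergism", 0.3, 0.7, True, False),
        CIClassification("moderate synergism", 0.7, 0.85, True, False),
        CIClassification("slight synergism", 0.85, 0.9, True, False),
        CIClassification("nearly additive", 0.9, 1.1, True, True),
        CIClassification("slight antagonism", 1.1, 1.2, False, True),
        CIClassification("moderate antagonism", 1.2, 1.45, False, True),
        CIClassification("antagonism", 1.45, 3.3, False, True),
        CIClassification("strong antagonism", 3.3, 10.0, False, True),
        CIClassification("very strong antagonism", 10.0, np.inf, False, False),
    )


#: The 11-band verbal scale, ordered from strongest synergism to strongest
#: antagonism.  The bands partition (0, inf).
CI_SCALE: tuple[CIClassification, ...] = _build_scale()


def classify_ci(ci: float) -> CIClassification:
    """Map a combination index onto the 11-band verbal scale.

    Boundary values belong to the band nearer CI = 1 (e.g. 0.9 and 1.1
    are "nearly additive", 0.85 is "slight synergism").
    """
    if not np.isfinite(ci) or ci <= 0:
        raise DomainError(f"ci must be finite and > 0, got {ci}")
    for band in CI_SCALE:
        if band.contains(ci):
            return band
    raise AssertionError("unreachable: CI scale partitions (0, inf)")


def combination_index(
    measurement: CombinationMeasurement,
    model_a: MedianEffectModel,
    model_b: MedianEffectModel,
) -> CIResult:
    """Compute the CI of one observed combination point.

    The iso-effective doses at the observed fa come from each agent's own
    median-effect fit.
    """
    fa = measurement.fa_observed
    if fa <= 0.0 or fa >= 1.0:
        raise UndefinedCIError(
            f"CI undefined at fa={fa}: iso-effective doses vanish or diverge"
        )
    dxa = dose_for_fa(model_a, fa)
    dxb = dose_for_fa(model_b, fa)
    ci = measurement.dose_a / dxa + measurement.dose_b / dxb
    return CIResult(ci=ci, fa=fa, dose_a=measurement.dose_a,
                    dose_b=measurement.dose_b, dxa=dxa, dxb=dxb)


def fit_mixture(
    design: ConstantRatioDesign, combo_data: DoseResponseDataset, **fit_kw
) -> MedianEffectModel:
    """Fit a median-effect model to a constant-ratio mixture.

    ``combo_data`` doses must be total dose (dose_a + dose_b) on the
    design's ratio; the mixture is then a single agent for all purposes.
    """
    return fit_median_effect(combo_data, **fit_kw)


def fa_ci_curve(
    model_a: MedianEffectModel,
    model_b: MedianEffectModel,
    mixture: MedianEffectModel,
    design: ConstantRatioDesign,
    fa_grid=DEFAULT_FA_GRID,
) -> FaCIProfile:
    """Simulate CI across effect levels (the Fa-CI plot).

    For each fa on the grid the mixture model supplies the total dose that
    produces fa; that dose is split on the constant ratio and the CI
    equation evaluated against the single-agent iso-effective doses.
    """
    fa = np.asarray(fa_grid, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise DomainError("fa_grid must lie strictly in (0, 1)")
    total = dose_for_fa(mixture, fa)
    dxa = dose_for_fa(model_a, fa)
    dxb = dose_for_fa(model_b, fa)
    ci = design.rho_a * total / dxa + design.rho_b * total / dxb
    return FaCIProfile(fa_grid=tuple(fa), ci_values=tuple(ci),
                       mixture_model=mixture, design=design)


def ci_at_design_point(
    design: ConstantRatioDesign,
    level_multiplier: float,
    per_experiment_data: dict,
) -> tuple[dict[str, CIResult], dict[str, str]]:
    """Per-experiment CI at one design level (e.g. the 1 x IC50 point).

    Parameters
    ----------
    per_experiment_data : dict
        ``experiment_id -> (model_a, model_b, fa_observed)`` where the
        models are that experiment's own single-agent fits and
        ``fa_observed`` is the combination's observed fraction affected
        at ``(level_multiplier * ic50_a, level_multiplier * ic50_b)``.

    Returns
    -------
    results, failures
        ``results``: ``experiment_id -> CIResult`` for every experiment
        that could be evaluated; ``failures``: ``experiment_id -> reason``
        for excluded experiments (reported, never silently dropped).
    """
    dose_a, dose_b = design.doses_at(level_multiplier)
    results: dict[str, CIResult] = {}
    failures: dict[str, str] = {}
    for exp_id, (model_a, model_b, fa_obs) in per_experiment_data.items():
        try:
            meas = CombinationMeasurement(dose_a=dose_a, dose_b=dose_b,
                                          fa_observed=fa_obs)
            results[exp_id] = combination_index(meas, model_a, model_b)
        except (DomainError, UndefinedCIError) as exc:
            failures[exp_id] = str(exc)
    return results, failures


@dataclass(frozen=True)
class Aggregate:
    """Mean +/- sample SD over n per-experiment values.

    ``sd`` is NaN when n = 1 (sample SD undefined), and the result is
    flagged accordingly.
    """

    mean: float
    sd: float
    n: int
    flags: tuple[str, ...] = field(default=())

    def __str__(self) -> str:
        sd = "undefined" if np.isnan(self.sd) else f"{self.sd:.3f}"
        return f"{self.mean:.3f} +/- {sd} (n={self.n})"


def aggregate(values) -> Aggregate:
    """Arithmetic mean and sample SD (n-1 denominator) across experiments."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot aggregate an empty collection")
    mean = float(arr.mean())
    if arr.size == 1:
        return Aggregate(mean=mean, sd=float("nan"), n=1,
                         flags=("sd-undefined-n1",))
    return Aggregate(mean=mean, sd=float(arr.std(ddof=1)), n=int(arr.size))


def design_dose_series(ic50: float, multipliers=DEFAULT_MULTIPLIERS):
    """Doses at fractions/multiples of an IC50, ascending."""
    if ic50 <= 0:
        raise DomainError(f"ic50 must be > 0, got {ic50}")
    mult = np.asarray(multipliers, dtype=float)
    if mult.size == 0 or np.any(mult <= 0):
        raise DomainError("multipliers must be a non-empty positive sequence")
    return tuple(np.sort(ic50 * mult))


def metal_complex_ratio(ligand_denticity_class: str) -> Fraction:
    """Chelator : metal molar ratio at one metal-binding equivalent.

    A hexadentate ligand fully coordinates one metal ion alone (1:1); a
    tridentate ligand needs two per ion (2:1).
    """
    ratios = {"hexadentate": Fraction(1, 1), "tridentate": Fraction(2, 1)}
    try:
        return ratios[ligand_denticity_class]
    except KeyError:
        raise DomainError(
            f"unrecognized denticity class {ligand_denticity_class!r}; "
            f"expected one of {sorted(ratios)}"
        ) from None
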