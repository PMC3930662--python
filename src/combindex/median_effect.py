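"""Median-effect dose-response model for a single agent.

The model is the mass-action law

    fa / fu = (D / Dm) ** m

where ``fa`` is the fraction of proliferation inhibited at dose ``D``,
``fu = 1 - fa`` the uninhibited fraction, ``Dm`` the median-effect dose
(operationally the IC50) and ``m`` the sigmoidicity of the curve.  On the
median-effect plot, log10(fa/fu) versus log10(D), the model is a straight
line with slope ``m`` and intercept ``-m * log10(Dm)``, so it is fitted by
ordinary least squares on the transformed data.

A constant-ratio two-drug mixture is treated as a single agent whose dose
is the total dose, which is how the combination module reuses this one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, FitInfeasibleError, ModelInvalidError

logger = logging.getLogger(__name__)

#: Default exclusion window: observations with fa <= FA_EPS or
#: fa >= 1 - FA_EPS are not usable on the log-odds scale.
FA_EPS = 0.01

__all__ = [
    "DoseResponseObservation",
    "DoseResponseDataset",
    "MedianEffectModel",
    "median_effect_transform",
    "fit_median_effect",
    "predict_fa",
    "dose_for_fa",
    "FA_EPS",
]


@dataclass(frozen=True)
class DoseResponseObservation:
    """One dose / fraction-affected pair.

    ``fu`` is derived, never stored independently, so ``fa + fu == 1``
    holds exactly.
    """

    dose: float
    fa: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose}")
        if not 0.0 <= self.fa <= 1.0:
            raise DomainError(f"fa must be in [0, 1], got {self.fa}")

    @property
    def fu(self) -> float:
        return 1.0 - self.fa


@dataclass(frozen=True)
class DoseResponseDataset:
    """Dose-response observations for one agent in one experiment.

    The agent may be a fixed-ratio mixture; then ``dose`` is total dose.
    """

    agent_id: str
    experiment_id: str
    observations: tuple[DoseResponseObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))

    def __len__(self) -> int:
        return len(self.observations)

    @classmethod
    def from_arrays(cls, agent_id, experiment_id, doses, fas,
                    clamp: bool = False) -> "DoseResponseDataset":
        """Build a dataset from parallel dose / fa arrays.

        With ``clamp=True``, fa values that fall outside [0, 1] (possible
        after control normalization of noisy signals) are clamped to the
        interval and the clamping is logged.
        """
        obs = []
        for d, f in zip(doses, fas, strict=True):
            f = float(f)
            if clamp and not 0.0 <= f <= 1.0:
                clamped = min(max(f, 0.0), 1.0)
                logger.info(
                    "clamping fa=%g to %g (agent=%s, experiment=%s, dose=%g)",
                    f, clamped, agent_id, experiment_id, d,
                )
                f = clamped
            obs.append(DoseResponseObservation(dose=float(d), fa=f))
        return cls(agent_id=agent_id, experiment_id=experiment_id,
                   observations=tuple(obs))


@dataclass(frozen=True)
class MedianEffectModel:
    """Fitted median-effect parameters with fit diagnostics.

    Attributes
    ----------
    dm : float
        Median-effect dose (IC50), same concentration units as the input
        doses (µM throughout this package).
    m : float
        Slope of the median-effect plot.  Must be positive for the dose
        inversion to be defined.
    r : float
        Pearson correlation coefficient of the median-effect plot.
    n_fit : int
        Number of observations retained in the regression.
    """

    dm: float
    m: float
    r: float = 1.0
    n_fit: int = 0
    excluded: tuple[DoseResponseObservation, ...] = field(default=())

    def __post_init__(self) -> None:
        if not np.isfinite(self.dm) or self.dm <= 0:
            raise ModelInvalidError(f"dm must be finite and > 0, got {self.dm}")
        if not np.isfinite(self.m):
            raise ModelInvalidError(f"m must be finite, got {self.m}")

    @property
    def valid(self) -> bool:
        return self.m > 0


def median_effect_transform(
    dataset: DoseResponseDataset, fa_eps: float = FA_EPS
):
    """Linearize a dataset onto the median-effect plot.

    Returns ``(x, y, retained, excluded)`` where ``x = log10(dose)`` and
    ``y = log10(fa / fu)`` for every retained observation, in input order.
    Observations with dose 0 or fa outside the open window
    ``(fa_eps, 1 - fa_eps)`` are excluded (the log-odds is unstable or
    undefined there) and returned rather than silently dropped.

    Raises
    ------
    FitInfeasibleError
        If fewer than 3 observations survive the window.
    """
    retained, excluded = [], []
    for ob in dataset.observations:
        if ob.dose > 0 and fa_eps < ob.fa < 1.0 - fa_eps:
            retained.append(ob)
        else:
            excluded.append(ob)
    if len(retained) < 3:
        raise FitInfeasibleError(
            f"only {len(retained)} observation(s) usable for agent "
            f"{dataset.agent_id!r} in experiment {dataset.experiment_id!r} "
            f"(need >= 3); excluded: "
            + ", ".join(f"(dose={o.dose:g}, fa={o.fa:g})" for o in excluded),
            excluded=excluded,
        )
    x = np.log10([ob.dose for ob in retained])
    y = np.log10([ob.fa / ob.fu for ob in retained])
    return x, y, tuple(retained), tuple(excluded)


def fit_median_effect(
    dataset: DoseResponseDataset, fa_eps: float = FA_EPS
) -> MedianEffectModel:
    """Fit the median-effect line by unweighted OLS on the transformed plot.

    ``m`` is the slope; ``dm = 10 ** (-intercept / m)``, so that the
    predicted fa at the fitted dm is exactly 0.5.

    Raises
    ------
    FitInfeasibleError
        Fewer than 3 usable points, or all retained doses identical.
    ModelInvalidError
        Fitted slope <= 0 (no usable inhibition model).
    """
    x, y, retained, excluded = median_effect_transform(dataset, fa_eps=fa_eps)
    if np.ptp(x) == 0:
        raise FitInfeasibleError(
            f"all retained doses equal ({10 ** x[0]:g}) for agent "
            f"{dataset.agent_id!r}; slope is unidentifiable",
            excluded=excluded,
        )
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ModelInvalidError(
            f"fitted slope m={m:g} <= 0 for agent {dataset.agent_id!r}; "
            "dose inversion undefined"
        )
    dm = float(10.0 ** (-res.intercept / m))
    model = MedianEffectModel(dm=dm, m=m, r=float(res.rvalue),
                              n_fit=len(retained), excluded=excluded)
    if model.r < 0.90:
        logger.warning(
            "low correlation on median-effect plot: r=%.4f for agent %s "
            "(experiment %s)", model.r, dataset.agent_id,
            dataset.experiment_id,
        )
    return model


def predict_fa(model: MedianEffectModel, dose) -> float:
    """Fraction affected at ``dose``: fa = 1 / (1 + (dm / dose) ** m).

    Accepts a scalar or array dose; every dose must be > 0.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise DomainError("dose must be > 0")
    if not model.valid:
        raise ModelInvalidError(f"model slope m={model.m:g} <= 0")
    fa = 1.0 / (1.0 + (model.dm / dose) ** model.m)
    return float(fa) if fa.ndim == 0 else fa


def dose_for_fa(model: MedianEffectModel, fa) -> float:
    """Iso-effective dose producing ``fa``: D = dm * (fa / fu) ** (1 / m).

    Inverse of :func:`predict_fa`; requires 0 < fa < 1.
    """
    fa = np.asarray(fa, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise DomainError("fa must lie strictly in (0, 1)")
    if not model.valid:
        raise ModelInvalidError(f"model slope m={model.m:g} <= 0")
    dose = model.dm * (fa / (1.0 - fa)) ** (1.0 / model.m)
    return float(dose) if dose.ndim == 0 else dose
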