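"""Simulated pre/post score cohorts with controlled shape, correlation, shift.

The generator emulates repeated-measures data in which the same construct is
scored on n cases at two occasions.  Marginals are drawn from the Pearson
distribution system with unit variance and a chosen skewness/kurtosis; the
pre-post dependence is imposed through the Cholesky factor of the 2x2
correlation matrix; and a treatment effect is injected by shifting every post
score by ``delta * sigma_dif`` where ``sigma_dif = sqrt(2*(1 - rho))`` is the
population SD of the difference scores for unit-variance occasions.  Because
the shift is constant while pre and post are imperfectly correlated, each
case still experiences a different amount of change.

Control-group designs draw a second, independent cohort under the same
condition with no shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import pearson
from ._exceptions import DegenerateSampleError

__all__ = [
    "MomentSpec",
    "DesignCondition",
    "PairedSample",
    "TwoGroupSample",
    "SEVEN_SHAPES",
    "SHAPE_NAMES",
    "NORMAL",
    "sigma_dif",
    "sample_pearson_system",
    "impose_correlation",
    "inject_effect",
    "simulate_paired_sample",
    "simulate_two_group_sample",
]


@dataclass(frozen=True)
class MomentSpec:
    """Target first four moments of a marginal score distribution.

    ``excess_kurtosis`` follows the g2 convention (normal = 0).
    """

    mean: float = 0.0
    sd: float = 1.0
    skewness: float = 0.0
    excess_kurtosis: float = 0.0

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        pearson.check_feasibility(self.skewness, self.excess_kurtosis)

    @property
    def key(self) -> tuple[float, float]:
        """(skewness, excess_kurtosis) pair identifying the shape."""
        return (self.skewness, self.excess_kurtosis)


#: The seven marginal shapes of the study grid, from extreme negative to
#: extreme positive skewness.  Kurtosis co-varies with |skewness|.
SEVEN_SHAPES: tuple[MomentSpec, ...] = tuple(
    MomentSpec(0.0, 1.0, g1, g2)
    for g1, g2 in [(-3, 18), (-2, 9), (-1, 2), (0, 0), (1, 2), (2, 9), (3, 18)]
)

NORMAL = SEVEN_SHAPES[3]

#: Names for the grid shapes, usable anywhere a shape is selected by label.
SHAPE_NAMES: dict[str, MomentSpec] = {
    "extreme_negative": SEVEN_SHAPES[0],
    "moderate_negative": SEVEN_SHAPES[1],
    "mild_negative": SEVEN_SHAPES[2],
    "normal": NORMAL,
    "mild_positive": SEVEN_SHAPES[4],
    "moderate_positive": SEVEN_SHAPES[5],
    "extreme_positive": SEVEN_SHAPES[6],
}


def sigma_dif(rho: float) -> float:
    """Population SD of post - pre for unit-variance occasions: sqrt(2(1-rho))."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    return math.sqrt(2.0 * (1.0 - rho))


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the simulation grid.

    delta_exp is the standardized mean of pre-post differences injected into
    the experimental group, in sigma_dif units; the control group (when the
    design has one) always gets delta_ctrl = 0.
    """

    delta_exp: float
    n: int
    rho: float
    shape: MomentSpec = NORMAL
    design: str = "single_group"
    delta_ctrl: float = 0.0

    def __post_init__(self):
        if self.design not in ("single_group", "control_group"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if not np.isfinite(self.delta_exp):
            raise ValueError("delta_exp must be finite")

    @property
    def sigma_dif(self) -> float:
        return sigma_dif(self.rho)


@dataclass
class PairedSample:
    """Pre and post scores for one group of cases."""

    pre: np.ndarray
    post: np.ndarray
    case_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.ndim != 1 or self.post.ndim != 1:
            raise ValueError("pre and post must be 1-d vectors")
        if self.pre.shape != self.post.shape:
            raise ValueError(
                f"pre and post lengths differ: {self.pre.size} vs {self.post.size}"
            )
        if self.pre.size < 2:
            raise ValueError("a paired sample needs at least 2 cases")
        if self.case_ids is None:
            self.case_ids = np.arange(1, self.pre.size + 1)
        else:
            self.case_ids = np.asarray(self.case_ids)
            if self.case_ids.size != self.pre.size:
                raise ValueError("case_ids length must match scores")

    @property
    def n(self) -> int:
        return self.pre.size

    @property
    def differences(self) -> np.ndarray:
        """Per-case change scores, post - pre."""
        return self.post - self.pre


@dataclass
class TwoGroupSample:
    """Independent experimental and control cohorts from one condition."""

    experimental: PairedSample
    control: PairedSample


def sample_pearson_system(
    spec: MomentSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n iid scores from the Pearson-system member matching ``spec``."""
    return pearson.sample_pearson(
        spec.mean, spec.sd, spec.skewness, spec.excess_kurtosis, n, rng
    )


def impose_correlation(
    x_star: np.ndarray, y_star: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mix two independent vectors so their population correlation is rho.

    Applies the Cholesky factor of [[1, rho], [rho, 1]]: x is returned
    unchanged and y = rho*x + sqrt(1-rho^2)*y*.  For non-normal marginals the
    mixing slightly attenuates the skewness/kurtosis of y; this drift is
    accepted, not corrected.
    """
    x_star = np.asarray(x_star, dtype=float)
    y_star = np.asarray(y_star, dtype=float)
    if x_star.shape != y_star.shape:
        raise ValueError("x_star and y_star must have equal length")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    y = rho * x_star + math.sqrt(1.0 - rho**2) * y_star
    return x_star, y


def inject_effect(
    y: np.ndarray,
    delta: float,
    rho: float | None = None,
    sigma_dif_value: float | None = None,
) -> np.ndarray:
    """Shift post scores by ``delta`` times the SD of the differences.

    With ``rho`` the population value sqrt(2(1-rho)) is used (1 / 0.775 /
    0.447 for rho = 0.5 / 0.7 / 0.9).  ``sigma_dif_value`` overrides it with
    an explicit SD — the simulators pass the per-sample SD of the pre-shift
    differences, which adapts each generated sample to the desired
    standardized mean so that the realized d equals the baseline d plus
    delta exactly.
    """
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    if (rho is None) == (sigma_dif_value is None):
        raise ValueError("pass exactly one of rho or sigma_dif_value")
    scale = sigma_dif(rho) if sigma_dif_value is None else float(sigma_dif_value)
    if scale <= 0:
        raise ValueError(f"sigma_dif_value must be > 0, got {scale}")
    return np.asarray(y, dtype=float) + delta * scale


def simulate_paired_sample(
    cond: DesignCondition, rng: np.random.Generator
) -> PairedSample:
    """Generate one single-group cohort: sample marginals, correlate, shift.

    The shift is delta times the sample SD of the baseline differences, so
    every case changes by the same raw amount but the sample-standardized
    mean change is centered on delta.
    """
    x_star = sample_pearson_system(cond.shape, cond.n, rng)
    y_star = sample_pearson_system(cond.shape, cond.n, rng)
    pre, post = impose_correlation(x_star, y_star, cond.rho)
    if cond.delta_exp != 0.0:
        s_dif = float(np.std(post - pre, ddof=1))
        if s_dif <= 0.0:
            raise DegenerateSampleError(
                "baseline differences have zero variance; cannot standardize shift"
            )
        post = inject_effect(post, cond.delta_exp, sigma_dif_value=s_dif)
    return PairedSample(pre=pre, post=post)


def simulate_two_group_sample(
    cond: DesignCondition, rng: np.random.Generator
) -> TwoGroupSample:
    """Generate independent experimental and control cohorts.

    Both groups share n, rho and marginal shape; only the experimental group
    receives the mean shift (delta_ctrl is fixed at 0).
    """
    experimental = simulate_paired_sample(cond, rng)
    ctrl_cond = replace(cond, delta_exp=cond.delta_ctrl, design="single_group")
    control = simulate_paired_sample(ctrl_cond, rng)
    return TwoGroupSample(experimental=experimental, control=control)
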