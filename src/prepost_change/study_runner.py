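"""Orchestration of the full simulation study.

The study grid crosses 13 standardized effect sizes (0 to 3.6 in steps of
0.3), three sample sizes (25/50/100), three pre-post correlations
(0.5/0.7/0.9) and seven marginal shapes — 819 cells per design, 500 samples
each.  A *condition row* fixes (shape, rho, n, design) and pools all 13
effect sizes, so one row contributes 13 x reps (abc, ibc) pairs to which the
four link families are fit, mirroring one scatterplot of the study.

Randomness: a master seed spawns one independent, order-invariant stream per
condition row via ``numpy.random.SeedSequence([seed, design, shape, rho, n])``
hashed onto stable integer keys, so rows may be computed in any order (or
concurrently) with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._exceptions import DegenerateSampleError, FitError
from . import change_statistics as cs
from .link_models import FAMILIES, LinkFunctionFit, fit_link
from .synthetic_cohorts import (
    SEVEN_SHAPES,
    DesignCondition,
    MomentSpec,
    simulate_paired_sample,
    simulate_two_group_sample,
)

__all__ = [
    "DELTA_GRID",
    "StudyConfig",
    "ConditionResult",
    "StudyResult",
    "condition_seed_sequence",
    "run_condition",
    "run_study",
    "summarize_tables",
    "save_tables",
]

logger = logging.getLogger(__name__)

#: The 13 standardized effect sizes of the study grid.
DELTA_GRID: tuple[float, ...] = tuple(round(0.3 * k, 10) for k in range(13))

_DEFAULT_CUTOFF = {
    "single_group": (cs.ONE_TAILED_CUTOFF, "one"),
    "control_group": (cs.TWO_TAILED_CUTOFF, "two"),
}


@dataclass
class StudyConfig:
    """Full description of one study run; defaults reproduce the 819-cell
    grid with 500 samples per condition."""

    deltas: tuple = DELTA_GRID
    ns: tuple = (25, 50, 100)
    rhos: tuple = (0.5, 0.7, 0.9)
    shapes: tuple = SEVEN_SHAPES
    reps_per_condition: int = 500
    design: str = "single_group"
    index: str = "sid"
    cutoff: float | None = None  # None -> design default (1.645 / 1.96)
    tails: str | None = None  # None -> design default (one / two)
    seed: int = 0

    def __post_init__(self):
        self.deltas = tuple(float(d) for d in self.deltas)
        self.ns = tuple(int(n) for n in self.ns)
        self.rhos = tuple(float(r) for r in self.rhos)
        self.shapes = tuple(
            s if isinstance(s, MomentSpec) else MomentSpec(0.0, 1.0, *s)
            for s in self.shapes
        )
        if self.design not in ("single_group", "control_group"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.index not in ("sid", "rci"):
            raise ValueError(f"unknown index {self.index!r}")
        if self.reps_per_condition < 1:
            raise ValueError("reps_per_condition must be >= 1")

    @property
    def cutoff_rule(self) -> tuple[float, str]:
        default = _DEFAULT_CUTOFF[self.design]
        return (
            self.cutoff if self.cutoff is not None else default[0],
            self.tails if self.tails is not None else default[1],
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shapes"] = [(s.skewness, s.excess_kurtosis) for s in self.shapes]
        for key in ("deltas", "ns", "rhos"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ConditionResult:
    """All (abc, ibc) pairs and link fits for one condition row."""

    shape: MomentSpec
    rho: float
    n: int
    design: str
    index: str
    cutoff: float
    tails: str
    deltas: np.ndarray
    abc: np.ndarray  # one effect size per simulated sample
    ibc: np.ndarray  # one (net) percentage per simulated sample
    fits: dict[str, LinkFunctionFit] = field(default_factory=dict)
    n_redrawn: int = 0

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.abc, self.ibc])

    def key(self) -> tuple:
        return (self.shape.key, self.rho, self.n)


@dataclass
class StudyResult:
    config: StudyConfig
    conditions: dict[tuple, ConditionResult]
    elapsed_seconds: float = 0.0


def condition_seed_sequence(
    seed: int, design: str, shape: MomentSpec, rho: float, n: int
) -> np.random.SeedSequence:
    """Deterministic, execution-order-invariant stream for one condition row."""
    key = [
        int(seed),
        0 if design == "single_group" else 1,
        int(round(shape.skewness * 1000)) & 0x7FFFFFFF,
        int(round(shape.excess_kurtosis * 1000)) & 0x7FFFFFFF,
        int(round(rho * 1000)),
        int(n),
    ]
    return np.random.SeedSequence(key)


def _one_sample_pair(cond, index, cutoff, tails, rng):
    """(abc, ibc) for a single simulated sample of one grid cell."""
    if cond.design == "single_group":
        sample = simulate_paired_sample(cond, rng)
        abc = cs.cohens_d_dif(sample).value
        scores = cs.sid_scores(sample) if index == "sid" else cs.rci_scores(sample)
        labels = cs.classify_reliable_change(scores, cutoff, tails)
        ibc = cs.percent_reliable(labels).value
    else:
        sample = simulate_two_group_sample(cond, rng)
        abc = cs.interaction_omega_squared(sample).value
        if index == "sid":
            s_exp = cs.sid_scores(sample.experimental)
            s_ctrl = cs.sid_scores(sample.control)
        else:
            s_exp = cs.rci_scores(sample.experimental)
            s_ctrl = cs.rci_scores(sample.control)
        l_exp = cs.classify_reliable_change(s_exp, cutoff, tails)
        l_ctrl = cs.classify_reliable_change(s_ctrl, cutoff, tails)
        ibc = cs.net_percent(l_exp, l_ctrl).value
    return abc, ibc


def run_condition(
    cond: DesignCondition,
    reps: int = 500,
    index: str = "sid",
    cutoff_rule: tuple[float, str] | None = None,
    rng: np.random.Generator | None = None,
    deltas=None,
) -> ConditionResult:
    """Simulate one condition row and fit all four link families.

    ``cond`` supplies (shape, rho, n, design); the effect-size grid defaults
    to the 13 study values (``deltas`` overrides it, and ``cond.delta_exp``
    is only used when ``deltas`` is not given and equals a single cell).
    Degenerate samples (zero-variance differences, probability ~0 under
    continuous generation) are redrawn once and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if deltas is None:
        deltas = DELTA_GRID
    deltas = np.asarray(deltas, dtype=float)
    cutoff, tails = (
        cutoff_rule if cutoff_rule is not None else _DEFAULT_CUTOFF[cond.design]
    )
    if rng is None:
        rng = np.random.default_rng(
            condition_seed_sequence(0, cond.design, cond.shape, cond.rho, cond.n)
        )
    abc = np.empty(deltas.size * reps)
    ibc = np.empty_like(abc)
    n_redrawn = 0
    i = 0
    for delta in deltas:
        cell = dataclasses.replace(cond, delta_exp=float(delta))
        for _ in range(reps):
            try:
                pair = _one_sample_pair(cell, index, cutoff, tails, rng)
            except DegenerateSampleError:
                n_redrawn += 1
                logger.warning(
                    "degenerate sample redrawn (delta=%s, n=%s, rho=%s)",
                    delta,
                    cond.n,
                    cond.rho,
                )
                pair = _one_sample_pair(cell, index, cutoff, tails, rng)
            abc[i], ibc[i] = pair
            i += 1
    result = ConditionResult(
        shape=cond.shape,
        rho=cond.rho,
        n=cond.n,
        design=cond.design,
        index=index,
        cutoff=cutoff,
        tails=tails,
        deltas=deltas,
        abc=abc,
        ibc=ibc,
        n_redrawn=n_redrawn,
    )
    clip = (0.0, 100.0) if cond.design == "single_group" else (-100.0, 100.0)
    if abc.size < 2:
        logger.warning("only %d point(s); link fitting skipped", abc.size)
        return result
    for family in FAMILIES:
        try:
            result.fits[family] = fit_link(result.points, family, clip=clip)
        except FitError as exc:
            logger.warning("%s fit failed for %s: %s", family, result.key(), exc)
    return result


def run_study(config: StudyConfig) -> StudyResult:
    """Run every condition row of the grid (shapes x rhos x ns)."""
    start = time.perf_counter()
    conditions: dict[tuple, ConditionResult] = {}
    total = len(config.shapes) * len(config.rhos) * len(config.ns)
    done = 0
    for shape in config.shapes:
        for rho in config.rhos:
            for n in config.ns:
                cond = DesignCondition(
                    delta_exp=0.0, n=n, rho=rho, shape=shape, design=config.design
                )
                rng = np.random.default_rng(
                    condition_seed_sequence(config.seed, config.design, shape, rho, n)
                )
                try:
                    res = run_condition(
                        cond,
                        reps=config.reps_per_condition,
                        index=config.index,
                        cutoff_rule=config.cutoff_rule,
                        rng=rng,
                        deltas=config.deltas,
                    )
                except Exception:
                    logger.exception(
                        "condition row %s failed; continuing", (shape.key, rho, n)
                    )
                    continue
                conditions[res.key()] = res
                done += 1
                logger.info(
                    "condition %d/%d done (shape=%s, rho=%s, n=%s)",
                    done,
                    total,
                    shape.key,
                    rho,
                    n,
                )
    return StudyResult(
        config=config,
        conditions=conditions,
        elapsed_seconds=time.perf_counter() - start,
    )


def summarize_tables(result: StudyResult, n: int = 25) -> dict[str, pd.DataFrame]:
    """Aggregate tables at one sample size: R^2 by family, and linear
    coefficients with standard errors, keyed by shape x rho."""
    r2_rows, coef_rows = [], []
    for res in result.conditions.values():
        if res.n != n:
            continue
        base = {
            "skewness": res.shape.skewness,
            "excess_kurtosis": res.shape.excess_kurtosis,
            "rho": res.rho,
        }
        r2_rows.append(
            {
                **base,
                **{
                    fam: (res.fits[fam].r_squared if fam in res.fits else np.nan)
                    for fam in FAMILIES
                },
            }
        )
        if "linear" in res.fits:
            fit = res.fits["linear"]
            coef_rows.append(
                {
                    **base,
                    "b0": fit.coefficients[0],
                    "b0_se": fit.standard_errors[0],
                    "b1": fit.coefficients[1],
                    "b1_se": fit.standard_errors[1],
                    "r_squared": fit.r_squared,
                }
            )
    columns_r2 = ["skewness", "excess_kurtosis", "rho", *FAMILIES]
    columns_coef = [
        "skewness", "excess_kurtosis", "rho", "b0", "b0_se", "b1", "b1_se", "r_squared",
    ]
    sort = ["skewness", "excess_kurtosis", "rho"]
    r2 = pd.DataFrame(r2_rows, columns=columns_r2)
    coef = pd.DataFrame(coef_rows, columns=columns_coef)
    if not r2.empty:
        r2 = r2.sort_values(sort, ignore_index=True)
    if not coef.empty:
        coef = coef.sort_values(sort, ignore_index=True)
    return {"r_squared": r2, "linear_coefficients": coef}


def save_tables(result: StudyResult, outdir, n: int = 25) -> None:
    """Write CSV tables, per-condition fit JSON and run metadata to outdir."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "fits").mkdir(parents=True, exist_ok=True)
    tables = summarize_tables(result, n=n)
    tables["r_squared"].to_csv(outdir / "tables" / "r_squared.csv", index=False)
    tables["linear_coefficients"].to_csv(
        outdir / "tables" / "linear_coefficients.csv", index=False
    )
    coeff_json = {
        "design": result.config.design,
        "n": n,
        "rows": tables["linear_coefficients"].to_dict(orient="records"),
    }
    with open(outdir / "tables" / "linear_coefficients.json", "w") as fh:
        json.dump(coeff_json, fh, indent=2)
    for key, res in result.conditions.items():
        name = f"shape{key[0][0]:+g}_{key[0][1]:+g}_rho{key[1]:g}_n{key[2]}.json"
        with open(outdir / "fits" / name, "w") as fh:
            json.dump(
                {
                    "condition": {
                        "skewness": res.shape.skewness,
                        "excess_kurtosis": res.shape.excess_kurtosis,
                        "rho": res.rho,
                        "n": res.n,
                        "design": res.design,
                        "index": res.index,
                        "cutoff": res.cutoff,
                        "tails": res.tails,
                    },
                    "n_redrawn": res.n_redrawn,
                    "fits": {fam: fit.to_dict() for fam, fit in res.fits.items()},
                },
                fh,
                indent=2,
            )
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(
            {
                "config": result.config.to_dict(),
                "elapsed_seconds": result.elapsed_seconds,
                "n_conditions": len(result.conditions),
            },
            fh,
            indent=2,
        )
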