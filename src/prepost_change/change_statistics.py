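"""Average-based and individual-based change statistics for pre-post data.

Average-based change (ABC) statistics describe the shift of the distribution
center between the two occasions:

* ``d = (M_post - M_pre) / S_dif`` — the mean pre-post difference
  standardized by the sample SD of the difference scores (single group).
* Hays' omega-squared for the group x occasion interaction of the 2x2 mixed
  design, ``w2 = gl(F - 1) / (gl(F - 1) + N)`` with gl = 1 and N the total
  number of scores counting both groups and both occasions (control-group
  design).  Negative estimates (F < 1) are retained, not floored at zero.

Individual-based change (IBC) statistics classify each case and aggregate:

* SID (standardized individual difference): ``D_i / S_dif``.
* RCI (reliable change index, unequal-variance form):
  ``D_i / sqrt(S_pre^2 (1 - r) + S_post^2 (1 - r))`` where the reliability r
  defaults to the sample pre-post correlation.
* A case changes reliably when its index strictly exceeds the cutoff
  (1.645 one-tailed, +/-1.96 two-tailed by convention).
* The percentage of reliable improvements, or, with a control group, the net
  percentage ``(P+_exp - P-_exp) - (P+_ctrl - P-_ctrl)``.

All sample SDs use the n - 1 denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateSampleError
from .synthetic_cohorts import PairedSample, TwoGroupSample

__all__ = [
    "ChangeLabel",
    "AbcEstimate",
    "IbcEstimate",
    "cohens_d_dif",
    "interaction_omega_squared",
    "sid_scores",
    "rci_scores",
    "classify_reliable_change",
    "percent_reliable",
    "net_percent",
    "analytic_percentage_normal",
    "case_changes",
    "ONE_TAILED_CUTOFF",
    "TWO_TAILED_CUTOFF",
]

#: Default cutoffs: one-tailed for single-group designs, two-tailed when a
#: control group makes worsening as relevant as improvement.
ONE_TAILED_CUTOFF = 1.645
TWO_TAILED_CUTOFF = 1.96


class ChangeLabel(str, enum.Enum):
    """Per-case reliable-change classification."""

    IMPROVEMENT = "reliable_improvement"
    WORSENING = "reliable_worsening"
    NO_CHANGE = "no_reliable_change"


@dataclass(frozen=True)
class AbcEstimate:
    """An average-based change estimate plus its defining components."""

    statistic: str  # "d" | "omega_squared"
    value: float
    components: dict


@dataclass(frozen=True)
class IbcEstimate:
    """An individual-based change estimate plus its defining components."""

    statistic: str  # "percent" | "net_percent"
    value: float
    components: dict


def _sd_dif(sample: PairedSample) -> float:
    s = float(np.std(sample.differences, ddof=1))
    if s <= 0.0 or not np.isfinite(s):
        raise DegenerateSampleError(
            "the pre-post differences have zero variance; d and SID are undefined"
        )
    return s


def cohens_d_dif(sample: PairedSample) -> AbcEstimate:
    """Standardized mean pre-post difference, d = (M_post - M_pre) / S_dif."""
    s_dif = _sd_dif(sample)
    m_pre = float(np.mean(sample.pre))
    m_post = float(np.mean(sample.post))
    return AbcEstimate(
        statistic="d",
        value=(m_post - m_pre) / s_dif,
        components={"M_pre": m_pre, "M_post": m_post, "S_dif": s_dif},
    )


def interaction_omega_squared(sample: TwoGroupSample) -> AbcEstimate:
    """Hays' omega-squared for the group x occasion interaction.

    For the 2x2 mixed design the interaction F equals the one-way ANOVA F
    (i.e. the squared independent-samples t) comparing the difference scores
    of the two groups.  N counts every score in the design: both groups and
    both occasions.
    """
    d_exp = sample.experimental.differences
    d_ctrl = sample.control.differences
    n1, n2 = d_exp.size, d_ctrl.size
    ss_within = float(
        np.sum((d_exp - d_exp.mean()) ** 2) + np.sum((d_ctrl - d_ctrl.mean()) ** 2)
    )
    if ss_within <= 0.0:
        raise DegenerateSampleError(
            "difference scores have zero within-group variance; F is undefined"
        )
    # The factor 1/2 converts the difference-score contrast to the
    # interaction contrast of the full design (diff = post - pre involves
    # both occasions), but it cancels in the F ratio.
    ms_within = ss_within / (n1 + n2 - 2)
    ss_between = (
        n1 * n2 / (n1 + n2) * (float(d_exp.mean()) - float(d_ctrl.mean())) ** 2
    )
    f_ab = ss_between / ms_within
    gl_ab = 1
    n_scores = 2 * (n1 + n2)
    value = gl_ab * (f_ab - 1.0) / (gl_ab * (f_ab - 1.0) + n_scores)
    return AbcEstimate(
        statistic="omega_squared",
        value=value,
        components={"F_AB": f_ab, "gl_AB": gl_ab, "N": n_scores},
    )


def sid_scores(sample: PairedSample) -> np.ndarray:
    """Standardized individual differences, D_i / S_dif."""
    return sample.differences / _sd_dif(sample)


def rci_scores(sample: PairedSample, reliability: float | None = None) -> np.ndarray:
    """Reliable change index, unequal-variance standard-error form.

    ``reliability`` defaults to the sample pre-post Pearson correlation,
    which yields the lowest false-positive rate among common choices.
    """
    s_pre = float(np.std(sample.pre, ddof=1))
    s_post = float(np.std(sample.post, ddof=1))
    if s_pre <= 0.0 or s_post <= 0.0:
        raise DegenerateSampleError(
            "pre or post scores have zero variance; the RCI is undefined"
        )
    if reliability is None:
        reliability = float(np.corrcoef(sample.pre, sample.post)[0, 1])
    if not reliability < 1.0:
        raise ValueError(f"reliability must be < 1, got {reliability}")
    denom = np.sqrt((s_pre**2 + s_post**2) * (1.0 - reliability))
    if denom <= 0.0 or not np.isfinite(denom):
        raise DegenerateSampleError("RCI standard error is zero or non-finite")
    return sample.differences / denom


def classify_reliable_change(
    index_values: np.ndarray, cutoff: float, tails: str
) -> np.ndarray:
    """Label each index value; values exactly at the cutoff do not count.

    One-tailed tests only flag improvements (the study injects positive
    effects); two-tailed tests flag both directions at +/-cutoff.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    values = np.asarray(index_values, dtype=float)
    # np.full would coerce the str-enum into a truncated unicode array
    labels = np.empty(values.shape, dtype=object)
    labels[:] = ChangeLabel.NO_CHANGE
    labels[values > cutoff] = ChangeLabel.IMPROVEMENT
    if tails == "two":
        labels[values < -cutoff] = ChangeLabel.WORSENING
    return labels


def _proportions(labels: np.ndarray) -> tuple[float, float]:
    labels = np.asarray(labels, dtype=object).ravel()
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    # explicit loop: numpy broadcasting mishandles str-subclass enum scalars
    n_up = sum(1 for lab in labels if ChangeLabel(lab) is ChangeLabel.IMPROVEMENT)
    n_down = sum(1 for lab in labels if ChangeLabel(lab) is ChangeLabel.WORSENING)
    return 100.0 * n_up / labels.size, 100.0 * n_down / labels.size


def percent_reliable(labels: np.ndarray) -> IbcEstimate:
    """Percentage of cases labelled as reliable improvements."""
    p_up, p_down = _proportions(labels)
    return IbcEstimate(
        statistic="percent", value=p_up, components={"P+": p_up, "P-": p_down}
    )


def net_percent(exp_labels: np.ndarray, ctrl_labels: np.ndarray) -> IbcEstimate:
    """Net percentage of changes attributable to treatment.

    ``(P+_exp - P-_exp) - (P+_ctrl - P-_ctrl)``; the raw value can range over
    [-200, 200] and is recorded unclipped.
    """
    pe_up, pe_down = _proportions(exp_labels)
    pc_up, pc_down = _proportions(ctrl_labels)
    value = (pe_up - pe_down) - (pc_up - pc_down)
    return IbcEstimate(
        statistic="net_percent",
        value=value,
        components={
            "P+_exp": pe_up,
            "P-_exp": pe_down,
            "P+_ctrl": pc_up,
            "P-_ctrl": pc_down,
        },
    )


def analytic_percentage_normal(delta: float, cutoff: float) -> float:
    """Expected percentage of index values above the cutoff for normal
    differences with known sigma: 100 * (1 - Phi(cutoff - delta)).

    Serves as the closed-form oracle for percent_reliable in the normal,
    known-variance limit (e.g. 5.0% at delta = 0, cutoff = 1.645).
    """
    return 100.0 * float(stats.norm.sf(cutoff - delta))


def case_changes(
    sample: PairedSample,
    index: str = "sid",
    cutoff: float = ONE_TAILED_CUTOFF,
    tails: str = "one",
    reliability: float | None = None,
) -> pd.DataFrame:
    """Per-case change table: difference, SID, RCI and the reliable-change
    label from the chosen index and cutoff rule."""
    if index not in ("sid", "rci"):
        raise ValueError(f"index must be 'sid' or 'rci', got {index!r}")
    sid = sid_scores(sample)
    rci = rci_scores(sample, reliability=reliability)
    chosen = sid if index == "sid" else rci
    labels = classify_reliable_change(chosen, cutoff, tails)
    return pd.DataFrame(
        {
            "case_id": sample.case_ids,
            "pre": sample.pre,
            "post": sample.post,
            "difference": sample.differences,
            "sid": sid,
            "rci": rci,
            "label": [lab.value for lab in labels],
        }
    )
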