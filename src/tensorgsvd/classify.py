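"""Patient stratification from a selected subtensor.

Discovery-set patients are split into high/low groups by their x-probelet
coefficients, using a robust cutoff of ``median + k * sMAD`` (k = 0.5 by
default), where sMAD is the standardized median absolute deviation.
Validation-set patients — profiled on possibly different probes — are split
by the Spearman rank correlation of their profiles with the first arraylet,
using the same rule on the correlations.  A classification is *robust* when
the two groups have significantly different survival at every cutoff in a
band of +/-0.1 sMAD around the nominal one.  Three binomial classifications
(e.g. across different chromosome arms) combine into prognostic groups A/B/C
by Hamming distance from the favorable label triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import logrank

__all__ = [
    "smad",
    "classify_by_probelet",
    "classify_by_arraylet_correlation",
    "robustness_scan",
    "platform_consistency",
    "combine_groups",
    "ClassificationResult",
]

#: Consistency constant making the MAD estimate the standard deviation of a
#: normal distribution (1 / Phi^{-1}(3/4)).
NORMAL_CONSISTENCY = 1.4826022185056018


def smad(v: np.ndarray, constant: float = NORMAL_CONSISTENCY) -> float:
    """Standardized median absolute deviation: ``constant * median(|v - median(v)|)``.

    Translation-invariant robust scale; returns 0 for a constant vector.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(constant * np.median(np.abs(v - np.median(v))))


@dataclass
class ClassificationResult:
    """Per-patient high/low stratification.

    ``scores`` are x-probelet coefficients (discovery) or Spearman arraylet
    correlations (validation); ``labels`` are 'high'/'low' by comparison with
    ``cutoff``; ``direction`` states which label is hypothesized favorable.
    ``robust`` is None until :func:`robustness_scan` fills it in.
    """

    patient_ids: tuple
    scores: np.ndarray
    labels: np.ndarray
    cutoff: float
    direction: str = "low"
    robust: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.patient_ids), "score": self.scores, "label": self.labels}
        )


def _threshold_labels(scores: np.ndarray, k: float):
    scale = smad(scores)
    if scale == 0:
        raise ValueError("scores have zero sMAD; cannot threshold a constant vector")
    cutoff = float(np.median(scores) + k * scale)
    labels = np.where(scores > cutoff, "high", "low")
    return labels, cutoff


def classify_by_probelet(
    coeffs: np.ndarray,
    patient_ids=None,
    k: float = 0.5,
    direction: str = "low",
) -> ClassificationResult:
    """Split patients at ``median + k * sMAD`` of their probelet coefficients.

    One-sided rule: 'high' means the coefficient exceeds the cutoff; everyone
    else is 'low'.  ``direction`` records which label is hypothesized
    favorable for survival (e.g. 'low' when a high coefficient tracks a
    tumor-exclusive alteration pattern).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 1 or coeffs.size < 2:
        raise ValueError("coeffs must be a 1-D vector of at least two patients")
    labels, cutoff = _threshold_labels(coeffs, k)
    if patient_ids is None:
        patient_ids = tuple(f"patient{i + 1}" for i in range(coeffs.size))
    return ClassificationResult(
        patient_ids=tuple(str(p) for p in patient_ids),
        scores=coeffs,
        labels=labels,
        cutoff=cutoff,
        direction=direction,
    )


def classify_by_arraylet_correlation(
    profiles: pd.DataFrame,
    arraylet: pd.Series,
    k: float = 0.5,
    min_shared_probes: int = 10,
    direction: str = "low",
) -> ClassificationResult:
    """Classify validation patients by Spearman correlation with an arraylet.

    ``profiles`` is a probes x patients frame (probe ids as index); the
    arraylet is a per-probe series.  Correlations are computed on the shared
    probes (at least ``min_shared_probes`` required) and thresholded with the
    same median + k*sMAD rule as the discovery classification.
    """
    profiles = pd.DataFrame(profiles)
    arraylet = pd.Series(arraylet)
    shared = profiles.index.intersection(arraylet.index)
    if len(shared) < min_shared_probes:
        raise ValueError(
            f"only {len(shared)} probes shared between profiles and arraylet; "
            f"need at least {min_shared_probes}"
        )
    sub = profiles.loc[shared].to_numpy(dtype=float)
    ref = stats.rankdata(arraylet.loc[shared].to_numpy(dtype=float))
    ranks = stats.rankdata(sub, axis=0)
    ref_c = ref - ref.mean()
    ranks_c = ranks - ranks.mean(axis=0)
    denom = np.linalg.norm(ranks_c, axis=0) * np.linalg.norm(ref_c)
    if np.any(denom == 0):
        raise ValueError("a profile or the arraylet is constant on the shared probes")
    corr = ranks_c.T @ ref_c / denom
    labels, cutoff = _threshold_labels(corr, k)
    return ClassificationResult(
        patient_ids=tuple(str(c) for c in profiles.columns),
        scores=corr,
        labels=labels,
        cutoff=cutoff,
        direction=direction,
    )


def robustness_scan(
    coeffs: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    k: float = 0.5,
    halfwidth: float = 0.1,
    step: float = 0.02,
    alpha: float = 0.05,
    min_group_size: int = 2,
):
    """Log-rank significance across a band of cutoffs around ``median + k*sMAD``.

    The classification is *robust* when the two groups differ significantly
    (log-rank p < ``alpha``) at every cutoff ``median + (k + d) * sMAD`` for
    ``d`` in ``[-halfwidth, +halfwidth]`` stepped by ``step``.  A cutoff
    leaving fewer than ``min_group_size`` patients in either group is
    non-evaluable and makes the scan non-robust.

    Returns
    -------
    robust : bool
    table : pandas.DataFrame
        Columns ``k``, ``cutoff``, ``n_high``, ``n_low``, ``p``, ``evaluable``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not (coeffs.size == time.size == event.size):
        raise ValueError("coeffs, time and event must be aligned")
    scale = smad(coeffs)
    if scale == 0:
        raise ValueError("scores have zero sMAD")
    med = np.median(coeffs)
    n_steps = int(round(halfwidth / step))
    offsets = np.arange(-n_steps, n_steps + 1) * step
    rows = []
    robust = True
    for d in offsets:
        cutoff = med + (k + d) * scale
        high = coeffs > cutoff
        n_high, n_low = int(high.sum()), int((~high).sum())
        if min(n_high, n_low) < min_group_size:
            rows.append((k + d, cutoff, n_high, n_low, np.nan, False))
            robust = False
            continue
        res = logrank(time, event, high.astype(int))
        rows.append((k + d, cutoff, n_high, n_low, res.p_value, True))
        if not res.p_value < alpha:
            robust = False
    table = pd.DataFrame(
        rows, columns=["k", "cutoff", "n_high", "n_low", "p", "evaluable"]
    )
    return robust, table


def platform_consistency(y_probelet: np.ndarray, tol: float = 0.15) -> bool:
    """Whether a y-probelet has approximately equal entries across platforms.

    True iff the maximal pairwise relative difference
    ``|y_i - y_j| / max(|y_i|, |y_j|)`` is at most ``tol``.  The tolerance is
    a configurable package default; equality across platforms means the
    pattern is platform-consistent rather than a platform artifact.
    """
    y = np.asarray(y_probelet, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two platforms")
    diff = np.abs(y[:, None] - y[None, :])
    scale = np.maximum(np.abs(y)[:, None], np.abs(y)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(scale > 0, diff / scale, 0.0)
    return bool(np.max(rel) <= tol)


def combine_groups(
    labels_arm1,
    labels_arm2,
    labels_arm3,
    favorable: tuple = ("low", "high", "high"),
) -> np.ndarray:
    """Combine three binomial classifications into prognostic groups A/B/C.

    A: the patient's label triple matches the favorable triple exactly.
    B: exactly one of the three labels differs (3 of the 8 triples).
    C: at least two differ (the remaining 4 triples).
    """
    arms = [np.asarray(a, dtype=object) for a in (labels_arm1, labels_arm2, labels_arm3)]
    n = arms[0].size
    if any(a.size != n for a in arms):
        raise ValueError("the three labelings must be aligned")
    for a in arms:
        bad = ~np.isin(a, ("high", "low"))
        if bad.any():
            raise ValueError(
                f"missing or invalid label at patient index {int(np.flatnonzero(bad)[0])}"
            )
    if len(favorable) != 3 or any(f not in ("high", "low") for f in favorable):
        raise ValueError("favorable must be a triple of 'high'/'low'")
    mismatches = sum((a != f).astype(int) for a, f in zip(arms, favorable))
    return np.array(["A", "B", "C"])[np.minimum(mismatches, 2)]
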