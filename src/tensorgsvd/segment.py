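"""Segmentation of an arraylet into constant copy-number segments.

A per-probe pattern, ordered by genomic position, is partitioned by recursive
binary splitting: at each step the candidate breakpoint maximizes the
two-sample t-statistic between the left and right parts, and the split is
accepted when a seeded permutation test (shuffling the probe values within
the segment) yields a p-value below ``alpha``.  This is a deliberately
simplified stand-in for full circular binary segmentation: same interface,
simpler internals.  Accepted segments are called amplified / deleted /
neutral against a baseline, flagged *focal* when shorter than 125 probes, and
scored for the fraction of patients carrying the alteration ("frequent" when
above 23%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import smad

__all__ = [
    "Segment",
    "segment",
    "call_segments",
    "focal_filter",
    "segment_frequency",
    "FOCAL_MAX_PROBES",
    "FREQUENT_FRACTION",
]

#: A called segment is focal when it spans strictly fewer probes than this.
FOCAL_MAX_PROBES = 125
#: A CNA is frequent when carried by strictly more than this patient fraction.
FREQUENT_FRACTION = 0.23


@dataclass(frozen=True)
class Segment:
    """Contiguous probe interval (1-based inclusive) with its mean level."""

    start_probe: int
    end_probe: int
    mean_level: float
    call: str = "uncalled"  # amplified | deleted | neutral | uncalled
    focal: bool = False

    @property
    def n_probes(self) -> int:
        return self.end_probe - self.start_probe + 1


def _max_t_split(x: np.ndarray):
    """Best breakpoint by two-sample t-statistic, vectorized over all splits.

    Returns (index i splitting into x[:i] / x[i:], |t| at that split).  An
    exactly-fitting split of a noiseless step has zero pooled variance and
    infinite t.
    """
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    i = np.arange(1, n)
    n1, n2 = i, n - i
    sum1, sum2 = cs[:-1], cs[-1] - cs[:-1]
    m1, m2 = sum1 / n1, sum2 / n2
    ss1 = cs2[:-1] - sum1 * m1
    ss2 = (cs2[-1] - cs2[:-1]) - sum2 * m2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / np.maximum(n - 2, 1)
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    t = np.where(diff == 0, 0.0, t)
    t = np.where((diff > 0) & ~np.isfinite(t), np.inf, t)
    j = int(np.argmax(t))
    return j + 1, float(t[j])


def _perm_pvalue(x: np.ndarray, t_obs: float, n_perm: int, rng) -> float:
    """Permutation p-value of the maximal split statistic."""
    perms = rng.permuted(np.broadcast_to(x, (n_perm, x.size)), axis=1)
    n = x.size
    cs = np.cumsum(perms, axis=1)
    cs2 = np.cumsum(perms * perms, axis=1)
    i = np.arange(1, n)
    n1, n2 = i, n - i
    sum1 = cs[:, :-1]
    sum2 = cs[:, -1:] - sum1
    m1, m2 = sum1 / n1, sum2 / n2
    ss1 = cs2[:, :-1] - sum1 * m1
    ss2 = (cs2[:, -1:] - cs2[:, :-1]) - sum2 * m2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ss1 + ss2) / max(n - 2, 1)
        t = np.abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    t = np.where(diff == 0, 0.0, t)
    t = np.where((diff > 0) & ~np.isfinite(t), np.inf, t)
    t_max = t.max(axis=1)
    return (1.0 + float(np.sum(t_max >= t_obs))) / (1.0 + n_perm)


def segment(
    arraylet: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 2,
) -> list[Segment]:
    """Recursive binary segmentation with a seeded permutation test.

    Splits a segment at the breakpoint maximizing the two-sample t-statistic
    whenever the permutation p-value of that statistic (over ``n_perm``
    within-segment shuffles) is below ``alpha``; recurses on both sides.
    Deterministic for a fixed ``seed``.  Returned segments tile the input
    contiguously in order.
    """
    x = np.asarray(arraylet, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("arraylet must be a 1-D vector of at least two probes")
    rng = np.random.default_rng(seed)
    out: list[Segment] = []

    def _recurse(lo: int, hi: int) -> None:  # [lo, hi) 0-based
        seg = x[lo:hi]
        n = hi - lo
        if n >= 2 * min_size and np.ptp(seg) > 0:
            split, t_obs = _max_t_split(seg)
            p = _perm_pvalue(seg, t_obs, n_perm, rng)
            if p < alpha:
                _recurse(lo, lo + split)
                _recurse(lo + split, hi)
                return
        out.append(
            Segment(start_probe=lo + 1, end_probe=hi, mean_level=float(seg.mean()))
        )

    _recurse(0, x.size)
    return out


def call_segments(
    segments: list[Segment],
    arraylet: np.ndarray,
    baseline: float = 0.0,
    delta: float | None = None,
) -> list[Segment]:
    """Call each segment amplified / deleted / neutral against ``baseline``.

    A segment is amplified when its mean level exceeds ``baseline + delta``
    and deleted when below ``baseline - delta``.  ``delta`` defaults to one
    robust standard deviation (sMAD) of the whole arraylet.  The focal flag
    is set for non-neutral segments spanning fewer than 125 probes.
    """
    if delta is None:
        delta = smad(np.asarray(arraylet, dtype=float))
    called = []
    for s in segments:
        if s.mean_level > baseline + delta:
            call = "amplified"
        elif s.mean_level < baseline - delta:
            call = "deleted"
        else:
            call = "neutral"
        called.append(
            replace(s, call=call, focal=(call != "neutral" and s.n_probes < FOCAL_MAX_PROBES))
        )
    return called


def focal_filter(segments: list[Segment]) -> list[Segment]:
    """Non-neutral segments spanning strictly fewer than 125 probes."""
    return [s for s in segments if s.call != "neutral" and s.n_probes < FOCAL_MAX_PROBES]


def segment_frequency(
    profiles: np.ndarray,
    seg: Segment,
    delta: float,
    baseline: float = 0.0,
    frequent_fraction: float = FREQUENT_FRACTION,
):
    """Fraction of patients altered over a called segment.

    A patient counts as altered when their mean copy number over the
    segment's probes exceeds ``baseline + delta`` (amplified segment) or
    falls below ``baseline - delta`` (deleted segment).

    Returns ``(fraction, frequent)`` where ``frequent`` is True when the
    fraction strictly exceeds ``frequent_fraction``.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a probes x patients matrix")
    if seg.start_probe < 1 or seg.end_probe > profiles.shape[0]:
        raise ValueError(
            f"segment [{seg.start_probe}, {seg.end_probe}] outside the "
            f"{profiles.shape[0]}-probe range"
        )
    if seg.call not in ("amplified", "deleted"):
        raise ValueError("segment must be called amplified or deleted")
    means = profiles[seg.start_probe - 1 : seg.end_probe].mean(axis=0)
    if seg.call == "amplified":
        altered = means > baseline + delta
    else:
        altered = means < baseline - delta
    fraction = float(altered.mean())
    return fraction, fraction > frequent_fraction
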