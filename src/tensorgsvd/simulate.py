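"""Synthetic paired tumor/normal copy-number cohorts with planted structure.

The generator emulates the structure of patient- and platform-matched but
probe-independent copy-number datasets: two tensors of K1 (tumor) and K2
(normal) probes x L patients x M platforms, each a sum of planted rank-1
patterns plus i.i.d. Gaussian noise.  A planted pattern is

    amplitude * (probe shape) (o) (carrier indicator) (o) (platform weights)

where the probe shape is piecewise constant over genomic blocks (so the
segmentation machinery has recoverable truth), the carrier indicator marks a
random patient subset, and the platform weights are equal by default
(platform-consistent).  Patterns can be planted tumor-exclusively (dataset 1
only), in both datasets ("common", e.g. a germline pattern carried by a
patient subset), or normal-exclusively.  Survival times for carriers follow
a proportional-hazards model with an exponential baseline and independent
uniform censoring.

Defaults describe a realistic desk-scale cohort: 500 tumor and 480 normal
probes, 60 patients, 2 platforms, 30% carriers, per-probe alteration levels
of about +/-0.5 (typical log-ratio magnitudes), noise sd 0.1, planted hazard
ratio 2 and a 40-month baseline median survival.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tensor import ThirdOrderTensor

__all__ = [
    "PlantedPattern",
    "SyntheticConfig",
    "PlantedTruth",
    "generate_pair",
    "generate_clinical",
    "generate_probe_annotation",
    "default_config",
]


@dataclass(frozen=True)
class PlantedPattern:
    """Specification of one planted rank-1 pattern.

    ``blocks`` lists ``(start_frac, end_frac, level)`` triples: constant
    copy-number levels over fractional probe intervals (half-open, as
    fractions of the probe dimension).  ``carrier_fraction`` of the patients
    carry the pattern; ``platform_weights`` scale it per platform.
    """

    name: str
    blocks: tuple = ((0.1, 0.5, 0.5), (0.6, 0.8, -0.4))
    carrier_fraction: float = 0.3
    platform_weights: tuple = (1.0, 1.0)
    amplitude: float = 1.0

    def probe_shape(self, n_probes: int) -> np.ndarray:
        shape = np.zeros(n_probes)
        for start, end, level in self.blocks:
            shape[int(round(start * n_probes)) : int(round(end * n_probes))] = level
        return shape


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic paired cohort."""

    K1: int = 500
    K2: int = 480
    L: int = 60
    M: int = 2
    planted_exclusive: tuple = (PlantedPattern(name="tumor_exclusive"),)
    planted_common: tuple = ()
    planted_normal_exclusive: tuple = ()
    noise_sd: float = 0.1
    hazard_ratio: float = 2.0
    baseline_median_months: float = 40.0
    censoring_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.K1 < self.L * self.M or self.K2 < self.L * self.M:
            raise ValueError("probe dimensions must satisfy K_i >= L*M")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        for p in (
            *self.planted_exclusive,
            *self.planted_common,
            *self.planted_normal_exclusive,
        ):
            if not 0 < p.carrier_fraction < 1:
                raise ValueError(f"pattern {p.name}: carrier fraction must be in (0,1)")
            if len(p.platform_weights) != self.M:
                raise ValueError(f"pattern {p.name}: needs {self.M} platform weights")


def default_config(**overrides) -> SyntheticConfig:
    """The package's reference study conditions (see module docstring)."""
    return replace(SyntheticConfig(), **overrides)


@dataclass
class PlantedTruth:
    """Record of everything planted, keyed by pattern name."""

    shapes1: dict
    shapes2: dict
    carriers: dict
    weights: dict
    amplitudes: dict
    exclusive_to: dict  # pattern name -> 1, 2 or 0 (common)


def generate_pair(cfg: SyntheticConfig):
    """Generate the tumor/normal tensor pair and the planted-truth record.

    Deterministic for a fixed ``cfg.seed``.  Returns ``(d1, d2, truth)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    K1, K2, L, M = cfg.K1, cfg.K2, cfg.L, cfg.M
    v1 = np.zeros((K1, L, M))
    v2 = np.zeros((K2, L, M))
    truth = PlantedTruth({}, {}, {}, {}, {}, {})

    # Carrier subsets for distinct patterns are drawn disjointly while
    # patients remain, so each planted pattern excites its own patient
    # direction and stays identifiable in the decomposition.
    available = list(range(L))

    def _plant(pattern: PlantedPattern, where: int) -> None:
        n_car = max(1, int(round(pattern.carrier_fraction * L)))
        carriers = np.zeros(L, dtype=bool)
        if n_car <= len(available):
            chosen = rng.choice(len(available), size=n_car, replace=False)
            idx = [available[j] for j in chosen]
            for j in sorted(chosen, reverse=True):
                del available[j]
        else:
            idx = rng.choice(L, size=n_car, replace=False)
        carriers[np.asarray(idx)] = True
        w = np.asarray(pattern.platform_weights, dtype=float)
        truth.carriers[pattern.name] = carriers
        truth.weights[pattern.name] = w
        truth.amplitudes[pattern.name] = pattern.amplitude
        truth.exclusive_to[pattern.name] = where
        if where in (1, 0):
            s1 = pattern.probe_shape(K1)
            truth.shapes1[pattern.name] = s1
            v1[...] += pattern.amplitude * np.einsum("k,l,m->klm", s1, carriers.astype(float), w)
        if where in (2, 0):
            s2 = pattern.probe_shape(K2)
            truth.shapes2[pattern.name] = s2
            v2[...] += pattern.amplitude * np.einsum("k,l,m->klm", s2, carriers.astype(float), w)

    for p in cfg.planted_exclusive:
        _plant(p, 1)
    for p in cfg.planted_common:
        _plant(p, 0)
    for p in cfg.planted_normal_exclusive:
        _plant(p, 2)

    if cfg.noise_sd > 0:
        v1 += rng.normal(0.0, cfg.noise_sd, v1.shape)
        v2 += rng.normal(0.0, cfg.noise_sd, v2.shape)

    patient_ids = tuple(f"patient{j + 1}" for j in range(L))
    platform_ids = tuple(f"platform{j + 1}" for j in range(M))
    d1 = ThirdOrderTensor(
        v1,
        probe_ids=tuple(f"t_probe{j + 1}" for j in range(K1)),
        patient_ids=patient_ids,
        platform_ids=platform_ids,
    )
    d2 = ThirdOrderTensor(
        v2,
        probe_ids=tuple(f"n_probe{j + 1}" for j in range(K2)),
        patient_ids=patient_ids,
        platform_ids=platform_ids,
    )
    return d1, d2, truth


def _uniform_censor_horizon(hazards: np.ndarray, target: float) -> float:
    """Horizon tau of Uniform(0, tau) censoring hitting the target rate.

    For exponential event times with rate h, censoring by C ~ U(0, tau) is
    P(C < T) = (1 - exp(-h*tau)) / (h*tau); solve the patient-average for tau.
    """

    def mean_censor(tau):
        x = hazards * tau
        return float(np.mean((1.0 - np.exp(-x)) / x)) - target

    lo, hi = 1e-9, 1e9
    return brentq(mean_censor, lo, hi, xtol=1e-10, rtol=1e-12)


def generate_clinical(
    carrier: np.ndarray,
    cfg: SyntheticConfig,
    seed: int | None = None,
    patient_ids=None,
    extra_covariate: np.ndarray | None = None,
    extra_hazard_ratio: float = 1.0,
) -> pd.DataFrame:
    """Survival table for a patient set with a planted carrier hazard ratio.

    Event times are exponential with baseline rate ``log 2 / baseline
    median``; carriers' hazard is multiplied by ``cfg.hazard_ratio`` (and
    optionally by ``extra_hazard_ratio`` for an independent second
    covariate).  Censoring is independent Uniform(0, tau) with tau solved to
    achieve approximately ``cfg.censoring_rate``.

    Returns a DataFrame with patient_id, time_months, event, carrier (and
    the extra covariate when given).
    """
    carrier = np.asarray(carrier, dtype=bool)
    n = carrier.size
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base = np.log(2.0) / cfg.baseline_median_months
    hazards = base * np.where(carrier, cfg.hazard_ratio, 1.0)
    if extra_covariate is not None:
        extra = np.asarray(extra_covariate, dtype=float)
        hazards = hazards * extra_hazard_ratio**extra
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate > 0:
        tau = _uniform_censor_horizon(hazards, cfg.censoring_rate)
        t_cens = rng.uniform(0.0, tau, size=n)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
    else:
        time, event = t_event, np.ones(n, dtype=bool)
    if patient_ids is None:
        patient_ids = [f"patient{j + 1}" for j in range(n)]
    out = pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "time_months": time,
            "event": event.astype(int),
            "carrier": carrier.astype(int),
        }
    )
    if extra_covariate is not None:
        out["extra"] = np.asarray(extra_covariate)
    return out


def generate_probe_annotation(K: int, arms: list) -> pd.DataFrame:
    """Probe annotation table: probe_id, chromosome, arm, position.

    ``arms`` lists ``(arm_label, probe_count)`` pairs whose counts must sum
    to ``K``; positions are strictly increasing within each arm.
    """
    counts = [int(c) for _, c in arms]
    if sum(counts) != K:
        raise ValueError(f"arm probe counts sum to {sum(counts)}, expected {K}")
    rows = []
    i = 0
    for label, count in arms:
        chrom = str(label).rstrip("pq") or str(label)
        for j in range(count):
            rows.append((f"probe{i + 1}", chrom, str(label), (j + 1) * 1000))
            i += 1
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "arm", "position"])
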