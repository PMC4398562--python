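"""Tensor GSVD of two third-order tensors with matched column dimensions.

Two copy-number tensors ``D1`` (K1 probes x L patients x M platforms) and
``D2`` (K2 x L x M) share the patient and platform dimensions but have
independent probe dimensions.  The tensor GSVD factors both simultaneously::

    D_i = R_i x_a U_i x_b Vx x_c Vy          (i = 1, 2)

into L*M paired rank-1 "subtensors": outer products of one dataset-specific
probe pattern (an *arraylet*, a column of ``U_i``), one shared patient pattern
(an *x-probelet*, a row of ``Vx.T``) and one shared platform pattern (a
*y-probelet*, a row of ``Vy.T``), weighted by the core tensors ``R_i`` of
"tensor generalized singular values".

``U_i`` come from the GSVD of the row-mode unfoldings; ``Vx`` and ``Vy`` from
the GSVDs of the x- and y-mode unfoldings.  The relative significance of the
paired subtensors is an angular distance ``Theta`` that provably equals the
row-mode angular distance ``theta[a]`` wherever it is defined, so a single
number per arraylet pair separates dataset-1-exclusive (+pi/4), common (0)
and dataset-2-exclusive (-pi/4) patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .gsvd import MatrixGSVD, RankDeficiencyError, angular_distances, matrix_gsvd

__all__ = [
    "ThirdOrderTensor",
    "TensorGSVD",
    "TensorGSVDResults",
    "SubtensorIndex",
    "tensor_gsvd",
    "unfold_row",
    "unfold_x",
    "unfold_y",
    "fold_row",
    "significance",
    "tensor_angular_distance",
    "hosvd",
    "Hosvd",
    "load_factorization",
]


@dataclass(frozen=True)
class ThirdOrderTensor:
    """A K x L x M array of relative copy numbers with axis annotations.

    Axes are probes x patients x platforms.  Identifier lists are optional and
    default to 1-based positional labels.
    """

    values: np.ndarray
    probe_ids: tuple = None
    patient_ids: tuple = None
    platform_ids: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be a 3-D array (probes x patients x platforms)")
        if not np.isfinite(v).all():
            raise ValueError("tensor values must be finite")
        object.__setattr__(self, "values", v)
        k, l, m = v.shape
        for name, n, prefix in (
            ("probe_ids", k, "probe"),
            ("patient_ids", l, "patient"),
            ("platform_ids", m, "platform"),
        ):
            ids = getattr(self, name)
            if ids is None:
                ids = tuple(f"{prefix}{j + 1}" for j in range(n))
            else:
                ids = tuple(str(x) for x in ids)
                if len(ids) != n:
                    raise ValueError(f"{name} length {len(ids)} != axis length {n}")
                if len(set(ids)) != n:
                    raise ValueError(f"{name} contains duplicates")
            object.__setattr__(self, name, ids)

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _values(T) -> np.ndarray:
    return T.values if isinstance(T, ThirdOrderTensor) else np.asarray(T, dtype=float)


def unfold_row(T) -> np.ndarray:
    """Row-mode unfolding: K x (L*M), column index n = l*M + m (m fastest).

    This ordering makes the Kronecker identity
    ``unfold_row(D) = U @ unfold_row(R) @ kron(Vx.T, Vy.T)`` hold literally.
    """
    v = _values(T)
    k, l, m = v.shape
    return v.reshape(k, l * m)


def fold_row(Dmat: np.ndarray, shape: tuple) -> np.ndarray:
    """Inverse of :func:`unfold_row` for a known (K, L, M) shape."""
    k, l, m = shape
    return np.asarray(Dmat, dtype=float).reshape(k, l, m)


def unfold_x(T) -> np.ndarray:
    """x-mode unfolding: (K*M) x L, rows stacked as (k, m) with m fastest.

    Column ``l`` is the vectorized patient slice ``T[:, l, :]``.
    """
    v = _values(T)
    k, l, m = v.shape
    return v.transpose(0, 2, 1).reshape(k * m, l)


def unfold_y(T) -> np.ndarray:
    """y-mode unfolding: (K*L) x M, rows stacked as (k, l) with l fastest."""
    v = _values(T)
    k, l, m = v.shape
    return v.reshape(k * l, m)


def significance(R: np.ndarray) -> np.ndarray:
    """Fractions ``P[a,b,c] = R[a,b,c]**2 / sum(R**2)``; they sum to 1."""
    R = np.asarray(R, dtype=float)
    total = float(np.sum(R * R))
    if total == 0.0:
        raise ValueError("core tensor is identically zero; significance undefined")
    return R * R / total


def tensor_angular_distance(
    R1: np.ndarray,
    R2: np.ndarray,
    sigma_row1: np.ndarray | None = None,
    sigma_row2: np.ndarray | None = None,
    rel_tol: float = 1e-12,
):
    """Per-subtensor angular distances ``Theta = arctan(R1/R2) - pi/4``.

    Entries where both cores vanish (below ``rel_tol`` times the largest core
    magnitude) are undefined and returned as NaN, with a boolean ``defined``
    mask alongside.  Where defined, ``Theta[a, b, c]`` equals the row-mode
    angular distance ``theta[a]`` (computed from ``sigma_row1``/``sigma_row2``
    when given) up to round-off.

    Returns
    -------
    theta_tensor : ndarray
        LM x L x M array of angular distances, NaN where undefined.
    theta_row : ndarray or None
        Row-mode angular distances, if the sigmas were supplied.
    defined : ndarray of bool
        Mask of entries where the ratio is defined.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.shape != R2.shape:
        raise ValueError("core tensors must have equal shapes")
    scale = max(np.max(np.abs(R1)), np.max(np.abs(R2)), np.finfo(float).tiny)
    defined = (np.abs(R1) > rel_tol * scale) | (np.abs(R2) > rel_tol * scale)
    theta = np.full(R1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = R1 / R2
    # R2 == 0 with R1 != 0 is the dataset-1-exclusive limit, +pi/4.
    inf_mask = defined & (R2 == 0.0)
    fin = defined & ~inf_mask
    theta[fin] = np.arctan(ratio[fin]) - np.pi / 4
    theta[inf_mask] = np.pi / 4
    theta_row = None
    if sigma_row1 is not None and sigma_row2 is not None:
        theta_row = angular_distances(sigma_row1, sigma_row2)
    return theta, theta_row, defined


@dataclass(frozen=True)
class SubtensorIndex:
    """A selected subtensor (1-based indices) with its significance and angle."""

    a: int
    b: int
    c: int
    significance1: float
    significance2: float
    theta: float
    most_exclusive: bool  # True when a == 1, the most dataset-1-exclusive arraylet


class TensorGSVD:
    """Model: tensor GSVD of a pair of probe-independent, column-matched tensors.

    Parameters
    ----------
    d1, d2 : ThirdOrderTensor or ndarray
        The two tensors; patient and platform dimensions must match and, when
        identifier lists are present, agree element-wise.  Each probe dimension
        must satisfy ``K_i >= L*M`` and all six unfoldings must have full
        column rank.

    Call :meth:`fit` to compute the factorization.
    """

    def __init__(self, d1, d2):
        self.d1 = d1 if isinstance(d1, ThirdOrderTensor) else ThirdOrderTensor(np.asarray(d1, dtype=float))
        self.d2 = d2 if isinstance(d2, ThirdOrderTensor) else ThirdOrderTensor(np.asarray(d2, dtype=float))
        s1, s2 = self.d1.shape, self.d2.shape
        if s1[1:] != s2[1:]:
            raise ValueError(
                f"patient/platform dimensions must match: {s1[1:]} vs {s2[1:]}"
            )
        if self.d1.patient_ids != self.d2.patient_ids:
            raise ValueError("patient identifiers differ between the two tensors")
        if self.d1.platform_ids != self.d2.platform_ids:
            raise ValueError("platform identifiers differ between the two tensors")
        l, m = s1[1], s1[2]
        for name, k in (("dataset 1", s1[0]), ("dataset 2", s2[0])):
            if k < l * m:
                raise ValueError(
                    f"{name}: probe dimension {k} < L*M = {l * m}; the row-mode "
                    "unfolding cannot have full column rank"
                )

    def fit(self) -> "TensorGSVDResults":
        d1, d2 = self.d1, self.d2
        k1, l, m = d1.shape
        k2 = d2.shape[0]

        def _gsvd(a, b, which):
            try:
                return matrix_gsvd(a, b)
            except RankDeficiencyError as err:
                raise RankDeficiencyError(f"{which} unfolding: {err}") from err

        row = _gsvd(unfold_row(d1), unfold_row(d2), "row-mode")
        gx = _gsvd(unfold_x(d1), unfold_x(d2), "x-mode")
        gy = _gsvd(unfold_y(d1), unfold_y(d2), "y-mode")

        Vx, Vy = gx.V, gy.V
        R1 = _core(d1.values, row.U1, Vx, Vy)
        R2 = _core(d2.values, row.U2, Vx, Vy)
        return TensorGSVDResults(
            model=self,
            U1=row.U1,
            U2=row.U2,
            Vx=Vx,
            Vy=Vy,
            R1=R1,
            R2=R2,
            sigma_row1=row.sigma1,
            sigma_row2=row.sigma2,
            sigma_x1=gx.sigma1,
            sigma_x2=gx.sigma2,
            sigma_y1=gy.sigma1,
            sigma_y2=gy.sigma2,
            theta_row=row.theta,
        )


def _core(values: np.ndarray, U: np.ndarray, Vx: np.ndarray, Vy: np.ndarray) -> np.ndarray:
    """Core ``R = D x_a U.T x_b inv(Vx) x_c inv(Vy)`` without forming Kroneckers."""
    k, l, m = values.shape
    lm = U.shape[1]
    G = np.einsum("ka,klm->alm", U, values)  # contract the probe mode
    # patient mode: solve Vx @ X = G along axis 1
    G = np.linalg.solve(Vx, G.transpose(1, 0, 2).reshape(l, lm * m))
    G = G.reshape(l, lm, m).transpose(1, 0, 2)
    # platform mode: solve Vy @ X = G along axis 2
    G = np.linalg.solve(Vy, G.transpose(2, 0, 1).reshape(m, lm * l))
    return G.reshape(m, lm, l).transpose(1, 2, 0)


@dataclass
class TensorGSVDResults:
    """Fitted tensor GSVD: factors, cores, significances and angular distances.

    ``U1``/``U2`` hold the arraylets (columns), ``Vx.T``/``Vy.T`` the x- and
    y-probelets (rows).  ``R1``/``R2`` are the LM x L x M core tensors.
    """

    model: TensorGSVD
    U1: np.ndarray
    U2: np.ndarray
    Vx: np.ndarray
    Vy: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    sigma_row1: np.ndarray
    sigma_row2: np.ndarray
    sigma_x1: np.ndarray
    sigma_x2: np.ndarray
    sigma_y1: np.ndarray
    sigma_y2: np.ndarray
    theta_row: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    # -- derived quantities -------------------------------------------------
    @property
    def significance1(self) -> np.ndarray:
        if "P1" not in self._cache:
            self._cache["P1"] = significance(self.R1)
        return self._cache["P1"]

    @property
    def significance2(self) -> np.ndarray:
        if "P2" not in self._cache:
            self._cache["P2"] = significance(self.R2)
        return self._cache["P2"]

    @property
    def theta(self) -> np.ndarray:
        """Tensor angular distances Theta[a,b,c] (NaN where undefined)."""
        if "theta" not in self._cache:
            th, _, defined = tensor_angular_distance(self.R1, self.R2)
            self._cache["theta"] = th
            self._cache["defined"] = defined
        return self._cache["theta"]

    @property
    def theta_defined(self) -> np.ndarray:
        self.theta
        return self._cache["defined"]

    def reconstruct(self, which: int) -> np.ndarray:
        """Rebuild dataset ``which`` by the triple tensor-matrix contraction."""
        R = self.R1 if which == 1 else self.R2
        U = self.U1 if which == 1 else self.U2
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        return np.einsum("abc,ka,lb,mc->klm", R, U, self.Vx, self.Vy, optimize=True)

    def subtensor(self, which: int, a: int, b: int, c: int) -> np.ndarray:
        """Weighted rank-1 subtensor ``R[a,b,c] * u_a (o) vx_b (o) vy_c`` (1-based)."""
        R = self.R1 if which == 1 else self.R2
        U = self.U1 if which == 1 else self.U2
        return R[a - 1, b - 1, c - 1] * np.einsum(
            "k,l,m->klm", U[:, a - 1], self.Vx[:, b - 1], self.Vy[:, c - 1]
        )

    def select_significant_subtensor(self, which: int = 1, tie_tol: float = 1e-9) -> SubtensorIndex:
        """Index (a, b, c) maximizing the significance fraction of dataset ``which``.

        Near-ties (within ``tie_tol`` of the maximum, relatively) are broken
        toward the lexicographically smallest index, with a warning.  Also
        reports whether the selected arraylet is the most dataset-1-exclusive
        one (a == 1), as the ordering convention guarantees for a genuinely
        exclusive pattern.
        """
        P = self.significance1 if which == 1 else self.significance2
        pmax = P.max()
        ties = np.argwhere(P >= pmax * (1.0 - tie_tol))
        if len(ties) > 1:
            warnings.warn(
                f"{len(ties)} subtensors tie for maximal significance; "
                "returning the lexicographically smallest index",
                stacklevel=2,
            )
        a, b, c = (int(v) for v in sorted(map(tuple, ties))[0])
        return SubtensorIndex(
            a=a + 1,
            b=b + 1,
            c=c + 1,
            significance1=float(self.significance1[a, b, c]),
            significance2=float(self.significance2[a, b, c]),
            theta=float(self.theta[a, b, c]),
            most_exclusive=(a == 0),
        )

    # -- presentation -------------------------------------------------------
    def summary(self, top: int = 5) -> str:
        """Plain-text summary: leading arraylet pairs and top subtensors."""
        lines = [
            "Tensor GSVD",
            f"  dataset 1: {self.U1.shape[0]} probes, dataset 2: {self.U2.shape[0]} probes, "
            f"{self.Vx.shape[0]} patients x {self.Vy.shape[0]} platforms",
            "",
            "  a    sigma1      sigma2      ratio       theta",
        ]
        n = min(top, len(self.sigma_row1))
        for a in range(n):
            lines.append(
                f"  {a + 1:<4d} {self.sigma_row1[a]:<11.4g} {self.sigma_row2[a]:<11.4g} "
                f"{self.sigma_row1[a] / self.sigma_row2[a]:<11.4g} {self.theta_row[a]:+.4f}"
            )
        P = self.significance1
        flat = np.argsort(P, axis=None)[::-1][:top]
        lines += ["", "  top subtensors by dataset-1 significance:",
                  "  (a,b,c)      P1          P2          Theta"]
        for idx in flat:
            a, b, c = np.unravel_index(idx, P.shape)
            th = self.theta[a, b, c]
            lines.append(
                f"  ({a + 1},{b + 1},{c + 1})      {P[a, b, c]:<11.4g} "
                f"{self.significance2[a, b, c]:<11.4g} {th:+.4f}"
            )
        return "\n".join(lines)

    def plot_angular_distances(self, ax=None):
        """Bar chart of the row-mode angular distances theta_a."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(1, len(self.theta_row) + 1), self.theta_row, color="0.3")
        ax.axhline(np.pi / 4, ls="--", c="r", lw=0.8)
        ax.axhline(-np.pi / 4, ls="--", c="g", lw=0.8)
        ax.set_xlabel("arraylet pair a")
        ax.set_ylabel(r"angular distance $\theta_a$")
        return ax

    # -- serialization ------------------------------------------------------
    def save(self, directory) -> None:
        """Write the factorization as tab-delimited text files.

        ``U1.tsv``/``U2.tsv``/``Vx.tsv``/``Vy.tsv`` hold the factor matrices
        (probe/patient/platform ids as the first column); ``core.tsv`` is a
        long-format table with columns a, b, c, R1, R2, P1, P2, theta.
        """
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        d1, d2 = self.model.d1, self.model.d2
        lm = self.U1.shape[1]
        cols = [f"a{j + 1}" for j in range(lm)]
        fmt = "%.17g"

        def _write(name, mat, index, columns):
            df = pd.DataFrame(mat, index=list(index), columns=columns)
            df.to_csv(directory / name, sep="\t", float_format=fmt)

        _write("U1.tsv", self.U1, d1.probe_ids, cols)
        _write("U2.tsv", self.U2, d2.probe_ids, cols)
        _write("Vx.tsv", self.Vx, d1.patient_ids, [f"b{j + 1}" for j in range(self.Vx.shape[1])])
        _write("Vy.tsv", self.Vy, d1.platform_ids, [f"c{j + 1}" for j in range(self.Vy.shape[1])])

        a, b, c = np.meshgrid(
            np.arange(1, self.R1.shape[0] + 1),
            np.arange(1, self.R1.shape[1] + 1),
            np.arange(1, self.R1.shape[2] + 1),
            indexing="ij",
        )
        core = pd.DataFrame(
            {
                "a": a.ravel(),
                "b": b.ravel(),
                "c": c.ravel(),
                "R1": self.R1.ravel(),
                "R2": self.R2.ravel(),
                "P1": self.significance1.ravel(),
                "P2": self.significance2.ravel(),
                "theta": self.theta.ravel(),
            }
        )
        core.to_csv(directory / "core.tsv", sep="\t", index=False, float_format=fmt)
        pd.Series(
            {
                "sigma_row1": " ".join(fmt % v for v in self.sigma_row1),
                "sigma_row2": " ".join(fmt % v for v in self.sigma_row2),
                "sigma_x1": " ".join(fmt % v for v in self.sigma_x1),
                "sigma_x2": " ".join(fmt % v for v in self.sigma_x2),
                "sigma_y1": " ".join(fmt % v for v in self.sigma_y1),
                "sigma_y2": " ".join(fmt % v for v in self.sigma_y2),
            }
        ).to_csv(directory / "sigmas.tsv", sep="\t", header=False)


def load_factorization(directory) -> TensorGSVDResults:
    """Read a factorization written by :meth:`TensorGSVDResults.save`."""
    import pandas as pd

    directory = Path(directory)
    U1 = pd.read_csv(directory / "U1.tsv", sep="\t", index_col=0, float_precision="round_trip")
    U2 = pd.read_csv(directory / "U2.tsv", sep="\t", index_col=0, float_precision="round_trip")
    Vx = pd.read_csv(directory / "Vx.tsv", sep="\t", index_col=0, float_precision="round_trip")
    Vy = pd.read_csv(directory / "Vy.tsv", sep="\t", index_col=0, float_precision="round_trip")
    core = pd.read_csv(directory / "core.tsv", sep="\t", float_precision="round_trip")
    sig = pd.read_csv(directory / "sigmas.tsv", sep="\t", header=None, index_col=0)[1]
    lm, l, m = U1.shape[1], Vx.shape[0], Vy.shape[0]
    R1 = core["R1"].to_numpy().reshape(lm, l, m)
    R2 = core["R2"].to_numpy().reshape(lm, l, m)

    def _vec(key):
        return np.array([float(x) for x in sig[key].split()])

    s1, s2 = _vec("sigma_row1"), _vec("sigma_row2")
    d1 = ThirdOrderTensor(
        np.einsum("abc,ka,lb,mc->klm", R1, U1.to_numpy(), Vx.to_numpy(), Vy.to_numpy(), optimize=True),
        probe_ids=U1.index,
        patient_ids=Vx.index,
        platform_ids=Vy.index,
    )
    d2 = ThirdOrderTensor(
        np.einsum("abc,ka,lb,mc->klm", R2, U2.to_numpy(), Vx.to_numpy(), Vy.to_numpy(), optimize=True),
        probe_ids=U2.index,
        patient_ids=Vx.index,
        platform_ids=Vy.index,
    )
    return TensorGSVDResults(
        model=TensorGSVD(d1, d2),
        U1=U1.to_numpy(),
        U2=U2.to_numpy(),
        Vx=Vx.to_numpy(),
        Vy=Vy.to_numpy(),
        R1=R1,
        R2=R2,
        sigma_row1=s1,
        sigma_row2=s2,
        sigma_x1=_vec("sigma_x1"),
        sigma_x2=_vec("sigma_x2"),
        sigma_y1=_vec("sigma_y1"),
        sigma_y2=_vec("sigma_y2"),
        theta_row=angular_distances(s1, s2),
    )


def tensor_gsvd(d1, d2) -> TensorGSVDResults:
    """Functional entry point: ``TensorGSVD(d1, d2).fit()``."""
    return TensorGSVD(d1, d2).fit()


def pattern_angular_distance(d1, d2, patient_vector, platform_vector) -> float:
    """Angular distance of a *specified* patient x platform pattern.

    For the shared-mode direction ``v = patient_vector (o) platform_vector``
    (unit-normalized), compares the energy of each tensor along it:
    ``theta = arctan(||D1 v|| / ||D2 v||) - pi/4``.  When ``v`` coincides
    with a factorization's probelet pair this equals that subtensor's angular
    distance; unlike the factorized Theta it remains meaningful for a pattern
    whose generalized-singular-value ratio is degenerate with the noise
    background (e.g. a pattern of equal weight in both datasets), where the
    corresponding arraylets are unique only up to rotation.
    """
    x = np.asarray(patient_vector, dtype=float)
    y = np.asarray(platform_vector, dtype=float)
    v = np.kron(x, y)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("pattern direction is zero")
    v = v / nv
    s1 = np.linalg.norm(unfold_row(d1) @ v)
    s2 = np.linalg.norm(unfold_row(d2) @ v)
    return float(np.arctan2(s1, s2) - np.pi / 4)


@dataclass(frozen=True)
class Hosvd:
    """Higher-order SVD: orthonormal mode factors and an all-orthogonal core."""

    factors: tuple
    core: np.ndarray

    def reconstruct(self) -> np.ndarray:
        A1, A2, A3 = self.factors
        return np.einsum("abc,ka,lb,mc->klm", self.core, A1, A2, A3, optimize=True)


def hosvd(T) -> Hosvd:
    """Higher-order SVD of a third-order tensor.

    Mode factors are the left singular vectors of the three unfoldings; the
    core is the tensor contracted with their transposes.  This is the
    single-tensor special case the tensor GSVD reduces to when the first
    tensor's row-mode unfolding is the identity.
    """
    v = _values(T)
    A1 = linalg.svd(unfold_row(v), full_matrices=False)[0]
    # unfold_x / unfold_y place the patient / platform mode on the columns,
    # so those mode factors are the right singular vectors.
    A2 = linalg.svd(unfold_x(v), full_matrices=False)[2].T
    A3 = linalg.svd(unfold_y(v), full_matrices=False)[2].T
    core = np.einsum("klm,ka,lb,mc->abc", v, A1, A2, A3, optimize=True)
    return Hosvd(factors=(A1, A2, A3), core=core)
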