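"""Ring geometry and synaptic weight matrices.

Both populations are laid out uniformly on a ring and every weight is a
function of the circular angular difference between the postsynaptic and
presynaptic neuron.  Three profiles matter for the default network:

* E->I  ``W(dth) = J- + (J+ - J-) exp(-dth^2 / (2 sigma^2))`` — peaked at
  zero offset, so active principal cells recruit interneurons at the same
  angle;
* I->E  ``W(dth) = G exp(-(dth - mu)^2 / (2 sigma^2))`` — with mu = 90 deg
  the profile has maxima at signed offsets of +-90 deg, making active
  interneurons suppress principal cells a quarter-ring away;
* I->I  uniform (all entries 1) by default.

J- and G are fixed by the normalization <W(dth)> = 1.  We apply it as the
discrete mean over each row's actual presynaptic angular-offset grid, so
every row mean equals 1 exactly (the continuous-integral alternative is
available via ``ConnectivityParams.normalization = "integral"``; at the
default network size the two differ by ~5e-6 relative).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ConnectivityParams

__all__ = [
    "RingGeometry",
    "ConnectivityMatrices",
    "angular_difference",
    "build_w_ei",
    "build_w_ie",
    "build_w_ii",
    "build_w_ee",
    "build_connectivity",
]


@dataclass(frozen=True)
class RingGeometry:
    """Uniform angular positions of principal cells and interneurons."""

    n_e: int = 1024
    n_i: int = 256

    def __post_init__(self) -> None:
        if self.n_e < 1 or self.n_i < 1:
            raise ValueError("population sizes must be >= 1")

    @property
    def theta_e(self) -> np.ndarray:
        """Angles of principal cells in degrees, [0, 360)."""
        return np.arange(self.n_e) * (360.0 / self.n_e)

    @property
    def theta_i(self) -> np.ndarray:
        """Angles of interneurons in degrees, [0, 360)."""
        return np.arange(self.n_i) * (360.0 / self.n_i)


@dataclass
class ConnectivityMatrices:
    """Dense weight matrices, indexed [postsynaptic, presynaptic]."""

    w_ei: np.ndarray  # (n_i, n_e), E->I
    w_ie: np.ndarray  # (n_e, n_i), I->E
    w_ii: np.ndarray  # (n_i, n_i), I->I
    w_ee: Optional[np.ndarray] = None  # (n_e, n_e), E->E variant
    j_minus_ei: float = 0.0  # baseline of the E->I profile (aligned rows)
    g_ie: float = 0.0  # amplitude of the I->E profile (aligned rows)


def angular_difference(theta_a, theta_b):
    """Circular angular distance in degrees, in [0, 180].

    Inputs are wrapped modulo 360, the result is symmetric in its
    arguments and satisfies ``angular_difference(a, b) ==
    min(|a - b|, 360 - |a - b|)``.
    """
    d = np.abs(np.mod(np.asarray(theta_a, dtype=float)
                      - np.asarray(theta_b, dtype=float), 360.0))
    return np.minimum(d, 360.0 - d)


def _pairwise_dtheta(theta_post: np.ndarray, theta_pre: np.ndarray) -> np.ndarray:
    return angular_difference(theta_post[:, None], theta_pre[None, :])


def _row_normalize(w: np.ndarray) -> np.ndarray:
    """Scale each row so its mean is exactly 1."""
    means = w.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise ValueError("normalization has no solution: non-positive row mean")
    return w / means


def _integral_mean(profile, lo: float = 0.0, hi: float = 360.0) -> float:
    """Continuous (1/360) integral of profile(angular_difference) over offsets."""
    from scipy.integrate import quad
    val, _ = quad(lambda phi: profile(min(phi, 360.0 - phi)), lo, hi, limit=400)
    return val / (hi - lo)


def build_w_ei(geom: RingGeometry, params: ConnectivityParams) -> np.ndarray:
    """E->I weights: baseline-plus-Gaussian profile peaked at zero offset.

    The baseline J- is the solution of  1 = J- + (J+ - J-) m  with m the
    mean of the unit Gaussian profile over the offset grid; it must be
    finite and the profile non-negative, otherwise the normalization fails.
    """
    dth = _pairwise_dtheta(geom.theta_i, geom.theta_e)
    gauss = np.exp(-dth**2 / (2.0 * params.sigma_ei**2))
    if params.normalization == "integral":
        m = _integral_mean(lambda d: np.exp(-d**2 / (2.0 * params.sigma_ei**2)))
    else:
        # every interneuron sits on the principal-cell grid, so one row's
        # offset multiset is shared by all rows
        m = gauss[0].mean()
    if abs(1.0 - m) < 1e-12:
        raise ValueError("degenerate sigma_ei: normalization has no solution")
    j_minus = (1.0 - params.j_plus_ei * m) / (1.0 - m)
    w = j_minus + (params.j_plus_ei - j_minus) * gauss
    if np.any(w < 0):
        raise ValueError("E->I profile went negative; j_plus_ei too large "
                         "for this sigma_ei")
    return w


def _j_minus_ei(geom: RingGeometry, params: ConnectivityParams) -> float:
    dth = angular_difference(geom.theta_e, geom.theta_e[0])
    m = np.exp(-dth**2 / (2.0 * params.sigma_ei**2)).mean()
    return (1.0 - params.j_plus_ei * m) / (1.0 - m)


def build_w_ie(geom: RingGeometry, params: ConnectivityParams) -> np.ndarray:
    """I->E weights: Gaussian profile displaced by mu_ie (90 deg default).

    In circular distance the profile peaks at dth = mu_ie, i.e. at signed
    offsets of +-mu_ie — two maxima per ring, which is what spaces the two
    bump attractors 180 deg apart.  Rows are normalized on their own offset
    grids: principal cells at the four distinct sub-grid offsets relative
    to the interneuron ring see angular grids shifted by up to 3/4 of an
    interneuron spacing, and a single amplitude G cannot make all row means
    exactly 1 (the residual is ~7e-6 at default size).
    """
    dth = _pairwise_dtheta(geom.theta_e, geom.theta_i)
    w = np.exp(-(dth - params.mu_ie)**2 / (2.0 * params.sigma_ie**2))
    if params.normalization == "integral":
        m = _integral_mean(
            lambda d: np.exp(-(d - params.mu_ie)**2 / (2.0 * params.sigma_ie**2)))
        if m <= 0:
            raise ValueError("degenerate sigma_ie: normalization has no solution")
        return w / m
    return _row_normalize(w)


def build_w_ii(geom: RingGeometry, params: ConnectivityParams) -> np.ndarray:
    """I->I weights: uniform (all ones) by default, or structured variants.

    ``unimodal`` is a Gaussian of the offset peaked at 0 deg; ``bimodal``
    adds an equal peak at 180 deg.  Structured profiles are normalized like
    the other matrices.
    """
    if params.w_ii_mode == "uniform":
        return np.ones((geom.n_i, geom.n_i))
    dth = _pairwise_dtheta(geom.theta_i, geom.theta_i)
    s2 = 2.0 * params.w_ii_sigma**2
    if params.w_ii_mode == "unimodal":
        w = np.exp(-dth**2 / s2)
    elif params.w_ii_mode == "bimodal":
        w = np.exp(-dth**2 / s2) + np.exp(-(dth - 180.0)**2 / s2)
    else:
        raise ValueError(f"unknown w_ii_mode {params.w_ii_mode!r}")
    if params.normalization == "integral":
        if params.w_ii_mode == "unimodal":
            m = _integral_mean(lambda d: np.exp(-d**2 / s2))
        else:
            m = _integral_mean(
                lambda d: np.exp(-d**2 / s2) + np.exp(-(d - 180.0)**2 / s2))
        return w / m
    return _row_normalize(w)


def build_w_ee(geom: RingGeometry, params: ConnectivityParams) -> np.ndarray:
    """E->E weights (variant): Gaussian peaked at zero offset, no autapses.

    The diagonal is zeroed before normalization, so each row mean over all
    n_e entries (including the structural zero) equals 1.
    """
    if not params.ee_enabled:
        raise ValueError("E->E connectivity variant is not enabled")
    dth = _pairwise_dtheta(geom.theta_e, geom.theta_e)
    w = np.exp(-dth**2 / (2.0 * params.sigma_ee**2))
    np.fill_diagonal(w, 0.0)
    if params.normalization == "integral":
        m = _integral_mean(lambda d: np.exp(-d**2 / (2.0 * params.sigma_ee**2)))
        return w / m
    return _row_normalize(w)


def build_connectivity(geom: RingGeometry,
                       params: ConnectivityParams) -> ConnectivityMatrices:
    """Build all weight matrices for the given geometry and parameters."""
    w_ei = build_w_ei(geom, params)
    w_ie = build_w_ie(geom, params)
    w_ii = build_w_ii(geom, params)
    w_ee = build_w_ee(geom, params) if params.ee_enabled else None
    return ConnectivityMatrices(
        w_ei=w_ei, w_ie=w_ie, w_ii=w_ii, w_ee=w_ee,
        j_minus_ei=_j_minus_ei(geom, params),
        g_ie=float(w_ie[0].max() if params.mu_ie == 0 else
                   1.0 / np.exp(-(angular_difference(geom.theta_e[0], geom.theta_i)
                                  - params.mu_ie)**2
                                / (2.0 * params.sigma_ie**2)).mean()),
    )


def export_matrices(mats: ConnectivityMatrices, path) -> None:
    """Write the weight matrices to an HDF5 file for inspection."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("w_ei", data=mats.w_ei)
        f.create_dataset("w_ie", data=mats.w_ie)
        f.create_dataset("w_ii", data=mats.w_ii)
        if mats.w_ee is not None:
            f.create_dataset("w_ee", data=mats.w_ee)
        f.attrs["j_minus_ei"] = mats.j_minus_ei
        f.attrs["g_ie"] = mats.g_ie
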