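"""Ewald-sphere geometry, orientation quadrature and the polar grid.

Geometry conventions
--------------------
The beam travels along +z with wavevector ``k_in = (0, 0, 2*pi/lambda)``.
Elastic scattering puts every recorded scattering vector ``k = k_out - k_in``
on the Ewald sphere ``|k + k_in| = |k_in| = R_E`` with ``R_E = 2*pi/lambda``.
Writing ``q = |k|`` and ``phi`` for the azimuth of the transverse components
``(k_x, k_y)``, the surface area element of the Ewald sphere is exactly
``dA = q dq dphi`` (substituting ``q = 2 R_E sin(theta/2)`` into
``R_E**2 sin(theta) dtheta dphi``), so a grid uniform in ``q`` and ``phi``
has exactly computable cell areas ``a_{r,s} = dphi * (q_hi**2 - q_lo**2)/2``
and the spherical-cap area out to ``q_max`` is ``pi * q_max**2``.

Photons are stored by their two transverse components ``(k_x, k_y)``; the
longitudinal component is recovered from the Ewald condition
(``k_z = sqrt(R_E**2 - k_t**2) - R_E <= 0``, forward branch).  This mapping
is one-to-one only for ``q <= sqrt(2) * R_E`` (scattering angles up to 90°),
which is therefore enforced as the representable ``kmax`` bound.

The orientation quadrature covers the two Ewald-sphere degrees of freedom
(beam-axis direction in the molecular frame) with a positive-weight
spherical quadrature; the third Euler angle (rotation about the beam axis)
is handled exactly downstream as cyclic shifts of the angular grid index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamParams",
    "OrientationQuadrature",
    "PolarGrid",
    "supported_orientation_counts",
    "build_orientation_quadrature",
    "build_polar_grid",
    "bin_photon",
    "bin_photons",
    "rotation_from_z_to",
    "q_from_transverse",
    "kvec_from_q_phi",
]


class PhotonOutOfRangeError(ValueError):
    """A photon lies beyond the grid's kmax."""


@dataclass(frozen=True)
class BeamParams:
    """Beam and recording parameters.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in Å.
    i0_eff : float
        Effective incident intensity scale: the expected photon count for
        Ewald-sphere orientation ``l`` is ``i0_eff * lambda_l`` where
        ``lambda_l`` is the intensity integral over the Ewald cap in Å⁻²
        units (see :func:`rasta.forward_sim.i0_from_physical_beam` for the
        conversion from physical beam parameters).
    kmax : float
        Å⁻¹ cutoff; photons with ``|k| > kmax`` are not recorded.
    """

    wavelength: float
    i0_eff: float
    kmax: float

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if not self.i0_eff > 0:
            raise ValueError("i0_eff must be positive")
        if not self.kmax > 0:
            raise ValueError("kmax must be positive")
        # sqrt(2)*R_E (90° scattering) so transverse components stay unique;
        # the physical backscattering bound would be 2*R_E.
        bound = np.sqrt(2.0) * self.ewald_radius
        if self.kmax > bound * (1 + 1e-12):
            raise ValueError(
                f"kmax={self.kmax} exceeds the transverse-representable bound "
                f"sqrt(2)*2*pi/wavelength = {bound:.6g} A^-1"
            )

    @property
    def ewald_radius(self) -> float:
        """``R_E = 2*pi/lambda`` in Å⁻¹."""
        return 2.0 * np.pi / self.wavelength

    @property
    def k_in(self) -> np.ndarray:
        """Incoming wavevector, beam along +z."""
        return np.array([0.0, 0.0, self.ewald_radius])


def supported_orientation_counts(max_count: int = 20000) -> list[int]:
    """Valid ``n_nodes`` for :func:`build_orientation_quadrature`.

    The rule is a Gauss-Legendre (polar) × uniform (azimuth) product grid
    with ``n_phi = 2 * n_theta``, hence ``n_nodes = 2 * t**2`` for integer
    ``t``, plus the trivial single-node rule.
    """
    counts = [1]
    t = 1
    while 2 * t * t <= max_count:
        counts.append(2 * t * t)
        t += 1
    return counts


@dataclass(frozen=True)
class OrientationQuadrature:
    """Rotations ``R_l`` with positive weights ``w_l`` summing to 1."""

    rotations: np.ndarray  # (n_R, 3, 3)
    weights: np.ndarray  # (n_R,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotations, dtype=np.float64)
        wts = np.asarray(self.weights, dtype=np.float64)
        if rot.ndim != 3 or rot.shape[1:] != (3, 3) or rot.shape[0] != wts.shape[0]:
            raise ValueError("rotations must be (n_R, 3, 3) matching weights")
        if np.any(wts <= 0) or abs(wts.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be positive and sum to 1")
        eye = np.eye(3)
        for R in rot:
            if not np.allclose(R @ R.T, eye, atol=1e-10):
                raise ValueError("rotations must be orthogonal")
            if abs(np.linalg.det(R) - 1.0) > 1e-10:
                raise ValueError("rotations must have determinant +1")
        object.__setattr__(self, "rotations", rot)
        object.__setattr__(self, "weights", wts)

    @property
    def n_rotations(self) -> int:
        return self.weights.shape[0]


def rotation_from_z_to(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix carrying the +z axis onto `direction`."""
    n = np.asarray(direction, dtype=np.float64)
    n = n / np.linalg.norm(n)
    c = n[2]
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # 180° about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.array([-n[1], n[0], 0.0])
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def build_orientation_quadrature(n_nodes: int) -> OrientationQuadrature:
    """Spherical quadrature of beam-axis directions, mapped to rotations.

    Nodes are a Gauss-Legendre × uniform-azimuth product rule on the unit
    sphere (``n_nodes = 2 t**2``), exact for spherical harmonics up to
    degree ``2t - 1``.  Each node direction ``n_l`` is mapped to the
    minimal rotation carrying +z onto ``n_l``; the residual beam-axis
    rotation is covered exactly by the angular-index shifts of the polar
    grid, so the choice of the third Euler angle here is immaterial.
    """
    if n_nodes == 1:
        return OrientationQuadrature(
            rotations=np.eye(3)[None, :, :], weights=np.array([1.0])
        )
    valid = supported_orientation_counts()
    if n_nodes not in valid:
        raise ValueError(
            f"unsupported n_nodes={n_nodes}; valid counts are 1 or 2*t**2: "
            f"{valid[:12]}..."
        )
    t = int(round(np.sqrt(n_nodes / 2)))
    x, gl_w = np.polynomial.legendre.leggauss(t)  # cos(theta) nodes on [-1, 1]
    n_phi = 2 * t
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    rotations = []
    weights = []
    for ci, wi in zip(x, gl_w):
        st = np.sqrt(max(0.0, 1.0 - ci * ci))
        for phi in phis:
            n = np.array([st * np.cos(phi), st * np.sin(phi), ci])
            rotations.append(rotation_from_z_to(n))
            weights.append(wi / 2.0 / n_phi)
    return OrientationQuadrature(
        rotations=np.array(rotations), weights=np.array(weights)
    )


def q_from_transverse(k_xy: np.ndarray, ewald_radius: float) -> np.ndarray:
    """Full scattering-vector magnitude from transverse components.

    ``q**2 = 2 R_E (R_E - sqrt(R_E**2 - k_t**2))`` on the forward branch.
    """
    kt2 = np.sum(np.atleast_2d(k_xy) ** 2, axis=-1)
    R = ewald_radius
    inside = np.clip(R * R - kt2, 0.0, None)
    return np.sqrt(2.0 * R * (R - np.sqrt(inside)))


def kvec_from_q_phi(q: np.ndarray, phi: np.ndarray, ewald_radius: float) -> np.ndarray:
    """3D scattering vectors on the Ewald sphere from ``(q, phi)``.

    ``cos(theta) = 1 - q**2/(2 R_E**2)``; returns shape (..., 3).
    """
    q = np.asarray(q, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    R = ewald_radius
    cos_t = 1.0 - q * q / (2.0 * R * R)
    sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 0.0, None))
    kt = R * sin_t
    return np.stack(
        [kt * np.cos(phi), kt * np.sin(phi), R * (cos_t - 1.0)], axis=-1
    )


@dataclass(frozen=True)
class PolarGrid:
    """Polar grid on the reference Ewald cap.

    Radial bins are uniform in ``q = |k|`` on ``[0, kmax]``; angular bins
    are uniform in azimuth ``phi`` on ``[0, 2*pi)`` starting at 0 (strict
    uniformity is required so beam-axis rotations act as cyclic index
    shifts).  Cell centers are the 3D points at the bin midpoints; cell
    areas are exact: ``a_{r,s} = dphi * (q_hi**2 - q_lo**2) / 2``.
    """

    n_r: int
    n_s: int
    kmax: float
    ewald_radius: float
    centers: np.ndarray = field(init=False, repr=False)  # (n_r, n_s, 3)
    areas: np.ndarray = field(init=False, repr=False)  # (n_r, n_s)
    q_edges: np.ndarray = field(init=False, repr=False)  # (n_r + 1,)
    q_centers: np.ndarray = field(init=False, repr=False)  # (n_r,)

    def __post_init__(self) -> None:
        if self.n_r < 1 or self.n_s < 2:
            raise ValueError("need n_r >= 1 and n_s >= 2")
        if self.kmax > np.sqrt(2.0) * self.ewald_radius * (1 + 1e-12):
            raise ValueError("kmax exceeds the representable bound sqrt(2)*R_E")
        q_edges = np.linspace(0.0, self.kmax, self.n_r + 1)
        q_cent = 0.5 * (q_edges[:-1] + q_edges[1:])
        dphi = 2.0 * np.pi / self.n_s
        phi_cent = (np.arange(self.n_s) + 0.5) * dphi
        areas = np.repeat(
            (dphi * 0.5 * (q_edges[1:] ** 2 - q_edges[:-1] ** 2))[:, None],
            self.n_s,
            axis=1,
        )
        qq, pp = np.meshgrid(q_cent, phi_cent, indexing="ij")
        centers = kvec_from_q_phi(qq, pp, self.ewald_radius)
        object.__setattr__(self, "q_edges", q_edges)
        object.__setattr__(self, "q_centers", q_cent)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "areas", areas)

    @property
    def dphi(self) -> float:
        return 2.0 * np.pi / self.n_s

    @property
    def n_cells(self) -> int:
        return self.n_r * self.n_s

    @property
    def cap_area(self) -> float:
        """Exact Ewald-cap area out to kmax: ``pi * kmax**2``."""
        return np.pi * self.kmax**2


def build_polar_grid(n_r: int, n_s: int, beam: BeamParams) -> PolarGrid:
    """Polar grid matching `beam` (kmax and Ewald radius)."""
    return PolarGrid(
        n_r=n_r, n_s=n_s, kmax=beam.kmax, ewald_radius=beam.ewald_radius
    )


def bin_photons(k_xy: np.ndarray, grid: PolarGrid) -> tuple[np.ndarray, np.ndarray]:
    """Radial and angular 0-based bin indices for transverse photons.

    Bins are right-open ``[low, high)`` except the outermost radial bin,
    which is closed at ``kmax``.  Raises
    :class:`PhotonOutOfRangeError` for ``|k| > kmax``.
    """
    k_xy = np.atleast_2d(np.asarray(k_xy, dtype=np.float64))
    q = q_from_transverse(k_xy, grid.ewald_radius)
    if np.any(q > grid.kmax * (1.0 + 1e-9)):
        raise PhotonOutOfRangeError(
            f"photon |k|={q.max():.6g} exceeds kmax={grid.kmax}"
        )
    r = np.minimum((q / grid.kmax * grid.n_r).astype(np.int64), grid.n_r - 1)
    phi = np.mod(np.arctan2(k_xy[:, 1], k_xy[:, 0]), 2.0 * np.pi)
    s = np.minimum((phi / (2.0 * np.pi) * grid.n_s).astype(np.int64), grid.n_s - 1)
    return r, s


def bin_photon(k_xy: np.ndarray, grid: PolarGrid) -> tuple[int, int]:
    """Single-photon version of :func:`bin_photons` (0-based indices)."""
    r, s = bin_photons(np.asarray(k_xy)[None, :], grid)
    return int(r[0]), int(s[0])
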