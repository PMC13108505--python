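"""Real spherical harmonic transforms and the pseudospectral local coupling.

Short-range (homogeneous) connectivity on the cortical sphere is a
convolution with a Laplacian kernel ``W(d) = exp(-d)/2`` of the geodesic
distance ``d`` in millimetres.  Because the kernel is sharp and rotationally
invariant, the convolution acts, to second order in the kernel width, as a
diagonal operator in the spherical harmonic basis with multiplier
``N - D l (l + 1)``, where ``N`` is the kernel's integral over the sphere
(a normalization) and ``D`` a diffusion coefficient given by its second
angular moment.  Applying the operator therefore costs two transforms
instead of a dense surface quadrature per node.

Conventions: real orthonormal spherical harmonics; coefficients stored in
(l, m)-major order, index ``l**2 + l + m`` for ``m in [-l, l]`` (so a map
truncated at degree ``L`` has ``(L + 1)**2`` coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import integrate, special

from .geometry import RegularSphericalGrid

__all__ = [
    "SHCoefficients",
    "SphericalHarmonicTransform",
    "LocalCouplingOperator",
    "sht_forward",
    "sht_inverse",
    "laplacian_kernel_coeffs",
    "build_local_coupling",
    "apply_local_coupling",
    "sigmoid",
    "degree_of_index",
]


def degree_of_index(n_coeffs: int) -> np.ndarray:
    """Degree ``l`` of each coefficient slot in (l, m)-major order."""
    lmax = int(np.sqrt(n_coeffs)) - 1
    if (lmax + 1) ** 2 != n_coeffs:
        raise ValueError("coefficient count must be a perfect square (L+1)^2")
    return np.repeat(np.arange(lmax + 1), 2 * np.arange(lmax + 1) + 1)


@dataclass
class SHCoefficients:
    """Real SH coefficients of a scalar map, truncated at degree ``lmax``."""

    lmax: int
    values: np.ndarray  # ((lmax+1)**2,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != ((self.lmax + 1) ** 2,):
            raise ValueError("coefficient vector must have length (lmax+1)^2")

    def truncated(self, new_lmax: int) -> "SHCoefficients":
        """Project onto degrees <= ``new_lmax`` (idempotent)."""
        if new_lmax >= self.lmax:
            return SHCoefficients(self.lmax, self.values.copy())
        keep = (new_lmax + 1) ** 2
        out = np.zeros_like(self.values)
        out[:keep] = self.values[:keep]
        return SHCoefficients(self.lmax, out)


def _real_basis_matrix(
    lmax: int, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Real orthonormal SH basis evaluated at arbitrary points.

    Returns ``(len(theta), (lmax+1)**2)``; points need not lie on a grid.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    n = len(theta)
    out = np.empty((n, (lmax + 1) ** 2))
    for l in range(lmax + 1):
        base = l * l + l
        out[:, base] = special.sph_harm_y(l, 0, theta, 0.0).real
        for m in range(1, l + 1):
            lam = special.sph_harm_y(l, m, theta, 0.0).real
            scale = np.sqrt(2.0) * (-1.0) ** m
            out[:, base + m] = scale * lam * np.cos(m * phi)
            out[:, base - m] = scale * lam * np.sin(m * phi)
    return out


class SphericalHarmonicTransform:
    """Forward/inverse real SHT on a :class:`RegularSphericalGrid`.

    The analysis (forward) operator is the quadrature-weighted adjoint of the
    synthesis (inverse) operator, which makes forward-then-inverse exact for
    band-limited fields and ``inverse`` adjoint-consistent under the grid's
    quadrature weights.
    """

    def __init__(self, grid: RegularSphericalGrid, lmax: int | None = None):
        if lmax is None:
            lmax = grid.lmax
        if lmax > grid.lmax:
            raise ValueError(
                f"transform degree {lmax} exceeds grid capability {grid.lmax}"
            )
        self.grid = grid
        self.lmax = int(lmax)
        th, ph = grid.node_angles()
        self.synthesis = _real_basis_matrix(self.lmax, th, ph)  # (n_nodes, ncoef)
        w = grid.quadrature_weights()
        self.analysis = (self.synthesis * w[:, None]).T  # (ncoef, n_nodes)
        self.degrees = degree_of_index(self.synthesis.shape[1])

    @property
    def n_coeffs(self) -> int:
        return (self.lmax + 1) ** 2

    def forward(self, field: np.ndarray) -> SHCoefficients:
        field = np.asarray(field, dtype=float)
        if field.shape[-1] != self.grid.n_nodes:
            raise ValueError("field length does not match grid node count")
        return SHCoefficients(self.lmax, field @ self.analysis.T)

    def inverse(self, coeffs: SHCoefficients | np.ndarray) -> np.ndarray:
        values = coeffs.values if isinstance(coeffs, SHCoefficients) else coeffs
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n_coeffs:
            raise ValueError("coefficient length does not match transform degree")
        return values @ self.synthesis.T

    def evaluate(
        self, coeffs: SHCoefficients | np.ndarray, theta: np.ndarray, phi: np.ndarray
    ) -> np.ndarray:
        """Synthesize the band-limited field at arbitrary (theta, phi) points."""
        values = coeffs.values if isinstance(coeffs, SHCoefficients) else coeffs
        basis = _real_basis_matrix(self.lmax, theta, phi)
        return basis @ np.asarray(values, dtype=float)


def sht_forward(field: np.ndarray, L: int, grid: RegularSphericalGrid) -> SHCoefficients:
    """Functional wrapper: forward transform of a grid field up to degree L."""
    return SphericalHarmonicTransform(grid, L).forward(field)


def sht_inverse(coeffs: SHCoefficients, grid: RegularSphericalGrid) -> np.ndarray:
    """Functional wrapper: synthesize coefficients on the grid."""
    return SphericalHarmonicTransform(grid, coeffs.lmax).inverse(coeffs)


def laplacian_kernel_coeffs(r: float) -> tuple[float, float]:
    """Normalization ``N`` and diffusion ``D`` of the Laplacian kernel.

    ``N = r^2 * 2pi * int_0^pi (1/2) exp(-r theta) sin(theta) dtheta`` and
    ``D = (1/4) r^2 * 2pi * int_0^pi theta^2 (1/2) exp(-r theta) sin(theta)
    dtheta`` (the azimuthal integral is an exact ``2 pi`` factor since the
    integrands are phi-independent).  ``r`` is the sphere radius in mm; the
    kernel argument ``r * theta`` is the geodesic distance in mm.
    """
    if r <= 0:
        raise ValueError("radius r must be positive")

    def integrand_n(t: float) -> float:
        return 0.5 * np.exp(-r * t) * np.sin(t)

    def integrand_d(t: float) -> float:
        return 0.25 * t * t * 0.5 * np.exp(-r * t) * np.sin(t)

    # integrand mass concentrates in theta ~ few/r; split there for accuracy
    split = min(np.pi, 30.0 / r)
    opts = dict(epsabs=1e-14, epsrel=1e-12, limit=200)
    n_val = sum(
        integrate.quad(integrand_n, a, b, **opts)[0]
        for a, b in ((0.0, split), (split, np.pi))
        if a < b
    )
    d_val = sum(
        integrate.quad(integrand_d, a, b, **opts)[0]
        for a, b in ((0.0, split), (split, np.pi))
        if a < b
    )
    return 2.0 * np.pi * r * r * n_val, 2.0 * np.pi * r * r * d_val


@dataclass
class LocalCouplingOperator:
    """Dense realization of the pseudospectral homogeneous-coupling operator.

    Acting on a grid field ``psi``:
    ``W psi = N psi + SHT^-1[ -D l (l+1) ] SHT psi``, with the spectral part
    truncated at ``degree``.  The dense matrix form makes each application
    (and its adjoint, needed for gradients) a single matmul.
    """

    normalization: float  # N
    diffusion: float  # D
    radius_mm: float
    degree: int
    matrix: np.ndarray  # (n_nodes, n_nodes)

    def multiplier(self, l: np.ndarray | int) -> np.ndarray | float:
        return self.normalization - self.diffusion * np.multiply(l, np.add(l, 1))

    def apply(self, field: np.ndarray) -> np.ndarray:
        field = np.asarray(field, dtype=float)
        if field.shape[-1] != self.matrix.shape[1]:
            raise ValueError("field length does not match operator grid")
        return field @ self.matrix.T

    def apply_adjoint(self, field: np.ndarray) -> np.ndarray:
        return np.asarray(field, dtype=float) @ self.matrix


def build_local_coupling(
    grid: RegularSphericalGrid,
    radius_mm: float = 100.0,
    degree: int | None = None,
) -> LocalCouplingOperator:
    """Construct the homogeneous-coupling operator for a grid.

    ``degree`` (default: the grid's degree, itself defaulting to 32) truncates
    the spectral Laplacian part; the ``N psi`` term is exact regardless.
    """
    if degree is None:
        degree = grid.lmax
    if degree > grid.lmax:
        raise ValueError("operator degree exceeds grid capability")
    n_coef, d_coef = laplacian_kernel_coeffs(radius_mm)
    sht = SphericalHarmonicTransform(grid, degree)
    lap_mult = -d_coef * sht.degrees * (sht.degrees + 1)
    mat = (sht.synthesis * lap_mult[None, :]) @ sht.analysis
    mat[np.diag_indices_from(mat)] += n_coef
    return LocalCouplingOperator(
        normalization=n_coef,
        diffusion=d_coef,
        radius_mm=radius_mm,
        degree=int(degree),
        matrix=mat,
    )


def apply_local_coupling(field: np.ndarray, op: LocalCouplingOperator) -> np.ndarray:
    """Functional wrapper for :meth:`LocalCouplingOperator.apply`."""
    return op.apply(field)


def sigmoid(q: np.ndarray | float, theta: float = -1.0) -> np.ndarray | float:
    """Logistic firing-rate function ``S(q, theta) = 1 / (1 + exp(-(q - theta)))``."""
    return special.expit(np.asarray(q, dtype=float) - theta)
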