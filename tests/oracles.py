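"""Independent brute-force oracles shared by the test suite."""

from __future__ import annotations

import numpy as np

from vepfield.geometry import RegularSphericalGrid
from vepfield.harmonics import SphericalHarmonicTransform


def direct_local_coupling(
    coeffs: np.ndarray,
    grid: RegularSphericalGrid,
    targets: np.ndarray,
    radius_mm: float = 100.0,
    n_theta: int = 60,
    n_phi: int = 48,
    theta_max: float = 0.25,
) -> np.ndarray:
    """Surface quadrature of the Laplacian-kernel convolution at target nodes.

    For each target, integrates ``e^{-r thbar}/2 * psi`` over the sphere in a
    rotated frame centred on the target (the kernel confines the integrand
    to ``thbar <~ theta_max`` for r = 100), with the band-limited field
    ``psi`` synthesized exactly from its coefficients at the quadrature
    points.  Independent of the spectral operator implementation.
    """
    sht = SphericalHarmonicTransform(grid)
    tnodes, tweights = np.polynomial.legendre.leggauss(n_theta)
    thbar = 0.5 * theta_max * (tnodes + 1.0)
    wth = 0.5 * theta_max * tweights
    phis = np.arange(n_phi) * (2 * np.pi / n_phi)
    wphi = 2 * np.pi / n_phi
    units = grid.unit_vectors()
    out = []
    for idx in targets:
        y = units[idx]
        helper = (
            np.array([1.0, 0.0, 0.0]) if abs(y[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        )
        e1 = np.cross(y, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(y, e1)
        pts = (
            np.sin(thbar)[:, None, None] * np.cos(phis)[None, :, None] * e1
            + np.sin(thbar)[:, None, None] * np.sin(phis)[None, :, None] * e2
            + np.cos(thbar)[:, None, None] * y
        )
        th_p = np.arccos(np.clip(pts[..., 2], -1, 1)).ravel()
        ph_p = np.arctan2(pts[..., 1], pts[..., 0]).ravel()
        psi = sht.evaluate(coeffs, th_p, ph_p).reshape(len(thbar), len(phis))
        kern = 0.5 * np.exp(-radius_mm * thbar) * np.sin(thbar)
        out.append(radius_mm**2 * wphi * np.sum(wth * kern * psi.sum(axis=1)))
    return np.array(out)
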