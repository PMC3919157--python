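"""Separable low-frequency cosine (DCT-II) bases.

Shared by the bias-field model and the small-deformation warp model.  A
field on an ``(n1, n2, n3)`` grid is represented by a coefficient array
``c[k1, k2, k3]`` through

    f(i, j, k) = sum_k c[k1,k2,k3] * b_k1(i) * b_k2(j) * b_k3(k)

with ``b_k(i) = cos(pi * k * (i + 0.5) / N)``.  The basis vectors are
exactly orthogonal under the discrete inner product, so full-grid least
squares reduces to a scaled tensor contraction.  Spatial frequencies are
expressed in millimetres (omega = pi * k / FOV_mm) so that derivative
penalties are invariant to voxel-size relabelling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dct_basis",
    "dct_basis_derivative",
    "n_orders_for_cutoff",
    "evaluate_field",
    "project_field",
]


def dct_basis(n: int, orders: int) -> np.ndarray:
    """Return an (n, orders) matrix of unit-amplitude cosine basis vectors."""
    i = np.arange(n)[:, None] + 0.5
    k = np.arange(orders)[None, :]
    return np.cos(np.pi * k * i / n)


def dct_basis_derivative(n: int, orders: int, spacing_mm: float, order: int = 1) -> np.ndarray:
    """Spatial derivative of the basis with respect to millimetre position.

    ``order`` 1 or 2.  Frequencies are ``pi * k / (n * spacing_mm)``.
    """
    i = np.arange(n)[:, None] + 0.5
    k = np.arange(orders)[None, :]
    omega = np.pi * k / (n * spacing_mm)
    phase = np.pi * k * i / n
    if order == 1:
        return -omega * np.sin(phase)
    if order == 2:
        return -(omega**2) * np.cos(phase)
    raise ValueError("derivative order must be 1 or 2")


def n_orders_for_cutoff(n: int, spacing_mm: float, cutoff_mm: float) -> int:
    """Number of basis orders (including DC) whose period is >= cutoff_mm.

    Basis order k on a field of view L has period 2L/k, so the highest
    retained order is floor(2L / cutoff).
    """
    fov = n * spacing_mm
    return int(np.floor(2.0 * fov / cutoff_mm)) + 1


def evaluate_field(coefs: np.ndarray, bases: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Evaluate a separable-basis field on the full grid.

    ``coefs`` has shape (k1, k2, k3); ``bases`` are the per-axis basis
    matrices with shapes (n_i, k_i).  Returns an (n1, n2, n3) array.
    """
    b1, b2, b3 = bases
    out = np.tensordot(coefs, b1, axes=(0, 1))  # (k2, k3, n1)
    out = np.tensordot(out, b2, axes=(0, 1))    # (k3, n1, n2)
    out = np.tensordot(out, b3, axes=(0, 1))    # (n1, n2, n3)
    return out


def project_field(field: np.ndarray, bases: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Least-squares coefficients of ``field`` on the full grid.

    Uses exact discrete orthogonality of the cosine vectors: the Gram
    matrix per axis is diagonal with entries n (k=0) and n/2 (k>0).
    """
    b1, b2, b3 = bases
    out = np.tensordot(field, b1, axes=(0, 0))  # (n2, n3, k1)
    out = np.tensordot(out, b2, axes=(0, 0))    # (n3, k1, k2)
    out = np.tensordot(out, b3, axes=(0, 0))    # (k1, k2, k3)
    for axis, b in enumerate((b1, b2, b3)):
        n, orders = b.shape
        gram = np.full(orders, n / 2.0)
        gram[0] = float(n)
        shape = [1, 1, 1]
        shape[axis] = orders
        out = out / gram.reshape(shape)
    return out
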