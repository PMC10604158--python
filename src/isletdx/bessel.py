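"""First-kind Bessel functions from their power series, and the derivative
operational matrix used by the windowed Bessel feature extractor.

J_n solves the Sturm-Liouville equation x^2 y'' + x y' + (x^2 - n^2) y = 0
and obeys J_n'(x) = (J_{n-1}(x) - J_{n+1}(x)) / 2, which the banded matrix D
encodes so that D applied to (J_0..J_n)^T yields the derivatives.

The series is alternating with terms growing to ~(x/2)^{2r}/(r!)^2 before
decaying, so a double-precision sum loses up to seven digits near x = 20.
Evaluation therefore runs in extended-precision decimal arithmetic, which
keeps the absolute error comfortably below 1e-10 on |x| <= 20, n <= 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, localcontext
from math import factorial

import numpy as np

_SERIES_PREC = 45
_MAX_TERMS = 400


def bessel_j(n: int, x: float) -> float:
    """J_n(x) for integer order n >= 0 via the defining power series.

    The series J_n(x) = sum_r (-1)^r / (r! Gamma(n+r+1)) (x/2)^{2r+n} is
    summed by the term recurrence t_{r+1} = -t_r * (x/2)^2 / ((r+1)(n+r+1));
    Gamma at integer arguments is the exact factorial.
    """
    if not float(n).is_integer() or n < 0:
        raise ValueError("integer orders n >= 0 only")
    n = int(n)
    with localcontext() as ctx:
        ctx.prec = _SERIES_PREC
        xd = Decimal(float(x))
        half = xd / 2
        q = half * half
        term = (Decimal(1) if n == 0 else half ** n) / Decimal(factorial(n))
        total = term
        stop = Decimal(10) ** (-_SERIES_PREC + 8)
        for r in range(1, _MAX_TERMS):
            term = -term * q / (r * (n + r))
            total += term
            if abs(term) <= stop * (abs(total) + Decimal(1)):
                break
        return float(total)


def bessel_j_vector(n_max: int, x: float) -> np.ndarray:
    """(J_0(x), ..., J_{n_max}(x))."""
    return np.array([bessel_j(k, x) for k in range(n_max + 1)])


def j0_first_zero(tol: float = 1e-12) -> float:
    """First positive zero of J_0 (~2.404826), by bisection on the series."""
    lo, hi = 2.0, 3.0
    flo = bessel_j(0, lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = bessel_j(0, mid)
        if (flo > 0) == (fm > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class BesselBasis:
    """Sampled Bessel basis: orders 0..order_max at fixed abscissae.

    ``basis_values[k, j] = J_k(abscissae[j])``.  The derivative operational
    matrix has first row (0, -1, 0, ...) from J_0' = -J_1 and interior rows
    (..., 1/2, 0, -1/2, ...) from the three-term recursion; the last row
    uses J_n'(x) = J_{n-1}(x) - (n/x) J_n(x) and is therefore x-dependent.
    """

    order_max: int
    abscissae: np.ndarray
    basis_values: np.ndarray

    @classmethod
    def build(cls, order_max: int, abscissae) -> "BesselBasis":
        if order_max < 0:
            raise ValueError("order_max must be >= 0")
        xs = np.asarray(abscissae, dtype=float)
        vals = np.array([[bessel_j(k, x) for x in xs] for k in range(order_max + 1)])
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite basis values")
        return cls(order_max, xs, vals)

    def derivative_matrix(self, x: float) -> np.ndarray:
        """(n+1)x(n+1) matrix D with D @ (J_0..J_n)(x) = (J_0'..J_n')(x)."""
        n = self.order_max
        D = np.zeros((n + 1, n + 1))
        if n >= 1:
            D[0, 1] = -1.0
        for k in range(1, n):
            D[k, k - 1] = 0.5
            D[k, k + 1] = -0.5
        if n >= 1:
            if x == 0:
                raise ValueError("last-row coefficients undefined at x = 0")
            D[n, n - 1] = 1.0
            D[n, n] = -n / x
        return D

    def j0_vector(self) -> np.ndarray:
        return self.basis_values[0]


def _fd_derivative(n: int, x: float, h: float) -> float:
    return (bessel_j(n, x + h) - bessel_j(n, x - h)) / (2 * h)


def bessel_derivative_check(basis: BesselBasis, x: float, h: float = 1e-6) -> float:
    """Max abs error of the derivative recursion at ``x``.

    Compares J_k'(x) (central finite difference) against
    (J_{k-1}(x) - J_{k+1}(x)) / 2 for k = 1..n-1, and validates the same
    rows of ``derivative_matrix`` applied to the Bessel vector.
    """
    n = basis.order_max
    if n < 2:
        raise ValueError("need order_max >= 2 to check interior rows")
    jv = bessel_j_vector(n, x)
    fd = np.array([_fd_derivative(k, x, h) for k in range(n + 1)])
    errs = []
    for k in range(1, n):
        rec = 0.5 * (jv[k - 1] - jv[k + 1])
        errs.append(abs(fd[k] - rec))
    if x != 0:
        dj = basis.derivative_matrix(x) @ jv
        errs.extend(abs(dj[k] - fd[k]) for k in range(0, n))
    else:
        # row-0 special form: J_0'(0) = 0 = (J_{-1} - J_1)/2 by symmetry
        errs.append(abs(fd[0] - 0.0))
    return float(max(errs))


def sturm_liouville_residual(n: int, x: float, h: float = 2e-4) -> float:
    """|x^2 J'' + x J' + (x^2 - n^2) J| at ``x`` with finite-difference
    derivatives; near zero for the true Bessel function."""
    j = bessel_j(n, x)
    j1 = _fd_derivative(n, x, h)
    j2 = (bessel_j(n, x + h) - 2 * j + bessel_j(n, x - h)) / h ** 2
    return abs(x ** 2 * j2 + x * j1 + (x ** 2 - n ** 2) * j)
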