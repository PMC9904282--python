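"""Closed-form reference solutions in spherically symmetric conductors.

EEG: Legendre-series surface potential of a current dipole inside a
multilayer concentric-sphere conductor, with per-degree radial transfer
coefficients obtained from the interface/boundary conditions of the
piecewise potential  u_j = A_j r^n + B_j r^-(n+1).  The homogeneous-sphere
special case also has a fully closed form (generating-function summation of
the series), exposed separately as an independent cross-check.

MEG: the Sarvas closed-form magnetic field of a dipole in any spherically
symmetric conductor — independent of the layer conductivities, exactly
zero for radial dipoles and for dipoles at the center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU0 = 4e-7 * np.pi  # T*m/A, exact


class AnalyticError(ValueError):
    pass


@dataclass(frozen=True)
class SphereModel:
    """Concentric-sphere conductor: radii descending (m), conductivities
    outermost first (S/m)."""

    center: np.ndarray
    radii: tuple
    conductivities: tuple

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        r = tuple(float(x) for x in self.radii)
        s = tuple(float(x) for x in self.conductivities)
        if len(r) != len(s):
            raise AnalyticError("radii and conductivities must pair up")
        if any(b >= a for a, b in zip(r, r[1:])) or r[-1] <= 0:
            raise AnalyticError("radii must be strictly decreasing, positive")
        if any(x <= 0 for x in s):
            raise AnalyticError("conductivities must be positive")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "conductivities", s)


# ---------------------------------------------------------------------------
# Legendre recurrences (vectorized over evaluation points)
# ---------------------------------------------------------------------------

def _legendre_iter(c: np.ndarray, nmax: int):
    """Yield (n, P_n(c), P_n^1(c)) for n = 1..nmax.

    Convention P_n^1 = sin(theta) dP_n/dc (no Condon-Shortley phase), so
    P_1^1 = sin(theta) >= 0.
    """
    s = np.sqrt(np.clip(1 - c * c, 0.0, 1.0))
    p_nm1 = np.ones_like(c)  # P_0
    p_n = c.copy()  # P_1
    q_nm1 = np.zeros_like(c)  # P_0^1
    q_n = s.copy()  # P_1^1
    yield 1, p_n, q_n
    for n in range(2, nmax + 1):
        p_np1 = ((2 * n - 1) * c * p_n - (n - 1) * p_nm1) / n
        q_np1 = ((2 * n - 1) * c * q_n - n * q_nm1) / (n - 1)
        p_nm1, p_n = p_n, p_np1
        q_nm1, q_n = q_n, q_np1
        yield n, p_n, q_n


# ---------------------------------------------------------------------------
# multilayer EEG series
# ---------------------------------------------------------------------------

def _surface_coefficient(n: int, x: np.ndarray, sig: np.ndarray, t: float) -> float:
    """Scaled per-degree surface transfer value g_n such that the surface
    potential is  sum_n g_n [ n m_r P_n + m_t P_n^1 cos(phi) ] / (4 pi sig_in R^2).

    ``x`` are interface+outer radii scaled by the outer radius (ascending,
    x[-1] == 1), ``sig`` the conductivities inside-out, ``t`` the scaled
    dipole radius.  Layer basis functions are normalized per layer to keep
    the linear system well conditioned at large n.
    """
    M = len(sig)
    pn = t ** (n - 1)  # scaled primary strength
    if M == 1:
        return pn * (2 * n + 1) / n
    # unknowns: [A1h] + [Ajh, Bjh for j=2..M]; layer j in [x[j-2], x[j-1]]
    # layer basis: Ajh*(rho/xt)^n + Bjh*(xb/rho)^(n+1), xt/xb = layer top/bottom
    nun = 2 * M - 1
    A = np.zeros((nun, nun))
    b = np.zeros(nun)

    def col_A(j):  # index of Ajh
        return 0 if j == 1 else 2 * j - 3

    def col_B(j):
        return 2 * j - 2

    def top(j):
        return x[j - 1]

    def bot(j):
        return 0.0 if j == 1 else x[j - 2]

    row = 0
    for j in range(1, M):
        xj = top(j)
        # continuity at xj: layer j (at its top) = layer j+1 (at its bottom)
        A[row, col_A(j)] = 1.0
        if j > 1:
            A[row, col_B(j)] = (bot(j) / xj) ** (n + 1)
        A[row, col_A(j + 1)] = -((xj / top(j + 1)) ** n)
        A[row, col_B(j + 1)] = -1.0
        if j == 1:
            b[row] = -pn * xj ** (-(n + 1))
        row += 1
        # current flux continuity (common 1/rho factor dropped)
        A[row, col_A(j)] = sig[j - 1] * n
        if j > 1:
            A[row, col_B(j)] = -sig[j - 1] * (n + 1) * (bot(j) / xj) ** (n + 1)
        A[row, col_A(j + 1)] = -sig[j] * n * (xj / top(j + 1)) ** n
        A[row, col_B(j + 1)] = sig[j] * (n + 1)
        if j == 1:
            b[row] = sig[0] * (n + 1) * pn * xj ** (-(n + 1))
        row += 1
    # outer no-flux at rho = 1 (top(M) == 1)
    A[row, col_A(M)] = sig[M - 1] * n
    A[row, col_B(M)] = -sig[M - 1] * (n + 1) * bot(M) ** (n + 1)
    sol = np.linalg.solve(A, b)
    return float(sol[col_A(M)] + sol[col_B(M)] * bot(M) ** (n + 1))


def eeg_sphere_potential(model: SphereModel, dipole, electrode_positions,
                         max_terms: int = 200, rel_tol: float = 1e-12) -> np.ndarray:
    """Average-referenced surface potentials (V) at electrodes on the outer
    sphere, for a dipole inside the innermost region containing it."""
    from .sources import Dipole  # noqa: F401  (duck-typed: position/moment)

    pos = np.asarray(dipole.position, dtype=float) - model.center
    mom = np.asarray(dipole.moment, dtype=float)
    R = model.radii[0]
    b = np.linalg.norm(pos)
    if b >= R:
        raise AnalyticError("dipole lies outside the conductor")
    elec = np.asarray(electrode_positions, dtype=float).reshape(-1, 3) - model.center
    er = np.linalg.norm(elec, axis=1)
    if (er == 0).any():
        raise AnalyticError("electrode at sphere center")
    elec = elec / er[:, None] * R  # project to the outer surface

    # local frame: z along dipole radius (or moment if central dipole)
    if b > 1e-14 * R:
        ez = pos / b
    else:
        mn = np.linalg.norm(mom)
        ez = mom / mn if mn > 0 else np.array([0.0, 0.0, 1.0])
    m_r = mom @ ez
    mt_vec = mom - m_r * ez
    mt = np.linalg.norm(mt_vec)
    ex = mt_vec / mt if mt > 1e-300 else _any_perpendicular(ez)
    ey = np.cross(ez, ex)

    ce = (elec @ ez) / R  # cos(theta) per electrode
    xe = elec @ ex
    ye = elec @ ey
    rho_t = np.hypot(xe, ye)
    cphi = np.where(rho_t > 0, xe / np.maximum(rho_t, 1e-300), 1.0)

    sig = np.array(model.conductivities[::-1])  # inside-out
    x = np.array(model.radii[::-1]) / R  # ascending, last == 1
    t = b / R

    V = np.zeros(len(elec))
    scale = 1.0 / (4 * np.pi * sig[0] * R * R)
    vmax = 0.0
    for n, Pn, Pn1 in _legendre_iter(ce, max_terms):
        g = _surface_coefficient(n, x, sig, t)
        term = scale * g * (n * m_r * Pn + mt * Pn1 * cphi)
        V += term
        vmax = max(vmax, np.abs(V).max())
        if n >= 10 and np.abs(term).max() < rel_tol * max(vmax, 1e-300):
            break
    return V - V.mean()


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# homogeneous sphere closed form (independent cross-check of the series)
# ---------------------------------------------------------------------------

def homogeneous_sphere_potential(radius: float, sigma: float, dipole,
                                 electrode_positions, center=(0, 0, 0)) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Obtained by generating-function summation of the Legendre series:
    with t = b/R, D = d/R (d the dipole-electrode distance) the radial and
    tangential parts sum to elementary functions.  Average-referenced.
    """
    center = np.asarray(center, dtype=float)
    pos = np.asarray(dipole.position, dtype=float) - center
    mom = np.asarray(dipole.moment, dtype=float)
    R = float(radius)
    b = np.linalg.norm(pos)
    elec = np.asarray(electrode_positions, dtype=float).reshape(-1, 3) - center
    elec = elec / np.linalg.norm(elec, axis=1)[:, None] * R

    if b < 1e-14 * R:
        # central dipole: only the n=1 term survives, V = 3 m.r / (4 pi sig R^3)
        V = 3.0 * (elec @ mom) / (4 * np.pi * sigma * R**3)
        return V - V.mean()

    ez = pos / b
    m_r = mom @ ez
    mt_vec = mom - m_r * ez
    mt = np.linalg.norm(mt_vec)
    ex = mt_vec / mt if mt > 1e-300 else _any_perpendicular(ez)

    c = (elec @ ez) / R
    s = np.sqrt(np.clip(1 - c * c, 0, 1))
    xe = elec @ ex
    ye = elec @ np.cross(ez, ex)
    rho_t = np.hypot(xe, ye)
    cphi = np.where(rho_t > 0, xe / np.maximum(rho_t, 1e-300), 1.0)

    t = b / R
    D = np.sqrt(1 - 2 * t * c + t * t)  # scaled dipole-electrode distance
    d3 = (R * D) ** 3

    # radial: sum (2n+1)/n t^(n-1) [n P_n] / R^2 summed in closed form
    rad = 2 * (R * c - b) / d3 + (1.0 / b) * (1.0 / (R * D) - 1.0 / R)
    # tangential: 2 R s / d^3 + (s/(b R)) * t (D+1) / (D (1 - t c + D))
    tang = 2 * R * s / d3 + s * (D + 1) / (R * R * D * (1 - t * c + D))

    V = (m_r * rad + mt * cphi * tang) / (4 * np.pi * sigma)
    return V - V.mean()


# ---------------------------------------------------------------------------
# Sarvas MEG field
# ---------------------------------------------------------------------------

def sarvas_field(model: SphereModel, dipole, points: np.ndarray) -> np.ndarray:
    """Magnetic field (T) at points outside a spherically symmetric
    conductor, Sarvas closed form; independent of layer conductivities."""
    center = model.center
    r0 = np.asarray(dipole.position, dtype=float) - center
    q = np.asarray(dipole.moment, dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 3) - center
    rn = np.linalg.norm(pts, axis=1)
    if (rn <= model.radii[0] * (1 - 1e-12)).any():
        raise AnalyticError("field point inside the conductor")
    a_vec = pts - r0
    a = np.linalg.norm(a_vec, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, pts)
    F = a * (rn * a + rn**2 - pts @ r0)
    gradF = (
        (a**2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * pts
        - (a + 2 * rn + ar / a)[:, None] * r0
    )
    qxr0 = np.cross(q, r0)
    B = (MU0 / (4 * np.pi * F**2))[:, None] * (
        F[:, None] * qxr0 - (pts @ qxr0)[:, None] * gradF
    )
    return B


def meg_sphere_field(model: SphereModel, dipole, coils) -> np.ndarray:
    """Per-channel Sarvas readings (T) for a coil model (integration points
    projected on orientations, weighted and summed per channel)."""
    readings = np.zeros(len(coils.channels))
    for i, ch in enumerate(coils.channels):
        B = sarvas_field(model, dipole, ch.points)
        readings[i] = float(np.sum(ch.weights * np.einsum("ij,ij->i", B, ch.orientations)))
    return readings
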