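"""Pontryagin extremal flow of the sub-Riemannian problem on SIM(2).

The time-optimal problem with controls on the unit ball in the
(X1, X3, X4) directions is treated through the Pontryagin maximum
principle.  In the left-invariant momenta ``h = (h1, h2, h3, h4)`` the
maximized Hamiltonian of the normal case is ``H = h1^2 + h3^2 + h4^2``
(normalized to 1 by arc length), the extremal controls are
``u1 = h1, u3 = h3, u4 = h4``, and the joint state obeys

    x'  = h1 e^sigma cos theta      h1' =  h3 h2 + h4 h1
    y'  = h1 e^sigma sin theta      h2' = -h3 h1 + h4 h2
    th' = h3                        h3' = -h1 h2
    s'  = h4                        h4' = -h1^2

Besides H, the flow conserves the two right-invariant integrals

    g1 = e^{-sigma} (h1 cos theta - h2 sin theta)
    g2 = e^{-sigma} (h2 cos theta + h1 sin theta)

which are the (constant) chart momenta p1, p2.  Two families admit
closed forms: the abnormal extremals (pure scale lines, x=y=theta=0,
sigma=+-t) and the fiber geodesics with h1(0)=h2(0)=0, where
theta = h30 t, sigma = h40 t; the latter stay optimal up to the
Maxwell time pi/|h30| at which the +-h30 pair meets again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .group import GroupElement, multiply, wrap_angle

__all__ = [
    "Covector",
    "ExtremalState",
    "ExtremalTrajectory",
    "pontryagin_value",
    "normal_rhs",
    "exponential_map",
    "abnormal_trajectory",
    "fiber_geodesic",
    "maxwell_pair",
    "first_integrals",
    "chart_momentum",
    "frame_momentum",
    "poisson_matrix",
    "vertical_tail",
    "first_identity_return",
    "random_unit_covectors",
]

_RTOL = 1e-12
_ATOL = 1e-14


@dataclass(frozen=True)
class Covector:
    """Vertical coordinates (h1, h2, h3, h4) in the left-invariant frame."""

    h1: float
    h2: float
    h3: float
    h4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.h1, self.h2, self.h3, self.h4], dtype=float)

    @property
    def hamiltonian(self) -> float:
        """H = h1^2 + h3^2 + h4^2 (quadratic convention)."""
        return self.h1**2 + self.h3**2 + self.h4**2

    def is_unit(self, tol: float = 1e-9) -> bool:
        return abs(self.hamiltonian - 1.0) <= tol

    def renormalized(self) -> "Covector":
        """Rescale so that h1^2 + h3^2 + h4^2 = 1 (h2 scaled along)."""
        n = math.sqrt(self.hamiltonian)
        if n == 0.0:
            raise ValueError("cannot normalize a covector with H = 0")
        return Covector(self.h1 / n, self.h2 / n, self.h3 / n, self.h4 / n)

    @classmethod
    def from_array(cls, a) -> "Covector":
        a = np.asarray(a, dtype=float)
        return cls(a[0], a[1], a[2], a[3])

    def to_dict(self) -> dict:
        return {"h1": self.h1, "h2": self.h2, "h3": self.h3, "h4": self.h4}


@dataclass(frozen=True)
class ExtremalState:
    """Joint horizontal/vertical state (q, h)."""

    q: GroupElement
    h: Covector

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.q.as_array(), self.h.as_array()])


@dataclass
class ExtremalTrajectory:
    """A time-sampled normal (or abnormal) extremal.

    ``q`` holds chart coordinates with theta *unwrapped* (continuous in
    t); use :meth:`state_at` / :meth:`endpoint` for wrapped group
    elements.  ``conserved`` logs (H, g1, g2) per sample.
    """

    times: np.ndarray          # (n,)
    q: np.ndarray              # (n, 4): x, y, theta (unwrapped), sigma
    h: np.ndarray              # (n, 4): h1..h4
    conserved: np.ndarray = field(default=None)  # (n, 3): H, g1, g2
    base: GroupElement = field(default_factory=GroupElement.identity)
    _dense = None              # optional scipy OdeSolution in local coords

    def __post_init__(self):
        if self.conserved is None:
            self.conserved = _conserved_log(self.q, self.h)

    @property
    def controls(self) -> np.ndarray:
        """Extremal controls (u1, u3, u4) = (h1, h3, h4) per sample."""
        return self.h[:, [0, 2, 3]]

    @property
    def length(self) -> float:
        return float(self.times[-1] - self.times[0])

    def state_at(self, i: int) -> ExtremalState:
        qi = GroupElement(*self.q[i])
        if self.base != GroupElement.identity():
            qi = multiply(self.base, qi)
        return ExtremalState(qi, Covector.from_array(self.h[i]))

    def endpoint(self) -> GroupElement:
        return self.state_at(len(self.times) - 1).q

    def conservation_drift(self) -> np.ndarray:
        """Max absolute drift of (H, g1, g2) relative to their t=0 values."""
        ref = self.conserved[0]
        scale = np.maximum(np.abs(ref), 1.0)
        return np.abs(self.conserved - ref).max(axis=0) / scale

    def max_speed_deviation(self) -> float:
        """Max deviation of the horizontal speed sqrt(u1^2+u3^2+u4^2) from 1."""
        sp = np.sqrt((self.controls**2).sum(axis=1))
        return float(np.abs(sp - 1.0).max())

    def max_contact_violation(self, dt: float = 1e-4) -> float:
        """Max |omega(dq/dt)| via central differences of the dense flow."""
        if self._dense is None:
            raise ValueError("trajectory has no dense solution attached")
        t = self.times
        ts = np.clip(t, t[0] + dt, t[-1] - dt)
        worst = 0.0
        for ti in ts:
            ya = self._dense(ti - dt)
            yb = self._dense(ti + dt)
            v = (yb[:4] - ya[:4]) / (2 * dt)
            ym = self._dense(ti)
            val = math.exp(-ym[3]) * (-math.sin(ym[2]) * v[0] + math.cos(ym[2]) * v[1])
            worst = max(worst, abs(val))
        return worst

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "t": self.times,
            "x": self.q[:, 0], "y": self.q[:, 1],
            "theta": self.q[:, 2], "sigma": self.q[:, 3],
            "h1": self.h[:, 0], "h2": self.h[:, 1],
            "h3": self.h[:, 2], "h4": self.h[:, 3],
            "H": self.conserved[:, 0],
            "g1": self.conserved[:, 1], "g2": self.conserved[:, 2],
        }
        return pd.DataFrame(cols)


def _conserved_log(q: np.ndarray, h: np.ndarray) -> np.ndarray:
    H = h[:, 0] ** 2 + h[:, 2] ** 2 + h[:, 3] ** 2
    ems = np.exp(-q[:, 3])
    c, s = np.cos(q[:, 2]), np.sin(q[:, 2])
    g1 = ems * (h[:, 0] * c - h[:, 1] * s)
    g2 = ems * (h[:, 1] * c + h[:, 0] * s)
    return np.column_stack([H, g1, g2])


def pontryagin_value(h: Covector, u) -> float:
    """Pontryagin function H_u = u1 h1 + u3 h3 + u4 h4."""
    ua = u.as_array() if hasattr(u, "as_array") else np.asarray(u, dtype=float)
    return float(ua[0] * h.h1 + ua[1] * h.h3 + ua[2] * h.h4)


def _rhs(t: float, y: np.ndarray) -> np.ndarray:
    es = math.exp(y[3])
    c, s = math.cos(y[2]), math.sin(y[2])
    h1, h2, h3, h4 = y[4], y[5], y[6], y[7]
    return np.array([
        h1 * es * c,
        h1 * es * s,
        h3,
        h4,
        h3 * h2 + h4 * h1,
        -h3 * h1 + h4 * h2,
        -h1 * h2,
        -h1 * h1,
    ])


def normal_rhs(s: ExtremalState) -> np.ndarray:
    """Derivative of the joint state (q, h) along the normal flow."""
    return _rhs(0.0, s.as_array())


def exponential_map(
    h0: Covector,
    T: float,
    n_samples: int = 200,
    base: GroupElement | None = None,
    renormalize: bool = False,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> ExtremalTrajectory:
    """Integrate the normal system from the identity (or ``base``).

    ``h0`` must lie on the level set C = {h1^2 + h3^2 + h4^2 = 1}
    (tolerance 1e-9) unless ``renormalize`` is set, in which case it is
    first projected onto C.
    """
    if T < 0:
        raise ValueError("T must be nonnegative")
    if not h0.is_unit():
        if renormalize:
            h0 = h0.renormalized()
        else:
            raise ValueError(
                "initial covector is off the level set h1^2+h3^2+h4^2=1; "
                "pass renormalize=True to project it"
            )
    base = base or GroupElement.identity()
    y0 = np.concatenate([np.zeros(4), h0.as_array()])
    times = np.linspace(0.0, T, max(2, n_samples))
    if T == 0.0:
        q = np.zeros((1, 4))
        h = h0.as_array()[None, :]
        return ExtremalTrajectory(np.array([0.0]), q, h, base=base)
    sol = solve_ivp(
        _rhs, (0.0, T), y0, method="DOP853", dense_output=True,
        rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover - DOP853 on smooth field
        raise RuntimeError(f"integration failed: {sol.message}")
    ys = sol.sol(times).T
    traj = ExtremalTrajectory(times, ys[:, :4].copy(), ys[:, 4:].copy(), base=base)
    traj._dense = sol.sol
    return traj


def abnormal_trajectory(T: float, direction: int = 1, n_samples: int = 200) -> ExtremalTrajectory:
    """Closed-form abnormal optimal trajectory: a pure scale line.

    x = y = theta = 0, sigma = +-t; unit speed.  It coincides with the
    normal fiber geodesic with (h30, h40) = (0, +-1), so abnormal
    extremals here are not strictly abnormal.
    """
    if T < 0:
        raise ValueError("T must be nonnegative")
    sgn = 1.0 if direction >= 0 else -1.0
    t = np.linspace(0.0, T, max(2, n_samples))
    q = np.zeros((len(t), 4))
    q[:, 3] = sgn * t
    h = np.tile([0.0, 0.0, 0.0, sgn], (len(t), 1))
    return ExtremalTrajectory(t, q, h)


def fiber_geodesic(
    h30: float, h40: float, T: float, n_samples: int = 200
) -> tuple[ExtremalTrajectory, float]:
    """Closed-form fiber geodesic and its cut time.

    For h1(0)=h2(0)=0 the motion stays over the identity's retinal
    point: theta = h30 t, sigma = h40 t.  The geodesic is optimal up to
    ``pi/|h30|`` (infinite when h30 = 0).
    """
    if abs(h30**2 + h40**2 - 1.0) > 1e-9:
        raise ValueError("fiber geodesic requires h30^2 + h40^2 = 1")
    t = np.linspace(0.0, T, max(2, n_samples))
    q = np.zeros((len(t), 4))
    q[:, 2] = h30 * t
    q[:, 3] = h40 * t
    h = np.tile([0.0, 0.0, h30, h40], (len(t), 1))
    cut = math.pi / abs(h30) if h30 != 0.0 else math.inf
    return ExtremalTrajectory(t, q, h), cut


def maxwell_pair(
    h30: float, h40: float, horizon_factor: float = 2.5, tol: float = 1e-10
) -> tuple[float, GroupElement]:
    """First meeting of the fiber-geodesic pair with h3(0) = +-h30.

    Integrates both extremals numerically and locates the first time at
    which they reach the same configuration (bisection on the angular
    coincidence function sin((theta_+ - theta_-)/2), then full-state
    verification).  Returns (meeting time, meeting configuration).
    """
    if h30 == 0.0:
        raise ValueError("h30 = 0 has no Maxwell point (geodesic optimal forever)")
    if abs(h30**2 + h40**2 - 1.0) > 1e-9:
        raise ValueError("requires h30^2 + h40^2 = 1")
    horizon = horizon_factor * math.pi / abs(h30)
    plus = exponential_map(Covector(0, 0, h30, h40), horizon, n_samples=50)
    minus = exponential_map(Covector(0, 0, -h30, h40), horizon, n_samples=50)

    def fang(t):
        return math.sin(0.5 * (plus._dense(t)[2] - minus._dense(t)[2]))

    ts = np.linspace(1e-6, horizon, 4000)
    vals = np.array([fang(t) for t in ts])
    for k in range(len(ts) - 1):
        if vals[k] == 0.0 or vals[k] * vals[k + 1] < 0:
            t_meet = brentq(fang, ts[k], ts[k + 1], xtol=tol)
            ya, yb = plus._dense(t_meet), minus._dense(t_meet)
            qa = GroupElement(*ya[:4])
            qb = GroupElement(*yb[:4])
            err = math.sqrt(
                (qa.x - qb.x) ** 2 + (qa.y - qb.y) ** 2
                + wrap_angle(qa.theta - qb.theta) ** 2 + (qa.sigma - qb.sigma) ** 2
            )
            if err < 1e-6:
                return t_meet, qa
    raise RuntimeError("no Maxwell meeting found within the horizon")


def first_integrals(s: ExtremalState) -> tuple[float, float, float]:
    """(H, g1, g2) at a joint state; all three are conserved by the flow."""
    h, q = s.h, s.q
    H = h.h1**2 + h.h3**2 + h.h4**2
    ems = math.exp(-q.sigma)
    c, sn = math.cos(q.theta), math.sin(q.theta)
    g1 = ems * (h.h1 * c - h.h2 * sn)
    g2 = ems * (h.h2 * c + h.h1 * sn)
    return H, g1, g2


def chart_momentum(h: Covector, q: GroupElement) -> np.ndarray:
    """Chart momenta (p1..p4) from frame momenta at q."""
    ems = math.exp(-q.sigma)
    c, s = math.cos(q.theta), math.sin(q.theta)
    return np.array([
        ems * (h.h1 * c - h.h2 * s),
        ems * (h.h1 * s + h.h2 * c),
        h.h3,
        h.h4,
    ])


def frame_momentum(p: np.ndarray, q: GroupElement) -> Covector:
    """Frame momenta (h1..h4) from chart momenta at q (inverse map)."""
    p = np.asarray(p, dtype=float)
    es = math.exp(q.sigma)
    c, s = math.cos(q.theta), math.sin(q.theta)
    return Covector(
        es * (p[0] * c + p[1] * s),
        es * (p[1] * c - p[0] * s),
        p[2],
        p[3],
    )


def poisson_matrix(h: Covector) -> tuple[np.ndarray, float, int]:
    """Poisson bivector P_ij = {h_i, h_j}, its determinant and rank.

    Nonzero brackets: {h1,h3} = -h2, {h1,h4} = -h1, {h2,h3} = h1,
    {h2,h4} = -h2.  det P = (h1^2 + h2^2)^2, so the coadjoint orbit has
    rank 0 on the fiber axis h1 = h2 = 0 and rank 4 otherwise.
    """
    U = np.zeros((4, 4))
    U[0, 2], U[0, 3] = -h.h2, -h.h1
    U[1, 2], U[1, 3] = h.h1, -h.h2
    P = U - U.T
    det = float(np.linalg.det(P))
    rank = int(np.linalg.matrix_rank(P, tol=1e-12))
    return P, det, rank


def _vertical_rhs(t, h):
    h1, h2, h3, h4 = h
    return [h3 * h2 + h4 * h1, -h3 * h1 + h4 * h2, -h1 * h2, -h1 * h1]


@dataclass(frozen=True)
class VerticalTailReport:
    """Diagnostics of the vertical subsystem at a long horizon."""

    T: float
    h_final: np.ndarray
    abs_h1: float
    abs_h2: float
    h3sq_plus_h4sq: float
    h4_nonincreasing: bool


def vertical_tail(h0: Covector, T_long: float = 50.0, n_samples: int = 2000) -> VerticalTailReport:
    """Integrate only the vertical part and report its asymptotics.

    For h1(0)^2 + h2(0)^2 > 0 and h4(0) < 0 the momenta h1, h2 decay to
    zero while h3, h4 settle on the unit circle (h4 is non-increasing
    along any normal extremal since h4' = -h1^2).  The h4(0) >= 0 case
    is reported as a numerical observation only.
    """
    if T_long < 10:
        raise ValueError("tail diagnostics need T_long >= 10")
    t = np.linspace(0.0, T_long, n_samples)
    sol = solve_ivp(
        _vertical_rhs, (0.0, T_long), h0.as_array(), t_eval=t,
        method="DOP853", rtol=_RTOL, atol=_ATOL,
    )
    hs = sol.y.T
    h4 = hs[:, 3]
    noninc = bool(np.all(np.diff(h4) <= 1e-10))
    hf = hs[-1]
    return VerticalTailReport(
        T=T_long,
        h_final=hf,
        abs_h1=float(abs(hf[0])),
        abs_h2=float(abs(hf[1])),
        h3sq_plus_h4sq=float(hf[2] ** 2 + hf[3] ** 2),
        h4_nonincreasing=noninc,
    )


def first_identity_return(
    h0: Covector, t_max: float = 10.0, coarse: int = 4000, tol: float = 1e-8
) -> float:
    """First time t > 0 at which Exp(h0, t) returns to the identity.

    Located blind from the numerically integrated flow: a coarse scan
    of the configuration distance to Id followed by bounded scalar
    minimization on the bracketing interval.
    """
    traj = exponential_map(h0, t_max, n_samples=50)
    dense = traj._dense

    def dist(t):
        y = dense(t)
        return math.sqrt(
            y[0] ** 2 + y[1] ** 2 + wrap_angle(y[2]) ** 2 + y[3] ** 2
        )

    ts = np.linspace(0.0, t_max, coarse)
    ds = np.array([dist(t) for t in ts])
    start = int(np.argmax(ds > 0.1)) if np.any(ds > 0.1) else 1
    for k in range(max(start, 1), coarse - 1):
        if ds[k] <= ds[k - 1] and ds[k] <= ds[k + 1] and ds[k] < 0.1:
            # dist^2 is smooth across a transversal return; dist is not
            res = minimize_scalar(
                lambda t: dist(t) ** 2, bounds=(ts[k - 1], ts[k + 1]),
                method="bounded", options={"xatol": 1e-13},
            )
            if math.sqrt(max(res.fun, 0.0)) < tol:
                return float(res.x)
    raise RuntimeError("no identity return found within t_max")


def random_unit_covectors(n: int, rng: np.random.Generator, h2_scale: float = 1.0) -> list[Covector]:
    """Draw covectors uniformly on the level set C = {h1^2+h3^2+h4^2 = 1}.

    h2 is unconstrained on C; it is drawn normal with the given scale.
    """
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    h2 = rng.normal(scale=h2_scale, size=n)
    return [Covector(v[i, 0], h2[i], v[i, 1], v[i, 2]) for i in range(n)]
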