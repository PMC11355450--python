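"""The similarity group SIM(2) of the plane.

SIM(2) collects the orientation-preserving similarity transformations:
translations, rotations and dilations.  In the cortical model it is the
configuration space of V1-like simple cells: a configuration
``q = (x, y, theta, sigma)`` holds a retinal position, a preferred
orientation ``theta`` on the circle, and a log-thickness ``sigma`` (the
contour thickness is ``kappa = exp(sigma)``).

An element acts on the plane through the homogeneous 3x3 matrix

    [ e^s cos(t)  -e^s sin(t)  x ]
    [ e^s sin(t)   e^s cos(t)  y ]
    [     0            0       1 ]

and all group operations here go through that representation, so the
matrix is the single source of truth for products and inverses.

The admissible ("horizontal") directions of motion are spanned by the
left-invariant frame fields X1, X3, X4; X2 is transversal and is cut out
by the contact one-form ``omega = e^{-sigma} (-sin t dx + cos t dy)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupElement",
    "MetricParams",
    "ControlVector",
    "wrap_angle",
    "identity",
    "multiply",
    "inverse",
    "frame_components",
    "frame_matrix",
    "contact_pairing",
    "horizontal_speed",
    "structure_constants",
    "bracket_numeric",
    "hormander_span_dimension",
]

_TWO_PI = 2.0 * math.pi


def wrap_angle(theta: float) -> float:
    """Wrap an angle to the interval (-pi, pi].  Idempotent."""
    w = math.remainder(float(theta), _TWO_PI)
    if w <= -math.pi:
        w += _TWO_PI
    return w


def wrap_angle_array(theta: np.ndarray) -> np.ndarray:
    """Vectorized :func:`wrap_angle`."""
    w = np.remainder(np.asarray(theta, dtype=float) + np.pi, _TWO_PI) - np.pi
    return np.where(w <= -np.pi, w + _TWO_PI, w)


@dataclass(frozen=True)
class GroupElement:
    """A configuration q = (x, y, theta, sigma) in SIM(2).

    ``theta`` is stored wrapped to (-pi, pi]; ``sigma`` is the natural
    logarithm of the thickness kappa.
    """

    x: float
    y: float
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        object.__setattr__(self, "theta", wrap_angle(self.theta))
        object.__setattr__(self, "sigma", float(self.sigma))

    @property
    def kappa(self) -> float:
        """Contour thickness kappa = exp(sigma)."""
        return math.exp(self.sigma)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta, self.sigma])

    def matrix(self) -> np.ndarray:
        """The homogeneous 3x3 matrix representation."""
        es = math.exp(self.sigma)
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array(
            [
                [es * c, -es * s, self.x],
                [es * s, es * c, self.y],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "GroupElement":
        """Re-parse a homogeneous similarity matrix into (x, y, theta, sigma)."""
        m = np.asarray(m, dtype=float)
        scale = math.hypot(m[0, 0], m[1, 0])
        if scale <= 0.0:
            raise ValueError("matrix has non-positive scale; not in SIM(2)")
        return cls(m[0, 2], m[1, 2], math.atan2(m[1, 0], m[0, 0]), math.log(scale))

    @classmethod
    def identity(cls) -> "GroupElement":
        return cls(0.0, 0.0, 0.0, 0.0)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "theta": self.theta, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "GroupElement":
        return cls(d["x"], d["y"], d["theta"], d["sigma"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def __mul__(self, other: "GroupElement") -> "GroupElement":
        return multiply(self, other)


@dataclass(frozen=True)
class MetricParams:
    """Weights of the sub-Riemannian metric.

    ``alpha`` penalizes the orientation rate u3, ``beta`` the scale rate
    u4.  The geodesic flow is implemented for the model case
    alpha = beta = 1; other values are carried for length computations
    only.
    """

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("metric weights must be positive")

    @property
    def is_model_case(self) -> bool:
        return self.alpha == 1.0 and self.beta == 1.0


@dataclass(frozen=True)
class ControlVector:
    """Horizontal controls (u1, u3, u4): tangential, orientation, scale rates."""

    u1: float
    u3: float
    u4: float

    def is_admissible(self, tol: float = 1e-12) -> bool:
        """True iff u1^2 + u3^2 + u4^2 <= 1 (the control set U)."""
        return self.u1**2 + self.u3**2 + self.u4**2 <= 1.0 + tol

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u3, self.u4])


def identity() -> GroupElement:
    return GroupElement.identity()


def multiply(a: GroupElement, b: GroupElement) -> GroupElement:
    """Group product a.b via the matrix representation."""
    return GroupElement.from_matrix(a.matrix() @ b.matrix())


def inverse(a: GroupElement) -> GroupElement:
    """Group inverse via the matrix representation."""
    return GroupElement.from_matrix(np.linalg.inv(a.matrix()))


def frame_components(q: GroupElement) -> np.ndarray:
    """Chart components of the left-invariant frame X1..X4 at q.

    Returns a 4x4 array whose rows are the (x, y, theta, sigma)-chart
    velocity components of X1, X2, X3, X4:

        X1 = e^sigma ( cos t, sin t, 0, 0)
        X2 = e^sigma (-sin t, cos t, 0, 0)
        X3 = (0, 0, 1, 0)
        X4 = (0, 0, 0, 1)
    """
    es = math.exp(q.sigma)
    c, s = math.cos(q.theta), math.sin(q.theta)
    return np.array(
        [
            [es * c, es * s, 0.0, 0.0],
            [-es * s, es * c, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def frame_matrix(q: GroupElement) -> np.ndarray:
    """4x4 matrix whose COLUMNS are X1..X4 at q (chart components)."""
    return frame_components(q).T


def contact_pairing(q: GroupElement, v: np.ndarray) -> float:
    """Value of the contact one-form omega at q on the chart velocity v.

    omega = e^{-sigma} (-sin t dx + cos t dy); a velocity is horizontal
    iff this pairing vanishes.
    """
    v = np.asarray(v, dtype=float)
    return math.exp(-q.sigma) * (-math.sin(q.theta) * v[0] + math.cos(q.theta) * v[1])


def horizontal_speed(u: ControlVector, m: MetricParams = MetricParams()) -> float:
    """Pointwise speed sqrt(u1^2 + alpha^2 u3^2 + beta^2 u4^2).

    Integrated along a horizontal curve this is the sub-Riemannian
    length l(gamma).
    """
    return math.sqrt(u.u1**2 + (m.alpha * u.u3) ** 2 + (m.beta * u.u4) ** 2)


#: Nonzero Lie brackets of the frame, as coefficients on X1..X4:
#: [X1,X3] = -X2, [X1,X4] = -X1, [X2,X3] = X1, [X2,X4] = -X2.
_BRACKET_TABLE = {
    (1, 3): (0.0, -1.0, 0.0, 0.0),
    (1, 4): (-1.0, 0.0, 0.0, 0.0),
    (2, 3): (1.0, 0.0, 0.0, 0.0),
    (2, 4): (0.0, -1.0, 0.0, 0.0),
}


def structure_constants() -> dict[tuple[int, int], np.ndarray]:
    """Lie brackets [Xi, Xj], i < j, as coefficient vectors on X1..X4.

    Pairs absent from the nonzero table are zero brackets.
    """
    out = {}
    for i in range(1, 5):
        for j in range(i + 1, 5):
            out[(i, j)] = np.array(_BRACKET_TABLE.get((i, j), (0.0, 0.0, 0.0, 0.0)))
    return out


def _field(i: int, coords: np.ndarray) -> np.ndarray:
    q = GroupElement(*coords)
    return frame_components(q)[i - 1]


def bracket_numeric(
    i: int, j: int, q: GroupElement, step: float = 1e-5
) -> np.ndarray:
    """[Xi, Xj] at q by central finite differences, in frame coefficients.

    The chart bracket is (D Xj) Xi - (D Xi) Xj; the result is expressed
    on the frame basis by solving against the frame matrix at q.
    """
    c0 = q.as_array()

    def jacobian(k: int) -> np.ndarray:
        jac = np.zeros((4, 4))
        for a in range(4):
            e = np.zeros(4)
            e[a] = step
            jac[:, a] = (_field(k, c0 + e) - _field(k, c0 - e)) / (2 * step)
        return jac

    xi, xj = _field(i, c0), _field(j, c0)
    chart = jacobian(j) @ xi - jacobian(i) @ xj
    return np.linalg.solve(frame_matrix(q), chart)


def hormander_span_dimension(q: GroupElement | None = None) -> int:
    """Dimension of span{X1, X3, X4, [X3, X1]} at q (bracket-generating test)."""
    q = q or GroupElement.identity()
    fm = frame_components(q)
    b31 = -bracket_numeric(1, 3, q)  # [X3,X1] = -[X1,X3]
    chart_b31 = frame_matrix(q) @ b31
    vs = np.vstack([fm[0], fm[2], fm[3], chart_b31])
    return int(np.linalg.matrix_rank(vs, tol=1e-8))
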