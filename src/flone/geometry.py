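"""Lorentz-model hyperbolic geometry.

The n-dimensional Lorentz (hyperboloid) model of hyperbolic space with
curvature ``c < 0`` is the point set

    L^n_c = { x in R^(n+1) : <x, x>_L = 1/c,  x_t > 0 },

where ``<x, y>_L = -x_t y_t + x_s . y_s`` is the Lorentzian (Minkowski) inner
product, coordinate 0 is the *time* dimension ``x_t`` and coordinates 1..n are
the *spatial* dimensions ``x_s``.  The origin is ``O = (sqrt(-1/c), 0, ..., 0)``.

All functions operate on NumPy arrays whose **last axis** holds the (n+1)
Minkowski coordinates, and broadcast over leading axes.  Curvature defaults to
``c = -1`` throughout; it is carried as a parameter for testability only.

The fully Lorentz linear layer maps a manifold point to a manifold point
without a detour through the tangent space:

    a   = lam * sigmoid(v.x + b) + eps          (scalar gate, a > 0)
    h   = W . dropout(x)                        (spatial image)
    y_s = a * h / ||h||,   y_t = sqrt(a^2 - 1/c)

so that ``<y, y>_L = -(a^2 - 1/c) + a^2 = 1/c`` holds by construction.  Note
the time coordinate uses ``a^2 - 1/c`` (i.e. ``a^2 + 1`` at c = -1): this is
the unique choice compatible with the manifold constraint, and with it any
gate floor ``eps > 0`` is admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateTransformError, DimensionError, GeometryError

#: default manifold-membership tolerance on |<x,x>_L - 1/c|
TAU_MANIFOLD = 1e-5

#: below this Lorentz norm the exponential map returns its base point exactly
_EXP_TINY = 1e-12


def _as_array(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise DimensionError(f"Lorentz coordinates need length >= 2, got {x.shape[-1]}")
    return x


def lorentz_inner(x, y) -> np.ndarray:
    """Lorentzian inner product ``-x_t y_t + x_s . y_s`` (broadcasts over leading axes)."""
    x = _as_array(x)
    y = _as_array(y)
    if x.shape[-1] != y.shape[-1]:
        raise DimensionError(
            f"coordinate length mismatch: {x.shape[-1]} vs {y.shape[-1]}"
        )
    return -x[..., 0] * y[..., 0] + np.sum(x[..., 1:] * y[..., 1:], axis=-1)


def origin(n: int, c: float = -1.0) -> np.ndarray:
    """The manifold origin ``O = (sqrt(-1/c), 0, ..., 0)`` in n+1 coordinates."""
    _check_curvature(c)
    o = np.zeros(n + 1)
    o[0] = np.sqrt(-1.0 / c)
    return o


def _check_curvature(c: float) -> None:
    if not (np.isfinite(c) and c < 0):
        raise GeometryError(f"curvature must be a negative real, got {c}")


def check_on_manifold(x, c: float = -1.0, tol: float = TAU_MANIFOLD):
    """Return ``(ok, deviation)`` where deviation is ``|<x,x>_L - 1/c|``.

    ``ok`` additionally requires a positive time coordinate.  Vectorized:
    arrays with leading axes yield boolean/float arrays.
    """
    _check_curvature(c)
    x = _as_array(x)
    dev = np.abs(lorentz_inner(x, x) - 1.0 / c)
    ok = (dev <= tol) & (x[..., 0] > 0)
    if x.ndim == 1:
        return bool(ok), float(dev)
    return ok, dev


def require_on_manifold(x, c: float = -1.0, tol: float = TAU_MANIFOLD) -> None:
    ok, dev = check_on_manifold(x, c, tol)
    if not np.all(ok):
        raise GeometryError(
            f"point(s) off the Lorentz manifold (max |<x,x>_L - 1/c| = {np.max(dev):.3g}, tol {tol:g})"
        )


def from_spatial(x_s, c: float = -1.0) -> np.ndarray:
    """Complete spatial coordinates to a manifold point: ``x_t = sqrt(||x_s||^2 - 1/c)``."""
    _check_curvature(c)
    x_s = np.asarray(x_s, dtype=float)
    t = np.sqrt(np.sum(x_s * x_s, axis=-1, keepdims=True) - 1.0 / c)
    return np.concatenate([t, x_s], axis=-1)


def sq_lorentz_distance(x, y, c: float = -1.0, validate: bool = True,
                        tol: float = TAU_MANIFOLD) -> np.ndarray:
    """Squared Lorentzian distance ``2/c - 2 <x, y>_L`` (nonnegative on the manifold).

    With ``validate=True`` both arguments are checked against the manifold
    constraint and a :class:`GeometryError` is raised beyond ``tol``.
    The tiny negative values that floating point can produce for nearly
    coincident points are clamped to 0.
    """
    if validate:
        require_on_manifold(x, c, tol)
        require_on_manifold(y, c, tol)
    d2 = 2.0 / c - 2.0 * lorentz_inner(x, y)
    return np.maximum(d2, 0.0)


def exp_map_origin(v_spatial, c: float = -1.0) -> np.ndarray:
    """Lift a Euclidean vector to the manifold via the exponential map at the origin.

    The input is first embedded in the tangent space of ``O`` as ``z = (0, v)``
    (which is Lorentz-orthogonal to ``O``), then mapped along the geodesic:

        exp_O(z) = cosh(sqrt(-c) ||z||_L) O + z sinh(sqrt(-c) ||z||_L) / (sqrt(-c) ||z||_L)

    with ``||z||_L = sqrt(<z,z>_L) = ||v||_2``.  The ``||z|| -> 0`` limit
    returns ``O`` exactly.
    """
    _check_curvature(c)
    v = np.atleast_1d(np.asarray(v_spatial, dtype=float))
    n = v.shape[-1]
    sc = np.sqrt(-c)
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    r = sc * nv
    o = origin(n, c)
    small = r < _EXP_TINY
    # guarded sinh(r)/r: series value 1 at r=0 (times sc cancels into coefficient below)
    with np.errstate(invalid="ignore", divide="ignore"):
        coeff = np.where(small, 1.0, np.sinh(r) / np.where(small, 1.0, r))
    out_t = np.cosh(r) * o[0]
    out_s = v * coeff
    return np.concatenate([out_t, out_s], axis=-1)


def exp_map(x, z, c: float = -1.0) -> np.ndarray:
    """Exponential map of tangent vector ``z`` at base point ``x`` (exp-map retraction).

    ``z`` must lie in the tangent space at ``x`` (``<z, x>_L = 0``); tangent
    vectors are spacelike, so ``<z,z>_L >= 0``.  Used by the Riemannian
    optimizer; zero (or numerically tiny) tangent vectors return ``x``.
    """
    _check_curvature(c)
    x = _as_array(x)
    z = np.asarray(z, dtype=float)
    sc = np.sqrt(-c)
    nrm2 = np.maximum(lorentz_inner(z, z), 0.0)
    nrm = np.sqrt(nrm2)[..., None]
    r = sc * nrm
    small = r < _EXP_TINY
    with np.errstate(invalid="ignore", divide="ignore"):
        coeff = np.where(small, 0.0, np.sinh(r) / np.where(small, 1.0, r))
    return np.cosh(r) * x + coeff * z


def tangent_project(x, u, c: float = -1.0) -> np.ndarray:
    """Orthogonal projection of an ambient vector onto the tangent space at ``x``.

    For ``<x,x>_L = 1/c`` the projection is ``u - c <x,u>_L x``.
    """
    _check_curvature(c)
    x = _as_array(x)
    u = np.asarray(u, dtype=float)
    return u - c * lorentz_inner(x, u)[..., None] * x


def lorentz_to_poincare(x, c: float = -1.0, validate: bool = True) -> np.ndarray:
    """Project manifold points onto the Poincare ball: ``x_s / (x_t + sqrt(-1/c))``.

    The image has Euclidean norm strictly below ``1/sqrt(-c)`` (the unit ball
    at c = -1); the origin maps to the ball center, and points at geodesic
    radius r map to radius ``tanh(r/2)`` (c = -1).
    """
    if validate:
        require_on_manifold(x, c)
    x = _as_array(x)
    return x[..., 1:] / (x[..., 0:1] + np.sqrt(-1.0 / c))


# ---------------------------------------------------------------------------
# fully Lorentz linear layer
# ---------------------------------------------------------------------------

@dataclass
class FLLinearWeights:
    """Weights of one fully Lorentz linear layer mapping L^n -> L^m.

    ``W`` has shape (m, n+1), ``v`` length n+1; ``lam`` (> 0) bounds the gate
    scale, ``eps`` is the gate floor and ``dropout_rate`` applies to the full
    (n+1)-coordinate input of the ``W`` branch during training only.
    """

    W: np.ndarray
    v: np.ndarray
    b: float = 0.0
    lam: float = 10.0
    eps: float = 1.0
    dropout_rate: float = 0.1

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] < 1:
            raise DimensionError(f"W must be a matrix with >= 1 row, got shape {self.W.shape}")
        if self.v.shape != (self.W.shape[1],):
            raise DimensionError(
                f"v must have length {self.W.shape[1]} to match W, got {self.v.shape}"
            )
        if not self.lam > 0:
            raise GeometryError(f"lam must be positive, got {self.lam}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise GeometryError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    @property
    def n_in(self) -> int:
        return self.W.shape[1] - 1

    @property
    def n_out(self) -> int:
        return self.W.shape[0]


def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


def full_lorentz_linear(x, weights: FLLinearWeights, c: float = -1.0,
                        training: bool = False, rng: np.random.Generator | None = None,
                        _cache: bool = False):
    """Apply a fully Lorentz linear layer; output satisfies the manifold constraint.

    With ``training=True`` dropout is applied (inverted scaling) to the input
    of the ``W`` branch; with ``training=False`` the map is deterministic.
    Raises :class:`DegenerateTransformError` when ``||W dropout(x)|| = 0``.

    When ``_cache=True`` returns ``(y, cache)`` with the intermediates needed
    by the analytic backward pass in :mod:`flone.training`.
    """
    _check_curvature(c)
    X = _as_array(x)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != weights.W.shape[1]:
        raise DimensionError(
            f"input has {X2.shape[1]} coordinates, layer expects {weights.W.shape[1]}"
        )
    mask = None
    Xd = X2
    if training and weights.dropout_rate > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        keep = 1.0 - weights.dropout_rate
        mask = (rng.random(X2.shape) < keep).astype(float) / keep
        Xd = X2 * mask
        # a sparse input row can lose every informative coordinate to the
        # mask; fall back to the undropped row there (rare, keeps h nonzero)
        dead = np.linalg.norm(Xd @ weights.W.T, axis=1) < 1e-12
        if np.any(dead):
            mask = np.where(dead[:, None], 1.0, mask)
            Xd = X2 * mask

    u = X2 @ weights.v + weights.b
    s = _sigmoid(u)
    a = weights.lam * s + weights.eps
    H = Xd @ weights.W.T
    nh = np.linalg.norm(H, axis=1)
    if np.any(nh < 1e-300):
        raise DegenerateTransformError(
            "W dropout(x) has zero norm: uninitialized or collapsed layer weights"
        )
    Hh = H / nh[:, None]
    yt = np.sqrt(a * a - 1.0 / c)
    Y = np.concatenate([yt[:, None], a[:, None] * Hh], axis=1)
    out = Y[0] if single else Y
    if _cache:
        cache = dict(X=X2, Xd=Xd, mask=mask, s=s, a=a, nh=nh, Hh=Hh, yt=yt,
                     weights=weights, c=c)
        return out, cache
    return out
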