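"""Gaussian radial-basis-function network with a Lyapunov-style adaptive law.

The network h(Z) = W^T S(Z) with Gaussian activations

    s_i(Z) = exp(-||Z - mu_i||^2 / eta^2)

approximates the unknown lumped drift of the synchronization error online.
Its weights follow the continuous-time update

    dW/dt = P [ S(Z) eps - xi W ]

where ``eps`` is the filtered error, ``P`` the (scalar, positive) adaptation
gain and ``xi`` a small leak that keeps the weights bounded when excitation
is poor (a sigma-modification).  The weights are integrated as part of the
global ODE, not as a discrete learning step.

Centers are laid out on a regular Cartesian grid; the default configuration
uses 21 nodes per dimension on [-2.5, 2.5] in two dimensions (441 nodes)
with shared width 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RBFApproximator", "NNInputMap", "grid_centers", "INPUT_MAPS"]


def grid_centers(bounds, nodes_per_dim: int, ndim: int | None = None) -> np.ndarray:
    """Regular grid of RBF centers, endpoints included.

    Parameters
    ----------
    bounds : (lo, hi) pair or sequence of such pairs
        Interval per dimension.  A single pair is broadcast to ``ndim``.
    nodes_per_dim : int
        Number of grid points along each dimension (>= 1).
    ndim : int, optional
        Number of dimensions when ``bounds`` is a single pair.

    Returns
    -------
    ndarray of shape (nodes_per_dim**ndim, ndim)
    """
    if nodes_per_dim < 1:
        raise ValueError(f"nodes_per_dim must be >= 1, got {nodes_per_dim}")
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim == 1:
        if ndim is None:
            ndim = 1
        bounds = np.tile(bounds, (ndim, 1))
    elif ndim is not None and len(bounds) != ndim:
        raise ValueError(f"got {len(bounds)} bound pairs for ndim={ndim}")
    axes = [np.linspace(lo, hi, nodes_per_dim) if nodes_per_dim > 1 else np.array([(lo + hi) / 2.0])
            for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


@dataclass
class RBFApproximator:
    """Gaussian RBF network state: centers, width, weights, adaptation gains."""

    centers: np.ndarray
    width: float = 0.25
    adapt_gain: float = 1.0
    leak: float = 1e-3
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] < 1:
            raise ValueError("need at least one center")
        if not (self.width > 0):
            raise ValueError(f"basis width must be positive, got {self.width}")
        if not (self.adapt_gain > 0):
            raise ValueError(f"adaptation gain must be positive, got {self.adapt_gain}")
        if not (self.leak > 0):
            raise ValueError(f"leak must be positive, got {self.leak}")
        if self.weights is None:
            self.weights = np.zeros(self.n_nodes)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_nodes,):
                raise ValueError(
                    f"weights length {self.weights.shape} does not match {self.n_nodes} centers")

    @property
    def n_nodes(self) -> int:
        return self.centers.shape[0]

    @property
    def input_dim(self) -> int:
        return self.centers.shape[1]

    def basis(self, Z) -> np.ndarray:
        """Activation vector S(Z); every entry in (0, 1], equal to 1 only at a center."""
        Z = np.asarray(Z, dtype=float).ravel()
        if Z.size != self.input_dim:
            raise ValueError(f"input has dimension {Z.size}, network expects {self.input_dim}")
        d2 = np.sum((self.centers - Z) ** 2, axis=1)
        return np.exp(-d2 / self.width ** 2)

    def predict(self, Z, weights: np.ndarray | None = None) -> float:
        """Network output W^T S(Z) (zero whenever the weights are all zero)."""
        w = self.weights if weights is None else np.asarray(weights, dtype=float)
        if w.shape != (self.n_nodes,):
            raise ValueError(f"weight vector of length {w.shape} does not match {self.n_nodes} nodes")
        return float(w @ self.basis(Z))

    def weight_derivative(self, Z, eps: float,
                          weights: np.ndarray | None = None) -> np.ndarray:
        """Adaptive law dW/dt = P [S(Z) eps - xi W]."""
        w = self.weights if weights is None else np.asarray(weights, dtype=float)
        return self.adapt_gain * (self.basis(Z) * float(eps) - self.leak * w)


@dataclass(frozen=True)
class NNInputMap:
    """Rule mapping the joint simulation state to the network input Z.

    ``name`` selects one of the built-in rules:

    - ``"potentials_normalized"`` (default): Z is the pair of membrane
      potentials affinely rescaled from ``v_range`` onto [-2.5, 2.5], the
      span of the default center grid.  The neuron pair operates around
      potentials of order ten, far outside the grid, so feeding raw
      potentials would silence every Gaussian node; normalizing keeps the
      network persistently excited along the whole trajectory.
    - ``"potentials"``: Z = (V_M, V_S), the raw membrane potentials.
    - ``"error"``: Z = (e, eps), the synchronization error and its
      filtered image (on the funnel's own scale).
    - ``"full"``: Z = the joint 8-dimensional neuron state.
    """

    name: str = "potentials_normalized"
    v_range: tuple = (0.0, 12.0)

    _DIMS = {"error": 2, "potentials": 2, "potentials_normalized": 2, "full": 8}

    def __post_init__(self) -> None:
        if self.name not in self._DIMS:
            raise ValueError(f"unknown input map {self.name!r}; choose from {sorted(self._DIMS)}")
        lo, hi = self.v_range
        if not (hi > lo):
            raise ValueError(f"v_range must be an increasing pair, got {self.v_range}")
        object.__setattr__(self, "v_range", (float(lo), float(hi)))

    @property
    def q(self) -> int:
        """Declared network input dimension."""
        return self._DIMS[self.name]

    def __call__(self, x_master, x_slave, e: float, eps: float) -> np.ndarray:
        if self.name == "error":
            return np.array([e, eps])
        if self.name == "potentials":
            return np.array([float(x_master[0]), float(x_slave[0])])
        if self.name == "potentials_normalized":
            mid, scale = self.normalization()
            return np.array([(float(x_master[0]) - mid) * scale,
                             (float(x_slave[0]) - mid) * scale])
        return np.concatenate([np.asarray(x_master, dtype=float).ravel(),
                               np.asarray(x_slave, dtype=float).ravel()])

    def normalization(self):
        """(midpoint, gain) of the affine map v_range -> [-2.5, 2.5]."""
        lo, hi = self.v_range
        return (lo + hi) / 2.0, 5.0 / (hi - lo)


INPUT_MAPS = tuple(NNInputMap._DIMS)
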