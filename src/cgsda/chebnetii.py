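"""Chebyshev-interpolation spectral graph convolution branch.

A ChebNetII layer filters node features with a degree-K polynomial of the
scaled graph Laplacian.  Instead of learning the monomial (Chebyshev
basis) coefficients directly, the filter is parameterized by its values
``gamma_j`` at the K+1 Chebyshev interpolation nodes
``x_j = cos((j+0.5)*pi/(K+1))``, which suppresses the Runge phenomenon of
high-order polynomial fits.  The layer output is

    sum_k w_k T_k(L_hat) F,   w_k = 2/(K+1) * sum_j gamma_j T_k(x_j)

evaluated by the three-term matrix recurrence, never by eigendecomposition.
With all ``gamma_j = 1`` the filter collapses to ``2 F`` (the node sums of
T_k vanish for k >= 1) — a useful closed form for testing and the reason
the all-ones initialization is a stable near-identity warm start.

The branch stacks ``M_C`` such layers.  Against over-smoothing, each
layer's input is the previous output concatenated with the MLP-encoded
initial features (residual injection), so widths grow by one hidden-block
per layer; a terminal linear projection maps back to the shared width.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, dropout, matmul, take_pairs

__all__ = ["chebyshev_nodes", "cheb_polynomial_value", "interpolation_weights",
           "scaled_laplacian", "chebnetii_propagate", "ChebBranch"]


def chebyshev_nodes(K: int) -> np.ndarray:
    """The K+1 Chebyshev interpolation nodes cos((j+0.5)π/(K+1)), decreasing."""
    if K < 0:
        raise ValueError("K must be >= 0")
    j = np.arange(K + 1)
    return np.cos((j + 0.5) * np.pi / (K + 1))


def cheb_polynomial_value(k: int, x: float) -> float:
    """T_k(x) by the three-term recurrence; equals cos(k·arccos x) on [-1,1]."""
    if abs(x) > 1:
        raise ValueError("|x| must be <= 1")
    if k == 0:
        return 1.0
    t_prev, t = 1.0, float(x)
    for _ in range(k - 1):
        t_prev, t = t, 2.0 * x * t - t_prev
    return t


def _node_value_table(K: int, halve_k0: bool) -> np.ndarray:
    """Matrix T[j, k] = T_k(x_j); column 0 halved for the original variant."""
    x = chebyshev_nodes(K)
    table = np.empty((K + 1, K + 1))
    table[:, 0] = 1.0
    if K >= 1:
        table[:, 1] = x
    for k in range(2, K + 1):
        table[:, k] = 2.0 * x * table[:, k - 1] - table[:, k - 2]
    if halve_k0:
        table[:, 0] *= 0.5
    return table


def interpolation_weights(gamma, K: int, halve_k0: bool = False):
    """Filter weights w_k = 2/(K+1) · Σ_j γ_j T_k(x_j).

    ``gamma`` may be a plain array (returns an array) or an autodiff
    :class:`Tensor` row vector (returns a Tensor, differentiable in γ).
    """
    table = _node_value_table(K, halve_k0)
    scale = 2.0 / (K + 1)
    if isinstance(gamma, Tensor):
        return matmul(gamma, Tensor(table)) * scale
    gamma = np.asarray(gamma, dtype=np.float64)
    if gamma.size != K + 1:
        raise ValueError(f"need {K + 1} gamma values, got {gamma.size}")
    return scale * (gamma.reshape(1, -1) @ table).ravel()


def scaled_laplacian(Y: np.ndarray) -> np.ndarray:
    """L_hat = L - I = -D^{-1/2} Y D^{-1/2}, with λ_max fixed to 2.

    Isolated nodes (degree 0) get zero rows and columns, so their features
    propagate to zero through the polynomial's k >= 1 terms and survive
    only via the k = 0 identity term and the residual path.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if not np.allclose(Y, Y.T):
        raise ValueError("Y must be symmetric")
    deg = Y.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    return -(inv_sqrt[:, None] * Y * inv_sqrt[None, :])


def chebnetii_propagate(L_hat: np.ndarray, F, gamma, halve_k0: bool = False):
    """Apply the order-K interpolated filter: Σ_k w_k T_k(L_hat) F.

    Evaluated with the matrix recurrence Z_0 = F, Z_1 = L_hat F,
    Z_k = 2 L_hat Z_{k-1} - Z_{k-2}; feature width is preserved.
    ``F`` and ``gamma`` may be arrays or Tensors (mixed is fine); the
    result is a Tensor iff either input is.
    """
    L_hat = np.asarray(L_hat, dtype=np.float64)
    tensor_out = isinstance(F, Tensor) or isinstance(gamma, Tensor)
    K = (gamma.data.size if isinstance(gamma, Tensor) else np.size(gamma)) - 1
    F_t = F if isinstance(F, Tensor) else Tensor(F)
    if F_t.data.shape[0] != L_hat.shape[0]:
        raise ValueError("feature row count must equal node count")
    g_t = gamma if isinstance(gamma, Tensor) else Tensor(np.reshape(gamma, (1, -1)))
    w = interpolation_weights(g_t, K, halve_k0)  # (1, K+1) Tensor

    L_t = Tensor(L_hat)
    z_prev, z = F_t, None
    out = z_prev * take_pairs(w, [0], [0])
    if K >= 1:
        z = matmul(L_t, F_t)
        out = out + z * take_pairs(w, [0], [1])
    for k in range(2, K + 1):
        z_prev, z = z, matmul(L_t, z) * 2.0 - z_prev
        out = out + z * take_pairs(w, [0], [k])
    return out if tensor_out else out.data


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-bound, bound, size=(n_in, n_out))


class ChebBranch:
    """Stack of ChebNetII layers with residual injection and terminal projection.

    Parameters per layer are just the K+1 interpolation values γ (all-ones
    initialized); the terminal projection is a learnable linear map from the
    final (possibly residual-grown) width to ``hidden``.
    """

    def __init__(self, hidden: int, orders: tuple[int, ...] = (3, 5),
                 residual: bool = True, halve_k0: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.orders = tuple(orders)
        self.residual = residual
        self.halve_k0 = halve_k0
        self.gammas = [Tensor(np.ones((1, K + 1)), requires_grad=True)
                       for K in self.orders]
        final_width = hidden * (len(self.orders) + 1) if residual else hidden
        # small-gain terminal projection (see GatedBranch): keeps the Gram
        # decoder's initial logits near zero
        self.W_out = Tensor(0.1 * _glorot(rng, final_width, hidden),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros((1, hidden)), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [*self.gammas, self.W_out, self.b_out]

    def forward(self, L_hat: np.ndarray, F_mlp: Tensor, *,
                training: bool = False, dropout_rate: float = 0.0,
                rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        F = F_mlp
        for gamma, K in zip(self.gammas, self.orders):
            layer_in = concat([F, F_mlp], axis=1) if self.residual else F
            layer_in = dropout(layer_in, dropout_rate, rng, training)
            F = chebnetii_propagate(L_hat, layer_in, gamma, self.halve_k0)
        return matmul(F, self.W_out) + self.b_out
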