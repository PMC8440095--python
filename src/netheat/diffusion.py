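"""Laplacian heat diffusion on a column-normalized PPI network.

The adjacency matrix A of confidence scores is normalized column-wise,

    A'[i, j] = A[i, j] / sum_k A[k, j],

so every column is a probability distribution over the neighbors of node j
(isolated nodes receive a self-loop, A'[j, j] = 1, so heat is conserved on
the whole network). Heat then evolves by the graph heat equation

    dH/dt = -L H,      L = I - A',      H_t = exp(-t L) H_0,

whose eigen-solution is the familiar componentwise exponential decay
H_t = sum_i exp(-lambda_i t) <v_i, H_0> v_i with lambda_i the eigenvalues
of L. Because columns of A' sum to one, the all-ones vector is a left null
vector of L and the total heat sum(H_t) is invariant in t; the seeds' initial
heat spreads to network neighbors without being created or destroyed.

Three solvers are provided: the default matrix-exponential action
(``expm``, scaling-and-squaring/Krylov via scipy, works at full-network
scale), a dense spectral solve (``spectral``, small graphs only, A' is
non-symmetric so it may be ill-conditioned and falls back to ``expm``), and
an ``iterative`` mode that advances time in fixed steps until the heat
vector stops changing. A dense Taylor-series oracle is kept alongside as an
independent ground truth for tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .ppi_io import PPINetwork, SeedSet, ValidationError

logger = logging.getLogger(__name__)

_MODES = ("expm", "spectral", "iterative")
_NEG_TOL = 1e-10  # numerical negatives below this magnitude are clamped to 0


class ConvergenceError(RuntimeError):
    """Iterative diffusion exceeded its step cap without converging."""


@dataclass
class DiffusionConfig:
    """Diffusion solver settings.

    t: diffusion time (default 0.5, the referenced diffusion package's
       default; the source text runs "default parameters" without printing t).
    mode: 'expm' (default), 'spectral' or 'iterative'.
    step: time increment for iterative mode.
    eps: infinity-norm convergence tolerance for iterative mode.
    series_terms: truncation order of the Taylor-series oracle.
    max_steps: iteration cap for iterative mode.
    """

    t: float = 0.5
    mode: str = "expm"
    step: float = 0.1
    eps: float = 1e-6
    series_terms: int = 30
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"diffusion time t={self.t} must be >= 0")
        if self.eps <= 0:
            raise ValidationError(f"eps={self.eps} must be > 0")
        if self.series_terms < 1:
            raise ValidationError("series_terms must be >= 1")
        if self.step <= 0:
            raise ValidationError(f"step={self.step} must be > 0")
        if self.mode not in _MODES:
            raise ValidationError(f"mode {self.mode!r} not in {_MODES}")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over an indexed node list."""

    matrix: sp.csc_matrix
    nodes: list[str]
    node_index: dict[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def laplacian(self) -> sp.csc_matrix:
        return (sp.identity(self.n, format="csc") - self.matrix).tocsc()


def column_normalize(network: PPINetwork) -> TransitionMatrix:
    """Build A' by dividing each column of the score adjacency matrix by its
    sum. Isolated nodes get a unit self-loop so columns always sum to 1."""
    if network.n_nodes == 0:
        raise ValidationError("cannot normalize an empty network")
    nodes = list(network.node_order)
    index = {n: i for i, n in enumerate(nodes)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for a, b, d in network.graph.edges(data=True):
        i, j = index[a], index[b]
        s = float(d["score"])
        rows += [i, j]
        cols += [j, i]
        data += [s, s]
    n = len(nodes)
    A = sp.csc_matrix(
        (np.asarray(data), (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))),
        shape=(n, n),
    )
    colsum = np.asarray(A.sum(axis=0)).ravel()
    isolated = colsum == 0
    inv = np.ones_like(colsum)
    inv[~isolated] = 1.0 / colsum[~isolated]
    Ap = (A @ sp.diags(inv)).tocsc()
    if isolated.any():
        Ap = (Ap + sp.diags(isolated.astype(float))).tocsc()
        logger.info("%d isolated nodes received self-loops", int(isolated.sum()))
    return TransitionMatrix(matrix=Ap, nodes=nodes, node_index=index)


def initial_heat(seeds: SeedSet, node_index: dict[str, int]) -> np.ndarray:
    """Uniform initial heat 1/|seeds| on each seed node, 0 elsewhere."""
    missing = [g for g in seeds.members if g not in node_index]
    if missing:
        raise ValidationError(f"seeds not in node index: {missing[:5]}")
    h0 = np.zeros(len(node_index))
    share = 1.0 / len(seeds.members)
    for g in seeds.members:
        h0[node_index[g]] = share
    return h0


def _clean(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    mask = (h < 0) & (h > -_NEG_TOL)
    if mask.any():
        h = h.copy()
        h[mask] = 0.0
    return h


def diffuse(
    transition: TransitionMatrix,
    h0: np.ndarray,
    config: DiffusionConfig | None = None,
) -> np.ndarray:
    """Evolve ``h0`` to time ``config.t`` under H_t = exp(-t L) H_0.

    ``iterative`` mode ignores ``t`` and advances in steps of ``config.step``
    until the heat vector stops changing (the stationary distribution).
    """
    config = config or DiffusionConfig()
    h0 = np.asarray(h0, dtype=float)
    if h0.shape != (transition.n,):
        raise ValidationError(
            f"heat vector shape {h0.shape} does not match node count {transition.n}"
        )
    if (h0 < 0).any():
        raise ValidationError("initial heat has negative entries")
    if config.mode == "iterative":
        h, _ = iterate_until_converged(
            transition, h0, step=config.step, eps=config.eps,
            max_steps=config.max_steps,
        )
        return h
    if config.t == 0:
        return h0.copy()
    if config.mode == "spectral":
        try:
            return _clean(_spectral_solve(transition, h0, config.t))
        except (np.linalg.LinAlgError, ValidationError) as exc:
            logger.warning("spectral solve failed (%s); falling back to expm", exc)
    L = transition.laplacian()
    return _clean(expm_multiply((-config.t) * L, h0))


def _spectral_solve(transition: TransitionMatrix, h0: np.ndarray, t: float) -> np.ndarray:
    # A' is non-symmetric; a dense eigendecomposition is only trustworthy on
    # small, well-conditioned problems.
    n = transition.n
    if n > 2000:
        raise ValidationError(f"spectral mode limited to <= 2000 nodes (got {n})")
    L = transition.laplacian().toarray()
    w, V = np.linalg.eig(L)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValidationError(f"eigenvector matrix ill-conditioned (cond={cond:.2e})")
    coeff = np.linalg.solve(V, h0.astype(complex))
    out = V @ (np.exp(-t * w) * coeff)
    if np.abs(out.imag).max() > 1e-8:
        raise ValidationError("non-negligible imaginary part in spectral solution")
    return out.real


def expm_series_oracle(
    transition: TransitionMatrix,
    h0: np.ndarray,
    t: float,
    n_terms: int = 30,
) -> np.ndarray:
    """Dense Taylor-series ground truth: sum_{k<=n_terms} (-tL)^k h0 / k!.

    Independent of the production solvers; intended for small graphs only.
    """
    L = transition.laplacian().toarray()
    h0 = np.asarray(h0, dtype=float)
    term = h0.copy()
    acc = h0.copy()
    for k in range(1, n_terms + 1):
        term = (-t / k) * (L @ term)
        acc += term
    return acc


def iterate_until_converged(
    transition: TransitionMatrix,
    h0: np.ndarray,
    step: float,
    eps: float,
    max_steps: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Advance time in increments of ``step`` until two consecutive heat
    vectors differ by less than ``eps`` in the infinity norm.

    Returns the converged heat vector and the stopping time.
    """
    if step <= 0 or eps <= 0:
        raise ValidationError("step and eps must be positive")
    L = transition.laplacian()
    h = np.asarray(h0, dtype=float)
    t = 0.0
    for _ in range(max_steps):
        h_next = _clean(expm_multiply((-step) * L, h))
        t += step
        if np.max(np.abs(h_next - h)) < eps:
            logger.info("iterative diffusion converged at t=%.4g", t)
            return h_next, t
        h = h_next
    raise ConvergenceError(
        f"no convergence within {max_steps} steps (step={step}, eps={eps})"
    )
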