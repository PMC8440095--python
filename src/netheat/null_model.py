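"""Permutation null model for heat values.

The significance of a gene's diffused heat is judged against the heat it
receives from random seed sets of the same size: ``n_perm`` node sets are
drawn uniformly without replacement from all network nodes, diffusion is run
from each, and the per-gene mean and standard deviation of the resulting
null heats standardize the real heat into a Z-score,

    Z(g) = (h - mean_null) / sd_null.

Null heats are streamed through Welford running moments so the full-network
configuration (1000 permutations x ~19k genes) never materializes the whole
permutation matrix; a ``store_heats`` option keeps it for small test runs.
The sample (n-1) standard deviation is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diffusion import DiffusionConfig, TransitionMatrix, diffuse
from .ppi_io import PPINetwork, SeedSet, ValidationError

logger = logging.getLogger(__name__)

_BATCH = 128  # permutation initial-heat columns diffused per expm call


@dataclass
class NullEnsemble:
    """Streaming per-gene moments of null heat values."""

    n_perm: int
    mean: np.ndarray
    m2: np.ndarray  # running sum of squared deviations (Welford)
    rng_seed: int | None = None
    heats: np.ndarray | None = field(default=None, repr=False)  # n_perm x n

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValidationError("need at least 2 permutations")

    @property
    def sd(self) -> np.ndarray:
        """Per-gene sample standard deviation (denominator n_perm - 1)."""
        return np.sqrt(self.m2 / (self.n_perm - 1))


@dataclass
class ZRecord:
    """Per-gene standardized heat. ``degenerate`` flags sd == 0 cases."""

    gene: str
    h: float
    null_mean: float
    null_sd: float
    z: float
    degenerate: bool = False


def sample_null_seed_sets(
    network: PPINetwork,
    size: int,
    n_perm: int,
    rng_seed: int,
) -> list[list[str]]:
    """Draw ``n_perm`` independent uniform sets of ``size`` distinct nodes.

    Seeds are NOT excluded from the draw: the null asks how much heat a gene
    collects from an arbitrary same-sized seed configuration.
    """
    nodes = list(network.node_order)
    if size > len(nodes):
        raise ValidationError(
            f"null set size {size} exceeds node count {len(nodes)}"
        )
    if n_perm < 2:
        raise ValidationError("n_perm must be >= 2")
    rng = np.random.default_rng(rng_seed)
    arr = np.array(nodes, dtype=object)
    return [list(rng.choice(arr, size=size, replace=False)) for _ in range(n_perm)]


def _uniform_h0(members: list[str], node_index: dict[str, int]) -> np.ndarray:
    h0 = np.zeros(len(node_index))
    share = 1.0 / len(members)
    for g in members:
        if g not in node_index:
            raise ValidationError(f"null seed {g!r} not in node index")
        h0[node_index[g]] = share
    return h0


def compute_null(
    transition: TransitionMatrix,
    sets: list[list[str]],
    config: DiffusionConfig | None = None,
    store_heats: bool = False,
    rng_seed: int | None = None,
) -> NullEnsemble:
    """Diffuse every null seed set and accumulate per-gene running moments.

    With the default ``expm`` solver the initial-heat vectors are stacked and
    diffused in batches of one matrix-exponential action each; other solver
    modes fall back to one diffusion per set.
    """
    from scipy.sparse.linalg import expm_multiply

    config = config or DiffusionConfig()
    n = transition.n
    n_perm = len(sets)
    if n_perm < 2:
        raise ValidationError("need at least 2 null sets")
    mean = np.zeros(n)
    m2 = np.zeros(n)
    stored = np.empty((n_perm, n)) if store_heats else None
    count = 0

    def _accumulate(cols: np.ndarray, start: int) -> None:
        # cols: n x b matrix of diffused null heats
        nonlocal count, mean, m2
        for j in range(cols.shape[1]):
            x = cols[:, j]
            count += 1
            delta = x - mean
            mean += delta / count
            m2 += delta * (x - mean)
            if stored is not None:
                stored[start + j] = x

    if config.mode == "expm" and config.t > 0:
        L = transition.laplacian()
        for start in range(0, n_perm, _BATCH):
            batch = sets[start : start + _BATCH]
            H0 = np.column_stack(
                [_uniform_h0(members, transition.node_index) for members in batch]
            )
            Ht = expm_multiply((-config.t) * L, H0)
            Ht = np.where((Ht < 0) & (Ht > -1e-10), 0.0, Ht)
            _accumulate(np.asarray(Ht), start)
    else:
        for i, members in enumerate(sets):
            try:
                h = diffuse(transition, _uniform_h0(members, transition.node_index), config)
            except Exception as exc:
                raise type(exc)(f"permutation {i}: {exc}") from exc
            _accumulate(h[:, None], i)

    logger.info("null ensemble: %d permutations over %d genes", n_perm, n)
    return NullEnsemble(n_perm=n_perm, mean=mean, m2=m2, rng_seed=rng_seed, heats=stored)


def z_scores(
    real_heat: np.ndarray,
    ensemble: NullEnsemble,
    nodes: list[str],
) -> list[ZRecord]:
    """Standardize each gene's real heat against its null distribution.

    Genes with null sd == 0 get z = +inf / -inf / 0 according to the sign of
    (h - null_mean) and are flagged ``degenerate``.
    """
    real_heat = np.asarray(real_heat, dtype=float)
    if real_heat.shape[0] != len(nodes) or ensemble.mean.shape[0] != len(nodes):
        raise ValidationError("heat vector, ensemble and node list misaligned")
    sd = ensemble.sd
    records: list[ZRecord] = []
    for i, gene in enumerate(nodes):
        h = float(real_heat[i])
        mu = float(ensemble.mean[i])
        s = float(sd[i])
        if s > 0:
            records.append(ZRecord(gene, h, mu, s, (h - mu) / s))
        else:
            z = np.inf if h > mu else (-np.inf if h < mu else 0.0)
            records.append(ZRecord(gene, h, mu, s, z, degenerate=True))
    return records
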