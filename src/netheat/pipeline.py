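"""End-to-end candidate-gene screen.

The screen chains four per-gene filters, each applied only to the survivors
of the previous one (the filters are independent per gene, so
short-circuiting cannot change the result):

1. heat:  diffused heat > heat_cutoff (default 1e-10) — discards nodes the
   seed signal never reaches;
2. Z:     permutation Z-score > z_cutoff (default 1.96);
3. MIS:   maximum interaction score with a seed > mis_cutoff (default 900,
   STRING's highest-confidence band; strict by default);
4. MFS:   maximum annotation cosine with a seed > mfs_cutoff (default 0.9,
   strict by default).

Seed genes themselves are excluded from the candidate output by default
(the screen looks for novel genes). Output rows are sorted by MFS
descending, ties broken by Z descending then gene identifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .diffusion import DiffusionConfig, column_normalize, diffuse, initial_heat
from .null_model import compute_null, sample_null_seed_sets, z_scores
from .ppi_io import (
    AnnotationTable,
    CandidateRecord,
    PPINetwork,
    SeedSet,
    ValidationError,
)
from .scoring import mfs, mis

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All cutoffs, comparison strictness and the permutation budget.

    Strict comparisons (``>``) are the default for MIS and MFS; set the
    ``*_strict`` flags to False for ``>=`` semantics. ``rng_seed`` drives the
    permutation null and must be supplied for a run.
    """

    heat_cutoff: float = 1e-10
    z_cutoff: float = 1.96
    mis_cutoff: float = 900
    mfs_cutoff: float = 0.9
    mis_strict: bool = True
    mfs_strict: bool = True
    n_perm: int = 1000
    rng_seed: int = 0
    exclude_seeds_from_output: bool = True
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)

    def __post_init__(self) -> None:
        for name in ("heat_cutoff", "z_cutoff", "mis_cutoff", "mfs_cutoff"):
            if not math.isfinite(float(getattr(self, name))):
                raise ValidationError(f"{name} must be finite")
        if self.n_perm < 2:
            raise ValidationError("n_perm must be >= 2")
        if isinstance(self.diffusion, dict):
            self.diffusion = DiffusionConfig(**self.diffusion)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StageCounts:
    """Survivor counts after each filter stage (monotone nonincreasing)."""

    n_heat: int
    n_z: int
    n_mis: int
    n_mfs: int

    def __post_init__(self) -> None:
        if not (self.n_heat >= self.n_z >= self.n_mis >= self.n_mfs >= 0):
            raise ValidationError(f"stage counts not monotone: {self}")


def run_pipeline(
    network: PPINetwork,
    seeds: SeedSet,
    annotations: AnnotationTable,
    config: PipelineConfig,
) -> tuple[list[CandidateRecord], StageCounts]:
    """Run diffusion, the permutation null and the staged screen.

    Returns the sorted candidate records (every one strictly passing all
    four cutoffs) and the per-stage survivor counts.
    """
    transition = column_normalize(network)
    nodes = transition.nodes
    h0 = initial_heat(seeds, transition.node_index)
    real = diffuse(transition, h0, config.diffusion)

    null_sets = sample_null_seed_sets(
        network, size=len(seeds), n_perm=config.n_perm, rng_seed=config.rng_seed
    )
    ensemble = compute_null(
        transition, null_sets, config.diffusion, rng_seed=config.rng_seed
    )
    zrecs = {r.gene: r for r in z_scores(real, ensemble, nodes)}

    seed_members = set(seeds.members)
    heat_of = {g: float(real[i]) for i, g in enumerate(nodes)}
    pool = [
        g for g in nodes
        if not (config.exclude_seeds_from_output and g in seed_members)
    ]

    stage_heat = [g for g in pool if heat_of[g] > config.heat_cutoff]
    stage_z = [g for g in stage_heat if zrecs[g].z > config.z_cutoff]

    def _passes(value: float, cutoff: float, strict: bool) -> bool:
        return value > cutoff if strict else value >= cutoff

    mis_of = {g: mis(g, seeds, network) for g in stage_z}
    stage_mis = [
        g for g in stage_z
        if _passes(mis_of[g], config.mis_cutoff, config.mis_strict)
    ]
    mfs_of = {g: mfs(g, seeds, annotations) for g in stage_mis}
    stage_mfs = [
        g for g in stage_mis
        if _passes(mfs_of[g], config.mfs_cutoff, config.mfs_strict)
    ]

    counts = StageCounts(
        n_heat=len(stage_heat),
        n_z=len(stage_z),
        n_mis=len(stage_mis),
        n_mfs=len(stage_mfs),
    )
    logger.info(
        "stage counts: heat=%d z=%d mis=%d mfs=%d",
        counts.n_heat, counts.n_z, counts.n_mis, counts.n_mfs,
    )

    records = [
        CandidateRecord(
            gene=g, heat=heat_of[g], z=zrecs[g].z, mis=mis_of[g], mfs=mfs_of[g]
        )
        for g in stage_mfs
    ]
    records.sort(key=lambda r: (-r.mfs, -r.z, r.gene))
    return records, counts


def export_subnetwork(
    records: list[CandidateRecord],
    seeds: SeedSet,
    network: PPINetwork,
    path: str | Path,
) -> None:
    """Write the edge list induced by candidates + seeds for visualization.

    TSV columns: node1, node2, score, edge_class in
    {seed-seed, seed-candidate, candidate-candidate}.
    """
    candidates = {r.gene for r in records}
    seed_members = set(seeds.members)
    keep = candidates | seed_members

    def _cls(a: str, b: str) -> str:
        n_seed = (a in seed_members) + (b in seed_members)
        return ("candidate-candidate", "seed-candidate", "seed-seed")[n_seed]

    rows = []
    for a, b, d in network.graph.edges(data=True):
        if a in keep and b in keep:
            x, y = sorted((a, b))
            rows.append((x, y, d["score"], _cls(a, b)))
    rows.sort()
    with Path(path).open("w") as fh:
        fh.write("node1\tnode2\tscore\tedge_class\n")
        for x, y, s, c in rows:
            fh.write(f"{x}\t{y}\t{s}\t{c}\n")
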