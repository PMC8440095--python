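"""Readers and writers for the pipeline's flat-file interfaces.

Three inputs are consumed:

* a STRING-dialect protein-links file (``protein1 protein2 combined_score``,
  whitespace separated, one header line, integer confidence scores on the
  150-999 scale, optionally taxon-prefixed identifiers such as ``9606.ENSP...``);
* a plain-text seed gene list, one identifier per line, ``#`` comments;
* a GMT annotation file carrying GO terms and KEGG pathways as gene sets.

One output is produced: the candidate table (TSV) plus helpers used by the
``simulate`` subcommand to write fixture files in the same dialects.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_MIN = 150
SCORE_MAX = 999

_TAXON_PREFIX = re.compile(r"^(\d+)\.(?=\S)")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a contract (score range, duplicates, ...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network with integer confidence
    scores (STRING combined-score scale, 150-999) as edge weights.

    ``node_order`` fixes node indexing by first appearance in the input so
    downstream matrices and permutation draws are reproducible run to run.
    """

    graph: nx.Graph
    node_order: list[str]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        g = nx.Graph()
        order: list[str] = []
        seen: set[str] = set()

        def _touch(n: str) -> None:
            if n not in seen:
                seen.add(n)
                order.append(n)
                g.add_node(n)

        for a, b, score in edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r} is not allowed")
            s = int(score)
            if not (SCORE_MIN <= s <= SCORE_MAX):
                raise ValidationError(
                    f"edge ({a},{b}) score {s} outside [{SCORE_MIN}, {SCORE_MAX}]"
                )
            _touch(a)
            _touch(b)
            if g.has_edge(a, b) and g[a][b]["score"] != s:
                raise ValidationError(
                    f"conflicting duplicate edge ({a},{b}): "
                    f"{g[a][b]['score']} vs {s}"
                )
            g.add_edge(a, b, score=s)
        for n in extra_nodes:
            _touch(n)
        return cls(graph=g, node_order=order)

    # -- queries ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, node: str) -> bool:
        return self.graph.has_node(node)

    def score(self, a: str, b: str) -> int:
        """Confidence score of edge (a, b) in either orientation; 0 if absent."""
        if self.graph.has_edge(a, b):
            return self.graph[a][b]["score"]
        return 0

    def neighbor_scores(self, node: str) -> dict[str, int]:
        return {nbr: d["score"] for nbr, d in self.graph[node].items()}


@dataclass
class SeedSet:
    """Validated disease genes mapped onto the network.

    ``members`` keeps input order; ``unmapped`` records identifiers absent
    from the network (dropped with a warning, mirroring a silent upstream
    ID-conversion step).
    """

    members: list[str]
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("seed set has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError("duplicate seed members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass
class AnnotationTable:
    """Functional gene sets (GO terms and KEGG pathways in one table).

    ``term_sets`` maps term identifier -> member genes; ``namespaces`` tags
    each term (e.g. ``GO`` vs ``KEGG``) based on an identifier-prefix
    convention. GO and KEGG terms deliberately share one vector space: the
    screen measures joint annotation overlap.
    """

    term_sets: dict[str, set[str]]
    namespaces: dict[str, str] = field(default_factory=dict)
    _gene_terms: dict[str, set[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term, genes in self.term_sets.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")

    def terms_of(self, gene: str) -> set[str]:
        if self._gene_terms is None:
            idx: dict[str, set[str]] = {}
            for term, genes in self.term_sets.items():
                for g in genes:
                    idx.setdefault(g, set()).add(term)
            self._gene_terms = idx
        return self._gene_terms.get(gene, set())

    @property
    def n_terms(self) -> int:
        return len(self.term_sets)


@dataclass
class CandidateRecord:
    """One row of the final candidate table."""

    gene: str
    heat: float
    z: float
    mis: int
    mfs: float


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _strip_taxon_prefixes(ids_a: list[str], ids_b: list[str]) -> tuple[list[str], list[str]]:
    """Strip a leading ``<digits>.`` taxon prefix when ALL identifiers carry
    one; leave all untouched when none does; raise on mixed prefixing."""
    all_ids = ids_a + ids_b
    prefixed = [bool(_TAXON_PREFIX.match(i)) for i in all_ids]
    if all(prefixed):
        return (
            [_TAXON_PREFIX.sub("", i) for i in ids_a],
            [_TAXON_PREFIX.sub("", i) for i in ids_b],
        )
    if any(prefixed):
        raise ValidationError(
            "mixed taxon prefixing: some identifiers carry a '<digits>.' "
            "prefix and some do not"
        )
    return ids_a, ids_b


def read_string_links(path: str | Path, min_score: int = SCORE_MIN) -> PPINetwork:
    """Read a STRING protein-links file into a :class:`PPINetwork`.

    The file has one header line followed by whitespace-separated triples
    ``protein1 protein2 combined_score``. Symmetric duplicates (A-B and B-A
    with the same score) collapse to one undirected edge; conflicting scores
    are an error, as are self-loops and scores outside [150, 999]. Only edges
    with ``score >= min_score`` are kept.
    """
    path = Path(path)
    ids_a: list[str] = []
    ids_b: list[str] = []
    scores: list[int] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 whitespace-separated fields, "
                    f"got {len(parts)}"
                )
            a, b, raw = parts
            try:
                s = int(raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer score {raw!r}"
                ) from None
            if not (SCORE_MIN <= s <= SCORE_MAX):
                raise ValidationError(
                    f"{path}:{lineno}: score {s} outside [{SCORE_MIN}, {SCORE_MAX}]"
                )
            ids_a.append(a)
            ids_b.append(b)
            scores.append(s)

    ids_a, ids_b = _strip_taxon_prefixes(ids_a, ids_b)
    kept = [
        (a, b, s)
        for a, b, s in zip(ids_a, ids_b, scores)
        if s >= min_score
    ]
    net = PPINetwork.from_edges(kept)
    logger.info(
        "read %s: %d nodes, %d edges (min_score=%d)",
        path, net.n_nodes, net.n_edges, min_score,
    )
    return net


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one identifier per line, ``#`` comments
    and blank lines ignored, duplicates dropped keeping first occurrence."""
    path = Path(path)
    out: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    with path.open() as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line in seen:
                n_dup += 1
                continue
            seen.add(line)
            out.append(line)
    if not out:
        raise ValidationError(f"{path}: no identifiers found")
    if n_dup:
        logger.info("read %s: dropped %d duplicate identifiers", path, n_dup)
    logger.info("read %s: %d identifiers", path, len(out))
    return out


def map_seeds(identifiers: Sequence[str], network: PPINetwork) -> SeedSet:
    """Intersect a gene list with the network's node set.

    Identifiers absent from the network are dropped with a warning; an empty
    intersection is an error.
    """
    if network.n_nodes == 0:
        raise ValidationError("network is empty")
    members = [g for g in identifiers if network.has_node(g)]
    unmapped = [g for g in identifiers if not network.has_node(g)]
    if unmapped:
        logger.warning(
            "%d seed identifiers not in network (dropped): %s",
            len(unmapped), ", ".join(unmapped[:10]),
        )
    if not members:
        raise ValidationError("no seed identifiers map to the network")
    return SeedSet(members=members, unmapped=unmapped)


def read_gmt(
    path: str | Path,
    namespaces: Mapping[str, str] | None = None,
) -> AnnotationTable:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    ``namespaces`` optionally maps a term-identifier prefix to a namespace
    tag (e.g. ``{"GO:": "GO", "hsa": "KEGG"}``); unmatched terms are tagged
    ``"default"``. Duplicate term identifiers are an error.
    """
    path = Path(path)
    term_sets: dict[str, set[str]] = {}
    tags: dict[str, str] = {}
    prefixes = sorted((namespaces or {}).items(), key=lambda kv: -len(kv[0]))
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need term, description and at least one gene"
                )
            term = fields[0].strip()
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in term_sets:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate term identifier {term!r}"
                )
            term_sets[term] = genes
            tags[term] = next(
                (tag for pre, tag in prefixes if term.startswith(pre)), "default"
            )
    logger.info("read %s: %d terms", path, len(term_sets))
    return AnnotationTable(term_sets=term_sets, namespaces=tags)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = ["gene_id", "heat", "z_score", "mis", "mfs"]


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return format(x, ".6g")


def write_candidate_table(records: Sequence[CandidateRecord], path: str | Path) -> None:
    """Write the candidate table as TSV with columns
    gene_id, heat, z_score, mis, mfs (floats at >= 4 significant digits)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CANDIDATE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{_fmt(r.heat)}\t{_fmt(r.z)}\t{int(r.mis)}\t{_fmt(r.mfs)}\n"
            )


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_candidate_table` output."""
    return pd.read_csv(path, sep="\t")


def write_string_links(network: PPINetwork, path: str | Path) -> None:
    """Write a network back out in the STRING protein-links dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, d in network.graph.edges(data=True):
            fh.write(f"{a} {b} {d['score']}\n")


def write_gene_list(identifiers: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in identifiers))


def write_gmt(table: AnnotationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for term, genes in table.term_sets.items():
            desc = table.namespaces.get(term, "default")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def write_heat_table(nodes: Sequence[str], heat, path: str | Path) -> None:
    """Two-column TSV dump (node, heat) of a heat vector."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node\theat\n")
        for n, h in zip(nodes, heat):
            fh.write(f"{n}\t{_fmt(float(h))}\n")


def write_truth(truth, path: str | Path) -> None:
    """Serialize fixture ground truth as JSON lines (one class per line)."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in truth.as_records():
            fh.write(json.dumps({key: value}) + "\n")
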