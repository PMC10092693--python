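"""Per-cell mitochondrial network metrics and phenotype classification.

From a :class:`~mitoquant.skeleton.SkeletonGraph` this module computes the
standard network summary: total length, connected components, node/edge
counts, free ends and junction types, average edge length, average degree,
PHI (length of the largest connected component relative to total length;
1 means a single connected network), and a composite connectivity score used
to call the fragmentation phenotype (fragmented below a threshold, 3.0 by
default).

Definitions
-----------
* ``avg_degree`` is the graph-theoretic mean degree: the sum of node degrees
  (a self-loop counts 2) divided by the number of graph nodes.  This is
  monotone in connectivity and equals 2E/N for loop-free graphs.
* ``n_nodes`` counts endpoints and branch points only: synthetic cycle
  anchors (bookkeeping nodes that let isolated loops carry length) are
  excluded, so free ends + junctions partition ``n_nodes`` for skeleton
  graphs.
* PHI's "largest component" is largest by total edge length, not node count
  — PHI is a length ratio.
* The default connectivity-score formula is a declared surrogate,
  ``phi * avg_degree * avg_edge_length_um``: it increases strictly in each
  factor and separates fragmented from filamentous networks.  Alternative
  formulas are pluggable via :data:`SCORE_FORMULAS`; the 3.0 phenotype
  threshold is calibrated to the default formula and must be re-calibrated
  if the formula is substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .skeleton import CYCLE_ANCHOR, FREE_END, ISOLATED, JUNCTION, PASSTHROUGH, SkeletonGraph

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkMetrics",
    "PhenotypeCall",
    "SCORE_FORMULAS",
    "compute_metrics",
    "connectivity_score",
    "classify_phenotype",
    "FRAGMENTED",
    "FILAMENTOUS_OR_MILD",
]

FRAGMENTED = "fragmented"
FILAMENTOUS_OR_MILD = "filamentous_or_mild"


@dataclass
class NetworkMetrics:
    """Per-cell mitochondrial network summary record."""

    total_length_um: float = 0.0
    n_components: int = 0
    n_nodes: int = 0
    n_edges: int = 0
    n_free_ends: int = 0
    n_junction3: int = 0
    n_junction4: int = 0
    n_junction_higher: int = 0
    avg_edge_length_um: float = math.nan
    avg_degree: float = math.nan
    phi: float = math.nan
    conn_score: float = math.nan

    def to_row(self) -> dict:
        """Fixed-name column mapping for CSV/JSON emission."""
        return {
            "total_length_um": self.total_length_um,
            "n_components": self.n_components,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "free_ends": self.n_free_ends,
            "junction3": self.n_junction3,
            "junction4": self.n_junction4,
            "avg_edge_length_um": self.avg_edge_length_um,
            "avg_degree": self.avg_degree,
            "phi": self.phi,
            "conn_score": self.conn_score,
        }


@dataclass
class PhenotypeCall:
    label: str
    score: float
    threshold: float


def compute_metrics(graph: SkeletonGraph, score_formula: str = "phi_degree_length") -> NetworkMetrics:
    """Compute all network metrics for a (possibly empty) skeleton graph.

    Empty graphs yield zero counts and missing (NaN) ratios; graphs without
    edges cannot define PHI or average edge length and report them missing.
    """
    m = NetworkMetrics()
    g = graph.g
    if g.number_of_nodes() == 0:
        logger.debug("empty graph: metrics are zero counts / missing ratios")
        return m
    m.n_edges = g.number_of_edges()
    m.total_length_um = graph.total_length()
    m.n_components = graph.n_components()
    kinds = [d["kind"] for _, d in g.nodes(data=True)]
    m.n_free_ends = sum(k == FREE_END for k in kinds)
    degrees = dict(g.degree())
    for n, d in g.nodes(data=True):
        if d["kind"] in (CYCLE_ANCHOR,):
            continue
        deg = degrees[n]
        if deg == 3:
            m.n_junction3 += 1
        elif deg == 4:
            m.n_junction4 += 1
        elif deg >= 5:
            m.n_junction_higher += 1
    m.n_nodes = sum(k != CYCLE_ANCHOR for k in kinds)
    n_all = g.number_of_nodes()
    m.avg_degree = sum(degrees.values()) / n_all if n_all else math.nan
    if m.n_edges > 0:
        m.avg_edge_length_um = m.total_length_um / m.n_edges
        comp_lengths = graph.component_lengths()
        if m.total_length_um > 0:
            m.phi = max(comp_lengths) / m.total_length_um
    m.conn_score = connectivity_score(m, formula=score_formula)
    return m


def _score_phi_degree_length(m: NetworkMetrics) -> float:
    return m.phi * m.avg_degree * m.avg_edge_length_um


#: Pluggable connectivity-score formulas, keyed by config id.
SCORE_FORMULAS = {"phi_degree_length": _score_phi_degree_length}


def connectivity_score(metrics: NetworkMetrics, formula: str = "phi_degree_length") -> float:
    """Composite connectivity score; NaN (missing) for an empty network."""
    if formula not in SCORE_FORMULAS:
        raise ValueError(f"unknown connectivity-score formula {formula!r}")
    if metrics.n_edges < 1 or not math.isfinite(metrics.phi):
        logger.debug("connectivity score undefined for an empty network")
        return math.nan
    return float(SCORE_FORMULAS[formula](metrics))


def classify_phenotype(metrics: NetworkMetrics, threshold: float = 3.0) -> PhenotypeCall:
    """Call the fragmentation phenotype from the connectivity score.

    Fragmented iff ``conn_score < threshold`` (strict); a score exactly at
    the threshold is called filamentous-or-mild.
    """
    if not math.isfinite(metrics.conn_score):
        raise ValueError("cannot classify phenotype: connectivity score is missing")
    label = FRAGMENTED if metrics.conn_score < threshold else FILAMENTOUS_OR_MILD
    return PhenotypeCall(label=label, score=metrics.conn_score, threshold=threshold)
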