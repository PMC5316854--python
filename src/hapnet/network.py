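"""Per-pathway interaction networks and dose-weighted edge/module scoring.

An edge between genes G1 and G2 is scored from their copy-number calls
(C1, C2) and dose-sensitivity weights (W1, W2):

* deletion branch — at least one call < 0:
  ``min(C1, 0) * W1 + min(C2, 0) * W2``  (an amplified partner contributes
  nothing, keeping the branch non-positive);
* gain branch — both calls >= 0: ``C1 * W1 + C2 * W2``.

The scorer is a pluggable strategy (see :data:`SCORERS`); every result
header records which one was used. Module scores are sums of edge scores
per sample, normalized against the score obtained when every node in the
module carries a monoallelic loss (call -1 everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .defaults import GISTIC_DOMAIN
from .io import (
    ConfigurationError,
    CopyNumberMatrix,
    DoseSensitivityMap,
    InteractionSet,
    ValidationError,
)

__all__ = [
    "EdgeScorer",
    "SCORERS",
    "DEFAULT_SCORER",
    "EdgeScore",
    "PathwayNetwork",
    "ModuleScoreTable",
    "build_pathway_network",
    "score_edge",
    "min_haploinsufficient_score",
    "score_module",
    "normalized_module_scores",
    "CompiledModule",
]

MODES = ("intrinsic", "cross_pathway", "expand1", "expand2")


# ---------------------------------------------------------------------------
# Edge scoring strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeScorer:
    """Two-branch GDS-weighted edge score.

    ``suppress_gain_partner`` controls whether, in the deletion branch, a
    gained partner's positive term is dropped (default) or retained (the
    alternative reconstruction for mixed "antagonistic" edges).
    """

    name: str
    suppress_gain_partner: bool = True

    def score(self, c1: float, c2: float, w1: int, w2: int) -> float:
        if c1 < 0 or c2 < 0:
            if self.suppress_gain_partner:
                return min(c1, 0) * w1 + min(c2, 0) * w2
            return c1 * w1 + c2 * w2
        return c1 * w1 + c2 * w2

    def branch(self, c1: float, c2: float) -> str:
        return "deletion" if (c1 < 0 or c2 < 0) else "gain"

    def score_arrays(self, c1: np.ndarray, c2: np.ndarray,
                     w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
        """Vectorized scoring; arrays broadcast edge-wise x sample-wise."""
        deletion = (c1 < 0) | (c2 < 0)
        gain_val = c1 * w1 + c2 * w2
        if self.suppress_gain_partner:
            del_val = np.minimum(c1, 0) * w1 + np.minimum(c2, 0) * w2
        else:
            del_val = gain_val
        return np.where(deletion, del_val, gain_val)

    def min_edge_score(self, w1: int, w2: int) -> float:
        """Edge score when both endpoints carry a monoallelic loss."""
        return self.score(-1, -1, w1, w2)


SCORERS: dict[str, EdgeScorer] = {
    "default": EdgeScorer("default", suppress_gain_partner=True),
    "mixed_partner": EdgeScorer("mixed_partner", suppress_gain_partner=False),
}
DEFAULT_SCORER = SCORERS["default"]


@dataclass(frozen=True)
class EdgeScore:
    value: float
    branch: str

    def __post_init__(self) -> None:
        if self.branch == "deletion" and self.value > 0:
            raise ValidationError("deletion-branch edge score must be <= 0")
        if self.branch == "gain" and self.value < 0:
            raise ValidationError("gain-branch edge score must be >= 0")


def score_edge(call1: int, call2: int, gds1: int, gds2: int,
               scorer: EdgeScorer = DEFAULT_SCORER) -> EdgeScore:
    """Score one edge from its endpoints' calls and GDS weights."""
    for c in (call1, call2):
        if c not in GISTIC_DOMAIN:
            raise ValidationError(f"call {c!r} outside {GISTIC_DOMAIN}")
    return EdgeScore(float(scorer.score(call1, call2, gds1, gds2)),
                     scorer.branch(call1, call2))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass
class PathwayNetwork:
    """One pathway's undirected scoring substrate.

    ``gds`` maps every node to its dose-sensitivity weight; ``members``
    flags nodes belonging to the seed gene set (relevant for cross-pathway
    and expansion modes).
    """

    name: str
    gds: dict[str, int]
    edges: tuple[tuple[str, str], ...]
    mode: str = "intrinsic"
    members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in self.gds or b not in self.gds:
                raise ValidationError(f"edge ({a!r}, {b!r}) endpoint missing from nodes")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                raise ValidationError(f"duplicate edge ({a!r}, {b!r})")
            seen.add(key)
        if self.mode == "intrinsic" and not set(self.gds) <= self.members:
            raise ValidationError("intrinsic network contains non-member nodes")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.gds)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def scorable(self) -> bool:
        return len(self.edges) > 0


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def build_pathway_network(
    name: str,
    pathway_genes: Iterable[str],
    interactions: InteractionSet,
    gds: DoseSensitivityMap,
    mode: str = "intrinsic",
    cross_universe: Iterable[str] | None = None,
) -> PathwayNetwork:
    """Select edges for a pathway under one of the four retention modes.

    intrinsic
        both endpoints in the pathway;
    cross_pathway
        one endpoint in the pathway, the other in pathway + ``cross_universe``
        (the companion gene sets; required for this mode);
    expand1 / expand2
        pathway plus its direct interactors (one / two interaction steps),
        keeping all edges among the expanded node set.

    An empty resulting edge set yields a network flagged unscorable, not an
    exception.
    """
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    members = frozenset(g.strip().upper() for g in pathway_genes)
    if mode == "cross_pathway":
        if cross_universe is None:
            raise ConfigurationError("cross_pathway mode requires cross_universe")
        universe = members | frozenset(g.strip().upper() for g in cross_universe)
        kept = [e for e in interactions.edges
                if (e[0] in members and e[1] in universe)
                or (e[1] in members and e[0] in universe)]
        node_set = members | {g for e in kept for g in e}
    elif mode == "intrinsic":
        kept = [e for e in interactions.edges if e[0] in members and e[1] in members]
        node_set = set(members)
    else:
        node_set = set(members)
        steps = 1 if mode == "expand1" else 2
        for _ in range(steps):
            frontier = {g for e in interactions.edges
                        if (e[0] in node_set) != (e[1] in node_set)
                        for g in e if g not in node_set}
            node_set |= frontier
        kept = [e for e in interactions.edges if e[0] in node_set and e[1] in node_set]
    edges = tuple(sorted(_canon(*e) for e in kept))
    node_gds = {g: gds.weight(g) for g in sorted(node_set)}
    return PathwayNetwork(name=name, gds=node_gds, edges=edges, mode=mode, members=members)


# ---------------------------------------------------------------------------
# Module scores
# ---------------------------------------------------------------------------


def min_haploinsufficient_score(network: PathwayNetwork,
                                scorer: EdgeScorer = DEFAULT_SCORER) -> float:
    """Module score when every node carries a monoallelic loss (call -1).

    This is the normalization anchor; it equals ``-sum(W1 + W2)`` over edges
    under the default scorer, and 0 for edgeless networks.
    """
    return float(sum(scorer.min_edge_score(network.gds[a], network.gds[b])
                     for a, b in network.edges))


def score_module(network: PathwayNetwork, sample_calls: Mapping[str, int],
                 scorer: EdgeScorer = DEFAULT_SCORER) -> float:
    """Sum of edge scores for one sample; absent genes count as call 0."""
    total = 0.0
    for a, b in network.edges:
        total += scorer.score(sample_calls.get(a, 0), sample_calls.get(b, 0),
                              network.gds[a], network.gds[b])
    return float(total)


class CompiledModule:
    """A network bound to a matrix's gene index for fast repeated scoring.

    Genes present in the network but absent from the matrix are scored as
    call 0 (``n_missing_genes`` counts them).
    """

    def __init__(self, network: PathwayNetwork, genes: Sequence[str],
                 scorer: EdgeScorer = DEFAULT_SCORER):
        self.network = network
        self.scorer = scorer
        index = {g: i for i, g in enumerate(genes)}
        pad = len(genes)  # virtual all-zero row for absent genes
        self._i1 = np.array([index.get(a, pad) for a, _ in network.edges], dtype=np.intp)
        self._i2 = np.array([index.get(b, pad) for _, b in network.edges], dtype=np.intp)
        self._w1 = np.array([network.gds[a] for a, _ in network.edges], dtype=np.float64)
        self._w2 = np.array([network.gds[b] for _, b in network.edges], dtype=np.float64)
        missing = {g for e in network.edges for g in e if g not in index}
        self.n_missing_genes = len(missing)
        self.min_score = min_haploinsufficient_score(network, scorer)

    def raw_scores(self, values: np.ndarray) -> np.ndarray:
        """Per-sample raw module scores for a (genes x samples) call array."""
        if not self.network.scorable:
            return np.zeros(values.shape[1])
        padded = np.vstack([values, np.zeros((1, values.shape[1]), dtype=values.dtype)])
        c1 = padded[self._i1]  # (edges, samples)
        c2 = padded[self._i2]
        scores = self.scorer.score_arrays(c1, c2, self._w1[:, None], self._w2[:, None])
        return scores.sum(axis=0)

    def normalized_scores(self, values: np.ndarray) -> np.ndarray:
        raw = self.raw_scores(values)
        if self.min_score == 0:
            return np.full(raw.shape, np.nan)
        return raw / abs(self.min_score)


@dataclass
class ModuleScoreTable:
    """Per-sample raw and normalized scores for one pathway."""

    pathway: str
    samples: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    min_haploinsufficient_score: float
    scorer: str
    mode: str
    scorable: bool = True
    n_missing_genes: int = 0

    @property
    def mean_normalized(self) -> float:
        return float(np.mean(self.normalized)) if self.scorable else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pathway": self.pathway,
            "sample": self.samples,
            "raw": self.raw,
            "normalized": self.normalized,
        })


def normalized_module_scores(network: PathwayNetwork, matrix: CopyNumberMatrix,
                             scorer: EdgeScorer = DEFAULT_SCORER) -> ModuleScoreTable:
    """Per-sample module scores normalized to the all-(-1) minimum.

    ``normalized = raw / |min_haploinsufficient_score|``: a cohort in which
    every node is monoallelically lost scores exactly -1. Unscorable
    (edgeless) networks yield NaN scores, to be excluded downstream.
    """
    if matrix.mode != "discrete":
        raise ConfigurationError("module scoring requires a discrete matrix")
    compiled = CompiledModule(network, matrix.genes, scorer)
    values = matrix.values.to_numpy()
    raw = compiled.raw_scores(values)
    if network.scorable:
        normalized = compiled.normalized_scores(values)
    else:
        raw = np.full(matrix.n_samples, np.nan)
        normalized = np.full(matrix.n_samples, np.nan)
    return ModuleScoreTable(
        pathway=network.name,
        samples=matrix.samples,
        raw=raw,
        normalized=normalized,
        min_haploinsufficient_score=compiled.min_score,
        scorer=scorer.name,
        mode=network.mode,
        scorable=network.scorable,
        n_missing_genes=compiled.n_missing_genes,
    )
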