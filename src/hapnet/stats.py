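"""Tumour-paired permutation null and pathway significance calls.

The null preserves each sample's own copy-number burden: within every
sample, the multiset of calls is kept and reassigned to genes by a uniform
random permutation. Each shuffled cohort is scored exactly like the
observed one; the observed and per-replicate null per-sample score
distributions are compared by a two-sample t-test, the replicate p-values
are aggregated as ``10 ** mean(log10 p)``, and Bonferroni correction gives
the q value used for the direction call.

Replicate r draws its permutation from RNG substream r of the run seed, so
results are reproducible regardless of pathway iteration order, and one
cohort shuffle per replicate scores all pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .defaults import ALPHA, N_REPLICATES
from .io import ConfigurationError, CopyNumberMatrix, DoseSensitivityMap, InteractionSet, PathwayCollection
from .network import (
    DEFAULT_SCORER,
    CompiledModule,
    EdgeScorer,
    PathwayNetwork,
    build_pathway_network,
)

__all__ = [
    "PermutationResult",
    "PanPathwayRun",
    "shuffle_cohort",
    "shuffle_values",
    "permutation_test",
    "adjust_bonferroni",
    "run_pan_pathway",
]

_P_FLOOR = np.finfo(float).tiny  # floor before log10 to avoid -inf


# ---------------------------------------------------------------------------
# Shuffling
# ---------------------------------------------------------------------------


def shuffle_values(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column (sample) of a genes x samples array independently."""
    perm = np.argsort(rng.random(values.shape), axis=0)
    return values[perm, np.arange(values.shape[1])]


def shuffle_cohort(matrix: CopyNumberMatrix, rng: np.random.Generator) -> CopyNumberMatrix:
    """Tumour-paired shuffle: reassign each sample's calls to genes at random.

    Per-sample call histograms are preserved exactly; gene and sample labels
    are unchanged.
    """
    if matrix.mode != "discrete":
        raise ConfigurationError("shuffle_cohort expects a discrete matrix")
    shuffled = shuffle_values(matrix.values.to_numpy(), rng)
    df = pd.DataFrame(shuffled, index=matrix.values.index, columns=matrix.values.columns)
    return CopyNumberMatrix(df, mode="discrete")


def _replicate_rngs(seed: int, n_reps: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_reps)]


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------


def adjust_bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted q = min(1, p * m)."""
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


def _welch_log10_p(observed: np.ndarray, null: np.ndarray, equal_var: bool) -> tuple[float, bool]:
    """log10 p of a two-sided two-sample t-test; degenerate tests yield p=1."""
    if np.ptp(observed) == 0 and np.ptp(null) == 0:
        return 0.0, True  # zero variance in both groups: no evidence, p = 1
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-degenerate inputs
        _, p = sps.ttest_ind(observed, null, equal_var=equal_var)
    if not np.isfinite(p):
        return 0.0, True
    return float(np.log10(max(p, _P_FLOOR))), False


@dataclass
class PermutationResult:
    """Observed-vs-null comparison for one pathway."""

    pathway: str
    n_edges: int
    observed: np.ndarray            # per-sample normalized scores
    null_means: np.ndarray          # per-replicate mean of null per-sample scores
    log10_p: np.ndarray             # per-replicate log10 p
    p: float                        # 10 ** mean(log10 p)
    q: float                        # Bonferroni-adjusted
    direction: str                  # deletion_enriched | amplification_enriched | none
    n_replicates: int
    n_degenerate: int
    seed: int
    alpha: float
    m_comparisons: int
    scorer: str = "default"

    @property
    def mean_observed(self) -> float:
        return float(np.mean(self.observed))

    @property
    def mean_null(self) -> float:
        return float(np.mean(self.null_means))


def _finalize(pathway: str, n_edges: int, observed: np.ndarray, null_means: np.ndarray,
              log10_p: np.ndarray, n_degenerate: int, alpha: float, m: int,
              seed: int, scorer_name: str) -> PermutationResult:
    p = float(10 ** np.mean(log10_p))
    q = adjust_bonferroni(p, m)
    diff = float(np.mean(observed) - np.mean(null_means))
    if q <= alpha and diff < 0:
        direction = "deletion_enriched"
    elif q <= alpha and diff > 0:
        direction = "amplification_enriched"
    else:
        direction = "none"
    return PermutationResult(
        pathway=pathway, n_edges=n_edges, observed=observed, null_means=null_means,
        log10_p=log10_p, p=p, q=q, direction=direction,
        n_replicates=len(log10_p), n_degenerate=n_degenerate, seed=seed,
        alpha=alpha, m_comparisons=m, scorer=scorer_name,
    )


def _permutation_engine(
    networks: Sequence[PathwayNetwork],
    matrix: CopyNumberMatrix,
    n_reps: int,
    seed: int,
    scorer: EdgeScorer,
    equal_var: bool,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], list[int]]:
    """Shared shuffle loop: one cohort shuffle per replicate scores all networks.

    Returns per-network (observed normalized scores, replicate null means,
    replicate log10 p, degenerate-replicate count).
    """
    values = matrix.values.to_numpy()
    compiled = [CompiledModule(nw, matrix.genes, scorer) for nw in networks]
    observed = [c.normalized_scores(values) for c in compiled]
    null_means = [np.empty(n_reps) for _ in networks]
    log10_p = [np.empty(n_reps) for _ in networks]
    n_degenerate = [0] * len(networks)
    for r, rng in enumerate(_replicate_rngs(seed, n_reps)):
        shuffled = shuffle_values(values, rng)
        for k, c in enumerate(compiled):
            null = c.normalized_scores(shuffled)
            null_means[k][r] = null.mean()
            lp, degenerate = _welch_log10_p(observed[k], null, equal_var)
            log10_p[k][r] = lp
            if degenerate:
                n_degenerate[k] += 1
    return observed, null_means, log10_p, n_degenerate


def permutation_test(
    network: PathwayNetwork,
    matrix: CopyNumberMatrix,
    n_reps: int = N_REPLICATES,
    alpha: float = ALPHA,
    m_comparisons: int = 1,
    seed: int = 0,
    scorer: EdgeScorer = DEFAULT_SCORER,
    equal_var: bool = False,
) -> PermutationResult:
    """Permutation significance for a single pathway network.

    For each replicate the cohort is shuffled (tumour-paired), rescored, and
    compared with the observed per-sample normalized scores by a two-sided
    t-test (Welch by default; ``equal_var=True`` for pooled-variance
    Student). Degenerate zero-variance comparisons contribute p = 1 and are
    counted.
    """
    if n_reps < 1:
        raise ConfigurationError(f"n_reps must be >= 1, got {n_reps}")
    if not network.scorable:
        raise ConfigurationError(f"network {network.name!r} is unscorable (no edges)")
    obs, nulls, lps, degs = _permutation_engine(
        [network], matrix, n_reps, seed, scorer, equal_var)
    return _finalize(network.name, network.n_edges, obs[0], nulls[0], lps[0],
                     degs[0], alpha, m_comparisons, seed, scorer.name)


@dataclass
class PanPathwayRun:
    """All per-pathway results of a cohort-wide run."""

    results: list[PermutationResult]
    unscorable: list[str] = field(default_factory=list)
    seed: int = 0
    scorer: str = "default"
    mode: str = "intrinsic"

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "pathway": r.pathway,
            "n_edges": r.n_edges,
            "mean_norm_score": r.mean_observed,
            "mean_null_score": r.mean_null,
            "p": r.p,
            "q": r.q,
            "direction": r.direction,
            "n_degenerate_reps": r.n_degenerate,
        } for r in self.results]
        df = pd.DataFrame(rows, columns=[
            "pathway", "n_edges", "mean_norm_score", "mean_null_score",
            "p", "q", "direction", "n_degenerate_reps"])
        return df.sort_values(["q", "pathway"], kind="stable").reset_index(drop=True)


def run_pan_pathway(
    collection: PathwayCollection,
    interactions: InteractionSet,
    gds: DoseSensitivityMap,
    matrix: CopyNumberMatrix,
    mode: str = "intrinsic",
    n_reps: int = N_REPLICATES,
    alpha: float = ALPHA,
    seed: int = 0,
    m_comparisons: int | None = None,
    scorer: EdgeScorer = DEFAULT_SCORER,
    equal_var: bool = False,
) -> PanPathwayRun:
    """Score and test every pathway in a collection against one cohort.

    Shuffle replicates are shared across pathways by replicate index, so the
    run costs O(n_reps) shuffles and is reproducible from the seed alone.
    ``m_comparisons`` defaults to the number of scorable pathways tested.
    In ``cross_pathway`` mode each pathway's companion universe is the union
    of all other pathways in the collection.
    """
    networks, unscorable = [], []
    for name, genes in collection.items():
        cross = None
        if mode == "cross_pathway":
            cross = set().union(*(set(collection[o]) for o in collection if o != name)) \
                if len(collection) > 1 else set()
        nw = build_pathway_network(name, genes, interactions, gds, mode=mode,
                                   cross_universe=cross)
        if nw.scorable:
            networks.append(nw)
        else:
            unscorable.append(name)
    if not networks:
        return PanPathwayRun([], unscorable, seed=seed, scorer=scorer.name, mode=mode)
    m = m_comparisons if m_comparisons is not None else len(networks)
    obs, nulls, lps, degs = _permutation_engine(
        networks, matrix, n_reps, seed, scorer, equal_var)
    results = [
        _finalize(nw.name, nw.n_edges, obs[k], nulls[k], lps[k], degs[k],
                  alpha, m, seed, scorer.name)
        for k, nw in enumerate(networks)
    ]
    return PanPathwayRun(results, unscorable, seed=seed, scorer=scorer.name, mode=mode)
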