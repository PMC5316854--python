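"""Readers and writers for the external input dialects.

Formats
-------
* Gene sets: GMT (Broad dialect) — ``name<TAB>description<TAB>gene...``.
* Interactions: TSV with a header row and two resolvable symbol columns.
* Dose sensitivity: one human gene symbol per row, one file per evidence
  source (yeast, mouse).
* Copy number: TSV, first column gene symbols, remaining columns samples;
  values either discrete calls in {-2,-1,0,1,2} or continuous log2 ratios.
* Mutation frequencies: two-column TSV ``gene<TAB>fraction``.

All readers accept gzip-compressed files (by ``.gz`` suffix), uppercase and
whitespace-trim gene symbols, and record dropped/imputed records in a
:class:`LoadReport`.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .defaults import GISTIC_DOMAIN, GDS_MOUSE, GDS_NONE, GDS_YEAST, LOG2_CUTS

__all__ = [
    "FormatError",
    "ConfigurationError",
    "ValidationError",
    "LoadReport",
    "PathwayCollection",
    "InteractionSet",
    "DoseSensitivityMap",
    "CopyNumberMatrix",
    "MutationFrequencyMap",
    "read_gene_sets",
    "write_gene_sets",
    "read_interactions",
    "write_interactions",
    "read_dose_sensitivity",
    "write_dose_sensitivity",
    "read_copy_number",
    "write_copy_number",
    "threshold_log2",
    "read_mutation_frequencies",
    "write_mutation_frequencies",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ConfigurationError(ValueError):
    """Caller-supplied options are inconsistent or unresolvable."""


class ValidationError(ValueError):
    """Loaded values violate a domain invariant."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _norm_symbol(sym: str) -> str:
    return sym.strip().upper()


@dataclass
class LoadReport:
    """Machine-readable record of what a reader dropped or repaired."""

    source: str = ""
    self_loops_dropped: int = 0
    duplicates_collapsed: int = 0
    imputed_cells: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Pathway collections (GMT)
# ---------------------------------------------------------------------------


@dataclass
class PathwayCollection:
    """Ordered mapping pathway name -> deduplicated gene tuple."""

    pathways: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def items(self):
        return self.pathways.items()

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.pathways.values():
            out.update(gs)
        return frozenset(out)


def _dedup_upper(genes: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in genes:
        g = _norm_symbol(g)
        if g and g not in seen:
            seen[g] = None
    return tuple(seen)


def read_gene_sets(path, curation: Mapping[str, Sequence[str]] | None = None) -> PathwayCollection:
    """Read a GMT file, optionally appending manually curated genes.

    ``curation`` maps pathway name -> extra gene symbols appended (and
    deduplicated) after the file's own genes.
    """
    pathways: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description, genes...")
            name = parts[0].strip()
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = _dedup_upper(parts[2:])
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
            descriptions[name] = parts[1]
    if curation:
        for name, extra in curation.items():
            if name in pathways:
                pathways[name] = _dedup_upper(list(pathways[name]) + list(extra))
    return PathwayCollection(pathways, descriptions)


def write_gene_sets(collection: PathwayCollection, path) -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Protein-protein interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionSet:
    """Undirected, deduplicated, self-loop-free gene interaction set.

    Edges are stored as lexicographically sorted 2-tuples.
    """

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a > b:
                raise ValidationError(f"edge ({a!r}, {b!r}) not in canonical order")

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, str]]) -> "InteractionSet":
        edges = set()
        for a, b in pairs:
            a, b = _norm_symbol(a), _norm_symbol(b)
            if a == b:
                continue
            edges.add((a, b) if a < b else (b, a))
        return InteractionSet(frozenset(edges))

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def __contains__(self, pair) -> bool:
        a, b = _norm_symbol(pair[0]), _norm_symbol(pair[1])
        return ((a, b) if a < b else (b, a)) in self.edges

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)


def read_interactions(path, columns: tuple = (0, 1)) -> tuple[InteractionSet, LoadReport]:
    """Read a two-symbol-column TSV into an undirected edge set.

    ``columns`` names (or 0-based positions of) the two symbol columns.
    Returns the edge set plus a report counting dropped self-loops and
    collapsed duplicate/reciprocal rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = []
    for c in columns:
        if isinstance(c, int):
            if c >= df.shape[1]:
                raise ConfigurationError(f"column index {c} out of range for {path}")
            cols.append(df.columns[c])
        elif c in df.columns:
            cols.append(c)
        else:
            raise ConfigurationError(f"column {c!r} not found in {path}")
    report = LoadReport(source=str(path))
    edges: set[tuple[str, str]] = set()
    for a, b in df[cols].itertuples(index=False):
        a, b = _norm_symbol(str(a)), _norm_symbol(str(b))
        if a == b:
            report.self_loops_dropped += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in edges:
            report.duplicates_collapsed += 1
        else:
            edges.add(key)
    return InteractionSet(frozenset(edges)), report


def write_interactions(interactions: InteractionSet, path,
                       columns: tuple[str, str] = ("gene1", "gene2")) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(columns) + "\n")
        for a, b in sorted(interactions.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Dose sensitivity
# ---------------------------------------------------------------------------


@dataclass
class DoseSensitivityMap:
    """Per-gene dose-sensitivity weight: 1 none, 2 yeast, 3 mouse.

    Unknown genes weigh 1. Mouse evidence overrides yeast.
    """

    gds: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {GDS_YEAST: "yeast", GDS_MOUSE: "mouse"}
        for gene, w in self.gds.items():
            if w not in (GDS_YEAST, GDS_MOUSE):
                raise ValidationError(f"gene {gene!r}: stored weight must be 2 or 3, got {w}")
            if self.provenance.get(gene) != expected[w]:
                raise ValidationError(f"gene {gene!r}: weight {w} inconsistent with provenance")

    def weight(self, gene: str) -> int:
        return self.gds.get(_norm_symbol(gene), GDS_NONE)

    def provenance_of(self, gene: str) -> str:
        return self.provenance.get(_norm_symbol(gene), "none")

    @staticmethod
    def from_sources(yeast: Iterable[str], mouse: Iterable[str]) -> "DoseSensitivityMap":
        gds: dict[str, int] = {}
        prov: dict[str, str] = {}
        for g in yeast:
            g = _norm_symbol(g)
            if g:
                gds[g], prov[g] = GDS_YEAST, "yeast"
        for g in mouse:
            g = _norm_symbol(g)
            if g:
                gds[g], prov[g] = GDS_MOUSE, "mouse"
        return DoseSensitivityMap(gds, prov)


def _read_symbol_list(path) -> list[str]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            sym = line.split("\t")[0].strip()
            if sym:
                out.append(sym)
    return out


def read_dose_sensitivity(yeast_path, mouse_path) -> DoseSensitivityMap:
    """Combine yeast and mouse evidence lists; mouse overrides yeast."""
    return DoseSensitivityMap.from_sources(
        _read_symbol_list(yeast_path), _read_symbol_list(mouse_path)
    )


def write_dose_sensitivity(gds: DoseSensitivityMap, yeast_path, mouse_path) -> None:
    with _open_text(yeast_path, "wt") as fh:
        for g in sorted(g for g, p in gds.provenance.items() if p == "yeast"):
            fh.write(g + "\n")
    with _open_text(mouse_path, "wt") as fh:
        for g in sorted(g for g, p in gds.provenance.items() if p == "mouse"):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Copy-number matrices
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberMatrix:
    """Genes x samples copy-number table.

    ``mode`` is ``"discrete"`` (integer calls in {-2..2}) or ``"continuous"``
    (finite log2 segment values awaiting :func:`threshold_log2`).
    """

    values: pd.DataFrame
    mode: str = "discrete"

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuous"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.values.isna().any().any():
            raise ValidationError("matrix contains missing cells after load")
        if self.mode == "discrete":
            arr = self.values.to_numpy()
            bad = ~np.isin(arr, GISTIC_DOMAIN)
            if bad.any():
                gi, si = np.argwhere(bad)[0]
                raise ValidationError(
                    f"gene {self.values.index[gi]!r}, sample {self.values.columns[si]!r}: "
                    f"call {arr[gi, si]!r} outside {GISTIC_DOMAIN}"
                )
        else:
            arr = self.values.to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                raise ValidationError("continuous matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def calls_for(self, sample: str) -> dict[str, int]:
        col = self.values[sample]
        return {g: int(v) for g, v in col.items()}


def read_copy_number(path, mode: str = "discrete") -> tuple[CopyNumberMatrix, LoadReport]:
    """Read a gene x sample TSV; missing cells are imputed to 0 and counted."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [_norm_symbol(str(g)) for g in df.index]
    report = LoadReport(source=str(path))
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        df = df.fillna(0)
        report.imputed_cells = n_missing
    if mode == "discrete":
        arr = df.to_numpy()
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{path}: non-integer value in discrete mode")
        df = df.astype(np.int8)
    return CopyNumberMatrix(df, mode=mode), report


def write_copy_number(matrix: CopyNumberMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def threshold_log2(matrix: CopyNumberMatrix, cuts: Sequence[float] = LOG2_CUTS) -> CopyNumberMatrix:
    """Discretize a continuous matrix with four ordered cuts.

    ``v <= t_del2`` -> -2; ``t_del2 < v <= t_del1`` -> -1;
    ``t_del1 < v < t_amp1`` -> 0; ``t_amp1 <= v < t_amp2`` -> +1;
    ``v >= t_amp2`` -> +2. Boundary values are assigned outward, toward
    the alteration.
    """
    if matrix.mode != "continuous":
        raise ConfigurationError("threshold_log2 expects a continuous matrix")
    t_del2, t_del1, t_amp1, t_amp2 = cuts
    if not (t_del2 < t_del1 < 0 < t_amp1 < t_amp2):
        raise ConfigurationError(f"thresholds must satisfy t_del2 < t_del1 < 0 < t_amp1 < t_amp2; got {cuts}")
    v = matrix.values.to_numpy(dtype=float)
    calls = np.zeros(v.shape, dtype=np.int8)
    calls[v <= t_del1] = -1
    calls[v <= t_del2] = -2
    calls[v >= t_amp1] = 1
    calls[v >= t_amp2] = 2
    df = pd.DataFrame(calls, index=matrix.values.index, columns=matrix.values.columns)
    return CopyNumberMatrix(df, mode="discrete")


# ---------------------------------------------------------------------------
# Mutation frequencies
# ---------------------------------------------------------------------------


@dataclass
class MutationFrequencyMap:
    """Per-gene fraction of the cohort carrying a mutation, in [0, 1]."""

    freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, f in self.freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"gene {g!r}: mutation frequency {f} outside [0, 1]")

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.freq.get(_norm_symbol(gene), default)

    def __len__(self) -> int:
        return len(self.freq)


def read_mutation_frequencies(path) -> MutationFrequencyMap:
    freq: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene<TAB>fraction")
            gene = _norm_symbol(parts[0])
            if gene.lower() == "gene":  # tolerated header row
                continue
            try:
                f = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {parts[1]!r} is not a number") from exc
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"{path}:{lineno}: frequency {f} outside [0, 1]")
            freq[gene] = f
    return MutationFrequencyMap(freq)


def write_mutation_frequencies(mut: MutationFrequencyMap, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("gene\tfrequency\n")
        for g in sorted(mut.freq):
            fh.write(f"{g}\t{mut.freq[g]}\n")
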