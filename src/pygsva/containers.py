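"""Core in-memory containers shared across the package.

The central objects mirror the data flow of single-sample gene-set
enrichment: a genes x samples :class:`ExpressionMatrix` and a
:class:`GeneSetCollection` go in, a gene-sets x samples
:class:`EnrichmentMatrix` comes out.  Intermediate per-sample rank
statistics live in :class:`RankMatrix` and individual random-walk
trajectories in :class:`WalkTrajectory`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "EnrichmentMatrix",
    "RankMatrix",
    "WalkTrajectory",
    "KcdfConfig",
    "WalkConfig",
    "CONTINUOUS",
    "COUNTS",
]

CONTINUOUS = "continuous"
COUNTS = "counts"


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of gene identifiers.

    Duplicate members are an input error dealt with at parse time
    (:func:`pygsva.genesets_io.read_gmt` drops them with a warning); the
    container itself refuses them outright so that set sizes are always
    well defined.
    """

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "members", tuple(self.members))
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named :class:`GeneSet` objects."""

    sets: list[GeneSet]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set name(s): {dupes}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of normalized expression values.

    ``value_kind`` declares the measurement scale: ``"continuous"`` for
    e.g. log2 microarray intensities, ``"counts"`` for non-negative
    integer sequencing counts.  The count invariant is enforced on
    construction.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    value_kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        p, n = self.values.shape
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match matrix shape")
        _check_unique(self.gene_ids, "gene identifiers")
        _check_unique(self.sample_ids, "sample identifiers")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.value_kind not in (CONTINUOUS, COUNTS):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == COUNTS:
            if (self.values < 0).any():
                raise ValueError("counts matrix contains negative entries")
            if not np.array_equal(self.values, np.round(self.values)):
                bad = np.argwhere(self.values != np.round(self.values))[0]
                raise ValueError(
                    "counts matrix contains fractional value at gene "
                    f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_kind: str = CONTINUOUS) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            value_kind=value_kind,
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            value_kind=self.value_kind,
        )


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples enrichment scores produced by one method."""

    scores: np.ndarray
    set_names: list[str]
    sample_ids: list[str]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score matrix shape does not match identifier lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def params_json(self) -> str:
        return json.dumps(self.params, sort_keys=True)


@dataclass
class RankMatrix:
    """Per-sample rank statistics of the expression-level statistic z.

    ``ranks`` holds, for each sample, a permutation of ``1..p`` where the
    largest z gets rank ``p`` (ties broken by gene row order).  ``sym``
    holds the tail-symmetric statistic ``|p/2 - rank|`` which up-weights
    both extremes of the per-sample rank distribution.  ``order`` holds,
    per sample, the gene row indices in walk traversal order (decreasing
    z, i.e. decreasing rank).
    """

    z: np.ndarray
    ranks: np.ndarray
    sym: np.ndarray
    order: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.z.shape[0]

    @property
    def n_samples(self) -> int:
        return self.z.shape[1]


@dataclass
class WalkTrajectory:
    """The random-walk vector nu(l), l = 1..p, for one (sample, gene set)."""

    nu: np.ndarray
    set_name: str = ""
    sample_id: str = ""


@dataclass
class KcdfConfig:
    """Configuration of the kernel CDF expression-level statistic.

    kernel
        ``"gaussian"`` for continuous data, ``"poisson"`` for counts,
        ``"none"`` to pass values through unchanged (pre-normalized
        inputs), ``"auto"`` to pick from the matrix's ``value_kind``.
    bandwidth_factor
        Gaussian per-gene bandwidth is ``bandwidth_factor * s_i`` with
        ``s_i`` the gene's sample standard deviation; default 1/4.
    poisson_r
        Offset added to each count when it serves as a Poisson kernel
        mean; 0.5 places the kernel mode at the observed count.
    """

    kernel: str = "auto"
    bandwidth_factor: float = 0.25
    poisson_r: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel not in ("auto", "gaussian", "poisson", "none"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")
        if self.poisson_r <= 0:
            raise ValueError("poisson_r must be positive")


@dataclass
class WalkConfig:
    """Configuration of the random walk and enrichment-score summary.

    tau
        Tail-weight exponent applied to the symmetric rank statistic
        inside the set (default 1; 0 gives unweighted cumulative
        fractions).
    es_mode
        ``"max"`` for the maximum deviation from zero (classical KS-like
        score, bimodal under the null) or ``"diff"`` for the signed sum
        of the largest positive and negative excursions (approximately
        normal under the null).
    """

    tau: float = 1.0
    es_mode: str = "diff"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.es_mode not in ("max", "diff"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")
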