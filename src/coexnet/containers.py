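"""Core in-memory containers shared across the pipeline.

The pipeline passes a small set of typed objects between stages: an
expression matrix with a processing-stage tag, a per-sample survival
table, named gene signatures, a module hierarchy discovered on the
planar filtered network, and a run configuration holding every
threshold and seed so that outputs can record their provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """An input violated a documented invariant."""


# stages of the expression QC chain, in order
EXPRESSION_STAGES = ("raw", "logged", "normalized", "residualized")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample real matrix with identifiers and a stage tag.

    ``stage_tag`` records how far along the QC chain
    (raw -> logged -> normalized -> residualized) the values are.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage_tag: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.stage_tag not in EXPRESSION_STAGES:
            raise ValidationError(f"unknown stage_tag {self.stage_tag!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValidationError("missing values present; drop incomplete rows on load")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        keep = [g for g in genes if g in idx]
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            keep, list(self.sample_ids), self.values[rows], self.stage_tag,
            dict(self.provenance),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        keep = [s for s in samples if s in pos]
        cols = [pos[s] for s in keep]
        return ExpressionMatrix(
            list(self.gene_ids), keep, self.values[:, cols], self.stage_tag,
            dict(self.provenance),
        )

    def with_values(self, values: np.ndarray, stage_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), values, stage_tag,
            dict(self.provenance),
        )


@dataclass
class SurvivalTable:
    """Per-sample time-to-event data: time > 0 (days), event in {0, 1}."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    strata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample id in survival table")
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValidationError("survival table column lengths differ")
        if (self.time <= 0).any():
            raise ValidationError("nonpositive survival time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        if self.strata is not None and len(self.strata) != len(self.sample_ids):
            raise ValidationError("strata rows do not match sample ids")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        keep = [s for s in samples if s in pos]
        rows = [pos[s] for s in keep]
        strata = self.strata.iloc[rows].reset_index(drop=True) if self.strata is not None else None
        return SurvivalTable(keep, self.time[rows], self.event[rows], strata)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "time": self.time, "event": self.event})
        if self.strata is not None:
            df = pd.concat([df, self.strata.reset_index(drop=True)], axis=1)
        return df


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with a direction (up/down/unsigned) and provenance."""

    name: str
    genes: frozenset[str]
    direction: str = "unsigned"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if self.direction not in ("up", "down", "unsigned"):
            raise ValidationError(f"bad signature direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, background: Iterable[str]) -> "GeneSignature":
        return GeneSignature(self.name, self.genes & frozenset(background),
                             self.direction, self.source)


@dataclass
class Module:
    """One coexpression module: a gene set at a compactness scale alpha."""

    module_id: str
    parent_id: str | None
    alpha: float
    genes: frozenset[str]
    hubs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.genes = frozenset(str(g) for g in self.genes)
        self.hubs = frozenset(str(g) for g in self.hubs)
        if not self.hubs <= self.genes:
            raise ValidationError(f"hubs of {self.module_id} not a subset of its genes")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleHierarchy:
    """A forest of parent/child modules, one tree per compactness scale."""

    modules: list[Module]

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate module ids")
        by_id = {m.module_id: m for m in self.modules}
        for m in self.modules:
            if m.parent_id is not None:
                if m.parent_id not in by_id:
                    raise ValidationError(f"unknown parent {m.parent_id} for {m.module_id}")
                parent = by_id[m.parent_id]
                if not m.genes < parent.genes:
                    raise ValidationError(
                        f"module {m.module_id} is not a proper subset of its parent"
                    )

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def get(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def roots(self) -> list[Module]:
        return [m for m in self.modules if m.parent_id is None]

    def children(self, module_id: str) -> list[Module]:
        return [m for m in self.modules if m.parent_id == module_id]

    def at_alpha(self, alpha: float) -> list[Module]:
        return [m for m in self.modules if np.isclose(m.alpha, alpha)]

    def leaves(self, alpha: float | None = None) -> list[Module]:
        pool = self.modules if alpha is None else self.at_alpha(alpha)
        parent_ids = {m.parent_id for m in pool if m.parent_id is not None}
        return [m for m in pool if m.module_id not in parent_ids]

    def non_root(self, alpha: float | None = None) -> list[Module]:
        pool = self.modules if alpha is None else self.at_alpha(alpha)
        return [m for m in pool if m.parent_id is not None]


@dataclass
class RunConfig:
    """All pipeline thresholds and seeds, recorded into output provenance."""

    correlation_method: str = "pearson"
    correlation_fdr: float = 0.05
    de_fdr: float = 0.05
    de_fc: float = 1.2
    emsg_alpha: float = 0.05
    alphas: tuple[float, ...] = (0.5, 1.0, 2.0)
    min_module_size: int = 10
    n_perm: int = 100
    hub_p_cut: float = 0.05
    neighborhood_k: int = 5
    preservation_z_cut: float = 2.0
    preservation_p_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError("correlation_method must be pearson or spearman")
        for name in ("correlation_fdr", "de_fdr", "emsg_alpha",
                     "hub_p_cut", "preservation_p_cut"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name}={v} outside (0, 1)")
        if self.de_fc <= 1:
            raise ValidationError("de_fc must exceed 1")
        if self.min_module_size < 3:
            raise ValidationError("min_module_size must be >= 3")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be positive")
        if self.neighborhood_k < 1:
            raise ValidationError("neighborhood_k must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alphas"] = list(self.alphas)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "alphas" in data:
            data["alphas"] = tuple(float(a) for a in data["alphas"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
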