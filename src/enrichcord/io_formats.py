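"""Readers and writers for the formats the pipeline touches.

Expression data travel as a pair of plain TSV files: a genes x samples matrix
of log2 intensities, and a sidecar design table keyed by sample id with the
four labels every sample must carry (platform, test site, condition A/B,
replicate index).  Gene sets use the MSigDB GMT dialect (tab-separated,
``set_id<TAB>description<TAB>member...``, trailing tabs ignored, no quoting).
Gene identifiers are opaque, case-sensitive strings.

All readers validate on entry and fail loudly: silent row loss or silently
coerced values would defeat the point of a reproducibility study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("platform", "site", "condition", "replicate")
CONDITIONS = ("A", "B")


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus per-sample design labels.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, genes as the index, samples as columns.
    design
        DataFrame indexed by sample id with columns ``platform``, ``site``,
        ``condition`` (``A`` or ``B``) and ``replicate`` (1-based int).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        dup = idx[idx.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id(s): {sorted(set(dup))[:5]}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"sample(s) missing from design: {missing[:5]}")
        # keep only + reorder design rows to the matrix's samples
        self.design = self.design.loc[list(self.values.columns)].copy()
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise FormatError(f"design lacks required column {col!r}")
            bad = self.design.index[self.design[col].isna()]
            if len(bad):
                raise FormatError(
                    f"design missing {col!r} for sample(s): {list(bad)[:5]}"
                )
        bad_cond = self.design.index[~self.design["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            raise FormatError(
                f"condition must be one of {CONDITIONS}; offending sample(s): "
                f"{list(bad_cond)[:5]}"
            )
        self.design["replicate"] = self.design["replicate"].astype(int)
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression values must all be finite")
        counts = self.design.groupby(["platform", "site", "condition"]).size()
        thin = counts[counts < 2]
        if len(thin):
            raise FormatError(
                f"every (platform, site, condition) cell needs >=2 replicates; "
                f"violated by {list(thin.index)[:5]}"
            )

    # -- conveniences ------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def platforms(self) -> list[str]:
        return list(dict.fromkeys(self.design["platform"]))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.design["site"]))

    def samples_for(
        self,
        *,
        platform: str | None = None,
        site: str | None = None,
        condition: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given design labels, in matrix order."""
        mask = pd.Series(True, index=self.design.index)
        if platform is not None:
            mask &= self.design["platform"] == platform
        if site is not None:
            mask &= self.design["site"] == site
        if condition is not None:
            mask &= self.design["condition"] == condition
        return list(self.design.index[mask])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionStudy":
        """Restrict to `genes` (which must all be present), preserving their order."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise FormatError(f"gene(s) not in study: {missing[:5]}")
        return ExpressionStudy(self.values.loc[list(genes)], self.design.copy())


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GO-term stand-ins)."""

    sets: dict[str, GeneSet]
    universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if sid != gs.set_id:
                raise FormatError(f"key {sid!r} != set id {gs.set_id!r}")
            if not gs.members:
                raise FormatError(f"gene set {sid!r} has no members")
            if len(set(gs.members)) != len(gs.members):
                raise FormatError(f"gene set {sid!r} has duplicated members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members_of(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id].members

    def ids(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, design_path) -> ExpressionStudy:
    """Read a genes x samples TSV and its sidecar design TSV.

    The matrix file has a header row of sample ids and gene ids in the first
    column; the design file is keyed by ``sample_id``.  Gene and sample order
    are preserved from the files.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicated gene id(s) in {path}: {sorted(set(dup))[:5]}")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value in {path}: {exc}") from exc
    n_data_lines = sum(
        1 for ln in Path(path).read_text().splitlines()[1:] if ln.strip()
    )
    if n_data_lines != len(values):
        raise FormatError(
            f"parsed {len(values)} genes but {path} has {n_data_lines} data lines"
        )
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if design.columns[0] not in ("sample_id", "sample"):
        raise FormatError(
            f"first design column must be sample_id, got {design.columns[0]!r}"
        )
    design = design.set_index(design.columns[0])
    return ExpressionStudy(values, design)


def write_expression_study(study: ExpressionStudy, matrix_path, design_path) -> None:
    study.values.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.8g")
    study.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a line are dropped with a warning."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            set_id, description, *members = fields
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "%s:%d: %d duplicated member(s) dropped from %s",
                    path, lineno, len(members) - len(deduped), set_id,
                )
            sets[set_id] = GeneSet(set_id, description, tuple(deduped))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def write_results_table(rows, path) -> None:
    """Write homogeneous records as TSV with >=6 significant digits on floats.

    `rows` may be a DataFrame or an iterable of mappings.  An empty input
    yields a header-only file when column names are recoverable.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
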