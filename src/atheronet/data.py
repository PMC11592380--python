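"""Core data containers and plain-text I/O.

The central object is :class:`ExpressionDataset`, a gene-by-sample matrix of
log2-scale expression values (or z-scores) together with per-sample group and
batch labels.  Groups are canonicalized to ``case`` / ``control``: for the
atherosclerosis cohorts this pipeline targets, *case* is the advanced-plaque
(or atheroma) arm and *control* the early-plaque (or normal-tissue) arm, and
all fold changes downstream are case minus control.

All on-disk formats are plain TSV/GMT/JSON so that fixtures and pipeline
outputs stay human-readable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CASE = "case"
CONTROL = "control"

#: accepted spellings for the two arms in sample-annotation files
_GROUP_ALIASES = {
    "case": CASE,
    "advanced": CASE,
    "atheroma": CASE,
    "plaque": CASE,
    "disease": CASE,
    "control": CONTROL,
    "early": CONTROL,
    "normal": CONTROL,
    "healthy": CONTROL,
}


class DataValidationError(ValueError):
    """Raised when a dataset or configuration violates its invariants."""


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with group and batch labels.

    Parameters
    ----------
    values
        DataFrame with unique uppercase gene symbols as index and unique
        sample ids as columns; log2-scale intensities or z-scores, no NaNs.
    groups
        Series mapping sample id -> ``"case"`` or ``"control"``.
    batches
        Series mapping sample id -> batch label (any hashable; stringified).
    """

    values: pd.DataFrame
    groups: pd.Series
    batches: pd.Series

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.strip().str.upper()
        samples = list(self.values.columns)
        if len(set(samples)) != len(samples):
            raise DataValidationError("sample ids must be unique")
        for name, series in (("groups", self.groups), ("batches", self.batches)):
            missing = set(samples) - set(series.index)
            if missing:
                raise DataValidationError(
                    f"{name} missing for samples: {sorted(missing)}"
                )
        self.groups = self.groups.reindex(samples).astype(str)
        self.batches = self.batches.reindex(samples).astype(str)
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise DataValidationError(
                f"group labels must be 'case'/'control', got {sorted(bad)}"
            )
        if self.values.isna().any().any():
            raise DataValidationError("expression matrix contains missing values")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Return a new dataset with ``values`` and labels restricted to its samples."""
        return ExpressionDataset(
            values=values.copy(),
            groups=self.groups.reindex(values.columns),
            batches=self.batches.reindex(values.columns),
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionDataset":
        return self.with_values(self.values.loc[:, samples])

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        return self.with_values(self.values.loc[genes])


def canonical_group(label: str) -> str:
    """Map a free-text group label to ``case``/``control``."""
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise DataValidationError(
            f"unrecognized group label {label!r}; expected one of "
            f"{sorted(_GROUP_ALIASES)}"
        )
    return _GROUP_ALIASES[key]


# ---------------------------------------------------------------------------
# TSV / GMT serialization
# ---------------------------------------------------------------------------

def write_expression_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def write_samples_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": ds.sample_ids, "group": ds.groups.values, "batch": ds.batches.values}
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(
    expr_path: str | Path, samples_path: str | Path
) -> ExpressionDataset:
    """Load an expression TSV (genes in rows) plus a sample-annotation TSV.

    The annotation file needs columns ``sample``, ``group``, ``batch``;
    group labels may use any alias recognized by :func:`canonical_group`.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    ann = pd.read_csv(samples_path, sep="\t", dtype=str)
    required = {"sample", "group", "batch"}
    if not required.issubset(ann.columns):
        raise DataValidationError(
            f"sample annotation must have columns {sorted(required)}"
        )
    ann = ann.set_index("sample")
    groups = ann["group"].map(canonical_group)
    return ExpressionDataset(values=values, groups=groups, batches=ann["batch"])


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    """Write genesets in GMT format (name, description, members...)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            desc = descriptions.get(name, "na")
            members = "\t".join(sets[name])
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g.strip().upper() for g in fields[2:] if g.strip()]
    return sets
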