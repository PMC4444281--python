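"""Expression-matrix input, gene-universe filtering and the differential-expression screen.

The pipeline's raw input is a genes x samples table of continuous expression
values (microarray log-intensities or anything on a comparable scale) together
with a sample -> group assignment for exactly two groups. The differential
screen is a per-gene two-sample t-test; the significant set defines the "DE"
gene universe while the full filtered table defines the "CO" universe used by
the network stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("coexnet")

__all__ = [
    "ExpressionMatrix",
    "ExpressionParseError",
    "read_expression_matrix",
    "filter_gene_universe",
    "differential_expression",
    "concat_groups",
]


class ExpressionParseError(ValueError):
    """Structured error for malformed expression input (names the offender)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with a two-group sample assignment.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene identifiers, columns by unique sample
        identifiers; entries are floats (NaN = missing).
    group_of_sample : dict
        Maps every sample identifier to one of two group labels.
    """

    values: pd.DataFrame
    group_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ExpressionParseError(f"duplicate gene identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ExpressionParseError(f"duplicate sample identifier: {dup!r}")
        missing = [s for s in cols if s not in self.group_of_sample]
        if missing:
            raise ExpressionParseError(f"sample without group assignment: {missing[0]!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.group_of_sample[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of_sample[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-table restricted to one group's samples (original order)."""
        cols = self.samples_of_group(group)
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return self.values[cols]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def read_expression_matrix(path, group_map_path) -> ExpressionMatrix:
    """Read an expression TSV (first column = gene ID, header = sample IDs)
    plus a two-column sample -> group TSV.

    Non-numeric cells become NaN; genes whose rows are entirely missing are
    dropped (count logged). Duplicate identifiers, samples without a group,
    or a group with fewer than two samples raise :class:`ExpressionParseError`.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = raw.apply(pd.to_numeric, errors="coerce")

    gm = pd.read_csv(group_map_path, sep="\t", header=None, dtype=str, comment="#")
    if gm.shape[1] < 2:
        raise ExpressionParseError(f"group map {group_map_path} needs 2 columns")
    # tolerate an optional header line like "sample<TAB>group"
    if list(gm.iloc[0, :2]) == ["sample", "group"]:
        gm = gm.iloc[1:]
    group_of_sample = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))

    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d genes with no finite values", int(all_missing.sum()))
        values = values.loc[~all_missing]

    em = ExpressionMatrix(values, group_of_sample)
    labels = em.groups
    if len(labels) != 2:
        raise ExpressionParseError(f"expected exactly 2 groups, found {labels!r}")
    for g in labels:
        n = len(em.samples_of_group(g))
        if n < 2:
            raise ExpressionParseError(f"group {g!r} has {n} sample(s); need >= 2")
    return em


def filter_gene_universe(matrix: ExpressionMatrix, keep_genes) -> ExpressionMatrix:
    """Restrict the matrix to a caller-supplied keep-list (original row order)."""
    keep = set(keep_genes)
    if not keep:
        raise ValueError("keep_genes is empty")
    mask = matrix.values.index.isin(keep)
    if not mask.any():
        raise ValueError("keep_genes shares no identifiers with the matrix")
    dropped = len(matrix.values) - int(mask.sum())
    logger.info("gene-universe filter: kept %d, dropped %d", int(mask.sum()), dropped)
    return ExpressionMatrix(matrix.values.loc[mask], dict(matrix.group_of_sample))


def concat_groups(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Join two single-group matrices over identical gene lists into one table."""
    if list(a.values.index) != list(b.values.index):
        raise ValueError("gene lists differ between the two matrices")
    values = pd.concat([a.values, b.values], axis=1)
    groups = dict(a.group_of_sample)
    groups.update(b.group_of_sample)
    return ExpressionMatrix(values, groups)


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    variant: str = "student",
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between the two groups.

    Parameters
    ----------
    alpha : float
        Two-sided significance level; ``significant`` is ``p < alpha``.
    variant : {"student", "welch"}
        Pooled-variance or unequal-variance t-test.
    group_order : (label_a, label_b), optional
        ``direction`` is the sign of mean(A) - mean(B); defaults to the
        column order of the matrix.

    Returns
    -------
    pandas.DataFrame
        One row per testable gene: gene, t_stat, p_value, direction
        ("up"/"down"/None on exact ties), significant. Genes with fewer than
        two finite values in a group are excluded (logged), not an error.
        Zero variance in both groups with equal means gives t=0, p=1.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    labels = matrix.groups
    if group_order is None:
        group_order = (labels[0], labels[1])
    ga, gb = group_order
    a = matrix.group_values(ga).to_numpy(dtype=float)
    b = matrix.group_values(gb).to_numpy(dtype=float)

    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    if not testable.all():
        logger.info("excluding %d untestable genes (<2 finite values in a group)",
                    int((~testable).sum()))
    genes = np.asarray(matrix.genes)[testable]
    a, b = a[testable], b[testable]

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"),
                               nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    diff = mean_a - mean_b

    # degenerate rows: zero variance in both groups
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(diff, 0.0)
    t[degenerate & equal_means] = 0.0
    p[degenerate & equal_means] = 1.0
    # zero variance but different means: infinitely strong evidence
    t[degenerate & ~equal_means] = np.sign(diff[degenerate & ~equal_means]) * np.inf
    p[degenerate & ~equal_means] = 0.0

    direction = np.where(diff > 0, "up", "down").astype(object)
    direction[equal_means] = None
    return pd.DataFrame(
        {
            "gene": genes,
            "t_stat": t,
            "p_value": p,
            "direction": direction,
            "significant": p < alpha,
        }
    ).reset_index(drop=True)
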