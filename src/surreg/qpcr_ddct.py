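"""Relative gene-expression quantification from qPCR Ct tables.

Implements the classic 2^-ddCt workflow: technical replicates are averaged to
one Ct per biological replicate; a target gene's expression ratio relative to
the reference gene is the geometric mean over biological replicates of
2^-(Ct_gene - Ct_ref); fold change between two strain/condition groups is
2^-ddCt with ddCt = dCt_num - dCt_den. Amplification efficiency is assumed
100% (fold base 2); a different efficiency can be supplied as a sensitivity
check (base = 1 + E).

Reference-gene choice follows the stability of mean Ct across experimental
groups: the candidate with the smallest SD of group-mean Ct ranks first.
In the T. barophilus dataset this selects pcna over the ribosomal-protein
genes S13 and S19.

Tables are tidy pandas DataFrames with columns
``gene, strain, pressure_MPa, sulfur, sulfur_conc_g_per_L, bio_replicate,
tech_replicate, ct``; a *group* is a column->value mapping selecting rows
(e.g. ``{"strain": "d517", "pressure_MPa": 70, "sulfur": "present"}``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRatio",
    "FoldChange",
    "read_ct_tsv",
    "reference_stability",
    "expression_ratio",
    "ddct_fold",
    "induction_response",
]

logger = logging.getLogger(__name__)

CT_COLUMNS = [
    "gene",
    "strain",
    "pressure_MPa",
    "sulfur",
    "sulfur_conc_g_per_L",
    "bio_replicate",
    "tech_replicate",
    "ct",
]

_GROUP_COLS = ["strain", "pressure_MPa", "sulfur", "sulfur_conc_g_per_L"]


@dataclass(frozen=True)
class ExpressionRatio:
    """Expression of one gene relative to the reference gene in one group."""

    gene: str
    reference_gene: str
    ratio: float  # geometric mean of per-replicate 2^-dCt
    sd: float  # SD of per-replicate ratios (NaN for a single replicate)
    sd_log2: float  # SD of per-replicate dCt values, the additive scale
    n_bio: int


@dataclass(frozen=True)
class FoldChange:
    """2^-ddCt fold change of one gene between two groups."""

    gene: str
    comparison: tuple[str, str]
    fold: float
    direction: str  # "up" | "down" | "unchanged"
    ddct: float


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError(f"{path}: non-finite Ct values present")
    return df


def _select(df: pd.DataFrame, group: Mapping[str, object]) -> pd.DataFrame:
    mask = pd.Series(True, index=df.index)
    for col, val in group.items():
        mask &= df[col] == val
    return df[mask]


def collapse_technical(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one Ct per (gene, group, bio replicate)."""
    keys = ["gene", *(c for c in _GROUP_COLS if c in df.columns), "bio_replicate"]
    return df.groupby(keys, as_index=False, sort=True)["ct"].mean()


def reference_stability(
    records: pd.DataFrame, candidate_genes: Sequence[str]
) -> pd.DataFrame:
    """Rank candidate reference genes by stability of their mean Ct.

    For each candidate the SD of its mean Ct across all strain x condition
    groups is computed; candidates are returned most-stable first. Exact ties
    are broken alphabetically and flagged.
    """
    rows = []
    group_cols = [c for c in _GROUP_COLS if c in records.columns]
    for gene in candidate_genes:
        sub = records[records["gene"] == gene]
        if sub.empty:
            raise ValueError(f"candidate reference gene {gene!r} absent from records")
        means = sub.groupby(group_cols, sort=True)["ct"].mean()
        if len(means) < 2:
            raise ValueError(
                f"candidate {gene!r} observed in fewer than 2 groups"
            )
        rows.append({"gene": gene, "ct_sd": float(means.std(ddof=1))})
    out = pd.DataFrame(rows).sort_values(["ct_sd", "gene"], kind="stable")
    out["tied"] = out["ct_sd"].duplicated(keep=False)
    return out.reset_index(drop=True)


def _per_replicate_dct(
    records: pd.DataFrame,
    gene: str,
    reference_gene: str,
    group: Mapping[str, object],
) -> pd.Series:
    """dCt = Ct_gene - Ct_ref per biological replicate within a group.

    Replicates missing the reference measurement are dropped with a warning;
    an empty result raises.
    """
    sub = collapse_technical(_select(records, group))
    gene_ct = sub[sub["gene"] == gene].set_index("bio_replicate")["ct"]
    ref_ct = sub[sub["gene"] == reference_gene].set_index("bio_replicate")["ct"]
    if gene_ct.empty:
        raise ValueError(f"gene {gene!r} not measured in group {dict(group)!r}")
    missing_ref = gene_ct.index.difference(ref_ct.index)
    for rep in missing_ref:
        logger.warning(
            "dropping bio replicate %r of gene %r: reference %r not measured",
            rep,
            gene,
            reference_gene,
        )
    common = gene_ct.index.intersection(ref_ct.index)
    if common.empty:
        raise ValueError(
            f"no bio replicate has both {gene!r} and reference "
            f"{reference_gene!r} in group {dict(group)!r}"
        )
    return gene_ct.loc[common] - ref_ct.loc[common]


def expression_ratio(
    records: pd.DataFrame,
    gene: str,
    reference_gene: str,
    group: Mapping[str, object],
    *,
    efficiency: float = 1.0,
) -> ExpressionRatio:
    """Expression ratio of ``gene`` to ``reference_gene`` within one group.

    Geometric averaging over biological replicates (dCt is the natural
    additive scale). Both the ratio-scale SD and the log2-scale SD are
    reported, since error bars can be drawn either way.
    """
    base = 1.0 + efficiency
    dct = _per_replicate_dct(records, gene, reference_gene, group)
    ratios = base ** (-dct)
    return ExpressionRatio(
        gene=gene,
        reference_gene=reference_gene,
        ratio=float(base ** (-dct.mean())),
        sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan"),
        sd_log2=float(dct.std(ddof=1)) if len(dct) > 1 else float("nan"),
        n_bio=int(len(dct)),
    )


def _group_name(group: Mapping[str, object]) -> str:
    return "/".join(f"{k}={v}" for k, v in group.items())


def ddct_fold(
    records: pd.DataFrame,
    gene: str,
    reference_gene: str,
    group_num: Mapping[str, object],
    group_den: Mapping[str, object],
    *,
    efficiency: float = 1.0,
    unchanged_band: tuple[float, float] = (0.5, 2.0),
) -> FoldChange:
    """2^-ddCt fold change of ``gene`` between numerator and denominator groups."""
    base = 1.0 + efficiency
    dct_num = _per_replicate_dct(records, gene, reference_gene, group_num).mean()
    dct_den = _per_replicate_dct(records, gene, reference_gene, group_den).mean()
    ddct = float(dct_num - dct_den)
    fold = float(base**-ddct)
    lo, hi = unchanged_band
    if lo <= fold <= hi:
        direction = "unchanged"
    else:
        direction = "up" if fold > hi else "down"
    return FoldChange(
        gene=gene,
        comparison=(_group_name(group_num), _group_name(group_den)),
        fold=fold,
        direction=direction,
        ddct=ddct,
    )


def induction_response(
    records: pd.DataFrame,
    genes: Sequence[str],
    pre_group: Mapping[str, object],
    post_group: Mapping[str, object],
    reference_gene: str = "pcna",
    **kwargs,
) -> pd.DataFrame:
    """Per-gene fold change after a stimulus (e.g. sulfur addition) vs before.

    One row per gene with the post-vs-pre fold and direction; genes missing
    from either group yield a row of NaN/NA so the run continues.
    """
    rows = []
    for gene in genes:
        try:
            fc = ddct_fold(
                records, gene, reference_gene, post_group, pre_group, **kwargs
            )
            rows.append(
                {
                    "gene": gene,
                    "fold": fc.fold,
                    "ddct": fc.ddct,
                    "direction": fc.direction,
                }
            )
        except ValueError as exc:
            logger.warning("induction_response: %s", exc)
            rows.append(
                {
                    "gene": gene,
                    "fold": float("nan"),
                    "ddct": float("nan"),
                    "direction": "NA",
                }
            )
    return pd.DataFrame(rows)
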