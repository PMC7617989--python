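"""Two-branch brain-metastasis hit calling and annotation-based refinement.

A gene passes the primary filter on one of two branches:

* ``multi_guide`` — at least ``multi_guide_min`` distinct qualifying guides,
  where a guide qualifies when it is detected in the brains (pooled over
  mice) AND its brain-cohort average exceeds its lung-cohort average (a
  gene-mean comparison is available behind
  ``require_per_guide_brain_gt_lung=False``);
* ``single_guide_rescue`` — exactly one brain-detected guide, that guide
  enriched in the brain (mean brain LFC > mean lung LFC), and at most
  ``lung_guide_max_for_rescue`` of the gene's guides detected in the lungs.

Passed genes are ranked by descending fold enrichment; the secondary filter
is a generic predicate engine over a caller-supplied gene annotation table
(e.g. tumor expression or dependency scores).
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrich import GeneEnrichment

__all__ = [
    "HitRuleConfig",
    "call_hits",
    "annotation_filter",
    "rank_hits",
    "parse_predicate",
]


class HitCallError(ValueError):
    pass


@dataclass(frozen=True)
class HitRuleConfig:
    """Knobs of the two-branch filter.

    ``abundance_scale`` selects how "brain average greater than lung
    average" is compared for brain-detected guides: "lfc" (default)
    compares control-referenced mean log2 fold changes, which is unbiased
    when the two tissues differ wildly in lineage diversity; "rpm"
    compares raw reads-per-million means.
    """

    multi_guide_min: int = 2
    lung_guide_max_for_rescue: int = 2
    require_per_guide_brain_gt_lung: bool = True
    abundance_scale: str = "lfc"

    def __post_init__(self) -> None:
        if self.multi_guide_min < 1:
            raise HitCallError("multi_guide_min must be >= 1")
        if self.lung_guide_max_for_rescue < 0:
            raise HitCallError("lung_guide_max_for_rescue must be >= 0")
        if self.abundance_scale not in ("lfc", "rpm"):
            raise HitCallError("abundance_scale must be 'lfc' or 'rpm'")


def call_hits(
    enrichment: GeneEnrichment, cfg: HitRuleConfig = HitRuleConfig()
) -> pd.DataFrame:
    """Apply the two-branch filter; returns one row per gene.

    Columns: gene, passed, branch ("multi_guide" / "single_guide_rescue" /
    "none"), fold_enrichment, p_value, q_value, rank (1..n over passed genes
    by descending fold enrichment; <NA> otherwise). The multi-guide branch
    takes precedence when both could apply. Output is sorted by gene and
    independent of input row order.
    """
    genes = enrichment.genes.sort_values("gene").reset_index(drop=True)
    gd = enrichment.guides.loc[~enrichment.guides["is_control"]]

    if cfg.abundance_scale == "lfc":
        brain_col, lung_col = "brain_mean_lfc", "lung_mean_lfc"
    else:
        brain_col, lung_col = "brain_mean_abundance", "lung_mean_abundance"

    multi_ok = {}
    lfc_ok = {}
    for gene, sub in gd.groupby("gene"):
        det = sub.loc[sub["brain_detected"]]
        if cfg.require_per_guide_brain_gt_lung:
            # count qualifying guides: present in the brains AND enriched
            n_qual = int((det[brain_col] > det[lung_col]).sum())
            multi_ok[gene] = n_qual >= cfg.multi_guide_min
        else:
            multi_ok[gene] = bool(
                len(det) >= cfg.multi_guide_min
                and sub[brain_col].mean() > sub[lung_col].mean()
            )
        lfc_ok[gene] = bool(
            len(det) == 1
            and (det["brain_mean_lfc"] > det["lung_mean_lfc"]).all()
        )

    branches = []
    for row in genes.itertuples():
        n_brain = row.n_guides_brain_detected
        if multi_ok.get(row.gene, False):
            branches.append("multi_guide")
        elif (
            n_brain == 1
            and lfc_ok.get(row.gene, False)
            and row.n_guides_lung_detected <= cfg.lung_guide_max_for_rescue
        ):
            branches.append("single_guide_rescue")
        else:
            branches.append("none")

    out = genes[
        ["gene", "fold_enrichment", "p_value", "q_value", "n_guides_brain_detected",
         "n_guides_lung_detected"]
    ].copy()
    out["branch"] = branches
    out["passed"] = out["branch"] != "none"
    return rank_hits(out)


def rank_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..n over passed genes by descending fold enrichment.

    Ties break by gene symbol (lexicographic), making the order
    deterministic; non-passed genes get a missing rank.
    """
    out = hits.copy()
    if not np.isfinite(out["fold_enrichment"].to_numpy(dtype=float)).all():
        raise HitCallError("fold_enrichment must be finite for ranking")
    passed = out.loc[out["passed"]].sort_values(
        ["fold_enrichment", "gene"], ascending=[False, True]
    )
    rank = pd.Series(pd.NA, index=out.index, dtype="Int64")
    rank.loc[passed.index] = np.arange(1, len(passed) + 1)
    out["rank"] = rank
    return out.sort_values("gene").reset_index(drop=True)


_OPS = {
    ">=": operator.ge,
    "<=": operator.le,
    ">": operator.gt,
    "<": operator.lt,
    "==": operator.eq,
    "!=": operator.ne,
}

_PRED_RE = re.compile(r"^\s*([A-Za-z_][\w.]*)\s*(>=|<=|==|!=|>|<)\s*(-?[\d.eE+]+)\s*$")


def parse_predicate(expr: str) -> tuple[str, str, float]:
    """Parse ``"column>=1.5"`` style predicate strings."""
    m = _PRED_RE.match(expr)
    if not m:
        raise HitCallError(f"cannot parse predicate {expr!r}")
    return m.group(1), m.group(2), float(m.group(3))


def annotation_filter(
    hits: pd.DataFrame,
    annotation: pd.DataFrame,
    predicates: Sequence[tuple[str, str, float] | str],
    keep_missing: bool = False,
) -> pd.DataFrame:
    """Keep hits whose gene satisfies every annotation predicate.

    Each predicate is ``(column, comparator, threshold)`` or an equivalent
    string. Genes with a missing score fail the predicate unless
    ``keep_missing`` is set; an unknown column is an error. With an empty
    predicate list the hits are returned unchanged.
    """
    preds = [parse_predicate(p) if isinstance(p, str) else p for p in predicates]
    if not preds:
        return hits.copy()
    ann = annotation.set_index("gene")
    for col, op, _ in preds:
        if col not in ann.columns:
            raise HitCallError(f"annotation table has no column {col!r}")
        if op not in _OPS:
            raise HitCallError(f"unknown comparator {op!r}")
    keep = []
    for gene in hits["gene"]:
        ok = True
        for col, op, thr in preds:
            val = ann[col].get(gene, np.nan)
            if pd.isna(val):
                ok = ok and keep_missing
            else:
                ok = ok and bool(_OPS[op](val, thr))
            if not ok:
                break
        keep.append(ok)
    return hits.loc[keep].reset_index(drop=True)
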