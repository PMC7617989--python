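"""Gene-level enrichment: detection, tissue means, fold enrichment, statistics.

A gene's brain-vs-lung fold enrichment is 2**(mean brain LFC - mean lung
LFC), where the gene's tissue mean is the mean over its guides of per-guide
tissue-mean LFC, and per-guide tissue means run over ALL samples of the
tissue (zeros enter through the pseudocounted LFC, avoiding the selection
bias of detected-only averaging). Significance comes from a one-sided
Wilcoxon rank-sum test of the gene's guide LFC values against the control
guides' LFC values in the brain, corrected across genes by
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GuideLibrary, SampleMeta
from .quant import GuideStats

__all__ = [
    "DetectionRule",
    "GeneEnrichment",
    "detect_guides",
    "gene_table",
    "wilcoxon_one_sided",
    "bh_adjust",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionRule:
    """When a guide counts as 'present' in a sample.

    Exactly one criterion is active: a raw read-count threshold (default:
    at least one read) or a normalized-abundance (RPM) threshold.
    """

    min_raw_count: int | None = 1
    min_abundance: float | None = None

    def __post_init__(self) -> None:
        if (self.min_raw_count is None) == (self.min_abundance is None):
            raise EnrichmentError(
                "exactly one of min_raw_count / min_abundance must be set"
            )
        if self.min_raw_count is not None and self.min_raw_count < 1:
            raise EnrichmentError("min_raw_count must be >= 1")


@dataclass(frozen=True)
class GeneEnrichment:
    """Gene-level enrichment table plus the per-guide tissue summary.

    ``genes``: one row per targeting gene with detection counts, tissue mean
    LFCs, fold enrichment and p/q values. ``guides``: one row per targeting
    guide with per-tissue mean abundance/LFC and detection flags — the
    per-guide evidence the hit-calling filter consumes.
    """

    genes: pd.DataFrame
    guides: pd.DataFrame


def detect_guides(
    cm: CountMatrix | pd.DataFrame,
    rule: DetectionRule = DetectionRule(),
    abundance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Boolean per-(guide, sample) detection under the configured rule."""
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    if rule.min_raw_count is not None:
        return counts >= rule.min_raw_count
    if abundance is None:
        raise EnrichmentError("abundance matrix required for an RPM detection rule")
    return abundance >= rule.min_abundance


def wilcoxon_one_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for 'x stochastically greater than y'.

    Uses the exact null distribution when the pooled size is at most 25 and
    there are no ties across the pooled values; otherwise the normal
    approximation with continuity and mid-rank tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EnrichmentError("Wilcoxon test requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="greater", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _per_sample_pvalue(
    lfc: pd.DataFrame,
    gene_guides: pd.Index,
    controls: pd.Index,
    samples: pd.Index,
) -> float:
    """Alternative testing unit: one test per brain sample, Fisher-combined."""
    ps = []
    for s in samples:
        ps.append(
            wilcoxon_one_sided(
                lfc.loc[gene_guides, s].to_numpy(), lfc.loc[controls, s].to_numpy()
            )
        )
    stat = -2.0 * np.sum(np.log(np.clip(ps, 1e-300, 1.0)))
    return float(sps.chi2.sf(stat, 2 * len(ps)))


def gene_table(
    stats: GuideStats,
    detection: pd.DataFrame,
    meta: SampleMeta,
    library: GuideLibrary,
    test: str = "pooled",
) -> GeneEnrichment:
    """Aggregate guide statistics to a per-gene enrichment table.

    Parameters
    ----------
    test : "pooled" (default) tests each gene's guide LFCs pooled across all
        brain samples against control LFCs pooled the same way; "per_sample"
        tests within each brain sample and combines by Fisher's method.
    """
    meta.require_brain_and_lung()
    library.require_controls()
    brain = [s for s in meta.samples_of("brain") if s in stats.lfc.columns]
    lung = [s for s in meta.samples_of("lung") if s in stats.lfc.columns]
    if not brain or not lung:
        raise EnrichmentError("no analyzable brain or lung samples after filtering")

    lfc, ab = stats.lfc, stats.abundance
    guides = library.guide_ids
    det = detection.reindex(index=guides, columns=ab.columns).fillna(False)

    guide_df = pd.DataFrame(
        {
            "guide_id": guides,
            "gene": library.genes.to_numpy(),
            "is_control": library.control_mask.to_numpy(),
            "brain_mean_abundance": ab.loc[guides, brain].mean(axis=1).to_numpy(),
            "lung_mean_abundance": ab.loc[guides, lung].mean(axis=1).to_numpy(),
            "brain_mean_lfc": lfc.loc[guides, brain].mean(axis=1).to_numpy(),
            "lung_mean_lfc": lfc.loc[guides, lung].mean(axis=1).to_numpy(),
            "brain_detected": det.loc[guides, brain].any(axis=1).to_numpy(),
            "lung_detected": det.loc[guides, lung].any(axis=1).to_numpy(),
        }
    )

    targeting = guide_df.loc[~guide_df["is_control"]]
    controls = library.control_guides
    ctrl_brain_lfc = lfc.loc[controls, brain].to_numpy().ravel()

    rows = []
    for gene, sub in targeting.groupby("gene", sort=True):
        gene_guides = pd.Index(sub["guide_id"])
        if test == "pooled":
            p = wilcoxon_one_sided(
                lfc.loc[gene_guides, brain].to_numpy().ravel(), ctrl_brain_lfc
            )
        elif test == "per_sample":
            p = _per_sample_pvalue(lfc, gene_guides, controls, pd.Index(brain))
        else:
            raise EnrichmentError(f"unknown test mode {test!r}")
        mean_brain = float(sub["brain_mean_lfc"].mean())
        mean_lung = float(sub["lung_mean_lfc"].mean())
        rows.append(
            {
                "gene": gene,
                "n_guides_library": len(sub),
                "n_guides_brain_detected": int(sub["brain_detected"].sum()),
                "n_guides_lung_detected": int(sub["lung_detected"].sum()),
                "mean_brain_lfc": mean_brain,
                "mean_lung_lfc": mean_lung,
                "fold_enrichment": float(2.0 ** (mean_brain - mean_lung)),
                "p_value": p,
            }
        )
    genes = pd.DataFrame(rows)
    genes["q_value"] = bh_adjust(genes["p_value"].to_numpy())
    return GeneEnrichment(genes=genes, guides=guide_df)
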