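"""Model/Results facade over the screen analysis.

``ScreenModel`` bundles a count matrix, its guide library and sample
metadata together with the analysis knobs (detection rule, pseudocount,
normalization); ``fit()`` runs normalization → control-referenced LFC →
gene-level enrichment → hit calling and returns a ``ScreenResults`` holding
the gene table, the per-guide evidence, the hit calls and a text
``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrich import DetectionRule, GeneEnrichment, detect_guides, gene_table
from .hits import HitRuleConfig, annotation_filter, call_hits
from .io import (
    CountMatrix,
    GuideLibrary,
    SampleMeta,
    read_counts,
    read_library,
    write_table,
)
from .quant import GuideStats, guide_lfc, normalize_cpm, normalize_median_ratio


class ScreenModel:
    """Brain-vs-lung enrichment model for one pooled in vivo screen.

    Parameters
    ----------
    counts, library, meta
        The guide-by-sample counts with their library annotation and sample
        metadata (tissue in {T0, lung, brain}).
    detection
        Per-sample presence rule (default: raw count >= 1).
    pseudocount
        RPM pseudocount of the control-referenced LFC (default 0.5).
    normalization
        "cpm" (reads per million, default) or "median_ratio".
    drop_empty_samples
        Exclude all-zero count columns (e.g. lineage-free brains) with a
        warning instead of failing normalization.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: GuideLibrary,
        meta: SampleMeta,
        detection: DetectionRule = DetectionRule(),
        pseudocount: float = 0.5,
        normalization: str = "cpm",
        drop_empty_samples: bool = True,
    ):
        library.require_controls()
        meta.require_brain_and_lung()
        missing = counts.samples.difference(meta.sample_ids)
        if len(missing):
            raise ValueError(f"count columns without metadata: {list(missing)}")
        self.counts = counts
        self.library = library
        self.meta = meta
        self.detection = detection
        self.pseudocount = pseudocount
        self.normalization = normalization
        self.drop_empty_samples = drop_empty_samples

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        library_path: str | Path,
        meta_path: str | Path,
        delimiter: str = "\t",
        **kwargs,
    ) -> "ScreenModel":
        library = read_library(library_path, delimiter=delimiter)
        counts, meta = read_counts(counts_path, meta_path, delimiter=delimiter, library=library)
        return cls(counts, library, meta, **kwargs)

    def _analyzable_counts(self) -> pd.DataFrame:
        counts = self.counts.counts.loc[self.library.guide_ids]
        zero = counts.columns[counts.sum(axis=0) == 0]
        if len(zero):
            if not self.drop_empty_samples:
                raise ValueError(f"all-zero samples present: {list(zero)}")
            warnings.warn(
                f"dropping {len(zero)} all-zero sample(s): {list(zero)}", stacklevel=2
            )
            counts = counts.drop(columns=zero)
        return counts

    def fit(
        self,
        hit_rule: HitRuleConfig = HitRuleConfig(),
        test: str = "pooled",
    ) -> "ScreenResults":
        counts = self._analyzable_counts()
        if self.normalization == "cpm":
            abundance = normalize_cpm(counts)
        elif self.normalization == "median_ratio":
            abundance = normalize_median_ratio(counts)
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        stats = guide_lfc(abundance, self.library, self.pseudocount)
        detection = detect_guides(counts, self.detection, abundance=abundance)
        enr = gene_table(stats, detection, self.meta, self.library, test=test)
        hits = call_hits(enr, hit_rule)
        return ScreenResults(
            model=self, stats=stats, enrichment=enr, hits=hits, hit_rule=hit_rule
        )


@dataclass
class ScreenResults:
    """Fitted screen analysis: gene table, guide evidence, hit calls."""

    model: ScreenModel
    stats: GuideStats
    enrichment: GeneEnrichment
    hits: pd.DataFrame
    hit_rule: HitRuleConfig

    @property
    def gene_table(self) -> pd.DataFrame:
        return self.enrichment.genes

    @property
    def guide_table(self) -> pd.DataFrame:
        return self.enrichment.guides

    def passed(self) -> pd.DataFrame:
        """Hit list ordered by rank (descending fold enrichment)."""
        return (
            self.hits.loc[self.hits["passed"]]
            .sort_values("rank")
            .reset_index(drop=True)
        )

    def filter_hits(self, annotation: pd.DataFrame, predicates, keep_missing=False):
        """Secondary annotation filter over the passed hit list."""
        return annotation_filter(self.passed(), annotation, predicates, keep_missing)

    def summary(self, top: int = 10) -> str:
        genes = self.gene_table
        meta = self.model.meta
        n_brain_det = int((genes["n_guides_brain_detected"] > 0).sum())
        branch_counts = self.hits["branch"].value_counts().to_dict()
        lines = [
            "Brain-metastasis screen enrichment summary",
            "=" * 44,
            f"genes tested:            {len(genes)}",
            f"guides (library):        {len(self.model.library.guide_ids)}"
            f"  (controls: {self.model.library.n_controls})",
            f"samples:                 {len(meta.samples_of('lung'))} lung, "
            f"{len(meta.samples_of('brain'))} brain, "
            f"{len(meta.samples_of('T0'))} T0",
            f"genes with >=1 guide detected in brain: {n_brain_det}",
            f"hits: {int(self.hits['passed'].sum())} "
            f"(multi_guide: {branch_counts.get('multi_guide', 0)}, "
            f"single_guide_rescue: {branch_counts.get('single_guide_rescue', 0)})",
            "",
            f"top hits by brain-vs-lung fold enrichment (max {top}):",
        ]
        cols = ["rank", "gene", "branch", "fold_enrichment", "p_value", "q_value"]
        head = self.passed().head(top)[cols]
        lines.append(head.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_table": outdir / "gene_table.tsv",
            "guide_table": outdir / "guide_table.tsv",
            "hits": outdir / "hits.tsv",
        }
        write_table(self.gene_table, paths["gene_table"])
        write_table(self.guide_table, paths["guide_table"])
        write_table(self.hits, paths["hits"])
        return paths

    def plot_lfc(self, ax=None):
        """Per-sample LFC distributions (controls in gray, lungs blue, brains red)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(7, 4))
        lfc = self.stats.lfc
        ctrl = self.model.library.control_mask
        colors = {"lung": "tab:blue", "brain": "tab:red", "T0": "tab:gray"}
        for s in lfc.columns:
            tissue = str(self.model.meta.tissue.get(s, "T0"))
            vals = np.sort(lfc[s].to_numpy())
            ax.plot(vals, np.linspace(0, 1, len(vals)), color=colors.get(tissue, "k"),
                    alpha=0.5, lw=1, label=tissue)
            cvals = np.sort(lfc.loc[ctrl.to_numpy(), s].to_numpy())
            ax.plot(cvals, np.linspace(0, 1, len(cvals)), color="gray", alpha=0.3, lw=0.8)
        handles, labels = ax.get_legend_handles_labels()
        seen = dict(zip(labels, handles))
        ax.legend(seen.values(), seen.keys(), frameon=False)
        ax.set_xlabel("log2 fold change vs control mean")
        ax.set_ylabel("empirical CDF")
        return ax
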