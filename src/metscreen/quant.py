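"""Guide quantification: read counting, CPM normalization, control-referenced LFC.

The read-to-count stage assigns each sequencing read to at most one library
guide by extracting the candidate protospacer (at a fixed offset, or right
after a vector anchor sequence) and matching it exactly or, optionally, with
a single substitution. Reads matching two or more guides at the allowed
distance are discarded as ambiguous, never assigned arbitrarily.

Downstream, counts are scaled to reads-per-million within each sample and
every guide's abundance is expressed as a log2 fold change relative to the
arithmetic mean of the control guides in the same sample, with a symmetric
pseudocount keeping zero-count guides finite.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .io import CountMatrix, GuideLibrary

__all__ = [
    "MatchConfig",
    "GuideStats",
    "count_reads",
    "normalize_cpm",
    "normalize_median_ratio",
    "guide_lfc",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: sentinel index marking a 1-mismatch variant shared by >=2 guides
_AMBIGUOUS = -2


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class MatchConfig:
    """How to locate and match the protospacer within each read.

    Exactly one of ``anchor`` (vector sequence immediately 5' of the
    protospacer) or ``fixed_offset`` must be active. ``max_mismatches`` is
    0 or 1; ``scan_revcomp`` additionally tries the reverse complement of
    reads that fail on the forward strand (off by default: stranded
    amplicon assumption).
    """

    anchor: str = ""
    fixed_offset: int | None = 0
    max_mismatches: int = 0
    min_read_length: int = 0
    scan_revcomp: bool = False

    def __post_init__(self) -> None:
        has_anchor = bool(self.anchor)
        has_offset = self.fixed_offset is not None
        if has_anchor == has_offset:
            raise QuantError("exactly one of anchor / fixed_offset must be set")
        if self.max_mismatches not in (0, 1):
            raise QuantError("max_mismatches must be 0 or 1")
        if has_offset and self.fixed_offset < 0:
            raise QuantError("fixed_offset must be >= 0")


@dataclass(frozen=True)
class GuideStats:
    """Per-(guide, sample) normalized abundance and control-referenced LFC."""

    abundance: pd.DataFrame  # RPM, guides x samples
    lfc: pd.DataFrame  # log2((abundance+a) / (control_mean+a))
    pseudocount: float


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _build_lookup(library: GuideLibrary, max_mismatches: int):
    exact: dict[str, int] = {
        seq: i for i, seq in enumerate(library.table["protospacer"])
    }
    variants: dict[str, int] = {}
    if max_mismatches == 1:
        for i, seq in enumerate(library.table["protospacer"]):
            for pos in range(len(seq)):
                for base in "ACGT":
                    if base == seq[pos]:
                        continue
                    var = seq[:pos] + base + seq[pos + 1 :]
                    if var in exact:
                        continue  # exact assignment takes precedence
                    prev = variants.get(var)
                    if prev is None:
                        variants[var] = i
                    elif prev != i:
                        variants[var] = _AMBIGUOUS
    return exact, variants


def _extract(seq: str, cfg: MatchConfig, length: int) -> str | None:
    if cfg.fixed_offset is not None:
        sub = seq[cfg.fixed_offset : cfg.fixed_offset + length]
        return sub if len(sub) == length else None
    pos = seq.find(cfg.anchor)
    if pos < 0:
        return None
    start = pos + len(cfg.anchor)
    sub = seq[start : start + length]
    return sub if len(sub) == length else None


def count_reads(
    fastq: str | Path | Iterable[str | Path],
    library: GuideLibrary,
    cfg: MatchConfig = MatchConfig(),
) -> tuple[pd.Series, dict]:
    """Count reads per guide from one or more FASTQ files (plain or gzip).

    Returns integer counts indexed like the library, and a QC dict with
    total / matched / ambiguous / unmatched read tallies, percentages,
    number of guides detected and control-guide coverage.
    """
    if isinstance(fastq, (str, Path)):
        fastq = [fastq]
    length = len(library.table["protospacer"].iloc[0])
    exact, variants = _build_lookup(library, cfg.max_mismatches)
    counts = np.zeros(len(library.guide_ids), dtype=np.int64)
    total = matched = ambiguous = 0
    for path in fastq:
        with _open_maybe_gzip(path) as handle:
            record_idx = 0
            try:
                for _title, seq, _qual in FastqGeneralIterator(handle):
                    record_idx += 1
                    total += 1
                    seq = seq.upper()
                    if len(seq) < max(cfg.min_read_length, length):
                        continue
                    tries = [seq]
                    if cfg.scan_revcomp:
                        tries.append(seq.translate(_COMPLEMENT)[::-1])
                    assigned = False
                    for s in tries:
                        sub = _extract(s, cfg, length)
                        if sub is None:
                            continue
                        idx = exact.get(sub)
                        if idx is None and cfg.max_mismatches == 1:
                            idx = variants.get(sub)
                        if idx is None:
                            continue
                        if idx == _AMBIGUOUS:
                            ambiguous += 1
                        else:
                            counts[idx] += 1
                            matched += 1
                        assigned = True
                        break
                    del assigned
            except ValueError as exc:
                raise QuantError(
                    f"malformed FASTQ record ~{record_idx + 1} in {path}: {exc}"
                ) from exc
    if total == 0:
        import warnings

        warnings.warn("empty FASTQ input: all guide counts are zero", stacklevel=2)
    series = pd.Series(counts, index=library.guide_ids, name="count")
    ctrl = series.loc[library.control_guides]
    qc = {
        "total_reads": total,
        "matched_reads": matched,
        "ambiguous_reads": ambiguous,
        "unmatched_reads": total - matched - ambiguous,
        "matched_pct": 100.0 * matched / total if total else 0.0,
        "ambiguous_pct": 100.0 * ambiguous / total if total else 0.0,
        "guides_detected": int((series > 0).sum()),
        "control_guides_detected": int((ctrl > 0).sum()),
        "control_mean_count": float(ctrl.mean()) if len(ctrl) else float("nan"),
    }
    return series, qc


def normalize_cpm(cm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to reads-per-million (column sums become 1e6)."""
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    colsums = counts.sum(axis=0)
    zero = colsums.index[colsums == 0]
    if len(zero):
        raise QuantError(f"zero total counts in sample(s): {list(zero)}")
    return counts / colsums * 1e6


def normalize_median_ratio(cm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """DESeq-style median-of-ratios normalization (alternative to CPM).

    Size factors are medians of per-guide ratios to the geometric-mean
    reference over guides nonzero in every sample; abundances are counts
    divided by the sample's size factor.
    """
    counts = (cm.counts if isinstance(cm, CountMatrix) else cm).astype(float)
    nonzero = (counts > 0).all(axis=1)
    if nonzero.sum() == 0:
        raise QuantError("median-ratio normalization needs >=1 guide nonzero everywhere")
    ref = np.exp(np.log(counts.loc[nonzero]).mean(axis=1))
    ratios = counts.loc[nonzero].div(ref, axis=0)
    size_factors = ratios.median(axis=0)
    if (size_factors <= 0).any():
        raise QuantError("non-positive size factor encountered")
    return counts / size_factors


def guide_lfc(
    abundance: pd.DataFrame,
    library: GuideLibrary,
    pseudocount: float = 0.5,
) -> GuideStats:
    """Control-referenced log2 fold change per guide and sample.

    lfc(g, s) = log2( (abundance(g,s) + a) / (mean_controls(s) + a) )

    where mean_controls(s) is the arithmetic mean abundance of the control
    guides in sample s and ``a`` the pseudocount (RPM units), applied
    symmetrically to numerator and denominator. Control guides receive LFC
    values too; their mean is ~0 when control dispersion is low.
    """
    if pseudocount <= 0:
        raise QuantError("pseudocount must be > 0")
    library.require_controls()
    missing = library.guide_ids.difference(abundance.index)
    if len(missing):
        raise QuantError(f"abundance matrix lacks library guides, e.g. {list(missing[:5])}")
    abundance = abundance.loc[library.guide_ids]
    ctrl_mean = abundance.loc[library.control_guides].mean(axis=0)
    if (ctrl_mean <= 0).any():
        # severe bottlenecks can wipe controls from a sample; the pseudocount
        # keeps the reference finite, but the sample's LFCs lean on it alone
        import warnings

        bad = list(ctrl_mean.index[ctrl_mean <= 0])
        warnings.warn(
            f"control guides have zero mean abundance in sample(s) {bad}; "
            "LFC reference falls back to the pseudocount there",
            stacklevel=2,
        )
    lfc = np.log2((abundance + pseudocount).div(ctrl_mean + pseudocount, axis=1))
    return GuideStats(abundance=abundance, lfc=lfc, pseudocount=pseudocount)
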