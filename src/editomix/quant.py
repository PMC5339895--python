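"""Per-site editing quantification from aligned reads.

Counts filtered bases at catalogued editing sites, derives per-site editing
levels (G / (A+G)), aggregates the conserved-editing index (CEI), applies
the coverage/group filter, and implements the host-gene expression-dominance
QC rule used to exclude samples whose CEI would be driven by one gene.

Strand convention: a minus-strand site has reference T on the plus strand;
read bases at such sites are complemented before tallying, so ``n_A``/``n_G``
always refer to the annotated (sense) strand.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._seq import A as _A, C as _C, G as _G, T as _T, encode

log = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    """Base-level filters shared by the per-site and repeat-index counters.

    ``min_phred`` is exclusive: a base passes only if its quality is
    strictly greater. ``min_coverage``/``min_groups`` implement the rule
    that a site must reach coverage in at least that many sample groups to
    be reported at all. ``unique_only`` drops multi-mapping reads (NH > 1
    or secondary/supplementary flags); turn it off for amplicon input.
    """

    min_phred: int = 25
    min_coverage: int = 15
    min_groups: int = 2
    unique_only: bool = True

    def validate(self) -> None:
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass
class CeiResult:
    """Coverage-weighted aggregate editing over conserved sites."""

    sample_id: str
    numerator: int  # A-to-G mismatch bases summed over conserved sites
    denominator: int  # all filtered bases observed at those sites
    cei: float


def _read_passes(read: pysam.AlignedSegment, unique_only: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if unique_only and read.has_tag("NH") and read.get_tag("NH") > 1:
        return False
    return True


def count_site_bases(
    alignments: str | Path | pysam.AlignmentFile,
    catalog: pd.DataFrame,
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Count filtered A/G/other bases at every catalog site in one sample.

    Returns a frame indexed by site key with columns ``n_A``, ``n_G``,
    ``n_other``, ``n_total``. Bases with phred <= ``min_phred`` contribute
    to neither numerator nor denominator; reads with a deletion or skip
    across the site contribute nothing.
    """
    config = config or QuantConfig()
    config.validate()

    catalog = catalog.copy()
    dup = catalog.index.duplicated()
    if dup.any():
        log.warning("collapsing %d duplicate catalog rows", int(dup.sum()))
        catalog = catalog[~dup]

    own = isinstance(alignments, (str, Path))
    sam = (
        pysam.AlignmentFile(str(alignments), "r", check_sq=False) if own else alignments
    )
    try:
        refs = set(sam.references)
        missing = set(catalog["chrom"]) - refs
        if missing:
            raise ValueError(f"catalog chromosomes absent from alignment header: {sorted(missing)}")

        by_chrom: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
        for chrom, sub in catalog.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            by_chrom[chrom] = (
                sub["pos"].to_numpy(dtype=np.int64) - 1,
                list(sub.index),
                list(sub["strand"]),
            )

        counts = {k: [0, 0, 0] for k in catalog.index}  # n_A, n_G, n_other
        n_reads = 0
        for read in sam:
            if not _read_passes(read, config.unique_only):
                continue
            n_reads += 1
            chrom = read.reference_name
            if chrom not in by_chrom:
                continue
            pos0, keys, strands = by_chrom[chrom]
            start, end = read.reference_start, read.reference_end
            lo = bisect_left(pos0, start)
            hi = bisect_right(pos0, end - 1)
            if lo == hi:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            simple = len(read.cigartuples) == 1 and read.cigartuples[0][0] == 0
            pairmap = None
            if not simple:
                pairmap = {
                    rpos: qpos
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True)
                }
            for i in range(lo, hi):
                rpos = int(pos0[i])
                qpos = rpos - start if simple else pairmap.get(rpos)
                if qpos is None:
                    continue
                if quals[qpos] <= config.min_phred:
                    continue
                base = encode(seq[qpos])[0]
                if base > 3:
                    continue
                if strands[i] == "-":
                    base = 3 - base
                slot = counts[keys[i]]
                if base == _A:
                    slot[0] += 1
                elif base == _G:
                    slot[1] += 1
                else:
                    slot[2] += 1
        if n_reads == 0:
            warnings.warn("alignment file contains no usable reads", stacklevel=2)
    finally:
        if own:
            sam.close()

    out = pd.DataFrame.from_dict(counts, orient="index", columns=["n_A", "n_G", "n_other"])
    out.index.name = "site"
    out["n_total"] = out.sum(axis=1)
    return out.loc[catalog.index]


def editing_levels(
    counts: dict[str, pd.DataFrame],
    config: QuantConfig | None = None,
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-site editing levels across samples, with the group coverage filter.

    ``counts`` maps sample id to a `count_site_bases` frame. A site is kept
    only if its filtered coverage reaches ``min_coverage`` in at least
    ``min_groups`` sample groups (a group counts if any of its samples
    qualifies); dropped sites disappear from the output entirely. Returns
    ``(levels, coverage, reasons)`` frames, all sites x samples; missing
    levels are NaN with a reason code.
    """
    config = config or QuantConfig()
    samples = list(counts)
    if not samples:
        raise ValueError("no samples supplied")
    groups = groups or {s: s for s in samples}

    sites = counts[samples[0]].index
    coverage = pd.DataFrame(
        {s: counts[s]["n_total"].reindex(sites).fillna(0).astype(int) for s in samples}
    )
    group_names = sorted(set(groups.values()))
    ok_groups = pd.DataFrame(
        {
            g: (coverage[[s for s in samples if groups[s] == g]] >= config.min_coverage).any(axis=1)
            for g in group_names
        }
    )
    keep = ok_groups.sum(axis=1) >= min(config.min_groups, len(group_names))
    sites = sites[keep.to_numpy()]

    levels = pd.DataFrame(np.nan, index=sites, columns=samples)
    reasons = pd.DataFrame("", index=sites, columns=samples)
    for s in samples:
        df = counts[s].reindex(sites)
        ag = df["n_A"] + df["n_G"]
        cov = df["n_total"]
        ok = (cov >= config.min_coverage) & (ag > 0)
        levels.loc[ok, s] = (df["n_G"] / ag)[ok]
        reasons.loc[cov < config.min_coverage, s] = "low coverage"
        reasons.loc[(cov >= config.min_coverage) & (ag == 0), s] = "no A/G bases"
    coverage = coverage.loc[sites]
    levels.index.name = coverage.index.name = reasons.index.name = "site"
    return levels, coverage, reasons


def compute_cei(
    counts: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    sample_id: str = "",
    equal_weights: bool = False,
) -> CeiResult:
    """Conserved-editing index: summed G bases over summed filtered bases.

    No per-site coverage cutoff is applied, so deeply covered sites weigh
    more. If ``catalog`` is given, only rows with ``conserved == 1`` enter;
    ``equal_weights=True`` instead averages per-site G/total ratios
    (amplicon-panel variant).
    """
    if catalog is not None:
        keep = catalog.index[catalog["conserved"] == 1]
        counts = counts.loc[counts.index.intersection(keep)]
    if counts.empty:
        raise ValueError("no conserved sites in counts")
    num = int(counts["n_G"].sum())
    den = int(counts["n_total"].sum())
    if equal_weights:
        per = counts[counts["n_total"] > 0]
        if per.empty:
            raise ValueError("CEI undefined: zero coverage at every conserved site")
        cei = float((per["n_G"] / per["n_total"]).mean())
    else:
        if den == 0:
            raise ValueError("CEI undefined: zero total coverage over conserved sites")
        cei = num / den
    return CeiResult(sample_id=sample_id, numerator=num, denominator=den, cei=cei)


def expression_dominance_check(
    fpkm: pd.Series | dict[str, float], threshold: float = 0.7
) -> tuple[bool, str, float]:
    """Flag a sample whose host-gene expression is dominated by one gene.

    Returns ``(flagged, dominant_gene, share)``; flagged when the top
    gene's share of total FPKM strictly exceeds ``threshold``. Flagged
    samples are excluded from CEI summaries by the pipeline.
    """
    s = pd.Series(fpkm, dtype=float)
    if s.empty or not np.isfinite(s).all():
        raise ValueError("FPKM values must be finite and non-empty")
    total = s.sum()
    if total <= 0:
        raise ValueError("total FPKM is zero; dominance share undefined")
    dominant = s.idxmax()
    share = float(s.max() / total)
    return share > threshold, str(dominant), share
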