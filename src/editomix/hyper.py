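"""Hyper-editing rescue of heavily edited reads.

Reads carrying many clustered A-to-G edits exceed a standard aligner's
mismatch budget and end up unmapped. The rescue scheme collapses the
A/G distinction: all adenosines are rewritten to guanosine in both the
unmapped reads and the genome, the reads are realigned in that three-letter
space, and the alignment is transformed back so every original mismatch
becomes visible. A read is accepted as hyper-edited when its back-
transformed mismatches are predominantly A-to-G. Antisense editing (seen
as T-to-C on the plus strand) is handled by a second, T-to-C-collapsed
index; accepted edits are reported in sense space (ref A, alt G).

Accepted reads are exportable as ordinary alignments so they can be merged
into the repeat editing index, and the per-million-mapped-reads rate
quantifies hyper-editing per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._seq import BASES, encode, decode

log = logging.getLogger(__name__)

_SENSES = ("+", "-")


@dataclass
class HyperConfig:
    """Acceptance thresholds and internal-aligner parameters."""

    min_edits_per_read: int = 5
    min_ag_fraction: float = 0.6
    max_other_mismatches: int = 1
    min_phred_at_edit: int = 25
    seed_length: int = 16
    max_transformed_mismatches: int = 2
    #: optional density mode: when set, the per-read edit threshold becomes
    #: max(min_edits_per_read, ceil(density x read length))
    min_edit_density: float | None = None

    def required_edits(self, read_length: int) -> int:
        if self.min_edit_density is None:
            return self.min_edits_per_read
        import math

        return max(self.min_edits_per_read, math.ceil(self.min_edit_density * read_length))

    def validate(self) -> None:
        if self.min_edits_per_read < 2:
            raise ValueError("min_edits_per_read must be >= 2")
        if not 0.0 < self.min_ag_fraction <= 1.0:
            raise ValueError("min_ag_fraction must be in (0, 1]")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int  # 0-based
    sense: str  # "+": A->G space; "-": T->C space (antisense editing)
    n_mismatch: int  # transformed-space mismatches


@dataclass
class EditCluster:
    """One rescued read with its back-transformed mismatch calls."""

    read_id: str
    chrom: str
    start: int
    sense: str
    mismatches: list[tuple[int, str, str, int]]  # (genome pos, ref, alt, phred)
    n_ag: int
    n_other: int
    accepted: bool
    reason: str
    sequence: str = ""
    qualities: tuple[int, ...] = ()

    @property
    def edit_positions(self) -> list[int]:
        return [p for p, ref, alt, _q in self.mismatches if ref == "A" and alt == "G"]


@dataclass
class SignatureProfile:
    """Neighbor-base preference around accepted edit sites vs background."""

    upstream: dict[str, float]
    downstream: dict[str, float]
    background_upstream: dict[str, float]
    background_downstream: dict[str, float]
    n_sites: int
    n_boundary_skipped: int

    @property
    def depletion_ratio_upstream_g(self) -> float:
        bg = self.background_upstream["G"]
        return self.upstream["G"] / bg if bg else float("inf")

    @property
    def enrichment_ratio_downstream_g(self) -> float:
        bg = self.background_downstream["G"]
        return self.downstream["G"] / bg if bg else float("inf")


@dataclass
class HyperRate:
    sample_id: str
    accepted_reads: int
    mapped_reads: int
    rate: float  # accepted reads per million mapped reads


def three_letter_transform(sequence: str, from_base: str = "A", to_base: str = "G") -> str:
    """Collapse one base into another (e.g. every A rewritten as G)."""
    return sequence.replace(from_base, to_base).replace(from_base.lower(), to_base.lower())


class TransformedIndex:
    """Seed lookup over the two collapsed genomes (A->G and T->C)."""

    def __init__(self, genome: dict[str, str], seed_length: int = 16):
        self.seed_length = seed_length
        self.genome = genome
        self.transformed: dict[str, dict[str, str]] = {}
        self.tbytes: dict[str, dict[str, np.ndarray]] = {}
        self.seeds: dict[str, dict[str, list[tuple[str, int]]]] = {}
        for sense, (f, t) in zip(_SENSES, (("A", "G"), ("T", "C"))):
            tg = {c: three_letter_transform(s, f, t) for c, s in genome.items()}
            lookup: dict[str, list[tuple[str, int]]] = {}
            for chrom, seq in tg.items():
                for i in range(len(seq) - seed_length + 1):
                    lookup.setdefault(seq[i : i + seed_length], []).append((chrom, i))
            self.transformed[sense] = tg
            self.tbytes[sense] = {
                c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in tg.items()
            }
            self.seeds[sense] = lookup


def align_transformed(read: str, index: TransformedIndex, config: HyperConfig | None = None) -> Hit | None:
    """Best unique ungapped hit of a read in transformed space, or None.

    Seeds are tried at the read start, middle and end; each candidate locus
    is extended ungapped and kept if its transformed-space mismatch count is
    within budget. Multiple equally good loci (including sense/antisense
    ties) make the read ambiguous and it is discarded.
    """
    config = config or HyperConfig()
    k = config.seed_length
    if len(read) < k:
        return None
    offsets = sorted({0, (len(read) - k) // 2, len(read) - k})
    best: list[Hit] = []
    best_mm = config.max_transformed_mismatches + 1
    for sense, (f, t) in zip(_SENSES, (("A", "G"), ("T", "C"))):
        tread = three_letter_transform(read, f, t)
        tread_arr = np.frombuffer(tread.encode(), dtype=np.uint8)
        tried: set[tuple[str, int]] = set()
        for off in offsets:
            for chrom, hitpos in index.seeds[sense].get(tread[off : off + k], ()):
                start = hitpos - off
                tg = index.tbytes[sense][chrom]
                if start < 0 or start + len(read) > len(tg) or (chrom, start) in tried:
                    continue
                tried.add((chrom, start))
                mm = int(np.count_nonzero(tg[start : start + len(read)] != tread_arr))
                if mm < best_mm:
                    best_mm = mm
                    best = [Hit(chrom, start, sense, mm)]
                elif mm == best_mm:
                    hit = Hit(chrom, start, sense, mm)
                    if hit not in best:
                        best.append(hit)
    if len(best) == 1:
        return best[0]
    if len(best) > 1:
        log.debug("ambiguous transformed alignment (%d equal loci)", len(best))
    return None


def back_transform_call(
    read: str,
    qualities: np.ndarray | list[int],
    genome: dict[str, str],
    hit: Hit,
    config: HyperConfig | None = None,
    read_id: str = "",
) -> EditCluster:
    """Compare the original read to the original genome and call edits.

    Mismatches with phred <= ``min_phred_at_edit`` are ignored entirely.
    For a sense hit, ref-A/read-G mismatches are edits; for an antisense
    hit, ref-T/read-C mismatches are, and every call is reported in sense
    space (complemented). The accept/reject verdict carries the first
    failing rule as its reason.
    """
    config = config or HyperConfig()
    config.validate()
    seq = genome[hit.chrom]
    if hit.start < 0 or hit.start + len(read) > len(seq):
        raise ValueError(f"hit at {hit.chrom}:{hit.start} extends beyond chromosome end")
    ref = seq[hit.start : hit.start + len(read)]
    quals = np.asarray(qualities, dtype=np.int16)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    edit_ref, edit_alt = ("A", "G") if hit.sense == "+" else ("T", "C")
    mismatches: list[tuple[int, str, str, int]] = []
    n_ag = n_other = 0
    for i, (rb, qb) in enumerate(zip(ref, read)):
        if rb == qb or rb not in BASES or qb not in BASES:
            continue
        if quals[i] <= config.min_phred_at_edit:
            continue
        if rb == edit_ref and qb == edit_alt:
            n_ag += 1
            out_ref, out_alt = "A", "G"
        else:
            n_other += 1
            out_ref, out_alt = (rb, qb) if hit.sense == "+" else (comp[rb], comp[qb])
        mismatches.append((hit.start + i, out_ref, out_alt, int(quals[i])))

    if n_ag < config.required_edits(len(read)):
        accepted, reason = False, "too few A-to-G edits"
    elif n_other > config.max_other_mismatches:
        accepted, reason = False, "other mismatches"
    elif n_ag / (n_ag + n_other) < config.min_ag_fraction:
        accepted, reason = False, "low A-to-G fraction"
    else:
        accepted, reason = True, "ok"
    return EditCluster(
        read_id=read_id,
        chrom=hit.chrom,
        start=hit.start,
        sense=hit.sense,
        mismatches=mismatches,
        n_ag=n_ag,
        n_other=n_other,
        accepted=accepted,
        reason=reason,
        sequence=read,
        qualities=tuple(int(q) for q in quals),
    )


def rescue_reads(
    fastq: str | Path,
    genome: dict[str, str],
    config: HyperConfig | None = None,
    index: TransformedIndex | None = None,
) -> list[EditCluster]:
    """Run the full rescue scheme over an unmapped-read FASTQ."""
    config = config or HyperConfig()
    index = index or TransformedIndex(genome, config.seed_length)
    clusters: list[EditCluster] = []
    with pysam.FastxFile(str(fastq)) as fq:
        for entry in fq:
            hit = align_transformed(entry.sequence, index, config)
            if hit is None:
                continue
            quals = entry.get_quality_array()
            clusters.append(
                back_transform_call(entry.sequence, quals, genome, hit, config, read_id=entry.name)
            )
    return clusters


def rescue_from_transformed_sam(
    sam: str | Path,
    genome: dict[str, str],
    config: HyperConfig | None = None,
) -> list[EditCluster]:
    """Back-transform externally produced transformed-space alignments.

    Escape hatch for running the realignment step with an external aligner
    on a collapsed genome: each record's sense must be carried in the
    ``XS`` tag (``+`` for the A-to-G genome, ``-`` for T-to-C); the
    original (untransformed) read sequence and qualities are taken from
    the record itself.
    """
    config = config or HyperConfig()
    clusters = []
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            sense = read.get_tag("XS") if read.has_tag("XS") else "+"
            hit = Hit(read.reference_name, read.reference_start, str(sense), 0)
            clusters.append(
                back_transform_call(
                    read.query_sequence,
                    read.query_qualities,
                    genome,
                    hit,
                    config,
                    read_id=read.query_name,
                )
            )
    return clusters


def signature_profile(clusters: list[EditCluster], genome: dict[str, str]) -> SignatureProfile:
    """Neighbor-base frequencies at accepted edits vs all genomic adenosines.

    Upstream/downstream are in the edited strand's 5'->3' sense: for an
    antisense edit the plus-strand neighbor bases are swapped and
    complemented. Background covers adenosines on both strands.
    """
    accepted = [c for c in clusters if c.accepted]
    if not any(c.edit_positions for c in accepted):
        raise ValueError("no accepted edit sites to profile")

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    up = dict.fromkeys(BASES, 0)
    down = dict.fromkeys(BASES, 0)
    skipped = 0
    n_sites = 0
    for cl in accepted:
        seq = genome[cl.chrom]
        for pos in cl.edit_positions:
            if pos - 1 < 0 or pos + 1 >= len(seq):
                skipped += 1
                continue
            if cl.sense == "+":
                u, d = seq[pos - 1], seq[pos + 1]
            else:
                u, d = comp[seq[pos + 1]], comp[seq[pos - 1]]
            if u in up and d in down:
                up[u] += 1
                down[d] += 1
                n_sites += 1

    bg_up = dict.fromkeys(BASES, 0)
    bg_down = dict.fromkeys(BASES, 0)
    for seq in genome.values():
        codes = encode(seq)
        for target, sense in ((0, "+"), (3, "-")):  # plus-strand A; minus-strand A (= T)
            pos = np.flatnonzero(codes == target)
            pos = pos[(pos > 0) & (pos < len(seq) - 1)]
            if sense == "+":
                u_codes, d_codes = codes[pos - 1], codes[pos + 1]
            else:
                u_codes, d_codes = 3 - codes[pos + 1], 3 - codes[pos - 1]
            for arr, acc in ((u_codes, bg_up), (d_codes, bg_down)):
                valid = arr[arr < 4]
                counts = np.bincount(valid, minlength=4)
                for bi, b in enumerate(BASES):
                    acc[b] += int(counts[bi])

    def _norm(d: dict[str, int]) -> dict[str, float]:
        total = sum(d.values())
        if total == 0:
            raise ValueError("empty neighbor-frequency vector")
        return {b: v / total for b, v in d.items()}

    return SignatureProfile(
        upstream=_norm(up),
        downstream=_norm(down),
        background_upstream=_norm(bg_up),
        background_downstream=_norm(bg_down),
        n_sites=n_sites,
        n_boundary_skipped=skipped,
    )


def hyper_rate(accepted_reads: int, mapped_reads: int, sample_id: str = "") -> HyperRate:
    """Hyper-edited reads per million mapped reads."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    return HyperRate(
        sample_id=sample_id,
        accepted_reads=accepted_reads,
        mapped_reads=mapped_reads,
        rate=accepted_reads * 1e6 / mapped_reads,
    )


def write_rescued_sam(
    clusters: list[EditCluster], genome: dict[str, str], path: str | Path
) -> Path:
    """Export accepted clusters as plain alignments for index merging."""
    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for cl in clusters:
            if not cl.accepted:
                continue
            a = pysam.AlignedSegment(sam.header)
            a.query_name = cl.read_id
            a.query_sequence = cl.sequence
            a.flag = 0
            a.reference_id = tid[cl.chrom]
            a.reference_start = cl.start
            a.mapping_quality = 255
            a.cigartuples = [(0, len(cl.sequence))]
            a.query_qualities = list(cl.qualities)
            a.set_tag("NH", 1)
            a.set_tag("XS", cl.sense)
            sam.write(a)
    return path
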