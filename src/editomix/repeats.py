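"""Global repeat (SINE) editing index.

The index generalises the Alu editing index to arbitrary annotated repeat
families: over every read base aligned to an adenosine inside a repeat, the
A-to-G entry is (# G read bases) / (# read bases at repeat adenosines).
All 12 ordered mismatch types are tabulated the same way, so the A-to-G
signal can be compared against the sequencing-noise floor. Reads rescued by
the hyper-editing scheme can be merged in as an extra alignment set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._seq import BASES, encode
from .quant import QuantConfig, _read_passes
from .synthetic import RepeatInterval

log = logging.getLogger(__name__)

#: code meaning: 0 = outside any repeat, 1 = plus-strand repeat, 2 = minus.
_OUT, _PLUS, _MINUS = 0, 1, 2


@dataclass
class RepeatBaseMap:
    """Per-chromosome repeat membership and reference bases.

    ``strand_code`` holds one byte per genome position (outside / plus /
    minus repeat); ``ref_code`` the encoded reference base. Overlapping
    same-strand intervals are merged; intervals overlapping on opposite
    strands are dropped (ambiguous A-strand) and counted in
    ``n_strand_conflicts``.
    """

    strand_code: dict[str, np.ndarray]
    ref_code: dict[str, np.ndarray]
    intervals: list[RepeatInterval] = field(default_factory=list)
    n_strand_conflicts: int = 0

    def adenosine_positions(self, chrom: str) -> np.ndarray:
        """0-based positions inside repeats whose sense-strand base is A."""
        sc, rc = self.strand_code[chrom], self.ref_code[chrom]
        plus_a = (sc == _PLUS) & (rc == 0)
        minus_a = (sc == _MINUS) & (rc == 3)
        return np.flatnonzero(plus_a | minus_a)


@dataclass
class MismatchIndexTable:
    """All 12 ordered mismatch indices for one sample."""

    sample_id: str
    numerator: dict[tuple[str, str], int]
    denominator: dict[str, int]

    def index(self, ref: str, alt: str) -> float:
        den = self.denominator.get(ref, 0)
        return self.numerator.get((ref, alt), 0) / den if den else 0.0

    @property
    def sine_editing_index(self) -> float:
        return self.index("A", "G")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample_id,
                "ref": x,
                "alt": y,
                "numerator": self.numerator.get((x, y), 0),
                "denominator": self.denominator.get(x, 0),
                "index": self.index(x, y),
            }
            for x in BASES
            for y in BASES
            if x != y
        ]
        return pd.DataFrame(rows)


def read_bed(path: str | Path) -> list[RepeatInterval]:
    """Parse a 6-column BED of repeat intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            if parts[5] not in "+-":
                raise ValueError(f"{path}:{ln}: strand must be + or -")
            out.append(RepeatInterval(parts[0], start, end, parts[3], parts[5]))
    return out


def build_repeat_map(
    genome: dict[str, str] | str | Path,
    repeats: list[RepeatInterval] | str | Path,
    families: set[str] | None = None,
) -> RepeatBaseMap:
    """Build the position-to-base lookup restricted to annotated repeats.

    ``genome`` may be a chrom-to-sequence dict or a FASTA path; ``repeats``
    a list of intervals or a BED path. ``families`` keeps only the named
    repeat families.
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        genome = {name: str(fa[name][:]) for name in fa.keys()}
    if isinstance(repeats, (str, Path)):
        repeats = read_bed(repeats)
    if families is not None:
        repeats = [iv for iv in repeats if iv.family in families]

    missing = {iv.chrom for iv in repeats} - set(genome)
    if missing:
        raise ValueError(f"BED chromosomes absent from FASTA: {sorted(missing)}")

    ref_code = {c: encode(s) for c, s in genome.items()}
    strand_code = {c: np.zeros(len(s), dtype=np.uint8) for c, s in genome.items()}

    # drop intervals that overlap an opposite-strand interval
    kept: list[RepeatInterval] = []
    n_conflicts = 0
    by_chrom: dict[str, list[RepeatInterval]] = {}
    for iv in repeats:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        bad = set()
        for i, a in enumerate(ivs):
            for j in range(i + 1, len(ivs)):
                b = ivs[j]
                if b.start >= a.end:
                    break
                if b.strand != a.strand:
                    bad.add(i)
                    bad.add(j)
        n_conflicts += len(bad)
        kept.extend(iv for j, iv in enumerate(ivs) if j not in bad)
    if n_conflicts:
        log.warning("dropped %d repeat intervals with strand conflicts", n_conflicts)

    for iv in kept:
        strand_code[iv.chrom][iv.start : iv.end] = _MINUS if iv.strand == "-" else _PLUS

    return RepeatBaseMap(
        strand_code=strand_code,
        ref_code=ref_code,
        intervals=kept,
        n_strand_conflicts=n_conflicts,
    )


def merged_intervals(rmap: RepeatBaseMap, chrom: str) -> list[tuple[int, int]]:
    """Merged repeat spans on one chromosome (for reporting)."""
    mask = rmap.strand_code[chrom] > 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _accumulate(
    sam: pysam.AlignmentFile,
    rmap: RepeatBaseMap,
    config: QuantConfig,
    pair_counts: np.ndarray,
) -> None:
    for read in sam:
        if not _read_passes(read, config.unique_only):
            continue
        chrom = read.reference_name
        if chrom not in rmap.strand_code:
            continue
        start, end = read.reference_start, read.reference_end
        simple = len(read.cigartuples) == 1 and read.cigartuples[0][0] == 0
        if simple:
            rpos = np.arange(start, end)
            qpos = np.arange(end - start)
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.array([p[0] for p in pairs])
            rpos = np.array([p[1] for p in pairs])
        sc = rmap.strand_code[chrom][rpos]
        inside = sc > 0
        if not inside.any():
            continue
        quals = np.asarray(read.query_qualities, dtype=np.int16)
        readc = encode(read.query_sequence)
        keep = inside & (quals[qpos] > config.min_phred) & (readc[qpos] < 4)
        if not keep.any():
            continue
        refc = rmap.ref_code[chrom][rpos[keep]].astype(np.int16)
        altc = readc[qpos[keep]].astype(np.int16)
        minus = sc[keep] == _MINUS
        refc[minus] = 3 - refc[minus]
        altc[minus] = 3 - altc[minus]
        np.add.at(pair_counts, refc * 4 + altc, 1)


def compute_editing_index(
    alignments: str | Path | pysam.AlignmentFile,
    rmap: RepeatBaseMap,
    config: QuantConfig | None = None,
    rescued: str | Path | pysam.AlignmentFile | None = None,
    sample_id: str = "",
) -> MismatchIndexTable:
    """Tabulate all 12 mismatch indices over repeat positions for one sample.

    Every filtered read base over a repeat position with reference X
    increments denominator(X) and, if the read base Y differs, numerator
    (X -> Y); minus-strand repeats are counted in complemented space so the
    A-to-G entry always measures sense-strand A-to-G. ``rescued``
    alignments (hyper-editing output) contribute identically.
    """
    config = config or QuantConfig()
    if all((rmap.strand_code[c] == 0).all() for c in rmap.strand_code):
        raise ValueError("repeat map is empty; no positions to index")

    pair_counts = np.zeros(16, dtype=np.int64)
    for source in (alignments, rescued):
        if source is None:
            continue
        own = isinstance(source, (str, Path))
        sam = pysam.AlignmentFile(str(source), "r", check_sq=False) if own else source
        try:
            _accumulate(sam, rmap, config, pair_counts)
        finally:
            if own:
                sam.close()

    numerator = {}
    denominator = {}
    for xi, x in enumerate(BASES):
        denominator[x] = int(pair_counts[xi * 4 : xi * 4 + 4].sum())
        for yi, y in enumerate(BASES):
            if x != y:
                numerator[(x, y)] = int(pair_counts[xi * 4 + yi])
    return MismatchIndexTable(sample_id=sample_id, numerator=numerator, denominator=denominator)


def index_report(tables: dict[str, MismatchIndexTable]) -> pd.DataFrame:
    """Tidy long-format report with per-sample signal-to-noise.

    Signal-to-noise is the A-to-G index over the median of the other 11
    indices; when that median is zero the value is ``inf`` (sentinel).
    Also reports the index on the x100 ("%"-like) scale.
    """
    if not tables:
        raise ValueError("no samples to report")
    frames = []
    for sid in sorted(tables):
        tab = tables[sid]
        df = tab.to_frame()
        others = df.loc[~((df["ref"] == "A") & (df["alt"] == "G")), "index"]
        noise = float(others.median())
        snr = np.inf if noise == 0 else tab.sine_editing_index / noise
        df["index_pct"] = df["index"] * 100
        df["signal_to_noise"] = snr
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
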