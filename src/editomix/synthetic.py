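"""Synthetic cohort generator for A-to-I editing studies.

Emulates a purified-brain-cell-type study design: a small genome carrying
SINE-like repeat families (B1/B2/B4 stand-ins), a catalog of conserved
recoding sites, per-cell-type editome truth profiles (neurons highest at
most sites; a COPA/COG3-like minority higher in astrocytes/endothelium),
and simulated read sets for pure cell types or whole-tissue mixtures with
full ground truth.

Reads are emitted pre-aligned (SAM) because the true origin of every read
is known by construction; heavily edited reads are written only to FASTQ,
mimicking the fraction of a library that defeats a standard aligner.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._seq import A, C, G, T, BASES, decode, encode, reverse_complement, wrap_fasta

#: The seven purified brain cell types of the emulated study design.
CELL_TYPES = ("neuron", "astrocyte", "opc", "nfo", "mo", "microglia", "endothelial")

#: Repeat family names (mouse SINE subfamilies screened by the index).
REPEAT_FAMILIES = ("B1", "B2", "B4")

#: Genes whose sites are edited more in astrocytes/endothelium than neurons.
ASTRO_HIGH_GENES = frozenset({"COPA_IV", "COG3_IV"})

#: The eight signature recoding sites with a known injury direction
#: (six neuron-high, expected to drop with neuronal density; two astro-high,
#: expected to rise).
SIGNATURE_GENES = (
    "FLNA_QR",
    "TMEM63B_QR",
    "CACNA1D_IM",
    "GRIK2_QR",
    "GRIK2_IV",
    "BLCAP_YC",
    "COPA_IV",
    "COG3_IV",
)

# Measured editing fractions in cultured primary neurons / astrocytes,
# injured and control conditions of the in-vitro model.
TABLE2_INJURY = {
    "FLNA_QR": (0.0726, 0.0196),
    "TMEM63B_QR": (0.316, 0.0126),
    "GRIK2_IV": (0.3874, 0.0376),
    "GRIK2_QR": (0.6935, 0.0468),
    "COPA_IV": (0.031, 0.1835),
    "COG3_IV": (0.2469, 0.8856),
}
TABLE2_CONTROL = {
    "FLNA_QR": (0.0723, 0.0178),
    "TMEM63B_QR": (0.3163, 0.013),
    "GRIK2_IV": (0.3819, 0.0274),
    "GRIK2_QR": (0.7043, 0.0295),
    "COPA_IV": (0.0329, 0.1804),
    "COG3_IV": (0.2297, 0.9195),
}

#: Default per-cell-type repeat (SINE) editing rates: neurons clearly highest.
DEFAULT_P_REPEAT = {
    "neuron": 0.02,
    "opc": 0.012,
    "astrocyte": 0.008,
    "nfo": 0.007,
    "mo": 0.006,
    "endothelial": 0.005,
    "microglia": 0.004,
}


@dataclass
class GenomeSpec:
    """Parameters of the synthetic genome and its repeat annotation."""

    n_chromosomes: int = 2
    chrom_length: int = 50_000
    repeat_count: int = 20  # copies per chromosome
    repeat_length: int = 200
    repeat_divergence: float = 0.1
    gc_content: float = 0.42
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length < self.repeat_count * self.repeat_length:
            raise ValueError(
                f"cannot pack {self.repeat_count} x {self.repeat_length} bp repeats "
                f"into a {self.chrom_length} bp chromosome"
            )
        if not 0.0 <= self.repeat_divergence <= 0.3:
            raise ValueError("repeat_divergence must be in [0, 0.3]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_chromosomes < 1 or self.repeat_count < 0:
            raise ValueError("n_chromosomes >= 1 and repeat_count >= 0 required")


@dataclass(frozen=True)
class RepeatInterval:
    """One annotated repeat copy, 0-based half-open on the plus strand."""

    chrom: str
    start: int
    end: int
    family: str
    strand: str


@dataclass
class CellEditomeTruth:
    """Ground-truth editome: per-site levels, repeat rates, expression weights.

    ``levels`` is a (site x cell type) frame of editing fractions;
    ``p_repeat`` maps cell type to its SINE-editing rate; ``expression``
    is a (gene x cell type) frame of FPKM-like weights (uniform by default).
    """

    levels: pd.DataFrame
    sites: pd.DataFrame  # catalog rows matching ``levels`` index
    p_repeat: dict[str, float]
    expression: pd.DataFrame

    @property
    def cell_types(self) -> list[str]:
        return list(self.levels.columns)

    def validate(self) -> None:
        vals = self.levels.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("editing rates must lie in [0, 1]")
        for ct, p in self.p_repeat.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"repeat editing rate for {ct} outside [0, 1]")
        if (self.expression.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression weights must be non-negative")


@dataclass
class SampleDesign:
    """Design of one simulated library."""

    sample_id: str
    mixture: dict[str, float]
    depth: float = 50.0  # mean reads per catalog site
    read_length: int = 100
    error_rate: float = 0.0
    phred_high: int = 35
    low_qual_fraction: float = 0.0  # fraction of bases miscalled at phred_low
    phred_low: int = 20
    repeat_depth: float = 0.0  # mean per-base coverage over repeat intervals
    hyper_fraction: float = 0.0  # hyper-edited unmapped reads per normal read
    min_hyper_edits: int = 6
    max_hyper_edits: int = 10
    hyper_signature_bias: bool = False
    background_unmapped: int = 0  # non-hyper-edited reads written to FASTQ
    stranded: bool = True  # False: half the alignments flagged as reverse-strand
    seed: int = 0

    def validate(self, cell_types: list[str]) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0.0 <= self.hyper_fraction <= 0.05:
            raise ValueError("hyper_fraction must be in [0, 0.05]")
        if not self.mixture:
            raise ValueError("mixture must not be empty")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, expected 1")
        missing = set(self.mixture) - set(cell_types)
        if missing:
            raise ValueError(f"mixture refers to unknown cell types: {sorted(missing)}")


@dataclass
class TruthTable:
    """Realized ground truth for one simulated sample."""

    sample_id: str
    site_counts: pd.DataFrame  # index site key; columns edited, total
    repeat_edited: int
    repeat_total: int
    hyper_reads: pd.DataFrame  # read_id, chrom, start, sense, n_edits, positions

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# truth sample={self.sample_id}\n")
            fh.write(f"# repeat_edited={self.repeat_edited} repeat_total={self.repeat_total}\n")
            self.site_counts.to_csv(fh, sep="\t", index_label="site")
        hp = path.with_suffix(".hyper.tsv")
        self.hyper_reads.to_csv(hp, sep="\t", index=False)


@dataclass
class SimulatedSample:
    """Paths and truth for one simulated library."""

    sample_id: str
    sam_path: Path
    fastq_path: Path
    truth: TruthTable


def site_key(chrom: str, pos: int, strand: str) -> str:
    """Canonical site identifier from chrom, 1-based position and strand."""
    return f"{chrom}:{pos}:{strand}"


# ---------------------------------------------------------------------------
# genome


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    n = min(len(a), len(b))
    return float(np.mean(a[:n] == b[:n]))


def build_genome(spec: GenomeSpec) -> tuple[dict[str, str], list[RepeatInterval]]:
    """Generate a synthetic genome with planted repeat copies.

    Each chromosome carries ``repeat_count`` copies drawn from the family
    consensus sequences, mutated at ``repeat_divergence`` per base, with
    roughly a third planted in inverted orientation. Family consensus
    sequences are drawn independently and re-drawn until mutual identity is
    below 80 % so placements are unambiguous.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    consensus: list[np.ndarray] = []
    for _ in REPEAT_FAMILIES:
        for _attempt in range(100):
            cand = _random_seq(rng, spec.repeat_length, spec.gc_content)
            if all(_identity(cand, other) < 0.8 for other in consensus):
                consensus.append(cand)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw dissimilar repeat consensus sequences")

    genome: dict[str, str] = {}
    repeats: list[RepeatInterval] = []
    slot = spec.chrom_length // max(spec.repeat_count, 1)
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, spec.chrom_length, spec.gc_content)
        for ri in range(spec.repeat_count):
            fam_idx = int(rng.integers(len(REPEAT_FAMILIES)))
            copy = consensus[fam_idx].copy()
            if spec.repeat_divergence > 0:
                mut = rng.random(spec.repeat_length) < spec.repeat_divergence
                shift = rng.integers(1, 4, size=int(mut.sum())).astype(np.uint8)
                copy[mut] = (copy[mut] + shift) % 4
            strand = "-" if rng.random() < 0.35 else "+"
            if strand == "-":
                copy = (3 - copy[::-1]).astype(np.uint8)
            lo = ri * slot
            hi = min((ri + 1) * slot, spec.chrom_length) - spec.repeat_length
            start = int(rng.integers(lo, hi + 1))
            seq[start : start + spec.repeat_length] = copy
            repeats.append(
                RepeatInterval(chrom, start, start + spec.repeat_length, REPEAT_FAMILIES[fam_idx], strand)
            )
        genome[chrom] = decode(seq)
    return genome, repeats


def make_site_catalog(
    genome: dict[str, str],
    repeats: list[RepeatInterval],
    n_sites: int = 24,
    seed: int = 0,
    minus_fraction: float = 0.25,
    n_nonconserved: int = 0,
) -> pd.DataFrame:
    """Pick editing-site positions outside repeats and label them with genes.

    The first eight conserved sites carry the signature recoding-gene labels
    (FLNA/TMEM63B/CACNA1D/GRIK2x2/BLCAP down-type, COPA/COG3 up-type); the
    rest get generic conserved labels. The reference base on the annotated
    strand is always adenosine (plus-strand A, or plus-strand T for minus
    sites).
    """
    if n_sites < len(SIGNATURE_GENES):
        genes = list(SIGNATURE_GENES[:n_sites])
    else:
        genes = list(SIGNATURE_GENES) + [f"CONS{i:02d}" for i in range(1, n_sites - len(SIGNATURE_GENES) + 1)]
    genes += [f"NC{i:03d}" for i in range(1, n_nonconserved + 1)]

    rng = np.random.default_rng(seed)
    codes = {c: encode(s) for c, s in genome.items()}
    in_repeat = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    for iv in repeats:
        in_repeat[iv.chrom][iv.start : iv.end] = True

    chroms = sorted(genome)
    rows = []
    used: set[tuple[str, int]] = set()
    for i, gene in enumerate(genes):
        strand = "-" if rng.random() < minus_fraction else "+"
        want = T if strand == "-" else A
        for _attempt in range(10_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos0 = int(rng.integers(1, len(genome[chrom]) - 1))
            if (
                codes[chrom][pos0] == want
                and not in_repeat[chrom][pos0]
                and (chrom, pos0) not in used
            ):
                used.add((chrom, pos0))
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "gene": gene,
                        "conserved": 0 if gene.startswith("NC") else 1,
                    }
                )
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place all catalog sites")
    cat = pd.DataFrame(rows)
    cat.index = [site_key(r.chrom, r.pos, r.strand) for r in cat.itertuples()]
    cat.index.name = "site"
    return cat


# ---------------------------------------------------------------------------
# editomes


def make_cell_editomes(
    catalog: pd.DataFrame,
    profile: str | dict = "paperlike",
    seed: int = 0,
    cell_types: tuple[str, ...] = CELL_TYPES,
) -> CellEditomeTruth:
    """Assign ground-truth editing levels to every catalog site per cell type.

    Profiles:

    ``"paperlike"``
        All seven cell types. Neurons strictly highest at every site except
        the COPA/COG3-like minority, where astrocytes and endothelium lead;
        OPCs are the runner-up lineage. Rates drawn per site from broad,
        seeded ranges.
    ``"table2"`` / ``"table2-control"``
        Neuron and astrocyte only, constant measured rates of the six
        recoding sites of the in-vitro injury model (injury resp. control
        condition); catalog rows for other genes are dropped.
    explicit ``dict``
        ``{gene_or_site_key: {cell_type: rate}}`` passed through unchanged.
    """
    if catalog.empty:
        raise ValueError("site catalog is empty")
    rng = np.random.default_rng(seed)

    if isinstance(profile, dict):
        cells = sorted({ct for rates in profile.values() for ct in rates})
        levels = pd.DataFrame(np.nan, index=catalog.index, columns=cells)
        for key, rates in profile.items():
            mask = (catalog.index == key) | (catalog["gene"] == key)
            if not mask.any():
                raise ValueError(f"explicit profile key {key!r} not in catalog")
            for ct, rate in rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"rate {rate} for {key}/{ct} outside [0, 1]")
                levels.loc[mask, ct] = rate
        levels = levels.dropna(how="any")
        sites = catalog.loc[levels.index]
    elif profile in ("table2", "table2-control"):
        table = TABLE2_INJURY if profile == "table2" else TABLE2_CONTROL
        sites = catalog[catalog["gene"].isin(table)].copy()
        if sites.empty:
            raise ValueError("catalog contains none of the six in-vitro panel genes")
        levels = pd.DataFrame(
            [[table[g][0], table[g][1]] for g in sites["gene"]],
            index=sites.index,
            columns=["neuron", "astrocyte"],
        )
    elif profile == "paperlike":
        # Non-neuron types share a latent low-editing profile drawn
        # independently of the neuron profile, so non-neurons correlate
        # with each other but not with neurons (the binary editome
        # structure seen across purified brain cell types); OPCs are the
        # runner-up lineage, astrocytes/endothelium lead at the COPA/
        # COG3-like minority sites.
        sites = catalog.copy()
        levels = pd.DataFrame(0.0, index=sites.index, columns=list(cell_types))
        for key, row in sites.iterrows():
            if row["gene"] in ASTRO_HIGH_GENES:
                astro = rng.uniform(0.5, 0.9)
                levels.loc[key, "astrocyte"] = astro
                levels.loc[key, "endothelial"] = astro * rng.uniform(0.5, 0.9)
                levels.loc[key, "neuron"] = rng.uniform(0.02, 0.05)
                for ct in ("opc", "nfo", "mo", "microglia"):
                    if ct in levels.columns:
                        levels.loc[key, ct] = astro * rng.uniform(0.1, 0.4)
            else:
                neuron = rng.uniform(0.35, 0.8)
                base = rng.uniform(0.01, 0.25)  # shared non-neuron level
                levels.loc[key, "neuron"] = neuron
                if "opc" in levels.columns:
                    levels.loc[key, "opc"] = min(base * rng.uniform(1.2, 1.6), 0.9 * neuron)
                for ct in ("astrocyte", "nfo", "mo", "microglia", "endothelial"):
                    if ct in levels.columns:
                        levels.loc[key, ct] = min(base * rng.uniform(0.6, 1.0), 0.9 * neuron)
        levels = levels[[c for c in cell_types if c in levels.columns]]
    else:
        raise ValueError(f"unknown editome profile {profile!r}")

    cells = list(levels.columns)
    p_repeat = {ct: DEFAULT_P_REPEAT.get(ct, 0.005) for ct in cells}
    expression = pd.DataFrame(1.0, index=sorted(sites["gene"].unique()), columns=cells)
    truth = CellEditomeTruth(levels=levels, sites=sites, p_repeat=p_repeat, expression=expression)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(read: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return read
    mask = rng.random(len(read)) < rate
    k = int(mask.sum())
    if k:
        read = read.copy()
        read[mask] = (read[mask] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    return read


def _qualities(n: int, design: SampleDesign, rng: np.random.Generator) -> np.ndarray:
    qual = np.full(n, design.phred_high, dtype=np.uint8)
    if design.low_qual_fraction > 0:
        qual[rng.random(n) < design.low_qual_fraction] = design.phred_low
    return qual


def _cell_probs(mixture: dict[str, float], weights: pd.Series | None) -> tuple[list[str], np.ndarray]:
    cells = list(mixture)
    p = np.array([mixture[c] for c in cells], dtype=float)
    if weights is not None:
        p = p * np.array([float(weights.get(c, 1.0)) for c in cells])
    total = p.sum()
    if total <= 0:
        raise ValueError("mixture x expression weights sum to zero")
    return cells, p / total


def simulate_sample(
    genome: dict[str, str],
    repeats: list[RepeatInterval],
    catalog: pd.DataFrame,
    truth: CellEditomeTruth,
    design: SampleDesign,
    outdir: str | Path,
) -> SimulatedSample:
    """Simulate one library: aligned SAM, unmapped hyper FASTQ, truth table.

    Every read is assigned a cell type with probability proportional to
    mixture fraction x expression weight of its locus; covered site bases
    become G (plus strand) or C (minus strand) with the cell type's true
    level; sequencing errors and phred values are then applied. Hyper-edited
    fragments carry ``min_hyper_edits``..``max_hyper_edits`` planted A-to-G
    changes and appear only in the FASTQ.
    """
    design.validate(truth.cell_types)
    missing = set(design.mixture) - set(truth.levels.columns)
    if missing:
        raise ValueError(f"no editome for cell types {sorted(missing)}")
    for key, row in catalog.iterrows():
        if row["chrom"] not in genome:
            raise ValueError(f"catalog chromosome {row['chrom']} not in genome")
        if not 1 <= row["pos"] <= len(genome[row["chrom"]]):
            raise ValueError(f"catalog site {key} beyond chromosome end")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    codes = {c: encode(s) for c, s in genome.items()}
    rl = design.read_length

    # (chrom, start, read codes, cell type name, read id); repeat edits and
    # sequencing errors are planted afterwards so that every read
    # overlapping a repeat is edited, regardless of why it was sequenced.
    records: list[list] = []
    n_normal = 0

    # --- catalog-site reads
    site_rows = []
    for key, row in catalog.iterrows():
        chrom, pos0, strand = row["chrom"], int(row["pos"]) - 1, row["strand"]
        L = len(genome[chrom])
        ncov = int(rng.poisson(design.depth))
        edited_n = 0
        if ncov:
            gene = row["gene"]
            wt = truth.expression.loc[gene] if gene in truth.expression.index else None
            cells, probs = _cell_probs(design.mixture, wt)
            if key in truth.levels.index:
                rates = np.array([truth.levels.loc[key].get(ct, 0.0) for ct in cells])
            else:
                rates = np.zeros(len(cells))
            cell_idx = rng.choice(len(cells), size=ncov, p=probs)
            edited = rng.random(ncov) < rates[cell_idx]
            edited_n = int(edited.sum())
            lo = max(0, pos0 - rl + 1)
            hi = min(pos0, L - rl)
            starts = rng.integers(lo, hi + 1, size=ncov)
            for j in range(ncov):
                start = int(starts[j])
                read = codes[chrom][start : start + rl].copy()
                if edited[j]:
                    read[pos0 - start] = C if strand == "-" else G
                records.append(
                    [chrom, start, read, cells[cell_idx[j]], f"{design.sample_id}_s{n_normal + j}"]
                )
            n_normal += ncov
        site_rows.append({"site": key, "edited": edited_n, "total": ncov})
    site_counts = pd.DataFrame(site_rows).set_index("site")

    # --- extra reads over repeat regions
    local = [iv for iv in repeats if iv.chrom in genome]
    if design.repeat_depth > 0 and local:
        span = sum(iv.end - iv.start for iv in local)
        n_rep = int(rng.poisson(design.repeat_depth * span / rl))
        lens = np.array([iv.end - iv.start for iv in local], dtype=float)
        iv_p = lens / lens.sum()
        cells, probs = _cell_probs(design.mixture, None)
        iv_idx = rng.choice(len(local), size=n_rep, p=iv_p)
        cell_idx = rng.choice(len(cells), size=n_rep, p=probs)
        for j in range(n_rep):
            iv = local[iv_idx[j]]
            L = len(genome[iv.chrom])
            lo = max(0, iv.start - rl + 1)
            hi = min(iv.end - 1, L - rl)
            start = int(rng.integers(lo, hi + 1))
            read = codes[iv.chrom][start : start + rl].copy()
            records.append([iv.chrom, start, read, cells[cell_idx[j]], f"{design.sample_id}_r{j}"])
        n_normal += n_rep

    # --- plant repeat edits on every read overlapping a repeat interval,
    # then apply sequencing errors
    repeat_edited = repeat_total = 0
    iv_by_chrom: dict[str, list[RepeatInterval]] = {}
    for iv in local:
        iv_by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in iv_by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    iv_starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in iv_by_chrom.items()}

    final_records: list[tuple[str, int, np.ndarray, np.ndarray, str]] = []
    for chrom, start, read, cell, rid in records:
        p_rep = truth.p_repeat.get(cell, 0.0)
        ivs = iv_by_chrom.get(chrom)
        if ivs:
            starts_arr = iv_starts[chrom]
            # walk left from the first interval starting at/after the read end
            i = int(np.searchsorted(starts_arr, start + rl, side="left")) - 1
            overlapping = []
            while i >= 0 and ivs[i].end > start:
                overlapping.append(ivs[i])
                i -= 1
            for iv in overlapping:
                a0 = max(start, iv.start) - start
                a1 = min(start + rl, iv.end) - start
                window = read[a0:a1]
                target = T if iv.strand == "-" else A
                apos = np.flatnonzero(window == target)
                if apos.size:
                    hit = rng.random(apos.size) < p_rep
                    window[apos[hit]] = C if iv.strand == "-" else G
                    repeat_total += int(apos.size)
                    repeat_edited += int(hit.sum())
        read = _apply_errors(read, design.error_rate, rng)
        qual = _qualities(rl, design, rng)
        final_records.append((chrom, start, read, qual, rid))
    records = final_records

    # --- hyper-edited unmapped reads (FASTQ only)
    chroms = sorted(genome)
    hyper_rows = []
    fastq_path = outdir / f"{design.sample_id}.unmapped.fastq"
    with open(fastq_path, "w") as fq:
        n_hyper = int(rng.poisson(design.hyper_fraction * max(n_normal, 1)))
        for j in range(n_hyper):
            for _attempt in range(1000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                L = len(genome[chrom])
                start = int(rng.integers(0, L - rl + 1))
                sense = "-" if rng.random() < 0.5 else "+"
                frag = codes[chrom][start : start + rl].copy()
                target = T if sense == "-" else A
                cand = np.flatnonzero(frag == target)
                if cand.size >= design.min_hyper_edits:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not place hyper-edited fragment")
            k = int(rng.integers(design.min_hyper_edits, min(design.max_hyper_edits, cand.size) + 1))
            if design.hyper_signature_bias:
                w = np.ones(cand.size)
                for ci, off in enumerate(cand):
                    gpos = start + off
                    if sense == "+":
                        up = codes[chrom][gpos - 1] if gpos > 0 else 255
                        down = codes[chrom][gpos + 1] if gpos + 1 < L else 255
                    else:  # sense space: upstream is gpos+1 complemented
                        up = 3 - codes[chrom][gpos + 1] if gpos + 1 < L else 255
                        down = 3 - codes[chrom][gpos - 1] if gpos > 0 else 255
                    if up == G:
                        w[ci] *= 0.1
                    if down == G:
                        w[ci] *= 5.0
                w /= w.sum()
                chosen = rng.choice(cand, size=k, replace=False, p=w)
            else:
                chosen = rng.choice(cand, size=k, replace=False)
            frag[np.sort(chosen)] = C if sense == "-" else G
            frag = _apply_errors(frag, design.error_rate, rng)
            rid = f"{design.sample_id}_h{j}"
            qual = _qualities(rl, design, rng)
            fq.write(f"@{rid}\n{decode(frag)}\n+\n{''.join(chr(q + 33) for q in qual)}\n")
            hyper_rows.append(
                {
                    "read_id": rid,
                    "chrom": chrom,
                    "start": start,
                    "sense": sense,
                    "n_edits": k,
                    "positions": ",".join(str(start + int(o)) for o in np.sort(chosen)),
                }
            )
        # non-hyper-edited decoys: half noisy genome fragments, half random junk
        for j in range(design.background_unmapped):
            rid = f"{design.sample_id}_b{j}"
            if j % 2 == 0:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, len(genome[chrom]) - rl + 1))
                frag = codes[chrom][start : start + rl].copy()
                frag = _apply_errors(frag, max(design.error_rate, 0.001), rng)
            else:
                frag = rng.integers(0, 4, size=rl).astype(np.uint8)
            qual = _qualities(rl, design, rng)
            fq.write(f"@{rid}\n{decode(frag)}\n+\n{''.join(chr(q + 33) for q in qual)}\n")

    hyper_df = pd.DataFrame(
        hyper_rows, columns=["read_id", "chrom", "start", "sense", "n_edits", "positions"]
    )

    # --- write coordinate-sorted SAM
    sam_path = outdir / f"{design.sample_id}.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    records.sort(key=lambda r: (tid[r[0]], r[1]))
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        strand_rng = np.random.default_rng(design.seed + 1)
        for chrom, start, read, qual, rid in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rid
            a.query_sequence = decode(read)
            # SEQ is always forward-strand in SAM; an unstranded library
            # just marks half the alignments as reverse-strand provenance
            a.flag = 16 if (not design.stranded and strand_rng.random() < 0.5) else 0
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = 255
            a.cigartuples = [(0, len(read))]
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in qual)
            )
            a.set_tag("NH", 1)
            sam.write(a)

    truth_table = TruthTable(
        sample_id=design.sample_id,
        site_counts=site_counts,
        repeat_edited=repeat_edited,
        repeat_total=repeat_total,
        hyper_reads=hyper_df,
    )
    return SimulatedSample(design.sample_id, sam_path, fastq_path, truth_table)


# ---------------------------------------------------------------------------
# file output helpers


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> Path:
    """Write the genome as FASTA and build its .fai index."""
    import pyfaidx

    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n{wrap_fasta(genome[chrom])}\n")
    pyfaidx.Faidx(str(path))
    return path


def write_repeats_bed(repeats: list[RepeatInterval], path: str | Path) -> Path:
    """Write repeat intervals as 6-column BED (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in repeats:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.family}\t0\t{iv.strand}\n")
    return path


def write_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    catalog.to_csv(path, sep="\t", index=False)
    return path
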