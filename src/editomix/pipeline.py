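"""Pipeline orchestration: staged runs, manifests, input validation.

A run executes stages in dependency order (simulate -> quant / sine-index /
hyper -> compose) from a single YAML configuration, records a manifest with
input/output hashes and parameters per stage, and supports partial stage
subsets when upstream outputs already exist on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as eio
from .composition import (
    cluster_editomes,
    differential_editing,
    editome_correlation,
    estimate_fraction_change,
    mix_editomes,
    simulate_density_change,
)
from .hyper import HyperConfig, hyper_rate, rescue_reads, signature_profile, write_rescued_sam, TransformedIndex
from .quant import QuantConfig, compute_cei, count_site_bases, editing_levels
from .repeats import build_repeat_map, compute_editing_index, index_report, read_bed
from .synthetic import (
    CELL_TYPES,
    GenomeSpec,
    SampleDesign,
    build_genome,
    make_cell_editomes,
    make_site_catalog,
    simulate_sample,
    write_catalog_tsv,
    write_genome_fasta,
    write_repeats_bed,
)

log = logging.getLogger("editomix.pipeline")

STAGES = ("simulate", "quant", "sine-index", "hyper", "compose")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    stage: str
    inputs: dict[str, str]
    parameters: dict
    outputs: dict[str, str]
    started: float
    finished: float


@dataclass
class Manifest:
    version: str
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        with open(path) as fh:
            data = json.load(fh)
        stages = [StageRecord(**s) for s in data.pop("stages")]
        return cls(stages=stages, **data)

    def verify_hashes(self) -> list[str]:
        """Return paths whose on-disk hash no longer matches the manifest."""
        stale = []
        for rec in self.stages:
            for mapping in (rec.inputs, rec.outputs):
                for path, digest in mapping.items():
                    p = Path(path)
                    if not p.exists() or _sha256(p) != digest:
                        stale.append(path)
        return stale


DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"n_chromosomes": 2, "chrom_length": 50_000, "repeat_count": 20, "repeat_length": 200},
    "catalog": {"n_sites": 24},
    "profile": "paperlike",
    "quant": {"min_phred": 25, "min_coverage": 15, "min_groups": 2},
    "hyper": {},
    "samples": [
        {"sample_id": "control_1", "mixture": "control", "depth": 400, "repeat_depth": 12, "hyper_fraction": 0.002},
        {"sample_id": "control_2", "mixture": "control", "depth": 400, "repeat_depth": 12, "hyper_fraction": 0.002},
        {"sample_id": "injured_1", "mixture": "injured", "depth": 400, "repeat_depth": 12, "hyper_fraction": 0.002},
        {"sample_id": "injured_2", "mixture": "injured", "depth": 400, "repeat_depth": 12, "hyper_fraction": 0.002},
    ],
    "mixtures": {
        "control": {
            "neuron": 0.5,
            "astrocyte": 0.2,
            "opc": 0.08,
            "nfo": 0.05,
            "mo": 0.07,
            "microglia": 0.05,
            "endothelial": 0.05,
        },
        # neuronal density reduced by 20%, rest redistributed
        "injured": None,
    },
    "neuron_delta": -0.2,
    "groups": {"control_1": "control", "control_2": "control", "injured_1": "injured", "injured_2": "injured"},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    if cfg["mixtures"].get("injured") is None:
        cfg["mixtures"]["injured"] = simulate_density_change(
            cfg["mixtures"]["control"], cfg.get("neuron_delta", -0.2)
        )
    return cfg


class DependencyError(RuntimeError):
    """A requested stage is missing outputs of an upstream stage."""


def run_pipeline(
    config: dict,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Manifest:
    """Run the requested stages in dependency order, recording a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    manifest = Manifest(version=__version__, seed=seed)
    stages = tuple(s for s in STAGES if s in stages)

    qc = QuantConfig(**config.get("quant", {}))
    hc = HyperConfig(**config.get("hyper", {}))
    fasta = outdir / "genome.fa"
    bed = outdir / "repeats.bed"
    cat_tsv = outdir / "catalog.tsv"
    truth_tsv = outdir / "editome_truth.tsv"

    def record(stage, inputs, params, outputs, t0):
        manifest.stages.append(
            StageRecord(
                stage=stage,
                inputs={str(p): _sha256(Path(p)) for p in inputs},
                parameters=params,
                outputs={str(p): _sha256(Path(p)) for p in outputs},
                started=t0,
                finished=time.time(),
            )
        )

    sample_ids = [s["sample_id"] for s in config["samples"]]

    if "simulate" in stages:
        t0 = time.time()
        gspec = GenomeSpec(seed=seed, **config.get("genome", {}))
        genome, repeats = build_genome(gspec)
        catalog = make_site_catalog(genome, repeats, seed=seed + 1, **config.get("catalog", {}))
        truth = make_cell_editomes(catalog, profile=config.get("profile", "paperlike"), seed=seed + 2)
        write_genome_fasta(genome, fasta)
        write_repeats_bed(repeats, bed)
        write_catalog_tsv(catalog, cat_tsv)
        eio.write_tsv(truth.levels, truth_tsv, seed=seed, params={"profile": config.get("profile")})
        outputs = [fasta, bed, cat_tsv, truth_tsv]
        for i, s in enumerate(config["samples"]):
            mixture = config["mixtures"][s["mixture"]] if isinstance(s["mixture"], str) else s["mixture"]
            design = SampleDesign(
                sample_id=s["sample_id"],
                mixture=mixture,
                depth=s.get("depth", 100),
                repeat_depth=s.get("repeat_depth", 0),
                hyper_fraction=s.get("hyper_fraction", 0.0),
                error_rate=s.get("error_rate", 0.001),
                seed=seed + 10 + i,
            )
            sim = simulate_sample(genome, repeats, catalog, truth, design, outdir)
            sim.truth.to_tsv(outdir / f"{s['sample_id']}.truth.tsv")
            outputs += [sim.sam_path, sim.fastq_path]
        record("simulate", [], {"genome": asdict(gspec)}, outputs, t0)

    def require(*paths):
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise DependencyError(f"missing upstream outputs: {missing}")

    catalog = None
    if {"quant", "sine-index", "hyper", "compose"} & set(stages):
        require(fasta, bed, cat_tsv)
        catalog = eio.read_catalog(cat_tsv)
        import pyfaidx

        fa = pyfaidx.Fasta(str(fasta))
        genome = {name: str(fa[name][:]) for name in fa.keys()}

    if "quant" in stages:
        t0 = time.time()
        counts = {}
        for sid in sample_ids:
            sam = outdir / f"{sid}.sam"
            require(sam)
            counts[sid] = count_site_bases(sam, catalog, qc)
            eio.write_tsv(counts[sid], outdir / f"{sid}.counts.tsv", seed=seed, params=asdict(qc))
        groups = config.get("groups") or {s: s for s in sample_ids}
        levels, coverage, reasons = editing_levels(counts, qc, groups)
        eio.write_tsv(levels, outdir / "levels.tsv", seed=seed, params=asdict(qc))
        eio.write_tsv(coverage, outdir / "coverage.tsv", seed=seed)
        fpkm = eio.read_fpkm(config["fpkm"]) if config.get("fpkm") else None
        cei_rows = []
        for sid in sample_ids:
            res = compute_cei(counts[sid], catalog, sample_id=sid)
            flagged = False
            if fpkm is not None and sid in fpkm.columns:
                from .quant import expression_dominance_check

                flagged, dominant, share = expression_dominance_check(fpkm[sid].dropna())
                if flagged:
                    log.warning("sample %s excluded from CEI summary: %s holds %.0f%% of FPKM",
                                sid, dominant, share * 100)
            cei_rows.append({"sample": sid, "numerator": res.numerator,
                             "denominator": res.denominator, "cei": res.cei,
                             "dominance_flagged": int(flagged)})
        cei_df = pd.DataFrame(cei_rows).set_index("sample")
        eio.write_tsv(cei_df, outdir / "cei.tsv", seed=seed)
        record(
            "quant",
            [outdir / f"{sid}.sam" for sid in sample_ids],
            asdict(qc),
            [outdir / f"{sid}.counts.tsv" for sid in sample_ids]
            + [outdir / "levels.tsv", outdir / "coverage.tsv", outdir / "cei.tsv"],
            t0,
        )

    if "sine-index" in stages or "hyper" in stages:
        rmap = build_repeat_map(genome, read_bed(bed))

    if "hyper" in stages:
        t0 = time.time()
        tindex = TransformedIndex(genome, hc.seed_length)
        rate_rows = []
        for sid in sample_ids:
            fq = outdir / f"{sid}.unmapped.fastq"
            require(fq, outdir / f"{sid}.sam")
            clusters = rescue_reads(fq, genome, hc, tindex)
            accepted = [c for c in clusters if c.accepted]
            write_rescued_sam(clusters, genome, outdir / f"{sid}.rescued.sam")
            with open(outdir / f"{sid}.clusters.tsv", "w") as fh:
                fh.write(eio.header_comment(seed, asdict(hc)))
                fh.write("read_id\tchrom\tstart\tsense\tn_ag\tn_other\taccepted\treason\n")
                for c in clusters:
                    fh.write(
                        f"{c.read_id}\t{c.chrom}\t{c.start}\t{c.sense}\t{c.n_ag}\t{c.n_other}\t{int(c.accepted)}\t{c.reason}\n"
                    )
            import pysam

            with pysam.AlignmentFile(str(outdir / f"{sid}.sam"), "r", check_sq=False) as sam:
                mapped = sum(1 for r in sam if not r.is_unmapped)
            hr = hyper_rate(len(accepted), mapped, sample_id=sid)
            rate_rows.append({"sample": sid, "accepted": hr.accepted_reads, "mapped": hr.mapped_reads, "rate": hr.rate})
            if accepted:
                prof = signature_profile(accepted, genome)
                sig = pd.DataFrame(
                    {
                        "upstream": prof.upstream,
                        "downstream": prof.downstream,
                        "background_upstream": prof.background_upstream,
                        "background_downstream": prof.background_downstream,
                    }
                )
                eio.write_tsv(sig, outdir / f"{sid}.signature.tsv", seed=seed)
        eio.write_tsv(pd.DataFrame(rate_rows).set_index("sample"), outdir / "hyper_rates.tsv", seed=seed)
        record(
            "hyper",
            [outdir / f"{sid}.unmapped.fastq" for sid in sample_ids],
            asdict(hc),
            [outdir / "hyper_rates.tsv"],
            t0,
        )

    if "sine-index" in stages:
        t0 = time.time()
        tables = {}
        for sid in sample_ids:
            sam = outdir / f"{sid}.sam"
            require(sam)
            rescued = outdir / f"{sid}.rescued.sam"
            tables[sid] = compute_editing_index(
                sam, rmap, qc, rescued=rescued if rescued.exists() else None, sample_id=sid
            )
        report = index_report(tables)
        eio.write_tsv(report, outdir / "sine_index.tsv", seed=seed, params=asdict(qc), index=False)
        record("sine-index", [outdir / f"{sid}.sam" for sid in sample_ids], asdict(qc), [outdir / "sine_index.tsv"], t0)

    if "compose" in stages:
        t0 = time.time()
        require(outdir / "levels.tsv", truth_tsv)
        levels = eio.read_tsv(outdir / "levels.tsv")
        groups = config.get("groups") or {}
        ctrl = [s for s in levels.columns if groups.get(s) == "control"]
        inj = [s for s in levels.columns if groups.get(s) == "injured"]
        if not ctrl or not inj:
            raise DependencyError("compose needs samples grouped as control/injured")
        diff = differential_editing(levels[ctrl], levels[inj])
        eio.write_tsv(diff, outdir / "differential.tsv", seed=seed)

        cell_levels = eio.read_tsv(truth_tsv)
        cond_c = levels[ctrl].mean(axis=1)
        cond_i = levels[inj].mean(axis=1)
        sine_path = outdir / "sine_index.tsv"
        repeat_deltas = None
        if sine_path.exists():
            rep = eio.read_tsv(sine_path, index_col=None)
            ag = rep[(rep["ref"] == "A") & (rep["alt"] == "G")].set_index("sample")["index"]
            rc = float(np.mean([ag[s] for s in ctrl if s in ag]))
            ri = float(np.mean([ag[s] for s in inj if s in ag]))
            from .synthetic import DEFAULT_P_REPEAT

            repeat_deltas = (
                DEFAULT_P_REPEAT["neuron"] - DEFAULT_P_REPEAT["astrocyte"],
                ri - rc,
            )
        corr = editome_correlation(
            cell_levels["neuron"], cell_levels["astrocyte"], cond_i, cond_c, repeat_deltas=repeat_deltas
        )
        eio.write_tsv(corr.pairs, outdir / "correlation_points.tsv", seed=seed, index=False)
        eio.write_tsv(
            pd.DataFrame([{"r": corr.r, "r2": corr.r2, "p": corr.p}]),
            outdir / "correlation.tsv",
            seed=seed,
            index=False,
        )
        est = estimate_fraction_change(cond_c, cond_i, cell_levels)
        eio.write_tsv(
            pd.DataFrame(
                [
                    {
                        "f_neuron_pre": est.fractions_pre.get("neuron", np.nan),
                        "f_neuron_post": est.fractions_post.get("neuron", np.nan),
                        "neuron_delta": est.neuron_delta,
                        "residual_pre": est.residual_pre,
                        "residual_post": est.residual_post,
                        "ill_conditioned": est.ill_conditioned,
                    }
                ]
            ),
            outdir / "fraction_change.tsv",
            seed=seed,
            index=False,
        )
        try:
            tree = cluster_editomes(levels)
            (outdir / "samples.nwk").write_text(tree.newick() + "\n")
        except ValueError as exc:
            log.info("clustering skipped: %s", exc)
        record(
            "compose",
            [outdir / "levels.tsv", truth_tsv],
            {},
            [outdir / "differential.tsv", outdir / "correlation.tsv", outdir / "fraction_change.tsv"],
            t0,
        )

    manifest.to_json(outdir / "manifest.json")
    return manifest


def validate_inputs(
    fasta: str | Path | None = None,
    bed: str | Path | None = None,
    catalog: str | Path | None = None,
    sam: str | Path | None = None,
) -> list[str]:
    """Report-only validation of pipeline inputs; returns violation strings."""
    report: list[str] = []
    genome = {}
    if fasta is not None:
        try:
            import pyfaidx

            fa = pyfaidx.Fasta(str(fasta))
            genome = {name: len(fa[name]) for name in fa.keys()}
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            report.append(f"{fasta}: FASTA parse error: {exc}")
    if bed is not None:
        with open(bed) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    report.append(f"{bed}:{ln}: fewer than 6 columns")
                    continue
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    report.append(f"{bed}:{ln}: non-integer coordinates")
                    continue
                if end <= start:
                    report.append(f"{bed}:{ln}: end <= start")
                if parts[5] not in "+-":
                    report.append(f"{bed}:{ln}: bad strand {parts[5]!r}")
                if genome and parts[0] not in genome:
                    report.append(f"{bed}:{ln}: chromosome {parts[0]} not in FASTA")
                elif genome and end > genome[parts[0]]:
                    report.append(f"{bed}:{ln}: interval beyond chromosome end")
    if catalog is not None:
        try:
            cat = eio.read_catalog(catalog)
        except ValueError as exc:
            report.append(str(exc))
            cat = None
        if cat is not None and genome:
            for key, row in cat.iterrows():
                if row["chrom"] not in genome:
                    report.append(f"{catalog}: site {key}: chromosome not in FASTA")
                elif not 1 <= row["pos"] <= genome[row["chrom"]]:
                    report.append(f"{catalog}: site {key}: position beyond chromosome length")
    if sam is not None:
        try:
            import pysam

            with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
                for _ in fh:
                    break
        except Exception as exc:  # noqa: BLE001
            report.append(f"{sam}: SAM parse error: {exc}")
    return report
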