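"""Generator: determinism, repeat divergence, editome presets, read-level truth."""

import numpy as np
import pandas as pd
import pytest

import editomix as em
from editomix._seq import reverse_complement
from editomix.synthetic import (
    TABLE2_INJURY,
    write_genome_fasta,
    write_repeats_bed,
)


def _bytes_of(genome, repeats, tmp_path, tag):
    fa = tmp_path / f"{tag}.fa"
    bed = tmp_path / f"{tag}.bed"
    with open(fa, "w") as fh:
        for c in sorted(genome):
            fh.write(f">{c}\n{genome[c]}\n")
    write_repeats_bed(repeats, bed)
    return fa.read_bytes(), bed.read_bytes()


def test_fixed_seed_gives_byte_identical_outputs(tmp_path):
    spec = em.GenomeSpec(seed=1)
    a = _bytes_of(*em.build_genome(spec), tmp_path, "a")
    b = _bytes_of(*em.build_genome(em.GenomeSpec(seed=1)), tmp_path, "b")
    assert a == b


def test_simulated_sam_and_fastq_deterministic(world, tmp_path):
    design = em.SampleDesign(
        sample_id="det", mixture={"neuron": 1.0}, depth=20, repeat_depth=3,
        hyper_fraction=0.005, error_rate=0.001, seed=11,
    )
    sims = [
        em.simulate_sample(world["genome"], world["repeats"], world["catalog"],
                           world["truth"], design, tmp_path / f"run{i}")
        for i in range(2)
    ]
    assert sims[0].sam_path.read_bytes() == sims[1].sam_path.read_bytes()
    assert sims[0].fastq_path.read_bytes() == sims[1].fastq_path.read_bytes()


def test_zero_divergence_copies_equal_family_consensus():
    genome, repeats = em.build_genome(em.GenomeSpec(seed=3, repeat_divergence=0.0))
    by_family = {}
    for iv in repeats:
        seq = genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        by_family.setdefault(iv.family, set()).add(seq)
    for fam, seqs in by_family.items():
        assert len(seqs) == 1, f"family {fam} copies diverged despite divergence=0"


def test_repeat_divergence_calibration():
    """Mean Hamming distance copy-vs-consensus matches the divergence rate."""
    genome, repeats = em.build_genome(
        em.GenomeSpec(seed=5, n_chromosomes=1, repeat_count=60, chrom_length=60 * 250,
                      repeat_length=200, repeat_divergence=0.1)
    )
    copies = {}
    for iv in repeats:
        seq = genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = reverse_complement(seq)
        copies.setdefault(iv.family, []).append(seq)
    dists = []
    for fam, seqs in copies.items():
        if len(seqs) < 5:
            continue
        # majority-vote consensus recovers the family sequence
        cols = np.array([[ord(c) for c in s] for s in seqs])
        consensus = np.array([np.bincount(col).argmax() for col in cols.T])
        dists.extend((cols != consensus).mean(axis=1))
    assert abs(np.mean(dists) - 0.1) < 0.02


def test_genome_spec_validation():
    with pytest.raises(ValueError, match="pack"):
        em.build_genome(em.GenomeSpec(chrom_length=1000, repeat_count=10, repeat_length=200))
    with pytest.raises(ValueError):
        em.GenomeSpec(repeat_divergence=0.5).validate()


def test_explicit_editome_rates_pass_through(world):
    cat = world["catalog"].iloc[:1]
    truth = em.make_cell_editomes(cat, {cat.index[0]: {"neuron": 0.7, "astrocyte": 0.03}})
    assert truth.levels.loc[cat.index[0], "neuron"] == 0.7
    assert truth.levels.loc[cat.index[0], "astrocyte"] == 0.03
    with pytest.raises(ValueError):
        em.make_cell_editomes(cat, {cat.index[0]: {"neuron": 1.2}})


def test_table2_preset_carries_measured_rates(world):
    truth = em.make_cell_editomes(world["catalog"], "table2")
    copa = truth.sites.index[truth.sites["gene"] == "COPA_IV"][0]
    assert truth.levels.loc[copa, "neuron"] == pytest.approx(0.031)
    assert truth.levels.loc[copa, "astrocyte"] == pytest.approx(0.1835)
    assert set(truth.sites["gene"]) == set(TABLE2_INJURY)


def test_paperlike_preset_neuron_top_at_most_sites(world):
    truth = world["truth"]
    frac = (truth.levels.idxmax(axis=1) == "neuron").mean()
    assert frac >= 0.8


def test_pure_sample_site_level_matches_binomial_truth(world, tmp_path):
    """Single site, known rate 0.5, depth 1e4: realized level within 3 SD."""
    cat = world["catalog"].iloc[:1]
    truth = em.make_cell_editomes(cat, {cat.index[0]: {"neuron": 0.5}})
    design = em.SampleDesign(sample_id="bin", mixture={"neuron": 1.0}, depth=10_000, seed=4)
    sim = em.simulate_sample(world["genome"], world["repeats"], cat, truth, design, tmp_path)
    counts = em.count_site_bases(sim.sam_path, cat)
    level = counts["n_G"].iloc[0] / (counts["n_A"].iloc[0] + counts["n_G"].iloc[0])
    assert level == pytest.approx(0.5, abs=0.015)


def test_half_half_mixture_level(world, tmp_path):
    """neuron 0.7 / astrocyte 0.03 at 50:50 gives (0.7+0.03)/2 = 0.365."""
    cat = world["catalog"].iloc[:1]
    truth = em.make_cell_editomes(cat, {cat.index[0]: {"neuron": 0.7, "astrocyte": 0.03}})
    design = em.SampleDesign(
        sample_id="mix", mixture={"neuron": 0.5, "astrocyte": 0.5}, depth=10_000, seed=8
    )
    sim = em.simulate_sample(world["genome"], world["repeats"], cat, truth, design, tmp_path)
    counts = em.count_site_bases(sim.sam_path, cat)
    level = counts["n_G"].iloc[0] / (counts["n_A"].iloc[0] + counts["n_G"].iloc[0])
    assert level == pytest.approx(0.365, abs=3 * np.sqrt(0.365 * 0.635 / 10_000))


def test_no_editing_no_errors_means_no_mismatches(world, tmp_path):
    cat = world["catalog"]
    zero = em.make_cell_editomes(cat, {k: {"neuron": 0.0} for k in cat.index})
    zero.p_repeat["neuron"] = 0.0
    design = em.SampleDesign(sample_id="clean", mixture={"neuron": 1.0}, depth=10,
                             repeat_depth=3, error_rate=0.0, seed=9)
    sim = em.simulate_sample(world["genome"], world["repeats"], cat, zero, design, tmp_path)
    import pysam

    with pysam.AlignmentFile(str(sim.sam_path), "r") as sam:
        for read in sam:
            ref = world["genome"][read.reference_name][
                read.reference_start : read.reference_end
            ]
            assert read.query_sequence == ref


def test_sam_roundtrip_counts_match_planted_truth(world, tmp_path):
    """Error-free reads: pileup counts equal the generator's truth table."""
    design = em.SampleDesign(sample_id="rt", mixture={"neuron": 1.0}, depth=40,
                             error_rate=0.0, seed=13)
    sim = em.simulate_sample(world["genome"], world["repeats"], world["catalog"],
                             world["truth"], design, tmp_path)
    counts = em.count_site_bases(sim.sam_path, world["catalog"])
    tt = sim.truth.site_counts
    assert (counts["n_G"] == tt["edited"]).all()
    assert (counts["n_total"] == tt["total"]).all()


def test_hyper_reads_only_in_fastq_with_enough_edits(neuron_sample):
    truth = neuron_sample.truth
    assert (truth.hyper_reads["n_edits"] >= 6).all()
    sam_names = set()
    import pysam

    with pysam.AlignmentFile(str(neuron_sample.sam_path), "r") as sam:
        for read in sam:
            sam_names.add(read.query_name)
    assert not (set(truth.hyper_reads["read_id"]) & sam_names)


def test_unstranded_toggle_only_changes_flags(world, tmp_path):
    """Unstranded libraries mark ~half the alignments reverse; counts are
    unchanged because SAM SEQ stays forward-strand."""
    kw = dict(sample_id="st", mixture={"neuron": 1.0}, depth=30, error_rate=0.0, seed=17)
    fwd = em.simulate_sample(world["genome"], world["repeats"], world["catalog"],
                             world["truth"], em.SampleDesign(**kw), tmp_path / "f")
    both = em.simulate_sample(world["genome"], world["repeats"], world["catalog"],
                              world["truth"], em.SampleDesign(stranded=False, **kw), tmp_path / "b")
    import pysam

    with pysam.AlignmentFile(str(both.sam_path), "r") as sam:
        flags = [r.is_reverse for r in sam]
    assert 0.3 < np.mean(flags) < 0.7
    c1 = em.count_site_bases(fwd.sam_path, world["catalog"])
    c2 = em.count_site_bases(both.sam_path, world["catalog"])
    pd.testing.assert_frame_equal(c1, c2)


def test_design_validation(world):
    with pytest.raises(ValueError, match="sum"):
        em.SampleDesign(sample_id="x", mixture={"neuron": 0.6}).validate(["neuron"])
    with pytest.raises(ValueError, match="hyper_fraction"):
        em.SampleDesign(sample_id="x", mixture={"neuron": 1.0}, hyper_fraction=0.2).validate(["neuron"])
    with pytest.raises(ValueError, match="unknown cell"):
        em.SampleDesign(sample_id="x", mixture={"ghost": 1.0}).validate(["neuron"])
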