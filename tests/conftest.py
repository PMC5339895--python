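import numpy as np
import pandas as pd
import pytest

import editomix as em

#: baseline whole-cortex composition: neurons ~half, rest split over glia,
#: microglia and endothelium
CONTROL_MIXTURE = {
    "neuron": 0.5,
    "astrocyte": 0.2,
    "opc": 0.08,
    "nfo": 0.05,
    "mo": 0.07,
    "microglia": 0.05,
    "endothelial": 0.05,
}


@pytest.fixture(scope="session")
def world():
    """Small synthetic study world shared across tests."""
    genome, repeats = em.build_genome(em.GenomeSpec(seed=1))
    catalog = em.make_site_catalog(genome, repeats, seed=2)
    truth = em.make_cell_editomes(catalog, "paperlike", seed=3)
    return {"genome": genome, "repeats": repeats, "catalog": catalog, "truth": truth}


@pytest.fixture(scope="session")
def neuron_sample(world, tmp_path_factory):
    """A pure-neuron library with repeat coverage and planted hyper reads."""
    design = em.SampleDesign(
        sample_id="neuron_pure",
        mixture={"neuron": 1.0},
        depth=60,
        repeat_depth=20,
        hyper_fraction=0.002,
        error_rate=0.001,
        seed=7,
    )
    outdir = tmp_path_factory.mktemp("neuron_sample")
    sim = em.simulate_sample(
        world["genome"], world["repeats"], world["catalog"], world["truth"], design, outdir
    )
    return sim


def write_sam(path, chrom_lengths, reads):
    """Write a toy SAM by hand: reads are (name, chrom, pos0, seq, quals, tags)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for name, chrom, pos0, seq, quals, *rest in reads:
            cigar = rest[0] if rest else f"{len(seq)}M"
            tags = rest[1] if len(rest) > 1 else ["NH:i:1"]
            qstr = "".join(chr(q + 33) for q in quals)
            fields = [name, "0", chrom, str(pos0 + 1), "255", cigar, "*", "0", "0", seq, qstr] + tags
            fh.write("\t".join(fields) + "\n")
    return path


@pytest.fixture
def toy_catalog():
    cat = pd.DataFrame(
        {
            "chrom": ["chrT", "chrT"],
            "pos": [11, 31],
            "strand": ["+", "-"],
            "gene": ["GENEA", "GENEB"],
            "conserved": [1, 1],
        }
    )
    cat.index = [em.synthetic.site_key(r.chrom, r.pos, r.strand) for r in cat.itertuples()]
    cat.index.name = "site"
    return cat
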