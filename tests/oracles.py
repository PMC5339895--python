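"""Independent brute-force oracles used only by the test suite.

These re-derive per-site base counts and repeat mismatch indices by parsing
SAM text directly and scanning read strings position by position — no
shared code with the package's counting machinery.
"""

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def parse_sam_text(path):
    """Minimal SAM text parser: yields dicts for mapped primary reads."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 0x4 or flag & 0x100 or flag & 0x800:
                continue
            tags = {t.split(":")[0]: t.split(":")[2] for t in f[11:]}
            reads.append(
                {
                    "name": f[0],
                    "chrom": f[2],
                    "pos0": int(f[3]) - 1,
                    "cigar": f[5],
                    "seq": f[9],
                    "quals": [ord(c) - 33 for c in f[10]],
                    "nh": int(tags.get("NH", 1)),
                }
            )
    return reads


def _aligned_pairs(read):
    """(query index, reference position) pairs from a simple CIGAR."""
    import re

    pairs = []
    q = 0
    r = read["pos0"]
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", read["cigar"]):
        n = int(n)
        if op in "M=X":
            for i in range(n):
                pairs.append((q + i, r + i))
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
    return pairs


def brute_site_counts(sam_path, catalog, min_phred=25, unique_only=True):
    """Per-site (n_A, n_G, n_other) by scanning every read base."""
    counts = {key: [0, 0, 0] for key in catalog.index}
    sites = {
        (row["chrom"], int(row["pos"]) - 1): (key, row["strand"])
        for key, row in catalog.iterrows()
    }
    for read in parse_sam_text(sam_path):
        if unique_only and read["nh"] > 1:
            continue
        for q, r in _aligned_pairs(read):
            hit = sites.get((read["chrom"], r))
            if hit is None:
                continue
            key, strand = hit
            if read["quals"][q] <= min_phred:
                continue
            base = read["seq"][q]
            if base not in "ACGT":
                continue
            if strand == "-":
                base = COMP[base]
            if base == "A":
                counts[key][0] += 1
            elif base == "G":
                counts[key][1] += 1
            else:
                counts[key][2] += 1
    return counts


def brute_mismatch_indices(sam_paths, genome, repeats, min_phred=25):
    """All 12 mismatch numerators/denominators over repeat positions."""
    membership = {}
    for iv in repeats:
        for p in range(iv.start, iv.end):
            membership[(iv.chrom, p)] = iv.strand
    numer = {}
    denom = {b: 0 for b in "ACGT"}
    if isinstance(sam_paths, (str, bytes)) or hasattr(sam_paths, "__fspath__"):
        sam_paths = [sam_paths]
    for sam_path in sam_paths:
        for read in parse_sam_text(sam_path):
            for q, r in _aligned_pairs(read):
                strand = membership.get((read["chrom"], r))
                if strand is None:
                    continue
                if read["quals"][q] <= min_phred:
                    continue
                ref = genome[read["chrom"]][r]
                alt = read["seq"][q]
                if ref not in "ACGT" or alt not in "ACGT":
                    continue
                if strand == "-":
                    ref, alt = COMP[ref], COMP[alt]
                denom[ref] += 1
                if alt != ref:
                    numer[(ref, alt)] = numer.get((ref, alt), 0) + 1
    return numer, denom
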