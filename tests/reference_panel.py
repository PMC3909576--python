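"""Published reference values for the 16-locus SSR panel and its 18 cultivars.

These printed summary numbers serve as inputs for arithmetic-anchor
checks: per-locus total allele counts, the fixed-allele accounting
(which cultivars are monomorphic for which allele at which locus), the
allelic ranges in bp, and the per-cultivar diversity summary columns.
"""

# locus -> (allelic range lo, hi, total allele count)
LOCI = {
    "mPdCIR10": (138, 176, 6),
    "mPdCIR15": (142, 157, 5),
    "mPdCIR25": (219, 257, 6),
    "mPdCIR32": (306, 321, 5),
    "mPdCIR70": (205, 227, 9),
    "mPdCIR78": (126, 173, 11),
    "mPdCIR85": (175, 199, 8),
    "mPdCIR93": (181, 197, 7),
    "PDCAT1": (103, 123, 4),
    "PDCAT2": (186, 209, 7),
    "PDCAT6": (142, 172, 7),
    "PDCAT8": (222, 258, 6),
    "PDCAT11": (154, 177, 6),
    "PDCAT14": (141, 163, 9),
    "PDCAT17": (131, 157, 6),
    "PDCAT18": (123, 149, 8),
}

CULTIVAR_CODES = [
    "A", "Ba", "Ber", "Bes", "D", "Hal", "Ham", "K", "N",
    "O", "S", "Sa", "So", "Tag", "Tal", "Tam", "Tas", "Z",
]

# locus -> {fixed allele size: cultivars monomorphic for it}
FIXED_ALLELES = {
    "mPdCIR10": {154: ["A", "Ber", "D", "Hal", "O", "S", "Tag", "Tam"]},
    "mPdCIR15": {142: ["Tag"], 157: ["Z"]},
    "mPdCIR25": {249: ["Ber"]},
    "mPdCIR32": {316: ["S", "Z"], 309: ["Tal"]},
    "mPdCIR70": {213: ["D"]},
    "mPdCIR78": {136: ["Tag"], 153: ["S"]},
    "mPdCIR85": {175: ["O"], 181: ["Hal"]},
    "mPdCIR93": {197: ["O"]},
    "PDCAT1": {103: ["Tam", "Z"], 105: ["Bes"], 119: ["A", "D", "Hal", "S"], 123: ["Tal"]},
    "PDCAT2": {186: ["Z"], 206: ["Bes"]},
    "PDCAT6": {150: ["Z"], 158: ["O"]},
    "PDCAT8": {246: ["S"], 252: ["Tal"]},
    "PDCAT11": {154: ["Z"], 159: ["S"]},
    "PDCAT14": {155: ["D", "Hal", "O", "Tag", "Tal", "Tam"]},
    "PDCAT17": {141: ["S"], 147: ["A", "D", "K", "N", "O"], 157: ["Tal"]},
    "PDCAT18": {},
}

# per-cultivar published summary columns: Na, F, P%
CULTIVAR_SUMMARY = {
    "Abel": (1.938, -0.973, 75.00),
    "Bamour": (2.813, -0.329, 100.00),
    "Berni": (2.625, -0.790, 87.50),
    "Bestian": (2.750, -0.855, 93.75),
    "Deglet": (1.688, -0.992, 62.50),
    "Halima": (1.750, -1.000, 75.00),
    "Hamria": (3.313, -0.842, 100.00),
    "Kathari": (2.500, -0.897, 93.75),
    "Noyat Meka": (2.563, -0.578, 93.75),
    "Omglaib": (1.563, -1.000, 56.25),
    "Saiedi": (1.813, -1.000, 81.25),
    "Saila": (1.625, -1.000, 62.50),
    "Sokeri": (5.125, -0.079, 100.00),
    "Tagiat": (1.813, -1.000, 81.25),
    "Talis": (1.625, -1.000, 62.50),
    "Tameg": (2.750, -0.802, 81.25),
    "Tasferit": (3.938, -0.319, 100.00),
    "Zebur": (1.625, -1.000, 62.50),
}

# identification key: per-locus labeled allele counts of the three key loci
KEY_ALLELE_COUNTS = (10, 7, 6)


def allele_count_table():
    """Toy genotype rows exhibiting exactly the published allele count per locus.

    Returns (rows, locus_names) for conftest-style table construction:
    samples pair consecutive ladder alleles so every published allele is
    observed at least once.
    """
    max_samples = max((count + 1) // 2 for _, _, count in LOCI.values())
    ladders = {}
    for locus, (lo, _hi, count) in LOCI.items():
        ladders[locus] = [lo + 2 * k for k in range(count)]
    rows = []
    for s in range(max_samples):
        calls = {}
        for locus, ladder in ladders.items():
            a = ladder[(2 * s) % len(ladder)]
            b = ladder[(2 * s + 1) % len(ladder)]
            calls[locus] = tuple(sorted((a, b)))
        rows.append((f"ref{s + 1}", "REF", calls))
    return rows, list(LOCI)


def fixed_allele_table():
    """Toy genotype rows realizing the published fixed-allele accounting.

    Every cultivar listed as fixed for an allele is homozygous for it;
    all other cultivars carry a range-endpoint heterozygote at that
    locus, so nothing else is fixed.  Two samples per cultivar.
    """
    rows = []
    for code in CULTIVAR_CODES:
        calls = {}
        for locus, (lo, hi, _count) in LOCI.items():
            fixed = next(
                (a for a, cvs in FIXED_ALLELES[locus].items() if code in cvs), None
            )
            calls[locus] = (fixed, fixed) if fixed is not None else (lo, hi)
        for rep in (1, 2):
            rows.append((f"{code}_{rep}", code, dict(calls)))
    return rows, list(LOCI)


def key_panel_table():
    """18 cultivars over three loci using exactly 10, 7 and 6 alleles.

    Genotypes are residue-coded so all cultivar profiles are pairwise
    distinct ((i mod 10, i mod 7) is injective for i < 18).
    """
    n10, n7, n6 = KEY_ALLELE_COUNTS
    ladder1 = [100 + 2 * k for k in range(n10)]
    ladder2 = [200 + 2 * k for k in range(n7)]
    ladder3 = [300 + 2 * k for k in range(n6)]
    rows = []
    for i in range(18):
        calls = {
            "K1": tuple(sorted((ladder1[i % n10], ladder1[(i + 3) % n10]))),
            "K2": tuple(sorted((ladder2[i % n7], ladder2[(i + 2) % n7]))),
            "K3": tuple(sorted((ladder3[i % n6], ladder3[(i + 1) % n6]))),
        }
        rows.append((f"cv{i + 1:02d}_1", f"cv{i + 1:02d}", calls))
    return rows, ["K1", "K2", "K3"]
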