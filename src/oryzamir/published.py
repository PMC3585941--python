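"""Published per-category read counts used as arithmetic inputs.

These are the printed unique-tag and total-read counts per annotation
category for the four grain-filling libraries (5, 7, 12 and 17 days after
fertilization), plus the in-text known-miRNA detection tallies.  They are
inputs to the summary arithmetic (percentage reproduction), not outputs of
this package.
"""

LIBRARIES = ("5DAF", "7DAF", "12DAF", "17DAF")

#: category -> library -> (unique_tags, total_reads)
CATEGORY_COUNTS = {
    "total_clean": {"5DAF": (4707574, 17029030), "7DAF": (5109716, 15582300),
                    "12DAF": (6367974, 15860692), "17DAF": (6302095, 15174972)},
    "match_genome": {"5DAF": (3670743, 15561105), "7DAF": (4264360, 14321820),
                     "12DAF": (5470464, 14454514), "17DAF": (5417780, 13707910)},
    "miRNA": {"5DAF": (6129, 651290), "7DAF": (7255, 1374266),
              "12DAF": (8245, 2450748), "17DAF": (7120, 1724461)},
    "siRNA": {"5DAF": (204284, 2071100), "7DAF": (140816, 915973),
              "12DAF": (117516, 564923), "17DAF": (101584, 445278)},
    "rRNA": {"5DAF": (68797, 834858), "7DAF": (101454, 2001144),
             "12DAF": (70404, 885193), "17DAF": (92539, 1310619)},
    "snRNA": {"5DAF": (2578, 8392), "7DAF": (2636, 12164),
              "12DAF": (1588, 3765), "17DAF": (1649, 4979)},
    "snoRNA": {"5DAF": (4348, 11898), "7DAF": (4117, 9137),
               "12DAF": (3142, 5373), "17DAF": (2531, 4070)},
    "tRNA": {"5DAF": (12375, 244390), "7DAF": (14750, 474879),
             "12DAF": (14654, 401166), "17DAF": (14482, 423497)},
    "repeat": {"5DAF": (1344549, 3465734), "7DAF": (1641597, 3423279),
               "12DAF": (2269893, 4447541), "17DAF": (2271866, 4543119)},
    "exon_antisense": {"5DAF": (125600, 645276), "7DAF": (161670, 729322),
                       "12DAF": (210993, 924274), "17DAF": (205936, 798123)},
    "exon_sense": {"5DAF": (197626, 753018), "7DAF": (257760, 657653),
                   "12DAF": (309246, 629469), "17DAF": (315164, 603255)},
    "intron_antisense": {"5DAF": (134049, 582606), "7DAF": (142854, 384622),
                         "12DAF": (181547, 319280), "17DAF": (182120, 301734)},
    "intron_sense": {"5DAF": (139087, 580316), "7DAF": (156079, 435601),
                     "12DAF": (200409, 406011), "17DAF": (197842, 382147)},
    "no_annotation": {"5DAF": (2468152, 7180152), "7DAF": (2478728, 5164260),
                      "12DAF": (2980337, 4822949), "17DAF": (2909262, 4633690)},
}

#: published percentages: category -> library -> (unique_pct, total_pct)
PRINTED_PCT = {
    "total_clean": {"5DAF": (100.00, 100.00), "7DAF": (100.00, 100.00), "12DAF": (100.00, 100.00), "17DAF": (100.00, 100.00)},
    "match_genome": {"5DAF": (77.98, 91.38), "7DAF": (83.46, 91.91), "12DAF": (85.91, 91.13), "17DAF": (85.97, 90.33)},
    "miRNA": {"5DAF": (0.13, 3.82), "7DAF": (0.14, 8.82), "12DAF": (0.13, 15.45), "17DAF": (0.11, 11.36)},
    "siRNA": {"5DAF": (4.34, 12.16), "7DAF": (2.76, 5.88), "12DAF": (1.85, 3.56), "17DAF": (1.61, 2.93)},
    "rRNA": {"5DAF": (1.46, 4.90), "7DAF": (1.99, 12.84), "12DAF": (1.11, 5.58), "17DAF": (1.47, 8.64)},
    "snRNA": {"5DAF": (0.05, 0.05), "7DAF": (0.05, 0.08), "12DAF": (0.02, 0.02), "17DAF": (0.03, 0.03)},
    "snoRNA": {"5DAF": (0.09, 0.07), "7DAF": (0.08, 0.06), "12DAF": (0.05, 0.03), "17DAF": (0.04, 0.03)},
    "tRNA": {"5DAF": (0.26, 1.44), "7DAF": (0.29, 3.05), "12DAF": (0.23, 2.53), "17DAF": (0.23, 2.79)},
    "repeat": {"5DAF": (28.56, 20.35), "7DAF": (32.13, 21.97), "12DAF": (35.65, 28.04), "17DAF": (36.05, 29.94)},
    "exon_antisense": {"5DAF": (2.67, 3.79), "7DAF": (3.16, 4.68), "12DAF": (3.31, 5.83), "17DAF": (3.27, 5.26)},
    "exon_sense": {"5DAF": (4.20, 4.42), "7DAF": (5.04, 4.22), "12DAF": (4.86, 3.97), "17DAF": (5.00, 3.98)},
    "intron_antisense": {"5DAF": (2.85, 3.42), "7DAF": (2.80, 2.47), "12DAF": (2.85, 2.01), "17DAF": (2.89, 1.99)},
    "intron_sense": {"5DAF": (2.95, 3.41), "7DAF": (3.05, 2.80), "12DAF": (3.15, 2.56), "17DAF": (3.14, 2.52)},
    "no_annotation": {"5DAF": (52.43, 42.16), "7DAF": (48.51, 33.14), "12DAF": (46.80, 30.41), "17DAF": (46.16, 30.54)},
}

#: printed percentages for the two roll-up rows (total-read basis)
MATCH_GENOME_TOTAL_PCT = {"5DAF": 91.38, "7DAF": 91.91,
                          "12DAF": 91.13, "17DAF": 90.33}
MATCH_GENOME_UNIQUE_PCT = {"5DAF": 77.98, "7DAF": 83.46,
                           "12DAF": 85.91, "17DAF": 85.97}

#: known-miRNA detection tallies: per-library detected, all-library union,
#: shared by all four libraries
KNOWN_DETECTED = {"5DAF": 380, "7DAF": 402, "12DAF": 390, "17DAF": 392}
KNOWN_UNION = 434
KNOWN_SHARED = 354
KNOWN_SHARED_PCT = 81.57

#: per-transition differential-expression tallies (significant, up, down)
DE_TALLIES = {"5DAF->7DAF": (107, 94, 13),
              "7DAF->12DAF": (67, 48, 19),
              "12DAF->17DAF": (47, 14, 33)}
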