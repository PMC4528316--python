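"""Reference QTL interval coordinates for maize flowering time (FT) and
plant height (PH) scans: (chrom, left bp, right bp, peak bp, published
rounded length in kb).  Used to validate interval summarisation and
overlap reporting against independently published roundings."""

FLOWERING_TIME_REGIONS = [
    ("1", 17_714_079, 22_596_124, 18_463_651, 4_882),
    ("1", 180_711_478, 183_050_137, 181_687_511, 2_339),
    ("2", 19_435_989, 19_451_856, 19_443_208, 16),
    ("2", 233_684_368, 234_219_869, 234_209_964, 536),
    ("4", 14_822_931, 17_108_700, 16_180_806, 2_286),
    ("5", 127_205_233, 127_239_082, 127_215_227, 34),
    ("5", 175_599_023, 186_393_293, 178_591_431, 10_794),
    ("6", 146_682_333, 147_926_947, 146_815_395, 1_245),
    ("7", 27_603_027, 27_613_362, 27_607_683, 10),
    ("7", 39_302_108, 39_309_960, 39_306_816, 8),
    ("8", 18_487_954, 21_420_111, 21_411_057, 2_932),
    ("8", 123_504_621, 142_361_278, 131_086_800, 18_857),
    ("10", 99_225_452, 102_316_547, 102_314_009, 3_091),
    ("10", 132_510_585, 132_547_745, 132_528_197, 37),
]

PLANT_HEIGHT_REGIONS = [
    ("3", 131_761_170, 133_787_782, 133_783_580, 2_027),
    ("4", 205_171_472, 226_328_731, 215_273_358, 21_157),
    ("5", 175_750_134, 175_756_910, 175_754_067, 7),
    ("5", 180_878_329, 180_885_452, 180_882_909, 7),
    ("6", 138_185_595, 147_926_947, 143_999_660, 9_741),
    ("8", 92_560_823, 92_576_189, 92_568_159, 15),
    ("9", 38_353_868, 38_359_043, 38_357_148, 5),
    ("9", 61_337_181, 61_343_573, 61_340_803, 6),
    ("9", 81_804_594, 82_892_514, 81_814_361, 1_088),
    ("9", 100_914_404, 103_222_106, 100_917_919, 2_308),
    ("9", 113_791_080, 114_932_420, 114_276_702, 1_141),
    ("9", 121_580_239, 125_181_457, 122_087_889, 3_601),
    ("9", 130_719_322, 130_920_301, 130_885_891, 201),
]

ALL_REGIONS = FLOWERING_TIME_REGIONS + PLANT_HEIGHT_REGIONS

# a 1.5-LOD linkage support interval contained in the second FT region on
# chromosome 8, for overlap-report checks
LINKAGE_INTERVAL_CHR8 = ("8", 127_700_000, 133_050_000)
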