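"""Analysis defaults shared by the library and the CLI.

Every threshold used by the pipeline lives here so that configuration,
documentation and tests draw from a single table.
"""

# Defaults for the core differential-methylation workflow.
DEFAULTS = {
    "tile_size": 100,          # bp per tiling window (non-overlapping)
    "step": 100,               # window step; v1 supports step == tile_size only
    "min_cpgs": 2,             # eligible CpGs required per tile
    "min_cov": 10,             # per-sample coverage floor for tile CpGs,
                               # pooled per-group floor for DMCs
    "min_diff": 10.0,          # percentage-point difference floor
    "q_threshold": 0.01,       # BH FDR cutoff
    "gap": 100,                # bp merge distance for DMC clustering (inclusive)
    "flank": 1000,             # bp flank for flanked overlap counting
    "fold_threshold": 5.0,     # expression fold-change cutoff (strict >)
    "background_n": 50000,     # random genome bins drawn for backgrounds
    "promoter_window": 1000,   # bp either side of TSS
    "tts_window": 1000,        # bp either side of TTS
    "shore_max": 2000,         # bp: island edge distance for shores
    "shelf_max": 4000,         # bp: island edge distance for shelves
    "genome_bin": 1000,        # bp genome bins for timing backgrounds
    "track_min_cov": 5,        # coverage floor for WGBS-analog tracks
    "late_max_e16": 25.0,      # timing: late regions stay at/below this at E16.5
    "min_gain": 40.0,          # timing: late regions gain at least this after E16.5
    "early_min_e16": 60.0,     # timing: early regions reach this by E16.5
    "drop_threshold": 20.0,    # KO comparison: percentage-point drop counted
}

# Magnitude histogram bin edges (percentage points, lower-inclusive).
MAGNITUDE_BINS = (10.0, 15.0, 20.0, 25.0, 30.0, 40.0)

#: LINE-1 subfamilies treated as evolutionarily young by default.
YOUNG_LINE_SUBFAMILIES = (
    "L1MdA_I",
    "L1MdTf_I",
    "L1MdTf_II",
    "L1MdA_II",
    "L1MdGf_I",
    "L1MdTf_III",
    "L1MdGf_II",
    "L1MdA_III",
)

#: Ordered developmental timepoint labels used by the timing module.
TIMEPOINTS = ("E13.5", "E16.5", "P0", "sperm")

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "other")

GROUPS = ("control", "mutant")
COHORTS = ("F1", "F2", "MatDef", "custom")
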