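"""Default 22-event panel definition with synthetic placeholder sequences.

The shipped panel names the cassette-exon events of the published DM1
biomarker panel (CLCN1 e7a, CACNA1S e29, INSR e11, ...) together with
per-event four-parameter-logistic (4PL) dose-response parameters that the
synthetic cohort generator uses as ground truth.  Isoform sequences and
genome coordinates are SYNTHETIC placeholders generated deterministically
from each event id: real panel sequences/coordinates come from the assay's
supplementary design files and can be supplied by the user via
``load_panel``.

Column order: event_id, gene_symbol, cassette_label, chrom, strand,
cassette_length (nt), multiplex_group, bottom, top, ec50, slope.  ``bottom``
is the 4PL asymptote at zero MBNL activity (the disease end of the
spectrum) and ``top`` the asymptote at high activity (healthy adults), so
events with ``bottom > top`` gain exon inclusion in DM1 ("up" events).

EC50 values span the published sensitivity spectrum: the five lowest
(0.263-0.390) are late responders, the five highest (0.745-1.03) early
responders, and the 12 intermediate values give a panel median EC50 of
0.619.
"""

from __future__ import annotations

# fmt: off
DEFAULT_EVENT_TABLE: list[tuple[str, str, str, str, str, int, str, float, float, float, float]] = [
    # event_id      gene       label  chrom   str  len  mux  bottom  top    ec50   slope
    ("CLCN1_e7a",   "CLCN1",    "e7a",  "chr7",  "+",  79, "A", 0.80, 0.10, 0.600, 2.5),
    ("CACNA1S_e29", "CACNA1S",  "e29",  "chr1",  "-",  57, "B", 0.15, 0.85, 0.638, 3.0),
    ("INSR_e11",    "INSR",     "e11",  "chr19", "-",  36, "A", 0.25, 0.80, 0.800, 2.0),
    ("ATP2A1_e22",  "ATP2A1",   "e22",  "chr16", "-",  42, "B", 0.10, 0.90, 0.540, 3.5),
    ("MBNL1_e5",    "MBNL1",    "e5",   "chr3",  "+",  54, "A", 0.70, 0.08, 0.570, 2.5),
    ("BIN1_e11",    "BIN1",     "e11",  "chr2",  "-",  45, "B", 0.20, 0.85, 0.290, 3.0),
    ("ANK2_e21",    "ANK2",     "e21",  "chr4",  "-", 102, "A", 0.25, 0.80, 0.263, 2.8),
    ("RYR1_e70",    "RYR1",     "e70",  "chr19", "+",  15, "B", 0.20, 0.75, 0.355, 2.2),
    ("VPS39_e3",    "VPS39",    "e3",   "chr15", "-",  33, "A", 0.15, 0.70, 0.320, 2.6),
    ("KIF13A_e32",  "KIF13A",   "e32",  "chr6",  "-", 120, "B", 0.20, 0.80, 0.470, 2.4),
    ("NFIX_e7",     "NFIX",     "e7",   "chr19", "-", 123, "A", 0.25, 0.85, 0.505, 2.8),
    ("CAMK2B_e13",  "CAMK2B",   "e13",  "chr7",  "-",  33, "B", 0.75, 0.15, 0.690, 1.8),
    ("CCPG1_e2",    "CCPG1",    "e2",   "chr15", "-",  75, "A", 0.80, 0.20, 0.870, 1.6),
    ("DMD_e78",     "DMD",      "e78",  "chrX",  "-",  32, "B", 0.35, 0.90, 0.710, 1.7),
    ("GOLGA4_e3",   "GOLGA4",   "e3",   "chr3",  "+",  51, "A", 0.60, 0.10, 0.725, 1.5),
    ("MBNL2_e5",    "MBNL2",    "e5",   "chr13", "-",  54, "B", 0.65, 0.10, 0.660, 2.2),
    ("LDB3_e11",    "LDB3",     "e11",  "chr10", "+",  69, "A", 0.78, 0.12, 0.430, 2.9),
    ("PDLIM3_e5",   "PDLIM3",   "e5",   "chr4",  "-",  30, "B", 0.18, 0.72, 0.390, 2.4),
    ("TNNT3_eF",    "TNNT3",    "eF",   "chr11", "+",  39, "A", 0.55, 0.05, 0.735, 1.9),
    ("SOS1_e25",    "SOS1",     "e25",  "chr2",  "-",  75, "B", 0.30, 0.78, 0.950, 1.8),
    ("MAPT_e3",     "MAPT",     "e3",   "chr17", "+",  87, "A", 0.70, 0.18, 1.030, 1.5),
    ("NCOR2_e45a",  "NCOR2",    "e45a", "chr12", "-",  60, "B", 0.28, 0.82, 0.745, 2.0),
]
# fmt: on

#: Flank length (nt) on each side of the cassette in the synthetic amplicons.
#: 100 nt keeps the exclusion amplicon (200 nt) longer than a 151 nt read.
DEFAULT_FLANK_LEN = 100

#: Activity at which the shipped reference Psi_DM95 placeholder is evaluated:
#: 5th percentile of the default DM1 activity distribution Uniform(0.05, 1).
SEVERE_ACTIVITY = 0.0975

#: The five panel events used as latent-class indicators (modest pairwise
#: correlation with the composite).
LCA_INDICATOR_EVENTS = ("CAMK2B_e13", "CCPG1_e2", "DMD_e78", "INSR_e11", "GOLGA4_e3")
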