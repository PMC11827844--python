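import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _bruteforce oracle

import spliceindex as si


TOY_SPECS = [
    ("EVA_e1", 20, 0.2, 0.8),
    ("EVB_e1", 30, 0.7, 0.1),
    ("EVC_e1", 40, 0.15, 0.9),
    ("EVD_e1", 25, 0.5, 0.95),
    ("EVE_e1", 35, 0.6, 0.05),
]


@pytest.fixture(scope="session")
def toy_panel() -> si.Panel:
    """Five synthetic events with short flanks: fast to align exhaustively."""
    return si.synthetic_panel(TOY_SPECS, flank_len=40, panel_name="toy5", version="t1")


@pytest.fixture(scope="session")
def panel22() -> si.Panel:
    return si.default_panel()


def simulate_library(panel, proportions, totals, read_length=60, error_rate=0.01, seed=7, tmpdir=None):
    """Paired FASTQ from known per-event inclusion proportions; returns
    (r1 path, r2 path, expected (inc, exc) counts per event)."""
    counts = {}
    for e, p, t in zip(panel, proportions, totals):
        inc = int(round(p * t))
        counts[e.event_id] = (inc, t - inc)
    r1 = str(tmpdir / "r1.fastq")
    r2 = str(tmpdir / "r2.fastq")
    si.simulate_reads(counts, panel, r1, r2, read_length=read_length, error_rate=error_rate, seed=seed)
    return r1, r2, counts


def read_pairs(r1, r2):
    from Bio import SeqIO

    return list(
        zip(
            (str(r.seq) for r in SeqIO.parse(r1, "fastq")),
            (str(r.seq) for r in SeqIO.parse(r2, "fastq")),
        )
    )
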