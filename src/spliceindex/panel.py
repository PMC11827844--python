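"""Splice-event panel data model.

A panel is an ordered collection of skipped-exon (cassette) events.  Each
event carries the two amplicon isoform sequences the targeted assay
produces -- inclusion (upstream flank + cassette + downstream flank) and
exclusion (upstream flank + downstream flank) -- plus the normative
reference inclusion levels used to normalize per-sample Psi into the
composite Splice Index.

Sequences are stored in transcript orientation (minus-strand events are
already reverse-complemented), so downstream read classification never
branches on strand.  Genomic coordinates are 0-based half-open on the
forward genomic strand.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._defaults import (
    DEFAULT_EVENT_TABLE,
    DEFAULT_FLANK_LEN,
    SEVERE_ACTIVITY,
)

__all__ = [
    "DiseaseDirection",
    "SpliceEvent",
    "Panel",
    "PanelError",
    "load_panel",
    "validate_panel",
    "write_reference_fasta",
    "write_panel_config",
    "default_panel",
    "synthetic_panel",
]

_BASES = np.array(list("ACGT"))


class PanelError(ValueError):
    """Raised when a panel configuration is missing data or inconsistent."""


class DiseaseDirection(str, Enum):
    """Sign of the DM1 shift in exon inclusion relative to healthy adults."""

    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class SpliceEvent:
    """One cassette-exon event of the amplicon panel.

    ``inclusion_seq``/``exclusion_seq`` are the amplicon isoform sequences
    sharing identical upstream and downstream flanks.  ``psi_median_control``
    and ``psi_dm95`` are the normative reference values (median inclusion in
    unaffected adults; severity-oriented 95th percentile in DM1) bounding
    the per-event normalization.
    """

    event_id: str
    gene_symbol: str
    cassette_label: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    inclusion_seq: str
    exclusion_seq: str
    multiplex_group: str
    psi_median_control: float
    psi_dm95: float

    @property
    def cassette_length(self) -> int:
        return self.exon_end - self.exon_start

    @property
    def disease_direction(self) -> DiseaseDirection:
        # Derived, never user-entered: keeps the sign consistent with the
        # reference values by construction.
        if self.psi_dm95 > self.psi_median_control:
            return DiseaseDirection.UP
        return DiseaseDirection.DOWN

    @property
    def flank_up_len(self) -> int:
        """Length of the shared upstream flank (maximal common prefix,
        capped at the exclusion amplicon length)."""
        inc, exc = self.inclusion_seq, self.exclusion_seq
        n = 0
        limit = min(len(inc), len(exc))
        while n < limit and inc[n] == exc[n]:
            n += 1
        return min(n, len(exc))

    @property
    def flank_down_len(self) -> int:
        return len(self.exclusion_seq) - self.flank_up_len

    def junctions(self, isoform: str) -> tuple[int, ...]:
        """Discriminating junction positions (0-based, between bases) in the
        requested isoform sequence.

        Inclusion has two (flank->cassette and cassette->flank); exclusion
        one (flank->flank).
        """
        up = self.flank_up_len
        if isoform == "inclusion":
            return (up, up + self.cassette_length)
        if isoform == "exclusion":
            return (up,)
        raise ValueError(f"unknown isoform {isoform!r}")

    def reference_span(self) -> float:
        return self.psi_dm95 - self.psi_median_control


@dataclass(frozen=True)
class Panel:
    """Ordered, uniquely identified collection of splice events."""

    events: tuple[SpliceEvent, ...]
    panel_name: str = "panel"
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise PanelError(f"duplicate event ids: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.events]

    def get(self, event_id: str) -> SpliceEvent:
        for e in self.events:
            if e.event_id == event_id:
                return e
        raise KeyError(event_id)


# ---------------------------------------------------------------------------
# validation

def validate_panel(panel: Panel, anchor: int = 6) -> list[str]:
    """Check every panel invariant; return diagnostics (empty iff valid).

    Each diagnostic names the offending event and the violated invariant.
    Junction k-mers (``anchor`` nt each side) must be unique within the
    event's two isoforms so that junction-spanning reads are discriminating.
    """
    diags: list[str] = []
    for e in panel:
        inc, exc = e.inclusion_seq, e.exclusion_seq
        if len(inc) - len(exc) != e.cassette_length:
            diags.append(
                f"{e.event_id}: isoform length difference "
                f"{len(inc) - len(exc)} != cassette_length {e.cassette_length}"
            )
            continue
        up, down = e.flank_up_len, e.flank_down_len
        if down < 0 or inc[:up] != exc[:up] or (down > 0 and inc[-down:] != exc[-down:]):
            diags.append(f"{e.event_id}: flank mismatch between isoforms")
            continue
        if e.reference_span() == 0:
            diags.append(f"{e.event_id}: zero normalization span (psi_dm95 == psi_median_control)")
        for v, name in ((e.psi_median_control, "psi_median_control"), (e.psi_dm95, "psi_dm95")):
            if not 0.0 <= v <= 1.0:
                diags.append(f"{e.event_id}: {name}={v} outside [0, 1]")
        both = inc + "#" + exc
        for iso, seq in (("inclusion", inc), ("exclusion", exc)):
            for j in e.junctions(iso):
                if j - anchor < 0 or j + anchor > len(seq):
                    diags.append(f"{e.event_id}: junction at {j} too close to {iso} end for anchor {anchor}")
                    continue
                kmer = seq[j - anchor : j + anchor]
                if both.count(kmer) != 1:
                    diags.append(
                        f"{e.event_id}: {iso} junction {2 * anchor}-mer at {j} not unique within isoforms"
                    )
    return diags


# ---------------------------------------------------------------------------
# IO

def write_reference_fasta(panel: Panel, path: str | os.PathLike) -> None:
    """Write isoform sequences as ``<event_id>_INC`` / ``<event_id>_EXC``
    FASTA records in panel order."""
    records = []
    for e in panel:
        records.append(SeqRecord(Seq(e.inclusion_seq), id=f"{e.event_id}_INC", description=""))
        records.append(SeqRecord(Seq(e.exclusion_seq), id=f"{e.event_id}_EXC", description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_panel_config(panel: Panel, path: str | os.PathLike) -> None:
    """Write the JSON panel configuration (everything except sequences)."""
    doc = {
        "panel_name": panel.panel_name,
        "version": panel.version,
        "events": [
            {
                "event_id": e.event_id,
                "gene_symbol": e.gene_symbol,
                "cassette_label": e.cassette_label,
                "chrom": e.chrom,
                "strand": e.strand,
                "exon_start": e.exon_start,
                "exon_end": e.exon_end,
                "multiplex_group": e.multiplex_group,
                "psi_median_control": e.psi_median_control,
                "psi_dm95": e.psi_dm95,
            }
            for e in panel
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_panel(config_path: str | os.PathLike, references_path: str | os.PathLike) -> Panel:
    """Load and validate a panel from a JSON config plus an isoform FASTA.

    The FASTA must hold two records per event, ``<event_id>_INC`` and
    ``<event_id>_EXC``.  Raises :class:`PanelError` naming the event on any
    missing isoform, duplicate id, or invariant violation.
    """
    with open(config_path) as fh:
        doc = json.load(fh)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(references_path), "fasta")}
    events = []
    for entry in doc["events"]:
        eid = entry["event_id"]
        inc = seqs.get(f"{eid}_INC")
        exc = seqs.get(f"{eid}_EXC")
        if inc is None or exc is None:
            missing = "_INC" if inc is None else "_EXC"
            raise PanelError(f"event {eid}: missing isoform record {eid}{missing} in {references_path}")
        events.append(
            SpliceEvent(
                event_id=eid,
                gene_symbol=entry["gene_symbol"],
                cassette_label=entry["cassette_label"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exon_start=int(entry["exon_start"]),
                exon_end=int(entry["exon_end"]),
                inclusion_seq=inc,
                exclusion_seq=exc,
                multiplex_group=entry["multiplex_group"],
                psi_median_control=float(entry["psi_median_control"]),
                psi_dm95=float(entry["psi_dm95"]),
            )
        )
    panel = Panel(tuple(events), panel_name=doc.get("panel_name", "panel"), version=str(doc.get("version", "0")))
    diags = validate_panel(panel)
    if diags:
        raise PanelError("invalid panel: " + "; ".join(diags))
    return panel


# ---------------------------------------------------------------------------
# synthetic panels

def _event_rng(event_id: str) -> np.random.Generator:
    # crc32 is stable across platforms/sessions, unlike hash().
    return np.random.default_rng(zlib.crc32(event_id.encode()))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _four_pl(x: float, bottom: float, top: float, ec50: float, slope: float) -> float:
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** slope)


def synthetic_panel(
    specs: list[tuple[str, int, float, float]],
    flank_len: int = DEFAULT_FLANK_LEN,
    panel_name: str = "synthetic",
    version: str = "0",
) -> Panel:
    """Build a panel with deterministic random isoform sequences.

    ``specs`` rows are ``(event_id, cassette_length, psi_median_control,
    psi_dm95)``.  Sequences are synthetic: generated from a per-event seeded
    RNG so the same ids always give the same panel.
    """
    events = []
    for i, (eid, clen, med, dm95) in enumerate(specs):
        rng = _event_rng(eid)
        up = _random_seq(rng, flank_len)
        cassette = _random_seq(rng, clen)
        down = _random_seq(rng, flank_len)
        start = 1_000_000 + 10_000 * i
        events.append(
            SpliceEvent(
                event_id=eid,
                gene_symbol=eid.split("_")[0],
                cassette_label=eid.split("_")[-1],
                chrom="chr1",
                strand="+",
                exon_start=start,
                exon_end=start + clen,
                inclusion_seq=up + cassette + down,
                exclusion_seq=up + down,
                multiplex_group="A" if i % 2 == 0 else "B",
                psi_median_control=med,
                psi_dm95=dm95,
            )
        )
    return Panel(tuple(events), panel_name=panel_name, version=version)


def default_panel() -> Panel:
    """The shipped 22-event DM1 panel with synthetic placeholder sequences.

    Reference values are the generator's 4PL truth evaluated at healthy
    (activity 1.0) and severe (5th-percentile DM1 activity) MBNL activity,
    so simulated cohorts and the shipped references are mutually consistent.
    Real assay sequences/coordinates are user-suppliable via
    :func:`load_panel`.
    """
    events = []
    for i, (eid, gene, label, chrom, strand, clen, mux, bottom, top, ec50, slope) in enumerate(
        DEFAULT_EVENT_TABLE
    ):
        rng = _event_rng(eid)
        up = _random_seq(rng, DEFAULT_FLANK_LEN)
        cassette = _random_seq(rng, clen)
        down = _random_seq(rng, DEFAULT_FLANK_LEN)
        start = 1_000_000 + 50_000 * i
        med = round(_four_pl(1.0, bottom, top, ec50, slope), 4)
        dm95 = round(_four_pl(SEVERE_ACTIVITY, bottom, top, ec50, slope), 4)
        events.append(
            SpliceEvent(
                event_id=eid,
                gene_symbol=gene,
                cassette_label=label,
                chrom=chrom,
                strand=strand,
                exon_start=start,
                exon_end=start + clen,
                inclusion_seq=up + cassette + down,
                exclusion_seq=up + down,
                multiplex_group=mux,
                psi_median_control=med,
                psi_dm95=dm95,
            )
        )
    return Panel(tuple(events), panel_name="dm1-si-22", version="1")
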