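"""Amplicon read-pair classification and per-event Psi estimation.

The classification contract mirrors what a junction-aware amplicon pipeline
enforces: each mate is aligned end-to-end (no spliced alignment, no
soft-clipping of the evaluated span, substitutions and indels scored as unit
edits) against both isoform sequences of an event, in both orientations.  A
mate is *informative* only if an optimal alignment covers a discriminating
splice junction with at least ``anchor`` nt on both sides, and it votes for
the isoform with the strictly better (smaller) edit distance.  Pairs whose
informative mates disagree, or that only touch shared flank sequence, are
ambiguous and never enter Psi; pairs aligning to neither isoform within the
edit threshold are unaligned.

Psi is the fraction of inclusion reads among informative (inclusion +
exclusion) reads, with a Wilson 95% binomial interval.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from enum import Enum
from itertools import zip_longest
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from statsmodels.stats.proportion import proportion_confint

from .panel import Panel, SpliceEvent

__all__ = [
    "Assignment",
    "ClassificationParams",
    "IsoformCounts",
    "PsiEstimate",
    "SampleCounts",
    "classify_read_pair",
    "quantify_sample",
    "estimate_psi",
    "counts_to_table",
    "write_counts_tsv",
    "read_counts_tsv",
]


class Assignment(str, Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    AMBIGUOUS = "ambiguous"
    UNALIGNED = "unaligned"


@dataclass(frozen=True)
class ClassificationParams:
    """Tunable knobs of the read classification contract.

    max_edit_frac
        Maximum edit distance as a fraction of read length; a mate above
        this threshold against both isoforms is unaligned.
    anchor
        Minimum nt required on each side of a discriminating junction
        (default 6; the smallest panel cassette is 15 nt, so both inclusion
        junctions stay separable).
    event_margin
        Minimum edit-distance advantage the best-scoring event must have
        over the runner-up for a pair to be attributed ("unambiguous"
        between events); ties go to the unassigned tally.
    """

    max_edit_frac: float = 0.1
    anchor: int = 6
    event_margin: int = 1


@dataclass
class IsoformCounts:
    event_id: str
    inclusion_count: int = 0
    exclusion_count: int = 0
    ambiguous_count: int = 0
    unaligned_count: int = 0

    @property
    def informative(self) -> int:
        return self.inclusion_count + self.exclusion_count


@dataclass
class PsiEstimate:
    event_id: str
    psi: float | None
    informative_reads: int
    ci_low: float | None
    ci_high: float | None
    qc_pass: bool


@dataclass
class SampleCounts:
    """Per-event counts plus the pairs not attributable to any single event."""

    counts: dict[str, IsoformCounts]
    unassigned: int = 0
    total_pairs: int = 0


# ---------------------------------------------------------------------------
# mate-level alignment

@dataclass
class _MateEval:
    d_inc: int | None
    d_exc: int | None
    informative_inc: bool
    informative_exc: bool

    @property
    def aligned(self) -> bool:
        return self.d_inc is not None or self.d_exc is not None

    @property
    def best(self) -> int | None:
        ds = [d for d in (self.d_inc, self.d_exc) if d is not None]
        return min(ds) if ds else None


def _align(read: str, target: str, max_dist: int) -> tuple[int, list[tuple[int, int]]] | None:
    """Best infix alignment of ``read`` within ``target`` over both
    orientations; returns (distance, optimal locations) or None above
    ``max_dist``.  Locations are (start, end) with end inclusive; when both
    orientations tie, locations from both are pooled."""
    res_f = edlib.align(read, target, mode="HW", task="locations", k=max_dist)
    res_r = edlib.align(reverse_complement(read), target, mode="HW", task="locations", k=max_dist)
    d_f = res_f["editDistance"]
    d_r = res_r["editDistance"]
    best = min(d for d in (d_f, d_r) if d != -1) if (d_f != -1 or d_r != -1) else -1
    if best == -1:
        return None
    locs: list[tuple[int, int]] = []
    if d_f == best:
        locs.extend(res_f["locations"])
    if d_r == best:
        locs.extend(res_r["locations"])
    return best, locs


def _covers_junction(
    locs: Iterable[tuple[int, int]], junctions: tuple[int, ...], anchor: int
) -> bool:
    # end is inclusive: a span [s, e] covers junction j (between bases
    # j-1 and j) with anchor m iff s <= j - m and e >= j + m - 1.
    for s, e in locs:
        for j in junctions:
            if s <= j - anchor and e >= j + anchor - 1:
                return True
    return False


def _evaluate_mate(read: str, event: SpliceEvent, params: ClassificationParams) -> _MateEval:
    if 2 * params.anchor > len(read):
        raise ValueError(
            f"junction anchor {params.anchor} too large for read of length {len(read)}"
        )
    max_dist = int(params.max_edit_frac * len(read))
    out: dict[str, tuple[int | None, bool]] = {}
    for iso, target in (("inclusion", event.inclusion_seq), ("exclusion", event.exclusion_seq)):
        hit = _align(read, target, max_dist)
        if hit is None:
            out[iso] = (None, False)
        else:
            d, locs = hit
            out[iso] = (d, _covers_junction(locs, event.junctions(iso), params.anchor))
    return _MateEval(
        d_inc=out["inclusion"][0],
        d_exc=out["exclusion"][0],
        informative_inc=out["inclusion"][1],
        informative_exc=out["exclusion"][1],
    )


def _mate_vote(ev: _MateEval) -> Assignment | None:
    """Vote of one mate: INCLUSION/EXCLUSION, None (no vote), or UNALIGNED."""
    if not ev.aligned:
        return Assignment.UNALIGNED
    d_inc = ev.d_inc if ev.d_inc is not None else np.inf
    d_exc = ev.d_exc if ev.d_exc is not None else np.inf
    if d_inc < d_exc and ev.informative_inc:
        return Assignment.INCLUSION
    if d_exc < d_inc and ev.informative_exc:
        return Assignment.EXCLUSION
    return None


def _pair_assignment(ev1: _MateEval, ev2: _MateEval) -> Assignment:
    v1, v2 = _mate_vote(ev1), _mate_vote(ev2)
    if v1 is Assignment.UNALIGNED and v2 is Assignment.UNALIGNED:
        return Assignment.UNALIGNED
    votes = {v for v in (v1, v2) if v in (Assignment.INCLUSION, Assignment.EXCLUSION)}
    if len(votes) == 1:
        return votes.pop()
    return Assignment.AMBIGUOUS


def classify_read_pair(
    read1: str,
    read2: str,
    event: SpliceEvent,
    params: ClassificationParams = ClassificationParams(),
) -> Assignment:
    """Classify one read pair against one event's isoforms.

    Unambiguous-assignment contract: only junction-covering mates with a
    strictly better alignment to one isoform vote; disagreeing or
    non-discriminating pairs are ambiguous; pairs aligning to neither
    isoform within the edit threshold are unaligned.
    """
    if not read1 or not read2:
        raise ValueError("reads must be non-empty")
    ev1 = _evaluate_mate(read1.upper(), event, params)
    ev2 = _evaluate_mate(read2.upper(), event, params)
    return _pair_assignment(ev1, ev2)


# ---------------------------------------------------------------------------
# sample-level quantification

def _open_maybe_gz(path: str | os.PathLike):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq_pairs(fastq_r1, fastq_r2) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    with _open_maybe_gz(fastq_r1) as h1, _open_maybe_gz(fastq_r2) as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        for i, (r1, r2) in enumerate(zip_longest(it1, it2)):
            if r1 is None or r2 is None:
                which = fastq_r2 if r1 is None else fastq_r1
                raise ValueError(f"unpaired/truncated FASTQ: {which} ends at record {i}")
            yield str(r1.seq).upper(), str(r2.seq).upper()


def quantify_sample(
    fastq_r1: str | os.PathLike,
    fastq_r2: str | os.PathLike,
    panel: Panel,
    params: ClassificationParams = ClassificationParams(),
) -> SampleCounts:
    """Classify every read pair of a paired FASTQ against the whole panel.

    Each pair is attributed to the event with the best (smallest) mate edit
    distance, provided the advantage over the runner-up event is at least
    ``params.event_margin``; cross-event ties and pairs aligning nowhere go
    to the global unassigned tally.  Deterministic given inputs.
    """
    result = SampleCounts(
        counts={e.event_id: IsoformCounts(e.event_id) for e in panel}, unassigned=0, total_pairs=0
    )
    for read1, read2 in _iter_fastq_pairs(fastq_r1, fastq_r2):
        result.total_pairs += 1
        evals: list[tuple[int, str, _MateEval, _MateEval]] = []
        for event in panel:
            ev1 = _evaluate_mate(read1, event, params)
            ev2 = _evaluate_mate(read2, event, params)
            scores = [d for d in (ev1.best, ev2.best) if d is not None]
            if scores:
                evals.append((min(scores), event.event_id, ev1, ev2))
        if not evals:
            result.unassigned += 1
            continue
        evals.sort(key=lambda t: t[0])
        if len(evals) > 1 and evals[1][0] - evals[0][0] < params.event_margin:
            result.unassigned += 1
            continue
        _, event_id, ev1, ev2 = evals[0]
        assignment = _pair_assignment(ev1, ev2)
        c = result.counts[event_id]
        if assignment is Assignment.INCLUSION:
            c.inclusion_count += 1
        elif assignment is Assignment.EXCLUSION:
            c.exclusion_count += 1
        elif assignment is Assignment.AMBIGUOUS:
            c.ambiguous_count += 1
        else:  # pragma: no cover - attributed pairs always have an alignment
            c.unaligned_count += 1
    return result


# ---------------------------------------------------------------------------
# Psi estimation

def estimate_psi(counts: IsoformCounts, min_depth: int = 100) -> PsiEstimate:
    """Psi = inclusion / (inclusion + exclusion) with a Wilson 95% CI.

    Ambiguous and unaligned reads never enter the denominator.  With zero
    informative reads the estimate is flagged (psi None, qc_pass False)
    rather than raising.
    """
    n = counts.informative
    if n == 0:
        return PsiEstimate(counts.event_id, None, 0, None, None, False)
    psi = counts.inclusion_count / n
    lo, hi = proportion_confint(counts.inclusion_count, n, alpha=0.05, method="wilson")
    return PsiEstimate(counts.event_id, psi, n, float(lo), float(hi), n >= min_depth)


def counts_to_table(sample: SampleCounts, min_depth: int = 100) -> pd.DataFrame:
    """Per-event TSV-ready table: counts, psi, Wilson CI, and QC flag."""
    rows = []
    for eid, c in sample.counts.items():
        est = estimate_psi(c, min_depth=min_depth)
        rows.append(
            {
                "event_id": eid,
                "inclusion": c.inclusion_count,
                "exclusion": c.exclusion_count,
                "ambiguous": c.ambiguous_count,
                "unaligned": c.unaligned_count,
                "psi": est.psi,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "qc_pass": est.qc_pass,
            }
        )
    return pd.DataFrame(rows)


def write_counts_tsv(sample: SampleCounts, path: str | os.PathLike, min_depth: int = 100) -> None:
    table = counts_to_table(sample, min_depth=min_depth)
    with open(path, "w") as fh:
        fh.write(f"# unassigned_pairs={sample.unassigned}\ttotal_pairs={sample.total_pairs}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
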