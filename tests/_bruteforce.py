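"""Brute-force reference classifier for amplicon read pairs.

Independent oracle for the package's read classification: enumerates the
full semi-global edit-distance dynamic program for every read against
every isoform of every event (both orientations), recovers *all* optimal
alignment spans, and applies the unambiguous-assignment contract
(junction coverage with anchor, strictly-better isoform, mate agreement,
cross-event uniqueness margin).  No shared code with the package's
edlib-based implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ENC = {c: i for i, c in enumerate("ACGTN")}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.int8, count=len(seq))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def semiglobal_final_rows(reads: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Final DP rows for every read of a (N, Lr) batch against one target.

    D[i][j] = min edits aligning the read prefix of length i to any target
    substring ending at j (free start in the target).  Returns the final
    row D[Lr][0..Lt] for each read, shape (N, Lt + 1).
    """
    n, lr = reads.shape
    lt = target.size
    idx = np.arange(lr + 1)
    col = np.broadcast_to(idx, (n, lr + 1)).astype(np.int32).copy()
    out = np.empty((n, lt + 1), dtype=np.int32)
    out[:, 0] = lr
    for j in range(1, lt + 1):
        sub = (reads != target[j - 1]).astype(np.int32)
        cand = np.empty_like(col)
        cand[:, 0] = 0  # free start: D[0][j] = 0
        cand[:, 1:] = np.minimum(col[:, :-1] + sub, col[:, 1:] + 1)
        # vertical relax D[i][j] <= D[i-1][j] + 1 via running minimum
        col = np.minimum.accumulate(cand - idx, axis=1) + idx
        out[:, j] = col[:, -1]
    return out


def _nw_last_row(read: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Global alignment cost of ``read`` vs every prefix of ``target``."""
    lt = target.size
    row = np.arange(lt + 1, dtype=np.int32)
    for i, rc in enumerate(read, start=1):
        new = np.empty_like(row)
        new[0] = i
        sub = (target != rc).astype(np.int32)
        cand = np.minimum(row[:-1] + sub, row[1:] + 1)
        new[1:] = np.minimum.accumulate(
            np.concatenate(([new[0]], cand)) - np.arange(lt + 1)
        )[1:] + np.arange(1, lt + 1)
        row = new
    return row


def optimal_spans(read: np.ndarray, target: np.ndarray, final_row: np.ndarray) -> list[tuple[int, int]]:
    """All (start, end-inclusive) spans achieving the optimal distance."""
    d_opt = int(final_row[1:].min())
    spans = []
    rev_read = read[::-1]
    for j in np.nonzero(final_row[1:] == d_opt)[0] + 1:
        e = int(j - 1)
        rev_prefix = target[:j][::-1]
        costs = _nw_last_row(rev_read, rev_prefix)
        for m in np.nonzero(costs == d_opt)[0]:
            s = int(j - m)
            if s <= e:
                spans.append((s, e))
    return spans


@dataclass
class _IsoHit:
    dist: int
    spans: list[tuple[int, int]]


class BruteForceClassifier:
    """Reference implementation of the pair-classification contract."""

    def __init__(self, panel, max_edit_frac: float = 0.1, anchor: int = 6, event_margin: int = 1):
        self.panel = panel
        self.max_edit_frac = max_edit_frac
        self.anchor = anchor
        self.event_margin = event_margin
        self.targets = {}  # (event_id, isoform) -> encoded target
        self.junctions = {}
        for event in panel:
            self.targets[(event.event_id, "inclusion")] = _encode(event.inclusion_seq)
            self.targets[(event.event_id, "exclusion")] = _encode(event.exclusion_seq)
            self.junctions[(event.event_id, "inclusion")] = event.junctions("inclusion")
            self.junctions[(event.event_id, "exclusion")] = event.junctions("exclusion")

    # -- batch alignment ---------------------------------------------------

    def _align_batch(self, reads: list[str]) -> dict:
        """distances[(event, isoform, orientation)] = (N,) best distance;
        also keeps final rows for span recovery."""
        enc_f = np.stack([_encode(r) for r in reads])
        enc_r = np.stack([_encode(_revcomp(r)) for r in reads])
        rows, dists = {}, {}
        for key, target in self.targets.items():
            for orient, enc in (("f", enc_f), ("r", enc_r)):
                fr = semiglobal_final_rows(enc, target)
                rows[key + (orient,)] = fr
                dists[key + (orient,)] = fr[:, 1:].min(axis=1)
        return {"rows": rows, "dists": dists, "enc": {"f": enc_f, "r": enc_r}}

    def _covers(self, data, i: int, key: tuple, best: int) -> bool:
        """Does any optimal alignment of read i (either orientation at the
        best distance) cover a discriminating junction with the anchor?"""
        juncs = self.junctions[key]
        m = self.anchor
        for orient in ("f", "r"):
            if data["dists"][key + (orient,)][i] != best:
                continue
            read = data["enc"][orient][i]
            target = self.targets[key]
            for s, e in optimal_spans(read, target, data["rows"][key + (orient,)][i]):
                for j in juncs:
                    if s <= j - m and e >= j + m - 1:
                        return True
        return False

    # -- contract ----------------------------------------------------------

    def classify_pairs(self, pairs: list[tuple[str, str]]) -> dict:
        """Counts per event (inclusion/exclusion/ambiguous) + unassigned."""
        r1 = [p[0].upper() for p in pairs]
        r2 = [p[1].upper() for p in pairs]
        data1 = self._align_batch(r1)
        data2 = self._align_batch(r2)
        max1 = int(self.max_edit_frac * len(r1[0]))
        max2 = int(self.max_edit_frac * len(r2[0]))
        counts = {
            e.event_id: {"inclusion": 0, "exclusion": 0, "ambiguous": 0} for e in self.panel
        }
        unassigned = 0
        for i in range(len(pairs)):
            per_event = []
            for event in self.panel:
                eid = event.event_id
                best = None
                for data, cap in ((data1, max1), (data2, max2)):
                    for iso in ("inclusion", "exclusion"):
                        d = min(
                            int(data["dists"][(eid, iso, "f")][i]),
                            int(data["dists"][(eid, iso, "r")][i]),
                        )
                        if d <= cap and (best is None or d < best):
                            best = d
                if best is not None:
                    per_event.append((best, eid))
            if not per_event:
                unassigned += 1
                continue
            per_event.sort()
            if len(per_event) > 1 and per_event[1][0] - per_event[0][0] < self.event_margin:
                unassigned += 1
                continue
            eid = per_event[0][1]
            votes = []
            any_aligned = False
            for data, cap in ((data1, max1), (data2, max2)):
                d_inc = min(
                    int(data["dists"][(eid, "inclusion", "f")][i]),
                    int(data["dists"][(eid, "inclusion", "r")][i]),
                )
                d_exc = min(
                    int(data["dists"][(eid, "exclusion", "f")][i]),
                    int(data["dists"][(eid, "exclusion", "r")][i]),
                )
                inc_ok = d_inc <= cap
                exc_ok = d_exc <= cap
                if not inc_ok and not exc_ok:
                    continue
                any_aligned = True
                if inc_ok and (not exc_ok or d_inc < d_exc):
                    if self._covers(data, i, (eid, "inclusion"), d_inc):
                        votes.append("inclusion")
                elif exc_ok and (not inc_ok or d_exc < d_inc):
                    if self._covers(data, i, (eid, "exclusion"), d_exc):
                        votes.append("exclusion")
            if not any_aligned:  # pragma: no cover - attributed implies aligned
                unassigned += 1
            elif len(set(votes)) == 1:
                counts[eid][votes[0]] += 1
            else:
                counts[eid]["ambiguous"] += 1
        return {"counts": counts, "unassigned": unassigned}
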