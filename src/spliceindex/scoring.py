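"""Normative reference derivation and composite Splice Index scoring.

Per-event inclusion levels are normalized against two normative anchors:
the median Psi of unaffected adult controls and a severity-oriented 95th
percentile of the DM1 distribution (the 5th percentile of raw Psi for
events whose inclusion falls in disease, so that the anchor always marks
the severe end).  Normalized values are

    (psi - psi_median_control) / (psi_dm95 - psi_median_control),

0 at the control median and 1 at the severe anchor regardless of shift
direction.  The Splice Index is the unweighted mean over qc-passing panel
events, clamped into [0, 1] ("rounding to the nearest integer" of slightly
out-of-range scores); event-level values are deliberately NOT clamped
before averaging.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .panel import Panel, SpliceEvent
from .quantify import PsiEstimate

__all__ = [
    "NormativeReference",
    "SIResult",
    "derive_reference",
    "normalize_psi",
    "compute_si",
    "normalized_delta_psi",
    "SpliceIndexScorer",
]


@dataclass
class NormativeReference:
    """Per-event (psi_median_control, psi_dm95) anchors for a cohort."""

    values: pd.DataFrame  # index event_id, columns psi_median_control / psi_dm95
    n_controls: int
    n_dm1: int
    version: str = "0"

    def __post_init__(self) -> None:
        v = self.values
        if not {"psi_median_control", "psi_dm95"}.issubset(v.columns):
            raise ValueError("reference table needs psi_median_control and psi_dm95 columns")
        span = v["psi_dm95"] - v["psi_median_control"]
        zero = v.index[span == 0].tolist()
        if zero:
            raise ValueError(f"zero normalization span for events {zero}")

    @property
    def event_ids(self) -> list[str]:
        return list(self.values.index)

    def event(self, event_id: str) -> tuple[float, float]:
        row = self.values.loc[event_id]
        return float(row["psi_median_control"]), float(row["psi_dm95"])

    @classmethod
    def from_panel(cls, panel: Panel, n_controls: int = 0, n_dm1: int = 0) -> "NormativeReference":
        values = pd.DataFrame(
            {
                "psi_median_control": [e.psi_median_control for e in panel],
                "psi_dm95": [e.psi_dm95 for e in panel],
            },
            index=pd.Index(panel.event_ids, name="event_id"),
        )
        return cls(values, n_controls=n_controls, n_dm1=n_dm1, version=panel.version)

    def to_tsv(self, path: str | os.PathLike, sidecar: bool = True) -> None:
        self.values.to_csv(path, sep="\t")
        if sidecar:
            meta = {
                "version": self.version,
                "n_controls": self.n_controls,
                "n_dm1": self.n_dm1,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)
                fh.write("\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "NormativeReference":
        values = pd.read_csv(path, sep="\t", index_col="event_id")
        meta_path = str(path) + ".json"
        meta = {"version": "0", "n_controls": 0, "n_dm1": 0}
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta.update(json.load(fh))
        return cls(values, n_controls=int(meta["n_controls"]), n_dm1=int(meta["n_dm1"]),
                   version=str(meta["version"]))


@dataclass
class SIResult:
    """Composite score for one sample: clamped SI, raw mean, and the
    per-event normalized values that produced it."""

    sample_id: str
    normalized: dict[str, float] = field(default_factory=dict)
    events_used: int = 0
    si_raw: float = float("nan")
    si: float = float("nan")
    qc_pass: bool = True
    reference_version: str = "0"


def derive_reference(
    control_psi: pd.DataFrame,
    dm1_psi: pd.DataFrame,
    oriented: bool = True,
    version: str = "0",
) -> NormativeReference:
    """Derive normative anchors from control and DM1 Psi matrices
    (rows samples, columns events).

    psi_median_control is the per-event control median.  psi_dm95 is the
    severity-oriented 95th percentile of the DM1 distribution: the 95th
    percentile of raw Psi when the DM1 median exceeds the control median,
    else the 5th percentile.  Percentiles interpolate linearly between
    order statistics (positions (n-1)p + 1).  With ``oriented=False`` the
    literal 95th percentile is used for every event.
    """
    if control_psi.shape[0] < 3:
        raise ValueError("need >= 3 control samples")
    if dm1_psi.shape[0] < 10:
        raise ValueError("need >= 10 DM1 samples")
    events = list(control_psi.columns)
    if list(dm1_psi.columns) != events:
        raise ValueError("control and DM1 matrices must share event columns")
    med, dm95 = {}, {}
    for ev in events:
        c = control_psi[ev].dropna().to_numpy(float)
        d = dm1_psi[ev].dropna().to_numpy(float)
        if c.size == 0 or d.size == 0:
            raise ValueError(f"event {ev}: no qc-passing values to derive reference from")
        m = float(np.median(c))
        if oriented and float(np.median(d)) <= m:
            q = float(np.percentile(d, 5))
        else:
            q = float(np.percentile(d, 95))
        med[ev], dm95[ev] = m, q
    values = pd.DataFrame(
        {"psi_median_control": med, "psi_dm95": dm95},
        index=pd.Index(events, name="event_id"),
    )
    return NormativeReference(values, n_controls=len(control_psi), n_dm1=len(dm1_psi), version=version)


def normalize_psi(psi: float, event: SpliceEvent | tuple[float, float]) -> float:
    """Scale one Psi between the control median (0) and the severe DM1
    anchor (1); values outside [0, 1] are possible and preserved."""
    if isinstance(event, SpliceEvent):
        med, dm95 = event.psi_median_control, event.psi_dm95
    else:
        med, dm95 = event
    span = dm95 - med
    if span == 0:
        raise ValueError("zero normalization span")
    return (psi - med) / span


def compute_si(
    psi_estimates: list[PsiEstimate] | dict[str, float],
    reference: NormativeReference,
    min_events: int = 18,
    sample_id: str = "sample",
) -> SIResult:
    """Average normalized Psi over qc-passing events into a 0-1 score.

    Events failing QC (or absent) are dropped; with fewer than
    ``min_events`` usable events the sample fails QC and gets no score.
    The raw mean is preserved in ``si_raw``; ``si`` is clamped to [0, 1].
    """
    usable: dict[str, float] = {}
    if isinstance(psi_estimates, dict):
        for eid, psi in psi_estimates.items():
            if eid in reference.event_ids and psi is not None and not np.isnan(psi):
                usable[eid] = float(psi)
    else:
        for est in psi_estimates:
            if est.qc_pass and est.psi is not None and est.event_id in reference.event_ids:
                usable[est.event_id] = est.psi
    if len(usable) < min_events:
        return SIResult(sample_id, {}, len(usable), float("nan"), float("nan"),
                        qc_pass=False, reference_version=reference.version)
    normalized = {eid: normalize_psi(p, reference.event(eid)) for eid, p in usable.items()}
    si_raw = float(np.mean(list(normalized.values())))
    return SIResult(
        sample_id,
        normalized,
        events_used=len(normalized),
        si_raw=si_raw,
        si=float(np.clip(si_raw, 0.0, 1.0)),
        qc_pass=True,
        reference_version=reference.version,
    )


def normalized_delta_psi(baseline: SIResult, followup: SIResult) -> dict[str, float]:
    """Per-event change in normalized Psi (follow-up minus baseline).

    Events missing at either time point are absent from the output; results
    scored against different reference versions cannot be compared.
    """
    if baseline.reference_version != followup.reference_version:
        raise ValueError(
            f"reference version mismatch: baseline {baseline.reference_version!r} "
            f"vs follow-up {followup.reference_version!r}"
        )
    shared = set(baseline.normalized) & set(followup.normalized)
    return {eid: followup.normalized[eid] - baseline.normalized[eid] for eid in sorted(shared)}


class SpliceIndexScorer(BaseEstimator, TransformerMixin):
    """Estimator wrapper: fit derives the normative reference from a cohort,
    transform normalizes Psi matrices, score_samples yields SI values.

    Parameters
    ----------
    min_events : minimum qc-passing events per sample for a score.
    oriented : severity-orient the DM1 95th percentile (5th percentile for
        events whose inclusion falls in disease).
    version : version tag stamped on the derived reference.
    """

    def __init__(self, min_events: int = 18, oriented: bool = True, version: str = "0"):
        self.min_events = min_events
        self.oriented = oriented
        self.version = version

    def fit(self, X: pd.DataFrame, y=None) -> "SpliceIndexScorer":
        """X: Psi matrix (samples x events); y: 0 for controls, 1 for DM1."""
        if y is None:
            raise ValueError("y (0=control, 1=DM1) is required to derive the reference")
        y = np.asarray(y)
        self.reference_ = derive_reference(
            X[y == 0], X[y == 1], oriented=self.oriented, version=self.version
        )
        return self

    def set_reference(self, reference: NormativeReference) -> "SpliceIndexScorer":
        """Use pre-derived anchors instead of fitting on a cohort."""
        self.reference_ = reference
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "reference_")
        ref = self.reference_
        out = {}
        for eid in ref.event_ids:
            if eid in X.columns:
                out[eid] = (X[eid] - ref.event(eid)[0]) / (ref.event(eid)[1] - ref.event(eid)[0])
        return pd.DataFrame(out, index=X.index)

    def score_samples(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-sample SI table: si, si_raw, events_used, qc_pass."""
        check_is_fitted(self, "reference_")
        rows = []
        for sid, row in X.iterrows():
            res = compute_si(row.dropna().to_dict(), self.reference_,
                             min_events=self.min_events, sample_id=str(sid))
            rows.append({"sample_id": str(sid), "si": res.si, "si_raw": res.si_raw,
                         "events_used": res.events_used, "qc_pass": res.qc_pass})
        return pd.DataFrame(rows).set_index("sample_id")
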