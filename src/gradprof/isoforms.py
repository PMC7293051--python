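"""Isoform sedimentation screen: ΔΨ across the gradient.

Alternative first-exon (AFE) and last-exon (ALE) isoforms of one gene can
sediment differently, implying isoform-specific localization.  Per event
and fraction we take an estimated Ψ (fraction of the gene's transcripts
using that isoform) with a confidence interval; isoforms whose CI is ever
wide are discarded, the per-isoform span of Ψ across fractions gives the
event's ΔΨ, and events are classed strong / moderate / non-regulated.
A conservation comparison then asks whether regulated events sit under
stronger purifying selection than non-regulated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .stats import bh_adjust, ecdf_table, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

EVENT_TYPES = ("AFE", "ALE")
PSI_COLUMNS = ["event_id", "event_type", "isoform_id", "fraction_index",
               "psi", "ci_low", "ci_high"]

CLASS_STRONG = "strong"
CLASS_MODERATE = "moderate"
CLASS_NON = "non_regulated"


@dataclass
class EventDeltaPsi:
    event_id: str
    event_type: str
    delta_psi: float
    label: str | None = None
    fractions_used: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_psi <= 1.0):
            raise ValidationError(f"{self.event_id}: delta_psi outside [0,1]")
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"{self.event_id}: unknown event type {self.event_type!r}")


def validate_psi_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the MISO-summary-like Ψ table invariants.

    Required columns: event_id, event_type (AFE/ALE), isoform_id,
    fraction_index, psi, ci_low, ci_high, with ci_low <= psi <= ci_high,
    all in [0,1].  Within an event and fraction the isoform Ψs should sum
    to ~1; deviations beyond 0.05 (estimation error) are warned about,
    not rejected.
    """
    missing = [c for c in PSI_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"psi table missing columns: {missing}")
    df = df.copy()
    for c in ("psi", "ci_low", "ci_high"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
    df["fraction_index"] = df["fraction_index"].astype(int)
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        raise ValidationError(
            f"unknown event types: {sorted(df.loc[bad_type, 'event_type'].unique())}")
    in_range = df[["psi", "ci_low", "ci_high"]].to_numpy()
    if ((in_range < -1e-9) | (in_range > 1 + 1e-9)).any():
        raise ValidationError("psi/CI values outside [0,1]")
    if ((df["ci_low"] > df["psi"] + 1e-9) | (df["psi"] > df["ci_high"] + 1e-9)).any():
        raise ValidationError("CI bounds must bracket psi")
    sums = df.groupby(["event_id", "fraction_index"])["psi"].sum()
    off = sums[(sums - 1.0).abs() > 0.05]
    if len(off):
        logger.warning("psi table: %d event/fraction groups with |sum(psi)-1| > 0.05", len(off))
    return df


def load_psi_table(path) -> pd.DataFrame:
    return validate_psi_table(pd.read_csv(path, sep="\t", comment="#"))


def filter_confident(df: pd.DataFrame, max_ci_width: float = 0.2) -> pd.DataFrame:
    """Keep isoforms whose CI width stays strictly below ``max_ci_width``
    in every fraction (default 0.2); events left with fewer than two
    isoforms are dropped entirely.  Idempotent."""
    if not (0 < max_ci_width <= 1):
        raise ValidationError("max_ci_width must lie in (0,1]")
    df = validate_psi_table(df)
    width = df["ci_high"] - df["ci_low"]
    max_w = width.groupby([df["event_id"], df["isoform_id"]]).transform("max")
    kept = df[max_w < max_ci_width]
    n_iso_dropped = (df[["event_id", "isoform_id"]].drop_duplicates().shape[0]
                     - kept[["event_id", "isoform_id"]].drop_duplicates().shape[0])
    iso_per_event = kept.groupby("event_id")["isoform_id"].nunique()
    good_events = set(iso_per_event[iso_per_event >= 2].index)
    out = kept[kept["event_id"].isin(good_events)].reset_index(drop=True)
    n_events_dropped = df["event_id"].nunique() - len(good_events)
    if n_iso_dropped or n_events_dropped:
        logger.info(
            "filter_confident: dropped %d isoforms by CI width, %d events left "
            "with <2 isoforms", n_iso_dropped, n_events_dropped)
    if out.empty:
        logger.warning("filter_confident: no event survived the CI filter")
    return out


def max_delta_psi(event_rows: pd.DataFrame) -> EventDeltaPsi:
    """ΔΨ of one event: the largest across-gradient span of Ψ.

    Per isoform, span = max Ψ - min Ψ over fractions; the event's ΔΨ is
    the maximum span over its isoforms.  For two-isoform events (Ψs
    summing to one) the two spans coincide, so this matches any reading
    of "maximum difference across the gradient for any pair of isoforms".
    """
    events = event_rows["event_id"].unique()
    if len(events) != 1:
        raise ValidationError("max_delta_psi expects rows of exactly one event")
    spans = []
    n_frac = 0
    for _, iso in event_rows.groupby("isoform_id"):
        if iso["fraction_index"].nunique() < 2:
            raise ValidationError(
                f"{events[0]}: isoform {iso['isoform_id'].iloc[0]} measured in <2 fractions")
        spans.append(float(iso["psi"].max() - iso["psi"].min()))
        n_frac = max(n_frac, iso["fraction_index"].nunique())
    return EventDeltaPsi(
        event_id=str(events[0]),
        event_type=str(event_rows["event_type"].iloc[0]),
        delta_psi=max(spans),
        fractions_used=n_frac,
    )


def screen_events(df: pd.DataFrame, max_ci_width: float = 0.2) -> list[EventDeltaPsi]:
    """CI-filter a Ψ table and compute ΔΨ for every surviving event."""
    kept = filter_confident(df, max_ci_width=max_ci_width)
    out = []
    for _, rows in kept.groupby("event_id", sort=True):
        out.append(max_delta_psi(rows))
    return out


def classify_events(
    events: list[EventDeltaPsi], strong_cut: float = 0.5, moderate_cut: float = 0.25
) -> list[EventDeltaPsi]:
    """Label events strong (ΔΨ > strong_cut), moderate (moderate_cut < ΔΨ
    <= strong_cut) or non-regulated.  A ΔΨ exactly at a boundary falls to
    the lower class (the defining inequalities are strict)."""
    if not (0 < moderate_cut < strong_cut < 1):
        raise ValidationError("need 0 < moderate_cut < strong_cut < 1")
    out = []
    for ev in events:
        if ev.delta_psi > strong_cut:
            label = CLASS_STRONG
        elif ev.delta_psi > moderate_cut:
            label = CLASS_MODERATE
        else:
            label = CLASS_NON
        out.append(EventDeltaPsi(event_id=ev.event_id, event_type=ev.event_type,
                                 delta_psi=ev.delta_psi, label=label,
                                 fractions_used=ev.fractions_used))
    return out


def conservation_group_test(
    labels: dict[str, str],
    scores: dict[str, float],
    alternative: str = "greater",
) -> dict:
    """Compare conservation scores of regulated vs non-regulated events.

    Each regulated class (strong, moderate) is tested against the
    non-regulated class by Wilcoxon rank-sum (one-sided 'greater' by
    default: regulated events expected to be more conserved), with BH
    across the two comparisons.  Returns ECDF tables per class for
    plotting plus the test records.  Empty classes are skipped with a
    warning.
    """
    by_class: dict[str, list[float]] = {CLASS_STRONG: [], CLASS_MODERATE: [], CLASS_NON: []}
    for ev, lab in labels.items():
        if lab not in by_class:
            raise ValidationError(f"unknown class label {lab!r}")
        if ev not in scores:
            logger.warning("event %s has no conservation score; skipped", ev)
            continue
        by_class[lab].append(float(scores[ev]))
    ecdfs = {lab: ecdf_table(v) for lab, v in by_class.items() if v}
    tests = []
    base = by_class[CLASS_NON]
    if not base:
        logger.warning("no non-regulated events; comparisons skipped")
        return {"ecdf": ecdfs, "tests": []}
    for lab in (CLASS_STRONG, CLASS_MODERATE):
        if not by_class[lab]:
            logger.warning("class %s empty; comparison skipped", lab)
            continue
        stat, p = wilcoxon_rank_sum(by_class[lab], base, alternative=alternative)
        tests.append({"class": lab, "vs": CLASS_NON, "statistic": stat, "p_raw": p,
                      "n_class": len(by_class[lab]), "n_reference": len(base)})
    if tests:
        q = bh_adjust([t["p_raw"] for t in tests])
        for t, qv in zip(tests, q):
            t["p_adj"] = float(qv)
    return {"ecdf": ecdfs, "tests": tests}


def events_to_frame(events: list[EventDeltaPsi]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"event_id": e.event_id, "event_type": e.event_type,
             "delta_psi": e.delta_psi, "label": e.label,
             "fractions_used": e.fractions_used}
            for e in events
        ]
    )
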