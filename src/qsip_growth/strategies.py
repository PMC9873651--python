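"""Growth-strategy classification and climate-induced strategy shifts.

Incorporators are classified by the timing of their peak average growth
rate (production of new 16S copies per g soil per day): rapid responders
peak in the 0–1 d interval, intermediate in 0–3 d, slow in 0–6 d. Comparing
a taxon's strategy between the control soil and a climate treatment yields
a shift record: "accelerated" (situations 1 slow→rapid, 2 intermediate→rapid,
3 slow→intermediate) or "delayed" (4 rapid→slow, 5 rapid→intermediate,
6 intermediate→slow).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import INTERVALS
from .util import round_half_up

STRATEGIES = ("rapid", "intermediate", "slow")
STRATEGY_OF_INTERVAL = dict(zip(INTERVALS, STRATEGIES))

#: (control strategy, treatment strategy) → situation code of the shift.
SITUATIONS = {
    ("slow", "rapid"): 1,
    ("intermediate", "rapid"): 2,
    ("slow", "intermediate"): 3,
    ("rapid", "slow"): 4,
    ("rapid", "intermediate"): 5,
    ("intermediate", "slow"): 6,
}
ACCELERATED = frozenset({1, 2, 3})
DELAYED = frozenset({4, 5, 6})


@dataclass(frozen=True)
class StrategyAssignment:
    taxon_id: str
    treatment: str
    strategy: str
    peak_interval: str
    mean_rates: tuple  # production by interval, copies/g soil/day


@dataclass(frozen=True)
class ShiftRecord:
    taxon_id: str
    comparison: str  # e.g. "Contr-eT"
    shift: str  # accelerated | delayed | unchanged | not_comparable
    situation: Optional[int]


def classify_strategy(taxon_id: str, treatment: str, rates) -> StrategyAssignment:
    """Assign the strategy by argmax of the three interval mean rates.

    Ties break toward the earlier interval (conservative toward "rapid";
    exact ties have measure zero in real data).
    """
    rates = tuple(float(r) for r in rates)
    if len(rates) != len(INTERVALS):
        raise ValidationError(f"need {len(INTERVALS)} interval rates, got {len(rates)}")
    if any(np.isnan(r) for r in rates):
        raise ValidationError(f"taxon {taxon_id!r}: NaN interval rate")
    peak = int(np.argmax(rates))  # argmax returns the first maximum: earlier interval
    return StrategyAssignment(taxon_id=taxon_id, treatment=treatment,
                              strategy=STRATEGIES[peak],
                              peak_interval=INTERVALS[peak], mean_rates=rates)


def classify_incorporators(estimates: pd.DataFrame,
                           metric: str = "production") -> pd.DataFrame:
    """Classify every incorporator taxon in every treatment.

    ``metric`` selects the peak statistic: "production" (new copies per g
    soil per day; the default) or "g" (1/day). Returns a tidy frame with one
    row per (taxon, treatment) plus the three interval means.
    """
    if metric not in ("production", "g"):
        raise ValidationError(f"unknown peak metric {metric!r}")
    inc = estimates[estimates["incorporator"]]
    rows = []
    for (taxon, trt), sub in inc.groupby(["taxon", "treatment"], sort=True):
        by_int = sub.set_index("interval")[metric]
        if not all(i in by_int.index for i in INTERVALS):
            continue  # needs all three interval means
        a = classify_strategy(taxon, trt, [by_int[i] for i in INTERVALS])
        rows.append({"taxon": a.taxon_id, "treatment": a.treatment,
                     "strategy": a.strategy, "peak_interval": a.peak_interval,
                     **{f"rate_{i}": r for i, r in zip(INTERVALS, a.mean_rates)}})
    return pd.DataFrame(rows)


def strategy_proportions(assignments: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Counts and percentages of the three strategies in one treatment."""
    sub = assignments[assignments["treatment"] == treatment]
    if sub.empty:
        raise ValidationError(f"no assignments in treatment {treatment!r}")
    counts = {s: int((sub["strategy"] == s).sum()) for s in STRATEGIES}
    return proportions_from_counts(counts)


def proportions_from_counts(counts: dict) -> pd.DataFrame:
    """Strategy percentages from raw counts (report convention: nearest
    integer, half up). Exact proportions sum to 100 before rounding."""
    total = sum(counts.get(s, 0) for s in STRATEGIES)
    if total == 0:
        raise ValidationError("no classified taxa")
    rows = []
    for s in STRATEGIES:
        n = counts.get(s, 0)
        pct = 100.0 * n / total
        rows.append({"strategy": s, "n_taxa": n, "percent": pct,
                     "percent_rounded": round_half_up(pct)})
    return pd.DataFrame(rows).set_index("strategy")


def detect_shift(a: StrategyAssignment, b: StrategyAssignment) -> ShiftRecord:
    """Shift of one taxon's strategy from control (a) to a treatment (b)."""
    if a.taxon_id != b.taxon_id:
        raise ValidationError(
            f"shift compares two taxa: {a.taxon_id!r} vs {b.taxon_id!r}")
    comparison = f"{a.treatment}-{b.treatment}"
    key = (a.strategy, b.strategy)
    if a.strategy == b.strategy:
        return ShiftRecord(a.taxon_id, comparison, "unchanged", None)
    code = SITUATIONS[key]
    shift = "accelerated" if code in ACCELERATED else "delayed"
    return ShiftRecord(a.taxon_id, comparison, shift, code)


def shift_table(assignments: pd.DataFrame, control: str = "Contr",
                taxa=None) -> pd.DataFrame:
    """All pairwise shift records between the control and every other
    treatment. Taxa not classified (= not incorporators) in both members of
    a comparison are recorded as not_comparable. ``taxa`` widens the roster
    beyond the classified taxa (e.g. to every OTU in the experiment)."""
    treatments = [t for t in assignments["treatment"].unique() if t != control]
    by_trt = {t: sub.set_index("taxon") for t, sub in assignments.groupby("treatment")}
    if control not in by_trt:
        raise ValidationError(f"no assignments in control treatment {control!r}")
    taxa = sorted(set(assignments["taxon"]) if taxa is None else set(taxa))
    rows = []
    for trt in sorted(treatments, key=str):
        for taxon in taxa:
            in_a = taxon in by_trt[control].index
            in_b = taxon in by_trt[trt].index
            comparison = f"{control}-{trt}"
            if not (in_a and in_b):
                rows.append({"taxon": taxon, "comparison": comparison,
                             "shift": "not_comparable", "situation": np.nan})
                continue
            a = _row_to_assignment(by_trt[control].loc[taxon], taxon, control)
            b = _row_to_assignment(by_trt[trt].loc[taxon], taxon, trt)
            rec = detect_shift(a, b)
            rows.append({"taxon": taxon, "comparison": comparison,
                         "shift": rec.shift,
                         "situation": np.nan if rec.situation is None else rec.situation})
    return pd.DataFrame(rows)


def _row_to_assignment(row, taxon, treatment) -> StrategyAssignment:
    rates = tuple(row[f"rate_{i}"] for i in INTERVALS) if f"rate_{INTERVALS[0]}" in row \
        else (np.nan, np.nan, np.nan)
    return StrategyAssignment(taxon_id=taxon, treatment=treatment,
                              strategy=row["strategy"],
                              peak_interval=row.get("peak_interval",
                                                    INTERVALS[STRATEGIES.index(row["strategy"])]),
                              mean_rates=rates)


def core_shifted_taxa(records: pd.DataFrame) -> tuple[set, set]:
    """Taxa with a consistent shift direction across all comparisons.

    Returns (always_accelerated, always_delayed): the intersections over the
    comparisons present in ``records`` of taxa accelerated (resp. delayed)
    in every one of them.
    """
    comparisons = sorted(records["comparison"].unique())
    if not comparisons:
        raise ValidationError("no shift records")
    acc, del_ = None, None
    for comp in comparisons:
        sub = records[records["comparison"] == comp]
        a = set(sub.loc[sub["shift"] == "accelerated", "taxon"])
        d = set(sub.loc[sub["shift"] == "delayed", "taxon"])
        acc = a if acc is None else acc & a
        del_ = d if del_ is None else del_ & d
    return acc, del_


def pooled_trait_labels(assignments: pd.DataFrame) -> pd.DataFrame:
    """Non-exclusive binary strategy labels pooled over treatments.

    A taxon is labelled 1 for a strategy if it exhibited that strategy in
    any treatment, so one OTU can carry several labels. This is the trait
    matrix fed to the pooled phylogenetic-signal analyses.
    """
    taxa = sorted(set(assignments["taxon"]))
    out = pd.DataFrame(0, index=taxa, columns=list(STRATEGIES), dtype=int)
    for _, row in assignments.iterrows():
        out.loc[row["taxon"], row["strategy"]] = 1
    return out


def strategy_matrix(assignments: pd.DataFrame, strategy: str,
                    treatments) -> pd.DataFrame:
    """Taxon × treatment binary membership matrix for one strategy."""
    taxa = sorted(set(assignments["taxon"]))
    out = pd.DataFrame(0, index=taxa, columns=list(treatments), dtype=int)
    sub = assignments[assignments["strategy"] == strategy]
    for _, row in sub.iterrows():
        if row["treatment"] in out.columns:
            out.loc[row["taxon"], row["treatment"]] = 1
    return out
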