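"""MSD immunoassay signal-ratio analysis for DPR antibody specificity.

Electrochemiluminescence signals from disease samples are normalised to
background signals from negative controls of the same sample type (C9
patient iPSC-motor neurons vs the isogenic KO line, patient postmortem
tissue vs non-mutant tissue, transgenic vs WT mouse brain).  A ratio of 1
means nonspecific signal; an antibody pair is called specific when its
ratio exceeds the threshold (default 1.5, strict) — across all sample
types for overall validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

#: positive sample type -> matched negative control of the same type
NEGATIVE_OF = {
    "C9_iPSC_MN": "KO_iPSC_MN",
    "C9_postmortem": "control_postmortem",
    "TG_mouse": "WT_mouse",
}

PLATE_COLUMNS = [
    "capture_ab",
    "detection_ab",
    "sample_type",
    "condition_id",
    "replicate_id",
    "signal",
]


@dataclass
class MsdWell:
    capture_ab: str
    detection_ab: str
    sample_type: str
    condition_id: str
    signal: float
    replicate_id: int = 1
    capture_lot: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be >= 0")


@dataclass
class SignalRatio:
    antibody_pair: tuple[str, str]
    sample_pairing: tuple[str, str]     # (positive type, matched negative)
    condition_id: str
    ratio: Optional[float]
    n_replicates: int
    sd: Optional[float]
    specific_call: bool = False
    threshold_used: float = 1.5
    reason: str = ""


WellInput = Union[Sequence[MsdWell], pd.DataFrame]


def plate_to_frame(wells: WellInput) -> pd.DataFrame:
    if isinstance(wells, pd.DataFrame):
        missing = set(PLATE_COLUMNS) - set(wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        return wells.copy()
    return pd.DataFrame(
        [
            {
                "capture_ab": w.capture_ab,
                "detection_ab": w.detection_ab,
                "sample_type": w.sample_type,
                "condition_id": w.condition_id,
                "replicate_id": w.replicate_id,
                "signal": w.signal,
            }
            for w in wells
        ],
        columns=PLATE_COLUMNS,
    )


def background_ratio(
    positive_wells: Sequence[MsdWell], negative_wells: Sequence[MsdWell]
) -> SignalRatio:
    """Mean positive signal over mean matched-negative signal.

    Both sides must share the antibody pair and condition, and the sample
    types must be a matched (positive, negative) pairing.  The replicate
    sd is propagated to the ratio; a zero negative mean leaves the ratio
    undefined with a reason.
    """
    if not positive_wells or not negative_wells:
        raise ValueError("need at least one replicate on each side")
    pairs = {(w.capture_ab, w.detection_ab) for w in positive_wells + list(negative_wells)}
    conds = {w.condition_id for w in positive_wells + list(negative_wells)}
    if len(pairs) != 1 or len(conds) != 1:
        raise ValueError("wells must share one antibody pair and one condition")
    pos_types = {w.sample_type for w in positive_wells}
    neg_types = {w.sample_type for w in negative_wells}
    if len(pos_types) != 1 or len(neg_types) != 1:
        raise ValueError("each side must hold a single sample type")
    pos_type, neg_type = pos_types.pop(), neg_types.pop()
    if NEGATIVE_OF.get(pos_type) != neg_type:
        raise ValueError(
            f"sample pairing ({pos_type}, {neg_type}) is not type-matched"
        )
    pair = pairs.pop()
    cond = conds.pop()
    p = [w.signal for w in positive_wells]
    n = [w.signal for w in negative_wells]
    mp = sum(p) / len(p)
    mn = sum(n) / len(n)
    n_rep = min(len(p), len(n))
    if mn == 0:
        return SignalRatio(
            pair, (pos_type, neg_type), cond, None, n_rep, None,
            reason="zero negative-control mean",
        )
    ratio = mp / mn
    sd = None
    if len(p) > 1 and len(n) > 1:
        sp = _sd(p)
        sn = _sd(n)
        sd = ratio * math.sqrt((sp / mp) ** 2 + (sn / mn) ** 2) if mp > 0 else None
    return SignalRatio(pair, (pos_type, neg_type), cond, ratio, n_rep, sd)


def _sd(values: Sequence[float]) -> float:
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def specificity_call(
    ratios: Union[SignalRatio, Sequence[SignalRatio]],
    threshold: float = 1.5,
    require_all_sample_types: bool = True,
) -> tuple[dict[tuple[str, str], bool], bool]:
    """Per-pairing specificity calls and the overall validation verdict.

    A pairing passes when its ratio strictly exceeds the threshold; the
    pair is validated overall when all pairings pass (or any pairing,
    when ``require_all_sample_types`` is off).  Undefined ratios fail.
    """
    if isinstance(ratios, SignalRatio):
        ratios = [ratios]
    per_pairing: dict[tuple[str, str], bool] = {}
    for r in ratios:
        passed = r.ratio is not None and r.ratio > threshold
        r.specific_call = passed
        r.threshold_used = threshold
        per_pairing[r.sample_pairing] = passed
    calls = list(per_pairing.values())
    overall = all(calls) if require_all_sample_types else any(calls)
    return per_pairing, overall and bool(calls)


def summarize_screen(
    wells: WellInput,
    threshold: float = 1.5,
    first_pass_positive_type: str = "C9_iPSC_MN",
) -> pd.DataFrame:
    """Ratio table over the whole (antibody pair, condition) screen grid.

    One row per (capture, detection, condition, pairing), sorted by ratio
    descending.  ``flagged`` marks pairs whose iPSC-motor-neuron pairing
    exceeds the threshold — the first-pass screen for candidate pairs.
    """
    df = plate_to_frame(wells)
    rows = []
    grouped = df.groupby(["capture_ab", "detection_ab", "condition_id"])
    for (cap, det, cond), g in grouped:
        for pos_type, neg_type in NEGATIVE_OF.items():
            pos = g[g["sample_type"] == pos_type]["signal"]
            neg = g[g["sample_type"] == neg_type]["signal"]
            if pos.empty or neg.empty:
                continue
            mn = neg.mean()
            ratio = pos.mean() / mn if mn > 0 else float("nan")
            n_rep = int(min(len(pos), len(neg)))
            sd = None
            if len(pos) > 1 and len(neg) > 1 and pos.mean() > 0 and mn > 0:
                sd = ratio * math.sqrt(
                    (pos.std(ddof=1) / pos.mean()) ** 2 + (neg.std(ddof=1) / mn) ** 2
                )
            rows.append(
                {
                    "capture_ab": cap,
                    "detection_ab": det,
                    "condition_id": cond,
                    "positive_type": pos_type,
                    "negative_type": neg_type,
                    "ratio": ratio,
                    "n_replicates": n_rep,
                    "sd": sd,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    firstpass = (
        table[table["positive_type"] == first_pass_positive_type]
        .assign(hit=lambda d: d["ratio"] > threshold)
        .groupby(["capture_ab", "detection_ab"])["hit"]
        .any()
    )
    table["flagged"] = [
        bool(firstpass.get((c, d), False))
        for c, d in zip(table["capture_ab"], table["detection_ab"])
    ]
    return table.sort_values("ratio", ascending=False).reset_index(drop=True)


def ratios_to_frame(ratios: Iterable[SignalRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "capture_ab": r.antibody_pair[0],
                "detection_ab": r.antibody_pair[1],
                "positive_type": r.sample_pairing[0],
                "negative_type": r.sample_pairing[1],
                "condition_id": r.condition_id,
                "ratio": r.ratio,
                "n_replicates": r.n_replicates,
                "sd": r.sd,
                "specific_call": r.specific_call,
                "threshold_used": r.threshold_used,
                "reason": r.reason,
            }
            for r in ratios
        ]
    )
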