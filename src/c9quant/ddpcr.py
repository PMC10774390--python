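"""ddPCR transcript-variant quantification.

Droplet digital PCR partitions a reaction into ~20000 droplets; the mean
copies per droplet follows from the positive-droplet fraction by Poisson
statistics, lambda = -ln(1 - p/N).  Wells with 10 or fewer positive
droplets are non-detected (flagged, never treated as zero).  Technical
replicates are averaged within each biological replicate, target
abundances are normalised to the UBE2D2-style reference target per
biological replicate, and variant fractions / fold changes are computed
on the normalised abundances with SEM over biological replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

#: canonical target names: V2 = exon 1B-2 transcript, V3 = exon 1A-2
TARGETS = ("V2", "V3", "reference")

WELL_COLUMNS = [
    "sample_id",
    "target",
    "bio_replicate",
    "tech_replicate",
    "positive_droplets",
    "total_droplets",
]


@dataclass
class DropletWell:
    sample_id: str
    target: str
    positive_droplets: int
    total_droplets: int
    bio_replicate: int = 1
    tech_replicate: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValueError("need 0 <= positive_droplets <= total_droplets")
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")


@dataclass
class TargetQuant:
    """Reference-normalised abundance of one target in one sample."""

    sample_id: str
    target: str
    lam_mean: float                  # copies per droplet, tech-pooled, bio-averaged
    normalized_mean: Optional[float]  # lambda_target / lambda_reference
    normalized_sem: Optional[float]
    n_bio: int
    passed_threshold: bool
    per_bio_normalized: dict[int, float]
    reason: str = ""


WellInput = Union[Sequence[DropletWell], pd.DataFrame]


def wells_to_frame(wells: WellInput) -> pd.DataFrame:
    if isinstance(wells, pd.DataFrame):
        missing = set(WELL_COLUMNS) - set(wells.columns)
        if missing:
            raise ValueError(f"droplet table missing columns: {sorted(missing)}")
        return wells.copy()
    return pd.DataFrame([w.__dict__ for w in wells], columns=WELL_COLUMNS)


def poisson_lambda(well: Union[DropletWell, tuple[int, int]]) -> float:
    """Poisson-corrected mean copies per droplet for one well.

    lambda = -ln(1 - positives/total); 0 positives gives exactly 0.
    Saturated wells (positives == total) have no finite estimate.
    """
    if isinstance(well, DropletWell):
        pos, total = well.positive_droplets, well.total_droplets
    else:
        pos, total = well
    if pos == total:
        raise ValueError("saturated well: every droplet positive, lambda undefined")
    return -math.log(1.0 - pos / total)


def filter_wells(
    wells: WellInput, min_positive_droplets: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split wells into (kept, flagged) by the positive-droplet threshold.

    Wells with more than ``min_positive_droplets`` positives are kept;
    the rest are below-threshold, i.e. non-detected rather than zero.
    """
    df = wells_to_frame(wells)
    keep = df["positive_droplets"] > min_positive_droplets
    return df[keep].reset_index(drop=True), df[~keep].reset_index(drop=True)


def quantify(
    wells: WellInput,
    reference_target: str = "reference",
    min_positive_droplets: int = 10,
) -> dict[tuple[str, str], TargetQuant]:
    """Full quantification: Poisson correction, thresholding, tech pooling,
    per-biological-replicate reference normalisation, replicate stats.

    Returns ``{(sample_id, target): TargetQuant}`` for non-reference
    targets.  A sample whose reference target fails the droplet threshold
    is invalidated (``passed_threshold`` False with a reason).
    """
    kept, _ = filter_wells(wells, min_positive_droplets)
    if kept.empty:
        return {}
    kept = kept.assign(
        lam=[
            poisson_lambda((int(p), int(t)))
            for p, t in zip(kept["positive_droplets"], kept["total_droplets"])
        ]
    )
    # pool technical replicates within each biological replicate first
    pooled = (
        kept.groupby(["sample_id", "target", "bio_replicate"])["lam"]
        .mean()
        .reset_index()
    )
    out: dict[tuple[str, str], TargetQuant] = {}
    for sample_id, sample_df in pooled.groupby("sample_id"):
        ref = sample_df[sample_df["target"] == reference_target].set_index(
            "bio_replicate"
        )["lam"]
        for target, tdf in sample_df.groupby("target"):
            if target == reference_target:
                continue
            tser = tdf.set_index("bio_replicate")["lam"]
            common = sorted(set(tser.index) & set(ref.index))
            if not common:
                out[(sample_id, target)] = TargetQuant(
                    sample_id, target, float(tser.mean()), None, None, 0, False,
                    {}, reason="reference target below droplet threshold",
                )
                continue
            per_bio = {int(b): float(tser[b] / ref[b]) for b in common}
            vals = np.array(list(per_bio.values()))
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else None
            out[(sample_id, target)] = TargetQuant(
                sample_id=sample_id,
                target=target,
                lam_mean=float(tser[common].mean()),
                normalized_mean=float(vals.mean()),
                normalized_sem=sem,
                n_bio=len(vals),
                passed_threshold=True,
                per_bio_normalized=per_bio,
            )
    return out


def normalize(target_quant: TargetQuant) -> Optional[float]:
    """Reference-normalised abundance of one quantified target."""
    return target_quant.normalized_mean if target_quant.passed_threshold else None


def variant_fractions(
    v2_quant: TargetQuant, v3_quant: TargetQuant
) -> tuple[Optional[float], Optional[float]]:
    """Fractions of transcripts carrying exon 1B (V2) vs exon 1A (V3).

    Computed on the reference-normalised abundances; a target invalidated
    by the droplet threshold contributes zero abundance only if the other
    is detected.  Returns (None, None) when neither target is quantified.
    """
    n2 = v2_quant.normalized_mean if v2_quant.passed_threshold else 0.0
    n3 = v3_quant.normalized_mean if v3_quant.passed_threshold else 0.0
    total = (n2 or 0.0) + (n3 or 0.0)
    if total <= 0:
        return None, None
    return n2 / total, n3 / total


def fold_change(
    condition: TargetQuant, baseline: TargetQuant
) -> tuple[Optional[float], Optional[float], str]:
    """Fold change of normalised abundance, condition over baseline.

    Returns (fold, sem, reason); SEM by first-order error propagation.
    Undefined (None) when the baseline is non-detected or zero.
    """
    if not baseline.passed_threshold or not baseline.normalized_mean:
        return None, None, "baseline non-detected or zero"
    if not condition.passed_threshold or condition.normalized_mean is None:
        return None, None, "condition non-detected"
    fold = condition.normalized_mean / baseline.normalized_mean
    sem = None
    if condition.normalized_sem is not None and baseline.normalized_sem is not None:
        rel = math.sqrt(
            (condition.normalized_sem / condition.normalized_mean) ** 2
            + (baseline.normalized_sem / baseline.normalized_mean) ** 2
        )
        sem = fold * rel
    return fold, sem, ""


def quants_to_frame(quants: Iterable[TargetQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "target": q.target,
                "lam_mean": q.lam_mean,
                "normalized_mean": q.normalized_mean,
                "normalized_sem": q.normalized_sem,
                "n_bio": q.n_bio,
                "passed_threshold": q.passed_threshold,
                "reason": q.reason,
            }
            for q in quants
        ]
    )
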