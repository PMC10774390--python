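"""CRISPR editing-outcome measurement and clone-purity classification.

A dual-gRNA excision removes a window spanning the repeat tract.  Because
the tract itself is unalignable at expansion scale, the per-read excision
size is measured from flank landmarks: two unique probes taken from the
reference template just outside the maximal excisable window are aligned
to the read (edlib infix alignment) and the excision equals the expected
unedited span between them minus the observed span.  Reads whose tract
still carries at least ``retained_min_repeats`` units are classified as
retained expansions instead.

Per-read measurements are grouped into editing outcomes per allele, and
the set of surviving outcomes (above a minimum read fraction) classifies
the clone: unedited, heterozygous excision, homozygous excision, or
impure (more than one outcome on an allele — a mixed clone).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from ._util import revcomp
from .config import LocusConfig
from .repeatcall import CcsRead, count_repeats, genotype_snps

INTACT = "intact"
EXCISION = "excision"
RETAINED = "retained_expansion"


@dataclass
class EditOutcome:
    allele_label: str
    kind: str                      # intact | excision | retained_expansion
    excision_length_nt: int        # 0 for intact / retained
    read_count: int
    fraction: float
    repeat_count_if_retained: Optional[int] = None


@dataclass
class ClonalityReport:
    classification: str            # unedited | heterozygous_excision |
    #                                homozygous_excision | impure
    outcomes: list[EditOutcome]
    dominant: Optional[EditOutcome]
    per_allele_dominant: dict[str, EditOutcome]
    min_outcome_fraction: float
    discarded_fraction: float
    qc_excluded_reads: int = 0


@dataclass
class ReadEdit:
    """One read's measured editing outcome (pre-grouping)."""

    read_id: str
    allele_label: str
    kind: str
    excision_length_nt: int        # signed raw measurement; <=0 ~ intact
    repeat_count: int = 0


def _template_tract(template: str, locus: LocusConfig) -> tuple[int, int]:
    """Locate the repeat tract in a noiseless template: (start, end)."""
    pos = template.find(locus.anchor5 + locus.repeat_unit)
    if pos < 0:
        # unexpanded or zero-repeat template: anchor alone
        pos = template.find(locus.anchor5)
        if pos < 0:
            raise ValueError("template lacks the 5' anchor")
    start = pos + len(locus.anchor5)
    end = start
    unit = locus.repeat_unit
    while template[end : end + 6] == unit:
        end += 6
    return start, end


def _landmarks(
    template: str,
    locus: LocusConfig,
    flank_margin: int,
    probe_len: int,
    gap: int,
) -> tuple[str, str, int]:
    """Left/right landmark probes and the expected unedited span between them."""
    t0, t1 = _template_tract(template, locus)
    w0, w1 = t0 - flank_margin, t1 + flank_margin
    if w0 - gap - probe_len < 0 or w1 + gap + probe_len > len(template):
        raise ValueError("flanks too short for landmark placement")
    left = template[w0 - gap - probe_len : w0 - gap]
    right = template[w1 + gap : w1 + gap + probe_len]
    expected_span = (w1 + gap) - (w0 - gap)
    return left, right, expected_span


def orient_by_probe(sequence: str, probe: str) -> tuple[str, Optional[str]]:
    """Orient a read by whichever strand aligns the landmark probe better."""
    fwd = edlib.align(probe, sequence, mode="HW", task="distance")["editDistance"]
    rc = revcomp(sequence)
    rev = edlib.align(probe, rc, mode="HW", task="distance")["editDistance"]
    limit = len(probe) // 4
    if min(fwd, rev) > limit:
        return sequence, None
    return (sequence, "+") if fwd <= rev else (rc, "-")


def measure_excision(
    oriented_seq: str,
    template: str,
    locus: LocusConfig,
    flank_margin: int = 30,
    probe_len: int = 60,
    gap: int = 6,
    retained_min_repeats: int = 50,
) -> tuple[int, str, int]:
    """Measure one read's excision against the unedited allele template.

    Returns ``(excision_length_nt, kind, repeat_count)``.  The excision
    length is the expected unedited span between the flank landmarks minus
    the observed span in the read; reads still carrying a large repeat
    tract are classified ``retained_expansion``.

    Raises ``ValueError`` when either landmark cannot be aligned (the read
    then belongs in the QC bucket, not in outcome grouping).
    """
    # a read still carrying a large tract is a retained expansion no matter
    # what the span against its reference measures (random indels drift the
    # span over a multi-kb tract); excised reads lack the counting anchor
    try:
        repeats, _, _ = count_repeats(oriented_seq, locus)
    except ValueError:
        repeats = 0
    if repeats >= retained_min_repeats:
        return 0, RETAINED, repeats

    left, right, expected = _landmarks(template, locus, flank_margin, probe_len, gap)
    limit = probe_len // 4
    res_l = edlib.align(left, oriented_seq, mode="HW", task="locations")
    res_r = edlib.align(right, oriented_seq, mode="HW", task="locations")
    if res_l["editDistance"] > limit or res_r["editDistance"] > limit:
        raise ValueError("flank landmarks unalignable")
    end_l = res_l["locations"][0][1]      # inclusive end of left probe
    start_r = res_r["locations"][0][0]
    observed = start_r - (end_l + 1)
    excision = expected - observed
    kind = EXCISION if excision > 0 else INTACT
    return excision, kind, repeats


def group_outcomes(
    measurements: Sequence[ReadEdit],
    collapse_tolerance: int = 0,
    snap_radius: int = 2,
    satellite_max_ratio: float = 0.45,
) -> list[EditOutcome]:
    """Group per-read measurements into editing outcomes per allele.

    Measurements are grouped by (allele, kind, excision length), merging
    lengths within ``collapse_tolerance`` (default 0: outcomes a few
    nucleotides apart stay distinct, as with the 17 vs 19 nt pair).  A
    separate satellite-absorption step then folds sparse neighbouring
    lengths — the +-1..2 nt scatter produced by random indel errors
    between the landmarks — into the adjacent dominant lengths.  Peaks
    are identified against the raw histogram in descending order: a
    length is a peak unless an already-accepted peak within
    ``snap_radius`` nt carries at least ``1/satellite_max_ratio`` times
    its reads, so genuinely distinct outcomes of comparable abundance
    (the paper's 2:1 pair two nucleotides apart) are never merged.  Each
    satellite length's reads are then divided among the peaks within
    reach proportionally to peak abundance — the symmetric-noise
    posterior — rather than handed wholesale to one side.

    Fractions are computed over all grouped reads and sum to 1.
    """
    total = len(measurements)
    outcomes: list[EditOutcome] = []
    if total == 0:
        return outcomes

    retained = [m for m in measurements if m.kind == RETAINED]
    sized = [m for m in measurements if m.kind != RETAINED]

    by_allele: dict[str, Counter] = defaultdict(Counter)
    for m in sized:
        by_allele[m.allele_label][m.excision_length_nt] += 1

    for allele, tally in sorted(by_allele.items()):
        # optional merging of genuinely-close outcomes
        values = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if collapse_tolerance > 0:
            merged: dict[int, int] = {}
            for v, n in values:
                home = next(
                    (p for p in merged if abs(p - v) <= collapse_tolerance), None
                )
                if home is None:
                    merged[v] = n
                else:
                    merged[home] += n
            values = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))

        counts = dict(values)
        if snap_radius > 0 and satellite_max_ratio > 0:
            # peak identification against the raw histogram, loudest first
            peaks: list[int] = []
            for v, n in values:
                dominated = any(
                    abs(p - v) <= snap_radius
                    and n <= satellite_max_ratio * counts[p]
                    for p in peaks
                )
                if not dominated:
                    peaks.append(v)
            # proportional assignment of satellite reads to nearby peaks
            final: dict[int, float] = {p: float(counts[p]) for p in peaks}
            for v, n in values:
                if v in final:
                    continue
                nearby = [p for p in peaks if abs(p - v) <= snap_radius]
                weight = sum(counts[p] for p in nearby)
                for p in nearby:
                    final[p] += n * counts[p] / weight
        else:
            final = {v: float(n) for v, n in values}

        for v, n in sorted(final.items()):
            if n <= 0:
                continue
            kind = EXCISION if v > 0 else INTACT
            outcomes.append(
                EditOutcome(
                    allele_label=allele,
                    kind=kind,
                    excision_length_nt=v if v > 0 else 0,
                    read_count=round(n),
                    fraction=n / total,
                )
            )

    by_allele_ret: dict[str, list[ReadEdit]] = defaultdict(list)
    for m in retained:
        by_allele_ret[m.allele_label].append(m)
    for allele, members in sorted(by_allele_ret.items()):
        reps = Counter(m.repeat_count for m in members)
        best = max(reps.values())
        mode = min(r for r, n in reps.items() if n == best)
        outcomes.append(
            EditOutcome(
                allele_label=allele,
                kind=RETAINED,
                excision_length_nt=0,
                read_count=len(members),
                fraction=len(members) / total,
                repeat_count_if_retained=mode,
            )
        )
    outcomes.sort(key=lambda o: (-o.fraction, -o.excision_length_nt, o.allele_label))
    return outcomes


def classify_clonality(
    outcomes: Sequence[EditOutcome],
    min_outcome_fraction: float = 0.05,
    qc_excluded_reads: int = 0,
) -> ClonalityReport:
    """Classify clone purity from grouped editing outcomes.

    Outcomes below ``min_outcome_fraction`` are discarded as noise.  An
    allele with two or more surviving outcomes marks the clone impure (a
    mixed pool, not a single clone).  Otherwise the per-allele kinds give
    the classification.  The dominant outcome is the highest-fraction one;
    ties break toward the larger excision, then the lexically smaller
    allele label.
    """
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    surviving = [o for o in outcomes if o.fraction >= min_outcome_fraction]
    discarded_fraction = sum(o.fraction for o in outcomes) - sum(
        o.fraction for o in surviving
    )
    per_allele: dict[str, list[EditOutcome]] = defaultdict(list)
    for o in surviving:
        per_allele[o.allele_label].append(o)

    if any(len(v) >= 2 for v in per_allele.values()):
        classification = "impure"
    else:
        kinds = [v[0].kind for v in per_allele.values()]
        n_exc = sum(k == EXCISION for k in kinds)
        if n_exc == 0:
            classification = "unedited"
        elif n_exc == len(kinds) and len(kinds) >= 2:
            classification = "homozygous_excision"
        else:
            classification = "heterozygous_excision"

    def rank(o: EditOutcome):
        return (-o.fraction, -o.excision_length_nt, o.allele_label)

    dominant = min(surviving, key=rank) if surviving else None
    per_allele_dominant = {
        allele: min(v, key=rank) for allele, v in sorted(per_allele.items())
    }
    return ClonalityReport(
        classification=classification,
        outcomes=list(outcomes),
        dominant=dominant,
        per_allele_dominant=per_allele_dominant,
        min_outcome_fraction=min_outcome_fraction,
        discarded_fraction=discarded_fraction,
        qc_excluded_reads=qc_excluded_reads,
    )


def analyze_clone(
    reads: Iterable[CcsRead],
    templates: dict[str, str],
    locus: LocusConfig,
    min_outcome_fraction: float = 0.05,
    retained_min_repeats: int = 50,
    collapse_tolerance: int = 0,
    flank_margin: int = 30,
) -> ClonalityReport:
    """End-to-end clone analysis: orient, phase, measure, group, classify.

    ``templates`` maps allele labels to their unedited reference template;
    reads are assigned to alleles via the phase-informative SNPs.  Reads
    that cannot be oriented, phased, or landmark-aligned, or that fail the
    pass filter, land in the QC bucket and are excluded from grouping.
    """
    if not templates:
        raise ValueError("at least one allele template is required")
    first_template = next(iter(templates.values()))
    left_probe, _, _ = _landmarks(first_template, locus, flank_margin, 60, 6)
    informative = [s for s in locus.snps if s.phased_informative]
    base_to_allele: dict[str, dict[str, str]] = {
        s.snp_id: {s.ref_base: s.ref_allele, s.alt_base: s.alt_allele}
        for s in informative
    }

    measurements: list[ReadEdit] = []
    qc = 0
    for read in reads:
        if read.passes < locus.min_passes:
            qc += 1
            continue
        seq, strand = orient_by_probe(read.sequence, left_probe)
        if strand is None:
            qc += 1
            continue
        allele: Optional[str] = None
        if informative:
            genotype = genotype_snps(seq, locus)
            for snp in informative:
                base = genotype.get(snp.snp_id)
                if base is not None:
                    allele = base_to_allele[snp.snp_id][base]
                    break
        else:
            allele = next(iter(templates))
        if allele is None or allele not in templates:
            qc += 1
            continue
        try:
            exc, kind, reps = measure_excision(
                seq,
                templates[allele],
                locus,
                flank_margin=flank_margin,
                retained_min_repeats=retained_min_repeats,
            )
        except ValueError:
            qc += 1
            continue
        measurements.append(ReadEdit(read.read_id, allele, kind, exc, reps))
    if not measurements:
        raise ValueError("no reads survived QC; cannot classify clone")
    outcomes = group_outcomes(measurements, collapse_tolerance=collapse_tolerance)
    return classify_clonality(
        outcomes, min_outcome_fraction=min_outcome_fraction, qc_excluded_reads=qc
    )


def report_to_dict(report: ClonalityReport) -> dict:
    """JSON-serialisable clone report."""

    def out(o: EditOutcome) -> dict:
        return {
            "allele": o.allele_label,
            "kind": o.kind,
            "excision_length_nt": o.excision_length_nt,
            "read_count": o.read_count,
            "fraction": round(o.fraction, 6),
            "repeat_count_if_retained": o.repeat_count_if_retained,
        }

    return {
        "classification": report.classification,
        "outcomes": [out(o) for o in report.outcomes],
        "dominant": out(report.dominant) if report.dominant else None,
        "per_allele_dominant": {
            a: out(o) for a, o in report.per_allele_dominant.items()
        },
        "min_outcome_fraction": report.min_outcome_fraction,
        "discarded_fraction": round(report.discarded_fraction, 6),
        "qc_excluded_reads": report.qc_excluded_reads,
    }
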