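"""Grouping on-target reads into the two C9orf72 alleles.

A diploid sample yields a bimodal per-read repeat-count distribution (the
WT-control line: roughly equal read numbers at 2 and 10 repeats).  Reads
are partitioned either by a phase-informative heterozygous SNP — the
preferred route, since a phased SNP identifies the allele even when repeat
lengths collide after editing — or, failing that, by the largest gap in
the sorted repeat counts subject to a minimum mode separation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import LocusConfig
from .repeatcall import RepeatCall


@dataclass
class AlleleCluster:
    """Per-allele repeat-length summary over its member reads."""

    allele_label: str
    read_ids: set[str]
    repeat_mode: int
    repeat_mean: float
    repeat_sd: float
    snp_haplotype: dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def read_count(self) -> int:
        return len(self.read_ids)


def length_to_repeats(tract_length_nt: int) -> int:
    """Convert a tract length in nucleotides to whole repeat units.

    Partial trailing units are not counted: 8950 nt -> 1491 repeats.
    """
    if tract_length_nt < 0:
        raise ValueError("tract length must be >= 0")
    return tract_length_nt // 6


def _mode(counts: list[int]) -> int:
    # ties broken toward the smaller count for reproducibility
    tally = Counter(counts)
    best = max(tally.values())
    return min(v for v, n in tally.items() if n == best)


def _build_cluster(label: str, members: list[RepeatCall], locus: LocusConfig) -> AlleleCluster:
    counts = [c.repeat_count for c in members]
    mean = sum(counts) / len(counts)
    sd = math.sqrt(sum((x - mean) ** 2 for x in counts) / (len(counts) - 1)) if len(counts) > 1 else 0.0
    haplotype: dict[str, Optional[str]] = {}
    for snp in locus.snps:
        obs = Counter(
            c.snp_genotype.get(snp.snp_id)
            for c in members
            if c.snp_genotype.get(snp.snp_id) is not None
        )
        haplotype[snp.snp_id] = obs.most_common(1)[0][0] if obs else None
    return AlleleCluster(
        allele_label=label,
        read_ids={c.read_id for c in members},
        repeat_mode=_mode(counts),
        repeat_mean=mean,
        repeat_sd=sd,
        snp_haplotype=haplotype,
    )


def cluster_alleles(
    calls: Iterable[RepeatCall],
    locus: LocusConfig,
    min_reads_per_allele: int = 5,
    min_mode_gap: int = 5,
) -> tuple[AlleleCluster, Optional[AlleleCluster]]:
    """Partition on-target calls into one or two allele clusters.

    SNP partition takes precedence when a phase-informative SNP shows both
    bases at adequate depth; otherwise a largest-gap split of the sorted
    repeat counts is used (minimum separation ``min_mode_gap``).  A single
    cluster is returned when no valid split exists (homozygous-like).
    Reads with a missing genotype at the informative SNP are assigned to
    the nearest repeat-length cluster; ties go to the larger cluster.
    """
    on_target = [c for c in calls if c.on_target]
    if len(on_target) < min_reads_per_allele:
        raise ValueError(
            f"need at least min_reads_per_allele={min_reads_per_allele} "
            f"on-target reads, got {len(on_target)}"
        )

    # --- SNP partition -------------------------------------------------
    for snp in locus.snps:
        if not snp.phased_informative:
            continue
        ref_members = [c for c in on_target if c.snp_genotype.get(snp.snp_id) == snp.ref_base]
        alt_members = [c for c in on_target if c.snp_genotype.get(snp.snp_id) == snp.alt_base]
        if len(ref_members) >= min_reads_per_allele and len(alt_members) >= min_reads_per_allele:
            missing = [
                c
                for c in on_target
                if c.snp_genotype.get(snp.snp_id) not in (snp.ref_base, snp.alt_base)
            ]
            groups = {snp.ref_allele: ref_members, snp.alt_allele: alt_members}
            modes = {lab: _mode([c.repeat_count for c in g]) for lab, g in groups.items()}
            for c in missing:
                dists = {lab: abs(c.repeat_count - m) for lab, m in modes.items()}
                dmin = min(dists.values())
                tied = [lab for lab, d in dists.items() if d == dmin]
                target = max(tied, key=lambda lab: len(groups[lab]))
                groups[target].append(c)
            clusters = sorted(
                (_build_cluster(lab, g, locus) for lab, g in groups.items()),
                key=lambda cl: cl.repeat_mode,
            )
            return clusters[0], clusters[1]

    # --- length partition ----------------------------------------------
    ordered = sorted(on_target, key=lambda c: c.repeat_count)
    counts = [c.repeat_count for c in ordered]
    gaps = [(counts[i + 1] - counts[i], i) for i in range(len(counts) - 1)]
    best_gap, split_at = max(gaps, key=lambda g: g[0]) if gaps else (0, 0)
    if best_gap >= min_mode_gap:
        low, high = ordered[: split_at + 1], ordered[split_at + 1 :]
        if len(low) >= min_reads_per_allele and len(high) >= min_reads_per_allele:
            return (
                _build_cluster("allele1", low, locus),
                _build_cluster("allele2", high, locus),
            )
    return _build_cluster("allele1", on_target, locus), None


def summarize_allele(cluster: AlleleCluster, dispersion_sd_max: float = 3.0) -> dict:
    """Summary record mirroring the per-allele report table.

    The modal repeat count is the headline size; the mean is reported
    alongside it (Southern-blot comparisons track the mean).  Clusters
    whose repeat-count spread exceeds ``dispersion_sd_max`` are flagged as
    high-dispersion — a sign of merged alleles or a mixed clone.
    """
    if cluster.read_count == 0:
        raise ValueError("cannot summarize an empty cluster")
    return {
        "allele_label": cluster.allele_label,
        "repeat_mode": cluster.repeat_mode,
        "repeat_mean": round(cluster.repeat_mean, 3),
        "repeat_sd": round(cluster.repeat_sd, 3),
        "read_count": cluster.read_count,
        "snp_haplotype": dict(cluster.snp_haplotype),
        "high_dispersion": cluster.repeat_sd > dispersion_sd_max,
    }
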