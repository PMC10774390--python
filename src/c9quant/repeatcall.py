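"""Per-read GGGGCC repeat calling from CCS long reads.

Each sequenced molecule spans the Cas9-excised C9orf72 fragment: a 5'
flank ending in the CGCCC counting anchor, the GGGGCC tract, and the 3'
flank.  Molecules are sequenced in both orientations (the minus-strand
unit reads GGCCCC), so every read is first oriented onto the plus strand.
Repeat counting then scans 6-nt windows immediately after the anchor,
classifying each as a repeat (edit distance to the unit within tolerance;
the scan advances by the aligned window length so indels do not shift the
reading frame) or as sequencing error.  The tract ends at the 3' anchor or
after ``termination_run`` consecutive unit-widths without a repeat match.

A read is on-target when both anchors were found and the molecule was
traversed at least ``min_passes`` times — i.e. it sequenced the entire
excised region at circular-consensus quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import pandas as pd

from ._util import find_approx, hamming, levenshtein, revcomp
from .config import LocusConfig

logger = logging.getLogger(__name__)


@dataclass
class CcsRead:
    """One circular-consensus read with its pass count."""

    read_id: str
    sequence: str
    passes: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.passes < 1:
            raise ValueError("pass count must be >= 1")


@dataclass
class RepeatCall:
    """Per-read repeat-calling result."""

    read_id: str
    strand: Optional[str] = None        # '+', '-' or None when unoriented
    anchor5_found: bool = False
    anchor3_found: bool = False
    repeat_count: int = 0
    error_window_count: int = 0
    tract_length_nt: int = 0
    passes: int = 1
    on_target: bool = False
    snp_genotype: dict[str, Optional[str]] = field(default_factory=dict)
    # waterfall track: (offset from anchor end, length, 'repeat'|'error')
    segments: list[tuple[int, int, str]] = field(default_factory=list)


def orient_read(read: CcsRead, locus: LocusConfig) -> tuple[str, Optional[str]]:
    """Orient a read so the 5' anchor lies on the plus strand.

    Returns ``(sequence, strand)``; strand is ``None`` when the anchor is
    found on neither strand (the read is flagged off-target downstream).
    Exact anchor hits are preferred over mismatched ones.
    """
    fwd = find_approx(read.sequence, locus.anchor5, locus.anchor_max_mismatches)
    rc = revcomp(read.sequence)
    rev = find_approx(rc, locus.anchor5, locus.anchor_max_mismatches)
    if fwd is None and rev is None:
        return read.sequence, None
    if rev is None or (fwd is not None and fwd[1] <= rev[1]):
        return read.sequence, "+"
    return rc, "-"


def _scan_tract(
    seq: str, start: int, locus: LocusConfig
) -> tuple[int, int, int, bool, list[tuple[int, int, str]]]:
    """Scan repeat windows from ``start``.

    Returns (repeat_count, error_window_count, tract_length_nt,
    anchor3_found, segments).
    """
    unit = locus.repeat_unit
    maxd = locus.max_unit_edit_distance
    anchor3 = locus.anchor3
    a3_len = len(anchor3)
    lookahead = 6 * locus.termination_run
    n = len(seq)

    def window_match(i: int) -> Optional[int]:
        """Aligned window length at ``i`` if within tolerance, else None."""
        if seq[i : i + 6] == unit:
            return 6
        best_len, best_d = None, maxd + 1
        for lw in (6, 5, 7):
            d = levenshtein(seq[i : i + lw], unit)
            if d < best_d:
                best_d, best_len = d, lw
        return best_len if best_d <= maxd else None

    def at_anchor3(i: int) -> bool:
        if not a3_len or i + a3_len > n + locus.anchor_max_mismatches:
            return False
        return hamming(seq[i : i + a3_len], anchor3) <= locus.anchor_max_mismatches

    repeats = errors = 0
    segments: list[tuple[int, int, str]] = []
    i = start
    tract_end = start
    anchor3_found = False
    while i < n:
        if at_anchor3(i):
            anchor3_found = True
            break
        lw = window_match(i)
        if lw is not None:
            repeats += 1
            segments.append((i - start, lw, "repeat"))
            i += lw
            tract_end = i
            continue
        # failed window: resynchronise on the next in-tolerance window or
        # the 3' anchor within the termination lookahead
        resync = None
        for j in range(i + 1, min(i + lookahead, n) + 1):
            if at_anchor3(j):
                resync, anchor3_found = j, True
                break
            if j < n and window_match(j) is not None:
                resync = j
                break
        if resync is None:
            break
        skipped = resync - i
        n_err = max(1, round(skipped / 6))
        errors += n_err
        segments.append((i - start, skipped, "error"))
        i = resync
        tract_end = resync
        if anchor3_found:
            break
    if anchor3_found:
        tract_length = i - start if not segments else max(tract_end, i) - start
    else:
        # drop trailing error windows that merely ran into the flank
        tract_length = (segments[-1][0] + segments[-1][1]) if segments else 0
        while segments and segments[-1][2] == "error":
            last = segments.pop()
            errors -= max(1, round(last[1] / 6))
            tract_length = (segments[-1][0] + segments[-1][1]) if segments else 0
    return repeats, errors, tract_length, anchor3_found, segments


def count_repeats(
    oriented_seq: str, locus: LocusConfig, anchor_end: Optional[int] = None
) -> tuple[int, int, int]:
    """Count repeat units immediately after the 5' anchor.

    ``anchor_end`` may be supplied when the anchor was already located;
    otherwise the leftmost (exact-preferred) anchor hit is used.  Returns
    ``(repeat_count, error_window_count, tract_length_nt)``; ``(0, 0, 0)``
    when nothing follows the anchor.
    """
    if anchor_end is None:
        hit = find_approx(oriented_seq, locus.anchor5, locus.anchor_max_mismatches)
        if hit is None:
            raise ValueError("5' anchor not found in oriented sequence")
        anchor_end = hit[0] + len(locus.anchor5)
    r, e, t, _, _ = _scan_tract(oriented_seq, anchor_end, locus)
    return r, e, t


def classify_on_target(
    anchor5_found: bool, anchor3_found: bool, passes: int, locus: LocusConfig
) -> bool:
    """On-target = sequenced the entire excised region at >= min_passes."""
    return anchor5_found and anchor3_found and passes >= locus.min_passes


def genotype_snps(
    oriented_seq: str,
    locus: LocusConfig,
    probe_half_width: int = 12,
) -> dict[str, Optional[str]]:
    """Genotype the configured SNPs on one oriented read.

    For each SNP two probes are built from the reference flank context —
    one carrying the ref base, one the alt — and aligned infix against the
    read (edlib).  The genotype is the base whose probe aligns with the
    smaller edit distance; ties or poor alignments of both probes yield
    ``None`` (missing), e.g. when the SNP sits inside an excised window.
    """
    out: dict[str, Optional[str]] = {}
    lf = locus.left_flank
    k = probe_half_width
    for snp in locus.snps:
        pos = snp.template_position
        if not lf or pos >= len(lf):
            out[snp.snp_id] = None
            continue
        left = lf[max(0, pos - k) : pos]
        right = lf[pos + 1 : pos + 1 + k]
        max_dist = (len(left) + len(right) + 1) // 4
        dists = {}
        for base in (snp.ref_base, snp.alt_base):
            probe = left + base + right
            res = edlib.align(probe, oriented_seq, mode="HW", task="distance")
            dists[base] = res["editDistance"]
        d_ref, d_alt = dists[snp.ref_base], dists[snp.alt_base]
        if d_ref == d_alt or min(d_ref, d_alt) > max_dist:
            out[snp.snp_id] = None
        else:
            out[snp.snp_id] = snp.ref_base if d_ref < d_alt else snp.alt_base
    return out


def call_read(read: CcsRead, locus: LocusConfig) -> RepeatCall:
    """Orient, count, genotype and filter a single read."""
    seq, strand = orient_read(read, locus)
    call = RepeatCall(read_id=read.read_id, strand=strand, passes=read.passes)
    if strand is None:
        call.snp_genotype = {s.snp_id: None for s in locus.snps}
        return call
    hit = find_approx(seq, locus.anchor5, locus.anchor_max_mismatches)
    assert hit is not None
    call.anchor5_found = True
    anchor_end = hit[0] + len(locus.anchor5)
    r, e, t, a3, segs = _scan_tract(seq, anchor_end, locus)
    call.repeat_count, call.error_window_count, call.tract_length_nt = r, e, t
    call.anchor3_found = a3
    call.segments = segs
    call.snp_genotype = genotype_snps(seq, locus)
    call.on_target = classify_on_target(True, a3, read.passes, locus)
    return call


def call_reads(reads: Iterable[CcsRead], locus: LocusConfig) -> list[RepeatCall]:
    """Batch driver: one RepeatCall per read, order preserved.

    Unreadable records are skipped with a warning, never aborting the batch.
    """
    calls: list[RepeatCall] = []
    for read in reads:
        try:
            calls.append(call_read(read, locus))
        except Exception:  # noqa: BLE001 - batch robustness by contract
            logger.warning("skipping unreadable read %r", getattr(read, "read_id", "?"))
    return calls


def calls_to_frame(calls: Iterable[RepeatCall]) -> pd.DataFrame:
    """Per-read call table (one row per read, SNP genotypes as columns)."""
    rows = []
    for c in calls:
        row = {
            "read_id": c.read_id,
            "strand": c.strand or "",
            "anchor5_found": c.anchor5_found,
            "anchor3_found": c.anchor3_found,
            "repeat_count": c.repeat_count,
            "error_window_count": c.error_window_count,
            "tract_length_nt": c.tract_length_nt,
            "passes": c.passes,
            "on_target": c.on_target,
        }
        for snp_id, base in c.snp_genotype.items():
            row[f"snp_{snp_id}"] = base if base is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def waterfall_tracks(calls: Iterable[RepeatCall]) -> list[dict]:
    """JSON-serialisable per-read classification tracks for waterfall plots."""
    tracks = []
    for c in sorted(calls, key=lambda c: c.repeat_count):
        tracks.append(
            {
                "read_id": c.read_id,
                "repeat_count": c.repeat_count,
                "on_target": c.on_target,
                "segments": [
                    {"start": s, "length": ln, "kind": kind}
                    for s, ln, kind in c.segments
                ],
            }
        )
    return tracks


def plot_waterfall(calls: Iterable[RepeatCall], ax=None):
    """Waterfall rendering: one horizontal line per molecule, repeat windows
    in blue, sequencing-error windows in grey."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    tracks = waterfall_tracks(calls)
    for y, tr in enumerate(tracks):
        for seg in tr["segments"]:
            color = "#2060c0" if seg["kind"] == "repeat" else "#b0b0b0"
            ax.hlines(y, seg["start"], seg["start"] + seg["length"], color=color, lw=2)
    ax.set_xlabel("nt after 5' anchor")
    ax.set_ylabel("CCS read")
    return ax
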