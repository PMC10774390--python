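"""Synthetic inputs for every pipeline stage.

The generator emulates the study's assay structure end to end: diploid
Cas9-excised template molecules (flanks hosting heterozygous SNPs, the
CGCCC counting anchor, a GGGGCC tract of 0-2000 units), multi-pass CCS
reads with i.i.d. per-base substitution/indel error emitted in both
orientations, edited clone pools with defined excision sizes and mixture
proportions, Poisson droplet partitioning for ddPCR wells, and MSD plate
signals with multiplicative lognormal noise over a background.

Flank sequences are scrubbed so that no window lies within one edit of
the repeat unit or one mismatch of the counting anchor (on either
strand): the real locus flanks are likewise distinguishable from the
tract, and scrubbing makes noiseless recovery exact by construction.

A registry of named fixtures reproduces the worked examples used across
the figures (WT 2/10 diploid, the three edited clones, the WT-neuron
ddPCR ratio, the antibody screen grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional

import numpy as np

from ._util import hamming, levenshtein, revcomp
from .config import LocusConfig, SnpDef
from .ddpcr import DropletWell
from .msd import NEGATIVE_OF, MsdWell
from .repeatcall import CcsRead

_BASES = "ACGT"
_B2I = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _B2I[ord(_b)] = _i
_I2B = np.frombuffer(_BASES.encode(), dtype=np.uint8)
_RC_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _RC_TABLE[_a] = _b

# deterministic seed for fixture reference flanks: fixtures are versioned
# objects, identical across runs regardless of the user-facing seed
_FIXTURE_FLANK_SEED = 987_201


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass
class TemplateSpec:
    """One unedited allele template: flanks, repeat count, SNP overrides."""

    allele_label: str
    left_flank: str
    repeat_count: int
    right_flank: str
    snp_overrides: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.repeat_count < 0:
            raise ValueError("repeat_count must be >= 0")


@dataclass
class ReadSimParams:
    """CCS read simulation: i.i.d. per-base error and pass-count sampling."""

    n_reads: int
    sub_rate: float = 0.004
    ins_rate: float = 0.003
    del_rate: float = 0.003
    pass_count_distribution: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.05, 2: 0.05, 3: 0.20, 4: 0.20, 5: 0.20, 6: 0.15, 8: 0.10, 10: 0.05,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        total = sum(self.pass_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pass_count_distribution must sum to 1")


@dataclass
class OutcomeSpec:
    """One editing outcome in a (possibly mixed) clone pool."""

    allele_label: str
    excision_length_nt: int = 0
    retain_expansion: bool = False
    proportion: float = 1.0


@dataclass
class EditSimSpec:
    outcomes: list[OutcomeSpec]
    seed: int = 0
    excisable_flank_margin: int = 30

    def __post_init__(self) -> None:
        total = sum(o.proportion for o in self.outcomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("outcome proportions must sum to 1")


@dataclass
class DdpcrSimParams:
    """Poisson droplet partitioning for one sample across replicate wells."""

    true_lambda: dict[str, float]
    droplets_per_well: int = 20000
    n_replicates: int = 3        # biological replicates
    n_tech_replicates: int = 3   # technical replicates per biological one
    sample_id: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.droplets_per_well <= 0:
            raise ValueError("droplets_per_well must be positive")
        if any(v < 0 for v in self.true_lambda.values()):
            raise ValueError("true_lambda values must be >= 0")


@dataclass
class MsdSimParams:
    """MSD plate simulation over an (antibody pair, sample type) grid.

    ``true_abundance`` maps (capture_ab, detection_ab, sample_type) to a
    multiplicative signal scale over ``background_signal``; negative
    control sample types are forced to scale 1.
    """

    true_abundance: dict[tuple[str, str, str], float]
    background_signal: float = 100.0
    noise_cv: float = 0.05
    n_replicates: int = 2
    condition_id: str = "cond-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_signal <= 0:
            raise ValueError("background_signal must be positive")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValueError("noise_cv must lie in [0, 1)")


# --------------------------------------------------------------------------
# flank construction
# --------------------------------------------------------------------------

def _violations(
    s: str, unit: str, anchor5: str, protected: tuple[tuple[int, int], ...] = ()
) -> list[tuple[int, int]]:
    """Windows within 1 edit of a repeat unit or 1 mismatch of an anchor.

    ``protected`` intervals mark genuine motif placements (the intended
    anchor and the adjacent repeat unit); any window that fully contains a
    protected interval is the scanner's intended match, not a hazard.
    """
    bad: list[tuple[int, int]] = []
    motifs6 = (unit, revcomp(unit))
    anchors = (anchor5, revcomp(anchor5))
    n = len(s)

    def shielded(i: int, lw: int) -> bool:
        return any(i <= ps and ps + pl <= i + lw for ps, pl in protected)

    for i in range(n):
        for a in anchors:
            la = len(a)
            if i + la <= n and hamming(s[i : i + la], a) <= 1 and not shielded(i, la):
                bad.append((i, la))
        for lw in (5, 6, 7):
            if i + lw > n or shielded(i, lw):
                continue
            w = s[i : i + lw]
            for m in motifs6:
                if levenshtein(w, m) <= 1:
                    bad.append((i, lw))
                    break
    return bad


def _scrub_core(
    core: list[str],
    contexts: Callable[[str], list[tuple[str, int, tuple[tuple[int, int], ...]]]],
    unit: str,
    anchor5: str,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> str:
    """Redraw flank bases until no context window resembles a motif.

    ``contexts(core_str)`` yields (assembled string, offset of the mutable
    core within it, protected motif intervals); violations touching only
    immutable context bases are likewise ignored.
    """
    for _ in range(max_rounds):
        dirty = False
        text = "".join(core)
        for assembled, offset, protected in contexts(text):
            for start, length in _violations(assembled, unit, anchor5, protected):
                mutable = [
                    j - offset
                    for j in range(start, start + length)
                    if 0 <= j - offset < len(core)
                ]
                if not mutable:
                    continue
                j = mutable[int(rng.integers(0, len(mutable)))]
                core[j] = _BASES[int(rng.integers(0, 4))]
                dirty = True
        if not dirty:
            return "".join(core)
    raise RuntimeError("flank scrubbing failed to converge")


@lru_cache(maxsize=8)
def make_reference_flanks(
    locus_unit: str = "GGGGCC",
    anchor5: str = "CGCCC",
    flank_len: int = 500,
    seed: int = _FIXTURE_FLANK_SEED,
) -> tuple[str, str]:
    """Generate scrubbed reference flanks (left ends with the 5' anchor)."""
    rng = np.random.default_rng(seed)
    left_core = [
        _BASES[i] for i in rng.integers(0, 4, size=flank_len - len(anchor5))
    ]
    right_core = [_BASES[i] for i in rng.integers(0, 4, size=flank_len)]
    la, lu = len(anchor5), len(locus_unit)
    # left core is followed by anchor (0-repeat junction) or anchor+unit
    left = _scrub_core(
        left_core,
        lambda c: [
            (c + anchor5, 0, ((len(c), la),)),
            (c + anchor5 + locus_unit, 0, ((len(c), la), (len(c) + la, lu))),
        ],
        locus_unit,
        anchor5,
        rng,
    )
    # right core is preceded by a repeat unit, or directly by the anchor
    pre = anchor5 + locus_unit
    right = _scrub_core(
        right_core,
        lambda c: [
            (pre + c, len(pre), ((0, la), (la, lu))),
            (anchor5 + c, len(anchor5), ((0, la),)),
        ],
        locus_unit,
        anchor5,
        rng,
    )
    return left + anchor5, right


# --------------------------------------------------------------------------
# template and read simulation
# --------------------------------------------------------------------------

def build_template(spec: TemplateSpec, locus: LocusConfig) -> str:
    """Assemble one allele template with SNP overrides applied.

    The returned string holds exactly ``spec.repeat_count`` tandem copies
    of the repeat unit immediately after the 5' anchor.  SNP positions
    inside the repeat tract are rejected (undefined coordinate frame).
    """
    if not spec.left_flank.endswith(locus.anchor5):
        raise ValueError("left_flank must end with the 5' anchor")
    tract_start = len(spec.left_flank)
    tract_end = tract_start + 6 * spec.repeat_count
    seq = list(spec.left_flank + locus.repeat_unit * spec.repeat_count + spec.right_flank)
    for pos, base in spec.snp_overrides:
        if tract_start <= pos < tract_end:
            raise ValueError(f"SNP override at {pos} lies inside the repeat tract")
        if not 0 <= pos < len(seq):
            raise ValueError(f"SNP override position {pos} outside template")
        if base not in _BASES:
            raise ValueError(f"invalid SNP base {base!r}")
        seq[pos] = base
    return "".join(seq)


def _noisy_copy(arr: np.ndarray, rng: np.random.Generator, p: ReadSimParams) -> np.ndarray:
    out = arr
    if p.sub_rate > 0:
        mask = rng.random(out.size) < p.sub_rate
        k = int(mask.sum())
        if k:
            out = out.copy()
            shift = rng.integers(1, 4, size=k)
            out[mask] = _I2B[(_B2I[out[mask]] + shift) % 4]
    if p.del_rate > 0:
        keep = rng.random(out.size) >= p.del_rate
        out = out[keep]
    if p.ins_rate > 0:
        slots = rng.random(out.size) < p.ins_rate
        pos = np.nonzero(slots)[0]
        if pos.size:
            out = np.insert(out, pos, _I2B[rng.integers(0, 4, size=pos.size)])
    return out


def _simulate_from_templates(
    templates: list[str],
    choice_p: Optional[list[float]],
    params: ReadSimParams,
    source: str,
) -> tuple[list[CcsRead], list[int]]:
    rng = np.random.default_rng(params.seed)
    arrays = [np.frombuffer(t.encode(), dtype=np.uint8) for t in templates]
    if choice_p is None:
        picks = np.zeros(params.n_reads, dtype=int)
    else:
        picks = rng.choice(len(templates), size=params.n_reads, p=choice_p)
    flips = rng.random(params.n_reads) < 0.5
    keys = sorted(params.pass_count_distribution)
    probs = [params.pass_count_distribution[k] for k in keys]
    passes = rng.choice(keys, size=params.n_reads, p=probs)
    reads = []
    for i in range(params.n_reads):
        arr = _noisy_copy(arrays[picks[i]], rng, params)
        if flips[i]:
            arr = _RC_TABLE[arr][::-1]
        reads.append(
            CcsRead(
                read_id=f"{source}-{i:05d}",
                sequence=arr.tobytes().decode(),
                passes=int(passes[i]),
                source=source,
            )
        )
    return reads, list(picks)


def simulate_ccs_reads(
    template: str, params: ReadSimParams, source: str = "sim"
) -> list[CcsRead]:
    """Simulate noisy multi-pass CCS reads from one template.

    Each read is a noisy copy of the template or, with probability 0.5,
    of its reverse complement (molecules sequence in both orientations),
    and carries a sampled pass count.  Deterministic under a fixed seed.
    """
    reads, _ = _simulate_from_templates([template], None, params, source)
    return reads


def simulate_diploid_reads(
    templates: dict[str, str], reads_per_allele: int, params: ReadSimParams
) -> list[CcsRead]:
    """Equal-depth reads from each allele of a diploid template pair."""
    out: list[CcsRead] = []
    for k, (label, template) in enumerate(sorted(templates.items())):
        p = ReadSimParams(
            n_reads=reads_per_allele,
            sub_rate=params.sub_rate,
            ins_rate=params.ins_rate,
            del_rate=params.del_rate,
            pass_count_distribution=params.pass_count_distribution,
            seed=params.seed + k,
        )
        out.extend(simulate_ccs_reads(template, p, source=label))
    return out


def apply_excision(template: str, locus: LocusConfig, excision_length_nt: int) -> str:
    """Remove ``excision_length_nt`` nucleotides centred on the repeat tract."""
    from .edits import _template_tract

    t0, t1 = _template_tract(template, locus)
    tract_len = t1 - t0
    if excision_length_nt < tract_len:
        raise ValueError(
            f"excision of {excision_length_nt} nt cannot span the "
            f"{tract_len} nt repeat tract"
        )
    extra = excision_length_nt - tract_len
    left_extra = (extra + 1) // 2
    right_extra = extra - left_extra
    return template[: t0 - left_extra] + template[t1 + right_extra :]


def simulate_edited_pool(
    base_specs: list[TemplateSpec],
    edit: EditSimSpec,
    params: ReadSimParams,
    locus: LocusConfig,
) -> list[CcsRead]:
    """Simulate a (possibly mixed) edited clone pool.

    Reads are drawn from the per-outcome edited templates in multinomial
    proportions.  Excision outcomes remove ``excision_length_nt``
    nucleotides spanning the repeat tract; retained outcomes keep the base
    template unchanged.
    """
    by_label = {s.allele_label: s for s in base_specs}
    templates: list[str] = []
    for o in edit.outcomes:
        if o.allele_label not in by_label:
            raise ValueError(f"outcome allele {o.allele_label!r} has no base spec")
        base = build_template(by_label[o.allele_label], locus)
        if o.retain_expansion or o.excision_length_nt == 0:
            templates.append(base)
        else:
            spec = by_label[o.allele_label]
            max_exc = 6 * spec.repeat_count + 2 * edit.excisable_flank_margin
            if o.excision_length_nt > max_exc:
                raise ValueError(
                    f"excision {o.excision_length_nt} nt exceeds the excisable "
                    f"window ({max_exc} nt)"
                )
            templates.append(apply_excision(base, locus, o.excision_length_nt))
    props = [o.proportion for o in edit.outcomes]
    reads, _ = _simulate_from_templates(templates, props, params, "pool")
    return reads


# --------------------------------------------------------------------------
# ddPCR and MSD simulation
# --------------------------------------------------------------------------

def simulate_droplets(params: DdpcrSimParams) -> list[DropletWell]:
    """Poisson droplet partitioning: positives ~ Binomial(N, 1 - e^(-lam))."""
    rng = np.random.default_rng(params.seed)
    wells: list[DropletWell] = []
    for bio in range(1, params.n_replicates + 1):
        for tech in range(1, params.n_tech_replicates + 1):
            for target in sorted(params.true_lambda):
                lam = params.true_lambda[target]
                p_pos = 1.0 - math.exp(-lam)
                positives = int(rng.binomial(params.droplets_per_well, p_pos))
                wells.append(
                    DropletWell(
                        sample_id=params.sample_id,
                        target=target,
                        positive_droplets=positives,
                        total_droplets=params.droplets_per_well,
                        bio_replicate=bio,
                        tech_replicate=tech,
                    )
                )
    return wells


def simulate_msd_plate(params: MsdSimParams) -> list[MsdWell]:
    """Plate signals: background x abundance scale x lognormal(CV) noise.

    Negative-control sample types always use abundance scale 1, so the
    expected signal ratio of a pairing equals the planted positive scale.
    """
    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))
    wells: list[MsdWell] = []
    negatives = set(NEGATIVE_OF.values())
    for (capture, detection, sample_type), scale in sorted(params.true_abundance.items()):
        eff_scale = 1.0 if sample_type in negatives else scale
        for rep in range(1, params.n_replicates + 1):
            noise = (
                math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                if params.noise_cv > 0
                else 1.0
            )
            wells.append(
                MsdWell(
                    capture_ab=capture,
                    detection_ab=detection,
                    sample_type=sample_type,
                    condition_id=params.condition_id,
                    signal=params.background_signal * eff_scale * noise,
                    replicate_id=rep,
                )
            )
    return wells


# --------------------------------------------------------------------------
# fixture registry
# --------------------------------------------------------------------------

@dataclass
class LongReadFixture:
    name: str
    locus: LocusConfig
    base_specs: dict[str, TemplateSpec]
    templates: dict[str, str]
    edit: Optional[EditSimSpec]
    truth: dict


def make_locus(
    flank_len: int = 500,
    snp_position: int = 250,
    snp_alt_offset: int = 1,
    ref_allele: str = "allele1",
    alt_allele: str = "allele2",
) -> LocusConfig:
    """Reference locus with scrubbed flanks and one phased SNP."""
    left, right = make_reference_flanks(flank_len=flank_len)
    ref_base = left[snp_position]
    alt_base = _BASES[(_BASES.index(ref_base) + snp_alt_offset) % 4]
    snp = SnpDef(
        snp_id="rs-sim-1",
        template_position=snp_position,
        ref_base=ref_base,
        alt_base=alt_base,
        phased_informative=True,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
    )
    return LocusConfig(left_flank=left, right_flank=right, snps=[snp])


def _diploid(
    locus: LocusConfig, repeats: dict[str, int], alt_allele: str
) -> dict[str, TemplateSpec]:
    snp = locus.snps[0]
    specs = {}
    for label, k in repeats.items():
        overrides = (
            [(snp.template_position, snp.alt_base)] if label == alt_allele else []
        )
        specs[label] = TemplateSpec(
            allele_label=label,
            left_flank=locus.left_flank,
            repeat_count=k,
            right_flank=locus.right_flank,
            snp_overrides=overrides,
        )
    return specs


def fixture_wt_2_10() -> LongReadFixture:
    """The WT-control diploid: one allele with 2 repeats, the other 10."""
    locus = make_locus(ref_allele="allele1", alt_allele="allele2")
    specs = _diploid(locus, {"allele1": 2, "allele2": 10}, alt_allele="allele2")
    templates = {k: build_template(s, locus) for k, s in specs.items()}
    return LongReadFixture(
        "WT-2/10", locus, specs, templates, None,
        truth={"modes": {"allele1": 2, "allele2": 10}},
    )


def _edit_fixture(
    name: str,
    repeats: dict[str, int],
    outcomes: list[OutcomeSpec],
    truth: dict,
) -> LongReadFixture:
    # the phased SNP marks the WT allele (alt base on WT)
    locus = make_locus(ref_allele="mutant", alt_allele="WT")
    specs = _diploid(locus, repeats, alt_allele="WT")
    templates = {k: build_template(s, locus) for k, s in specs.items()}
    return LongReadFixture(
        name, locus, specs, templates, EditSimSpec(outcomes=outcomes), truth
    )


def fixture_het_20nt_retained() -> LongReadFixture:
    """Heterozygous excision: 20 nt deletion on the WT allele, the mutant
    allele retains its 1491-repeat expansion (8946 nt tract)."""
    return _edit_fixture(
        "het-20NT-retained",
        {"WT": 2, "mutant": 1491},
        [
            OutcomeSpec("WT", excision_length_nt=20, proportion=0.5),
            OutcomeSpec("mutant", retain_expansion=True, proportion=0.5),
        ],
        truth={
            "classification": "heterozygous_excision",
            "excisions": {"WT": 20},
            "retained_repeats": {"mutant": 1491},
        },
    )


def fixture_hom_48_32() -> LongReadFixture:
    """Homozygous excision: 48 nt on the mutant allele, 32 nt on the WT,
    equal read counts.  Excision sizes are reference-relative, so the
    mutant base template carries a compact tract."""
    return _edit_fixture(
        "hom-48/32",
        {"WT": 2, "mutant": 5},
        [
            OutcomeSpec("mutant", excision_length_nt=48, proportion=0.5),
            OutcomeSpec("WT", excision_length_nt=32, proportion=0.5),
        ],
        truth={
            "classification": "homozygous_excision",
            "excisions": {"mutant": 48, "WT": 32},
        },
    )


def fixture_impure_27_19_17() -> LongReadFixture:
    """Impure clone: WT -27 nt (52% of reads); mutant -17 nt twice as
    abundant as mutant -19 nt (32% / 16%)."""
    return _edit_fixture(
        "impure-27/19/17",
        {"WT": 2, "mutant": 2},
        [
            OutcomeSpec("WT", excision_length_nt=27, proportion=0.52),
            OutcomeSpec("mutant", excision_length_nt=17, proportion=0.32),
            OutcomeSpec("mutant", excision_length_nt=19, proportion=0.16),
        ],
        truth={
            "classification": "impure",
            "fractions": {("WT", 27): 0.52, ("mutant", 17): 0.32, ("mutant", 19): 0.16},
            "dominant": ("WT", 27),
            "per_allele_dominant": {"WT": 27, "mutant": 17},
        },
    )


def fixture_wt_neuron_ddpcr(seed: int = 0) -> DdpcrSimParams:
    """WT-neuron transcript mix: 96% of C9orf72 mRNA carries exon 1B.

    True concentrations (copies/droplet): V2 (exon 1B) 0.48, V3 (exon 1A)
    0.02, reference 0.50 — a 96:4 variant ratio at comfortably detectable
    droplet counts.
    """
    return DdpcrSimParams(
        true_lambda={"V2": 0.48, "V3": 0.02, "reference": 0.50},
        droplets_per_well=20000,
        n_replicates=3,
        n_tech_replicates=3,
        sample_id="WT-neuron",
        seed=seed,
    )


def fixture_msd_ratio_grid(seed: int = 0) -> MsdSimParams:
    """Antibody screen grid with two planted specific pairs (scale >= 2),
    one mouse-only pair (2.4 in transgenic mouse, flat elsewhere), and two
    nonspecific pairs (scale 1)."""
    pairs_scales = {
        ("MABN889", "GA-det"): {"C9_iPSC_MN": 2.5, "C9_postmortem": 2.2, "TG_mouse": 2.8},
        ("TALS828.179", "GP-det"): {"C9_iPSC_MN": 2.1, "C9_postmortem": 2.0, "TG_mouse": 2.3},
        ("ABN1354", "PR-det"): {"C9_iPSC_MN": 1.0, "C9_postmortem": 1.0, "TG_mouse": 2.4},
        ("AB-GR-1", "GR-det"): {"C9_iPSC_MN": 1.0, "C9_postmortem": 1.0, "TG_mouse": 1.0},
        ("AB-PA-1", "PA-det"): {"C9_iPSC_MN": 1.0, "C9_postmortem": 1.0, "TG_mouse": 1.0},
    }
    abundance: dict[tuple[str, str, str], float] = {}
    for (cap, det), scales in pairs_scales.items():
        for pos_type, scale in scales.items():
            abundance[(cap, det, pos_type)] = scale
            abundance[(cap, det, NEGATIVE_OF[pos_type])] = 1.0
    return MsdSimParams(true_abundance=abundance, seed=seed)


FIXTURES: dict[str, Callable] = {
    "WT-2/10": fixture_wt_2_10,
    "het-20NT-retained": fixture_het_20nt_retained,
    "hom-48/32": fixture_hom_48_32,
    "impure-27/19/17": fixture_impure_27_19_17,
    "WT-neuron-ddPCR": fixture_wt_neuron_ddpcr,
    "MSD-ratio-grid": fixture_msd_ratio_grid,
}
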