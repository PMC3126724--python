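"""Assembly of tagged SSR/indel assays and APLP-style ASO+LSO SNP assays.

An SSR/indel assay is an ordinary primer pair with the 16-nt tag prepended to
the forward primer and a "gtttctt" PIG-tail (promoting uniform non-templated
adenylation) prepended to the reverse primer.  The one hard design rule is
the Tm gap: the core forward primer must melt at least 6 degC above its tag,
otherwise labeling leaks into the amplification stage and amplification
itself can fail.

A SNP assay follows the amplified-product-length-polymorphism pattern: one
common tailed locus-specific oligo (LSO) downstream of the SNP, plus two
allele-specific oligos (ASOs) whose 3'-terminal base is the allele.  Because
a single 3' mismatch rarely suffices to reject the wrong allele, a G or C
within 6 nt upstream of the SNP base is replaced by A or T (rendered
lowercase) to destabilize mishybridization; the two tagged ASOs also differ
by exactly 1 nt in length so alleles separate on size as well as dye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import (
    DesignError,
    InvalidSequenceError,
    NoDestabilizerError,
    SelfPrimingWarning,
    TmGapError,
)
from .tagset import SplitTag
from .thermo import (
    CALIBRATED_CONDITIONS,
    ThermoConditions,
    melt_temp,
    revcomp,
    round_tm,
)

__all__ = [
    "MarkerAssay",
    "AsoRecord",
    "SnpAssay",
    "Protocol",
    "Stage",
    "DEFAULT_PIGTAIL",
    "attach_tag",
    "pigtail",
    "build_ssr_assay",
    "gc_run_check",
    "GcRunVerdict",
    "AsoDesignParams",
    "design_aso_pair",
    "SnpVerdict",
    "validate_snp_assay",
]

DEFAULT_PIGTAIL = "gtttctt"
_VALID = frozenset("ACGT")


def _check_core(core: str, what: str, min_len: int = 15) -> str:
    cu = core.upper()
    if len(cu) < min_len:
        raise InvalidSequenceError(
            f"{what} length {len(cu)} below minimum {min_len}"
        )
    bad = [c for c in cu if c not in _VALID]
    if bad:
        raise InvalidSequenceError(f"{what} contains non-ACGT character {bad[0]!r}")
    return cu


def attach_tag(tag: SplitTag, forward_core: str) -> str:
    """Prepend the tag to a forward core primer (plain 5' concatenation).

    Warns (does not fail) if the core contains the tag's own 3'-terminal
    8-mer, a self-priming risk for the labeled tag primer.
    """
    cu = _check_core(forward_core, "forward core")
    seed = tag.full_seq[-8:]
    if seed in cu:
        warnings.warn(
            f"core contains tag {tag.name} 3'-terminal seed {seed}; "
            "labeled tag primer may prime internally",
            SelfPrimingWarning,
            stacklevel=2,
        )
    return tag.full_seq + cu


def pigtail(reverse_core: str, tail: str = DEFAULT_PIGTAIL) -> str:
    """Prepend the (lowercase) tail to a reverse core, preserving core case."""
    return tail.lower() + reverse_core


@dataclass(frozen=True)
class MarkerAssay:
    """A tagged SSR/indel assay: cores, tag, dye and derived working oligos.

    ``expected_size_range`` is the untagged product size window in bp, used
    for panel size-separation checks.
    """

    name: str
    forward_core: str
    reverse_core: str
    tag: SplitTag
    dye: str
    tagged_forward: str
    tailed_reverse: str
    pigtail: str = DEFAULT_PIGTAIL
    expected_size_range: tuple[int, int] | None = None
    motif: str | None = None
    accession: str | None = None
    core_tm: float | None = None


def build_ssr_assay(
    name: str,
    forward_core: str,
    reverse_core: str,
    tag: SplitTag,
    dye: str,
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
    min_gap: float = 6.0,
    expected_size_range: tuple[int, int] | None = None,
    motif: str | None = None,
    accession: str | None = None,
    tail: str = DEFAULT_PIGTAIL,
) -> MarkerAssay:
    """Assemble a tagged SSR/indel assay and enforce the Tm-gap rule.

    Raises :class:`TmGapError` when the core forward primer melts less than
    ``min_gap`` degC above the tag — assays in that regime amplified too
    weakly in practice, so the gap is a hard error rather than a warning.
    """
    fwd = _check_core(forward_core, "forward core")
    rev = _check_core(reverse_core, "reverse core")
    core_tm = round_tm(melt_temp(fwd, conditions))
    if core_tm - tag.tm < min_gap:
        raise TmGapError(core_tm, tag.tm, min_gap)
    return MarkerAssay(
        name=name,
        forward_core=fwd,
        reverse_core=rev,
        tag=tag,
        dye=dye,
        tagged_forward=attach_tag(tag, fwd),
        tailed_reverse=pigtail(rev, tail),
        pigtail=tail,
        expected_size_range=expected_size_range,
        motif=motif,
        accession=accession,
        core_tm=core_tm,
    )


@dataclass(frozen=True)
class GcRunVerdict:
    passed: bool
    longest_gc_run: int
    max_run: int


def gc_run_check(seq: str, max_run: int = 5) -> GcRunVerdict:
    """Fail iff a contiguous stretch of G/C (any mix) exceeds ``max_run``.

    Locally GC-rich stretches anneal too stably for allele-specific
    rejection, so such candidates are excluded from ASO design.
    """
    longest = run = 0
    for c in seq.upper():
        run = run + 1 if c in "GC" else 0
        longest = max(longest, run)
    return GcRunVerdict(passed=longest <= max_run, longest_gc_run=longest, max_run=max_run)


# ---------------------------------------------------------------------------
# SNP assays


@dataclass(frozen=True)
class AsoRecord:
    """One allele-specific oligo: core (introduced mismatch lowercase, 3'
    base = allele), its tag/dye, and the derived tagged primer."""

    allele: str
    core: str
    introduced_mismatch_offset: int
    tag: SplitTag
    dye: str
    tagged: str

    @property
    def tagged_length(self) -> int:
        return len(self.tagged)


@dataclass(frozen=True)
class SnpAssay:
    """An ASO pair plus common LSO for one biallelic SNP."""

    name: str
    snp_alleles: tuple[str, str]
    lso: str
    asos: tuple[AsoRecord, AsoRecord]
    accession: str | None = None


@dataclass(frozen=True)
class AsoDesignParams:
    """Knobs for ASO/LSO design on a genomic template.

    ``min_core_tm`` keeps cores comfortably above the tag Tm so the two-stage
    gap holds; ``mismatch_window`` is the 1..6 offset range searched for a
    G/C to weaken; ``replacements`` maps the removed base to its transversion
    partner.
    """

    min_core_tm: float = 55.0
    min_core_len: int = 16
    max_core_len: int = 32
    mismatch_window: tuple[int, int] = (1, 6)
    replacements: dict | None = None
    max_gc_run: int = 5
    min_lso_len: int = 16
    max_lso_len: int = 32
    lso_gap: int = 20
    tail: str = DEFAULT_PIGTAIL

    def repl(self) -> dict:
        return self.replacements or {"G": "T", "C": "A"}


def _core_with_edits(template: str, start: int, snp_pos: int, allele: str,
                     mm_pos: int, repl_base: str) -> str:
    """Render an ASO core: template[start..snp_pos], allele at 3' (upper),
    introduced replacement lowercase at mm_pos."""
    bases = list(template[start : snp_pos + 1].upper())
    bases[-1] = allele.upper()
    bases[mm_pos - start] = repl_base.lower()
    return "".join(bases)


def design_aso_pair(
    template: str,
    snp_pos: int,
    alleles: tuple[str, str],
    tags: tuple[SplitTag, SplitTag],
    dyes: tuple[str, str],
    params: AsoDesignParams = AsoDesignParams(),
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
    name: str = "snp",
) -> SnpAssay:
    """Design a tagged ASO pair and LSO around a SNP on a template.

    ``snp_pos`` is the 0-based index of the SNP base; ``alleles`` are the two
    variants.  The first allele's core ends at the SNP and is extended 5'
    until it clears ``min_core_tm`` and the GC-run rule; the second allele's
    core takes one extra 5' template base so the tagged primers differ by
    exactly 1 nt.  A G/C at offset 1..6 upstream of the SNP base is replaced
    by its transversion partner (lowercase); the smallest offset wins.  The
    LSO is the pigtailed reverse-orientation primer on the flank downstream
    of the SNP.
    """
    tu = template.upper()
    a1, a2 = (a.upper() for a in alleles)
    if a1 == a2:
        raise DesignError("alleles must differ")
    if tags[0].full_seq == tags[1].full_seq:
        raise DesignError("the two ASOs must carry distinct tags")
    if snp_pos < 25:
        raise DesignError(
            f"upstream flank too short: need >= 25 nt before the SNP, have {snp_pos}"
        )

    # destabilizing mismatch: smallest offset in the window with template G/C
    lo, hi = params.mismatch_window
    repl = params.repl()
    mm_pos = None
    for offset in range(lo, hi + 1):
        base = tu[snp_pos - offset]
        if base in repl:
            mm_pos = snp_pos - offset
            mm_offset = offset
            repl_base = repl[base]
            break
    if mm_pos is None:
        raise NoDestabilizerError(
            f"no G/C at offsets {lo}-{hi} upstream of the SNP base to replace"
        )

    # allele-1 core: extend 5' until Tm and GC-run constraints clear
    chosen_len = None
    for length in range(params.min_core_len, params.max_core_len + 1):
        start = snp_pos - length + 1
        if start < 0:
            break
        core = _core_with_edits(tu, start, snp_pos, a1, mm_pos, repl_base)
        if not gc_run_check(core, params.max_gc_run).passed:
            continue
        if melt_temp(core.upper(), conditions) >= params.min_core_tm:
            chosen_len = length
            break
    if chosen_len is None:
        raise DesignError(
            "no ASO core in the allowed length range meets the Tm and GC-run rules"
        )

    start1 = snp_pos - chosen_len + 1
    start2 = start1 - 1
    if start2 < 0:
        raise DesignError("upstream flank too short for the staggered second ASO")
    core1 = _core_with_edits(tu, start1, snp_pos, a1, mm_pos, repl_base)
    core2 = _core_with_edits(tu, start2, snp_pos, a2, mm_pos, repl_base)

    aso1 = AsoRecord(a1, core1, mm_offset, tags[0], dyes[0], tags[0].full_seq + core1)
    aso2 = AsoRecord(a2, core2, mm_offset, tags[1], dyes[1], tags[1].full_seq + core2)

    # LSO on the downstream flank, reverse orientation
    lso_start = snp_pos + 1 + params.lso_gap
    lso_core = None
    for length in range(params.min_lso_len, params.max_lso_len + 1):
        end = lso_start + length
        if end > len(tu):
            break
        cand = revcomp(tu[lso_start:end])
        if not gc_run_check(cand, params.max_gc_run).passed:
            continue
        if melt_temp(cand, conditions) >= params.min_core_tm:
            lso_core = cand
            break
    if lso_core is None:
        raise DesignError("downstream flank too short or unsuitable for the LSO")

    return SnpAssay(
        name=name,
        snp_alleles=(a1, a2),
        lso=pigtail(lso_core, params.tail),
        asos=(aso1, aso2),
    )


@dataclass(frozen=True)
class SnpVerdict:
    passed: bool
    reasons: tuple[str, ...]
    tagged_lengths: tuple[int, int]


def validate_snp_assay(assay: SnpAssay,
                       mismatch_window: tuple[int, int] = (1, 6)) -> SnpVerdict:
    """Check every template-free SNP-assay invariant on an annotated record.

    Verifies per ASO: 3'-terminal core base equals the allele; the annotated
    introduced-mismatch offset is in the window and points at a lowercase
    core base; the tagged primer is tag + core.  Across the pair: distinct
    tags and a tagged-length difference of exactly 1 bp.  The identity of the
    replaced template base is not checkable without the template and is not
    judged here.
    """
    reasons = []
    for rec in assay.asos:
        if rec.core[-1].upper() != rec.allele.upper():
            reasons.append(
                f"ASO/{rec.allele}: 3' base {rec.core[-1]!r} != allele {rec.allele}"
            )
        lo, hi = mismatch_window
        off = rec.introduced_mismatch_offset
        if not (lo <= off <= hi):
            reasons.append(f"ASO/{rec.allele}: mismatch offset {off} outside [{lo},{hi}]")
        else:
            pos = len(rec.core) - 1 - off
            if pos < 0 or not rec.core[pos].islower():
                reasons.append(
                    f"ASO/{rec.allele}: no lowercase introduced mismatch at offset {off}"
                )
        if not rec.tagged.upper().startswith(rec.tag.full_seq):
            reasons.append(f"ASO/{rec.allele}: tagged primer lacks tag prefix")
        if rec.tagged.upper() != (rec.tag.full_seq + rec.core.upper()):
            reasons.append(f"ASO/{rec.allele}: tagged primer != tag + core")
    if assay.asos[0].tag.full_seq == assay.asos[1].tag.full_seq:
        reasons.append("the two ASOs carry the same tag")
    lens = (assay.asos[0].tagged_length, assay.asos[1].tagged_length)
    if abs(lens[0] - lens[1]) != 1:
        reasons.append(f"tagged lengths {lens} do not differ by exactly 1 bp")
    return SnpVerdict(passed=not reasons, reasons=tuple(reasons), tagged_lengths=lens)


# ---------------------------------------------------------------------------
# Cycling program (data only)


@dataclass(frozen=True)
class Stage:
    cycles: int
    denature_c: float = 94.0
    denature_s: int = 20
    anneal_c: float = 57.0
    anneal_s: int = 30
    extend_c: float | None = None
    extend_s: int | None = None


@dataclass(frozen=True)
class Protocol:
    """The two-stage cycling program: conventional amplification, then a
    short low-temperature labeling stage, with the reduced primer loads that
    leave tagged product single-stranded for the labeling primer."""

    initial_denature_c: float = 94.0
    initial_denature_min: float = 3.0
    stage1: Stage = field(default_factory=lambda: Stage(cycles=31, anneal_c=57.0))
    stage2: Stage = field(
        default_factory=lambda: Stage(
            cycles=3, anneal_c=49.0, anneal_s=10, extend_c=72.0, extend_s=5
        )
    )
    final_extension_c: float = 72.0
    final_extension_min: float = 10.0
    reverse_pmol: float = 2.0
    tagged_forward_pmol: float = 0.5
    labeled_tag_pmol: float = 0.5

    def __post_init__(self):
        if not self.stage2.anneal_c < self.stage1.anneal_c:
            raise ValueError(
                "stage-2 (labeling) annealing must be below stage-1 annealing"
            )


DEFAULT_PROTOCOL = Protocol()
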