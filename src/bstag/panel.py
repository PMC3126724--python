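"""Single-tube panel assembly and rule-based two-stage labeling simulation.

A panel co-assigns (tag, dye) pairs to assays sharing one tube.  Feasibility
requires: every tag used once, at most six assays (the size of the shipped
tag pool), and any two assays sharing a dye separated in apparent size by a
guard band.  Apparent size is the untagged product length plus the 16-nt tag
plus a dye-dependent electrophoretic mobility offset — the attached dye is
what pushes the observed shift into the 13-17 bp range.

The labeling simulation is deliberately rule-based, not kinetic: stage 1
forms each assay's tagged product pool if the sequence-specific core primer
anneals at the stage-1 temperature while the labeled tag primer is held off
by its lower Tm; stage 2 emits a labeled peak for every (labeled tag primer,
product pool) pair whose tag duplex passes the annealing gate.  The claims
this must reproduce — exclusive labeling, no peak from a mismatched tag
combination, the three-cycle plateau — are qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .assay import DEFAULT_PROTOCOL, MarkerAssay, Protocol
from .errors import SwapRejectedError
from .tagset import SplitTag
from .thermo import (
    CALIBRATED_CONDITIONS,
    AnnealPolicy,
    ThermoConditions,
    anneals,
    melt_temp,
    revcomp,
)

__all__ = [
    "DyeSpec",
    "DEFAULT_DYES",
    "PanelEntry",
    "PanelPolicy",
    "Panel",
    "PanelInfeasible",
    "Peak",
    "YieldPools",
    "apparent_size",
    "build_panel",
    "validate_panel",
    "dye_swap",
    "simulate_labeling",
    "labeling_yield",
]


@dataclass(frozen=True)
class DyeSpec:
    """A fluorescent dye: detection channel plus mobility offset (bp).

    Offsets are placeholders spanning [-3, +1] so that tag length + offset
    reproduces the observed 13-17 bp apparent-size shift; calibrate per
    instrument for real data.
    """

    name: str
    channel: int
    mobility_offset: float = 0.0


DEFAULT_DYES: tuple[DyeSpec, ...] = (
    DyeSpec("6-FAM", 0, -3.0),
    DyeSpec("VIC", 1, -2.0),
    DyeSpec("NED", 2, -1.0),
    DyeSpec("PET", 3, 1.0),
)


def apparent_size(product_len: float, tag: SplitTag, dye: DyeSpec) -> float:
    """Electrophoretic size estimate of a labeled product (bp)."""
    if product_len <= 0:
        raise ValueError(f"product length must be > 0, got {product_len}")
    return product_len + len(tag.full_seq) + dye.mobility_offset


@dataclass(frozen=True)
class PanelEntry:
    """One assay slot in a panel: identity, size window, optional cores and
    optional pre-assigned tag/dye (kept fixed by the builder when present)."""

    name: str
    size_range: tuple[float, float]
    tag: SplitTag | None = None
    dye: str | None = None
    forward_core: str | None = None

    @classmethod
    def from_assay(cls, assay: MarkerAssay) -> "PanelEntry":
        if assay.expected_size_range is None:
            raise ValueError(f"assay {assay.name} has no expected_size_range")
        return cls(
            name=assay.name,
            size_range=assay.expected_size_range,
            tag=assay.tag,
            dye=assay.dye,
            forward_core=assay.forward_core,
        )


@dataclass(frozen=True)
class PanelPolicy:
    size_tolerance: float = 10.0
    max_assays: int = 6


@dataclass(frozen=True)
class Assignment:
    entry: PanelEntry
    tag: SplitTag
    dye: DyeSpec

    def window(self) -> tuple[float, float]:
        lo, hi = self.entry.size_range
        return (
            apparent_size(lo, self.tag, self.dye),
            apparent_size(hi, self.tag, self.dye),
        )


@dataclass(frozen=True)
class Panel:
    """A validated set of (assay, tag, dye) assignments for one tube."""

    assignments: tuple[Assignment, ...]
    policy: PanelPolicy = field(default_factory=PanelPolicy)

    def assignment(self, name: str) -> Assignment:
        for a in self.assignments:
            if a.entry.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class PanelInfeasible:
    """Why no assignment exists: the violated constraint and a conflict set
    such that removing any one named assay restores feasibility."""

    reason: str
    conflict: tuple[str, ...]


def _violations(assignments: Sequence[Assignment], policy: PanelPolicy) -> list[str]:
    out = []
    if len(assignments) > policy.max_assays:
        out.append(
            f"{len(assignments)} assays exceed the {policy.max_assays}-assay tube limit"
        )
    tags = [a.tag.full_seq for a in assignments]
    if len(set(tags)) != len(tags):
        out.append("duplicate tag within the panel")
    for i in range(len(assignments)):
        for j in range(i + 1, len(assignments)):
            a, b = assignments[i], assignments[j]
            if a.dye.name != b.dye.name:
                continue
            (alo, ahi), (blo, bhi) = a.window(), b.window()
            gap = max(blo - ahi, alo - bhi)
            if gap < policy.size_tolerance:
                out.append(
                    f"same-dye windows of {a.entry.name} and {b.entry.name} "
                    f"separated by {gap:.1f} < {policy.size_tolerance} bp"
                )
    return out


def validate_panel(panel: Panel) -> list[str]:
    """All panel-invariant violations (empty list means valid)."""
    return _violations(panel.assignments, panel.policy)


def _search(entries, tag_pool, dye_pool, policy) -> tuple[Assignment, ...] | None:
    """Deterministic backtracking over (dye, tag) choices per entry; prefers
    unused dyes, then pool order; pre-assigned tags/dyes are fixed."""
    dyes_by_name = {d.name: d for d in dye_pool}
    chosen: list[Assignment] = []

    def options(entry: PanelEntry):
        if entry.tag is not None:
            tag_opts = [entry.tag]
        else:
            used = {a.tag.full_seq for a in chosen}
            tag_opts = [t for t in tag_pool if t.full_seq not in used]
        if entry.dye is not None:
            dye_opts = [dyes_by_name[entry.dye]]
        else:
            used_dyes = {a.dye.name for a in chosen}
            fresh = [d for d in dye_pool if d.name not in used_dyes]
            dye_opts = fresh + [d for d in dye_pool if d.name in used_dyes]
        for d in dye_opts:
            for t in tag_opts:
                yield t, d

    def extend(i: int) -> bool:
        if i == len(entries):
            return True
        for tag, dye in options(entries[i]):
            cand = Assignment(entries[i], tag, dye)
            if not _violations([*chosen, cand], policy):
                chosen.append(cand)
                if extend(i + 1):
                    return True
                chosen.pop()
        return False

    return tuple(chosen) if extend(0) else None


def build_panel(
    assays: Sequence[MarkerAssay | PanelEntry],
    tag_pool: Sequence[SplitTag],
    dye_pool: Sequence[DyeSpec] = DEFAULT_DYES,
    policy: PanelPolicy = PanelPolicy(),
) -> Panel | PanelInfeasible:
    """Assign (tag, dye) to co-tubed assays, or diagnose infeasibility.

    Deterministic backtracking in input order; entries carrying a
    pre-assigned tag or dye keep it.  On failure the diagnosis names the
    violated constraint and a minimal conflict set: removing any one member
    restores feasibility.
    """
    entries = [
        e if isinstance(e, PanelEntry) else PanelEntry.from_assay(e) for e in assays
    ]
    if len({d.channel for d in dye_pool}) != len(dye_pool):
        raise ValueError("dye pool has duplicate detection channels")

    if len(entries) > policy.max_assays:
        return PanelInfeasible(
            reason=f"{len(entries)} assays exceed the {policy.max_assays}-assay limit",
            conflict=tuple(e.name for e in entries),
        )
    if len(entries) > len(tag_pool):
        return PanelInfeasible(
            reason=f"{len(entries)} assays but only {len(tag_pool)} tags available",
            conflict=tuple(e.name for e in entries),
        )

    solution = _search(entries, tag_pool, dye_pool, policy)
    if solution is not None:
        return Panel(assignments=solution, policy=policy)

    conflict = []
    for i in range(len(entries)):
        rest = entries[:i] + entries[i + 1 :]
        if _search(rest, tag_pool, dye_pool, policy) is not None:
            conflict.append(entries[i].name)
    return PanelInfeasible(
        reason="no (tag, dye) assignment satisfies the separability constraints",
        conflict=tuple(conflict) if conflict else tuple(e.name for e in entries),
    )


def dye_swap(panel: Panel, assay_name: str, new_dye: DyeSpec) -> Panel:
    """Replace one assay's dye, keeping its tag; atomic on failure.

    Raises :class:`SwapRejectedError` (leaving the input panel untouched)
    when the swapped panel would violate an invariant.
    """
    found = False
    new_assignments = []
    for a in panel.assignments:
        if a.entry.name == assay_name:
            new_assignments.append(replace(a, dye=new_dye))
            found = True
        else:
            new_assignments.append(a)
    if not found:
        raise KeyError(f"no assay named {assay_name!r} in panel")
    candidate = Panel(assignments=tuple(new_assignments), policy=panel.policy)
    problems = validate_panel(candidate)
    if problems:
        raise SwapRejectedError(
            f"swap of {assay_name} to {new_dye.name} rejected: {problems[0]}"
        )
    return candidate


# ---------------------------------------------------------------------------
# Labeling simulation


@dataclass(frozen=True)
class Peak:
    """One simulated electropherogram peak."""

    dye: str
    apparent_size: float
    assay: str
    allele: int
    labeled: bool = True


def simulate_labeling(
    panel: Panel,
    templates: Mapping[str, Sequence[int]],
    labeled_primers: Sequence[tuple[SplitTag, DyeSpec]],
    protocol: Protocol = DEFAULT_PROTOCOL,
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
    policy: AnnealPolicy = AnnealPolicy(),
) -> list[Peak]:
    """Rule-based two-stage labeling: returns the labeled peaks.

    ``templates`` maps assay name to the allele product lengths (untagged bp)
    present in the sample.  Stage 1: an assay's tagged product pool forms if
    its core primer anneals at the stage-1 temperature; a labeled tag primer
    whose Tm reaches the stage-1 temperature is not suppressed by the gap
    rule and would label during amplification — such pools are still only
    reported once, at stage 2.  Stage 2: each (labeled primer, pool) pair
    yields peaks iff the labeled tag anneals on the pool's tag site.
    """
    t1 = protocol.stage1.anneal_c
    t2 = protocol.stage2.anneal_c
    pools = []  # (assignment, allele lengths)
    for a in panel.assignments:
        lengths = templates.get(a.entry.name)
        if not lengths:
            continue
        if a.entry.forward_core is not None:
            core_tm = melt_temp(a.entry.forward_core, conditions)
            if core_tm < t1 - policy.margin:
                continue  # no amplification: pool never forms
        pools.append((a, tuple(lengths)))

    peaks: list[Peak] = []
    for ltag, ldye in labeled_primers:
        if ltag.tm >= t1:
            # gap rule violated: this tag would co-amplify during stage 1
            # instead of waiting for the labeling stage
            import warnings

            warnings.warn(
                f"labeled tag {ltag.name} Tm {ltag.tm} reaches the stage-1 "
                f"annealing temperature {t1}; labeling is not confined to stage 2",
                UserWarning,
                stacklevel=2,
            )
        for a, lengths in pools:
            site = revcomp(a.tag.full_seq)  # strand displayed by the ss product
            if anneals(ltag.full_seq, site, t2, conditions, policy):
                for idx, ln in enumerate(lengths):
                    peaks.append(
                        Peak(
                            dye=ldye.name,
                            apparent_size=apparent_size(ln, ltag, ldye),
                            assay=a.entry.name,
                            allele=idx,
                        )
                    )
    peaks.sort(key=lambda p: (p.dye, p.apparent_size, p.assay, p.allele))
    return peaks


@dataclass(frozen=True)
class YieldPools:
    """Stage-2 pool model: single-stranded tagged template, labeled primer,
    and the per-cycle conversion fraction of remaining template."""

    template: float = 1.0
    primer: float = 0.85
    conversion: float = 0.4

    def __post_init__(self):
        if self.template <= 0 or self.primer <= 0:
            raise ValueError("pool amounts must be > 0")
        if not (0 < self.conversion <= 1):
            raise ValueError("conversion fraction must be in (0, 1]")


def labeling_yield(cycles: int, pools: YieldPools = YieldPools()) -> list[float]:
    """Cumulative labeled product after 0..cycles labeling cycles.

    Each cycle converts ``min(conversion x remaining template, remaining
    primer)``; the curve is non-decreasing and concave, rising near-linearly
    while both pools are ample and flattening once the labeled primer runs
    out — with the default pools the fourth-cycle increment falls below 20%
    of the first, the observed plateau shape.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    template, primer = pools.template, pools.primer
    out = [0.0]
    total = 0.0
    for _ in range(cycles):
        converted = min(pools.conversion * template, primer)
        template -= converted
        primer -= converted
        total += converted
        out.append(total)
    return out


def panel_to_json(panel: Panel) -> str:
    import json

    return json.dumps(
        {
            "policy": {
                "size_tolerance": panel.policy.size_tolerance,
                "max_assays": panel.policy.max_assays,
            },
            "assignments": [
                {
                    "assay": a.entry.name,
                    "size_range": list(a.entry.size_range),
                    "forward_core": a.entry.forward_core,
                    "tag": {
                        "name": a.tag.name,
                        "full_seq": a.tag.full_seq,
                        "scaffold5": a.tag.scaffold5,
                        "split_base": a.tag.split_base,
                        "scaffold3": a.tag.scaffold3,
                        "barcode": a.tag.barcode,
                        "tm": a.tag.tm,
                    },
                    "dye": {
                        "name": a.dye.name,
                        "channel": a.dye.channel,
                        "mobility_offset": a.dye.mobility_offset,
                    },
                }
                for a in panel.assignments
            ],
        },
        indent=2,
    )


def panel_from_json(text: str) -> Panel:
    import json

    obj = json.loads(text)
    assignments = tuple(
        Assignment(
            entry=PanelEntry(
                name=d["assay"],
                size_range=tuple(d["size_range"]),
                tag=SplitTag(**d["tag"]),
                dye=d["dye"]["name"],
                forward_core=d.get("forward_core"),
            ),
            tag=SplitTag(**d["tag"]),
            dye=DyeSpec(**d["dye"]),
        )
        for d in obj["assignments"]
    )
    return Panel(assignments=assignments, policy=PanelPolicy(**obj["policy"]))


def peaks_to_csv(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        fh.write("dye,apparent_size,assay,allele\n")
        for p in peaks:
            fh.write(f"{p.dye},{p.apparent_size:.1f},{p.assay},{p.allele}\n")


def render_peaks(peaks: Sequence[Peak], path) -> None:
    """Optional electropherogram sketch (one subplot per dye channel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dyes = sorted({p.dye for p in peaks})
    fig, axes = plt.subplots(max(len(dyes), 1), 1, figsize=(8, 1.8 * max(len(dyes), 1)),
                             squeeze=False)
    for ax, dye in zip(axes.ravel(), dyes):
        xs = [p.apparent_size for p in peaks if p.dye == dye]
        ax.vlines(xs, 0, 1)
        ax.set_ylabel(dye)
        ax.set_yticks([])
    axes.ravel()[-1].set_xlabel("apparent size (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
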