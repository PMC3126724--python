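"""Bar-coded split tag data model, validators and deterministic generator.

A tag is a 16-nt 5' primer extension built on a fixed scaffold: a 7-nt 5'
basal part, a variable "split" base at position 8, a 5-nt 3' basal part, and
a 3-nt bar-code whose last base is G or C (GC clamp).  The split base breaks
the conserved basal region into two sub-priming-length halves, so tags that
share part of a bar-code still present each other with a broken duplex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

from . import thermo
from .errors import InvalidSequenceError, ScaffoldViolationError
from .thermo import (
    CALIBRATED_CONDITIONS,
    DuplexReport,
    ThermoConditions,
    duplex_score,
    melt_temp,
    revcomp,
    round_tm,
)

__all__ = [
    "Scaffold",
    "DEFAULT_SCAFFOLD",
    "SplitTag",
    "TagConstraints",
    "PairPolicy",
    "TagVerdict",
    "PairReport",
    "SetReport",
    "GenerationResult",
    "parse_tag",
    "validate_tag",
    "conserved_positions",
    "pair_discrimination",
    "validate_set",
    "generate_tagset",
    "write_tag_tsv",
    "read_tag_tsv",
    "tags_to_json",
    "tags_from_json",
]

_VALID = frozenset("ACGT")

# fixed tag anatomy (1-based): scaffold5 = 1..7, split = 8, scaffold3 = 9..13,
# barcode = 14..16
TAG_LENGTH = 16
SPLIT_POS = 8
BARCODE_LENGTH = 3


def _check_acgt(seq: str, what: str) -> str:
    su = seq.upper()
    bad = [c for c in su if c not in _VALID]
    if bad:
        raise InvalidSequenceError(f"{what} contains non-ACGT character {bad[0]!r}")
    return su


@dataclass(frozen=True)
class Scaffold:
    """The conserved basal sequence shared by every tag in a set.

    Defaults are the consensus of the published six-tag set, originally
    derived from a 12-mer RAPD primer known not to amplify plant templates.
    """

    part5: str = "CTAGTAT"
    part3: str = "AGGAC"

    def __post_init__(self):
        p5 = _check_acgt(self.part5, "scaffold part5")
        p3 = _check_acgt(self.part3, "scaffold part3")
        if len(p5) != 7:
            raise InvalidSequenceError(f"scaffold part5 must be 7 nt, got {len(p5)}")
        if len(p3) != 5:
            raise InvalidSequenceError(f"scaffold part3 must be 5 nt, got {len(p3)}")
        object.__setattr__(self, "part5", p5)
        object.__setattr__(self, "part3", p3)


DEFAULT_SCAFFOLD = Scaffold()


@dataclass(frozen=True)
class SplitTag:
    """A parsed 16-nt bar-coded split tag with its cached Tm (degC)."""

    name: str
    full_seq: str
    scaffold5: str
    split_base: str
    scaffold3: str
    barcode: str
    tm: float

    def __post_init__(self):
        if self.scaffold5 + self.split_base + self.scaffold3 + self.barcode != self.full_seq:
            raise InvalidSequenceError("tag fields do not concatenate to full_seq")
        if len(self.full_seq) != TAG_LENGTH:
            raise InvalidSequenceError(
                f"tag must be {TAG_LENGTH} nt, got {len(self.full_seq)}"
            )

    @property
    def gc_clamped(self) -> bool:
        return self.barcode[-1] in "GC"


def parse_tag(
    seq: str,
    scaffold: Scaffold = DEFAULT_SCAFFOLD,
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
    name: str | None = None,
) -> SplitTag:
    """Decompose a 16-nt sequence into tag fields against a scaffold.

    Positions 1-7 and 9-13 must equal the scaffold; a deviation there raises
    :class:`ScaffoldViolationError` listing the offending positions.  The
    default name is ``"F9" + barcode``.
    """
    su = _check_acgt(seq, "tag sequence")
    if len(su) != TAG_LENGTH:
        raise InvalidSequenceError(f"tag must be {TAG_LENGTH} nt, got {len(su)}")
    expected = scaffold.part5 + "?" + scaffold.part3 + "???"
    bad = [
        i + 1
        for i in range(TAG_LENGTH)
        if expected[i] != "?" and su[i] != expected[i]
    ]
    if bad:
        raise ScaffoldViolationError(bad)
    barcode = su[13:16]
    return SplitTag(
        name=name or ("F9" + barcode),
        full_seq=su,
        scaffold5=su[0:7],
        split_base=su[7],
        scaffold3=su[8:13],
        barcode=barcode,
        tm=round_tm(melt_temp(su, conditions)),
    )


@dataclass(frozen=True)
class TagConstraints:
    """Structural and thermodynamic requirements on a single tag.

    ``tm_window`` brackets the published set (47.2-51.7 degC) with slack so a
    tag neither competes with sequence-specific primers (upper bound) nor
    fails to prime at the labeling temperature (lower bound).
    """

    tm_window: tuple[float, float] = (46.0, 53.0)
    require_gc_clamp: bool = True


@dataclass(frozen=True)
class TagVerdict:
    tag: SplitTag
    passed: bool
    reasons: tuple[str, ...]


def validate_tag(tag: SplitTag, constraints: TagConstraints = TagConstraints()) -> TagVerdict:
    """Check the GC clamp and Tm window; returns a verdict, never raises."""
    reasons = []
    if constraints.require_gc_clamp and not tag.gc_clamped:
        reasons.append("3' clamp: barcode must end in G or C")
    lo, hi = constraints.tm_window
    if not (lo <= tag.tm <= hi):
        reasons.append(f"Tm {tag.tm} outside window [{lo}, {hi}]")
    return TagVerdict(tag=tag, passed=not reasons, reasons=tuple(reasons))


def conserved_positions(tags: Sequence[SplitTag]) -> list[int]:
    """1-based positions identical across all tags (column-wise scan)."""
    if len(tags) < 2:
        raise ValueError("conserved_positions requires at least 2 tags")
    seqs = [t.full_seq for t in tags]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"tags have unequal lengths: {sorted(lengths)}")
    n = lengths.pop()
    return [i + 1 for i in range(n) if len({s[i] for s in seqs}) == 1]


@dataclass(frozen=True)
class PairPolicy:
    """Mutual-discrimination rule for a tag pair.

    The published set is the reference point: every pair there differs in the
    bar-code (hence a 3'-anchored run of at most 2 on the cross-duplex) and
    accumulates a 3'-weighted mismatch penalty of at least 3.  Requiring a
    literal split-base difference would reject published pairs, so the rule
    is bar-code uniqueness plus a weighted-score floor.
    """

    min_weighted_score: float = 3.0
    require_barcode_diff: bool = True


@dataclass(frozen=True)
class PairReport:
    tag_a: SplitTag
    tag_b: SplitTag
    report_ab: DuplexReport  # A's probe on a B-tagged template
    report_ba: DuplexReport
    passed: bool
    reasons: tuple[str, ...]


def pair_discrimination(
    tag_a: SplitTag,
    tag_b: SplitTag,
    policy: PairPolicy = PairPolicy(),
    weights: Sequence[float] | None = None,
) -> PairReport:
    """Score both cross-annealing orientations of a tag pair.

    Orientation A->B puts A's sequence as the probe and the strand displayed
    by a B-tagged product (the reverse complement of B) as the template site;
    the base-wise comparison then reduces to A versus B directly.
    """
    if (tag_a.scaffold5, tag_a.scaffold3) != (tag_b.scaffold5, tag_b.scaffold3):
        raise ValueError("pair_discrimination requires tags sharing a scaffold")
    rep_ab = duplex_score(tag_a.full_seq, revcomp(tag_b.full_seq), weights)
    rep_ba = duplex_score(tag_b.full_seq, revcomp(tag_a.full_seq), weights)
    reasons = []
    if policy.require_barcode_diff and tag_a.barcode == tag_b.barcode:
        reasons.append("barcode collision")
    if min(rep_ab.weighted_score, rep_ba.weighted_score) < policy.min_weighted_score:
        reasons.append(
            f"weighted score {min(rep_ab.weighted_score, rep_ba.weighted_score)} "
            f"below threshold {policy.min_weighted_score}"
        )
    return PairReport(
        tag_a=tag_a,
        tag_b=tag_b,
        report_ab=rep_ab,
        report_ba=rep_ba,
        passed=not reasons,
        reasons=tuple(reasons),
    )


@dataclass(frozen=True)
class SetReport:
    tag_verdicts: tuple[TagVerdict, ...]
    pair_reports: tuple[PairReport, ...]
    min_pairwise_weighted_score: float
    max_pairwise_longest_run: int
    passed: bool


def validate_set(
    tags: Sequence[SplitTag],
    policy: PairPolicy = PairPolicy(),
    constraints: TagConstraints = TagConstraints(),
) -> SetReport:
    """Aggregate per-tag and all-unordered-pairs checks into one report."""
    if len(tags) < 2:
        raise ValueError("validate_set requires at least 2 tags")
    verdicts = tuple(validate_tag(t, constraints) for t in tags)
    pairs = tuple(
        pair_discrimination(a, b, policy) for a, b in combinations(tags, 2)
    )
    min_score = min(
        min(p.report_ab.weighted_score, p.report_ba.weighted_score) for p in pairs
    )
    max_run = max(
        max(p.report_ab.longest_contiguous_run, p.report_ba.longest_contiguous_run)
        for p in pairs
    )
    passed = all(v.passed for v in verdicts) and all(p.passed for p in pairs)
    return SetReport(
        tag_verdicts=verdicts,
        pair_reports=pairs,
        min_pairwise_weighted_score=min_score,
        max_pairwise_longest_run=max_run,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# Generation


@dataclass(frozen=True)
class GenerationResult:
    """Outcome of tag-set generation with the filter funnel log.

    ``feasible`` is False when no size-k subset of passing candidates meets
    the pair policy; ``max_feasible_k`` then reports the largest set size the
    greedy selector could reach under the same policy.
    """

    tags: tuple[SplitTag, ...]
    feasible: bool
    max_feasible_k: int
    achieved_min_score: float
    log: dict

    def __iter__(self):
        return iter(self.tags)


def _pair_score(seq_a: str, seq_b: str, weights: Sequence[float]) -> float:
    return sum(w for a, b, w in zip(seq_a, seq_b, weights) if a != b)


def _find_clique(adj: list[set[int]], k: int, n: int, budget: int = 2_000_000):
    """First (lexicographically smallest) k-clique by ordered backtracking.

    Returns (clique or None, nodes_left_in_budget); budget exhaustion returns
    (None, 0) and the caller falls back to greedy.
    """
    clique: list[int] = []
    best: list[int] | None = None
    nodes = budget

    def extend(start: int, allowed: set[int]) -> bool:
        nonlocal best, nodes
        if len(clique) == k:
            best = list(clique)
            return True
        if len(clique) + len(allowed) < k:
            return False
        for v in sorted(a for a in allowed if a >= start):
            nodes -= 1
            if nodes <= 0:
                return False
            clique.append(v)
            if extend(v + 1, allowed & adj[v]):
                return True
            clique.pop()
        return False

    extend(0, set(range(n)))
    return best, nodes


def generate_tagset(
    scaffold: Scaffold = DEFAULT_SCAFFOLD,
    k: int = 6,
    constraints: TagConstraints = TagConstraints(),
    policy: PairPolicy = PairPolicy(),
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
    weights: Sequence[float] | None = None,
) -> GenerationResult:
    """Deterministically design a size-k tag set on a scaffold.

    The candidate space is the 4 split bases x 32 GC-clamped bar-codes = 128
    tags, enumerated lexicographically.  Candidates failing the single-tag
    constraints are dropped; among the survivors the selector returns a
    subset maximizing the minimum pairwise 3'-weighted mismatch score
    (threshold descent plus lexicographic clique backtracking, which is exact;
    a greedy max-min fallback engages only if the search budget is exhausted).
    Identical inputs always give identical output.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (the pairwise policy is undefined for k=1)")
    if weights is None:
        weights = thermo.default_weights(TAG_LENGTH)

    candidates: list[SplitTag] = []
    for split in "ACGT":
        for b1, b2 in product("ACGT", repeat=2):
            for b3 in "CG":
                seq = scaffold.part5 + split + scaffold.part3 + b1 + b2 + b3
                candidates.append(parse_tag(seq, scaffold, conditions))
    n_candidates = len(candidates)

    passing = [t for t in candidates if validate_tag(t, constraints).passed]
    log = {
        "candidates_enumerated": n_candidates,
        "candidates_passing_single_tag": len(passing),
    }
    n = len(passing)

    if n < k:
        return GenerationResult((), False, n if n >= 2 else 0, 0.0, log)

    score = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = _pair_score(passing[i].full_seq, passing[j].full_seq, weights)
            score[i][j] = score[j][i] = s

    def adjacency(threshold: float) -> list[set[int]]:
        adj = [set() for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if score[i][j] >= threshold and (
                    not policy.require_barcode_diff
                    or passing[i].barcode != passing[j].barcode
                ):
                    adj[i].add(j)
                    adj[j].add(i)
        return adj

    thresholds = sorted(
        {score[i][j] for i in range(n) for j in range(i + 1, n)}
        | {policy.min_weighted_score},
        reverse=True,
    )
    thresholds = [t for t in thresholds if t >= policy.min_weighted_score]

    chosen: list[int] | None = None
    achieved = 0.0
    for t in thresholds:
        adj = adjacency(t)
        clique, left = _find_clique(adj, k, n)
        if clique is not None:
            chosen, achieved = clique, t
            break
        if left <= 0:
            # budget exhausted at this threshold: deterministic greedy max-min
            chosen = _greedy_maxmin(score, adj, k, n)
            if chosen is not None:
                achieved = min(
                    score[i][j] for i, j in combinations(chosen, 2)
                )
                break

    if chosen is None:
        # infeasible at the policy threshold; find largest achievable k greedily
        adj = adjacency(policy.min_weighted_score)
        max_k = 0
        for kk in range(k - 1, 1, -1):
            c, _ = _find_clique(adj, kk, n, budget=200_000)
            if c is not None:
                max_k = kk
                break
        log["selection"] = "infeasible"
        return GenerationResult((), False, max_k, 0.0, log)

    tags = tuple(passing[i] for i in sorted(chosen))
    log["selection"] = "exact-threshold-clique"
    log["achieved_min_weighted_score"] = achieved
    return GenerationResult(tags, True, k, achieved, log)


def _greedy_maxmin(score, adj, k: int, n: int) -> list[int] | None:
    """Greedy max-min fallback: start from each vertex in order, repeatedly
    add the candidate maximizing the minimum score to the chosen set
    (lexicographic tie-break); return the first start reaching size k."""
    for start in range(n):
        chosen = [start]
        ok = True
        while len(chosen) < k:
            best_v, best_min = None, -1.0
            for v in range(n):
                if v in chosen or any(v not in adj[c] for c in chosen):
                    continue
                m = min(score[v][c] for c in chosen)
                if m > best_min:
                    best_v, best_min = v, m
            if best_v is None:
                ok = False
                break
            chosen.append(best_v)
        if ok:
            return sorted(chosen)
    return None


# ---------------------------------------------------------------------------
# I/O


def write_tag_tsv(tags: Iterable[SplitTag], path) -> None:
    """Write a tag table with columns name, sequence, tm."""
    with open(path, "w") as fh:
        fh.write("name\tsequence\ttm\n")
        for t in tags:
            fh.write(f"{t.name}\t{t.full_seq}\t{t.tm:.1f}\n")


def read_tag_tsv(
    path,
    scaffold: Scaffold = DEFAULT_SCAFFOLD,
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
) -> list[SplitTag]:
    """Read a name/sequence/tm table; Tm is recomputed, names are kept."""
    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        if "name" not in idx or "sequence" not in idx:
            raise ValueError(f"tag table {path} must have 'name' and 'sequence' columns")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            tags.append(
                parse_tag(parts[idx["sequence"]], scaffold, conditions,
                          name=parts[idx["name"]])
            )
    return tags


def tags_to_json(tags: Iterable[SplitTag]) -> str:
    return json.dumps(
        [
            {
                "name": t.name,
                "full_seq": t.full_seq,
                "scaffold5": t.scaffold5,
                "split_base": t.split_base,
                "scaffold3": t.scaffold3,
                "barcode": t.barcode,
                "tm": t.tm,
            }
            for t in tags
        ],
        indent=2,
    )


def tags_from_json(text: str) -> list[SplitTag]:
    return [SplitTag(**d) for d in json.loads(text)]
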