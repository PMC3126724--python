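"""In-silico mispriming screen: priming sites and predicted amplicons.

Stands in for the empirical no-amplification screen (and the homology search
preceding it): a primer is considered able to prime at a genomic position iff
its 3'-terminal seed matches the template exactly and the remaining bases
accumulate at most a capped number of mismatches.  The seed default of 8 nt
is one more than the split sub-sequence length shown not to bind.  Two
opposite-strand sites with converging 3' ends on the same record and a
bounded span predict an amplicon.

Coordinates are 0-based half-open internally; written TSV is 1-based
inclusive and BED stays 0-based half-open per that format's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

from .errors import InvalidSequenceError
from .thermo import DuplexReport, duplex_score, revcomp

__all__ = [
    "ScanParams",
    "PrimingSite",
    "Amplicon",
    "ScreenReport",
    "find_priming_sites",
    "predict_amplicons",
    "screen_assay",
    "screen_tags",
    "sites_to_tsv",
    "sites_to_bed",
    "amplicons_to_tsv",
]


@dataclass(frozen=True)
class ScanParams:
    """Site-scan stringency.

    ``seed_len`` (s): exact-match 3'-terminal seed; ``max_mismatches`` (m):
    cap over the full primer footprint; ``max_product``: longest span paired
    into an amplicon.  The empirical screen ran an annealing gradient rather
    than an (s, m) rule; the mapping chosen here is recorded in report
    headers so downstream readers see it was a modeling decision.
    """

    seed_len: int = 8
    max_mismatches: int = 2
    max_product: int = 2000


@dataclass(frozen=True)
class PrimingSite:
    """A predicted primer-binding location on a background sequence.

    ``start``/``end`` are 0-based half-open on the forward strand; ``strand``
    '+' means the primer reads left-to-right on the forward strand (extends
    rightward), '-' means it matches the reverse complement (extends left).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    three_prime_match: int
    total_mismatches: int
    primer_label: str = ""
    report: DuplexReport | None = field(default=None, compare=False)


@dataclass(frozen=True)
class Amplicon:
    """A predicted product between a '+' forward site and a '-' reverse site."""

    seq_id: str
    forward: PrimingSite
    reverse: PrimingSite
    product_length: int
    forward_label: str = ""
    reverse_label: str = ""


def _scan_forward(primer: str, seq_id: str, seq: str, params: ScanParams,
                  label: str) -> list[tuple[int, int, int, int, DuplexReport]]:
    """All windows on `seq` (read 5'->3') matching `primer` with an exact
    3'-terminal seed; returns (start, end, anchored, mismatches, report)."""
    out = []
    seed = primer[-params.seed_len:]
    plen = len(primer)
    pos = seq.find(seed)
    while pos != -1:
        end = pos + params.seed_len
        start = end - plen
        if start >= 0:
            window = seq[start:end]
            # primer anneals to the complement of this window; scoring the
            # window's revcomp as the template site reduces to direct
            # base-wise comparison primer vs window
            rep = duplex_score(primer, revcomp(window))
            if (
                rep.total_mismatches <= params.max_mismatches
                and rep.three_prime_anchored_run >= params.seed_len
            ):
                out.append((start, end, rep.three_prime_anchored_run,
                            rep.total_mismatches, rep))
        pos = seq.find(seed, pos + 1)
    return out


def find_priming_sites(
    primer: str,
    sequences: Mapping[str, str],
    params: ScanParams = ScanParams(),
    label: str = "",
) -> list[PrimingSite]:
    """Scan a sequence collection for predicted priming sites on both strands.

    Uses exact search for the primer's 3'-terminal s-mer, then extends and
    scores the full footprint.  N in the background never matches any primer
    base.  Results are sorted by (seq_id, start, strand).
    """
    pu = primer.upper()
    if len(pu) < params.seed_len:
        raise InvalidSequenceError(
            f"primer length {len(pu)} shorter than seed length {params.seed_len}"
        )
    sites: list[PrimingSite] = []
    for seq_id, seq in sequences.items():
        su = seq.upper()
        n = len(su)
        for start, end, anch, mism, rep in _scan_forward(pu, seq_id, su, params, label):
            sites.append(PrimingSite(seq_id, start, end, "+", anch, mism, label, rep))
        rc = revcomp(su)
        for s0, e0, anch, mism, rep in _scan_forward(pu, seq_id, rc, params, label):
            sites.append(
                PrimingSite(seq_id, n - e0, n - s0, "-", anch, mism, label, rep)
            )
    sites.sort(key=lambda s: (s.seq_id, s.start, s.strand))
    return sites


def predict_amplicons(
    forward_primers: Sequence[tuple[str, str]],
    reverse_primers: Sequence[tuple[str, str]],
    sequences: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> list[Amplicon]:
    """Pair converging opposite-strand sites into predicted products.

    Primers are (label, sequence) pairs.  A '+' site of any forward primer
    and a '-' site of any reverse primer on the same record predict a product
    spanning forward.start to reverse.end when the 3' ends converge and the
    span does not exceed ``params.max_product``.
    """
    fwd_sites: list[PrimingSite] = []
    rev_sites: list[PrimingSite] = []
    for lab, seq in forward_primers:
        fwd_sites.extend(
            s for s in find_priming_sites(seq, sequences, params, lab)
            if s.strand == "+"
        )
    for lab, seq in reverse_primers:
        rev_sites.extend(
            s for s in find_priming_sites(seq, sequences, params, lab)
            if s.strand == "-"
        )
    out: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.seq_id != r.seq_id:
                continue
            if not (f.start <= r.start and f.end <= r.end):
                continue
            product = r.end - f.start
            if 0 < product <= params.max_product:
                out.append(
                    Amplicon(f.seq_id, f, r, product, f.primer_label, r.primer_label)
                )
    out.sort(key=lambda a: (a.seq_id, a.forward.start, a.reverse.end,
                            a.forward_label, a.reverse_label))
    return out


@dataclass(frozen=True)
class ScreenReport:
    """Specificity verdict: pass iff zero unintended amplicons were predicted."""

    passed: bool
    sites: tuple[PrimingSite, ...]
    amplicons: tuple[Amplicon, ...]
    intended: tuple[Amplicon, ...]
    unintended: tuple[Amplicon, ...]
    header: str

    def summary(self) -> str:
        return (
            f"{self.header}\n"
            f"sites: {len(self.sites)}; amplicons: {len(self.amplicons)} "
            f"({len(self.intended)} intended, {len(self.unintended)} unintended); "
            f"{'PASS' if self.passed else 'FAIL'}"
        )


def _header(params: ScanParams) -> str:
    return (
        f"# in-silico screen: 3'-seed {params.seed_len} nt exact, "
        f"<= {params.max_mismatches} mismatches, product <= {params.max_product} bp "
        "(rule-based stand-in for an annealing-gradient no-amplification assay)"
    )


def screen_assay(
    assay,
    sequences: Mapping[str, str],
    params: ScanParams = ScanParams(),
    intended_locus: tuple[str, int, int] | None = None,
) -> ScreenReport:
    """Screen a marker assay's two working oligos against backgrounds.

    ``intended_locus`` is an optional (seq_id, start, end) half-open window;
    amplicons whose forward site starts inside it count as intended, anything
    else as unintended.  Pass iff no unintended amplicons.
    """
    fwd = assay.tagged_forward.upper()
    rev = assay.tailed_reverse.upper()
    amps = predict_amplicons(
        [(assay.name + ":F", fwd)], [(assay.name + ":R", rev)], sequences, params
    )
    sites = tuple(
        find_priming_sites(fwd, sequences, params, assay.name + ":F")
        + find_priming_sites(rev, sequences, params, assay.name + ":R")
    )
    intended, unintended = [], []
    for a in amps:
        if (
            intended_locus is not None
            and a.seq_id == intended_locus[0]
            and intended_locus[1] <= a.forward.start < intended_locus[2]
        ):
            intended.append(a)
        else:
            unintended.append(a)
    return ScreenReport(
        passed=not unintended,
        sites=sites,
        amplicons=tuple(amps),
        intended=tuple(intended),
        unintended=tuple(unintended),
        header=_header(params),
    )


def screen_tags(
    tags,
    sequences: Mapping[str, str],
    params: ScanParams = ScanParams(),
) -> ScreenReport:
    """Screen a tag set alone: every ordered tag pair as a pseudo primer pair.

    Reproduces, on synthetic backgrounds, the check that the tag primers give
    no product by themselves or in any two-primer combination.
    """
    labeled = [(t.name, t.full_seq) for t in tags]
    sites: list[PrimingSite] = []
    for lab, seq in labeled:
        sites.extend(find_priming_sites(seq, sequences, params, lab))
    amps: list[Amplicon] = []
    for (la, sa), (lb, sb) in permutations(labeled, 2):
        amps.extend(predict_amplicons([(la, sa)], [(lb, sb)], sequences, params))
    # a single tag can also pair with itself on opposite strands
    for la, sa in labeled:
        amps.extend(predict_amplicons([(la, sa)], [(la, sa)], sequences, params))
    amps.sort(key=lambda a: (a.seq_id, a.forward.start, a.reverse.end,
                             a.forward_label, a.reverse_label))
    return ScreenReport(
        passed=not amps,
        sites=tuple(sites),
        amplicons=tuple(amps),
        intended=(),
        unintended=tuple(amps),
        header=_header(params),
    )


# ---------------------------------------------------------------------------
# Writers (TSV 1-based inclusive; BED 0-based half-open)


def sites_to_tsv(sites: Iterable[PrimingSite], path, params: ScanParams = ScanParams()) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params) + "\n")
        fh.write("seq_id\tstart\tend\tstrand\tprimer\tthree_prime_match\tmismatches\n")
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.start + 1}\t{s.end}\t{s.strand}\t"
                f"{s.primer_label}\t{s.three_prime_match}\t{s.total_mismatches}\n"
            )


def sites_to_bed(sites: Iterable[PrimingSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.start}\t{s.end}\t{s.primer_label}\t"
                f"{s.total_mismatches}\t{s.strand}\n"
            )


def amplicons_to_tsv(amplicons: Iterable[Amplicon], path,
                     params: ScanParams = ScanParams()) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params) + "\n")
        fh.write("seq_id\tstart\tend\tproduct_length\tforward\treverse\n")
        for a in amplicons:
            fh.write(
                f"{a.seq_id}\t{a.forward.start + 1}\t{a.reverse.end}\t"
                f"{a.product_length}\t{a.forward_label}\t{a.reverse_label}\n"
            )
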