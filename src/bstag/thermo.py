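"""Nearest-neighbor melting temperatures and duplex discrimination scoring.

The tag system relies on two thermodynamic facts: (i) every tag melts a few
degrees below the sequence-specific primers, so labeling can be confined to a
short low-temperature second stage, and (ii) any two tags present each other
with a broken duplex — a mismatch near the 3' bar-code and another at the
split position — so a labeled tag primer never extends on a product carrying a
different tag.  ``melt_temp`` handles (i) with a standard unified
nearest-neighbor model; ``duplex_score``/``anneals`` handle (ii) with a
positional mismatch model (runs of perfect match plus 3'-weighted penalties),
which mirrors the design argument that split sub-sequences of seven
nucleotides or fewer are too short to prime.

Buffer conditions behind the published tag Tm values are recovered by a grid
search over standard salt and oligo concentrations (``calibrate_conditions``);
the calibrated point is shipped as ``CALIBRATED_CONDITIONS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Iterable, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "ThermoConditions",
    "DuplexReport",
    "AnnealPolicy",
    "CalibrationResult",
    "CALIBRATED_CONDITIONS",
    "melt_temp",
    "round_tm",
    "calibrate_conditions",
    "duplex_score",
    "default_weights",
    "anneals",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case-preserving translate)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sequence(seq: str, min_len: int = 8) -> str:
    su = seq.upper()
    if len(su) < min_len:
        from .errors import InvalidSequenceError

        raise InvalidSequenceError(
            f"sequence length {len(su)} below minimum {min_len}: {seq!r}"
        )
    for i, base in enumerate(su):
        if base not in _VALID_BASES:
            from .errors import InvalidSequenceError

            raise InvalidSequenceError(
                f"invalid character {seq[i]!r} at position {i + 1}; "
                "only A, C, G, T are accepted"
            )
    return su


@dataclass(frozen=True)
class ThermoConditions:
    """Salt and oligonucleotide concentration context for Tm calculations.

    All concentrations are in mol/L.  ``monovalent_salt`` must be positive
    (the salt correction is undefined at zero); the others may be zero.
    """

    monovalent_salt: float = 0.05
    divalent_salt: float = 0.0015
    oligo_conc: float = 200e-9
    dntp_conc: float = 0.0002

    def __post_init__(self):
        for name in ("monovalent_salt", "divalent_salt", "oligo_conc", "dntp_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0 for the salt correction")


#: Conditions recovered by grid calibration against the six published tags;
#: under these every published tag Tm is reproduced at 0.1 degC precision.
CALIBRATED_CONDITIONS = ThermoConditions(
    monovalent_salt=0.05,
    divalent_salt=0.0015,
    oligo_conc=200e-9,
    dntp_conc=0.0002,
)


def melt_temp(sequence: str, conditions: ThermoConditions = CALIBRATED_CONDITIONS) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Uses the unified NN parameter set with a SantaLucia-style monovalent salt
    correction and divalent/dNTP adjustment.  Deterministic and
    strand-symmetric: a sequence and its reverse complement describe the same
    duplex and return the same Tm.

    Parameters
    ----------
    sequence:
        Primer sequence 5'->3', at least 8 nt, alphabet {A, C, G, T}
        (case-insensitive).
    conditions:
        Buffer context; defaults to the calibrated shipped conditions.
    """
    su = _check_sequence(sequence)
    return float(
        _mt.Tm_NN(
            su,
            nn_table=_mt.DNA_NN3,
            Na=conditions.monovalent_salt * 1e3,  # mM
            K=0.0,
            Tris=0.0,
            Mg=conditions.divalent_salt * 1e3,  # mM
            dNTPs=conditions.dntp_conc * 1e3,  # mM
            dnac1=conditions.oligo_conc * 1e9,  # nM
            dnac2=0.0,
            saltcorr=5,
        )
    )


def round_tm(tm: float) -> float:
    """Round a Tm to 0.1 degC, half-up, matching reported precision."""
    return float(Decimal(repr(tm)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Calibration

#: Documented finite grids of standard buffer values (mol/L) searched by
#: calibrate_conditions.  Monovalent: common PCR/hybridization Na+ levels;
#: divalent: MgCl2 from 0 to 3 mM; oligo: typical primer loads; dNTP: none,
#: standard 0.2 mM, and a high-dNTP mix.
MONOVALENT_GRID: tuple[float, ...] = (0.020, 0.050, 0.075, 0.100, 0.150)
DIVALENT_GRID: tuple[float, ...] = (0.0, 0.0005, 0.001, 0.0015, 0.002, 0.0025, 0.003)
OLIGO_GRID: tuple[float, ...] = (50e-9, 100e-9, 200e-9, 250e-9, 500e-9)
DNTP_GRID: tuple[float, ...] = (0.0, 0.0002, 0.0008)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the condition grid search.

    ``residuals`` maps each input sequence to predicted minus published Tm
    under the selected conditions.  ``success`` is False when no grid point
    brings the maximum absolute residual within ``tolerance``; the best
    point found is still reported so the residuals can be inspected.
    """

    conditions: ThermoConditions
    residuals: dict[str, float]
    max_residual: float
    tolerance: float
    success: bool

    def summary(self) -> str:
        lines = [
            f"calibration {'succeeded' if self.success else 'FAILED'}: "
            f"max |residual| {self.max_residual:.3f} degC (tolerance {self.tolerance})",
            f"  conditions: Na+ {self.conditions.monovalent_salt} M, "
            f"Mg2+ {self.conditions.divalent_salt} M, "
            f"oligo {self.conditions.oligo_conc} M, dNTP {self.conditions.dntp_conc} M",
        ]
        for seq, res in self.residuals.items():
            lines.append(f"  {seq}: {res:+.3f}")
        return "\n".join(lines)


def calibrate_conditions(
    tag_table: Sequence[tuple[str, float]],
    tolerance: float = 0.5,
    monovalent_grid: Iterable[float] = MONOVALENT_GRID,
    divalent_grid: Iterable[float] = DIVALENT_GRID,
    oligo_grid: Iterable[float] = OLIGO_GRID,
    dntp_grid: Iterable[float] = DNTP_GRID,
) -> CalibrationResult:
    """Recover buffer conditions from (sequence, published Tm) pairs.

    Exhaustively evaluates the documented grids and returns the point
    minimizing the maximum absolute Tm residual over the table.  The grid is
    traversed in a fixed order and only strict improvements are kept, so the
    result is deterministic.  A table whose best point exceeds ``tolerance``
    yields ``success=False`` (a report, not an exception); an empty table is
    an error.
    """
    entries = [(str(s).upper(), float(t)) for s, t in tag_table]
    if not entries:
        raise ValueError("calibration requires at least one (sequence, Tm) entry")
    # Duplicates carry no information for a max-residual fit; drop them so a
    # repeated entry behaves exactly like a single one.
    entries = list(dict.fromkeys(entries))

    best: tuple[float, ThermoConditions, dict[str, float]] | None = None
    for mono, diva, oligo, dntp in product(
        monovalent_grid, divalent_grid, oligo_grid, dntp_grid
    ):
        cond = ThermoConditions(mono, diva, oligo, dntp)
        residuals = {s: melt_temp(s, cond) - t for s, t in entries}
        worst = max(abs(r) for r in residuals.values())
        if best is None or worst < best[0]:
            best = (worst, cond, residuals)

    worst, cond, residuals = best
    return CalibrationResult(
        conditions=cond,
        residuals=residuals,
        max_residual=worst,
        tolerance=tolerance,
        success=worst <= tolerance,
    )


# ---------------------------------------------------------------------------
# Positional duplex model


def default_weights(length: int) -> tuple[float, ...]:
    """3'-proximity weight vector: 3 for the 3'-terminal 3 positions, 2 for
    positions 4-8 from the 3' end, 1 elsewhere.  Index 0 is the probe 5' end.

    The heavy 3' weights encode the GC-clamped landing emphasis: a mismatch
    under the polymerase footprint is far more disruptive than one near 5'.
    """
    weights = []
    for i in range(length):
        from_3p = length - i  # 1 for the 3'-terminal base
        if from_3p <= 3:
            weights.append(3.0)
        elif from_3p <= 8:
            weights.append(2.0)
        else:
            weights.append(1.0)
    return tuple(weights)


@dataclass(frozen=True)
class DuplexReport:
    """Base-wise description of a probe annealed to a template site.

    Positions are 1-based from the probe 5' end.  ``three_prime_anchored_run``
    is the perfect-match run ending at the probe 3' terminus — the quantity
    that decides whether a polymerase can initiate.  ``weighted_score`` sums
    the 3'-proximity weights over mismatch positions; zero iff perfect match.
    """

    mismatch_positions: tuple[int, ...]
    total_mismatches: int
    three_prime_anchored_run: int
    longest_contiguous_run: int
    weighted_score: float
    probe_length: int = field(default=0, compare=False)

    @property
    def perfect(self) -> bool:
        return self.total_mismatches == 0


def duplex_score(
    probe: str,
    template_site: str,
    weights: Sequence[float] | None = None,
) -> DuplexReport:
    """Score a probe against the template strand it would anneal to.

    ``template_site`` is given 5'->3' as the strand the probe anneals to; the
    probe is compared base-by-base against the reverse complement of that
    strand.  N on the template never matches.

    Raises a length-mismatch error for unequal lengths.
    """
    if len(probe) != len(template_site):
        raise ValueError(
            f"probe length {len(probe)} != template site length {len(template_site)}"
        )
    pu = probe.upper()
    target = revcomp(template_site.upper())
    n = len(pu)
    if weights is None:
        weights = default_weights(n)
    elif len(weights) != n:
        raise ValueError(f"weight vector length {len(weights)} != probe length {n}")

    mask = [pu[i] == target[i] and target[i] != "N" and pu[i] != "N" for i in range(n)]
    mismatches = tuple(i + 1 for i, ok in enumerate(mask) if not ok)

    longest = run = 0
    for ok in mask:
        run = run + 1 if ok else 0
        longest = max(longest, run)
    anchored = 0
    for ok in reversed(mask):
        if not ok:
            break
        anchored += 1

    score = float(sum(weights[p - 1] for p in mismatches))
    return DuplexReport(
        mismatch_positions=mismatches,
        total_mismatches=len(mismatches),
        three_prime_anchored_run=anchored,
        longest_contiguous_run=longest,
        weighted_score=score,
        probe_length=n,
    )


@dataclass(frozen=True)
class AnnealPolicy:
    """Rule-based gate deciding whether a probe primes at a given temperature.

    ``seed_len``: minimum perfect-match run ending at the probe 3' terminus
    (a split sub-sequence of 7 nt does not prime, hence the default 8).
    ``mismatch_cap``: maximum tolerated mismatches over the whole duplex.
    ``margin``: degC below the annealing temperature at which a duplex still
    forms transiently enough to be extended.
    ``min_duplex``: shortest perfect sub-duplex considered bindable at all.
    """

    seed_len: int = 8
    mismatch_cap: int = 2
    margin: float = 3.0
    min_duplex: int = 8


def anneals(
    probe: str,
    template_site: str,
    annealing_temp: float,
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
    policy: AnnealPolicy = AnnealPolicy(),
    weights: Sequence[float] | None = None,
) -> bool:
    """True iff the probe is predicted to prime on the site at the given
    annealing temperature.

    Two gates must pass: (i) the longest perfectly matched sub-duplex, modeled
    as an independent short duplex, melts no more than ``policy.margin`` degC
    below the annealing temperature; (ii) the positional report passes the
    policy (3'-anchored run at least ``seed_len``, mismatch count at most
    ``mismatch_cap``).  An unbounded temperature therefore never anneals.
    """
    report = duplex_score(probe, template_site, weights)
    if report.three_prime_anchored_run < policy.seed_len:
        return False
    if report.total_mismatches > policy.mismatch_cap:
        return False
    if report.longest_contiguous_run < policy.min_duplex:
        return False
    if math.isinf(annealing_temp):
        return False

    # locate the longest matched run and melt that sub-sequence
    pu = probe.upper()
    target = revcomp(template_site.upper())
    best_start = best_len = run_start = run_len = 0
    for i in range(len(pu)):
        if pu[i] == target[i] and pu[i] != "N":
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    sub = pu[best_start : best_start + best_len]
    return melt_temp(sub, conditions) >= annealing_temp - policy.margin
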