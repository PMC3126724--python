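"""Seeded synthetic backgrounds with planted loci.

Emulates the screening substrates of the original evaluation — genomic DNA
from a dozen plant species — with uniform-composition random sequence, so
every screening and simulation stage is testable without downloads.  The
generator is fully deterministic: identical (seed, spec) produce
byte-identical FASTA and truth tables.  What random sequence does *not*
emulate: real base composition bias, repeat families, and paralogy, so a
clean screen here is a correctness check of the scanner, not evidence about
any real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .thermo import revcomp

__all__ = [
    "PlantedSequence",
    "PlantedSSR",
    "PlantedSNP",
    "FixtureSpec",
    "FixtureSet",
    "make_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedSequence:
    """An explicit sequence written into a background (e.g. a primer site).

    ``strand`` '-' plants the reverse complement.  ``mismatch_at`` (1-based
    position within ``seq``) flips that base to its transversion partner
    before planting, for constructing near-miss sites.
    """

    seq: str
    background: int
    position: int
    strand: str = "+"
    mismatch_at: int | None = None
    name: str = "site"


@dataclass(frozen=True)
class PlantedSSR:
    """An SSR locus: forward site + motif repeats + reverse site.

    The planted allele is ``repeats[0]``; product lengths for every allele
    are recorded in the truth table (spacer-free arithmetic:
    len(forward) + repeats*len(motif) + len(reverse))."""

    name: str
    forward_site: str
    reverse_site: str  # reverse primer sequence 5'->3' (revcomp is planted)
    motif: str
    repeats: tuple[int, ...]
    background: int
    position: int


@dataclass(frozen=True)
class PlantedSNP:
    """A biallelic SNP context: the planted base is ``alleles[0]``."""

    name: str
    alleles: tuple[str, str]
    background: int
    position: int


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic background collection.

    Defaults mirror the scale of the original no-amplification screen:
    twelve species stand-ins of 20 kb each.
    """

    seed: int
    n_backgrounds: int = 12
    background_length: int = 20_000
    planted: tuple = ()


@dataclass
class FixtureSet:
    sequences: dict[str, str]
    truth: list[dict]

    def truth_tsv(self) -> str:
        cols = ["name", "type", "seq_id", "start", "end", "detail"]
        lines = ["\t".join(cols)]
        for row in self.truth:
            lines.append("\t".join(str(row[c]) for c in cols))
        return "\n".join(lines) + "\n"


def _transversion(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base.upper()]


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_fixtures(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureSet:
    """Generate backgrounds, plant loci, and (optionally) write files.

    Backgrounds are named ``bg01`` .. ``bgNN``.  Planting overwrites the
    background in place; a locus extending past the end of its background is
    an error.  Truth-table coordinates are 1-based inclusive.  When
    ``outdir`` is given, ``backgrounds.fasta`` and ``truth.tsv`` are written
    there (byte-deterministic per seed).
    """
    rng = np.random.default_rng(spec.seed)
    arrays = [
        _random_background(rng, spec.background_length)
        for _ in range(spec.n_backgrounds)
    ]
    ids = [f"bg{i + 1:02d}" for i in range(spec.n_backgrounds)]
    truth: list[dict] = []

    def plant(background: int, position: int, insert: str, name: str,
              kind: str, detail: str):
        if background >= spec.n_backgrounds:
            raise ValueError(f"{name}: background index {background} out of range")
        if position + len(insert) > spec.background_length:
            raise ValueError(
                f"{name}: planted locus ({len(insert)} nt at {position}) "
                f"exceeds background length {spec.background_length}"
            )
        arrays[background][position : position + len(insert)] = np.frombuffer(
            insert.upper().encode(), dtype="S1"
        )
        truth.append(
            {
                "name": name,
                "type": kind,
                "seq_id": ids[background],
                "start": position + 1,
                "end": position + len(insert),
                "detail": detail,
            }
        )

    for locus in spec.planted:
        if isinstance(locus, PlantedSequence):
            seq = locus.seq.upper()
            if locus.mismatch_at is not None:
                i = locus.mismatch_at - 1
                seq = seq[:i] + _transversion(seq[i]) + seq[i + 1 :]
            if locus.strand == "-":
                seq = revcomp(seq)
            plant(locus.background, locus.position, seq, locus.name,
                  "primer-site", f"strand={locus.strand}")
        elif isinstance(locus, PlantedSSR):
            allele0 = locus.repeats[0]
            insert = (
                locus.forward_site.upper()
                + locus.motif.upper() * allele0
                + revcomp(locus.reverse_site.upper())
            )
            lengths = [
                len(locus.forward_site) + r * len(locus.motif) + len(locus.reverse_site)
                for r in locus.repeats
            ]
            plant(
                locus.background, locus.position, insert, locus.name, "SSR",
                f"motif={locus.motif};repeats={','.join(map(str, locus.repeats))};"
                f"product_lengths={','.join(map(str, lengths))}",
            )
        elif isinstance(locus, PlantedSNP):
            plant(
                locus.background, locus.position, locus.alleles[0], locus.name,
                "SNP", f"alleles={locus.alleles[0]}/{locus.alleles[1]}",
            )
        else:
            raise TypeError(f"unknown planted locus type: {type(locus)!r}")

    sequences = {
        sid: arr.tobytes().decode() for sid, arr in zip(ids, arrays)
    }
    fixture = FixtureSet(sequences=sequences, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_fasta

        write_fasta(sequences, outdir / "backgrounds.fasta")
        (outdir / "truth.tsv").write_text(fixture.truth_tsv())
    return fixture
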