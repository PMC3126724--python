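"""FASTA and marker-sheet I/O.

Marker sheets are tab-separated and mirror the printed assay tables: one row
per oligo, lowercase segments (PIG-tail, introduced ASO mismatches) preserved
verbatim, so that parsing a sheet and re-rendering it is byte-identical.
Human-facing coordinates are 1-based inclusive everywhere; BED output (see
:mod:`bstag.specificity`) stays 0-based half-open.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO

from .assay import AsoRecord, MarkerAssay, SnpAssay
from .errors import FastaParseError, MarkerTableError
from .tagset import SplitTag
from .thermo import CALIBRATED_CONDITIONS, ThermoConditions, melt_temp, round_tm

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_marker_table",
    "write_assay_sheet",
    "assays_to_json",
]

MARKER_COLUMNS = [
    "marker", "accession", "motif", "role", "tag", "dye",
    "size_min", "size_max", "sequence",
]
SNP_COLUMNS = ["marker", "accession", "snp", "role", "allele", "tag", "dye", "sequence"]


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered {id: sequence} mapping.

    Case is preserved.  Duplicate ids, an empty file, or content before the
    first header are parse errors carrying a line number where known.
    """
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FastaParseError(f"empty FASTA file: {path}")
        if not first[1].startswith(">"):
            raise FastaParseError("expected '>' header", line=first[0])
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaParseError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(collection: Mapping[str, str], path, width: int = 60) -> None:
    """Write an {id: sequence} mapping, wrapping sequence lines at 60 columns."""
    with open(path, "w") as fh:
        for seq_id, seq in collection.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Marker sheets


def _split_tail(oligo: str) -> tuple[str, str]:
    """Split a rendered reverse/LSO oligo into (lowercase tail, core)."""
    i = 0
    while i < len(oligo) and oligo[i].islower():
        i += 1
    return oligo[:i], oligo[i:]


def read_marker_table(
    path,
    tags: Mapping[str, SplitTag],
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
) -> tuple[list[MarkerAssay], list[SnpAssay]]:
    """Parse a marker sheet into SSR/indel assays and SNP assays.

    ``tags`` maps tag names to parsed tags; a row naming an unknown tag, a
    tagged sequence not starting with its named tag, or a non-ACGT core is a
    row-level error.  All row errors are collected into one
    :class:`MarkerTableError`.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [
            line.rstrip("\n").split("\t") for line in fh if line.strip()
        ]
    idx = {c: i for i, c in enumerate(header)}

    def get(row, col, default=""):
        i = idx.get(col)
        return row[i] if i is not None and i < len(row) else default

    errors: dict[int, str] = {}
    is_snp_sheet = "snp" in idx and "allele" in idx

    ssr: list[MarkerAssay] = []
    snp: list[SnpAssay] = []

    def check_acgt(seq, rowno, what):
        bad = [c for c in seq.upper() if c not in "ACGT"]
        if bad:
            errors[rowno] = f"{what}: non-ACGT character {bad[0]!r}"
            return False
        return True

    if not is_snp_sheet:
        pending: dict[str, dict] = {}
        order: list[str] = []
        for rowno, row in enumerate(rows, 1):
            marker = get(row, "marker")
            role = get(row, "role").lower()
            rec = pending.setdefault(marker, {})
            if marker not in order:
                order.append(marker)
            if role == "forward":
                tag_name = get(row, "tag")
                if tag_name not in tags:
                    errors[rowno] = f"unknown tag {tag_name!r}"
                    continue
                tag = tags[tag_name]
                seq = get(row, "sequence")
                if not seq.upper().startswith(tag.full_seq):
                    errors[rowno] = (
                        f"forward sequence does not start with tag {tag_name}"
                    )
                    continue
                core = seq[len(tag.full_seq):]
                if not check_acgt(core, rowno, "forward core"):
                    continue
                rec.update(
                    tag=tag, dye=get(row, "dye"), tagged_forward=seq,
                    forward_core=core,
                    accession=get(row, "accession") or None,
                    motif=get(row, "motif") or None,
                    size_min=get(row, "size_min"), size_max=get(row, "size_max"),
                )
            elif role == "reverse":
                seq = get(row, "sequence")
                tail, core = _split_tail(seq)
                if not check_acgt(core, rowno, "reverse core"):
                    continue
                rec.update(tailed_reverse=seq, reverse_core=core, pigtail=tail)
            else:
                errors[rowno] = f"unknown role {role!r}"
        if errors:
            raise MarkerTableError(errors)
        for marker in order:
            rec = pending[marker]
            if "tag" not in rec or "reverse_core" not in rec:
                continue
            size_range = None
            if rec.get("size_min") and rec.get("size_max"):
                size_range = (int(rec["size_min"]), int(rec["size_max"]))
            ssr.append(
                MarkerAssay(
                    name=marker,
                    forward_core=rec["forward_core"],
                    reverse_core=rec["reverse_core"],
                    tag=rec["tag"],
                    dye=rec["dye"],
                    tagged_forward=rec["tagged_forward"],
                    tailed_reverse=rec["tailed_reverse"],
                    pigtail=rec["pigtail"],
                    expected_size_range=size_range,
                    motif=rec.get("motif"),
                    accession=rec.get("accession"),
                    core_tm=round_tm(melt_temp(rec["forward_core"], conditions)),
                )
            )
        return ssr, snp

    # SNP sheet
    pending = {}
    order = []
    for rowno, row in enumerate(rows, 1):
        marker = get(row, "marker")
        role = get(row, "role").upper()
        rec = pending.setdefault(
            marker,
            {"accession": get(row, "accession") or None, "snp": get(row, "snp"),
             "asos": []},
        )
        if marker not in order:
            order.append(marker)
        if role == "LSO":
            rec["lso"] = get(row, "sequence")
        elif role == "ASO":
            tag_name = get(row, "tag")
            if tag_name not in tags:
                errors[rowno] = f"unknown tag {tag_name!r}"
                continue
            tag = tags[tag_name]
            seq = get(row, "sequence")
            if not seq.upper().startswith(tag.full_seq):
                errors[rowno] = f"ASO sequence does not start with tag {tag_name}"
                continue
            core = seq[len(tag.full_seq):]
            if not check_acgt(core, rowno, "ASO core"):
                continue
            lower = [i for i, c in enumerate(core) if c.islower()]
            offset = (len(core) - 1 - max(lower)) if lower else 0
            rec["asos"].append(
                AsoRecord(
                    allele=get(row, "allele"),
                    core=core,
                    introduced_mismatch_offset=offset,
                    tag=tag,
                    dye=get(row, "dye"),
                    tagged=seq,
                )
            )
        else:
            errors[rowno] = f"unknown role {role!r}"
    if errors:
        raise MarkerTableError(errors)
    for marker in order:
        rec = pending[marker]
        if len(rec["asos"]) != 2 or "lso" not in rec:
            continue
        alleles = tuple(rec["snp"].split("/")) if rec["snp"] else tuple(
            a.allele for a in rec["asos"]
        )
        snp.append(
            SnpAssay(
                name=marker,
                snp_alleles=alleles,  # type: ignore[arg-type]
                lso=rec["lso"],
                asos=tuple(rec["asos"]),
                accession=rec["accession"],
            )
        )
    return ssr, snp


def write_assay_sheet(assays: Iterable[MarkerAssay | SnpAssay], path) -> None:
    """Render assays back to the tab-separated sheet layout.

    A sheet holds either SSR/indel assays or SNP assays (the printed tables
    are separate); mixing both in one call is an error.
    """
    assays = list(assays)
    kinds = {type(a) for a in assays}
    if kinds <= {MarkerAssay}:
        with open(path, "w") as fh:
            fh.write("\t".join(MARKER_COLUMNS) + "\n")
            for a in assays:
                lo, hi = a.expected_size_range or ("", "")
                fh.write(
                    f"{a.name}\t{a.accession or ''}\t{a.motif or ''}\tforward\t"
                    f"{a.tag.name}\t{a.dye}\t{lo}\t{hi}\t{a.tagged_forward}\n"
                )
                fh.write(
                    f"{a.name}\t{a.accession or ''}\t{a.motif or ''}\treverse\t"
                    f"\t\t\t\t{a.tailed_reverse}\n"
                )
    elif kinds <= {SnpAssay}:
        with open(path, "w") as fh:
            fh.write("\t".join(SNP_COLUMNS) + "\n")
            for a in assays:
                snp = "/".join(a.snp_alleles)
                fh.write(
                    f"{a.name}\t{a.accession or ''}\t{snp}\tLSO\t\t\t\t{a.lso}\n"
                )
                for rec in a.asos:
                    fh.write(
                        f"{a.name}\t{a.accession or ''}\t{snp}\tASO\t{rec.allele}\t"
                        f"{rec.tag.name}\t{rec.dye}\t{rec.tagged}\n"
                    )
    else:
        raise ValueError("a sheet holds either SSR/indel assays or SNP assays")


def assays_to_json(assays: Iterable[MarkerAssay | SnpAssay]) -> str:
    import dataclasses
    import json

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))

    return json.dumps([a for a in assays], default=encode, indent=2)
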