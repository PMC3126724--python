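"""Loaders for the published six-tag set and demonstration assay sheets.

The shipped sheets mirror the original report's tables: the six tags with
their Tm values, four tagged citrus SSR assays, and two ASO/LSO SNP assays.
The SSR size windows in the sheet are illustrative values for panel and
simulation demos (the source tables print no size windows).
"""

from __future__ import annotations

from importlib import resources

from .assay import MarkerAssay, SnpAssay
from .tagset import SplitTag, read_tag_tsv
from .thermo import CALIBRATED_CONDITIONS, ThermoConditions

__all__ = [
    "PUBLISHED_TAG_TABLE",
    "published_tags",
    "published_ssr_assays",
    "published_snp_assays",
    "data_path",
]

#: (name, sequence, reported Tm in degC) for the six shipped tags.
PUBLISHED_TAG_TABLE: tuple[tuple[str, str, float], ...] = (
    ("F9GAC", "CTAGTATCAGGACGAC", 51.3),
    ("F9GTC", "CTAGTATGAGGACGTC", 51.3),
    ("F9TAC", "CTAGTATCAGGACTAC", 47.2),
    ("F9GCC", "CTAGTATTAGGACGCC", 51.7),
    ("F9CCG", "CTAGTATTAGGACCCG", 50.8),
    ("F9AGG", "CTAGTATTAGGACAGG", 47.5),
)


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("bstag.data") / name


def published_tags(
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
) -> dict[str, SplitTag]:
    """The six shipped tags, parsed and Tm-annotated, keyed by name."""
    tags = read_tag_tsv(data_path("table1_tags.tsv"), conditions=conditions)
    return {t.name: t for t in tags}


def published_ssr_assays(
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
) -> list[MarkerAssay]:
    """The four demonstration SSR assays (tagged forward + tailed reverse)."""
    from .io import read_marker_table

    ssr, _ = read_marker_table(
        data_path("table2_ssr.tsv"), published_tags(conditions), conditions
    )
    return ssr


def published_snp_assays(
    conditions: ThermoConditions = CALIBRATED_CONDITIONS,
) -> list[SnpAssay]:
    """The two demonstration ASO/LSO SNP assays."""
    from .io import read_marker_table

    _, snp = read_marker_table(
        data_path("table3_snp.tsv"), published_tags(conditions), conditions
    )
    return snp
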