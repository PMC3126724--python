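"""YAML configuration: thermodynamic conditions and screening/pair policies.

Recognized keys (all optional; defaults are the shipped calibrated values):

``monovalent_salt``, ``divalent_salt``, ``oligo_conc``, ``dntp_conc``
    Buffer concentrations in mol/L.
``seed_len``, ``mismatch_cap``
    Annealing/screening gate: exact 3'-seed length and mismatch cap.
``weights``
    Explicit 3'-proximity weight vector (5'->3'), overriding the default
    3/2/1 scheme.
``tm_window``
    [low, high] tag Tm window in degC.
``min_weighted_score``
    Pair-discrimination score floor.
``min_gap``
    Required core-minus-tag Tm gap in degC.
``size_tolerance``, ``max_assays``
    Panel guard band (bp) and tube capacity.
``max_product``
    Longest predicted amplicon (bp) in the specificity screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .panel import PanelPolicy
from .specificity import ScanParams
from .tagset import PairPolicy, TagConstraints
from .thermo import CALIBRATED_CONDITIONS, AnnealPolicy, ThermoConditions

__all__ = ["ToolConfig", "load_config"]


@dataclass(frozen=True)
class ToolConfig:
    conditions: ThermoConditions = CALIBRATED_CONDITIONS
    anneal: AnnealPolicy = field(default_factory=AnnealPolicy)
    scan: ScanParams = field(default_factory=ScanParams)
    constraints: TagConstraints = field(default_factory=TagConstraints)
    pair_policy: PairPolicy = field(default_factory=PairPolicy)
    panel_policy: PanelPolicy = field(default_factory=PanelPolicy)
    min_gap: float = 6.0
    weights: tuple[float, ...] | None = None


def load_config(path: str | Path | None = None) -> ToolConfig:
    """Build a :class:`ToolConfig` from a YAML file (or defaults if None)."""
    if path is None:
        return ToolConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}

    cond = ThermoConditions(
        monovalent_salt=raw.get("monovalent_salt", CALIBRATED_CONDITIONS.monovalent_salt),
        divalent_salt=raw.get("divalent_salt", CALIBRATED_CONDITIONS.divalent_salt),
        oligo_conc=raw.get("oligo_conc", CALIBRATED_CONDITIONS.oligo_conc),
        dntp_conc=raw.get("dntp_conc", CALIBRATED_CONDITIONS.dntp_conc),
    )
    anneal = AnnealPolicy(
        seed_len=raw.get("seed_len", 8),
        mismatch_cap=raw.get("mismatch_cap", 2),
    )
    scan = ScanParams(
        seed_len=raw.get("seed_len", 8),
        max_mismatches=raw.get("mismatch_cap", 2),
        max_product=raw.get("max_product", 2000),
    )
    constraints = TagConstraints(
        tm_window=tuple(raw.get("tm_window", (46.0, 53.0))),
    )
    pair_policy = PairPolicy(
        min_weighted_score=raw.get("min_weighted_score", 3.0),
    )
    panel_policy = PanelPolicy(
        size_tolerance=raw.get("size_tolerance", 10.0),
        max_assays=raw.get("max_assays", 6),
    )
    weights = tuple(raw["weights"]) if "weights" in raw else None
    return ToolConfig(
        conditions=cond,
        anneal=anneal,
        scan=scan,
        constraints=constraints,
        pair_policy=pair_policy,
        panel_policy=panel_policy,
        min_gap=raw.get("min_gap", 6.0),
        weights=weights,
    )
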