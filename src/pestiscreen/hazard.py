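"""Ecotoxicity and performance screening rules.

Three cutoff rules plus a reference-percentile score:

* **Rule of 2** — the safer chemical space: log D_o/w < 1.7 (low
  bioavailability) AND ΔE > 6 eV (low covalent reactivity), both strict.
* **Briggs Rule of 3** — log D_o/w < 3, the efficacy/safety balance used
  for pesticide active ingredients (strict).
* **E_LUMO percentile** — standing of a compound's LUMO energy within the
  distribution of no- to low-concern chemicals; since most toxicants are
  electrophiles, a higher E_LUMO (higher percentile) means increased
  safety. Values below the 1st percentile render as "<1st".
* **Performance bounds** — per-category inclusive log D_o/w and ΔE ranges
  for functional classes and modes of action; a compound outside its
  category's box is unlikely to retain function there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import Cutoffs, FrameworkConfig
from .errors import (
    CategoryLookupError,
    ConfigurationError,
    DescriptorError,
)
from .models import BoundsTable, Compound, HazardAssessment
from .photodeg import percentile_rank


@dataclass(frozen=True)
class RuleOf2:
    """Flags of the safer-chemical-space check."""

    log_d_ok: bool
    reactivity_ok: bool

    @property
    def in_safe_space(self) -> bool:
        return self.log_d_ok and self.reactivity_ok


def rule_of_2(
    log_d: float, delta_e_ev: float, cutoffs: Optional[Cutoffs] = None
) -> RuleOf2:
    """Safer-space flags: log D < 1.7 and ΔE > 6 eV, strict inequalities."""
    cutoffs = cutoffs or Cutoffs()
    if not (math.isfinite(log_d) and math.isfinite(delta_e_ev)):
        raise DescriptorError(
            f"rule_of_2 needs finite inputs, got log_d={log_d}, "
            f"delta_e={delta_e_ev}"
        )
    return RuleOf2(
        log_d_ok=log_d < cutoffs.log_d_safe,
        reactivity_ok=delta_e_ev > cutoffs.delta_e_safe_ev,
    )


def briggs_ok(log_d: float, cutoff: float = 3.0) -> bool:
    """Briggs Rule of 3: log D_o/w < 3, strict."""
    return log_d < cutoff


def elumo_percentile(e_lumo_ev: float, reference: Sequence[float]) -> float:
    """Percentile of E_LUMO within the no/low-concern reference set, 0–100.

    Monotone non-decreasing in ``e_lumo_ev`` for a fixed reference. Shares
    the counting-percentile convention of
    :func:`pestiscreen.photodeg.percentile_rank`.
    """
    if reference is None or len(reference) == 0:
        raise ConfigurationError(
            "empty E_LUMO reference; set elumo_reference in the config"
        )
    return percentile_rank(reference, e_lumo_ev)


def format_percentile(p: float) -> str:
    """Display form of a percentile: '<1st', '15th', '42nd', '90th', ..."""
    if p < 1.0:
        return "<1st"
    n = int(p)
    if 10 <= n % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")
    return f"{n}{suffix}"


@dataclass(frozen=True)
class BoundsVerdict:
    """Outcome of a performance-bounds lookup for one category."""

    category: str
    within: bool
    log_d_ok: bool
    delta_e_ok: bool

    @property
    def failed_axes(self) -> tuple[str, ...]:
        axes = []
        if not self.log_d_ok:
            axes.append("log_d")
        if not self.delta_e_ok:
            axes.append("delta_e")
        return tuple(axes)


def bounds_check(
    log_d: float,
    delta_e_ev: float,
    category: str,
    table: Optional[BoundsTable] = None,
) -> BoundsVerdict:
    """Check a compound against its category's performance box.

    Ranges are inclusive on both ends. Unknown categories raise
    :class:`CategoryLookupError` listing the valid ones.
    """
    table = table if table is not None else FrameworkConfig().bounds_table
    entry = table.get(category)
    if entry is None:
        raise CategoryLookupError(
            f"unknown category {category!r}; valid: {table.categories()}"
        )
    ld_ok = entry.log_d_min <= log_d <= entry.log_d_max
    de_ok = entry.delta_e_min <= delta_e_ev <= entry.delta_e_max
    return BoundsVerdict(
        category=category, within=ld_ok and de_ok,
        log_d_ok=ld_ok, delta_e_ok=de_ok,
    )


def assess_hazard(
    compound: Compound, config: Optional[FrameworkConfig] = None
) -> HazardAssessment:
    """Full hazard screen for one compound."""
    config = config or FrameworkConfig()
    if compound.log_d is None:
        raise DescriptorError(f"compound {compound.id!r}: log_d required")
    flags = rule_of_2(compound.log_d, compound.delta_e, config.cutoffs)
    return HazardAssessment(
        compound_id=compound.id,
        log_d_ok=flags.log_d_ok,
        reactivity_ok=flags.reactivity_ok,
        in_safe_space=flags.in_safe_space,
        briggs_ok=briggs_ok(compound.log_d, config.cutoffs.briggs_log_d),
        elumo_percentile=elumo_percentile(
            compound.e_lumo, config.elumo_reference
        ) if compound.e_lumo is not None else float("nan"),
    )
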