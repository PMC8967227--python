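"""Screening orchestration: tiers → per-compound rows → reports.

``screen`` runs the full structure-to-process pipeline over a compound
table and a sensitizer panel: pairwise electron-transfer predictions,
mixture averaging, composite percentile scoring, hazard rules, performance
bounds, and the three "semaphore" codings used in the heatmap reports:

* photodegradation: five bins (red → green) over the composite score, by
  quintile, a score exactly at a bin edge going to the higher bin;
* ecotoxicity: light green inside the safer chemical space, light red
  outside;
* E_LUMO: purple at or above the 50th percentile of the no/low-concern
  reference, pink from the 1st to below the 50th, black below the 1st.

``compare_redesign`` quantifies a parent → analog redesign as deltas in
log D, ΔE, composite score, and E_LUMO percentile, plus whether the analog
retains every performance box the parent satisfied. Comparisons are only
allowed between assessments produced under the same configuration (checked
by config hash).
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .config import FrameworkConfig
from .errors import (
    ComparabilityError,
    ConfigurationError,
    PestiscreenError,
    ValidationError,
)
from .hazard import assess_hazard, bounds_check
from .models import Compound, SensitizerPanel
from .photodeg import assess_pairs, composite_score, summarize_mixture

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bracket:
    """A half-open percentile interval [lo, hi); the topmost bracket
    (hi == 100) also contains 100 itself."""

    lo: float
    hi: float
    label: str

    def contains(self, score: float) -> bool:
        if self.lo <= score < self.hi:
            return True
        return score == self.hi == 100.0


#: Default composite-score brackets used in reports.
DEFAULT_BRACKETS = (
    Bracket(0.0, 50.0, "<50th"),
    Bracket(50.0, 75.0, "50-74th"),
    Bracket(75.0, 90.0, "75-89th"),
    Bracket(90.0, 100.0, ">=90th"),
)


class PhotodegSemaphore(str, enum.Enum):
    red = "red"
    orange = "orange"
    yellow = "yellow"
    light_green = "light_green"
    green = "green"


class EcotoxSemaphore(str, enum.Enum):
    light_green = "light_green"
    light_red = "light_red"


class ElumoSemaphore(str, enum.Enum):
    purple = "purple"
    pink = "pink"
    black = "black"


_PHOTODEG_ORDER = [
    PhotodegSemaphore.red,
    PhotodegSemaphore.orange,
    PhotodegSemaphore.yellow,
    PhotodegSemaphore.light_green,
    PhotodegSemaphore.green,
]


def photodeg_semaphore(score: float) -> PhotodegSemaphore:
    """Quintile bin of the composite score; edge scores go to the higher
    bin (score 100 stays green)."""
    idx = min(int(score // 20.0), 4)
    return _PHOTODEG_ORDER[idx]


def ecotox_semaphore(in_safe_space: bool) -> EcotoxSemaphore:
    return (EcotoxSemaphore.light_green if in_safe_space
            else EcotoxSemaphore.light_red)


def elumo_semaphore(percentile: float) -> ElumoSemaphore:
    if percentile < 1.0:
        return ElumoSemaphore.black
    if percentile < 50.0:
        return ElumoSemaphore.pink
    return ElumoSemaphore.purple


@dataclass
class ScreenRow:
    """All tier outputs for one compound, plus its semaphores."""

    compound_id: str
    log_d: float
    delta_e_ev: float
    e_lumo_ev: float
    mean_dg_et0: float
    mean_log_k: float
    n_pairs: int
    pct_log_k: float
    pct_dg: float
    score: float
    bracket: str
    log_d_ok: bool
    reactivity_ok: bool
    in_safe_space: bool
    briggs_ok: bool
    elumo_percentile: float
    photodeg_semaphore: PhotodegSemaphore
    ecotox_semaphore: EcotoxSemaphore
    elumo_semaphore: ElumoSemaphore
    #: category → within-bounds verdict, for every category the compound
    #: declares (functional class and/or MOA)
    bounds: dict[str, bool] = field(default_factory=dict)
    config_hash: str = ""


@dataclass
class ScreenReport:
    """Result of a full screening run."""

    rows: list[ScreenRow]
    config_hash: str
    n_compounds: int
    n_pairs: int
    elumo_reference_synthetic: bool

    def row(self, compound_id: str) -> ScreenRow:
        for r in self.rows:
            if r.compound_id == compound_id:
                return r
        raise ValidationError(f"no screened compound {compound_id!r}")

    # -- serialization -----------------------------------------------------

    def to_records(self) -> list[dict]:
        recs = []
        for r in self.rows:
            d = {
                "compound_id": r.compound_id,
                "log_d": r.log_d,
                "delta_e_ev": r.delta_e_ev,
                "e_lumo_ev": r.e_lumo_ev,
                "mean_dg_et0": r.mean_dg_et0,
                "mean_log_k": r.mean_log_k,
                "n_pairs": r.n_pairs,
                "pct_log_k": r.pct_log_k,
                "pct_dg": r.pct_dg,
                "score": r.score,
                "bracket": r.bracket,
                "log_d_ok": r.log_d_ok,
                "reactivity_ok": r.reactivity_ok,
                "in_safe_space": r.in_safe_space,
                "briggs_ok": r.briggs_ok,
                "elumo_percentile": r.elumo_percentile,
                "photodeg_semaphore": r.photodeg_semaphore.value,
                "ecotox_semaphore": r.ecotox_semaphore.value,
                "elumo_semaphore": r.elumo_semaphore.value,
                "bounds": dict(r.bounds),
                "config_hash": r.config_hash,
            }
            recs.append(d)
        return recs

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "n_compounds": self.n_compounds,
                "n_pairs": self.n_pairs,
                "elumo_reference_synthetic": self.elumo_reference_synthetic,
                "rows": self.to_records(),
            },
            indent=2,
            sort_keys=True,
        ) + "\n"

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ScreenReport":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        rows = []
        for d in data["rows"]:
            rows.append(ScreenRow(
                compound_id=d["compound_id"],
                log_d=d["log_d"],
                delta_e_ev=d["delta_e_ev"],
                e_lumo_ev=d["e_lumo_ev"],
                mean_dg_et0=d["mean_dg_et0"],
                mean_log_k=d["mean_log_k"],
                n_pairs=d["n_pairs"],
                pct_log_k=d["pct_log_k"],
                pct_dg=d["pct_dg"],
                score=d["score"],
                bracket=d["bracket"],
                log_d_ok=d["log_d_ok"],
                reactivity_ok=d["reactivity_ok"],
                in_safe_space=d["in_safe_space"],
                briggs_ok=d["briggs_ok"],
                elumo_percentile=d["elumo_percentile"],
                photodeg_semaphore=PhotodegSemaphore(d["photodeg_semaphore"]),
                ecotox_semaphore=EcotoxSemaphore(d["ecotox_semaphore"]),
                elumo_semaphore=ElumoSemaphore(d["elumo_semaphore"]),
                bounds=dict(d["bounds"]),
                config_hash=d["config_hash"],
            ))
        return cls(
            rows=rows,
            config_hash=data["config_hash"],
            n_compounds=data["n_compounds"],
            n_pairs=data["n_pairs"],
            elumo_reference_synthetic=data["elumo_reference_synthetic"],
        )

    def write(self, out_dir: Union[str, Path], stem: str = "screen") -> list[Path]:
        """Write the report in CSV and JSON dialects; returns the paths."""
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        json_path = out / f"{stem}.json"
        json_path.write_text(self.to_json(), encoding="utf-8")
        recs = self.to_records()
        for r in recs:
            r["bounds"] = ";".join(
                f"{k}={'within' if v else 'outside'}"
                for k, v in sorted(r["bounds"].items())
            )
        csv_path = out / f"{stem}.csv"
        pd.DataFrame(recs).to_csv(csv_path, index=False)
        return [csv_path, json_path]


def screen(
    compounds: Sequence[Compound],
    panel: SensitizerPanel,
    config: Optional[FrameworkConfig] = None,
    brackets: Sequence[Bracket] = DEFAULT_BRACKETS,
) -> ScreenReport:
    """Run the full tiered screen over a compound population.

    Deterministic: equal inputs and config give byte-identical reports.
    Needs at least two compounds (composite percentiles require a
    population).
    """
    config = config or FrameworkConfig()
    if len(compounds) < 2:
        raise ValidationError("screen needs >= 2 compounds")
    chash = config.config_hash()

    pairs = assess_pairs(compounds, panel, config)
    summaries = summarize_mixture(pairs)
    scores = {s.compound_id: s for s in composite_score(summaries)}
    summary_by_id = {s.compound_id: s for s in summaries}

    rows = []
    for c in compounds:
        try:
            summ = summary_by_id[c.id]
            sc = scores[c.id]
            haz = assess_hazard(c, config)
            bounds: dict[str, bool] = {}
            if c.functional_class is not None:
                v = bounds_check(c.log_d, c.delta_e,
                                 c.functional_class.value, config.bounds_table)
                bounds[c.functional_class.value] = v.within
            if c.moa is not None:
                v = bounds_check(c.log_d, c.delta_e, c.moa.value,
                                 config.bounds_table)
                bounds[c.moa.value] = v.within
            bracket_label = ""
            for b in brackets:
                if b.contains(sc.score):
                    bracket_label = b.label
                    break
            rows.append(ScreenRow(
                compound_id=c.id,
                log_d=c.log_d,
                delta_e_ev=c.delta_e,
                e_lumo_ev=c.e_lumo,
                mean_dg_et0=summ.mean_dg_et0,
                mean_log_k=summ.mean_log_k,
                n_pairs=summ.n_pairs,
                pct_log_k=sc.pct_log_k,
                pct_dg=sc.pct_dg,
                score=sc.score,
                bracket=bracket_label,
                log_d_ok=haz.log_d_ok,
                reactivity_ok=haz.reactivity_ok,
                in_safe_space=haz.in_safe_space,
                briggs_ok=haz.briggs_ok,
                elumo_percentile=haz.elumo_percentile,
                photodeg_semaphore=photodeg_semaphore(sc.score),
                ecotox_semaphore=ecotox_semaphore(haz.in_safe_space),
                elumo_semaphore=elumo_semaphore(haz.elumo_percentile),
                bounds=bounds,
                config_hash=chash,
            ))
        except PestiscreenError as exc:
            raise type(exc)(f"compound {c.id!r}: {exc}") from exc
    return ScreenReport(
        rows=rows,
        config_hash=chash,
        n_compounds=len(compounds),
        n_pairs=len(pairs),
        elumo_reference_synthetic=config.elumo_reference_synthetic,
    )


def bracket_counts(
    rows: Sequence[ScreenRow],
    brackets: Sequence[Bracket] = DEFAULT_BRACKETS,
    predicate: Optional[Callable[[ScreenRow], bool]] = None,
) -> dict[str, int]:
    """Count filtered rows per composite-score bracket.

    Brackets must be pairwise disjoint. Rows matching no bracket are
    tallied under ``"unbracketed"`` so the counts always sum to the number
    of rows passing the filter.
    """
    for i, a in enumerate(brackets):
        for b in brackets[i + 1:]:
            if a.lo < b.hi and b.lo < a.hi:
                raise ConfigurationError(
                    f"overlapping brackets: {a.label!r} and {b.label!r}"
                )
    counts = {b.label: 0 for b in brackets}
    counts["unbracketed"] = 0
    for r in rows:
        if predicate is not None and not predicate(r):
            continue
        for b in brackets:
            if b.contains(r.score):
                counts[b.label] += 1
                break
        else:
            counts["unbracketed"] += 1
    return counts


@dataclass
class RedesignDelta:
    """Analog-minus-parent deltas for a redesign comparison."""

    parent_id: str
    analog_id: str
    d_log_d: float
    d_delta_e_ev: float
    d_composite_score: float
    d_elumo_percentile: float
    #: for every category the parent satisfied: does the analog still?
    bounds_retained: dict[str, bool]


def compare_redesign(parent: ScreenRow, analog: ScreenRow) -> RedesignDelta:
    """Quantify a parent → analog redesign.

    Both rows must come from screens run under the same configuration and
    reference population (enforced via the embedded config hash).
    """
    if parent.config_hash != analog.config_hash:
        raise ComparabilityError(
            "parent and analog were assessed under different configs "
            f"({parent.config_hash} vs {analog.config_hash}); "
            "rescreen them together"
        )
    retained = {
        cat: analog.bounds.get(cat, False)
        for cat, ok in parent.bounds.items()
        if ok
    }
    return RedesignDelta(
        parent_id=parent.compound_id,
        analog_id=analog.compound_id,
        d_log_d=analog.log_d - parent.log_d,
        d_delta_e_ev=analog.delta_e_ev - parent.delta_e_ev,
        d_composite_score=analog.score - parent.score,
        d_elumo_percentile=analog.elumo_percentile - parent.elumo_percentile,
        bounds_retained=retained,
    )


@dataclass
class BracketDensity:
    """Centroid and half-SD ellipse of one bracket in (log D, ΔE) space."""

    label: str
    n: int
    mean_log_d: float
    mean_delta_e: float
    radius_log_d: float  # SD/2 along log D
    radius_delta_e: float  # SD/2 along ΔE


def density_summary(
    rows: Sequence[ScreenRow],
    brackets: Sequence[Bracket] = DEFAULT_BRACKETS,
) -> tuple[list[BracketDensity], list[tuple[float, float]]]:
    """Per-bracket (log D, ΔE) centroids with half-SD ellipse radii.

    Returns the per-bracket summaries (brackets with fewer than two rows
    are omitted with a warning) and the displacement vectors between
    adjacent reported bracket centroids.
    """
    out: list[BracketDensity] = []
    for b in brackets:
        members = [r for r in rows if b.contains(r.score)]
        if len(members) < 2:
            log.warning("bracket %s has %d rows; omitted from density "
                        "summary", b.label, len(members))
            continue
        ld = np.array([r.log_d for r in members])
        de = np.array([r.delta_e_ev for r in members])
        out.append(BracketDensity(
            label=b.label,
            n=len(members),
            mean_log_d=float(ld.mean()),
            mean_delta_e=float(de.mean()),
            radius_log_d=float(ld.std(ddof=1) / 2.0),
            radius_delta_e=float(de.std(ddof=1) / 2.0),
        ))
    vectors = [
        (out[i + 1].mean_log_d - out[i].mean_log_d,
         out[i + 1].mean_delta_e - out[i].mean_delta_e)
        for i in range(len(out) - 1)
    ]
    return out, vectors


_SEMAPHORE_COLORS = {
    PhotodegSemaphore.red: "#d62728",
    PhotodegSemaphore.orange: "#ff7f0e",
    PhotodegSemaphore.yellow: "#ffdd44",
    PhotodegSemaphore.light_green: "#98df8a",
    PhotodegSemaphore.green: "#2ca02c",
    EcotoxSemaphore.light_green: "#98df8a",
    EcotoxSemaphore.light_red: "#ff9896",
    ElumoSemaphore.purple: "#9467bd",
    ElumoSemaphore.pink: "#f7b6d2",
    ElumoSemaphore.black: "#000000",
}


def semaphore_heatmap(rows: Sequence[ScreenRow], path: Union[str, Path]) -> Path:
    """Render the three-column semaphore heatmap to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(
        figsize=(4.0, max(2.0, 0.28 * len(rows) + 1.0))
    )
    columns = ["photodegradation", "ecotoxicity", "E_LUMO"]
    for i, r in enumerate(rows):
        cells = [r.photodeg_semaphore, r.ecotox_semaphore, r.elumo_semaphore]
        for j, cell in enumerate(cells):
            ax.add_patch(Rectangle(
                (j, len(rows) - 1 - i), 1, 1,
                facecolor=_SEMAPHORE_COLORS[cell], edgecolor="white",
            ))
    ax.set_xlim(0, 3)
    ax.set_ylim(0, len(rows))
    ax.set_xticks([0.5, 1.5, 2.5])
    ax.set_xticklabels(columns, fontsize=8)
    ax.set_yticks([len(rows) - 1 - i + 0.5 for i in range(len(rows))])
    ax.set_yticklabels([r.compound_id for r in rows], fontsize=6)
    ax.tick_params(length=0)
    for spine in ax.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
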