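"""Readers and writers for compound tables and sensitizer panels.

CSV dialect: UTF-8, header row required, decimal point only. Column names
are configurable through ``column_map`` (canonical name → actual name in the
file), which absorbs arbitrary supplementary-table layouts.

Ingestion is strict by default — any invalid row aborts the read — for
reproducibility; ``strict=False`` skips and logs bad rows instead.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import ConfigurationError, RowParseError, ValidationError
from .models import Compound, FunctionalClass, Moa, Sensitizer, SensitizerPanel

log = logging.getLogger(__name__)

#: Canonical compound-table columns. id plus the three descriptors are
#: required; the rest are optional.
COMPOUND_COLUMNS = (
    "id", "name", "smiles", "e_homo_ev", "e_lumo_ev", "log_d",
    "functional_class", "moa",
)
REQUIRED_COMPOUND_COLUMNS = ("id", "e_homo_ev", "e_lumo_ev", "log_d")

SENSITIZER_COLUMNS = ("id", "cdom_class", "e_somo_ev")


def _parse_float(raw: object, column: str, row: int) -> float:
    text = "" if raw is None else str(raw).strip()
    if text == "" or text.lower() == "nan":
        raise RowParseError(row, f"missing value in column {column!r}")
    try:
        value = float(text)
    except ValueError as exc:
        raise RowParseError(
            row, f"non-numeric value {text!r} in column {column!r}"
        ) from exc
    if not math.isfinite(value):
        raise RowParseError(row, f"non-finite value in column {column!r}")
    return value


def _opt_str(raw: object) -> Optional[str]:
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return None
    return text


def read_compounds(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    strict: bool = True,
) -> list[Compound]:
    """Read a compound descriptor table from CSV.

    ``column_map`` maps canonical column names (``id``, ``e_homo_ev``,
    ``e_lumo_ev``, ``log_d``, and optionally ``name``, ``smiles``,
    ``functional_class``, ``moa``) to the names used in the file.

    Raises :class:`ConfigurationError` when a required mapped column is
    absent, :class:`RowParseError` (strict) on the first invalid row, and
    :class:`ValidationError` on duplicate ids.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"compound file not found: {p}")
    frame = pd.read_csv(p, dtype=str, keep_default_na=False)
    cmap = {c: c for c in COMPOUND_COLUMNS}
    if column_map:
        cmap.update(column_map)

    for canonical in REQUIRED_COMPOUND_COLUMNS:
        if cmap[canonical] not in frame.columns:
            raise ConfigurationError(
                f"required column {cmap[canonical]!r} (for {canonical!r}) "
                f"missing from {p.name}; present: {list(frame.columns)}"
            )

    compounds: list[Compound] = []
    skipped: list[int] = []
    for row_idx, row in enumerate(frame.to_dict(orient="records")):
        try:
            cid = _opt_str(row.get(cmap["id"]))
            if cid is None:
                raise RowParseError(row_idx, "empty compound id")
            fc_raw = _opt_str(row.get(cmap["functional_class"], None))
            moa_raw = _opt_str(row.get(cmap["moa"], None))
            try:
                fc = FunctionalClass(fc_raw) if fc_raw else None
            except ValueError as exc:
                raise RowParseError(
                    row_idx, f"unknown functional_class {fc_raw!r}"
                ) from exc
            try:
                moa = Moa(moa_raw) if moa_raw else None
            except ValueError as exc:
                raise RowParseError(row_idx, f"unknown moa {moa_raw!r}") from exc
            try:
                compound = Compound(
                    id=cid,
                    name=_opt_str(row.get(cmap["name"], None)),
                    smiles=_opt_str(row.get(cmap["smiles"], None)),
                    e_homo=_parse_float(row.get(cmap["e_homo_ev"]), "e_homo_ev", row_idx),
                    e_lumo=_parse_float(row.get(cmap["e_lumo_ev"]), "e_lumo_ev", row_idx),
                    log_d=_parse_float(row.get(cmap["log_d"]), "log_d", row_idx),
                    functional_class=fc,
                    moa=moa,
                )
            except ValidationError as exc:
                raise RowParseError(row_idx, str(exc)) from exc
            compounds.append(compound)
        except RowParseError:
            if strict:
                raise
            skipped.append(row_idx)
    if skipped:
        log.warning(
            "skipped %d invalid rows in %s: %s", len(skipped), p.name, skipped
        )

    ids = [c.id for c in compounds]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate compound ids in {p.name}: {dupes}")
    return compounds


def write_compounds(compounds: Iterable[Compound], path: Union[str, Path]) -> None:
    """Write compounds to the canonical CSV layout (bit-exact round trip)."""
    rows = []
    for c in compounds:
        rows.append({
            "id": c.id,
            "name": c.name if c.name is not None else "",
            "smiles": c.smiles if c.smiles is not None else "",
            "e_homo_ev": repr(c.e_homo) if c.e_homo is not None else "",
            "e_lumo_ev": repr(c.e_lumo) if c.e_lumo is not None else "",
            "log_d": repr(c.log_d) if c.log_d is not None else "",
            "functional_class": c.functional_class.value if c.functional_class else "",
            "moa": c.moa.value if c.moa else "",
        })
    pd.DataFrame(rows, columns=list(COMPOUND_COLUMNS)).to_csv(path, index=False)


def read_sensitizers(path: Union[str, Path]) -> SensitizerPanel:
    """Read a sensitizer panel CSV (columns: id, cdom_class, e_somo_ev)."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"sensitizer file not found: {p}")
    frame = pd.read_csv(p, dtype=str, keep_default_na=False)
    for col in ("id", "e_somo_ev"):
        if col not in frame.columns:
            raise ConfigurationError(
                f"required column {col!r} missing from {p.name}"
            )
    sensitizers = []
    for row_idx, row in enumerate(frame.to_dict(orient="records")):
        sid = _opt_str(row.get("id"))
        if sid is None:
            raise RowParseError(row_idx, "empty sensitizer id")
        sensitizers.append(Sensitizer(
            id=sid,
            cdom_class=_opt_str(row.get("cdom_class")) or "unknown",
            e_somo=_parse_float(row.get("e_somo_ev"), "e_somo_ev", row_idx),
        ))
    panel = SensitizerPanel(sensitizers)
    log.info("read %d sensitizers from %s", len(panel), p.name)
    return panel


def write_sensitizers(panel: SensitizerPanel, path: Union[str, Path]) -> None:
    rows = [
        {"id": s.id, "cdom_class": s.cdom_class, "e_somo_ev": repr(s.e_somo)}
        for s in panel
    ]
    pd.DataFrame(rows, columns=list(SENSITIZER_COLUMNS)).to_csv(path, index=False)


def write_report(
    records: Sequence[Mapping[str, object]],
    base_path: Union[str, Path],
    columns: Optional[Sequence[str]] = None,
) -> tuple[Path, Path]:
    """Write a report in both CSV and JSON dialects.

    ``base_path`` is the stem; ``<stem>.csv`` and ``<stem>.json`` are
    produced. Returns the two paths.
    """
    base = Path(base_path)
    frame = pd.DataFrame(list(records), columns=list(columns) if columns else None)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    frame.to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(list(map(dict, records)), indent=2, sort_keys=True,
                   default=str) + "\n",
        encoding="utf-8",
    )
    return csv_path, json_path
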