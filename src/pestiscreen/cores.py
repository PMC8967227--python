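"""SMARTS-based detection of PPRI-oxidizable cores.

Five core chemotypes are recognized — phenols, anilines, aryl ethers,
sulfides, and thiols — the motifs most readily oxidized by photochemically
produced reactive intermediates in sunlit waters. A molecule may carry
several cores at once; dataset partitioning keys compounds by their exact
core combination.

The packaged SMARTS are deliberately minimal patterns that reproduce the
worked exemplar molecules; screening campaigns with a vetted pattern table
should load it with :meth:`CorePatternSet.from_file`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from rdkit import Chem
from rdkit import RDLogger

from .errors import ConfigurationError, StructureError, ValidationError
from .models import Compound, CoreClass

log = logging.getLogger(__name__)

# RDKit is chatty on stderr about bad SMILES; we raise our own errors.
RDLogger.DisableLog("rdApp.error")

#: Minimal default patterns, one per core class.
#: - phenol: hydroxyl oxygen on an aromatic carbon
#: - aniline: neutral amine nitrogen on an aromatic carbon, excluding
#:   N-oxides/nitro and amide/sulfonamide nitrogens
#: - aryl ether: H-free divalent oxygen with at least one aromatic neighbor
#: - sulfide: H-free divalent sulfur between two carbons
#: - thiol: S-H sulfur on carbon
DEFAULT_SMARTS: dict[CoreClass, list[str]] = {
    CoreClass.phenol: ["[OX2H1][c]"],
    CoreClass.aniline: ["[NX3;!$([N]=O);!$([N][C,S]=[O,S])][c]"],
    CoreClass.aryl_ether: ["[OX2;H0]([c])[#6]"],
    CoreClass.sulfide: ["[SX2;H0]([#6])[#6]"],
    CoreClass.thiol: ["[SX2H1][#6]"],
}


@dataclass
class CorePatternSet:
    """A mapping core class → SMARTS patterns (non-exclusive)."""

    patterns: dict[CoreClass, list[str]]
    _compiled: dict[CoreClass, list[Chem.Mol]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for cls in CoreClass:
            smarts_list = self.patterns.get(cls)
            if not smarts_list:
                raise ConfigurationError(
                    f"pattern set has no SMARTS for class {cls.value!r}"
                )
            compiled = []
            for smarts in smarts_list:
                mol = Chem.MolFromSmarts(smarts)
                if mol is None:
                    raise ConfigurationError(
                        f"invalid SMARTS for {cls.value!r}: {smarts!r}"
                    )
                compiled.append(mol)
            self._compiled[cls] = compiled

    @classmethod
    def default(cls) -> "CorePatternSet":
        return cls({k: list(v) for k, v in DEFAULT_SMARTS.items()})

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "CorePatternSet":
        """Load a plain-text two-column (class, SMARTS) pattern file.

        Blank lines and ``#`` comments are ignored; a class may appear on
        several lines, accumulating patterns.
        """
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"pattern file not found: {p}")
        patterns: dict[CoreClass, list[str]] = {c: [] for c in CoreClass}
        for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{p.name}:{lineno}: expected 'class SMARTS', got {line!r}"
                )
            try:
                core = CoreClass(parts[0])
            except ValueError as exc:
                raise ConfigurationError(
                    f"{p.name}:{lineno}: unknown core class {parts[0]!r} "
                    f"(valid: {[c.value for c in CoreClass]})"
                ) from exc
            patterns[core].append(parts[1])
        return cls(patterns)

    def compiled(self, core: CoreClass) -> list[Chem.Mol]:
        return self._compiled[core]


def _mol_from_smiles(smiles: Optional[str]) -> Chem.Mol:
    if not smiles:
        raise StructureError(str(smiles), "missing SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    """RDKit canonical SMILES (default aromaticity perception)."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def detect_cores(
    smiles: str, patterns: Optional[CorePatternSet] = None
) -> frozenset[CoreClass]:
    """Return the (possibly empty) set of oxidizable cores in a molecule.

    Detection is a property of the molecular graph, not of the particular
    SMILES spelling: any SMILES of the same molecule yields the same set.
    """
    patterns = patterns or CorePatternSet.default()
    mol = _mol_from_smiles(smiles)
    found = set()
    for core in CoreClass:
        if any(mol.HasSubstructMatch(q) for q in patterns.compiled(core)):
            found.add(core)
    return frozenset(found)


def combination_key(cores: Iterable[CoreClass]) -> str:
    """Canonical key for a core combination: sorted names joined by '+'."""
    return "+".join(sorted(c.value for c in cores))


@dataclass
class PartitionResult:
    """Outcome of partitioning a dataset by exact core combination."""

    counts: dict[str, int]
    no_core_ids: list[str]

    @property
    def n_with_core(self) -> int:
        return sum(self.counts.values())


def partition_dataset(
    compounds: Sequence[Compound],
    patterns: Optional[CorePatternSet] = None,
    strict: bool = True,
) -> PartitionResult:
    """Count compounds by their exact core-class combination.

    Every compound is counted exactly once, under the '+'-joined sorted key
    of all classes it matches; compounds matching nothing are reported
    separately in ``no_core_ids``. In strict mode any unparseable SMILES
    aborts with the full list of offending ids.
    """
    patterns = patterns or CorePatternSet.default()
    counts: Counter[str] = Counter()
    no_core: list[str] = []
    bad_ids: list[str] = []
    for c in compounds:
        try:
            cores = detect_cores(c.smiles or "", patterns)
        except StructureError:
            bad_ids.append(c.id)
            continue
        if cores:
            counts[combination_key(cores)] += 1
        else:
            no_core.append(c.id)
    if bad_ids:
        if strict:
            raise StructureError(
                ",".join(bad_ids),
                f"unparseable SMILES for compounds: {bad_ids}",
            )
        log.warning("skipped %d compounds with bad SMILES: %s",
                    len(bad_ids), bad_ids)
    return PartitionResult(counts=dict(counts), no_core_ids=no_core)


def deduplicate(compounds: Sequence[Compound]) -> list[Compound]:
    """Collapse duplicates by canonical structure, keeping first occurrence.

    Compounds without SMILES are keyed by id instead. The removal log is
    emitted at INFO level.
    """
    seen: dict[str, str] = {}
    kept: list[Compound] = []
    removed: list[tuple[str, str]] = []
    for c in compounds:
        key = "smiles:" + canonical_smiles(c.smiles) if c.smiles else "id:" + c.id
        if key in seen:
            removed.append((c.id, seen[key]))
        else:
            seen[key] = c.id
            kept.append(c)
    for dup_id, kept_id in removed:
        log.info("removed duplicate %s (same structure as %s)", dup_id, kept_id)
    return kept


def annotate_cores(
    compounds: Sequence[Compound], patterns: Optional[CorePatternSet] = None
) -> list[Compound]:
    """Fill ``core_classes`` on each compound that has a SMILES."""
    patterns = patterns or CorePatternSet.default()
    for c in compounds:
        if c.smiles:
            c.core_classes = detect_cores(c.smiles, patterns)
    return list(compounds)
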