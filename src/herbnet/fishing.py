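"""Ligand-based target fishing.

A query compound is aligned against every ligand of a target-annotated
reference library; the per-target score is the best shape-Tanimoto over that
target's ligands, and a target is predicted when the best score reaches the
similarity threshold (default 0.8). Predicted targets are then intersected
with a disease protein set, and per-herb target sets can be summarised as a
multi-set Venn decomposition to expose how much of the target space the herbs
share.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import Molecule, read_sdf
from .errors import IntegrityError, ValidationError
from .shape import DEFAULT_P, shape_tanimoto
from .util import round_half_up

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.8


@dataclass
class LigandLibrary:
    """Reference ligands in binding poses, each annotated with one protein target."""

    entries: list[tuple[Molecule, str]]

    def __post_init__(self):
        for mol, target in self.entries:
            if len(mol) < 1:
                raise ValidationError(f"library ligand {mol.id!r} has no atoms")
            if not target:
                raise ValidationError(f"library ligand {mol.id!r} has empty target id")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def target_ids(self) -> list[str]:
        seen = dict.fromkeys(t for _, t in self.entries)
        return list(seen)

    @classmethod
    def from_files(cls, sdf_path: str | Path, annotation_path: str | Path) -> "LigandLibrary":
        """Load ligand poses (SDF) plus a ligand_id -> target_id annotation TSV."""
        mols = read_sdf(sdf_path)
        annot = pd.read_csv(annotation_path, sep="\t", dtype=str)
        if not {"ligand_id", "target_id"} <= set(annot.columns):
            raise IntegrityError(f"annotation {annotation_path} needs ligand_id and target_id")
        mapping = dict(zip(annot["ligand_id"].str.strip(), annot["target_id"].str.strip()))
        entries = []
        for mol in mols:
            if mol.id not in mapping:
                raise IntegrityError(f"ligand {mol.id!r} has no target annotation")
            entries.append((mol, mapping[mol.id]))
        return cls(entries)


@dataclass
class CompoundTargetMap:
    """Predicted compound -> target associations at the screening threshold."""

    associations: list[tuple[str, str, float]]  # (compound_id, target_id, best score)
    no_hits: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        pairs = [(c, t) for c, t, _ in self.associations]
        if len(set(pairs)) != len(pairs):
            raise IntegrityError("duplicate (compound, target) association")
        for c, t, s in self.associations:
            if s < self.threshold:
                raise IntegrityError(f"association ({c}, {t}) below threshold: {s}")

    @property
    def compound_degrees(self) -> dict[str, int]:
        """K: number of predicted targets per compound."""
        deg: dict[str, int] = {}
        for c, _, _ in self.associations:
            deg[c] = deg.get(c, 0) + 1
        return deg

    @property
    def target_degrees(self) -> dict[str, int]:
        """N: number of compounds hitting each target."""
        deg: dict[str, int] = {}
        for _, t, _ in self.associations:
            deg[t] = deg.get(t, 0) + 1
        return deg

    @property
    def compound_ids(self) -> set[str]:
        return {c for c, _, _ in self.associations}

    @property
    def predicted_targets(self) -> set[str]:
        return {t for _, t, _ in self.associations}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.associations, columns=["compound_id", "target_id", "score"])

    def write_tsv(self, path: str | Path) -> None:
        lines = ["compound_id\ttarget_id\tscore"]
        for c, t, s in self.associations:
            lines.append(f"{c}\t{t}\t{s:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DiseaseGeneSet:
    """A named disease protein set (upper-cased gene/protein symbols)."""

    proteins: frozenset[str]
    name: str = "disease"
    provenance: str = ""

    def __post_init__(self):
        if not self.proteins:
            raise ValidationError("disease gene set is empty")
        self.proteins = frozenset(p.strip().upper() for p in self.proteins)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "DiseaseGeneSet":
        """Read either a one-symbol-per-line list or a single-line GMT record."""
        path = Path(path)
        lines = [l.strip() for l in path.read_text().splitlines() if l.strip()]
        if len(lines) == 1 and "\t" in lines[0]:
            parts = lines[0].split("\t")
            return cls(frozenset(parts[2:]), name=name or parts[0], provenance=parts[1])
        return cls(frozenset(lines), name=name or path.stem)


@dataclass(frozen=True)
class VennCounts:
    """Region decomposition of 2-6 overlapping sets."""

    regions: Mapping[frozenset, int]  # exclusive region -> count
    union_size: int
    intersection_size: int
    set_sizes: Mapping[str, int]


# ---------------------------------------------------------------------------
# Operations

def screen_compound(
    query: Molecule,
    lib: LigandLibrary,
    threshold: float = DEFAULT_THRESHOLD,
    p: float = DEFAULT_P,
    weighted: bool = True,
) -> list[tuple[str, float]]:
    """Targets whose best-ligand shape-Tanimoto reaches the threshold.

    Sorted by descending score, ties broken by target id.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if len(lib) == 0:
        raise ValidationError("ligand library is empty")
    best: dict[str, float] = {}
    for ligand, target in lib.entries:
        score = shape_tanimoto(query, ligand, p=p, weighted=weighted).tanimoto
        if score > best.get(target, -1.0):
            best[target] = score
    hits = [(t, s) for t, s in best.items() if s >= threshold]
    return sorted(hits, key=lambda ts: (-ts[1], ts[0]))


def predict_target_map(
    compounds: Sequence[Molecule],
    lib: LigandLibrary,
    threshold: float = DEFAULT_THRESHOLD,
    p: float = DEFAULT_P,
    weighted: bool = True,
) -> CompoundTargetMap:
    """Screen every compound and collect the association map plus a no-hit list."""
    ids = [m.id for m in compounds]
    if len(set(ids)) != len(ids):
        raise ValidationError("compound ids are not unique")
    associations: list[tuple[str, str, float]] = []
    no_hits: list[str] = []
    for mol in compounds:
        hits = screen_compound(mol, lib, threshold=threshold, p=p, weighted=weighted)
        if hits:
            associations.extend((mol.id, t, s) for t, s in hits)
        else:
            no_hits.append(mol.id)
    return CompoundTargetMap(associations, no_hits, threshold=threshold)


def map_to_disease(
    ctmap: CompoundTargetMap, disease: DiseaseGeneSet
) -> tuple[CompoundTargetMap, float]:
    """Restrict associations to disease targets; report the disease fraction.

    The fraction is 100 * |distinct predicted targets in the disease set| /
    |distinct predicted targets|, rounded half-up to 2 decimals.
    """
    if not disease.proteins:
        raise ValidationError("disease set is empty")
    kept = [
        (c, t, s) for c, t, s in ctmap.associations
        if t.strip().upper() in disease.proteins
    ]
    predicted = ctmap.predicted_targets
    in_disease = {t for t in predicted if t.strip().upper() in disease.proteins}
    fraction = 100.0 * len(in_disease) / len(predicted) if predicted else 0.0
    restricted = CompoundTargetMap(kept, list(ctmap.no_hits), threshold=ctmap.threshold)
    return restricted, round_half_up(fraction, 2)


def herb_target_overlap(per_herb_targets: Mapping[str, Iterable[str]]) -> VennCounts:
    """Exclusive Venn-region counts for 2-6 herb target sets.

    Region counts are keyed by the frozenset of herbs sharing those targets and
    sum exactly to the union size.
    """
    sets = {h: set(ts) for h, ts in per_herb_targets.items()}
    k = len(sets)
    if not (2 <= k <= 6):
        raise ValidationError(f"herb overlap supports 2-6 sets, got {k}")
    union: set[str] = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for size in range(1, k + 1):
        for combo in combinations(sorted(sets), size):
            inside = set.intersection(*(sets[h] for h in combo))
            outside = set().union(*(sets[h] for h in sets if h not in combo)) if size < k else set()
            count = len(inside - outside)
            if count:
                regions[frozenset(combo)] = count
    intersection = set.intersection(*sets.values())
    return VennCounts(
        regions=regions,
        union_size=len(union),
        intersection_size=len(intersection),
        set_sizes={h: len(s) for h, s in sets.items()},
    )
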