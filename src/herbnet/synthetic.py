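"""Seeded generators for every input the pipeline consumes, with planted truth.

Real inputs for this kind of study (herbal ingredient structures, predicted
ADME descriptors, ligand-target reference libraries, disease protein lists,
annotation databases) are proprietary or service-generated; the generators
here emulate their statistical shape while recording exact ground truth, so
each pipeline stage has a planted oracle:

* reference ligands are seeded Gaussian atom clouds at bond-scale spacing;
* "active" screening compounds are rigidly moved, jittered copies of library
  ligands (their true targets are recorded), decoys are fresh clouds;
* descriptor tables plant rule violations at controlled per-rule rates with
  values just past each threshold;
* annotation databases plant blocks of high-Jaccard enriched terms over a
  disease-overlapping query pool.

Molecules are geometry-only (elements, coordinates, radii; no bonds), since
the downstream shape engine consumes nothing else. One global seed fans out
to fixed per-artifact child seeds so any single artifact can be regenerated
independently.

A second section provides deterministic fixtures that realize published
summary counts (set systems with prescribed per-set sizes/union/intersection,
bipartite graphs with a prescribed edge count); these are synthetic stand-ins
for supplementary tables that exist only as figures or PDFs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    Atom,
    DescriptorRecord,
    FormulaTable,
    Molecule,
    vdw_radius,
    write_descriptor_table,
    write_formula_table,
    write_sdf,
)
from .enrichment import AnnotationDB
from .errors import GenerationError, ValidationError
from .fishing import CompoundTargetMap, DiseaseGeneSet, LigandLibrary
from .shape import RigidTransform

HERB_CODES = ("SC", "RS", "SW", "MD", "NZ", "GQ")

# child-seed offsets: each artifact can be regenerated on its own
_SEED_LIBRARY = 1
_SEED_SCREEN = 2
_SEED_DESCRIPTORS = 3
_SEED_ANNOTATIONS = 4

_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_PROBS = (0.70, 0.10, 0.15, 0.05)
_CLOUD_SD = 1.8  # A; Gaussian cloud scale giving drug-like radii of gyration
_MIN_DIST = 1.2  # A; bond-scale nearest-neighbour floor


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator suite (all deterministic given ``seed``)."""

    seed: int = 42
    n_targets: int = 5
    ligands_per_target: int = 2
    n_actives: int = 20
    n_decoys: int = 20
    jitter_sd: float = 0.05  # A, per-coordinate noise on actives
    atoms_per_molecule: tuple[int, int] = (8, 16)
    solubility_rate: float = 0.15
    bbb_rate: float = 0.15
    cyp2d6_rate: float = 0.15
    absorption_rate: float = 0.15
    disease_fraction: float = 0.6  # fraction of the target universe in the disease set
    n_terms: int = 16  # enriched terms, split across module blocks
    n_null_terms: int = 4
    term_size: tuple[int, int] = (8, 12)
    n_herbs: int = 6
    module_blocks: int = 2

    def __post_init__(self):
        if self.n_targets < 0 or self.n_actives < 0 or self.n_decoys < 0:
            raise ValidationError("counts must be non-negative")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        for r in (self.solubility_rate, self.bbb_rate, self.cyp2d6_rate, self.absorption_rate,
                  self.disease_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"rates must be in [0, 1], got {r}")
        if not (1 <= self.n_herbs <= len(HERB_CODES)):
            raise ValidationError(f"n_herbs must be in [1, {len(HERB_CODES)}]")

    @property
    def herb_codes(self) -> tuple[str, ...]:
        return HERB_CODES[: self.n_herbs]


@dataclass
class GroundTruth:
    """What the generators planted; the exact oracle for downstream stages."""

    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    herb_assignment: dict[str, str] = field(default_factory=dict)
    decoy_ids: set[str] = field(default_factory=set)
    rule_violators: dict[str, set[str]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    module_blocks: list[list[str]] = field(default_factory=list)
    disease_set: set[str] = field(default_factory=set)
    query_pool: set[str] = field(default_factory=set)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        self.planted_edges |= other.planted_edges
        self.herb_assignment.update(other.herb_assignment)
        self.decoy_ids |= other.decoy_ids
        for code, ids in other.rule_violators.items():
            self.rule_violators.setdefault(code, set()).update(ids)
        self.enriched_terms |= other.enriched_terms
        self.module_blocks.extend(other.module_blocks)
        self.disease_set |= other.disease_set
        self.query_pool |= other.query_pool
        return self

    @property
    def violator_union(self) -> set[str]:
        return set().union(*self.rule_violators.values()) if self.rule_violators else set()

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_edges"] = sorted(map(list, self.planted_edges))
        for key in ("decoy_ids", "enriched_terms", "disease_set", "query_pool"):
            d[key] = sorted(d[key])
        d["rule_violators"] = {c: sorted(v) for c, v in self.rule_violators.items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# geometry helpers

def _random_cloud(rng: np.random.Generator, n_atoms: int, max_tries: int = 1000) -> np.ndarray:
    """Gaussian point cloud with a bond-scale nearest-neighbour floor (rejection)."""
    points: list[np.ndarray] = []
    while len(points) < n_atoms:
        for attempt in range(max_tries + 1):
            if attempt == max_tries:
                raise GenerationError(
                    f"could not place atom {len(points) + 1}/{n_atoms} after {max_tries} tries"
                )
            cand = rng.normal(scale=_CLOUD_SD, size=3)
            if all(np.linalg.norm(cand - p) >= _MIN_DIST for p in points):
                points.append(cand)
                break
    return np.array(points)


def _random_molecule(rng: np.random.Generator, mol_id: str, n_atoms: int) -> Molecule:
    coords = _random_cloud(rng, n_atoms)
    elements = rng.choice(_ELEMENTS, size=n_atoms, p=_ELEMENT_PROBS)
    atoms = [Atom(e, c, vdw_radius(e)) for e, c in zip(elements, coords)]
    return Molecule(mol_id, atoms)


def _random_rigid(rng: np.random.Generator) -> RigidTransform:
    q = rng.normal(size=4)
    t = rng.uniform(-10.0, 10.0, size=3)
    return RigidTransform(q, t)


# ---------------------------------------------------------------------------
# generators

def generate_ligand_library(spec: SyntheticSpec) -> tuple[LigandLibrary, GroundTruth]:
    """Target-annotated reference ligands: ``ligands_per_target`` clouds per target."""
    if spec.n_targets < 1:
        raise ValidationError("n_targets must be >= 1")
    rng = np.random.default_rng(spec.seed + _SEED_LIBRARY)
    lo, hi = spec.atoms_per_molecule
    entries = []
    for i in range(spec.n_targets):
        target = f"T{i + 1:02d}"
        for j in range(spec.ligands_per_target):
            n_atoms = int(rng.integers(lo, hi + 1))
            mol = _random_molecule(rng, f"{target}_L{j + 1}", n_atoms)
            entries.append((mol, target))
    return LigandLibrary(entries), GroundTruth()


def generate_screen_set(
    spec: SyntheticSpec, library: LigandLibrary
) -> tuple[list[Molecule], FormulaTable, GroundTruth]:
    """Screening compounds: jittered+rigidly-moved library copies plus decoy clouds.

    Actives cycle through the library templates; every compound is assigned
    round-robin to the spec's herbs. Planted compound-target edges are recorded.
    """
    rng = np.random.default_rng(spec.seed + _SEED_SCREEN)
    lo, hi = spec.atoms_per_molecule
    gt = GroundTruth()
    herbs = spec.herb_codes
    molecules: list[Molecule] = []
    members: dict[str, list[str]] = {h: [] for h in herbs}
    serial = 0
    for i in range(spec.n_actives):
        template, target = library.entries[i % len(library.entries)]
        herb = herbs[serial % len(herbs)]
        cid = f"{herb}{serial + 1:03d}"
        serial += 1
        coords = template.coords + rng.normal(scale=spec.jitter_sd, size=(len(template), 3))
        coords = _random_rigid(rng).apply(coords)
        molecules.append(template.transformed(coords, new_id=cid))
        members[herb].append(cid)
        gt.planted_edges.add((cid, target))
        gt.herb_assignment[cid] = herb
    for _ in range(spec.n_decoys):
        herb = herbs[serial % len(herbs)]
        cid = f"{herb}{serial + 1:03d}"
        serial += 1
        molecules.append(_random_molecule(rng, cid, int(rng.integers(lo, hi + 1))))
        members[herb].append(cid)
        gt.decoy_ids.add(cid)
        gt.herb_assignment[cid] = herb
    return molecules, FormulaTable(members), gt


def generate_descriptor_table(
    spec: SyntheticSpec, compound_ids: Sequence[str]
) -> tuple[list[DescriptorRecord], GroundTruth]:
    """ADME descriptors with per-rule violations planted at the spec'd rates.

    Violating values sit just past each threshold (e.g. solubility below -8);
    safe values sit comfortably inside bounds. Overlap between per-rule
    violator sets is allowed and recorded.
    """
    rng = np.random.default_rng(spec.seed + _SEED_DESCRIPTORS)
    gt = GroundTruth(rule_violators={"SOLUBILITY": set(), "BBB": set(),
                                     "CYP2D6": set(), "ABSORPTION": set()})
    records = []
    for cid in compound_ids:
        viol_sol = rng.random() < spec.solubility_rate
        viol_bbb = rng.random() < spec.bbb_rate
        viol_cyp = rng.random() < spec.cyp2d6_rate
        viol_abs = rng.random() < spec.absorption_rate
        sol = rng.uniform(-12.0, -8.2) if viol_sol else rng.uniform(-6.0, -1.0)
        bbb = 3 if viol_bbb else int(rng.integers(0, 3))
        absorption = 3 if viol_abs else int(rng.integers(0, 3))
        records.append(DescriptorRecord(cid, sol, bbb, viol_cyp, absorption))
        if viol_sol:
            gt.rule_violators["SOLUBILITY"].add(cid)
        if viol_bbb:
            gt.rule_violators["BBB"].add(cid)
        if viol_cyp:
            gt.rule_violators["CYP2D6"].add(cid)
        if viol_abs:
            gt.rule_violators["ABSORPTION"].add(cid)
    return records, gt


def generate_annotation_db(
    spec: SyntheticSpec, target_universe: Sequence[str]
) -> tuple[AnnotationDB, DiseaseGeneSet, GroundTruth]:
    """Annotation database with planted enriched term blocks plus a disease set.

    The disease set covers ``disease_fraction`` of the target universe (plus
    filler proteins, so disease membership is not trivially the universe).
    Enriched terms draw most members from a per-block slice of the disease
    pool, giving high within-block Jaccard and near-zero between-block
    Jaccard; null terms draw uniformly from background filler.
    """
    rng = np.random.default_rng(spec.seed + _SEED_ANNOTATIONS)
    universe = [t.upper() for t in target_universe]
    if not universe:
        raise ValidationError("target universe is empty")
    n_fill = max(150, 3 * len(universe))
    filler = [f"BG{i + 1:04d}" for i in range(n_fill)]
    background = frozenset(universe) | frozenset(filler)

    n_disease = max(1, int(round(spec.disease_fraction * len(universe))))
    disease_universe = list(rng.choice(universe, size=n_disease, replace=False))
    disease_extra = list(rng.choice(filler, size=min(20, n_fill), replace=False))
    disease = DiseaseGeneSet(frozenset(disease_universe) | frozenset(disease_extra),
                             name="synthetic-disease")

    # enriched blocks live on the in-universe disease pool, so the pipeline's
    # disease-mapped query (a subset of the universe) carries their signal
    pool = sorted(set(disease_universe))
    blocks = max(1, spec.module_blocks)
    per_block = max(2, spec.n_terms // blocks)
    lo, hi = spec.term_size
    gt = GroundTruth(disease_set=set(disease.proteins), query_pool=set(pool))
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    slice_size = max(1, len(pool) // blocks)
    for b in range(blocks):
        base_pool = pool[b * slice_size: (b + 1) * slice_size] or pool[-slice_size:]
        base_n = min(max(lo, 2), len(base_pool))
        base = list(rng.choice(base_pool, size=base_n, replace=False))
        block_ids = []
        for t in range(per_block):
            tid = f"GO:{b + 1:02d}{t + 1:02d}"
            members = set(base)
            # per-term variation only when the base is large enough that the
            # within-block Jaccard provably stays above the 0.5 default
            if len(base) >= 7:
                if rng.random() < 0.5:
                    members.discard(base[int(rng.integers(0, len(base)))])
                if rng.random() < 0.3:
                    members.add(filler[int(rng.integers(0, n_fill))])
            terms[tid] = (f"planted block {b + 1} term {t + 1}", frozenset(members))
            block_ids.append(tid)
            gt.enriched_terms.add(tid)
        gt.module_blocks.append(block_ids)
    for t in range(spec.n_null_terms):
        tid = f"GO:NULL{t + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(filler, size=min(size, n_fill), replace=False))
        terms[tid] = (f"null term {t + 1}", members)
    return AnnotationDB(terms, background), disease, gt


def simulate(spec: SyntheticSpec, out_dir: str | Path) -> GroundTruth:
    """Run every generator and write the full input bundle to ``out_dir``.

    Files: library.sdf, library_annot.tsv, compounds.sdf, formula.tsv,
    descriptors.tsv, disease.txt, annotations.gmt, background.txt,
    groundtruth.json. Deterministic and byte-stable per spec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library, gt = generate_ligand_library(spec)
    write_sdf([m for m, _ in library.entries], out / "library.sdf")
    annot_lines = ["ligand_id\ttarget_id"] + [f"{m.id}\t{t}" for m, t in library.entries]
    (out / "library_annot.tsv").write_text("\n".join(annot_lines) + "\n")

    compounds, formula, gt_screen = generate_screen_set(spec, library)
    gt.merge(gt_screen)
    write_sdf(compounds, out / "compounds.sdf")
    write_formula_table(formula, out / "formula.tsv")

    records, gt_desc = generate_descriptor_table(spec, [m.id for m in compounds])
    gt.merge(gt_desc)
    write_descriptor_table(records, out / "descriptors.tsv")

    db, disease, gt_annot = generate_annotation_db(spec, library.target_ids)
    gt.merge(gt_annot)
    db.write_gmt(out / "annotations.gmt")
    (out / "background.txt").write_text("\n".join(sorted(db.background)) + "\n")
    (out / "disease.txt").write_text("\n".join(sorted(disease.proteins)) + "\n")
    gt.to_json(out / "groundtruth.json")
    return gt


# ---------------------------------------------------------------------------
# Published-count fixtures (synthetic stand-ins for undeposited supplementary
# tables; they realize summary counts exactly, not the real identities).

def make_margin_sets(
    sizes: Mapping[str, int], union_size: int, common_size: int, prefix: str = "T"
) -> dict[str, set[str]]:
    """Deterministic set system with prescribed per-set sizes, union and k-way
    intersection.

    ``common_size`` elements belong to every set; the remaining
    ``union_size - common_size`` elements are assigned to 1..k-1 sets by a
    largest-margin-first greedy, which realizes the margins exactly whenever a
    realization exists.
    """
    names = list(sizes)
    k = len(names)
    margins = {h: sizes[h] - common_size for h in names}
    if any(m < 0 for m in margins.values()):
        raise ValidationError("a set size is smaller than the common core")
    extras = union_size - common_size
    total = sum(margins.values())
    if not (extras <= total <= extras * (k - 1)) and extras > 0:
        raise ValidationError("margins cannot be realized with the given union/intersection")
    universe = [f"{prefix}{i + 1:04d}" for i in range(union_size)]
    sets: dict[str, set[str]] = {h: set(universe[:common_size]) for h in names}
    remaining = total
    for idx in range(extras):
        r = extras - idx  # targets still to assign, including this one
        lower = max(1, remaining - (r - 1) * (k - 1))
        upper = min(k - 1, remaining - (r - 1))
        m = min(max(int(np.ceil(remaining / r)), lower), upper)
        ranked = sorted(names, key=lambda h: (-margins[h], h))[:m]
        for h in ranked:
            if margins[h] <= 0:
                raise ValidationError("margins cannot be realized (greedy exhausted a set)")
            sets[h].add(universe[common_size + idx])
            margins[h] -= 1
        remaining -= m
    if remaining != 0:
        raise ValidationError("margins cannot be realized exactly")
    return sets


def make_bipartite_pairs(
    n_left: int, n_right: int, n_edges: int, stride: int = 7
) -> list[tuple[int, int]]:
    """Deterministic bipartite edge list with every left node covered.

    Edge quota is split as evenly as possible over left nodes; node ``i``
    connects to right nodes ``(i * stride + j) mod n_right``. Requires
    ``n_edges <= n_left * n_right`` and per-node quota <= n_right.
    """
    if n_edges > n_left * n_right:
        raise ValidationError("more edges requested than pairs available")
    base, extra = divmod(n_edges, n_left)
    if base + 1 > n_right:
        raise ValidationError("per-node quota exceeds the right-side size")
    pairs = []
    for i in range(n_left):
        deg = base + (1 if i < extra else 0)
        for j in range(deg):
            pairs.append((i, (i * stride + j) % n_right))
    return pairs


def make_ct_count_fixture(
    n_herbs: int, n_compounds: int, n_targets: int, n_edges: int
) -> tuple[FormulaTable, CompoundTargetMap]:
    """Formula + association map realizing given class sizes and edge count."""
    herbs = [HERB_CODES[i] if i < len(HERB_CODES) else f"H{i + 1}" for i in range(n_herbs)]
    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    targets = [f"T{i + 1:04d}" for i in range(n_targets)]
    members: dict[str, list[str]] = {h: [] for h in herbs}
    for i, cid in enumerate(compounds):
        members[herbs[i % n_herbs]].append(cid)
    pairs = make_bipartite_pairs(n_compounds, n_targets, n_edges)
    associations = [(compounds[i], targets[j], 0.9) for i, j in pairs]
    return FormulaTable(members), CompoundTargetMap(associations)


def make_tf_count_fixture(
    n_targets: int, n_modules: int, n_pairs: int
) -> tuple[list[str], dict[str, set[str]]]:
    """Target list + module annotation realizing given pair/target/module counts."""
    targets = [f"T{i + 1:04d}" for i in range(n_targets)]
    modules = [f"M{i + 1}" for i in range(n_modules)]
    annot: dict[str, set[str]] = {t: set() for t in targets}
    for i, j in make_bipartite_pairs(n_targets, n_modules, n_pairs, stride=3):
        annot[targets[i]].add(modules[j])
    return targets, annot


def make_admet_count_fixture(
    per_herb_retained: Mapping[str, int], n_total: int
) -> tuple[list[DescriptorRecord], FormulaTable]:
    """Descriptor table + formula whose filter outcome matches given counts.

    Retained compounds get safe descriptor values; the ``n_total - retained``
    removed compounds (spread evenly over the herbs) violate the four rules in
    rotation.
    """
    n_retained = sum(per_herb_retained.values())
    n_removed = n_total - n_retained
    if n_removed < 0:
        raise ValidationError("retained counts exceed the total")
    herbs = list(per_herb_retained)
    removed_per_herb = {h: n_removed // len(herbs) for h in herbs}
    for h in herbs[: n_removed % len(herbs)]:
        removed_per_herb[h] += 1
    records: list[DescriptorRecord] = []
    members: dict[str, list[str]] = {h: [] for h in herbs}
    bad = 0
    for h in herbs:
        for i in range(per_herb_retained[h] + removed_per_herb[h]):
            cid = f"{h}{i + 1:03d}"
            members[h].append(cid)
            if i < per_herb_retained[h]:
                records.append(DescriptorRecord(cid, -4.0, 1, False, 1))
            else:
                rule = bad % 4
                bad += 1
                records.append(
                    DescriptorRecord(
                        cid,
                        -9.0 if rule == 0 else -4.0,
                        3 if rule == 1 else 1,
                        rule == 2,
                        3 if rule == 3 else 1,
                    )
                )
    return records, FormulaTable(members)


def make_prediction_fixture(
    n_predicted_targets: int, n_disease_overlap: int, disease_total: int
) -> tuple[CompoundTargetMap, DiseaseGeneSet]:
    """Association map with a given distinct-target count plus a disease set
    overlapping it in exactly ``n_disease_overlap`` targets."""
    targets = [f"T{i + 1:04d}" for i in range(n_predicted_targets)]
    associations = [(f"C{i + 1:04d}", t, 0.9) for i, t in enumerate(targets)]
    disease = set(targets[:n_disease_overlap])
    disease |= {f"DZ{i + 1:04d}" for i in range(disease_total - n_disease_overlap)}
    return CompoundTargetMap(associations), DiseaseGeneSet(frozenset(disease))
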