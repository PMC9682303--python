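"""Landmark, tree, module-map and result I/O, plus taxon reconciliation.

Supported formats
-----------------
* TPS landmark files — ``LM=``/``LM3=`` headers, coordinate lines, ``ID=``
  specimen identifiers.  ``SCALE=`` and ``IMAGE=`` lines are accepted and
  ignored (superimposition removes scale anyway).
* Wide coordinate tables (CSV/TSV) — one row per specimen, columns
  ``x1,y1[,z1],x2,...`` plus ``specimen_id`` and optionally ``species``.
* Newick trees (through :class:`~phylomorph.tree.Phylogeny`).
* Module maps as YAML (``module: [1-based landmark indices]``) or two-column
  CSV (``landmark,module``).

Species labels are parsed from the specimen ID with a configurable regex
(default: everything before the last underscore); a sidecar CSV mapping
``specimen_id -> species`` overrides the regex.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .tree import Phylogeny

__all__ = [
    "LandmarkSet", "ModuleMap", "TaxonMatchReport",
    "read_landmarks", "write_landmarks", "read_tree",
    "read_module_map", "write_module_map", "match_taxa",
    "species_from_id", "normalize_taxon",
]

DEFAULT_SPECIES_REGEX = r"^(.+)_[^_]+$"


@dataclass
class LandmarkSet:
    """One specimen's raw landmark configuration."""

    specimen_id: str
    species: str
    coords: np.ndarray  # k landmarks x d dims
    view: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError(f"{self.specimen_id}: coords must be 2-D (k x d)")
        k, d = self.coords.shape
        if k < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks, got {k}")
        if d not in (2, 3):
            raise ValueError(f"{self.specimen_id}: dimension must be 2 or 3, got {d}")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"{self.specimen_id}: missing or non-finite coordinates")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class ModuleMap:
    """Partition of landmarks into named modules.

    ``assignment[i]`` is the module label of landmark ``i`` (0-based);
    ``module_names`` fixes the module order.
    """

    assignment: list[str]
    module_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.assignment = [str(a) for a in self.assignment]
        if not self.module_names:
            seen: dict[str, None] = {}
            for a in self.assignment:
                seen.setdefault(a)
            self.module_names = list(seen)
        missing = set(self.module_names) - set(self.assignment)
        if missing:
            raise ValueError(f"empty module(s): {sorted(missing)}")
        extra = set(self.assignment) - set(self.module_names)
        if extra:
            raise ValueError(f"assignment uses unknown module(s): {sorted(extra)}")

    @property
    def k(self) -> int:
        return len(self.assignment)

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def landmarks(self, module: str) -> np.ndarray:
        """0-based landmark indices belonging to ``module``."""
        return np.flatnonzero(np.asarray(self.assignment) == module)

    def columns(self, module: str, d: int) -> np.ndarray:
        """Flattened-coordinate column indices of ``module`` for dimension d."""
        lm = self.landmarks(module)
        return (lm[:, None] * d + np.arange(d)[None, :]).ravel()

    def merged(self, groups: dict[str, Sequence[str]]) -> "ModuleMap":
        """New map merging old modules into named groups (used by the battery)."""
        lookup = {}
        for new, olds in groups.items():
            for old in olds:
                lookup[old] = new
        assignment = [lookup[a] for a in self.assignment]
        return ModuleMap(assignment, list(groups))


# --------------------------------------------------------------------- TPS

def _parse_species(specimen_id: str, species_regex: str,
                   sidecar: dict[str, str] | None) -> str:
    if sidecar is not None and specimen_id in sidecar:
        return sidecar[specimen_id]
    m = re.match(species_regex, specimen_id)
    return m.group(1) if m else specimen_id


def _load_sidecar(path) -> dict[str, str]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    return dict(zip(df[cols["specimen_id"]].astype(str),
                    df[cols["species"]].astype(str)))


def read_landmarks(path, format: str = "tps", *,
                   species_regex: str = DEFAULT_SPECIES_REGEX,
                   species_table=None) -> list[LandmarkSet]:
    """Read a TPS or wide-table landmark file into LandmarkSets.

    All specimens must share the same landmark count and dimensionality;
    a mismatch is a hard error naming the offending specimen.
    """
    sidecar = _load_sidecar(species_table) if species_table is not None else None
    if format == "tps":
        sets = _read_tps(path, species_regex, sidecar)
    elif format == "table":
        sets = _read_table(path, species_regex, sidecar)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    if not sets:
        raise ValueError(f"{path}: no specimens found")
    k, d = sets[0].k, sets[0].d
    for s in sets:
        if (s.k, s.d) != (k, d):
            raise ValueError(
                f"specimen {s.specimen_id!r} has {s.k} landmarks x {s.d} dims; "
                f"expected {k} x {d} (from first specimen)")
    return sets


def _read_tps(path, species_regex, sidecar) -> list[LandmarkSet]:
    sets: list[LandmarkSet] = []
    lines = Path(path).read_text().splitlines()
    i, n_spec = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = re.match(r"^LM(3?)=(\d+)$", line, flags=re.IGNORECASE)
        if not m:
            raise ValueError(f"{path}:{i + 1}: expected LM= header, got {line!r}")
        d = 3 if m.group(1) else 2
        k = int(m.group(2))
        n_spec += 1
        coords = np.empty((k, d))
        i += 1
        for j in range(k):
            if i >= len(lines):
                raise ValueError(f"{path}: truncated specimen {n_spec}")
            parts = lines[i].split()
            if len(parts) != d:
                raise ValueError(
                    f"{path}:{i + 1}: expected {d} coordinates, got {len(parts)}")
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError:
                raise ValueError(
                    f"{path}:{i + 1}: non-numeric coordinate in {lines[i]!r}")
            i += 1
        specimen_id = f"specimen_{n_spec}"
        view = None
        while i < len(lines) and lines[i].strip() and \
                not re.match(r"^LM3?=", lines[i].strip(), flags=re.IGNORECASE):
            tag = lines[i].strip()
            if tag.upper().startswith("ID="):
                specimen_id = tag[3:].strip()
            elif tag.upper().startswith("VIEW="):
                view = tag[5:].strip()
            # SCALE=, IMAGE=, CURVES= etc. are accepted and ignored
            i += 1
        species = _parse_species(specimen_id, species_regex, sidecar)
        sets.append(LandmarkSet(specimen_id, species, coords, view))
    return sets


def write_landmarks(sets: Sequence[LandmarkSet], path, format: str = "tps") -> None:
    if format == "tps":
        with open(path, "w") as fh:
            for s in sets:
                header = "LM3=" if s.d == 3 else "LM="
                fh.write(f"{header}{s.k}\n")
                for row in s.coords:
                    fh.write(" ".join(repr(float(x)) for x in row) + "\n")
                fh.write(f"ID={s.specimen_id}\n")
    elif format == "table":
        _write_table(sets, path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def _read_table(path, species_regex, sidecar) -> list[LandmarkSet]:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    if "specimen_id" not in cols:
        raise ValueError(f"{path}: need a 'specimen_id' column")
    axes = "xyz" if any(re.fullmatch(r"z\d+", c.lower()) for c in df.columns) else "xy"
    d = len(axes)
    k = max(int(m.group(1)) for c in df.columns
            if (m := re.fullmatch(r"x(\d+)", c.lower())))
    coord_cols = [cols[f"{ax}{i}"] for i in range(1, k + 1) for ax in axes]
    sets = []
    for _, row in df.iterrows():
        sid = str(row[cols["specimen_id"]])
        vals = row[coord_cols].to_numpy(dtype=float).reshape(k, d)
        species = (str(row[cols["species"]]) if "species" in cols
                   else _parse_species(sid, species_regex, sidecar))
        sets.append(LandmarkSet(sid, species, vals))
    return sets


def _write_table(sets: Sequence[LandmarkSet], path) -> None:
    k, d = sets[0].k, sets[0].d
    axes = "xyz"[:d]
    cols = [f"{ax}{i}" for i in range(1, k + 1) for ax in axes]
    rows = []
    for s in sets:
        rows.append({"specimen_id": s.specimen_id, "species": s.species,
                     **dict(zip(cols, s.coords.ravel()))})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# -------------------------------------------------------------------- trees

def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths.

    Negative branch lengths and duplicate tip labels are hard errors
    (enforced by the Phylogeny constructor); polytomies are fine.
    """
    return Phylogeny.read(path)


# -------------------------------------------------------------- module maps

def read_module_map(path) -> ModuleMap:
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        spec = yaml.safe_load(path.read_text())
        if not isinstance(spec, dict):
            raise ValueError(f"{path}: YAML module map must be a mapping")
        k = max(max(v) for v in spec.values())
        assignment: list[str | None] = [None] * k
        for module, idx in spec.items():
            for i in idx:
                if assignment[i - 1] is not None:
                    raise ValueError(f"{path}: landmark {i} assigned twice")
                assignment[i - 1] = str(module)
        holes = [i + 1 for i, a in enumerate(assignment) if a is None]
        if holes:
            raise ValueError(f"{path}: unassigned landmark(s) {holes}")
        return ModuleMap(assignment, [str(m) for m in spec])
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    df = df.sort_values(cols["landmark"])
    idx = df[cols["landmark"]].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: landmark column must cover 1..k exactly once")
    return ModuleMap(df[cols["module"]].astype(str).tolist())


def write_module_map(mm: ModuleMap, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        spec = {m: (mm.landmarks(m) + 1).tolist() for m in mm.module_names}
        path.write_text(yaml.safe_dump(spec, sort_keys=False))
    else:
        pd.DataFrame({"landmark": np.arange(1, mm.k + 1),
                      "module": mm.assignment}).to_csv(path, index=False)


# ---------------------------------------------------------- taxon matching

def normalize_taxon(name: str) -> str:
    """Whitespace-stripped, spaces unified to underscores; case untouched."""
    return re.sub(r"\s+", "_", name.strip())


@dataclass
class TaxonMatchReport:
    dropped_from_shapes: list[str]
    dropped_from_tree: list[str]

    @property
    def empty(self) -> bool:
        return not (self.dropped_from_shapes or self.dropped_from_tree)


def match_taxa(shapes, tree: Phylogeny):
    """Reconcile species-mean shapes with a phylogeny.

    Returns ``(shapes_subset, pruned_tree, report)`` where both carry exactly
    the intersection of species, in the pruned tree's tip order.  Names are
    normalised (whitespace/underscores) before matching but remain
    case-sensitive so that true mismatches stay visible.
    """
    shape_species = [normalize_taxon(s) for s in shapes.species]
    tree_species = [normalize_taxon(t) for t in tree.tip_labels]
    common = set(shape_species) & set(tree_species)
    if not common:
        raise ValueError("no species shared between shape data and tree")
    report = TaxonMatchReport(
        dropped_from_shapes=sorted(set(shape_species) - common),
        dropped_from_tree=sorted(set(tree_species) - common),
    )
    if len(common) < 2:
        raise ValueError("fewer than 2 shared species after matching")
    keep = [lab for lab, norm in zip(tree.tip_labels, tree_species)
            if norm in common]
    pruned = tree.prune(keep) if report.dropped_from_tree else tree
    order = [normalize_taxon(t) for t in pruned.tip_labels]
    sub = shapes.subset_species(order, normalized_from=shape_species)
    return sub, pruned, report
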