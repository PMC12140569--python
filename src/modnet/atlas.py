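"""Hierarchical functional-module atlas construction.

Builds the node table of a whole-brain parcellation (centroids in MNI mm),
labels each node with a Brodmann area (BA) by looking up the BA volume at
the node centroid, splits BA21/BA22 into anterior and posterior parts at
the median y coordinate, and assigns every node to the functional-module
hierarchy (four levels, from ten fine modules to one whole-domain module).

The hierarchy itself is data, not code: a YAML specification (see
``modnet/data/language_modules.yaml``) lists, per level, the module names,
their hemisphere scope and their members — Level 1 in terms of BA codes
with optional anterior/posterior qualifiers, higher levels as unions of
Level-1 modules. Other domain systems (e.g. a somatosensory-motor module
over BA1–BA4) are expressed by writing a new specification file.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: sentinel used in tables for "outside the domain system"
NONE_LABEL = "none"


# ---------------------------------------------------------------------------
# module-hierarchy specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemberSpec:
    """One Level-1 member: a BA code plus an optional anterior/posterior part."""

    ba: int
    part: str | None = None  # "ant", "post" or None (whole area)

    @classmethod
    def parse(cls, text: str) -> "MemberSpec":
        text = text.strip()
        if not text.upper().startswith("BA"):
            raise ValueError(f"member specifier must look like 'BA21[:ant|:post]', got {text!r}")
        body = text[2:]
        if ":" in body:
            code, part = body.split(":", 1)
            part = part.strip().lower()
            if part not in ("ant", "post"):
                raise ValueError(f"unknown subdivision {part!r} in {text!r}")
            return cls(int(code), part)
        return cls(int(body), None)


@dataclass(frozen=True)
class ModuleDef:
    name: str
    hemisphere: str               # "each" (one module per hemisphere) or "both"
    members: tuple[MemberSpec, ...] = ()   # level 1 only
    level1: tuple[str, ...] = ()           # levels > 1: names of level-1 parents


@dataclass
class ModuleHierarchy:
    """Validated multi-level module specification."""

    name: str
    language_bas: frozenset[int]
    split_bas: frozenset[int]
    levels: dict[int, list[ModuleDef]] = field(default_factory=dict)

    def validate(self) -> None:
        if sorted(self.levels) != [1, 2, 3, 4]:
            raise ValueError("hierarchy must define levels 1-4")
        # level-1 members must partition the domain BAs without overlap
        seen: set[MemberSpec] = set()
        covered: set[int] = set()
        for mod in self.levels[1]:
            for m in mod.members:
                if m in seen:
                    raise ValueError(f"member {m} appears in two Level-1 modules")
                seen.add(m)
                covered.add(m.ba)
        if covered != set(self.language_bas):
            raise ValueError(
                f"Level-1 members cover BAs {sorted(covered)} but the domain "
                f"declares {sorted(self.language_bas)}"
            )
        for ba in self.split_bas:
            parts = {m.part for m in seen if m.ba == ba}
            if parts != {"ant", "post"}:
                raise ValueError(f"split BA{ba} must appear with both :ant and :post")
        l1_names = {m.name for m in self.levels[1]}
        for lvl in (2, 3, 4):
            for mod in self.levels[lvl]:
                unknown = set(mod.level1) - l1_names
                if unknown:
                    raise ValueError(f"level {lvl} module {mod.name!r} references unknown {unknown}")
        l4 = self.levels[4]
        if len(l4) != 1 or set(l4[0].level1) != l1_names:
            raise ValueError("Level 4 must be a single module covering every Level-1 module")

    def module_count(self, level: int) -> int:
        """Number of concrete modules at a level (hemisphere-expanded)."""
        return sum(2 if m.hemisphere == "each" else 1 for m in self.levels[level])

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModuleHierarchy":
        levels: dict[int, list[ModuleDef]] = {}
        for lvl, mods in cfg["levels"].items():
            defs = []
            for m in mods:
                defs.append(
                    ModuleDef(
                        name=m["name"],
                        hemisphere=m.get("hemisphere", "each"),
                        members=tuple(MemberSpec.parse(s) for s in m.get("members", [])),
                        level1=tuple(m.get("level1", [])),
                    )
                )
            levels[int(lvl)] = defs
        spec = cls(
            name=cfg.get("name", "unnamed"),
            language_bas=frozenset(int(b) for b in cfg["language_bas"]),
            split_bas=frozenset(int(b) for b in cfg.get("split_bas", [])),
            levels=levels,
        )
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path) -> "ModuleHierarchy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_language_hierarchy() -> ModuleHierarchy:
    """The packaged language-system specification (ten Level-1 modules)."""
    ref = importlib.resources.files("modnet") / "data" / "language_modules.yaml"
    return ModuleHierarchy.from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# node table
# ---------------------------------------------------------------------------

def compute_parcel_centroids(
    label_img,
    midline_tol_mm: float = 0.0,
    compartment: str = "cortical",
    hemisphere_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Node table from an integer-labeled parcellation volume.

    Each distinct nonzero label becomes one node whose centroid is the mean
    of the MNI-mm coordinates of all voxels carrying the label (voxel indices
    pushed through the image affine). Hemisphere is the sign of centroid x;
    within ``midline_tol_mm`` of the midline (or for subcortical parcels) the
    caller may override via ``hemisphere_labels``.

    Parameters
    ----------
    label_img : nibabel spatial image (or object with get_fdata()/affine)
        Integer-labeled 3D parcellation.
    midline_tol_mm : float
        |x| below this requires an entry in ``hemisphere_labels``.
    compartment : str
        "cortical" or "subcortical", recorded per node.
    hemisphere_labels : dict, optional
        label -> "left"/"right" override (used for midline/subcortical nodes).

    Returns
    -------
    pandas.DataFrame with columns node_id, x, y, z, hemisphere, compartment.
    """
    affine = np.asarray(label_img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("label volume affine is not invertible")
    data = np.asarray(label_img.get_fdata()).round().astype(int)
    labels = np.unique(data)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("label volume contains no nonzero labels")

    rows = []
    for lab in labels:
        idx = np.argwhere(data == lab)  # (k, 3) voxel indices
        mm = idx @ affine[:3, :3].T + affine[:3, 3]
        cx, cy, cz = mm.mean(axis=0)
        if hemisphere_labels and int(lab) in hemisphere_labels:
            hemi = hemisphere_labels[int(lab)]
        elif abs(cx) <= midline_tol_mm:
            raise ValueError(
                f"label {lab}: centroid x={cx:.2f} within midline tolerance and "
                "no hemisphere override supplied"
            )
        else:
            hemi = "left" if cx < 0 else "right"
        rows.append((int(lab), cx, cy, cz, hemi, compartment))
    return pd.DataFrame(rows, columns=["node_id", "x", "y", "z", "hemisphere", "compartment"])


# ---------------------------------------------------------------------------
# Brodmann labeling
# ---------------------------------------------------------------------------

def assign_brodmann(nodes: pd.DataFrame, ba_img, language_bas) -> pd.DataFrame:
    """Label each node with the BA of the map voxel containing its centroid.

    The centroid is mapped back to voxel space by the inverse affine and
    rounded to the nearest voxel (no interpolation). Labels of 0, labels not
    in ``language_bas`` and out-of-bounds centroids yield a missing BA.

    Returns a DataFrame with columns node_id, ba (nullable int), ap
    (initially "not_applicable" everywhere; see split_anterior_posterior).
    """
    language_bas = {int(b) for b in language_bas}
    affine = np.asarray(ba_img.affine, dtype=float)
    inv = np.linalg.inv(affine)
    data = np.asarray(ba_img.get_fdata()).round().astype(int)

    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    vox = np.rint(coords @ inv[:3, :3].T + inv[:3, 3]).astype(int)

    bas: list[float | int] = []
    for (i, j, k), nid in zip(vox, nodes["node_id"]):
        if not (0 <= i < data.shape[0] and 0 <= j < data.shape[1] and 0 <= k < data.shape[2]):
            logger.warning("node %s centroid outside BA map bounds; labeled none", nid)
            bas.append(np.nan)
            continue
        lab = int(data[i, j, k])
        bas.append(lab if lab in language_bas else np.nan)
    out = pd.DataFrame(
        {
            "node_id": nodes["node_id"].to_numpy(),
            "ba": pd.array(bas, dtype="Int64"),
            "ap": "not_applicable",
        }
    )
    return out


def split_anterior_posterior(
    labeling: pd.DataFrame,
    nodes: pd.DataFrame,
    ba: int,
    reference: str = "map_voxels",
    ba_img=None,
) -> pd.DataFrame:
    """Split one BA's nodes into anterior/posterior at the median y, per hemisphere.

    The dividing line is the median y coordinate of a reference set computed
    separately for each hemisphere: either every voxel of that BA in the map
    (``map_voxels``, requires ``ba_img``) or the centroids of the member
    nodes (``member_nodes``). Nodes with centroid y strictly greater than the
    median are anterior; ties go to posterior.
    """
    if reference not in ("map_voxels", "member_nodes"):
        raise ValueError(f"unknown reference {reference!r}")
    out = labeling.copy()
    merged = out.merge(nodes[["node_id", "x", "y", "z", "hemisphere"]], on="node_id")

    if reference == "map_voxels":
        if ba_img is None:
            raise ValueError("map_voxels reference requires the BA map image")
        affine = np.asarray(ba_img.affine, dtype=float)
        data = np.asarray(ba_img.get_fdata()).round().astype(int)
        idx = np.argwhere(data == int(ba))
        if idx.size == 0:
            raise ValueError(f"BA{ba} absent from the map")
        mm = idx @ affine[:3, :3].T + affine[:3, 3]

    for hemi, sign in (("left", -1), ("right", 1)):
        members = merged[(merged["ba"] == int(ba)) & (merged["hemisphere"] == hemi)]
        if members.empty:
            continue
        if reference == "map_voxels":
            ys = mm[np.sign(mm[:, 0]) == sign, 1]
            if ys.size == 0:
                raise ValueError(f"BA{ba} has no {hemi}-hemisphere voxels in the map")
        else:
            ys = members["y"].to_numpy()
        med = float(np.median(ys))
        ap = np.where(members["y"].to_numpy() > med, "anterior", "posterior")
        out.loc[out["node_id"].isin(members["node_id"]), "ap"] = ap
    return out


# ---------------------------------------------------------------------------
# hierarchy assignment
# ---------------------------------------------------------------------------

_HEMI_SUFFIX = {"left": "L", "right": "R"}
_AP_TO_PART = {"anterior": "ant", "posterior": "post"}


def build_module_hierarchy(
    labeling: pd.DataFrame, nodes: pd.DataFrame, spec: ModuleHierarchy
) -> pd.DataFrame:
    """Assign every node to a module at each hierarchy level.

    Returns a DataFrame with columns node_id, level1, level3, level4 (module
    name or "none") and level2 (semicolon-joined set of names, possibly
    multi-valued: a Level-1 module may feed two Level-2 modules).
    """
    spec.validate()
    merged = labeling.merge(nodes[["node_id", "hemisphere"]], on="node_id")

    # level-1 lookup: (ba, part-or-None) -> module base name
    l1_lookup: dict[tuple[int, str | None], str] = {}
    for mod in spec.levels[1]:
        for m in mod.members:
            l1_lookup[(m.ba, m.part)] = mod.name
    # level-1 base name -> level-2 base names
    l2_parents: dict[str, list[str]] = {m.name: [] for m in spec.levels[1]}
    for mod in spec.levels[2]:
        for parent in mod.level1:
            l2_parents[parent].append(mod.name)
    l3_name = spec.levels[3][0].name
    l4_name = spec.levels[4][0].name

    present_members = set()
    rows = []
    for _, r in merged.iterrows():
        if pd.isna(r["ba"]):
            rows.append((r["node_id"], NONE_LABEL, NONE_LABEL, NONE_LABEL, NONE_LABEL))
            continue
        ba = int(r["ba"])
        part = _AP_TO_PART.get(r["ap"])
        key = (ba, part) if (ba, part) in l1_lookup else (ba, None)
        if key not in l1_lookup:
            logger.warning("node %s: BA%s%s not in hierarchy spec", r["node_id"], ba,
                           f":{part}" if part else "")
            rows.append((r["node_id"], NONE_LABEL, NONE_LABEL, NONE_LABEL, NONE_LABEL))
            continue
        present_members.add(key)
        suffix = _HEMI_SUFFIX[r["hemisphere"]]
        l1 = f"{l1_lookup[key]} {suffix}"
        l2 = ";".join(sorted(f"{p} {suffix}" for p in l2_parents[l1_lookup[key]])) or NONE_LABEL
        rows.append((r["node_id"], l1, l2, f"{l3_name} {suffix}", l4_name))

    missing = set(l1_lookup) - present_members
    if missing:
        warnings.warn(
            f"hierarchy members with no labeled node: "
            f"{sorted((b, p or '') for b, p in missing)}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["node_id", "level1", "level2", "level3", "level4"])


def module_members(assignment: pd.DataFrame, module: str, level: int) -> np.ndarray:
    """node_ids belonging to ``module`` at ``level`` (handles the level-2 sets)."""
    col = f"level{level}"
    if level == 2:
        mask = assignment[col].map(lambda s: module in s.split(";"))
    else:
        mask = assignment[col] == module
    return assignment.loc[mask, "node_id"].to_numpy()


def internode_distance_report(
    nodes: pd.DataFrame,
    assignment: pd.DataFrame,
    module: str,
    level: int = 1,
    distance_thresholds_mm: tuple[float, ...] = (40.0,),
) -> dict:
    """Pairwise Euclidean distance summary for one module's nodes.

    Returns the median distance over all unordered node pairs and, for each
    threshold d, the fraction of pairs farther apart than d mm.
    """
    ids = module_members(assignment, module, level)
    sub = nodes[nodes["node_id"].isin(ids)]
    if len(sub) < 2:
        raise ValueError(f"module {module!r} has fewer than 2 nodes")
    xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
    dists = np.array(
        [np.linalg.norm(a - b) for a, b in itertools.combinations(xyz, 2)]
    )
    report = {
        "module": module,
        "level": level,
        "n_nodes": len(sub),
        "n_pairs": len(dists),
        "median_mm": float(np.median(dists)),
    }
    for d in distance_thresholds_mm:
        report[f"frac_gt_{d:g}mm"] = float(np.mean(dists > d))
    return report
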