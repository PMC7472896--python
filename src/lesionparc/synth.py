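"""Synthetic cohorts with vascular-territory lesion structure.

Stroke damage is not spatially random: an occlusion in the arterial tree
knocks out every territory fed by the branches below it, so voxels within
one territory (and, more weakly, within sibling territories) are damaged
together.  This module generates (i) a random binary arterial tree whose
leaves own Voronoi-style territories inside a brain mask, (ii) patient
abnormality maps produced by sampling an occlusion site on that tree, with
per-patient watershed (boundary) jitter and background noise, (iii) a
behavioural battery driven by latent factors tied to critical territories,
and (iv) binary deficit labels under a region damage-fraction /
deficit-probability rule.  Every generator is bit-reproducible given its
seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BrainMask, Volume, gaussian_smooth

# ---------------------------------------------------------------------------
# Vascular tree and atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VascularNode:
    id: int
    parent: int | None
    occlusion_weight: float


@dataclass
class VascularTree:
    """Rooted binary tree of arterial branches.

    Each leaf owns exactly one territory label; ``seed_points`` maps a
    territory label to the voxel index its territory was grown from.
    Occlusion weights set how often each node is the sampled occlusion
    site (weights need not be normalised).
    """

    nodes: list[VascularNode]
    leaf_territory: dict[int, int]
    seed_points: dict[int, tuple[int, int, int]]

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {len(roots)}")
        ids = {n.id for n in self.nodes}
        for n in self.nodes:
            if n.parent is not None and n.parent not in ids:
                raise ValueError(f"node {n.id} has unknown parent {n.parent}")
            if n.occlusion_weight < 0:
                raise ValueError("occlusion weights must be non-negative")
        if sum(n.occlusion_weight for n in self.nodes) <= 0:
            raise ValueError("occlusion weights must sum to a positive value")
        # acyclicity: walking up from every node must reach the root
        by_id = {n.id: n for n in self.nodes}
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent is not None:
                if cur.id in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(cur.id)
                cur = by_id[cur.parent]
        leaves = self.leaf_ids()
        if set(self.leaf_territory) != set(leaves):
            raise ValueError("every leaf (and only leaves) must map to a territory")

    @property
    def root(self) -> VascularNode:
        return next(n for n in self.nodes if n.parent is None)

    def children(self, node_id: int) -> list[VascularNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def leaf_ids(self) -> list[int]:
        have_child = {n.parent for n in self.nodes if n.parent is not None}
        return [n.id for n in self.nodes if n.id not in have_child]

    def leaves_under(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            cur = stack.pop()
            kids = self.children(cur)
            if not kids:
                out.append(cur)
            else:
                stack.extend(k.id for k in kids)
        return sorted(out)

    def territories_under(self, node_id: int) -> list[int]:
        return sorted(self.leaf_territory[l] for l in self.leaves_under(node_id))

    # -- JSON round trip ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"id": n.id, "parent": n.parent, "occlusion_weight": n.occlusion_weight}
                    for n in self.nodes
                ],
                "leaf_territory": {str(k): v for k, v in self.leaf_territory.items()},
                "seed_points": {str(k): list(v) for k, v in self.seed_points.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "VascularTree":
        d = json.loads(text)
        return cls(
            nodes=[VascularNode(**n) for n in d["nodes"]],
            leaf_territory={int(k): int(v) for k, v in d["leaf_territory"].items()},
            seed_points={int(k): tuple(v) for k, v in d["seed_points"].items()},
        )


@dataclass
class ParcellationAtlas:
    """Labelled parcellation volume (0 = background) with label names."""

    labels: Volume
    names: dict[int, str]

    def __post_init__(self) -> None:
        if self.labels.role != "label":
            self.labels = Volume(self.labels.data, self.labels.affine, "label")
        present = set(np.unique(self.labels.data).tolist()) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named labels missing from the volume: {sorted(missing)}")

    @property
    def label_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels.data).tolist()) - {0})

    def region_mask(self, label: int) -> Volume:
        if label not in self.label_ids:
            raise ValueError(f"unknown territory label {label}")
        return self.labels.with_data(
            (np.asarray(self.labels.data) == label).astype(np.uint8), role="binary"
        )


@dataclass
class CohortSpec:
    """Study conditions for a simulated lesion cohort.

    ``beta_a``/``beta_b`` parameterise the Beta distribution of per-voxel
    damage intensity inside occluded territories (default mean 0.8,
    i.e. heavy but variable abnormality); ``boundary_jitter_mm`` is the
    RMS magnitude of the smooth per-patient displacement applied to
    territory boundaries (watershed variability); ``background_noise`` is
    the SD of the clipped additive noise outside the lesion.
    """

    n_patients: int = 70
    beta_a: float = 8.0
    beta_b: float = 2.0
    boundary_jitter_mm: float = 2.0
    background_noise: float = 0.02
    fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("beta_a", "beta_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("boundary_jitter_mm", "background_noise", "fwhm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class BehaviourGenSpec:
    """Generating model of the behavioural battery.

    ``loadings`` is the tests x factors matrix W; each test's score is
    ``100 * clip(W @ f + eps, 0, 1)`` with latent factors ``f`` in [0, 1]
    derived from lesion load and ``eps ~ N(0, uniqueness_sd)``.
    """

    loadings: pd.DataFrame
    uniqueness_sd: float = 0.1
    scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.loadings.to_numpy(dtype=float))):
            raise ValueError("loading matrix must be finite")
        if self.uniqueness_sd < 0:
            raise ValueError("uniqueness_sd must be non-negative")


# ---------------------------------------------------------------------------
# Default grids and the reference battery loading pattern
# ---------------------------------------------------------------------------


def default_brain_mask(
    grid_shape: tuple[int, int, int] = (32, 38, 32), voxel_size_mm: float = 4.0
) -> BrainMask:
    """Desk-scale ellipsoidal brain mask (~14k voxels at the default 4 mm)."""
    shape = np.asarray(grid_shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * shape / 2.0
    centre = (shape - 1) / 2.0
    semi = shape / 2.0 - 2.0
    ijk = np.indices(grid_shape).reshape(3, -1).T
    inside = (((ijk - centre) / semi) ** 2).sum(axis=1) <= 1.0
    data = inside.reshape(grid_shape).astype(np.uint8)
    return BrainMask(Volume(data, affine, "binary"))


#: the 21-test battery: (name, dominant factor, dominant loading)
_BATTERY = [
    ("delayed_repetition_words", "phonology", 0.888),
    ("delayed_repetition_nonwords", "phonology", 0.883),
    ("immediate_repetition_nonwords", "phonology", 0.881),
    ("immediate_repetition_words", "phonology", 0.858),
    ("boston_naming", "phonology", 0.823),
    ("naming_64_item", "phonology", 0.813),
    ("forward_digit_span", "phonology", 0.746),
    ("backward_digit_span", "phonology", 0.595),
    ("spoken_sentence_comprehension", "phonology", 0.521),
    ("spoken_word_picture_matching", "semantics", 0.801),
    ("type_token_ratio", "semantics", 0.718),
    ("written_word_picture_matching", "semantics", 0.713),
    ("camel_cactus_pictures", "semantics", 0.688),
    ("synonym_judgement_96", "semantics", 0.658),
    ("minimal_pairs_nonwords", "executive", 0.814),
    ("ravens_coloured_matrices", "executive", 0.735),
    ("minimal_pairs_words", "executive", 0.705),
    ("brixton_spatial_anticipation", "executive", 0.698),
    ("speech_tokens", "fluency", 0.885),
    ("mean_length_utterance", "fluency", 0.831),
    ("words_per_minute", "fluency", 0.768),
]

FACTOR_NAMES = ["phonology", "semantics", "executive", "fluency"]

#: secondary strong loading observed in the reference battery
_SECONDARY = {"written_word_picture_matching": ("executive", 0.504)}


def reference_battery_loadings(off_loading: float = 0.2) -> pd.DataFrame:
    """21 x 4 generating loading matrix of the reference aphasia battery.

    Strong (>= 0.5) loadings carry their published magnitudes; every other
    entry is a uniform weak cross-loading of ``off_loading``.
    """
    W = pd.DataFrame(
        off_loading, index=[t[0] for t in _BATTERY], columns=FACTOR_NAMES, dtype=float
    )
    for name, fac, val in _BATTERY:
        W.loc[name, fac] = val
    for name, (fac, val) in _SECONDARY.items():
        W.loc[name, fac] = val
    return W


# ---------------------------------------------------------------------------
# Atlas generation
# ---------------------------------------------------------------------------


def _sample_binary_tree(n_leaves: int, rng: np.random.Generator,
                        leaf_weight: float, internal_weight: float,
                        root_weight: float) -> tuple[list[VascularNode], list[int]]:
    """Grow a random binary tree by splitting random leaves; returns nodes
    (weights assigned by role) and the leaf ids in creation order."""
    parent: dict[int, int | None] = {0: None}
    leaves = [0]
    next_id = 1
    while len(leaves) < n_leaves:
        i = int(rng.integers(len(leaves)))
        node = leaves.pop(i)
        for _ in range(2):
            parent[next_id] = node
            leaves.append(next_id)
            next_id += 1
    leaf_set = set(leaves)
    nodes = []
    for nid, par in parent.items():
        if par is None:
            w = root_weight
        elif nid in leaf_set:
            w = leaf_weight
        else:
            w = internal_weight
        nodes.append(VascularNode(nid, par, w))
    return nodes, sorted(leaf_set)


def make_vascular_atlas(
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    brain_mask: BrainMask,
    n_terminal_branches: int,
    seed: int,
    leaf_weight: float = 1.0,
    internal_weight: float = 0.5,
    root_weight: float = 0.25,
) -> tuple[VascularTree, ParcellationAtlas]:
    """Random arterial tree plus its territory parcellation of the mask.

    Territory seed voxels are placed by farthest-point sampling inside the
    mask (even spatial coverage) and every in-mask voxel is assigned to its
    nearest seed in mm, i.e. a Voronoi partition.  Deterministic given
    ``seed``.
    """
    if n_terminal_branches < 2:
        raise ValueError("need at least 2 terminal branches")
    idx = brain_mask.indices
    if n_terminal_branches > len(idx):
        raise ValueError("more terminal branches than in-mask voxels")
    rng = np.random.default_rng(seed)
    mm = idx.astype(float) @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]

    # farthest-point sampling of seed locations
    seeds = [int(rng.integers(len(idx)))]
    d2 = np.sum((mm - mm[seeds[0]]) ** 2, axis=1)
    for _ in range(n_terminal_branches - 1):
        nxt = int(np.argmax(d2))
        seeds.append(nxt)
        d2 = np.minimum(d2, np.sum((mm - mm[nxt]) ** 2, axis=1))

    nodes, leaf_ids = _sample_binary_tree(
        n_terminal_branches, rng, leaf_weight, internal_weight, root_weight
    )
    # order seeds along their first spatial principal axis so that leaves
    # created together (siblings) tend to own neighbouring territories
    seed_mm = mm[seeds]
    axis = np.linalg.svd(seed_mm - seed_mm.mean(0), full_matrices=False)[2][0]
    order = np.argsort(seed_mm @ axis, kind="stable")
    labels_for_leaf = {leaf: lab + 1 for lab, leaf in enumerate(leaf_ids)}
    seed_points = {
        lab + 1: tuple(int(x) for x in idx[seeds[order[lab]]])
        for lab in range(n_terminal_branches)
    }

    seed_pos = np.array([mm[seeds[order[lab]]] for lab in range(n_terminal_branches)])
    dist = np.linalg.norm(mm[:, None, :] - seed_pos[None, :, :], axis=2)
    assign = np.argmin(dist, axis=1) + 1

    lab_vol = np.zeros(grid_shape, dtype=np.int32)
    lab_vol[tuple(idx.T)] = assign
    atlas = ParcellationAtlas(
        Volume(lab_vol, affine, "label"),
        {lab: f"territory_{lab:02d}" for lab in range(1, n_terminal_branches + 1)},
    )
    tree = VascularTree(nodes, labels_for_leaf, seed_points)
    return tree, atlas


# ---------------------------------------------------------------------------
# Lesion simulation
# ---------------------------------------------------------------------------


def _check_tree_atlas(tree: VascularTree, atlas: ParcellationAtlas) -> None:
    if sorted(tree.leaf_territory.values()) != atlas.label_ids:
        raise ValueError("tree leaves and atlas labels are inconsistent")


def simulate_patient_lesions(
    tree: VascularTree,
    atlas: ParcellationAtlas,
    spec: CohortSpec,
    occlusion_nodes: Sequence[int] | None = None,
) -> list[Volume]:
    """Simulate abnormality maps for a cohort of stroke patients.

    Per patient an occlusion node is drawn proportional to its weight and
    every territory below it receives Beta(a, b) damage intensity; the
    territory boundaries are first displaced by a smooth random field of
    RMS magnitude ``boundary_jitter_mm`` (per-patient watershed
    variability), background noise is added, the map is optionally
    smoothed and clipped to [0, 1].
    """
    _check_tree_atlas(tree, atlas)
    rng = np.random.default_rng(spec.seed)
    vol = atlas.labels
    grid_shape = vol.grid_shape
    mask = np.asarray(vol.data) > 0
    idx = np.argwhere(mask)
    mm = vol.voxel_to_mm(idx)

    label_of_territory = {}
    seed_pos = []
    for lab in atlas.label_ids:
        label_of_territory[lab] = len(seed_pos)
        seed_pos.append(vol.voxel_to_mm(np.asarray(tree.seed_points[lab])))
    seed_pos = np.asarray(seed_pos)

    weights = np.array([n.occlusion_weight for n in tree.nodes], dtype=float)
    probs = weights / weights.sum()
    node_ids = [n.id for n in tree.nodes]

    if occlusion_nodes is not None and len(occlusion_nodes) != spec.n_patients:
        raise ValueError("occlusion_nodes must list one node per patient")

    jitter_smooth_vox = 2.0  # correlation length of the boundary field
    out: list[Volume] = []
    for p in range(spec.n_patients):
        if occlusion_nodes is not None:
            node = int(occlusion_nodes[p])
        else:
            node = int(node_ids[rng.choice(len(node_ids), p=probs)])
        damaged = set(tree.territories_under(node))

        if spec.boundary_jitter_mm > 0:
            disp = np.empty((len(idx), 3))
            for ax in range(3):
                f = ndimage.gaussian_filter(
                    rng.standard_normal(grid_shape), jitter_smooth_vox
                )
                f_mask = f[tuple(idx.T)]
                sd = f_mask.std()
                disp[:, ax] = (
                    spec.boundary_jitter_mm * f_mask / sd if sd > 0 else 0.0
                )
            pos = mm + disp
        else:
            pos = mm
        dist = np.linalg.norm(pos[:, None, :] - seed_pos[None, :, :], axis=2)
        assign = np.asarray(atlas.label_ids)[np.argmin(dist, axis=1)]

        intensity = np.zeros(len(idx))
        dmg = np.isin(assign, sorted(damaged))
        n_dmg = int(dmg.sum())
        if n_dmg:
            intensity[dmg] = rng.beta(spec.beta_a, spec.beta_b, size=n_dmg)
        if spec.background_noise > 0:
            intensity += rng.normal(0.0, spec.background_noise, size=len(idx))
        data = np.zeros(grid_shape)
        data[tuple(idx.T)] = intensity
        volume = Volume(np.clip(data, 0.0, 1.0), vol.affine, "abnormality")
        if spec.fwhm_mm > 0:
            volume = gaussian_smooth(volume, spec.fwhm_mm)
            volume = Volume(
                np.clip(volume.data * mask, 0.0, 1.0), vol.affine, "abnormality"
            )
        out.append(volume)
    return out


# ---------------------------------------------------------------------------
# Behaviour simulation
# ---------------------------------------------------------------------------


def simulate_behaviour(
    lesions: Sequence[Volume],
    atlas: ParcellationAtlas,
    critical_territories: Mapping[str, Sequence[int]],
    spec: BehaviourGenSpec,
) -> pd.DataFrame:
    """Patients x tests behavioural score table driven by lesion load.

    Each factor's latent value for a patient is ``1 - mean abnormality``
    over its critical territories; test scores are the loading-weighted
    factor mix plus unique noise, clipped to [0, 1] and scaled to 0-100.
    """
    factors = list(spec.loadings.columns)
    for f in factors:
        if f not in critical_territories or len(critical_territories[f]) == 0:
            raise ValueError(f"factor {f!r} needs at least one critical territory")
    lab_data = np.asarray(atlas.labels.data)
    region_idx = {}
    for f in factors:
        sel = np.isin(lab_data, np.asarray(list(critical_territories[f])))
        if not sel.any():
            raise ValueError(f"unknown territory label(s) for factor {f!r}")
        region_idx[f] = np.argwhere(sel)

    rng = np.random.default_rng(spec.seed)
    n = len(lesions)
    F = np.empty((n, len(factors)))
    for i, vol in enumerate(lesions):
        d = np.asarray(vol.data, dtype=float)
        for j, f in enumerate(factors):
            F[i, j] = 1.0 - d[tuple(region_idx[f].T)].mean()
    W = spec.loadings.to_numpy(dtype=float)
    eps = rng.normal(0.0, spec.uniqueness_sd, size=(n, W.shape[0]))
    scores = spec.scale * np.clip(F @ W.T + eps, 0.0, 1.0)
    return pd.DataFrame(
        scores,
        index=[f"patient_{i:03d}" for i in range(n)],
        columns=list(spec.loadings.index),
    )


def simulate_battery(
    n_patients: int, spec: BehaviourGenSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behavioural battery with independent latent abilities.

    Latent factor values are drawn i.i.d. Uniform(0, 1) per patient (no
    lesion model involved); scores follow the same loading-mix rule as
    :func:`simulate_behaviour`.  Returns (scores, latent factors).
    """
    rng = np.random.default_rng(spec.seed)
    factors = list(spec.loadings.columns)
    F = rng.uniform(0.0, 1.0, size=(n_patients, len(factors)))
    W = spec.loadings.to_numpy(dtype=float)
    eps = rng.normal(0.0, spec.uniqueness_sd, size=(n_patients, W.shape[0]))
    scores = spec.scale * np.clip(F @ W.T + eps, 0.0, 1.0)
    ids = [f"patient_{i:03d}" for i in range(n_patients)]
    return (
        pd.DataFrame(scores, index=ids, columns=list(spec.loadings.index)),
        pd.DataFrame(F, index=ids, columns=factors),
    )


def latent_factors(
    lesions: Sequence[Volume],
    atlas: ParcellationAtlas,
    critical_territories: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Ground-truth latent factor values (1 - mean critical-territory load)."""
    lab_data = np.asarray(atlas.labels.data)
    cols = {}
    for f, labs in critical_territories.items():
        sel = np.isin(lab_data, np.asarray(list(labs)))
        idx = np.argwhere(sel)
        cols[f] = [
            1.0 - np.asarray(v.data, dtype=float)[tuple(idx.T)].mean()
            for v in lesions
        ]
    return pd.DataFrame(cols, index=[f"patient_{i:03d}" for i in range(len(lesions))])


# ---------------------------------------------------------------------------
# Deficit labels
# ---------------------------------------------------------------------------


def simulate_deficit_labels(
    region_mask,
    binary_lesions,
    damage_fraction: float = 0.2,
    deficit_prob: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binary behavioural-deficit label per patient for one region truth.

    A patient is *damaged* iff their lesion covers at least
    ``damage_fraction`` of the region; damaged patients exhibit a deficit
    with probability ``deficit_prob``; intact patients never do.

    ``binary_lesions`` may be a sequence of binary volumes on the region's
    grid, or a pre-extracted (patients, n_region_voxels) boolean array.
    """
    if not 0 < damage_fraction <= 1:
        raise ValueError("damage_fraction must lie in (0, 1]")
    if not 0 <= deficit_prob <= 1:
        raise ValueError("deficit_prob must lie in [0, 1]")
    if isinstance(region_mask, Volume):
        region = np.asarray(region_mask.data) > 0
    else:
        region = np.asarray(region_mask) > 0
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("region mask is empty")
    if isinstance(binary_lesions, np.ndarray) and binary_lesions.ndim == 2:
        sub = binary_lesions > 0
        if sub.shape[1] == n_region:  # columns already restricted to the region
            frac = sub.mean(axis=1)
        elif region.ndim == 1 and sub.shape[1] == region.shape[0]:
            frac = sub[:, region].mean(axis=1)
        else:
            raise ValueError("lesion matrix does not match region size")
    else:
        frac = np.array(
            [np.asarray(v.data)[region].mean() for v in binary_lesions], dtype=float
        )
    damaged = frac >= damage_fraction
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = damaged & (rng.random(len(damaged)) < deficit_prob)
    return labels.astype(np.int8)
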