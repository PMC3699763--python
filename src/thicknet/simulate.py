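"""Synthetic two-group cohort generator and fixture graphs.

The generator emulates the statistical structure the covariance-network
analysis assumes: per-subject mean ROI thickness confounded by age and
gender, with a group-specific inter-regional covariance imposed through
shared latent factors.  Each correlation block (a set of ROIs with target
within-block residual correlation r) draws one standard-normal factor per
subject and mixes it as

    e_i = √r · f_block + √(1−r) · ε_i,

so every pair inside the block has population correlation exactly r while
e_i keeps unit variance.  Thickness is then

    base_i + age_slope·age + gender_offset·gender + noise_sd · e_i.

Group-specific blocks let disparities be planted: :func:`plant_disparity`
lowers group-2 within-ventral correlation and raises within-dorsal
correlation by the same amount, the ground truth the dorsal/ventral
disparity analysis is meant to recover.

Default cohort dimensions mirror the study design the pipeline targets:
35 + 32 subjects over 148 cortical ROIs (74 per hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .cohort import Cohort, ROIAtlas
from .errors import SpecError
from .graphs import BinaryNetwork

__all__ = [
    "CorrelationBlock",
    "CohortSpec",
    "generate_cohort",
    "plant_disparity",
    "synthetic_atlas",
    "fixture_graph",
]


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of ROI indices sharing a target within-block correlation."""

    rois: tuple[int, ...]
    r: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(int(i) for i in self.rois))
        if len(set(self.rois)) != len(self.rois):
            raise SpecError(f"duplicate ROI indices in block {self.rois}")
        if not 0.0 <= self.r < 1.0:
            raise SpecError(f"block correlation must lie in [0, 1), got {self.r}")


def _as_blocks(blocks: Iterable) -> tuple[CorrelationBlock, ...]:
    out = []
    for b in blocks:
        if isinstance(b, CorrelationBlock):
            out.append(b)
        else:
            rois, r = b
            out.append(CorrelationBlock(tuple(rois), float(r)))
    return tuple(out)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic two-group cohort.

    Defaults reproduce the target study design: 35 controls + 32 patients,
    148 ROIs, young-adult ages, mild cortical age-thinning, and residual
    noise on the scale of ROI-averaged thickness variability.
    """

    n_group1: int = 35
    n_group2: int = 32
    n_rois: int = 148
    age_mean: float = 24.4          # years
    age_sd: float = 5.0             # years
    gender_prob: float = 0.33       # P(gender code = 1)
    age_slope: float = -0.01        # mm per year of age
    gender_offset: float = 0.05     # mm shift for gender code 1
    base_thickness_mean: float = 2.5  # mm
    base_thickness_sd: float = 0.25   # mm, across ROIs
    noise_sd: float = 0.15            # mm, residual scale
    blocks_group1: tuple[CorrelationBlock, ...] = field(default=())
    blocks_group2: tuple[CorrelationBlock, ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks_group1", _as_blocks(self.blocks_group1))
        object.__setattr__(self, "blocks_group2", _as_blocks(self.blocks_group2))
        if self.n_rois < 4:
            raise SpecError("n_rois must be at least 4")
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise SpecError("both groups need at least 1 subject")
        if not 0.0 <= self.gender_prob <= 1.0:
            raise SpecError("gender_prob must lie in [0, 1]")
        if self.age_sd < 0 or self.base_thickness_sd < 0 or self.noise_sd <= 0:
            raise SpecError("scale parameters must be non-negative (noise_sd > 0)")
        for blocks in (self.blocks_group1, self.blocks_group2):
            seen: set[int] = set()
            for b in blocks:
                if max(b.rois, default=-1) >= self.n_rois:
                    raise SpecError(
                        f"block {b.rois} references ROI beyond n_rois={self.n_rois}"
                    )
                if seen & set(b.rois):
                    raise SpecError(
                        f"overlapping ROI-index sets in block structure: {b.rois}"
                    )
                seen |= set(b.rois)

    def blocks_for_group(self, which: int) -> tuple[CorrelationBlock, ...]:
        if which == 1:
            return self.blocks_group1
        if which == 2:
            return self.blocks_group2
        raise SpecError(f"group must be 1 or 2, got {which}")


def modular_spec(
    n_modules: int = 20,
    within_r: float = 0.5,
    **kwargs,
) -> CohortSpec:
    """Convenience spec whose ROIs partition into equal-size correlated modules.

    Both groups share the same modular structure.  The default module scale
    (~7 ROIs per module on a 148-ROI atlas) mimics the fine-grained
    community structure of empirical covariance networks: many small tightly
    correlated neighborhoods over a diffuse sampling-noise background, which
    places the thresholded graph in the small-world regime.  Coarse,
    lobe-sized modules would instead yield near-disjoint cliques whose
    clustering exceeds even the ring-lattice benchmark.
    """
    spec = CohortSpec(**kwargs)
    edges = np.linspace(0, spec.n_rois, n_modules + 1).astype(int)
    blocks = tuple(
        CorrelationBlock(tuple(range(edges[m], edges[m + 1])), within_r)
        for m in range(n_modules)
        if edges[m + 1] - edges[m] >= 2
    )
    return replace(spec, blocks_group1=blocks, blocks_group2=blocks)


def synthetic_atlas(n_rois: int) -> ROIAtlas:
    """ROIs on a sphere-like grid with Z increasing in ROI index.

    The prescribed Z ordering makes dorsal/ventral assignment controllable:
    with distinct Z values, the upper half of the index range is dorsal.
    Hemisphere alternates left/right so both hemispheres are populated.
    """
    idx = np.arange(n_rois)
    z = -60.0 + 120.0 * idx / max(n_rois - 1, 1)
    radius = 70.0 * np.sqrt(np.clip(1.0 - (z / 62.0) ** 2, 0.05, None))
    angle = np.pi * (3.0 - np.sqrt(5.0)) * idx  # golden-angle spiral
    x = radius * np.cos(angle)
    y = radius * np.sin(angle)
    hemi = np.where(idx % 2 == 0, "left", "right")
    x = np.where(hemi == "left", -np.abs(x), np.abs(x))
    names = tuple(
        f"roi_{'L' if h == 'left' else 'R'}_{i:03d}" for i, h in zip(idx, hemi)
    )
    return ROIAtlas(names=names, hemisphere=tuple(hemi.tolist()), centroids=np.column_stack([x, y, z]))


def _residual_structure(
    rng: np.random.Generator, n_subjects: int, n_rois: int,
    blocks: tuple[CorrelationBlock, ...],
) -> np.ndarray:
    """Unit-variance residual field with the requested block correlations."""
    e = rng.standard_normal((n_subjects, n_rois))
    for b in blocks:
        factor = rng.standard_normal(n_subjects)
        idx = np.asarray(b.rois)
        e[:, idx] = np.sqrt(b.r) * factor[:, None] + np.sqrt(1.0 - b.r) * e[:, idx]
    return e


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic cohort; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_group1 + spec.n_group2
    base = rng.normal(spec.base_thickness_mean, spec.base_thickness_sd, spec.n_rois)
    base = np.clip(base, 1.0, None)  # ROI-mean thickness stays physically plausible
    age = rng.normal(spec.age_mean, spec.age_sd, n_total)
    gender = (rng.random(n_total) < spec.gender_prob).astype(float)
    group = np.concatenate(
        [np.ones(spec.n_group1, dtype=int), np.full(spec.n_group2, 2, dtype=int)]
    )
    e = np.empty((n_total, spec.n_rois))
    e[: spec.n_group1] = _residual_structure(
        rng, spec.n_group1, spec.n_rois, spec.blocks_group1
    )
    e[spec.n_group1:] = _residual_structure(
        rng, spec.n_group2, spec.n_rois, spec.blocks_group2
    )
    thickness = (
        base[None, :]
        + spec.age_slope * age[:, None]
        + spec.gender_offset * gender[:, None]
        + spec.noise_sd * e
    )
    ids = tuple(
        f"{'C' if g == 1 else 'P'}{i + 1:03d}" for i, g in enumerate(group)
    )
    return Cohort(
        thickness=thickness,
        age=age,
        gender=gender,
        group=group,
        atlas=synthetic_atlas(spec.n_rois),
        subject_ids=ids,
    )


def plant_disparity(
    spec: CohortSpec,
    ventral_rois: Iterable[int],
    dorsal_rois: Iterable[int],
    delta_r: float,
) -> CohortSpec:
    """Plant a dorsal-up / ventral-down connectivity alteration in group 2.

    Group-2 blocks are derived from group-1 blocks: any block fully inside
    ``ventral_rois`` has its correlation reduced by ``delta_r``, any block
    fully inside ``dorsal_rois`` raised by ``delta_r``; other blocks are
    copied unchanged.  The resulting correlations must stay in [0, 1).
    """
    ventral = set(int(i) for i in ventral_rois)
    dorsal = set(int(i) for i in dorsal_rois)
    if ventral & dorsal:
        raise SpecError("ventral and dorsal ROI sets must be disjoint")
    new_blocks = []
    for b in spec.blocks_group1:
        rois = set(b.rois)
        if rois <= ventral:
            r = b.r - delta_r
        elif rois <= dorsal:
            r = b.r + delta_r
        else:
            r = b.r
        if not 0.0 <= r < 1.0:
            raise SpecError(
                f"planted correlation {r:.3f} out of [0, 1) for block {b.rois}"
            )
        new_blocks.append(CorrelationBlock(b.rois, r))
    return replace(spec, blocks_group2=tuple(new_blocks))


_FIXTURE_KINDS = ("path", "complete", "empty", "ring_lattice", "star", "disconnected_pair")


def fixture_graph(kind: str, n: int) -> BinaryNetwork:
    """Small deterministic graphs of a named family, for oracle testing.

    ``disconnected_pair`` splits the nodes into two cliques with no edges
    between them, so cross-component distances are infinite.
    """
    if n < 1:
        raise SpecError("n must be at least 1")
    adj = np.zeros((n, n), dtype=np.int8)
    if kind == "path":
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = 1
    elif kind == "complete":
        adj[:] = 1
        np.fill_diagonal(adj, 0)
    elif kind == "empty":
        pass
    elif kind == "ring_lattice":
        for i in range(n):
            j = (i + 1) % n
            if i != j:
                adj[i, j] = adj[j, i] = 1
    elif kind == "star":
        adj[0, 1:] = adj[1:, 0] = 1
    elif kind == "disconnected_pair":
        half = (n + 1) // 2
        adj[:half, :half] = 1
        adj[half:, half:] = 1
        np.fill_diagonal(adj, 0)
    else:
        raise SpecError(f"unknown fixture graph kind {kind!r}; choose from {_FIXTURE_KINDS}")
    return BinaryNetwork(adj, group=kind)
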