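"""Stochastic branching vascular trees emulating choroidal neovascular networks.

A lesion is modelled as a trunk chain radiating from the lesion centre with
recursively branching side chains of decreasing caliber ("tiny capillaries
emanating from the center of the lesion").  The single ``complexity`` knob
controls branching probability and terminal density, and therefore the
fractal dimension and flow area of the rasterized lesion.

Monotonicity in ``complexity`` is enforced by construction: every potential
branch site owns a private random stream keyed by its position in the tree
(not by traversal order), and the site sprouts a branch iff its uniform draw
falls below the complexity-scaled branching probability.  At a fixed seed,
the tree generated at a lower complexity is therefore an exact subtree of
the tree generated at any higher complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Segment", "VesselTree", "generate_vessel_tree", "prune_tree"]

# Per-generation structural constants.  Calibers (µm) strictly decrease with
# generation; chain lengths and branch probabilities taper so that terminal
# capillaries are short and dense.
MAX_GENERATION = 4
CALIBER_UM = (32.0, 18.0, 10.0, 5.5, 3.0)
CHAIN_NODES = (12, 5, 4, 2, 2)      # chain links per branch at each generation
SEGMENT_LEN_MM = (0.17, 0.12, 0.085, 0.06, 0.042)
BRANCH_PROB_SCALE = (0.90, 0.85, 0.80, 0.75)  # scales branching odds, per parent generation
FIELD_MARGIN_MM = 0.15


@dataclass(frozen=True)
class Segment:
    """One straight vessel segment in lesion (field) coordinates, mm."""

    start: tuple[float, float]
    end: tuple[float, float]
    caliber_um: float
    generation: int
    parent: int  # index into VesselTree.segments, -1 for the first trunk link


@dataclass
class VesselTree:
    """A connected rooted tree of vessel segments within a square field."""

    segments: list[Segment]
    root_xy: tuple[float, float]
    field_mm: float
    seed: int

    def __len__(self) -> int:
        return len(self.segments)

    def max_generation(self) -> int:
        return max((s.generation for s in self.segments), default=-1)


_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _node_uniform(seed: int, node_id: tuple[int, ...], salt: int) -> float:
    """Deterministic U(0,1) draw keyed by (seed, tree position, salt).

    Each node owns its own draws independent of traversal order, which is
    what makes tree growth monotone in the complexity parameter.
    """
    h = _splitmix64(int(seed) & _MASK64)
    for part in node_id:
        h = _splitmix64(h ^ ((int(part) + 1) & _MASK64))
    h = _splitmix64(h ^ (salt & _MASK64))
    return h / 2**64


def _clamp(xy: np.ndarray, field_mm: float) -> np.ndarray:
    return np.clip(xy, FIELD_MARGIN_MM, field_mm - FIELD_MARGIN_MM)


def generate_vessel_tree(
    complexity: float,
    field_mm: float = 4.5,
    seed: int = 0,
    size_scale: float = 1.0,
    caliber_scale: float = 1.0,
) -> VesselTree:
    """Grow a seeded stochastic CNV-like tree.

    Parameters
    ----------
    complexity
        Branching intensity in [0, 1].  0 yields a single unbranched trunk
        chain; higher values add nested generations of short capillaries.
    field_mm
        Physical side length of the square field the lesion must stay inside.
    seed
        Reproducibility seed; two calls with identical arguments return
        identical segment lists.
    size_scale
        Multiplies all segment lengths; controls lesion footprint (and hence
        flow surface area) independently of branching complexity.
    caliber_scale
        Multiplies all segment calibers; adjusts flow area through vessel
        width without changing the network's spatial extent.
    """
    if not (0.0 <= complexity <= 1.0):
        raise ValueError(f"complexity must be in [0, 1], got {complexity}")
    if field_mm <= 0:
        raise ValueError("field_mm must be positive")

    root = (field_mm / 2.0, field_mm / 2.0)
    segments: list[Segment] = []

    # Terminal branches shorten as complexity rises (denser, finer periphery).
    len_factor = size_scale * (1.05 - 0.15 * complexity)

    def grow_chain(
        node_id: tuple[int, ...],
        start: np.ndarray,
        heading: float,
        generation: int,
        parent_idx: int,
    ) -> None:
        pos = start
        prev_idx = parent_idx
        for link in range(CHAIN_NODES[generation]):
            link_id = node_id + (link,)
            heading = heading + 0.9 * (_node_uniform(seed, link_id, 1) - 0.5)
            step = (
                SEGMENT_LEN_MM[generation]
                * len_factor
                * (0.7 + 0.6 * _node_uniform(seed, link_id, 2))
            )
            end = _clamp(pos + step * np.array([np.cos(heading), np.sin(heading)]), field_mm)
            segments.append(
                Segment(
                    start=(float(pos[0]), float(pos[1])),
                    end=(float(end[0]), float(end[1])),
                    caliber_um=CALIBER_UM[generation] * caliber_scale,
                    generation=generation,
                    parent=prev_idx,
                )
            )
            prev_idx = len(segments) - 1
            pos = end
            if generation < MAX_GENERATION:
                # Sublinear in complexity so sparse lesions still branch a
                # little; monotone, so subtree nesting is preserved.
                p_branch = BRANCH_PROB_SCALE[generation] * complexity**0.7 if complexity else 0.0
                for slot in (0, 1):
                    site_id = link_id + (slot + 1,)
                    u = _node_uniform(seed, site_id, 3)
                    side = 1.0 if slot == 0 else -1.0
                    branch_heading = heading + side * (
                        0.6 + 0.7 * _node_uniform(seed, site_id, 4)
                    )
                    if u < p_branch:
                        grow_chain(
                            link_id + (slot + 1,),
                            pos,
                            branch_heading,
                            generation + 1,
                            prev_idx,
                        )

    heading0 = 2.0 * np.pi * _node_uniform(seed, (), 0)
    grow_chain((0,), np.asarray(root, dtype=float), heading0, 0, -1)
    return VesselTree(segments=segments, root_xy=root, field_mm=field_mm, seed=seed)


def prune_tree(tree: VesselTree, caliber_threshold_um: float) -> VesselTree:
    """Remove every segment thinner than ``caliber_threshold_um`` and its subtree.

    Emulates the pruning effect of anti-VEGF loading, which erases the tiny
    peripheral capillaries while the trunk persists.  The generation-0 trunk
    chain is always kept, so a threshold above the trunk caliber returns the
    bare trunk; the result remains a connected tree rooted at the same root.
    """
    if caliber_threshold_um < 0:
        raise ValueError("caliber threshold must be non-negative")
    keep: dict[int, int] = {}
    new_segments: list[Segment] = []
    for idx, seg in enumerate(tree.segments):
        parent_kept = seg.parent == -1 or seg.parent in keep
        if not parent_kept:
            continue
        if seg.generation > 0 and seg.caliber_um < caliber_threshold_um:
            continue
        new_parent = -1 if seg.parent == -1 else keep[seg.parent]
        keep[idx] = len(new_segments)
        new_segments.append(replace(seg, parent=new_parent))
    return VesselTree(
        segments=new_segments, root_xy=tree.root_xy, field_mm=tree.field_mm, seed=tree.seed
    )
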