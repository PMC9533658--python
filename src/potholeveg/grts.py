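"""Stratified, spatially balanced site selection (GRTS).

Generalized random tessellation stratified sampling assigns each frame
point a hierarchical base-4 address by recursive quadrant subdivision of
the bounding box, independently permuting the four quadrant digits in every
cell with a seeded counter-based generator.  Sorting a stratum's points by
this randomized address maps two-dimensional space onto a line that
preserves proximity, so a systematic sample with a random start along the
ordering is spatially balanced.  The selected sites are then re-ordered by
reverse hierarchical ordering (base-4 digits of the sample position,
reversed), which makes every prefix of the ordered sample spatially
balanced as well — the first ``n_primary`` sites serve as the designed
sample and the remainder as ordered alternates for replacing primaries
that prove unsampleable.

Equal-inclusion (unweighted) selection only, matching a design whose
analysis is by unweighted category counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SiteFrame",
    "StratumConfig",
    "SelectedSite",
    "SelectionDraw",
    "GRTSError",
    "hierarchical_address",
    "reverse_hierarchical_order",
    "grts_draw",
    "replace_site",
    "read_site_frame",
    "write_draw",
]


class GRTSError(ValueError):
    pass


@dataclass(frozen=True)
class FramePoint:
    site_id: str
    x: float
    y: float
    stratum: str


@dataclass
class SiteFrame:
    """Point frame of candidate sites with stratum labels."""

    points: list[FramePoint]
    bbox: tuple[float, float, float, float] = None  # xmin, ymin, xmax, ymax

    def __post_init__(self) -> None:
        ids = [p.site_id for p in self.points]
        if len(ids) != len(set(ids)):
            raise GRTSError("duplicate site_ids in frame")
        if self.bbox is None and self.points:
            xs = [p.x for p in self.points]
            ys = [p.y for p in self.points]
            self.bbox = (min(xs), min(ys), max(xs), max(ys))
        if self.bbox is not None:
            xmin, ymin, xmax, ymax = self.bbox
            for p in self.points:
                if not (xmin <= p.x <= xmax and ymin <= p.y <= ymax):
                    raise GRTSError(f"{p.site_id} outside bounding box")

    def strata(self) -> list[str]:
        return sorted({p.stratum for p in self.points})

    def stratum_points(self, stratum: str) -> list[FramePoint]:
        return [p for p in self.points if p.stratum == stratum]


@dataclass
class StratumConfig:
    """Per-stratum primary/alternate sample sizes and the global seed."""

    sizes: dict[str, tuple[int, int]]  # stratum -> (n_primary, n_alternate)
    seed: int = 0

    def validate(self, frame: SiteFrame) -> None:
        for stratum, (np_, na) in self.sizes.items():
            avail = len(frame.stratum_points(stratum))
            if np_ + na > avail:
                raise GRTSError(
                    f"stratum {stratum!r}: requested {np_}+{na} sites "
                    f"but frame holds {avail}"
                )


@lru_cache(maxsize=1_000_000)
def _digit_perm(seed: int, level: int, cell: int) -> tuple[int, ...]:
    """Random permutation of the 4 quadrant digits for one cell.

    Keyed by (seed, level, cell index) through a SeedSequence, so the
    permutation for a cell is reproducible and independent of visit order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, level, cell]))
    return tuple(int(v) for v in rng.permutation(4))


def hierarchical_address(
    point: tuple[float, float],
    bbox: tuple[float, float, float, float],
    depth: int,
    seed: Optional[int] = None,
) -> str:
    """Randomized hierarchical base-4 address of a point.

    At each level the current cell is split into quadrants; the point's
    quadrant index (0=SW, 1=SE, 2=NW, 3=NE) is remapped through that cell's
    seeded digit permutation (identity when ``seed`` is None).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    x, y = point
    xmin, ymin, xmax, ymax = bbox
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        raise GRTSError(f"point {point} outside bounding box {bbox}")
    digits = []
    cell = 0  # index of the current cell in row-major order of its level
    for level in range(depth):
        xmid, ymid = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
        qx = int(x > xmid)
        qy = int(y > ymid)
        q = 2 * qy + qx
        if seed is None:
            d = q
        else:
            d = int(_digit_perm(seed, level, cell)[q])
        digits.append(str(d))
        cell = cell * 4 + q
        xmin, xmax = (xmid, xmax) if qx else (xmin, xmid)
        ymin, ymax = (ymid, ymax) if qy else (ymin, ymid)
    return "".join(digits)


def reverse_hierarchical_order(n: int) -> np.ndarray:
    """Permutation of range(n): positions sorted by reversed base-4 digits.

    Visiting an ordered systematic sample in this order makes every prefix
    spread over the sampled line — hence over space — as evenly as possible.
    """
    if n <= 1:
        return np.arange(n)
    depth = 1
    while 4**depth < n:
        depth += 1
    keys = []
    for i in range(4**depth):
        digits = []
        v = i
        for _ in range(depth):
            digits.append(v % 4)
            v //= 4
        # digits are least-significant first, so reading them most-significant
        # first yields the reversed-digit sort key
        rev = sum(d * 4 ** (depth - 1 - k) for k, d in enumerate(digits))
        keys.append((rev, i))
    order = [i for _, i in sorted(keys) if i < n]
    return np.array(order)


@dataclass
class SelectedSite:
    site_id: str
    stratum: str
    order_rank: int  # position in reverse-hierarchical sample order
    role: str  # "primary" | "alternate"
    replaced_by: Optional[str] = None


@dataclass
class SelectionDraw:
    """Ordered stratified draw with primary/alternate roles and replacements."""

    sites: list[SelectedSite]
    seed: int
    replacement_log: list[tuple[str, str, str]] = field(default_factory=list)

    def by_stratum(self, stratum: str) -> list[SelectedSite]:
        return [s for s in self.sites if s.stratum == stratum]

    def primaries(self) -> list[SelectedSite]:
        return [s for s in self.sites if s.role == "primary" and s.replaced_by is None]

    def alternates(self) -> list[SelectedSite]:
        return [s for s in self.sites if s.role == "alternate"]

    def active(self) -> list[SelectedSite]:
        """Sites currently designated for sampling (primaries after swaps)."""
        return self.primaries()

    def get(self, site_id: str) -> SelectedSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


def _min_unique_depth(
    pts: Sequence[FramePoint], bbox, seed: int, start: int = 4, max_depth: int = 16
) -> int:
    for depth in range(start, max_depth + 1):
        addrs = [hierarchical_address((p.x, p.y), bbox, depth, seed) for p in pts]
        if len(set(addrs)) == len(addrs):
            return depth
    return max_depth


def grts_draw(
    frame: SiteFrame, config: StratumConfig, depth: Optional[int] = None
) -> SelectionDraw:
    """Draw a stratified, spatially balanced sample from a point frame.

    Within each stratum: randomized hierarchical addresses at ``depth``
    levels (default 8, deepened until addresses are unique, ties broken by
    site_id), frame sorted by address, systematic sample of
    n_primary + n_alternate with a seeded random start, sample re-ordered by
    reverse hierarchical ordering; the first n_primary are primaries.
    Deterministic given frame, config and seed.
    """
    config.validate(frame)
    selected: list[SelectedSite] = []
    for si, stratum in enumerate(sorted(config.sizes)):
        n_primary, n_alt = config.sizes[stratum]
        n = n_primary + n_alt
        pts = frame.stratum_points(stratum)
        if not pts:
            raise GRTSError(f"stratum {stratum!r} not present in frame")
        d = depth or max(8, _min_unique_depth(pts, frame.bbox, config.seed, start=8))
        addressed = sorted(
            ((hierarchical_address((p.x, p.y), frame.bbox, d, config.seed), p.site_id, p)
             for p in pts),
            key=lambda t: (t[0], t[1]),
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1_000_003 + si])
        )
        step = len(addressed) / n
        start = rng.uniform(0, step)
        picks = [addressed[int(start + k * step)][2] for k in range(n)]
        order = reverse_hierarchical_order(n)
        ranked = [picks[i] for i in order]
        for rank, p in enumerate(ranked):
            role = "primary" if rank < n_primary else "alternate"
            selected.append(SelectedSite(p.site_id, stratum, rank, role))
    return SelectionDraw(sites=selected, seed=config.seed)


def replace_site(draw: SelectionDraw, site_id: str, reason: str = "") -> SelectionDraw:
    """Replace a primary site with its stratum's next unused alternate.

    Alternates are consumed in reverse-hierarchical order, preserving the
    spatial balance of the active sample; the swap is recorded in the
    replacement log.  Mutates and returns ``draw``.
    """
    site = draw.get(site_id)
    if site.role != "primary":
        raise GRTSError(f"{site_id} is not a primary site")
    if site.replaced_by is not None:
        raise GRTSError(f"{site_id} was already replaced")
    used = {r[1] for r in draw.replacement_log}
    candidates = [
        s for s in draw.by_stratum(site.stratum)
        if s.role == "alternate" and s.site_id not in used
    ]
    if not candidates:
        raise GRTSError(f"stratum {site.stratum!r}: no alternates remain")
    alt = min(candidates, key=lambda s: s.order_rank)
    site.replaced_by = alt.site_id
    alt.role = "primary"
    draw.replacement_log.append((site_id, alt.site_id, reason))
    return draw


def read_site_frame(path: Union[str, Path]) -> SiteFrame:
    """Read a frame from delimited text with header site_id,x,y,stratum."""
    df = pd.read_csv(path, dtype={"site_id": str, "stratum": str})
    missing = [c for c in ("site_id", "x", "y", "stratum") if c not in df.columns]
    if missing:
        raise GRTSError(f"{path}: missing columns {missing}")
    pts = [
        FramePoint(r.site_id, float(r.x), float(r.y), r.stratum)
        for r in df.itertuples(index=False)
    ]
    return SiteFrame(points=pts)


def write_frame(frame: SiteFrame, path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(p.site_id, p.x, p.y, p.stratum) for p in frame.points],
        columns=["site_id", "x", "y", "stratum"],
    ).to_csv(path, index=False)


def write_draw(draw: SelectionDraw, path: Union[str, Path]) -> None:
    """Write a draw as delimited text: site_id,stratum,order_rank,role,replaced_by."""
    pd.DataFrame(
        [
            (s.site_id, s.stratum, s.order_rank, s.role, s.replaced_by or "")
            for s in sorted(draw.sites, key=lambda s: (s.stratum, s.order_rank))
        ],
        columns=["site_id", "stratum", "order_rank", "role", "replaced_by"],
    ).to_csv(path, index=False)
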