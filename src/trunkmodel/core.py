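"""Sapwood and heartwood trunk profiles from pipe-model and branch-thinning theory.

The trunk model predicts the cross-sectional sapwood and heartwood areas of a
tree trunk at any height from breast height upward.  It combines two classical
ideas:

* the simple pipe model of plant form — conductive (sapwood) area at a height
  is proportional to the amount of foliage above it, each leaf unit being
  served by a pipe of fixed area; disused pipes, whose foliage has died,
  accumulate as heartwood; and
* a branch-thinning model — every branch (including the whole tree) grows in
  discrete growth cycles, each terminal bud forming ``mu`` new tips per cycle,
  while an age-dependent carrying capacity ``K(n) = alpha * (n + 1)**d`` caps
  the number of tips a branch of age ``n`` cycles can sustain, excess
  sub-branches being discarded.

Leaves live for ``l_g`` growth cycles.  Leaves currently on the tree above a
height of ``h`` growth modules define the sapwood pipe count ``F_S(h, n)``;
leaves that once were there but have died (by age or by branch thinning)
define the heartwood pipe count ``F_H(h, n)``.  A fraction ``kappa`` of the
pipes stays on the trunk at each ramification passed on the way up, so the
trunk share of the pipes at height ``h`` is ``kappa ** log2(g(h, n))`` where
``g(h, n)`` is the expected number of growth modules at distance ``h``.  The
trunk areas are then

    S_area(h, n) = kappa**log2(g(h, n)) * c_S * F_S(h, n)
    H_area(h, n) = kappa**log2(g(h, n)) * c_H * F_H(h, n)

with ``c_S`` and ``c_H`` the sapwood and heartwood area per pipe.

The module is organised in the order the method runs:

1.  domain types (parameters, tree metadata, measured/predicted profiles);
2.  closed-form model (tip counts, module counts, leaf censuses, profiles);
3.  agent-based growth simulator (independent oracle and data generator);
4.  calibration (pattern-search least squares, prediction, goodness of fit);
5.  delimited-text / JSON input-output and the command-line interface.
"""

from __future__ import annotations

import argparse
import dataclasses
import io
import json
import logging
import math
import sys
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__version__ = "0.1.0"

logger = logging.getLogger("trunkmodel")

#: Relative tolerance used when comparing tip counts against a carrying
#: capacity; guards against spurious thinning triggered by round-off.
_CAP_RTOL = 1e-12

_DEFAULT_BREAST_HEIGHT = 1.3


def _setup_logging(verbose: bool = False) -> None:
    """Route structured log lines (timestamp, level, event) to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def _round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero upward."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# 1. Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Branch-thinning parameters plus the leaf life span, in growth-cycle units.

    Parameters
    ----------
    alpha : float
        Proportionality constant of the branch carrying capacity (tips).
        Must be positive.
    d : float
        Exponent of the branch carrying capacity (dimensionless, positive).
        ``d ~ 3`` if tips compete for space, ``1 <= d <= 3`` if for light.
    mu : float
        Expected number of tips formed at each growth module per cycle.
        Must exceed 1 for the tree to grow.
    l_g : int
        Number of growth cycles a leaf stays on the tree (non-negative).
    """

    alpha: float
    d: float
    mu: float
    l_g: int

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.d > 0):
            raise ValueError(f"d must be positive, got {self.d}")
        if not (self.mu > 1):
            raise ValueError(f"mu must exceed 1, got {self.mu}")
        if not (isinstance(self.l_g, (int, np.integer)) and self.l_g >= 0):
            raise ValueError(f"l_g must be a non-negative integer, got {self.l_g}")


@dataclass(frozen=True)
class TrunkParams:
    """Trunk partition fraction and pipe areas.

    ``kappa`` is the fraction of pipes that remains on the trunk after each
    branching point, traversed base to tip; ``c_S`` and ``c_H`` are the
    sapwood and heartwood cross-sectional area per pipe (any consistent area
    unit).  ``c_H = 0`` (or ``c_S = 0``) encodes a degenerate tree in which
    the corresponding compartment is absent.
    """

    kappa: float
    c_S: float
    c_H: float

    def __post_init__(self) -> None:
        if not (0 < self.kappa <= 1):
            raise ValueError(f"kappa must be in (0, 1], got {self.kappa}")
        if self.c_S < 0 or self.c_H < 0:
            raise ValueError("pipe areas must be non-negative")


@dataclass(frozen=True)
class TreeMetadata:
    """Bridge between physical units and growth-cycle units for one tree.

    The number of growth cycles is ``n = round(age_years * cycles_per_year)``
    (ties rounded half up; cycles are discrete) and the average growth-module
    length is ``height / n``.
    """

    age_years: float
    height: float
    cycles_per_year: int
    breast_height: float = _DEFAULT_BREAST_HEIGHT
    species_label: str = ""
    location_label: str = ""

    def __post_init__(self) -> None:
        if not (self.age_years > 0):
            raise ValueError("age_years must be positive")
        if not (self.height > 0):
            raise ValueError("height must be positive")
        if not (isinstance(self.cycles_per_year, (int, np.integer)) and self.cycles_per_year >= 1):
            raise ValueError("cycles_per_year must be a positive integer")
        if not (0 < self.breast_height < self.height):
            raise ValueError("breast_height must lie strictly below tree height")
        if self.n_cycles < 2:
            raise ValueError(
                f"age {self.age_years} y at {self.cycles_per_year} cycles/y "
                f"gives n = {self.n_cycles} < 2 growth cycles"
            )

    @property
    def n_cycles(self) -> int:
        """Tree age in growth cycles."""
        return _round_half_up(self.age_years * self.cycles_per_year)

    @property
    def module_length(self) -> float:
        """Average physical length of one growth module."""
        return self.height / self.n_cycles

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Profile:
    """Paired (height, sapwood area, heartwood area) series.

    Heights are physical (same length unit as the tree height), strictly
    increasing; areas are non-negative in a consistent area unit.  ``kind``
    distinguishes measured from model-predicted profiles.
    """

    heights: np.ndarray
    sapwood_areas: np.ndarray
    heartwood_areas: np.ndarray
    kind: str = "measured"

    def __post_init__(self) -> None:
        object.__setattr__(self, "heights", np.asarray(self.heights, dtype=float))
        object.__setattr__(self, "sapwood_areas", np.asarray(self.sapwood_areas, dtype=float))
        object.__setattr__(self, "heartwood_areas", np.asarray(self.heartwood_areas, dtype=float))
        if self.kind not in ("measured", "predicted"):
            raise ValueError(f"kind must be 'measured' or 'predicted', got {self.kind!r}")
        k = len(self.heights)
        if k < 2:
            raise ValueError("a profile needs at least 2 measurement heights")
        if len(self.sapwood_areas) != k or len(self.heartwood_areas) != k:
            raise ValueError("heights and area columns must have equal length")
        if not np.all(np.diff(self.heights) > 0):
            raise ValueError("heights must be strictly increasing")
        if np.any(self.heights <= 0):
            raise ValueError("heights must be positive")
        if np.any(self.sapwood_areas < 0) or np.any(self.heartwood_areas < 0):
            raise ValueError("areas must be non-negative")

    @property
    def total_areas(self) -> np.ndarray:
        """Stem (trunk) total cross-sectional area: sapwood plus heartwood."""
        return self.sapwood_areas + self.heartwood_areas

    def __len__(self) -> int:
        return len(self.heights)


# ---------------------------------------------------------------------------
# 2. Closed-form trunk model
# ---------------------------------------------------------------------------


def carrying_capacity(params: GrowthParams, n: int) -> float:
    """Maximum sustainable number of tips ``K(n) = alpha * (n + 1)**d``.

    ``n`` is the branch age in growth cycles; must be non-negative.
    """
    if n < 0:
        raise ValueError(f"branch age must be non-negative, got {n}")
    return params.alpha * (n + 1) ** params.d


def _log_b(params: GrowthParams, k: int) -> float:
    # log of b(k) = min(mu**k, alpha*(k+1)**d), stable for large k.
    return min(k * math.log(params.mu),
               math.log(params.alpha) + params.d * math.log(k + 1))


def _log_b_array(params: GrowthParams, n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return np.minimum(k * math.log(params.mu),
                      math.log(params.alpha) + params.d * np.log(k + 1.0))


def expected_tips(params: GrowthParams, n: int) -> float:
    """Expected number of tips ``b(n) = min(mu**n, K(n))`` on a branch of age ``n``.

    Growth is initially geometric in the cycle count and later capped by the
    carrying capacity.  ``b(0) = min(1, alpha)``: a seedling carries one tip
    unless the capacity is below one.
    """
    if n < 0:
        raise ValueError(f"branch age must be non-negative, got {n}")
    return math.exp(_log_b(params, n))


def module_count(params: GrowthParams, l: int, n: int) -> float:
    """Expected number of growth modules ``g(l, n) = b(n) / b(n - l)``.

    ``g(l, n)`` counts modules at a distance of ``l`` growth cycles from the
    base of a branch ``n`` cycles old, for ``1 <= l <= n``; zero outside that
    range.  The upper end ``g(n, n) = b(n) / b(0)`` counts the newest modules,
    i.e. the tips.
    """
    if n < 1:
        raise ValueError(f"tree age n must be at least 1, got {n}")
    if l < 1 or l > n:
        return 0.0
    return math.exp(_log_b(params, n) - _log_b(params, n - l))


def live_leaf_count(params: GrowthParams, h: int, n: int) -> float:
    """Expected leaves currently on the tree at distance ``>= h``: ``F_S(h, n)``.

    Only modules formed within the last ``l_g`` cycles still carry their leaf,
    so the sum runs over ``l = max(h, n - l_g) .. n``.  Proportional to the
    sapwood pipe count at height ``h``.
    """
    if h < 0:
        raise ValueError(f"height index must be non-negative, got {h}")
    if h > n:
        warnings.warn(f"height index {h} lies above the tree top n={n}; returning 0")
        return 0.0
    if n < 1:
        return 0.0
    lo = max(h, n - params.l_g)
    return sum(module_count(params, l, n) for l in range(lo, n + 1))


def dead_leaf_count(params: GrowthParams, h: int, n: int) -> float:
    """Expected leaves once on the tree at distance ``>= h`` but since lost: ``F_H(h, n)``.

    Two loss channels are book-kept cycle by cycle ``m = h + 1 .. n``:

    * thinning — modules at distance ``l`` present at cycle ``m - 1`` but
      discarded by cycle ``m`` lose their leaf if it was still alive
      (``l >= m - 1 - l_g``), contributing ``g(l, m-1) - g(l, m)``;
    * age — the leaves of the cohort at distance ``l = m - 1 - l_g`` reach the
      end of their life span at cycle ``m``, contributing the surviving module
      count ``g(m - 1 - l_g, m)`` whenever that distance is at or above ``h``.

    The age term is included for ``m - 1 - l_g >= h`` (the cohort at distance
    exactly ``h`` counts: its leaves were at or above ``h``), which makes
    ``F_S + F_H`` conserve the number of leaves ever formed at distance
    ``>= h`` exactly.  Proportional to the heartwood pipe count.
    """
    if h < 0:
        raise ValueError(f"height index must be non-negative, got {h}")
    if h > n:
        warnings.warn(f"height index {h} lies above the tree top n={n}; returning 0")
        return 0.0
    total = 0.0
    for m in range(h + 1, n + 1):
        l_age = m - 1 - params.l_g
        if l_age >= h:
            total += module_count(params, l_age, m)
        if m >= 2:
            for l in range(max(h, l_age), m):
                total += module_count(params, l, m - 1) - module_count(params, l, m)
    return total


def _distance_tables(params: GrowthParams, n: int):
    """Per-distance leaf bookkeeping, vectorised.

    Returns ``(g_n, alive, dead)`` arrays indexed by distance ``l = 0 .. n``:
    current module counts ``g(l, n)``, live-leaf counts (``g(l, n)`` for the
    recent cohorts ``l >= n - l_g``, else 0) and cumulative dead-leaf counts
    (leaves ever formed at ``l``, i.e. ``g(l, l)``, minus those alive).
    """
    lb = _log_b_array(params, n)
    l = np.arange(n + 1)
    g_n = np.exp(lb[n] - lb[n - l])
    g_n[0] = 0.0  # the base itself carries no module
    ever = np.exp(lb - lb[0])
    ever[0] = 0.0
    alive = np.where(n - l <= params.l_g, g_n, 0.0)
    # g(l, l) >= g(l, n) holds analytically (g is non-increasing in tree
    # age); clip round-off so dead-leaf counts are never negative.
    dead = np.maximum(ever - alive, 0.0)
    return g_n, alive, dead


def leaf_census(params: GrowthParams, n: int):
    """``(F_S, F_H)`` arrays over all height indices ``h = 0 .. n`` at once.

    Tail sums of the per-distance live and dead leaf counts; algebraically
    identical to :func:`live_leaf_count` / :func:`dead_leaf_count` but O(n).
    """
    if n < 1:
        raise ValueError(f"tree age n must be at least 1, got {n}")
    _, alive, dead = _distance_tables(params, n)
    f_s = np.cumsum(alive[::-1])[::-1]
    f_h = np.cumsum(dead[::-1])[::-1]
    return f_s, f_h


def trunk_fraction(params: TrunkParams, g_hn: float) -> float:
    """Fraction of the stem pipes that lies on the trunk: ``kappa**log2(g)``.

    ``log2 g(h, n)`` is the expected number of ramifications of the trunk
    below height ``h``; each ramification keeps a fraction ``kappa`` of the
    pipes on the trunk.
    """
    if g_hn < 1:
        raise ValueError(
            f"module count must be >= 1 (got {g_hn}); a value below 1 would "
            "imply a negative number of trunk ramifications"
        )
    return params.kappa ** math.log2(g_hn)


def height_to_cycles(z: float, meta: TreeMetadata) -> int:
    """Map a physical height to the nearest growth-cycle index in ``[0, n]``."""
    if not (0 <= z <= meta.height):
        raise ValueError(
            f"height {z} outside the tree [0, {meta.height}]"
        )
    n = meta.n_cycles
    return min(n, max(0, _round_half_up(z * n / meta.height)))


def trunk_profile(
    gp: GrowthParams,
    tp: TrunkParams,
    meta: TreeMetadata,
    heights: Sequence[float],
) -> Profile:
    """Predicted sapwood and heartwood trunk areas at the given physical heights.

    Each height is mapped to its growth-cycle index ``h``; the trunk areas are
    ``kappa**log2(g(h, n)) * c_S * F_S(h, n)`` and the analogous heartwood
    expression.  The model is only valid from breast height upward: lower
    heights are rejected (butt swell near the ground is outside the model).
    """
    heights = np.asarray(heights, dtype=float)
    if np.any(heights < meta.breast_height):
        bad = heights[heights < meta.breast_height]
        raise ValueError(
            f"heights {bad.tolist()} lie below breast height "
            f"{meta.breast_height}; the trunk model is only valid from breast "
            "height upward"
        )
    n = meta.n_cycles
    g_n, _, _ = _distance_tables(gp, n)
    f_s, f_h = leaf_census(gp, n)
    h_idx = np.array([height_to_cycles(z, meta) for z in heights])
    log2g = np.where(h_idx > 0, np.log2(np.maximum(g_n[h_idx], 1.0)), 0.0)
    frac = tp.kappa ** log2g
    return Profile(
        heights=heights,
        sapwood_areas=frac * tp.c_S * f_s[h_idx],
        heartwood_areas=frac * tp.c_H * f_h[h_idx],
        kind="predicted",
    )


def mean_field_consistent(params: GrowthParams, n: int) -> bool:
    """Whether the closed forms are reachable by the growth process up to age ``n``.

    ``b(m) = min(mu**m, K(m))`` presumes that once the capacity binds it stays
    reachable, i.e. ``mu * b(m - 1) >= K(m)`` at every capacity-bound cycle;
    with ``alpha >= 1`` so that the seedling is not thinned at birth.  Outside
    this regime the simulated process falls below the closed forms (the
    capacity grows faster than the surviving tips can multiply).
    """
    if params.alpha < 1:
        return False
    prev = expected_tips(params, 0)
    for m in range(1, n + 1):
        b_m = expected_tips(params, m)
        if b_m < carrying_capacity(params, m) * (1 - 1e-12):  # geometric phase
            prev = b_m
            continue
        if params.mu * prev < b_m * (1 - 1e-12):
            return False
        prev = b_m
    return True


# ---------------------------------------------------------------------------
# 3. Agent-based growth simulator
# ---------------------------------------------------------------------------
#
# The simulator grows an explicit module graph cycle by cycle and doubles as
# (a) the independent brute-force oracle for the closed forms above and
# (b) a synthetic-profile generator.
#
# Two modes:
#
# * "deterministic" — exact expectation propagation.  Every module carries a
#   real-valued weight (its expected multiplicity).  Tips spawn ceil(mu)
#   children whose weights sum to mu times the parent weight; when a branch
#   overshoots its carrying capacity, the weights of its entire subtree are
#   scaled down proportionally (the expectation of discarding sub-branches
#   uniformly at random).  This forward process never evaluates b, g, F_S or
#   F_H, yet reproduces them exactly in the mean-field-consistent regime.
#
# * "stochastic" — one integer realisation.  Tips spawn floor(mu) plus a
#   Bernoulli(mu - floor(mu)) extra child; the integer capacity is the
#   stochastic rounding floor(K) + Bernoulli(frac(K)) (unbiased with respect
#   to K); excess tips are removed by random-descent discards of whole
#   sub-branches, child chosen with probability proportional to its live tip
#   count, recursing when the chosen sub-branch is larger than the excess, so
#   the realised count lands exactly on the integer capacity.
#
# Leaf bookkeeping (both modes): each surviving new module carries one leaf
# unit.  A module discarded in the very cycle it formed is treated as never
# having developed and is excluded from the "ever formed" census.  A leaf is
# exposed to thinning through cycle birth + l_g + 1 and ages out at the end of
# that cycle; at a census at cycle n it is alive iff n - birth <= l_g.


@dataclass
class SimTree:
    """Explicit module graph with leaf and pipe bookkeeping.

    Modules are stored in parallel lists indexed by module id; ``parent`` is
    ``-1`` for modules attached to the tree base.  ``weight`` is the expected
    multiplicity in deterministic mode (identically 1 for live modules in
    stochastic mode).  ``ever`` is the weight at the end of the birth cycle
    (zero for modules discarded at birth).  Per-module leaf state:
    ``leaf_alive`` plus accumulated ``leaf_dead_thin`` / ``leaf_dead_age``.
    """

    params: GrowthParams
    n: int
    mode: str
    seed: int | None
    parent: list = field(default_factory=list)
    birth: list = field(default_factory=list)
    children: list = field(default_factory=list)
    alive: list = field(default_factory=list)
    weight: list = field(default_factory=list)
    ever: list = field(default_factory=list)
    leaf_alive: list = field(default_factory=list)
    leaf_dead_thin: list = field(default_factory=list)
    leaf_dead_age: list = field(default_factory=list)
    leaf_death_cycle: list = field(default_factory=list)
    leaf_death_cause: list = field(default_factory=list)
    on_trunk: list = field(default_factory=list)
    levels: list = field(default_factory=list)  # node ids per distance

    def n_modules(self) -> int:
        return len(self.parent)

    def to_text(self) -> str:
        """Line-oriented dump, one module per line (debugging aid)."""
        lines = ["id\tparent\tbirth\talive\tweight\tever\tleaf_alive\tleaf_dead_thin\tleaf_dead_age\ton_trunk"]
        for i in range(self.n_modules()):
            lines.append(
                f"{i}\t{self.parent[i]}\t{self.birth[i]}\t{int(self.alive[i])}\t"
                f"{self.weight[i]:.12g}\t{self.ever[i]:.12g}\t{self.leaf_alive[i]:.12g}\t"
                f"{self.leaf_dead_thin[i]:.12g}\t{self.leaf_dead_age[i]:.12g}\t{int(self.on_trunk[i]) if self.on_trunk else 0}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class SimCensus:
    """Per-distance and per-height counts at the final cycle of a grown tree.

    Arrays are indexed by distance/height ``0 .. n``.  ``g_sim[l]`` are live
    module counts; ``f_s[h]`` / ``f_h[h]`` live and lost leaves at distance
    ``>= h``; ``ever[h]`` leaves ever formed at distance ``>= h``;
    ``live_tips`` the tip count of the whole tree.
    """

    n: int
    mode: str
    g_sim: np.ndarray
    f_s: np.ndarray
    f_h: np.ndarray
    ever: np.ndarray
    live_tips: float


def _add_module(tree: SimTree, parent: int, birth: int, weight: float) -> int:
    i = tree.n_modules()
    tree.parent.append(parent)
    tree.birth.append(birth)
    tree.children.append([])
    tree.alive.append(True)
    tree.weight.append(weight)
    tree.ever.append(0.0)
    tree.leaf_alive.append(weight)
    tree.leaf_dead_thin.append(0.0)
    tree.leaf_dead_age.append(0.0)
    tree.leaf_death_cycle.append(None)
    tree.leaf_death_cause.append(None)
    if parent >= 0:
        tree.children[parent].append(i)
    return i


def _scale_node(tree: SimTree, j: int, f: float, m: int, new_this_cycle: bool) -> None:
    # Proportional discard of a fraction (1 - f) of module j's multiplicity.
    lg = tree.params.l_g
    tree.weight[j] *= f
    if tree.leaf_alive[j] > 0.0:
        if new_this_cycle:
            tree.leaf_alive[j] *= f  # never counted as formed
        elif m <= tree.birth[j] + lg + 1:
            tree.leaf_dead_thin[j] += tree.leaf_alive[j] * (1.0 - f)
            tree.leaf_alive[j] *= f


def _grow_deterministic(tree: SimTree, n: int, max_nodes: int) -> None:
    gp = tree.params
    mu, alpha, d, lg = gp.mu, gp.alpha, gp.d, gp.l_g
    n_children = math.ceil(mu)
    w_child = mu / n_children
    tree.levels = [[] for _ in range(n + 1)]
    for m in range(1, n + 1):
        parents = tree.levels[m - 1] if m > 1 else [-1]
        est = len(parents) * n_children + tree.n_modules()
        if est > max_nodes:
            raise MemoryError(
                f"simulated tree would exceed {max_nodes} modules at cycle {m}"
            )
        for p in parents:
            wp = tree.weight[p] if p >= 0 else 1.0
            for _ in range(n_children):
                i = _add_module(tree, p, m, wp * w_child)
                tree.levels[m].append(i)
        # Capacity enforcement, youngest branches first, whole tree last.
        level_w = [math.fsum(tree.weight[j] for j in tree.levels[l]) for l in range(m + 1)]
        tips = level_w[m]
        for a in range(0, m + 1):
            r = m - a
            if a == m:
                tau = tips  # the whole tree, rooted at the base
            else:
                if level_w[r] <= 0.0:
                    continue
                tau = tips / level_w[r]
            cap = alpha * (a + 1) ** d
            if tau <= cap * (1.0 + _CAP_RTOL):
                continue
            f = cap / tau
            lo = m if a == 0 else r + 1  # an age-0 branch is its own module
            for l in range(lo, m + 1):
                for j in tree.levels[l]:
                    _scale_node(tree, j, f, m, tree.birth[j] == m)
                level_w[l] *= f
            tips = level_w[m]
        # Newly surviving modules now count as formed.
        for j in tree.levels[m]:
            tree.ever[j] = tree.weight[j]
        # Age deaths: the cohort of cycle m - lg - 1 reaches the end of life.
        lo_age = m - lg - 1
        if lo_age >= 1:
            for j in tree.levels[lo_age]:
                if tree.leaf_alive[j] > 0.0:
                    tree.leaf_dead_age[j] += tree.leaf_alive[j]
                    tree.leaf_alive[j] = 0.0
                    tree.leaf_death_cycle[j] = tree.birth[j] + lg
                    tree.leaf_death_cause[j] = "age"
    tree.on_trunk = [False] * tree.n_modules()


def _int_capacity(k: float, rng: np.random.Generator) -> int:
    base = math.floor(k)
    fr = k - base
    return base + (1 if (fr > 0 and rng.random() < fr) else 0)


def _discard_subtree(tree: SimTree, root: int, m: int) -> int:
    """Mark a whole sub-branch dead; return the number of live tips removed."""
    lg = tree.params.l_g
    removed = 0
    stack = [root]
    while stack:
        j = stack.pop()
        if not tree.alive[j]:
            continue
        tree.alive[j] = False
        if tree.birth[j] == m:
            removed += 1
            tree.leaf_alive[j] = 0.0  # discarded at birth: never formed
        else:
            if tree.leaf_alive[j] > 0.0 and m <= tree.birth[j] + lg + 1:
                tree.leaf_dead_thin[j] = tree.leaf_alive[j]
                tree.leaf_alive[j] = 0.0
                tree.leaf_death_cycle[j] = m
                tree.leaf_death_cause[j] = "thinning"
        stack.extend(tree.children[j])
    return removed


def _grow_stochastic(tree: SimTree, n: int, rng: np.random.Generator, max_nodes: int) -> None:
    gp = tree.params
    mu, alpha, d, lg = gp.mu, gp.alpha, gp.d, gp.l_g
    mu_lo = math.floor(mu)
    mu_fr = mu - mu_lo
    tree.levels = [[] for _ in range(n + 1)]
    for m in range(1, n + 1):
        parents = [-1] if m == 1 else [j for j in tree.levels[m - 1] if tree.alive[j]]
        for p in parents:
            k = mu_lo + (1 if (mu_fr > 0 and rng.random() < mu_fr) else 0)
            for _ in range(k):
                i = _add_module(tree, p, m, 1.0)
                tree.levels[m].append(i)
        if tree.n_modules() > max_nodes:
            raise MemoryError(
                f"simulated tree would exceed {max_nodes} modules at cycle {m}"
            )
        # Subtree live-tip counts, computed once per cycle bottom-up.
        tips_in = [0] * tree.n_modules()
        for l in range(m, 0, -1):
            for j in tree.levels[l]:
                if not tree.alive[j]:
                    continue
                if l == m:
                    tips_in[j] = 1
                else:
                    tips_in[j] = sum(tips_in[c] for c in tree.children[j] if tree.alive[c])

        def _drop(c: int) -> int:
            removed = _discard_subtree(tree, c, m)
            anc = tree.parent[c]
            tips_in[c] = 0
            while anc >= 0:  # propagate the count change up to the tree base
                tips_in[anc] -= removed
                anc = tree.parent[anc]
            return removed

        def _remove(branch_root: int, excess: int) -> None:
            # Random-descent discard: child chosen with probability
            # proportional to its live-tip count; discard it whole when it
            # fits in the excess, otherwise recurse into it.  A branch whose
            # tips would all be removed is discarded whole.
            if branch_root >= 0 and excess >= tips_in[branch_root]:
                _drop(branch_root)
                return
            while excess > 0:
                v = branch_root
                while True:
                    kids = [c for c in tree.children[v] if tree.alive[c] and tips_in[c] > 0] \
                        if v >= 0 else [j for j in tree.levels[1] if tree.alive[j] and tips_in[j] > 0]
                    if not kids:
                        return
                    w = np.array([tips_in[c] for c in kids], dtype=float)
                    c = kids[rng.choice(len(kids), p=w / w.sum())]
                    if tips_in[c] <= excess:
                        excess -= _drop(c)
                        break
                    v = c

        # Youngest branches first (an age-0 branch is the new module itself),
        # then older branch roots, finally the whole tree.
        if alpha < 1:
            for j in list(tree.levels[m]):
                if tree.alive[j] and 1 > _int_capacity(alpha, rng):
                    _discard_subtree(tree, j, m)
                    tips_in[j] = 0
                    anc = tree.parent[j]
                    while anc >= 0:
                        tips_in[anc] -= 1
                        anc = tree.parent[anc]
        for a in range(1, m):
            cap_val = alpha * (a + 1) ** d
            for j in tree.levels[m - a]:
                if not tree.alive[j] or tips_in[j] == 0:
                    continue
                cap = _int_capacity(cap_val, rng)
                if tips_in[j] > cap:
                    _remove(j, tips_in[j] - cap)
        total = sum(tips_in[j] for j in tree.levels[1] if tree.alive[j])
        cap = _int_capacity(alpha * (m + 1) ** d, rng)
        if total > cap:
            _remove(-1, total - cap)
        for j in tree.levels[m]:
            if tree.alive[j]:
                tree.ever[j] = 1.0
        lo_age = m - lg - 1
        if lo_age >= 1:
            for j in tree.levels[lo_age]:
                if tree.leaf_alive[j] > 0.0:
                    tree.leaf_dead_age[j] = tree.leaf_alive[j]
                    tree.leaf_alive[j] = 0.0
                    tree.leaf_death_cycle[j] = tree.birth[j] + lg
                    tree.leaf_death_cause[j] = "age"
    tree.on_trunk = [False] * tree.n_modules()


def grow(
    gp: GrowthParams,
    n: int,
    mode: str = "deterministic",
    seed: int | None = None,
    max_nodes: int = 2_000_000,
) -> SimTree:
    """Grow a tree for ``n`` cycles under the extended branch-thinning process.

    See the section comment above for the exact semantics of the two modes.
    Deterministic mode propagates expectations and is reproducible without a
    seed; stochastic mode is reproducible given one.
    """
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    tree = SimTree(params=gp, n=n, mode=mode, seed=seed)
    if mode == "deterministic":
        _grow_deterministic(tree, n, max_nodes)
    else:
        rng = np.random.default_rng(seed)
        _grow_stochastic(tree, n, rng, max_nodes)
    return tree


def census(tree: SimTree) -> SimCensus:
    """Exact counts of modules and live/lost leaves per distance and height."""
    n = tree.n
    g_l = np.zeros(n + 1)
    alive_l = np.zeros(n + 1)
    dead_l = np.zeros(n + 1)
    ever_l = np.zeros(n + 1)
    for l in range(1, n + 1):
        for j in tree.levels[l]:
            if tree.alive[j]:
                g_l[l] += tree.weight[j]
            alive_l[l] += tree.leaf_alive[j]
            dead_l[l] += tree.leaf_dead_thin[j] + tree.leaf_dead_age[j]
            ever_l[l] += tree.ever[j]
    return SimCensus(
        n=n,
        mode=tree.mode,
        g_sim=g_l,
        f_s=np.cumsum(alive_l[::-1])[::-1],
        f_h=np.cumsum(dead_l[::-1])[::-1],
        ever=np.cumsum(ever_l[::-1])[::-1],
        live_tips=float(g_l[n]),
    )


def trunk_assign(tree: SimTree, kappa: float, seed: int | None = 0) -> dict:
    """Designate the trunk path and count its ramifications below each height.

    The trunk is the chain of surviving modules from the base to the top:
    the lexicographically-first live child in deterministic mode, a uniformly
    random live child in stochastic mode.  A junction counts as a branching
    event when at least two live branches leave it; ``r_sim(h)`` is the number
    of branching events strictly below height ``h`` (the base junction sits at
    height 0).  Returns ``r_sim``, the realised trunk pipe fractions
    ``kappa**r_sim(h)`` and, for diagnostic comparison, the model's
    approximation ``kappa**log2 g(h, n)``.
    """
    if not (0 < kappa <= 1):
        raise ValueError(f"kappa must be in (0, 1], got {kappa}")
    n = tree.n
    rng = np.random.default_rng(seed)
    tree.on_trunk = [False] * tree.n_modules()
    events = np.zeros(n + 1)  # junction at height l -> events[l]
    node = -1
    for l in range(0, n):
        kids = ([j for j in tree.levels[1] if tree.alive[j]] if node == -1
                else [c for c in tree.children[node] if tree.alive[c]])
        if not kids:  # the chosen chain was thinned away: re-designate
            warnings.warn("trunk path extinct above height %d; stopping there" % l)
            break
        if len(kids) >= 2:
            events[l] = 1.0
        node = kids[0] if tree.mode == "deterministic" else kids[rng.choice(len(kids))]
        tree.on_trunk[node] = True
    r_sim = np.concatenate([[0.0], np.cumsum(events[:-1])])  # events below h
    g_n, _, _ = _distance_tables(tree.params, n)
    log2g = np.where(np.arange(n + 1) > 0, np.log2(np.maximum(g_n, 1.0)), 0.0)
    return {
        "r_sim": r_sim,
        "fraction_sim": kappa ** r_sim,
        "fraction_model": kappa ** log2g,
    }


def synthesize_profile(
    gp: GrowthParams,
    tp: TrunkParams,
    meta: TreeMetadata,
    n_heights: int = 12,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Profile:
    """Generate a synthetic measured profile from the model's closed forms.

    Areas are evaluated on an even grid of ``n_heights`` heights from breast
    height to 95 % of the tree height and perturbed by independent
    multiplicative lognormal(0, ``noise_sigma``) factors; ``noise_sigma = 0``
    reproduces the model exactly.  Emulates the sparse stem-analysis profiles
    the model is calibrated against in practice.
    """
    if n_heights < 4:
        raise ValueError("need at least 4 heights")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    zs = np.linspace(meta.breast_height, 0.95 * meta.height, n_heights)
    exact = trunk_profile(gp, tp, meta, zs)
    s, h = exact.sapwood_areas, exact.heartwood_areas
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s * rng.lognormal(0.0, noise_sigma, size=len(zs))
        h = h * rng.lognormal(0.0, noise_sigma, size=len(zs))
    return Profile(heights=zs, sapwood_areas=s, heartwood_areas=h, kind="measured")


# ---------------------------------------------------------------------------
# 4. Calibration, prediction and goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationSettings:
    """Pattern-search configuration for fitting (alpha, d, mu, kappa).

    The four parameters are optimised on a unit-cube rescaling of their
    bounds (``alpha`` on a log10 scale, the rest linear) so mesh steps are
    comparable across parameters.  ``d`` is expected in roughly [1, 3] on
    geometric grounds; the bounds leave margin on both sides.  ``mu`` must
    exceed 1 for growth; values above 4 are biologically implausible.
    """

    alpha_bounds: tuple = (1.0, 1e5)
    d_bounds: tuple = (0.5, 3.5)
    mu_bounds: tuple = (1.0 + 1e-6, 4.0)
    kappa_bounds: tuple = (1e-6, 1.0)
    initial_point: tuple = (10.0, 1.5, 2.0, 0.8)  # (alpha, d, mu, kappa)
    initial_mesh: float = 0.25
    expansion: float = 2.0
    contraction: float = 0.5
    mesh_tol: float = 1e-6
    max_iter: int = 400
    random_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_bounds", "d_bounds", "mu_bounds", "kappa_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be non-degenerate, got {(lo, hi)}")
        if not (self.expansion > 1 and 0 < self.contraction < 1):
            raise ValueError("need expansion > 1 > contraction > 0")
        if self.mesh_tol <= 0 or self.initial_mesh <= 0:
            raise ValueError("mesh sizes must be positive")
        if self.max_iter < 1 or self.random_restarts < 0:
            raise ValueError("max_iter must be >= 1 and random_restarts >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSettings":
        kw = dict(d)
        for k in ("alpha_bounds", "d_bounds", "mu_bounds", "kappa_bounds", "initial_point"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)


def _decode(x: np.ndarray, s: CalibrationSettings) -> tuple:
    la, ha = math.log10(s.alpha_bounds[0]), math.log10(s.alpha_bounds[1])
    alpha = 10.0 ** (la + x[0] * (ha - la))
    d = s.d_bounds[0] + x[1] * (s.d_bounds[1] - s.d_bounds[0])
    mu = s.mu_bounds[0] + x[2] * (s.mu_bounds[1] - s.mu_bounds[0])
    kappa = s.kappa_bounds[0] + x[3] * (s.kappa_bounds[1] - s.kappa_bounds[0])
    return alpha, d, mu, kappa


def _encode(alpha: float, d: float, mu: float, kappa: float, s: CalibrationSettings) -> np.ndarray:
    la, ha = math.log10(s.alpha_bounds[0]), math.log10(s.alpha_bounds[1])
    x = np.array([
        (math.log10(alpha) - la) / (ha - la),
        (d - s.d_bounds[0]) / (s.d_bounds[1] - s.d_bounds[0]),
        (mu - s.mu_bounds[0]) / (s.mu_bounds[1] - s.mu_bounds[0]),
        (kappa - s.kappa_bounds[0]) / (s.kappa_bounds[1] - s.kappa_bounds[0]),
    ])
    return np.clip(x, 0.0, 1.0)


@dataclass
class PatternSearchResult:
    x: np.ndarray
    fun: float
    iteration_log: list
    n_evaluations: int


def pattern_search(
    f: Callable[[np.ndarray], float],
    settings: CalibrationSettings,
    x0: np.ndarray | None = None,
) -> PatternSearchResult:
    """Generalised pattern search on the unit cube, best of several restarts.

    From each start the 2k axis-direction neighbours at the current mesh size
    are polled; the incumbent moves to the best improving poll and the mesh
    expands, otherwise the mesh contracts; a start terminates when the mesh
    falls below tolerance or the iteration budget is spent.  Iterate values
    are non-increasing and the returned value never exceeds the value at the
    initial point.  Deterministic given ``settings.seed``.
    """
    rng = np.random.default_rng(settings.seed)
    if x0 is None:
        x0 = _encode(*settings.initial_point, settings)
    x0 = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    k = len(x0)
    starts = [x0] + [rng.random(k) for _ in range(settings.random_restarts)]
    best_x, best_f, best_log = None, math.inf, []
    n_eval = 0

    for x_start in starts:
        x = x_start.copy()
        fx = float(f(x))
        n_eval += 1
        if not math.isfinite(fx):
            raise ValueError("objective is not finite at the initial point")
        mesh = settings.initial_mesh
        log = [(0, fx)]
        it = 0
        while mesh >= settings.mesh_tol and it < settings.max_iter:
            it += 1
            cand_f, cand_x = fx, None
            any_finite = False
            for i in range(k):
                for sgn in (1.0, -1.0):
                    xp = x.copy()
                    xp[i] = min(1.0, max(0.0, xp[i] + sgn * mesh))
                    if xp[i] == x[i]:
                        continue
                    fp = float(f(xp))
                    n_eval += 1
                    if math.isfinite(fp):
                        any_finite = True
                        if fp < cand_f:
                            cand_f, cand_x = fp, xp
            if not any_finite:
                raise ValueError("objective not finite at any polled point")
            if cand_x is not None:
                x, fx = cand_x, cand_f
                mesh = min(mesh * settings.expansion, 0.5)
                log.append((it, fx))
            else:
                mesh *= settings.contraction
        log.append((it, fx))
        if fx < best_f:
            best_x, best_f, best_log = x, fx, log
    return PatternSearchResult(x=best_x, fun=best_f, iteration_log=best_log, n_evaluations=n_eval)


def _usable_heights(measured: Profile, meta: TreeMetadata) -> np.ndarray:
    mask = measured.heights >= meta.breast_height
    if mask.sum() < len(measured):
        logger.debug(
            "dropping %d measurement(s) below breast height", int((~mask).sum())
        )
    return mask


def scale_pipe_areas(
    gp: GrowthParams,
    kappa: float,
    measured: Profile,
    meta: TreeMetadata,
) -> tuple:
    """Pipe areas ``(c_S, c_H)`` that match the model to the lowest measurement.

    The measured sapwood (heartwood) area at the first usable height is
    divided by the trunk-model pipe count there,
    ``kappa**log2 g(h_p, n) * F(h_p, n)``.  If a predicted pipe count is zero
    (e.g. no heartwood yet on a young tree) the corresponding area per pipe is
    set to zero, with a warning, so the modelled compartment vanishes.
    """
    mask = _usable_heights(measured, meta)
    if not mask.any():
        raise ValueError("no measurement at or above breast height")
    idx = int(np.argmax(mask))
    s_p = measured.heights[idx]
    n = meta.n_cycles
    h_p = height_to_cycles(s_p, meta)
    g_hp = module_count(gp, h_p, n) if h_p >= 1 else 1.0
    frac = kappa ** math.log2(max(g_hp, 1.0))
    f_s, f_h = leaf_census(gp, n)
    out = []
    for name, star, pipes in (
        ("sapwood", measured.sapwood_areas[idx], frac * f_s[h_p]),
        ("heartwood", measured.heartwood_areas[idx], frac * f_h[h_p]),
    ):
        if pipes <= 0.0:
            if star > 0:
                warnings.warn(
                    f"model predicts no {name} pipes at the scaling height "
                    f"{s_p}; the modelled {name} area is identically zero"
                )
            out.append(0.0)
        else:
            out.append(star / pipes)
    return tuple(out)


def _model_areas(
    gp: GrowthParams, kappa: float, c_s: float, c_h: float,
    meta: TreeMetadata, heights: np.ndarray,
):
    n = meta.n_cycles
    g_n, _, _ = _distance_tables(gp, n)
    f_s, f_h = leaf_census(gp, n)
    h_idx = np.array([height_to_cycles(z, meta) for z in heights])
    log2g = np.where(h_idx > 0, np.log2(np.maximum(g_n[h_idx], 1.0)), 0.0)
    frac = kappa ** log2g
    return frac * c_s * f_s[h_idx], frac * c_h * f_h[h_idx]


def objective(
    gp: GrowthParams,
    kappa: float,
    measured: Profile,
    meta: TreeMetadata,
) -> float:
    """Least-squares calibration error in squared-area units.

    After nested pipe-area scaling at the first usable height, the sum over
    measurement heights of the squared sapwood and heartwood area residuals.
    """
    mask = _usable_heights(measured, meta)
    if mask.sum() < 2:
        raise ValueError("need at least 2 measurement heights at or above breast height")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c_s, c_h = scale_pipe_areas(gp, kappa, measured, meta)
    zs = measured.heights[mask]
    s_mod, h_mod = _model_areas(gp, kappa, c_s, c_h, meta, zs)
    return float(
        np.sum((s_mod - measured.sapwood_areas[mask]) ** 2)
        + np.sum((h_mod - measured.heartwood_areas[mask]) ** 2)
    )


@dataclass
class CalibrationResult:
    """Fitted parameters plus fit diagnostics, sufficient to re-run the fit."""

    growth: GrowthParams
    trunk: TrunkParams
    objective_value: float
    r2: dict
    nrmsd: dict
    meta: TreeMetadata
    settings: CalibrationSettings
    iteration_log: list
    n_evaluations: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "growth": dataclasses.asdict(self.growth),
            "trunk": dataclasses.asdict(self.trunk),
            "objective_value": self.objective_value,
            "r2": self.r2,
            "nrmsd": self.nrmsd,
            "meta": self.meta.to_dict(),
            "settings": self.settings.to_dict(),
            "iteration_log": [[int(i), float(v)] for i, v in self.iteration_log],
            "n_evaluations": self.n_evaluations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            growth=GrowthParams(**d["growth"]),
            trunk=TrunkParams(**d["trunk"]),
            objective_value=d["objective_value"],
            r2=d["r2"],
            nrmsd=d["nrmsd"],
            meta=TreeMetadata(**d["meta"]),
            settings=CalibrationSettings.from_dict(d["settings"]),
            iteration_log=[tuple(t) for t in d["iteration_log"]],
            n_evaluations=d["n_evaluations"],
            version=d.get("version", __version__),
        )


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot`` about the observed mean."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(o) != len(p) or len(o) < 2:
        raise ValueError("need equal-length sequences of at least 2 values")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are all equal")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def nrmsd(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square deviation normalised by the observed range."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(o) != len(p) or len(o) < 2:
        raise ValueError("need equal-length sequences of at least 2 values")
    rng = float(o.max() - o.min())
    if rng == 0.0:
        raise ValueError("NRMSD undefined: observed range is zero")
    return float(np.sqrt(np.mean((o - p) ** 2))) / rng


def _fit_metrics(measured: Profile, predicted: Profile) -> tuple:
    r2, nr = {}, {}
    for name, o, p in (
        ("total", measured.total_areas, predicted.total_areas),
        ("sapwood", measured.sapwood_areas, predicted.sapwood_areas),
        ("heartwood", measured.heartwood_areas, predicted.heartwood_areas),
    ):
        try:
            r2[name] = r_squared(o, p)
            nr[name] = nrmsd(o, p)
        except ValueError:
            logger.debug("degenerate observed %s profile; R^2/NRMSD undefined", name)
            r2[name] = None
            nr[name] = None
    return r2, nr


def calibrate(
    measured: Profile,
    meta: TreeMetadata,
    l_g: int,
    settings: CalibrationSettings | None = None,
) -> CalibrationResult:
    """Fit (alpha, d, mu, kappa) to a measured profile by pattern-search least squares.

    The leaf life span ``l_g`` and the number of growth cycles per year are
    species knowledge fixed a priori, not fitted.  The pipe areas ``c_S`` and
    ``c_H`` are rescaled at the lowest usable measurement inside every
    objective evaluation, so only four parameters are searched.
    """
    if settings is None:
        settings = CalibrationSettings()
    mask = _usable_heights(measured, meta)
    if mask.sum() < 2:
        raise ValueError("need at least 2 measurement heights at or above breast height")

    def f(x: np.ndarray) -> float:
        alpha, d, mu, kappa = _decode(x, settings)
        try:
            gp = GrowthParams(alpha=alpha, d=d, mu=mu, l_g=l_g)
            return objective(gp, kappa, measured, meta)
        except (ValueError, OverflowError):
            return math.inf

    res = pattern_search(f, settings)
    alpha, d, mu, kappa = _decode(res.x, settings)
    gp = GrowthParams(alpha=alpha, d=d, mu=mu, l_g=l_g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c_s, c_h = scale_pipe_areas(gp, kappa, measured, meta)
    tp = TrunkParams(kappa=kappa, c_S=c_s, c_H=c_h)
    fit = trunk_profile(gp, tp, meta, measured.heights[mask])
    obs = Profile(
        heights=measured.heights[mask],
        sapwood_areas=measured.sapwood_areas[mask],
        heartwood_areas=measured.heartwood_areas[mask],
        kind="measured",
    )
    r2, nr = _fit_metrics(obs, fit)
    logger.info(
        "calibrated: alpha=%.4g d=%.4g mu=%.4g kappa=%.4g c_S=%.4g c_H=%.4g "
        "objective=%.4g R2(total)=%s",
        alpha, d, mu, kappa, c_s, c_h, res.fun,
        "n/a" if r2["total"] is None else f"{r2['total']:.4f}",
    )
    return CalibrationResult(
        growth=gp,
        trunk=tp,
        objective_value=res.fun,
        r2=r2,
        nrmsd=nr,
        meta=meta,
        settings=settings,
        iteration_log=res.iteration_log,
        n_evaluations=res.n_evaluations,
    )


def predict(
    cal: CalibrationResult,
    new_meta: TreeMetadata,
    heights: Sequence[float],
) -> Profile:
    """Profile of a conspecific tree from its age and height alone.

    Re-derives the cycle count and module length from ``new_meta`` and applies
    the calibrated parameters — including the pipe areas ``c_S`` and ``c_H`` —
    unchanged; prediction uses no measurement of the new tree.
    """
    return trunk_profile(cal.growth, cal.trunk, new_meta, heights)


def pipe_model_baseline(
    measured: Profile,
    gp: GrowthParams,
    meta: TreeMetadata,
) -> Profile:
    """Simple-pipe-model baseline: the whole trunk area treated as sapwood pipes.

    The trunk area is modelled as ``c * F_S(h, n)`` with the single constant
    ``c`` scaled so the modelled area matches the measured *total* area at the
    first usable height (the classical model takes the area at breast height
    to be sapwood).  No heartwood, no trunk-fraction attenuation — which is
    why this baseline overestimates the area in the crown.
    """
    mask = _usable_heights(measured, meta)
    if mask.sum() < 2:
        raise ValueError("need at least 2 measurement heights at or above breast height")
    zs = measured.heights[mask]
    n = meta.n_cycles
    f_s, _ = leaf_census(gp, n)
    h_idx = np.array([height_to_cycles(z, meta) for z in zs])
    idx0 = 0
    total0 = (measured.sapwood_areas[mask] + measured.heartwood_areas[mask])[idx0]
    denom = f_s[h_idx[idx0]]
    c = total0 / denom if denom > 0 else 0.0
    return Profile(
        heights=zs,
        sapwood_areas=c * f_s[h_idx],
        heartwood_areas=np.zeros(len(zs)),
        kind="predicted",
    )


# ---------------------------------------------------------------------------
# 5. Input/output and command-line interface
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ("height", "sapwood_area", "heartwood_area")


def read_profile(path: str) -> Profile:
    """Read a profile from delimited text.

    Comma-separated with header columns ``height``, ``sapwood_area`` and
    ``heartwood_area``; lines starting with ``#`` are comments.  Rows are
    sorted by height; duplicate heights and negative areas are reported with
    the offending line number.  Units are passed through unchanged and must be
    consistent within a file.
    """
    with open(path) as fh:
        raw = fh.readlines()
    data_lines, line_nos = [], []
    for i, line in enumerate(raw, start=1):
        if line.strip() == "" or line.lstrip().startswith("#"):
            continue
        data_lines.append(line)
        line_nos.append(i)
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    try:
        df = pd.read_csv(io.StringIO("".join(data_lines)))
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header has {list(df.columns)}")
    rows = line_nos[1:]  # data rows, header excluded
    if len(rows) != len(df):
        rows = list(range(2, len(df) + 2))  # fallback numbering
    for col in _PROFILE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} value {df[col].iloc[bad[0]]!r} on line {rows[bad[0]]}"
            )
        df[col] = vals
    neg = np.where((df["sapwood_area"] < 0) | (df["heartwood_area"] < 0))[0]
    if len(neg):
        raise ValueError(f"{path}: negative area on line {rows[neg[0]]}")
    order = np.argsort(df["height"].to_numpy(), kind="stable")
    hts = df["height"].to_numpy()[order]
    dup = np.where(np.diff(hts) <= 0)[0]
    if len(dup):
        raise ValueError(
            f"{path}: duplicated height {hts[dup[0] + 1]} on line {rows[order[dup[0] + 1]]}"
        )
    return Profile(
        heights=hts,
        sapwood_areas=df["sapwood_area"].to_numpy()[order],
        heartwood_areas=df["heartwood_area"].to_numpy()[order],
        kind="measured",
    )


def write_profile(profile: Profile, path: str, provenance: dict | None = None) -> None:
    """Write a profile as delimited text, with provenance in comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# trunkmodel v{__version__} profile kind={profile.kind}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(",".join(_PROFILE_COLUMNS) + "\n")
        for z, s, h in zip(profile.heights, profile.sapwood_areas, profile.heartwood_areas):
            fh.write(f"{z:.17g},{s:.17g},{h:.17g}\n")


def write_result(cal: CalibrationResult, path: str) -> None:
    """Serialise a calibration result as JSON (parameters, metrics, settings, seed)."""
    with open(path, "w") as fh:
        json.dump(cal.to_dict(), fh, indent=2)
        fh.write("\n")


def read_result(path: str) -> CalibrationResult:
    with open(path) as fh:
        return CalibrationResult.from_dict(json.load(fh))


@dataclass
class RunConfig:
    """Validated run configuration: tree metadata, species knowledge, settings.

    ``l_g`` is derived as ``round(leaf_lifespan_years * cycles_per_year)``.
    """

    meta: TreeMetadata
    l_g: int
    settings: CalibrationSettings
    growth: GrowthParams | None = None
    trunk: TrunkParams | None = None
    seed: int = 0
    n_heights: int = 12
    noise_sigma: float = 0.0


def load_config(path: str) -> RunConfig:
    """Load a JSON (or YAML, as a convenience dialect) run configuration."""
    with open(path) as fh:
        text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        try:
            import yaml

            raw = yaml.safe_load(text)
        except Exception as exc:
            raise ValueError(f"{path}: neither valid JSON nor YAML: {exc}") from exc
    if not isinstance(raw, dict) or "tree" not in raw:
        raise ValueError(f"{path}: config must be a mapping with a 'tree' block")
    meta = TreeMetadata(**raw["tree"])
    species = raw.get("species", {})
    lifespan = species.get("leaf_lifespan_years", 0.0)
    l_g = _round_half_up(lifespan * meta.cycles_per_year)
    if l_g < 0:
        raise ValueError("leaf life span must be non-negative")
    settings = CalibrationSettings.from_dict(raw.get("calibration", {}))
    seed = int(raw.get("seed", 0))
    if "seed" in raw and "calibration" in raw and "seed" not in raw["calibration"]:
        settings = dataclasses.replace(settings, seed=seed)
    elif "seed" in raw and "calibration" not in raw:
        settings = dataclasses.replace(settings, seed=seed)
    growth = trunk = None
    if "parameters" in raw:
        p = raw["parameters"]
        growth = GrowthParams(alpha=p["alpha"], d=p["d"], mu=p["mu"], l_g=l_g)
        trunk = TrunkParams(kappa=p["kappa"], c_S=p["c_sapwood"], c_H=p["c_heartwood"])
    return RunConfig(
        meta=meta,
        l_g=l_g,
        settings=settings,
        growth=growth,
        trunk=trunk,
        seed=seed,
        n_heights=int(raw.get("n_heights", 12)),
        noise_sigma=float(raw.get("noise_sigma", 0.0)),
    )


def _cmd_simulate(args: argparse.Namespace) -> int:
    cfg = load_config(args.config)
    if cfg.growth is None or cfg.trunk is None:
        raise ValueError("simulate requires a 'parameters' block in the config")
    seed = cfg.seed if args.seed is None else args.seed
    sigma = cfg.noise_sigma if args.noise is None else args.noise
    prof = synthesize_profile(
        cfg.growth, cfg.trunk, cfg.meta,
        n_heights=cfg.n_heights, noise_sigma=sigma, seed=seed,
    )
    write_profile(prof, args.out, provenance={
        "command": "simulate", "seed": seed, "noise_sigma": sigma,
        "alpha": cfg.growth.alpha, "d": cfg.growth.d, "mu": cfg.growth.mu,
        "l_g": cfg.growth.l_g, "kappa": cfg.trunk.kappa,
        "c_sapwood": cfg.trunk.c_S, "c_heartwood": cfg.trunk.c_H,
        "age_years": cfg.meta.age_years, "height": cfg.meta.height,
        "cycles_per_year": cfg.meta.cycles_per_year,
    })
    logger.info("wrote synthetic profile with %d heights to %s", len(prof), args.out)
    return 0


def _cmd_calibrate(args: argparse.Namespace) -> int:
    cfg = load_config(args.config)
    settings = cfg.settings
    if args.seed is not None:
        settings = dataclasses.replace(settings, seed=args.seed)
    measured = read_profile(args.profile)
    cal = calibrate(measured, cfg.meta, cfg.l_g, settings)
    write_result(cal, args.out)
    for q in ("total", "sapwood", "heartwood"):
        r2 = cal.r2[q]
        nr = cal.nrmsd[q]
        print(f"{q:<10} R2={'n/a' if r2 is None else format(r2, '.4f')} "
              f"NRMSD={'n/a' if nr is None else format(nr, '.4f')}")
    logger.info("wrote calibration result to %s", args.out)
    return 0


def _cmd_predict(args: argparse.Namespace) -> int:
    cal = read_result(args.result)
    new_meta = dataclasses.replace(
        cal.meta, age_years=args.age, height=args.height,
    )
    zs = np.linspace(new_meta.breast_height, 0.95 * new_meta.height, args.n_heights)
    prof = predict(cal, new_meta, zs)
    write_profile(prof, args.out, provenance={
        "command": "predict", "result": args.result,
        "age_years": args.age, "height": args.height,
    })
    logger.info("wrote predicted profile with %d heights to %s", len(prof), args.out)
    return 0


def _cmd_evaluate(args: argparse.Namespace) -> int:
    obs = read_profile(args.observed)
    pred = read_profile(args.predicted)
    if len(obs) != len(pred) or not np.allclose(obs.heights, pred.heights, rtol=1e-9):
        raise ValueError("observed and predicted profiles must share the same heights")
    r2, nr = _fit_metrics(obs, pred)
    for q in ("total", "sapwood", "heartwood"):
        print(f"{q:<10} R2={'n/a' if r2[q] is None else format(r2[q], '.4f')} "
              f"NRMSD={'n/a' if nr[q] is None else format(nr[q], '.4f')}")
    if args.baseline:
        if not args.result:
            raise ValueError("--baseline requires --result for the fitted growth parameters")
        cal = read_result(args.result)
        base = pipe_model_baseline(obs, cal.growth, cal.meta)
        r2b = r_squared(obs.total_areas, base.total_areas)
        print(f"{'baseline':<10} R2={r2b:.4f} (simple pipe model, total area)")
    return 0


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="trunkmodel",
        description="Sapwood/heartwood trunk profiles: simulate, calibrate, predict, evaluate.",
    )
    p.add_argument("-v", "--verbose", action="store_true", help="debug logging")
    sub = p.add_subparsers(dest="command", required=True)

    s = sub.add_parser("simulate", help="write a synthetic profile from a config")
    s.add_argument("--config", required=True)
    s.add_argument("--out", required=True)
    s.add_argument("--noise", type=float, default=None, help="lognormal sigma override")
    s.add_argument("--seed", type=int, default=None)
    s.set_defaults(func=_cmd_simulate)

    c = sub.add_parser("calibrate", help="fit the trunk model to a measured profile")
    c.add_argument("--profile", required=True)
    c.add_argument("--config", required=True)
    c.add_argument("--out", required=True)
    c.add_argument("--seed", type=int, default=None)
    c.set_defaults(func=_cmd_calibrate)

    r = sub.add_parser("predict", help="predict a conspecific tree from age and height")
    r.add_argument("--result", required=True)
    r.add_argument("--age", type=float, required=True)
    r.add_argument("--height", type=float, required=True)
    r.add_argument("--out", required=True)
    r.add_argument("--n-heights", type=int, default=12)
    r.set_defaults(func=_cmd_predict)

    e = sub.add_parser("evaluate", help="R2 and NRMSD of a prediction against observations")
    e.add_argument("--observed", required=True)
    e.add_argument("--predicted", required=True)
    e.add_argument("--baseline", action="store_true",
                   help="also report the simple-pipe-model baseline")
    e.add_argument("--result", default=None,
                   help="calibration result JSON (needed for --baseline)")
    e.set_defaults(func=_cmd_evaluate)
    return p


def main(argv: Sequence[str] | None = None) -> int:
    """Command-line entry point; returns the process exit code."""
    parser = build_parser()
    args = parser.parse_args(argv)
    _setup_logging(args.verbose)
    try:
        return args.func(args)
    except FileNotFoundError as exc:
        logger.error("file not found: %s", exc.filename or exc)
        print(f"error: file not found: {exc.filename or exc}", file=sys.stderr)
        return 2
    except (ValueError, KeyError, TypeError) as exc:
        logger.error("%s", exc)
        print(f"error: {exc}", file=sys.stderr)
        return 2


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
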