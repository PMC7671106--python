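"""Seeded synthetic-data generators with the statistical structure the
analysis assumes.

The generators emulate the shape of the real inputs -- a birth-death
phylogeny, multivariate Brownian trait evolution with optional group mean
shifts, Dirichlet diet-importance profiles concentrated on a focal prey
category, and block-structured binary prey-trait matrices with flip noise --
so that every pipeline stage is testable end to end without any downloads.
They target statistical structure only, not the empirical distributions of
any particular measurement set.

All generators are bit-reproducible given (seed, configuration).  A single
run seed is spawned into independent sub-streams per generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diet import DietRecord, DietRecordSet
from .prey import PreyTraitMatrix

__all__ = [
    "SynthConfig",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_diet_profiles",
    "simulate_prey_traits",
]


@dataclass
class SynthConfig:
    """Configuration for the synthetic study.

    Defaults mirror the real study's dimensions: 54 species, 7 characters,
    6 prey categories, diets strongly concentrated on one focal category.
    """

    seed: int = 0
    n_species: int = 54
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_characters: int = 7
    bm_rate: float = 1.0
    group_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    # diet generation
    focal_weight: float = 0.8
    concentration: float = 10.0
    # prey-trait blocks
    n_blocks: int = 6
    items_per_block: int = 5
    traits_per_block: int = 4
    p_flip: float = 0.01

    def __post_init__(self) -> None:
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValueError("need birth rate > death rate >= 0")
        if not 0 <= self.p_flip < 0.5:
            raise ValueError("p_flip must be in [0, 0.5)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> dendropy.Tree:
    """Birth-death tree conditioned on ``n_species`` extant tips.

    Simulation retries (up to ``max_retries``) rather than GSA sampling; the
    resulting mild conditioning bias is acceptable for generating test data.
    Tips are labelled ``sp01..spNN``.
    """
    if birth_rate <= death_rate or death_rate < 0:
        raise ValueError("need birth rate > death rate >= 0")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_species,
                rng=rng,
            )
            break
        except Exception as err:  # extinct replicate: retry
            last_err = err
    else:
        raise RuntimeError(
            f"no surviving tree with {n_species} tips in {max_retries} tries"
        ) from last_err
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    # guard against zero-length edges (ultrametric simulators can emit them)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and (edge.length is None or edge.length <= 0):
            edge.length = 1e-9
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    rate: float | np.ndarray = 1.0,
    n_characters: int | None = None,
    group_shifts: dict[str, np.ndarray] | None = None,
    groups: dict[str, str] | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Multivariate Brownian motion along the tree from a zero root state.

    ``rate`` is either a scalar (isotropic) or a positive-definite p x p rate
    matrix; tip covariance equals rate x shared path length.  Optional group
    mean shifts are added at the tips: ``groups`` maps tip label -> group
    label and ``group_shifts`` maps group label -> length-p shift vector.
    Returns tip label -> trait vector.
    """
    if n_characters is None:
        n_characters = (
            rate.shape[0] if isinstance(rate, np.ndarray) else 1
        )
    p = n_characters
    if isinstance(rate, np.ndarray):
        if rate.shape != (p, p):
            raise ValueError("rate matrix shape mismatch")
        chol = np.linalg.cholesky(rate)  # raises on non-PD
    else:
        if rate < 0:
            raise ValueError("scalar rate must be nonnegative")
        chol = np.sqrt(rate) * np.eye(p)
    rng = np.random.default_rng(seed)
    values: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.zeros(p)
        else:
            t = node.edge.length
            step = chol @ rng.standard_normal(p) * np.sqrt(t)
            values[node] = values[node.parent_node] + step
    out = {}
    for leaf in tree.leaf_node_iter():
        v = values[leaf].copy()
        if groups is not None and group_shifts is not None:
            gl = groups.get(leaf.taxon.label)
            if gl is not None and gl in group_shifts:
                v = v + np.asarray(group_shifts[gl], dtype=float)
        out[leaf.taxon.label] = v
    return out


def simulate_diet_profiles(
    species: list[str],
    categories: list[str],
    focal: dict[str, str],
    items_by_category: dict[str, list[str]],
    focal_weight: float = 0.8,
    concentration: float = 10.0,
    seed: int = 0,
) -> DietRecordSet:
    """Dirichlet diet profiles tilted toward each species' focal category.

    Per-species category importances are drawn from a Dirichlet whose mean
    puts ``focal_weight`` on the focal category and spreads the remainder
    uniformly; ``concentration`` controls the spread around that mean.  Each
    category's importance is then split uniformly across its prey items and
    emitted as one single-study record set.
    """
    rng = np.random.default_rng(seed)
    k = len(categories)
    if k < 2:
        raise ValueError("need at least 2 categories")
    records: list[DietRecord] = []
    rest = (1.0 - focal_weight) / (k - 1)
    for sp in species:
        fc = focal[sp]
        alpha = np.array(
            [focal_weight if c == fc else rest for c in categories]
        ) * concentration * k
        weights = rng.dirichlet(alpha)
        for c, w in zip(categories, weights):
            items = items_by_category[c]
            for item in items:
                records.append(
                    DietRecord(
                        species=sp, study="synthetic", prey_item=item,
                        importance=float(w / len(items)),
                    )
                )
    return DietRecordSet(records=records)


def simulate_prey_traits(
    n_blocks: int = 6,
    items_per_block: int = 5,
    traits_per_block: int = 4,
    p_flip: float = 0.01,
    seed: int = 0,
) -> tuple[PreyTraitMatrix, dict[str, int]]:
    """Block-diagonal binary prey-trait matrix with Bernoulli flip noise.

    Block b's prototype has ones exactly on its own ``traits_per_block``
    columns, so two prototypes in different blocks differ in
    ``2 * traits_per_block`` traits.  Every cell is then flipped
    independently with probability ``p_flip``.  Returns the matrix and the
    planted block membership (item name -> block index).
    """
    if not 0 <= p_flip < 0.5:
        raise ValueError("p_flip must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = n_blocks * items_per_block
    t = n_blocks * traits_per_block
    proto = np.zeros((n, t))
    names = []
    planted = {}
    for b in range(n_blocks):
        for i in range(items_per_block):
            row = b * items_per_block + i
            name = f"item_b{b + 1}_{i + 1}"
            names.append(name)
            planted[name] = b
            proto[row, b * traits_per_block : (b + 1) * traits_per_block] = 1
    flips = rng.random((n, t)) < p_flip
    vals = np.abs(proto - flips.astype(float))
    m = PreyTraitMatrix(
        items=tuple(names),
        traits=tuple(f"trait_{j + 1}" for j in range(t)),
        values=vals,
    )
    return m, planted
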