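"""Experimental design: species pool and sown-richness-gradient plots.

The default design mirrors a classical grassland biodiversity experiment:
a pool of 60 species in four functional groups (12 legumes, 16 grasses,
20 tall herbs, 12 small herbs), mixture plots sown at richness 1, 2, 4, 8
or 16 with 16 distinct compositions per level (14 at richness 16, where
mono-functional-group mixtures of the two 12-species groups cannot be
assembled), plots spread equally across 4 blocks, plus one small
monoculture-reference plot per pool species supplying the per-species
monoculture yields used by the additive partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FUNCTIONAL_GROUPS = ("legume", "grass", "tall_herb", "small_herb")

#: species per functional group in the default pool (sums to 60)
POOL_SPLIT = {"legume": 12, "grass": 16, "tall_herb": 20, "small_herb": 12}

RICHNESS_LEVELS = (1, 2, 4, 8, 16)
N_BLOCKS = 4
COMPOSITIONS_PER_LEVEL = 16
COMPOSITIONS_AT_16 = 14


@dataclass(frozen=True)
class Species:
    """One pool species: short id and functional-group membership."""

    species_id: str
    functional_group: str

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"unknown functional group {self.functional_group!r}; "
                f"expected one of {FUNCTIONAL_GROUPS}"
            )


@dataclass
class PlotDesign:
    """One experimental unit.

    Attributes
    ----------
    plot_id : str
        Unique plot label.
    block : int
        Spatial block, 1–4.
    sown_richness : int
        Number of species sown (1, 2, 4, 8 or 16).
    composition : frozenset of str
        Sown species ids; cardinality equals ``sown_richness``.
    fg_richness : int
        Number of distinct functional groups in the composition.
    is_monoculture_reference : bool
        True for the small per-species monoculture plots that supply the
        monoculture yields M_i for the additive partition.
    """

    plot_id: str
    block: int
    sown_richness: int
    composition: frozenset = field(default_factory=frozenset)
    fg_richness: int = 1
    is_monoculture_reference: bool = False

    def __post_init__(self) -> None:
        self.composition = frozenset(self.composition)
        if len(self.composition) != self.sown_richness:
            raise ValueError(
                f"plot {self.plot_id}: composition size {len(self.composition)} "
                f"!= sown_richness {self.sown_richness}"
            )
        if not 1 <= self.block <= N_BLOCKS:
            raise ValueError(f"plot {self.plot_id}: block {self.block} outside 1–{N_BLOCKS}")


def default_species_pool() -> list[Species]:
    """Return the default 60-species pool with the 12/16/20/12 split.

    Species ids encode the group: ``leg01``…``leg12``, ``gra01``…``gra16``,
    ``tal01``…``tal20``, ``sma01``…``sma12``.
    """
    prefix = {"legume": "leg", "grass": "gra", "tall_herb": "tal", "small_herb": "sma"}
    pool = []
    for fg in FUNCTIONAL_GROUPS:
        for k in range(1, POOL_SPLIT[fg] + 1):
            pool.append(Species(f"{prefix[fg]}{k:02d}", fg))
    return pool


def _fg_richness(composition: frozenset, fg_of: dict[str, str]) -> int:
    return len({fg_of[s] for s in composition})


def build_default_design(seed: int) -> list[PlotDesign]:
    """Build the default plot design for a given random seed.

    Draws 16 distinct random compositions at each sown richness 1, 2, 4 and 8
    and 14 at richness 16, spreads the plots equally across the 4 blocks
    (round-robin within each richness level), and appends one
    monoculture-reference plot per pool species. Duplicate compositions are
    resampled internally and never emitted. Deterministic for a fixed seed.

    Parameters
    ----------
    seed : int
        Seed for the composition draw.

    Returns
    -------
    list of PlotDesign
        78 mixture/main plots followed by 60 monoculture-reference plots.
    """
    rng = np.random.default_rng(seed)
    pool = default_species_pool()
    ids = [sp.species_id for sp in pool]
    fg_of = {sp.species_id: sp.functional_group for sp in pool}

    plots: list[PlotDesign] = []
    for level in RICHNESS_LEVELS:
        n_comp = COMPOSITIONS_AT_16 if level == 16 else COMPOSITIONS_PER_LEVEL
        seen: set[frozenset] = set()
        compositions: list[frozenset] = []
        guard = 0
        while len(compositions) < n_comp:
            comp = frozenset(rng.choice(ids, size=level, replace=False).tolist())
            guard += 1
            if guard > 100_000:  # pragma: no cover - combinatorially unreachable
                raise RuntimeError(f"could not draw {n_comp} distinct compositions at richness {level}")
            if comp in seen:
                continue
            # at richness 16 a mono-functional-group mixture of the two
            # 12-species groups is impossible anyway; reject any
            # mono-functional-group draw at this level for symmetry
            if level == 16 and _fg_richness(comp, fg_of) == 1:
                continue
            seen.add(comp)
            compositions.append(comp)
        for j, comp in enumerate(compositions):
            plots.append(
                PlotDesign(
                    plot_id=f"B{j % N_BLOCKS + 1}R{level:02d}C{j + 1:02d}",
                    block=j % N_BLOCKS + 1,
                    sown_richness=level,
                    composition=comp,
                    fg_richness=_fg_richness(comp, fg_of),
                )
            )

    for j, sp in enumerate(ids):
        plots.append(
            PlotDesign(
                plot_id=f"MONO_{sp}",
                block=j % N_BLOCKS + 1,
                sown_richness=1,
                composition=frozenset({sp}),
                fg_richness=1,
                is_monoculture_reference=True,
            )
        )
    return plots


def design_table(design: list[PlotDesign]):
    """Flatten a design into a pandas DataFrame (one row per plot)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in design],
            "block": [p.block for p in design],
            "sown_richness": [p.sown_richness for p in design],
            "fg_richness": [p.fg_richness for p in design],
            "is_monoculture_reference": [p.is_monoculture_reference for p in design],
            "composition": [";".join(sorted(p.composition)) for p in design],
        }
    )


def design_from_table(df) -> list[PlotDesign]:
    """Inverse of :func:`design_table`."""
    plots = []
    for row in df.itertuples(index=False):
        plots.append(
            PlotDesign(
                plot_id=str(row.plot_id),
                block=int(row.block),
                sown_richness=int(row.sown_richness),
                composition=frozenset(str(row.composition).split(";")),
                fg_richness=int(row.fg_richness),
                is_monoculture_reference=bool(row.is_monoculture_reference),
            )
        )
    return plots
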