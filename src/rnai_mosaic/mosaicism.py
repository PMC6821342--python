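"""Intestinal-lineage mosaicism scoring.

The C. elegans intestine derives entirely from the E blastomere, which
produces 20 terminal cells with invariant names and positions.  Ten of the
20 undergo nuclear division without cell division (binucleate), four
sometimes do (variable), and six never do (mononucleate) — so an animal
carries between 30 and 34 intestinal nuclei.  Scoring each nucleus of each
cell as silenced ("off") or expressing ("on") across a cohort of animals
asks whether any cell *always* requires one silencing mechanism: a cell
that is "on" in every animal relies exclusively on the somatic RdRP, while
a cell "off" in every animal can always fall back on the germline RdRP.
Functional mosaicism is the observation that neither extreme holds — the
complement of cells differs animal to animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LineageTable",
    "MosaicMatrix",
    "CellCategory",
    "default_lineage",
    "enumerate_lineage",
    "check_binucleate_concordance",
    "categorize_cells",
    "sister_concordance_test",
]

logger = logging.getLogger(__name__)

NUCLEATION_CLASSES = ("binucleate", "variable", "mononucleate")


@dataclass(frozen=True)
class LineageTable:
    """The 20 terminal E-lineage intestinal cells and their nucleation class.

    ``cells`` maps cell name -> class in ("binucleate", "variable",
    "mononucleate"), in anterior-to-posterior table order.  The default
    table (see :func:`default_lineage`) carries the canonical class counts
    10/4/6; the name-to-class assignment is a placeholder (the true mapping
    is anatomical) and real mappings can be supplied instead.
    """

    cells: tuple[tuple[str, str], ...]
    expected_counts: dict[str, int] = field(
        default_factory=lambda: {"binucleate": 10, "variable": 4, "mononucleate": 6}
    )

    def validate(self) -> None:
        names = [name for name, _cls in self.cells]
        problems = []
        if len(self.cells) != sum(self.expected_counts.values()):
            problems.append(
                f"expected {sum(self.expected_counts.values())} cells, got {len(self.cells)}"
            )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            problems.append(f"duplicate cell names: {dupes}")
        for name, cls in self.cells:
            if cls not in NUCLEATION_CLASSES:
                problems.append(f"cell {name}: unknown nucleation class {cls!r}")
        observed = self.class_counts()
        for cls, want in self.expected_counts.items():
            if observed.get(cls, 0) != want:
                problems.append(
                    f"class {cls}: expected {want} cells, got {observed.get(cls, 0)}"
                )
        if problems:
            raise ValueError("invalid lineage table: " + "; ".join(problems))

    def class_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in NUCLEATION_CLASSES}
        for _name, cls in self.cells:
            if cls in counts:
                counts[cls] += 1
        return counts

    @property
    def names(self) -> list[str]:
        return [name for name, _cls in self.cells]

    def nucleation_class(self, name: str) -> str:
        for cell, cls in self.cells:
            if cell == name:
                return cls
        raise KeyError(name)

    def sister_pairs(self) -> list[tuple[str, str]]:
        """Adjacent-cell pairs in table order (placeholder sister relation)."""
        names = self.names
        return [(names[i], names[i + 1]) for i in range(0, len(names) - 1, 2)]


def default_lineage() -> LineageTable:
    """The default 20-cell E-lineage table.

    Names follow the E-lineage division-history style (EaLAAD ... EpRPPP).
    Classes are assigned so the canonical counts hold — 10 binucleate,
    4 variable, 6 mononucleate; the specific name-to-class pairing is a
    configurable placeholder.
    """
    suffixes = ["AAD", "AAV", "APA", "APP", "PPP"]
    names = [
        f"E{ap}{lr}{suffix}"
        for ap in ("a", "p")
        for lr in ("L", "R")
        for suffix in suffixes
    ]
    # anterior 6 mononucleate, middle 10 binucleate, posterior 4 variable
    classes = ["mononucleate"] * 6 + ["binucleate"] * 10 + ["variable"] * 4
    return LineageTable(cells=tuple(zip(names, classes)))


def enumerate_lineage(table: LineageTable | None = None) -> dict:
    """Validate a lineage table and summarise its cell and nucleus counts.

    Returns total cell count, per-class counts, and the minimum and maximum
    possible nucleus totals (variable cells contribute 1 or 2 nuclei).
    """
    if table is None:
        table = default_lineage()
    table.validate()
    counts = table.class_counts()
    min_nuclei = counts["mononucleate"] + 2 * counts["binucleate"] + counts["variable"]
    max_nuclei = counts["mononucleate"] + 2 * counts["binucleate"] + 2 * counts["variable"]
    return {
        "n_cells": len(table.cells),
        "class_counts": counts,
        "min_nuclei": min_nuclei,
        "max_nuclei": max_nuclei,
    }


@dataclass
class MosaicMatrix:
    """Animal x cell grid of per-nucleus on/off states.

    ``states[animal][cell]`` is a tuple of 1 or 2 entries from {"on",
    "off"} — one per nucleus.  "on" = GFP-positive = the cell required the
    somatic RdRP for silencing and failed; "off" = GFP-negative = silenced.
    """

    animals: list[str]
    lineage: LineageTable
    states: dict[str, dict[str, tuple[str, ...]]]

    def validate(self) -> None:
        problems = []
        for animal in self.animals:
            row = self.states.get(animal)
            if row is None:
                problems.append(f"animal {animal}: missing states")
                continue
            for name, cls in self.lineage.cells:
                nuclei = row.get(name)
                if nuclei is None:
                    problems.append(f"animal {animal} cell {name}: missing")
                    continue
                if any(s not in ("on", "off") for s in nuclei):
                    problems.append(f"animal {animal} cell {name}: bad state {nuclei}")
                n = len(nuclei)
                ok = {
                    "binucleate": n == 2,
                    "mononucleate": n == 1,
                    "variable": n in (1, 2),
                }[cls]
                if not ok:
                    problems.append(
                        f"animal {animal} cell {name}: {n} nuclei "
                        f"inconsistent with class {cls}"
                    )
        if problems:
            raise ValueError("invalid mosaic matrix: " + "; ".join(problems))

    def cell_state(self, animal: str, cell: str) -> str:
        """Collapse per-nucleus states to one per-cell state.

        Concordant nuclei make this unambiguous.  A (invalid) discordant
        binucleate cell collapses to "on" with a warning; run
        :func:`check_binucleate_concordance` to surface such cells.
        """
        nuclei = self.states[animal][cell]
        if len(set(nuclei)) > 1:
            logger.warning(
                "animal %s cell %s has discordant nuclei %s; scoring as 'on'",
                animal, cell, nuclei,
            )
            return "on"
        return nuclei[0]

    def nucleus_totals(self) -> dict[str, int]:
        return {
            animal: sum(len(self.states[animal][c]) for c in self.lineage.names)
            for animal in self.animals
        }


def check_binucleate_concordance(matrix: MosaicMatrix) -> list[tuple[str, str]]:
    """List every (animal, cell) whose two nuclei disagree.

    An empty list means the matrix is concordant — the observed rule that
    both nuclei of a binucleate intestinal cell always share one silencing
    requirement.
    """
    violations = []
    for animal in matrix.animals:
        for cell in matrix.lineage.names:
            nuclei = matrix.states[animal][cell]
            if len(nuclei) == 2 and nuclei[0] != nuclei[1]:
                violations.append((animal, cell))
    return violations


@dataclass(frozen=True)
class CellCategory:
    """Cross-animal summary for one cell."""

    cell: str
    category: str       # "always_on" | "always_off" | "mixed"
    n_on: int
    n_off: int


def categorize_cells(matrix: MosaicMatrix) -> list[CellCategory]:
    """Classify each cell as always_on, always_off, or mixed across animals.

    "always_on" means the cell failed to silence in every animal (relied
    exclusively on the somatic RdRP); "always_off" means it silenced in
    every animal.  Functional mosaicism predicts every cell is "mixed" once
    enough animals are scored.
    """
    if not matrix.animals:
        raise ValueError("matrix has no animals")
    out = []
    for cell in matrix.lineage.names:
        states = [matrix.cell_state(animal, cell) for animal in matrix.animals]
        n_on = states.count("on")
        n_off = states.count("off")
        if n_off == 0:
            category = "always_on"
        elif n_on == 0:
            category = "always_off"
        else:
            category = "mixed"
        out.append(CellCategory(cell=cell, category=category, n_on=n_on, n_off=n_off))
    return out


def sister_concordance_test(
    matrix: MosaicMatrix,
    lineage_pairs: list[tuple[str, str]] | None = None,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for lineage-correlated silencing.

    The statistic S is the mean over animals of the fraction of sister-cell
    pairs whose collapsed cell states agree.  The null distribution permutes
    cell states *within each animal*, preserving each animal's overall
    silencing burden while destroying lineage structure.  Returns
    (S_observed, p) with p = (1 + #{S_perm >= S_obs}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if lineage_pairs is None:
        lineage_pairs = matrix.lineage.sister_pairs()
    if not lineage_pairs:
        raise ValueError("no sister pairs supplied")
    rng = np.random.default_rng(seed)
    names = matrix.lineage.names
    name_idx = {n: i for i, n in enumerate(names)}
    pair_idx = np.array([(name_idx[a], name_idx[b]) for a, b in lineage_pairs])
    # animals x cells matrix of collapsed binary states
    grid = np.array(
        [
            [1 if matrix.cell_state(animal, cell) == "on" else 0 for cell in names]
            for animal in matrix.animals
        ],
        dtype=np.int8,
    )

    def statistic(g: np.ndarray) -> float:
        agree = g[:, pair_idx[:, 0]] == g[:, pair_idx[:, 1]]
        return float(agree.mean(axis=1).mean())

    s_obs = statistic(grid)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permuted(grid, axis=1)
        if statistic(perm) >= s_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return s_obs, p
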