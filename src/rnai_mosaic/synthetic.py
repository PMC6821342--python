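"""Synthetic cohorts, image stacks, and mosaic matrices with known truth.

Every downstream stage — variant filtering and in silico complementation,
3D object counting, and mosaicism scoring — is exercised against data
generated here, where the ground truth (planted allelic series, background
variants, object positions and volumes, per-cell silencing states) is
recorded exactly.  Generators emulate the statistical structure the
analysis assumes:

* a **mutant cohort**: 23 ENU-mutagenised strains, each with ~Poisson(30)
  candidate mutations over a 20,000-gene genome, optionally carrying
  planted allelic series (distinct mutations in one gene across designated
  mutants — the complementation signal) and shared pre-existing background
  variants (byte-identical across strains); quality/depth/fraction values
  straddle the filter thresholds so filtering is exercised;
* an **image stack**: Gaussian-blob nuclei at chosen depths and compact
  sub-resolution mRNA foci whose above-threshold volumes straddle the
  0.015-0.2 um^3 counting window, plus additive noise and empty leading
  slices;
* a **mosaic matrix**: per-animal, per-cell, per-nucleus on/off states over
  the 20-cell intestinal lineage, with binucleate concordance enforced.

All generators are deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import VoxelGrid
from .mosaicism import LineageTable, MosaicMatrix, default_lineage
from .variants import MutantVariantSet, VariantCall

__all__ = [
    "CohortConfig",
    "CohortGroundTruth",
    "StackSpec",
    "NucleusSpec",
    "FocusSpec",
    "StackGroundTruth",
    "MosaicConfig",
    "gen_mutant_cohort",
    "gen_image_stack",
    "gen_mosaic_cohort",
]

CHROMOSOMES = ("chrI", "chrII", "chrIII", "chrIV", "chrV", "chrX")
BASES = ("A", "C", "G", "T")
_GENE_SPAN = 5000  # bp allotted per gene on its chromosome

_EFFECTS = ("missense", "synonymous", "nonsense", "splice_junction", "noncoding", "deletion")
_EFFECT_WEIGHTS = (0.60, 0.18, 0.05, 0.05, 0.09, 0.03)


class ConfigurationError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters for a synthetic whole-genome-sequenced mutant cohort.

    ``planted_series`` lists (gene_id, mutant_ids) pairs, each planting
    *distinct* mutations in that gene into every named mutant — a true
    allelic series complementation should recover.  ``n_background_shared``
    identical variants are planted into two or more mutants each, emulating
    pre-mutagenesis background.  ``p_low_qual`` / ``p_low_depth`` /
    ``p_low_fraction`` set the fraction of random variants drawn *below*
    each filter threshold (quality 20, depth 2, variant-read fraction 0.66)
    so the filters have work to do.
    """

    n_mutants: int = 23
    n_genes: int = 20000
    mean_mutations_per_mutant: float = 30.0
    planted_series: tuple[tuple[str, tuple[str, ...]], ...] = ()
    n_background_shared: int = 5
    p_low_qual: float = 0.08
    p_low_depth: float = 0.04
    p_low_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_mutants < 2:
            raise ConfigurationError("n_mutants must be >= 2")
        if self.n_genes <= self.mean_mutations_per_mutant:
            raise ConfigurationError("n_genes must exceed mean_mutations_per_mutant")
        if self.n_background_shared < 0:
            raise ConfigurationError("n_background_shared must be >= 0")
        for p_name in ("p_low_qual", "p_low_depth", "p_low_fraction"):
            if not (0.0 <= getattr(self, p_name) <= 1.0):
                raise ConfigurationError(f"{p_name} must be in [0, 1]")
        valid_ids = set(self.mutant_ids())
        for gene, mutants in self.planted_series:
            if len(set(mutants)) < 2:
                raise ConfigurationError(
                    f"planted_series for {gene} must name >= 2 distinct mutants"
                )
            unknown = set(mutants) - valid_ids
            if unknown:
                raise ConfigurationError(
                    f"planted_series for {gene} names unknown mutants {sorted(unknown)}"
                )

    def mutant_ids(self) -> list[str]:
        return [f"mut{i:02d}" for i in range(1, self.n_mutants + 1)]

    def gene_ids(self) -> list[str]:
        return [f"gene{i:05d}" for i in range(1, self.n_genes + 1)]


@dataclass
class CohortGroundTruth:
    """What was planted, for parameter-recovery checks."""

    planted_series: list[tuple[str, tuple[str, ...]]]   # gene -> mutants
    background_sites: list[tuple[tuple[str, int, str, str], tuple[str, ...]]]
    seed: int


def _gene_locus(gene_index: int, n_genes: int) -> tuple[str, int]:
    """Deterministic (chrom, base position) for a 0-based gene index."""
    per_chrom = math.ceil(n_genes / len(CHROMOSOMES))
    chrom = CHROMOSOMES[gene_index // per_chrom]
    base = (gene_index % per_chrom) * _GENE_SPAN + 1
    return chrom, base


def _draw_qual(rng: np.random.Generator, low: bool) -> float:
    return float(rng.uniform(2.0, 19.5)) if low else float(rng.uniform(20.0, 60.0))


def _draw_depth(rng: np.random.Generator, low: bool) -> int:
    return int(rng.integers(0, 2)) if low else int(2 + rng.poisson(13))


def _draw_fraction(rng: np.random.Generator, low: bool) -> float:
    return float(rng.uniform(0.05, 0.65)) if low else float(rng.uniform(0.66, 1.0))


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(len(BASES), size=2, replace=False)
    return BASES[ref], BASES[alt]


def gen_mutant_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[list[MutantVariantSet], CohortGroundTruth]:
    """Generate per-mutant variant sets with recorded ground truth.

    ``seed`` overrides ``config.seed`` when given.  Planted allelic-series
    variants are guaranteed to pass all default filters and sit at distinct
    positions; background-shared variants are byte-identical across their
    carrier mutants.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    mutant_ids = config.mutant_ids()
    gene_ids = config.gene_ids()
    sets = {mid: MutantVariantSet(mid) for mid in mutant_ids}

    # random candidate mutations
    for mid in mutant_ids:
        n_var = rng.poisson(config.mean_mutations_per_mutant)
        gene_idx = rng.choice(config.n_genes, size=min(n_var, config.n_genes), replace=False)
        for gi in gene_idx:
            chrom, base = _gene_locus(int(gi), config.n_genes)
            pos = base + int(rng.integers(0, _GENE_SPAN - 1000))
            ref, alt = _snv_alleles(rng)
            effect = _EFFECTS[rng.choice(len(_EFFECTS), p=_EFFECT_WEIGHTS)]
            sets[mid].variants.append(
                VariantCall(
                    mutant_id=mid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    qual=_draw_qual(rng, rng.random() < config.p_low_qual),
                    depth=_draw_depth(rng, rng.random() < config.p_low_depth),
                    alt_fraction=_draw_fraction(rng, rng.random() < config.p_low_fraction),
                    gene_id=gene_ids[int(gi)],
                    effect=effect,
                )
            )

    # planted allelic series: distinct positions in one gene per mutant
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for gene, series_mutants in config.planted_series:
        gi = gene_index.get(gene)
        if gi is None:
            raise ConfigurationError(f"planted_series gene {gene} not in genome")
        chrom, base = _gene_locus(gi, config.n_genes)
        offsets = rng.choice(_GENE_SPAN - 1000, size=len(series_mutants), replace=False)
        for mid, off in zip(series_mutants, offsets):
            ref, alt = _snv_alleles(rng)
            sets[mid].variants.append(
                VariantCall(
                    mutant_id=mid,
                    chrom=chrom,
                    pos=base + int(off),
                    ref=ref,
                    alt=alt,
                    qual=float(rng.uniform(30.0, 60.0)),
                    depth=int(2 + rng.poisson(13)),
                    alt_fraction=float(rng.uniform(0.8, 1.0)),
                    gene_id=gene,
                    effect="missense",
                )
            )

    # shared background: byte-identical variants in >= 2 mutants
    background_sites = []
    for _ in range(config.n_background_shared):
        gi = int(rng.integers(0, config.n_genes))
        chrom, base = _gene_locus(gi, config.n_genes)
        pos = base + int(rng.integers(0, _GENE_SPAN - 1000))
        ref, alt = _snv_alleles(rng)
        n_carriers = min(config.n_mutants, 2 + int(rng.poisson(1)))
        carriers = tuple(
            sorted(rng.choice(mutant_ids, size=n_carriers, replace=False))
        )
        for mid in carriers:
            sets[mid].variants.append(
                VariantCall(
                    mutant_id=mid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    qual=float(rng.uniform(30.0, 60.0)),
                    depth=int(2 + rng.poisson(13)),
                    alt_fraction=float(rng.uniform(0.8, 1.0)),
                    gene_id=gene_ids[gi],
                    effect="missense",
                )
            )
        background_sites.append(((chrom, pos, ref, alt), carriers))

    truth = CohortGroundTruth(
        planted_series=[(g, tuple(m)) for g, m in config.planted_series],
        background_sites=background_sites,
        seed=seed,
    )
    return [sets[mid] for mid in mutant_ids], truth


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusSpec:
    """A nucleus to render: a 3D Gaussian blob.

    ``center`` in um (z, y, x); ``radius`` in um sets the blob scale
    (sigma = radius / 2); ``expected_state`` is the intended on/off call at
    the depth-appropriate threshold.
    """

    center: tuple[float, float, float]
    radius: float
    peak: float
    expected_state: str = "on"


@dataclass(frozen=True)
class FocusSpec:
    """A sub-resolution mRNA focus with a target above-threshold volume.

    The blob's sigma is chosen so the sphere where intensity >= the
    detection threshold has the requested physical volume; the rendered
    (voxelised) volume approximates it.
    """

    center: tuple[float, float, float]
    volume: float
    peak: float = 120.0


@dataclass(frozen=True)
class StackSpec:
    """Geometry and content of a synthetic confocal stack."""

    shape: tuple[int, int, int] = (64, 128, 128)          # (slices, rows, cols)
    voxel_size: tuple[float, float, float] = (0.125, 0.1, 0.1)
    n_slices_total: int = 319
    nuclei: tuple[NucleusSpec, ...] = ()
    foci: tuple[FocusSpec, ...] = ()
    focus_threshold: float = 50.0     # detection threshold the foci volumes refer to
    noise_sd: float = 0.0
    noise_floor: float = 5.0
    leading_empty_slices: int = 0
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        extent = tuple(n * v for n, v in zip(self.shape, self.voxel_size))
        for i, obj in enumerate(list(self.nuclei) + list(self.foci)):
            for axis in range(3):
                if not (0.0 <= obj.center[axis] <= extent[axis]):
                    raise ConfigurationError(
                        f"object {i} center {obj.center} outside grid extent {extent}"
                    )
        for f in self.foci:
            if f.volume <= 0:
                raise ConfigurationError("focus volumes must be > 0")
            if f.peak <= self.focus_threshold:
                raise ConfigurationError(
                    "focus peak must exceed focus_threshold to have any "
                    "above-threshold volume"
                )
        for nuc in self.nuclei:
            if nuc.radius <= 0:
                raise ConfigurationError("nucleus radii must be > 0")
            if nuc.peak < 0:
                raise ConfigurationError("intensities must be >= 0")
        if self.leading_empty_slices < 0:
            raise ConfigurationError("leading_empty_slices must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.allow_overlap:
            self._check_separation()

    def _effective_radii(self) -> list[tuple[tuple[float, float, float], float]]:
        out = [(n.center, n.radius) for n in self.nuclei]
        for f in self.foci:
            out.append((f.center, (3.0 * f.volume / (4.0 * math.pi)) ** (1.0 / 3.0)))
        return out

    def _check_separation(self) -> None:
        objs = self._effective_radii()
        for i in range(len(objs)):
            for j in range(i + 1, len(objs)):
                ci, ri = objs[i]
                cj, rj = objs[j]
                d = math.dist(ci, cj)
                if d < 2.0 * (ri + rj):
                    raise ConfigurationError(
                        f"objects at {ci} and {cj} are {d:.3f} um apart, closer than "
                        f"2 x sum of radii ({2 * (ri + rj):.3f} um); set "
                        "allow_overlap=True to render a merged pair"
                    )


@dataclass
class StackGroundTruth:
    """Planted objects with intended classification."""

    nuclei: list[dict]
    foci: list[dict]
    n_in_window: int
    leading_empty_slices: int
    n_slices_total: int
    seed: int


def _render_gaussian(
    arr: np.ndarray,
    voxel_size: tuple[float, float, float],
    center_um: tuple[float, float, float],
    sigma_um: float,
    peak: float,
    z_offset_um: float,
) -> None:
    """Add an isotropic (in um) Gaussian blob into ``arr`` in place."""
    vz, vy, vx = voxel_size
    cz = center_um[0] + z_offset_um
    cy, cx = center_um[1], center_um[2]
    reach = 4.0 * sigma_um
    z0 = max(0, int((cz - reach) / vz))
    z1 = min(arr.shape[0], int((cz + reach) / vz) + 2)
    y0 = max(0, int((cy - reach) / vy))
    y1 = min(arr.shape[1], int((cy + reach) / vy) + 2)
    x0 = max(0, int((cx - reach) / vx))
    x1 = min(arr.shape[2], int((cx + reach) / vx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    # voxel-center physical coordinates
    zz = (np.arange(z0, z1) + 0.5) * vz
    yy = (np.arange(y0, y1) + 0.5) * vy
    xx = (np.arange(x0, x1) + 0.5) * vx
    d2 = (
        (zz[:, None, None] - cz) ** 2
        + (yy[None, :, None] - cy) ** 2
        + (xx[None, None, :] - cx) ** 2
    )
    arr[z0:z1, y0:y1, x0:x1] += peak * np.exp(-d2 / (2.0 * sigma_um**2))


def focus_sigma(volume: float, peak: float, threshold: float) -> float:
    """Sigma (um) so the >= threshold isosurface encloses ``volume`` um^3."""
    r_star = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_star / math.sqrt(2.0 * math.log(peak / threshold))


def _calibrated_focus_sigma(
    volume: float,
    peak: float,
    threshold: float,
    voxel_size: tuple[float, float, float],
    center_um: tuple[float, float, float],
) -> float:
    """Sigma tuned to the voxel raster so the rendered volume is exact.

    Small foci span only a few voxels, so the continuous isosurface volume
    quantises badly.  Instead of the analytic sigma, pick sigma so that
    exactly round(volume / voxel volume) voxel *centers* fall inside the
    above-threshold radius for this particular center placement.
    """
    vz, vy, vx = voxel_size
    vox_vol = vz * vy * vx
    target = max(1, round(volume / vox_vol))
    sigma0 = focus_sigma(volume, peak, threshold)
    reach = 4.0 * sigma0 + max(voxel_size)
    # squared distances from the center to nearby voxel centers
    zz = (np.arange(math.floor((center_um[0] - reach) / vz),
                    math.ceil((center_um[0] + reach) / vz) + 1) + 0.5) * vz
    yy = (np.arange(math.floor((center_um[1] - reach) / vy),
                    math.ceil((center_um[1] + reach) / vy) + 1) + 0.5) * vy
    xx = (np.arange(math.floor((center_um[2] - reach) / vx),
                    math.ceil((center_um[2] + reach) / vx) + 1) + 0.5) * vx
    d2 = (
        (zz[:, None, None] - center_um[0]) ** 2
        + (yy[None, :, None] - center_um[1]) ** 2
        + (xx[None, None, :] - center_um[2]) ** 2
    ).ravel()
    d2.sort()
    if target > d2.size:
        target = d2.size
    # radius that encloses exactly `target` voxel centers (nudged past ties)
    r2 = d2[target - 1]
    r = math.sqrt(r2) + 1e-9
    return r / math.sqrt(2.0 * math.log(peak / threshold))


def gen_image_stack(
    spec: StackSpec | None = None, seed: int | None = None
) -> tuple[VoxelGrid, StackGroundTruth]:
    """Render a synthetic stack and record every planted object.

    Nuclei are Gaussian blobs with sigma = radius / 2.  Foci are truncated
    Gaussians whose above-threshold (``focus_threshold``) volume matches
    their nominal volume up to voxelisation.  Content starts after
    ``leading_empty_slices`` noise-only slices; noise is folded-normal with
    scale ``noise_sd`` and is clipped strictly below ``noise_floor`` so
    empty slices stay below the floor.
    """
    if spec is None:
        spec = StackSpec()
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    arr = np.zeros(spec.shape, dtype=float)
    if spec.noise_sd > 0:
        noise = np.abs(rng.normal(0.0, spec.noise_sd, size=spec.shape))
        arr += np.minimum(noise, 0.99 * spec.noise_floor)

    z_offset = spec.leading_empty_slices * spec.voxel_size[0]
    nuclei_truth = []
    for nuc in spec.nuclei:
        _render_gaussian(
            arr, spec.voxel_size, nuc.center, nuc.radius / 2.0, nuc.peak, z_offset
        )
        shifted = (nuc.center[0] + z_offset, nuc.center[1], nuc.center[2])
        nuclei_truth.append(
            {
                "center": shifted,
                "radius": nuc.radius,
                "peak": nuc.peak,
                "expected_state": nuc.expected_state,
                "slice_index": int(shifted[0] / spec.voxel_size[0]) + 1,
            }
        )

    gate_lo, gate_hi = 0.015, 0.2
    foci_truth = []
    for f in spec.foci:
        shifted_center = (f.center[0] + z_offset, f.center[1], f.center[2])
        sigma = _calibrated_focus_sigma(
            f.volume, f.peak, spec.focus_threshold, spec.voxel_size, shifted_center
        )
        _render_gaussian(arr, spec.voxel_size, f.center, sigma, f.peak, z_offset)
        shifted = (f.center[0] + z_offset, f.center[1], f.center[2])
        foci_truth.append(
            {
                "center": shifted,
                "volume": f.volume,
                "peak": f.peak,
                "sigma": sigma,
                "in_window": gate_lo <= f.volume <= gate_hi,
            }
        )

    grid = VoxelGrid(arr, spec.voxel_size)
    truth = StackGroundTruth(
        nuclei=nuclei_truth,
        foci=foci_truth,
        n_in_window=sum(1 for f in foci_truth if f["in_window"]),
        leading_empty_slices=spec.leading_empty_slices,
        n_slices_total=spec.n_slices_total,
        seed=seed,
    )
    return grid, truth


# ---------------------------------------------------------------------------
# mosaic matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MosaicConfig:
    """Parameters for a synthetic silencing-mosaicism cohort.

    ``p_off_per_cell`` is the per-cell probability of being silenced
    (GFP-off) in any animal — a scalar, or a mapping cell name -> p.
    Variable-division cells are binucleate with probability
    ``p_binucleate_variable``.  Both nuclei of a binucleate cell always
    share the cell's state.
    """

    n_animals: int = 10
    p_off_per_cell: float | dict[str, float] = 0.5
    p_binucleate_variable: float = 0.5
    lineage: LineageTable | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        probs = (
            self.p_off_per_cell.values()
            if isinstance(self.p_off_per_cell, dict)
            else [self.p_off_per_cell]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("p_off_per_cell values must be in [0, 1]")
        if not (0.0 <= self.p_binucleate_variable <= 1.0):
            raise ConfigurationError("p_binucleate_variable must be in [0, 1]")
        lineage = self.lineage or default_lineage()
        lineage.validate()

    def p_off(self, cell: str) -> float:
        if isinstance(self.p_off_per_cell, dict):
            return self.p_off_per_cell[cell]
        return self.p_off_per_cell


def gen_mosaic_cohort(
    config: MosaicConfig | None = None, seed: int | None = None
) -> MosaicMatrix:
    """Sample per-cell silencing states for a cohort of animals.

    Cell states are independent Bernoulli draws (off with the cell's
    ``p_off``); binucleate cells replicate their state across both nuclei,
    enforcing the concordance rule observed in real animals.
    """
    if config is None:
        config = MosaicConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lineage = config.lineage or default_lineage()
    animals = [f"animal{i:02d}" for i in range(1, config.n_animals + 1)]
    states: dict[str, dict[str, tuple[str, ...]]] = {}
    for animal in animals:
        row: dict[str, tuple[str, ...]] = {}
        for cell, cls in lineage.cells:
            state = "off" if rng.random() < config.p_off(cell) else "on"
            if cls == "binucleate":
                n_nuclei = 2
            elif cls == "mononucleate":
                n_nuclei = 1
            else:
                n_nuclei = 2 if rng.random() < config.p_binucleate_variable else 1
            row[cell] = (state,) * n_nuclei
        states[animal] = row
    return MosaicMatrix(animals=animals, lineage=lineage, states=states)
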