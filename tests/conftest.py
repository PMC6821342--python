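import numpy as np
import pytest

from rnai_mosaic import synthetic, variants


@pytest.fixture
def small_cohort():
    """A 4-mutant cohort with one planted allelic series and known truth."""
    cfg = synthetic.CohortConfig(
        n_mutants=4,
        n_genes=500,
        mean_mutations_per_mutant=10,
        planted_series=(("gene00042", ("mut01", "mut03")),),
        n_background_shared=2,
        seed=7,
    )
    return synthetic.gen_mutant_cohort(cfg)


@pytest.fixture
def make_variant():
    """Factory for a VariantCall with sensible defaults, overridable per test."""

    def _make(**kw):
        defaults = dict(
            mutant_id="mut01",
            chrom="chrI",
            pos=1000,
            ref="A",
            alt="T",
            qual=40.0,
            depth=15,
            alt_fraction=0.9,
            gene_id="geneX",
            effect="missense",
        )
        defaults.update(kw)
        return variants.VariantCall(**defaults)

    return _make


def run_complementation(cohort, n_genes, bonf=None):
    """Filter -> remove background -> pairwise complementation."""
    filtered = [
        variants.MutantVariantSet(m.mutant_id, variants.filter_variants(m.variants))
        for m in cohort
    ]
    cleaned = variants.remove_shared_background(filtered)
    return variants.in_silico_complementation(cleaned, n_genes, bonf)


def flood_fill_objects(arr: np.ndarray, threshold: float) -> list[frozenset]:
    """Brute-force 26-connected component extraction by BFS flood fill.

    Independent oracle for count_objects_3d: no labelling library, just
    neighbourhood walking.
    """
    mask = arr >= threshold
    visited = np.zeros(arr.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    components = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = []
        while stack:
            z, y, x = stack.pop()
            comp.append((z, y, x))
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < arr.shape[0]
                    and 0 <= ny < arr.shape[1]
                    and 0 <= nx < arr.shape[2]
                    and mask[nz, ny, nx]
                    and not visited[nz, ny, nx]
                ):
                    visited[nz, ny, nx] = True
                    stack.append((nz, ny, nx))
        components.append(frozenset(comp))
    return components
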