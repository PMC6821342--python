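"""Mutant identification by variant filtering and in silico complementation.

A forward-genetic screen yields a set of independently isolated mutant
strains, each carrying one causal mutation buried among dozens of incidental
ENU-induced and pre-existing background changes.  Whole-genome sequencing of
every strain produces a table of candidate variants per mutant.  The causal
gene is found *in silico* by the classical complementation logic: two
independent mutants with **different** mutations in the **same** gene very
probably both carry their causal lesion there, because by chance two random
sets of ~30 mutated genes drawn from a ~20,000-gene genome almost never
overlap.

The pipeline here is:

1. :func:`filter_variants` — keep high-confidence, consequential calls
   (quality, read support, variant-read fraction, effect class).
2. :func:`detect_deletions` — flag candidate deletions from depressed
   coverage windows.
3. :func:`remove_shared_background` — byte-identical variants seen in two
   or more mutants predate mutagenesis and are discarded everywhere.
4. :func:`in_silico_complementation` — all pairwise comparisons; each pair's
   shared-gene count is scored with an exact hypergeometric tail probability
   (:func:`shared_gene_pvalue`) against a Bonferroni-corrected family-wise
   threshold (:func:`bonferroni_threshold`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

__all__ = [
    "VariantCall",
    "MutantVariantSet",
    "FilterPolicy",
    "CoverageTrack",
    "SharedGeneResult",
    "BonferroniConfig",
    "EFFECT_CLASSES",
    "filter_variants",
    "detect_deletions",
    "remove_shared_background",
    "in_silico_complementation",
    "shared_gene_pvalue",
    "bonferroni_threshold",
]

#: Recognised variant effect classes.
EFFECT_CLASSES = frozenset(
    {"synonymous", "missense", "nonsense", "splice_junction", "noncoding", "deletion"}
)


class VariantRecordError(ValueError):
    """A malformed variant record; the message names the offending row."""


@dataclass(frozen=True)
class VariantCall:
    """One candidate sequence change in one mutant strain.

    Attributes
    ----------
    mutant_id : str
        Strain label.
    chrom : str
        Chromosome name.
    pos : int
        1-based position.
    ref, alt : str
        Reference and alternate alleles.
    qual : float
        Phred33 variant quality.
    depth : int
        Aligned reads covering the site.
    alt_fraction : float
        Fraction of reads carrying the variant, in [0, 1].
    gene_id : str or None
        Gene label, or None for intergenic calls.
    effect : str
        One of :data:`EFFECT_CLASSES`.
    """

    mutant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    alt_fraction: float
    gene_id: str | None
    effect: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise VariantRecordError(
                f"{self.mutant_id} {self.chrom}:{self.pos}: "
                f"alt_fraction {self.alt_fraction} outside [0, 1]"
            )
        if self.depth < 0:
            raise VariantRecordError(
                f"{self.mutant_id} {self.chrom}:{self.pos}: negative depth"
            )
        if self.qual < 0:
            raise VariantRecordError(
                f"{self.mutant_id} {self.chrom}:{self.pos}: negative qual"
            )
        if self.pos < 1:
            raise VariantRecordError(
                f"{self.mutant_id} {self.chrom}:{self.pos}: positions are 1-based"
            )
        if self.effect not in EFFECT_CLASSES:
            raise VariantRecordError(
                f"{self.mutant_id} {self.chrom}:{self.pos}: "
                f"unknown effect {self.effect!r}"
            )

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Identity key (chrom, pos, ref, alt) used for background matching."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutantVariantSet:
    """All retained variants for one mutant strain."""

    mutant_id: str
    variants: list[VariantCall] = field(default_factory=list)

    def gene_set(self) -> frozenset[str]:
        """Distinct mutated genes (variants without a gene_id are ignored)."""
        return frozenset(v.gene_id for v in self.variants if v.gene_id is not None)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds used to call mutations from raw variant tables.

    All comparisons are inclusive: a variant is retained when
    ``qual >= min_qual``, ``depth >= min_reads`` and
    ``alt_fraction >= min_fraction`` (or the per-gene override), and its
    effect class is consequential.  ``fraction_overrides`` lowers the
    fraction threshold for designated loci — used when a locus is present in
    extra (e.g. transgenic) copies that dilute the variant-read fraction.
    """

    min_qual: float = 20.0
    min_reads: int = 2
    min_fraction: float = 0.66
    fraction_overrides: dict[str, float] = field(default_factory=dict)
    retained_effects: frozenset[str] = frozenset(
        {"missense", "nonsense", "splice_junction", "deletion"}
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")
        for gene, frac in self.fraction_overrides.items():
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"fraction override for {gene} must be in (0, 1]")
        bad = set(self.retained_effects) - EFFECT_CLASSES
        if bad:
            raise ValueError(f"unknown effect classes in retained_effects: {bad}")

    def fraction_threshold(self, gene_id: str | None) -> float:
        if gene_id is not None and gene_id in self.fraction_overrides:
            return self.fraction_overrides[gene_id]
        return self.min_fraction


def filter_variants(
    calls: list[VariantCall], policy: FilterPolicy | None = None
) -> list[VariantCall]:
    """Retain high-confidence consequential variants.

    Order is preserved and the input list is not modified.  The operation is
    idempotent: filtering an already-filtered list is a no-op.
    """
    if policy is None:
        policy = FilterPolicy()
    out = []
    for v in calls:
        if v.qual < policy.min_qual:
            continue
        if v.depth < policy.min_reads:
            continue
        if v.alt_fraction < policy.fraction_threshold(v.gene_id):
            continue
        if v.effect not in policy.retained_effects:
            continue
        out.append(v)
    return out


@dataclass
class CoverageTrack:
    """Mean aligned-read depth in fixed-width, non-overlapping windows.

    ``starts`` are 1-based window start positions, sorted ascending; each
    window spans ``window_size`` bases.
    """

    chrom: str
    starts: np.ndarray
    mean_depth: np.ndarray
    window_size: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        if self.starts.size != self.mean_depth.size:
            raise ValueError("starts and mean_depth lengths differ")
        if self.starts.size and np.any(np.diff(self.starts) < self.window_size):
            raise ValueError("windows must be sorted and non-overlapping")


def detect_deletions(
    track: CoverageTrack, min_windows: int = 2, factor: float = 0.25
) -> list[tuple[str, int, int]]:
    """Flag candidate deletions as runs of low-coverage windows.

    A deletion is a maximal run of at least ``min_windows`` consecutive
    windows whose mean depth is below ``factor`` times the track-wide mean
    depth.  Intervals are returned as 1-based closed ``(chrom, start, end)``
    coordinates.
    """
    if track.starts.size == 0:
        raise ValueError("empty coverage track")
    global_mean = float(track.mean_depth.mean())
    low = track.mean_depth < factor * global_mean
    intervals: list[tuple[str, int, int]] = []
    i = 0
    n = low.size
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1] and track.starts[j + 1] == track.starts[j] + track.window_size:
            j += 1
        if j - i + 1 >= min_windows:
            intervals.append(
                (track.chrom, int(track.starts[i]), int(track.starts[j]) + track.window_size - 1)
            )
        i = j + 1
    return intervals


def remove_shared_background(
    mutants: list[MutantVariantSet],
) -> list[MutantVariantSet]:
    """Eliminate variants that predate mutagenesis.

    Any variant whose (chrom, pos, ref, alt) identity occurs in two or more
    mutants is removed from *all* mutants: independently induced identical
    point mutations are vanishingly unlikely, so shared calls are background
    present in the ancestral strain.  Different mutations in the same gene
    are untouched — they are the complementation signal.
    """
    if len(mutants) < 2:
        raise ValueError("background removal needs at least 2 mutants")
    seen_in: dict[tuple, set[str]] = {}
    for m in mutants:
        for v in m.variants:
            seen_in.setdefault(v.site_key, set()).add(m.mutant_id)
    shared = {k for k, ids in seen_in.items() if len(ids) >= 2}
    return [
        MutantVariantSet(
            m.mutant_id, [v for v in m.variants if v.site_key not in shared]
        )
        for m in mutants
    ]


def shared_gene_pvalue(n_genes: int, m1: int, m2: int, k: int) -> float:
    """Exact tail probability of sharing >= k mutated genes by chance.

    Under the null, the two mutants' gene sets (sizes ``m1`` and ``m2``) are
    independent uniform draws without replacement from ``n_genes`` genes;
    the overlap X is hypergeometric.  Returns P(X >= k), evaluated in log
    space with log-gamma factorials so that genome-scale arguments are
    numerically stable.  Symmetric in (m1, m2); equals 1 when k == 0.
    """
    if not (0 <= m1 <= n_genes and 0 <= m2 <= n_genes):
        raise ValueError("m1 and m2 must lie in [0, n_genes]")
    if not (0 <= k <= min(m1, m2)):
        raise ValueError("k must lie in [0, min(m1, m2)]")
    if k == 0:
        return 1.0

    def log_comb(n: int, r: int) -> float:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    # P(X = j) = C(m1, j) C(N - m1, m2 - j) / C(N, m2)
    lo = max(0, m1 + m2 - n_genes)
    hi = min(m1, m2)
    denom = log_comb(n_genes, m2)
    log_terms = [
        log_comb(m1, j) + log_comb(n_genes - m1, m2 - j) - denom
        for j in range(max(k, lo), hi + 1)
    ]
    if not log_terms:
        return 0.0
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return float(min(1.0, math.exp(total)))


@dataclass(frozen=True)
class BonferroniConfig:
    """Family-wise error control for all pairwise mutant comparisons."""

    alpha: float = 0.05
    n_comparisons: int = 253

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")


def bonferroni_threshold(bonf: BonferroniConfig) -> float:
    """Per-comparison significance threshold alpha / n_comparisons, unrounded."""
    return bonf.alpha / bonf.n_comparisons


@dataclass(frozen=True)
class SharedGeneResult:
    """Complementation outcome for one unordered mutant pair."""

    mutant_a: str
    mutant_b: str
    shared_genes: frozenset[str]
    m1: int
    m2: int
    k: int
    n_genes: int
    p_value: float
    significant: bool


def in_silico_complementation(
    mutants: list[MutantVariantSet],
    n_genes: int = 20000,
    bonf: BonferroniConfig | None = None,
) -> list[SharedGeneResult]:
    """Score every unordered mutant pair for shared mutated genes.

    Expects background-removed, filtered variant sets.  For n mutants,
    returns n(n-1)/2 results ordered by lexicographic mutant-id pair.  A
    pair is significant when its hypergeometric tail probability beats the
    Bonferroni-corrected threshold.
    """
    if len(mutants) < 2:
        raise ValueError("complementation needs at least 2 mutants")
    if bonf is None:
        n = len(mutants)
        bonf = BonferroniConfig(n_comparisons=n * (n - 1) // 2)
    threshold = bonferroni_threshold(bonf)
    ordered = sorted(mutants, key=lambda m: m.mutant_id)
    gene_sets = {m.mutant_id: m.gene_set() for m in ordered}
    results = []
    for a, b in itertools.combinations(ordered, 2):
        ga, gb = gene_sets[a.mutant_id], gene_sets[b.mutant_id]
        shared = ga & gb
        p = shared_gene_pvalue(n_genes, len(ga), len(gb), len(shared))
        results.append(
            SharedGeneResult(
                mutant_a=a.mutant_id,
                mutant_b=b.mutant_id,
                shared_genes=frozenset(shared),
                m1=len(ga),
                m2=len(gb),
                k=len(shared),
                n_genes=n_genes,
                p_value=p,
                significant=p < threshold,
            )
        )
    return results
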