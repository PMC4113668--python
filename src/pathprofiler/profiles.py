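"""Binary pathway profiles and profile-level statistics.

A disease (or subtype) is encoded as a binary vector over a fixed,
ordered pathway universe: bit n is 1 exactly when the n-th pathway is
enriched in the tumor-vs-normal contrast.  On top of that encoding this
module provides the reproducibility statistic r = Nc / ((N + N') / 2)
between two enriched sets, consensus (reference) profiles across
datasets, the Venn partition of several subtype profiles into common and
subtype-specific regions, common-pathway fractions, top-k DEG overlap,
and FDR-cutoff sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, GeneStat

__all__ = [
    "PathwayProfile",
    "ReproducibilityResult",
    "VennPartition",
    "build_profile",
    "reproducibility",
    "reference_profile",
    "venn_partition",
    "cep_fractions",
    "top_k_deg_overlap",
    "fdr_sweep",
    "read_profile_matrix",
    "write_profile_matrix",
]


@dataclass(frozen=True)
class PathwayProfile:
    """Binary enrichment vector p = (p1, ..., pN) over a pathway universe."""

    disease_label: str
    pathway_ids: tuple
    bits: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_ids", tuple(self.pathway_ids))
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        if len(self.pathway_ids) != len(self.bits):
            raise ValueError("pathway_ids and bits must have equal length")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("duplicate pathway ids in universe")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def enriched_set(self) -> frozenset:
        return frozenset(pid for pid, b in zip(self.pathway_ids, self.bits) if b)


@dataclass(frozen=True)
class ReproducibilityResult:
    """Overlap statistics for two enriched sets: r = Nc / ((N + N') / 2)."""

    N: int
    N_prime: int
    N_c: int
    r: float


@dataclass(frozen=True)
class VennPartition:
    """Disjoint membership-pattern regions of several enrichment sets.

    ``regions`` maps a frozenset of subtype labels (the pathways
    enriched in exactly those subtypes) to the pathway-id set of that
    region; only non-empty patterns are kept.  The all-subtypes pattern
    is the common-enriched (CEP) region; singletons are
    subtype-specific.
    """

    regions: dict
    subtype_totals: dict
    subtypes: tuple

    @property
    def cep(self) -> frozenset:
        return frozenset(self.regions.get(frozenset(self.subtypes), frozenset()))

    def specific(self, subtype: str) -> frozenset:
        return frozenset(self.regions.get(frozenset({subtype}), frozenset()))


def _check_universe(profiles: Sequence[PathwayProfile]) -> tuple:
    universes = {p.pathway_ids for p in profiles}
    if len(universes) != 1:
        raise ValueError("profiles are defined over different pathway universes")
    return next(iter(universes))


def build_profile(results: Iterable[EnrichmentResult], universe: Sequence[str], label: str) -> PathwayProfile:
    """Binary profile over ``universe`` from per-pathway enrichment flags.

    Pathways with no result get bit 0 (they were untestable on this
    dataset); a result for a pathway outside the universe is an error.
    """
    universe = tuple(universe)
    known = set(universe)
    flags = {}
    for r in results:
        if r.pathway_id not in known:
            raise ValueError(f"result for pathway {r.pathway_id!r} outside the profile universe")
        flags[r.pathway_id] = int(r.enriched)
    bits = tuple(flags.get(pid, 0) for pid in universe)
    return PathwayProfile(disease_label=label, pathway_ids=universe, bits=bits)


def reproducibility(a, b) -> ReproducibilityResult:
    """r = Nc / ((N + N') / 2) for two profiles or two plain sets.

    N and N' are the enriched-set sizes, Nc their overlap; symmetric in
    its arguments and in [0, 1], with r = 1 exactly for equal non-empty
    sets.  Undefined (raises) when both sets are empty.
    """
    set_a = a.enriched_set if isinstance(a, PathwayProfile) else frozenset(a)
    set_b = b.enriched_set if isinstance(b, PathwayProfile) else frozenset(b)
    if isinstance(a, PathwayProfile) and isinstance(b, PathwayProfile):
        _check_universe([a, b])
    N, N_prime = len(set_a), len(set_b)
    if N + N_prime == 0:
        raise ValueError("reproducibility undefined: both enriched sets are empty")
    N_c = len(set_a & set_b)
    r = N_c / ((N + N_prime) / 2)
    return ReproducibilityResult(N=N, N_prime=N_prime, N_c=N_c, r=float(r))


def reference_profile(profiles: Sequence[PathwayProfile], min_support: int = 2, label: str = "reference") -> PathwayProfile:
    """Consensus profile: bit 1 where >= ``min_support`` inputs are enriched.

    The default of 2 encodes "enriched in more than one data set": a
    pathway supported by multiple independent datasets is taken as more
    reliable than one seen only once.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for a reference profile")
    universe = _check_universe(profiles)
    counts = np.sum([p.bits for p in profiles], axis=0)
    bits = tuple(int(c >= min_support) for c in counts)
    return PathwayProfile(disease_label=label, pathway_ids=universe, bits=bits)


def venn_partition(profiles: Mapping[str, PathwayProfile]) -> VennPartition:
    """Partition all enriched pathways by their subtype-membership pattern.

    Every pathway enriched anywhere lands in exactly one region; for s
    subtypes at most 2^s - 1 non-empty patterns exist.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    _check_universe(list(profiles.values()))
    subtypes = tuple(profiles)
    regions: dict = {}
    enriched = {s: profiles[s].enriched_set for s in subtypes}
    for pid in frozenset().union(*enriched.values()):
        pattern = frozenset(s for s in subtypes if pid in enriched[s])
        regions.setdefault(pattern, set()).add(pid)
    regions = {k: frozenset(v) for k, v in regions.items()}
    totals = {s: len(enriched[s]) for s in subtypes}
    return VennPartition(regions=regions, subtype_totals=totals, subtypes=subtypes)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cep_fractions(partition: VennPartition):
    """Share of each subtype's enriched pathways that lies in the CEP region.

    Returns ``(exact, rounded)`` mappings subtype -> percentage; the
    rounded form is half-up to integer percent for report tables, the
    exact real is kept for machine use.  A subtype with zero enriched
    pathways gets NaN / None (fraction undefined).
    """
    cep = partition.cep
    exact: dict = {}
    rounded: dict = {}
    for s in partition.subtypes:
        total = partition.subtype_totals[s]
        if total == 0:
            exact[s] = float("nan")
            rounded[s] = None
        else:
            pct = 100.0 * len(cep) / total
            exact[s] = pct
            rounded[s] = _round_half_up(pct)
    return exact, rounded


def top_k_deg_overlap(stats_a: Sequence[GeneStat], stats_b: Sequence[GeneStat], k: int = 1500) -> ReproducibilityResult:
    """Reproducibility of the top-k differentially expressed genes.

    Takes the k best-ranked genes from each list (rank 1 = largest |t|,
    ties already broken deterministically upstream) and computes r on
    the two gene sets; with N = N' = k this reduces to r = Nc / k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(stats_a) or k > len(stats_b):
        raise ValueError(f"k={k} exceeds a gene list length ({len(stats_a)}, {len(stats_b)})")
    top_a = {s.gene for s in stats_a if s.rank <= k}
    top_b = {s.gene for s in stats_b if s.rank <= k}
    return reproducibility(top_a, top_b)


def fdr_sweep(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    cutoffs: Sequence[float],
) -> list:
    """Reproducibility of the two enriched sets re-called at each FDR cutoff.

    Enriched flags are recomputed from the stored q-values (q <= cutoff);
    cutoffs must be ascending in (0, 1].  Pairs where both re-called sets
    are empty report r as None.
    """
    cutoffs = list(cutoffs)
    if any(not (0 < c <= 1) for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 1]")
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    out = []
    for c in cutoffs:
        set_a = {r.pathway_id for r in results_a if r.q_value <= c}
        set_b = {r.pathway_id for r in results_b if r.q_value <= c}
        if not set_a and not set_b:
            out.append((c, None))
        else:
            out.append((c, reproducibility(set_a, set_b).r))
    return out


def write_profile_matrix(profiles: Sequence[PathwayProfile], path, header_comment: str | None = None) -> None:
    """Pathways x diseases 0/1 matrix as TSV (heatmap-tool friendly)."""
    universe = _check_universe(profiles)
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("pathway_id\t" + "\t".join(p.disease_label for p in profiles) + "\n")
        for i, pid in enumerate(universe):
            fh.write(pid + "\t" + "\t".join(str(p.bits[i]) for p in profiles) + "\n")


def read_profile_matrix(path) -> list:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    universe = tuple(str(i) for i in df.index)
    return [
        PathwayProfile(disease_label=str(col), pathway_ids=universe, bits=tuple(int(v) for v in df[col]))
        for col in df.columns
    ]
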