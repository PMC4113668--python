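"""Synthetic tumor/normal cohorts with planted pathway perturbations.

The generator emulates the statistical structure the profile analysis
assumes: a gene universe partitioned into (overlapping) pathways, one
normal cohort, and per-subtype tumor cohorts in which every pathway of a
shared set (a CEP-like core common to all subtypes) plus a
subtype-specific set has a fraction of its genes mean-shifted.  Shifts
are constant across the tumor samples of a subtype — a fixed
differential-expression signal, matching the two-phenotype contrast the
enrichment stage tests — with Rademacher sign per gene, so dysregulation
in either direction must be detected.  Clinical annotations are emitted
consistent with each subtype so the classification cascade can be tested
against planted labels.  The planted truth object supports recovery
scoring for every downstream stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datasets import ExpressionDataset
from .pathways import Pathway, PathwayCollection
from .subtyping import ClinicalRecord, SUBTYPES

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_pathways",
    "simulate_cohort",
    "simulate_study",
    "write_truth_json",
    "read_truth_json",
]

# Clinical annotation templates consistent with each subtype.
_CLINICAL_TEMPLATE = {
    "LuminalA": dict(er_ihc="positive", pr_ihc="positive", her2_ihc="negative",
                     her2_fish="negative", pam50="LumA"),
    "LuminalB": dict(er_ihc="positive", pr_ihc="positive", her2_ihc="negative",
                     her2_fish="negative", pam50="LumB"),
    "TripleNegative": dict(er_ihc="negative", pr_ihc="negative", her2_ihc="negative",
                           her2_fish="negative", pam50="Basal"),
    "HER2pos": dict(er_ihc="negative", pr_ihc="negative", her2_ihc="positive",
                    her2_fish="positive", pam50="Her2"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults mirror the conditions the analysis is evaluated under: 175
    pathways of 16-60 genes over a 10000-gene universe, 50 tumor samples
    per subtype against 50 shared normals, a 28-pathway shared
    (CEP-like) perturbed core plus 4/2/4/7 subtype-specific pathways,
    and a mean shift of 2 noise SDs applied to half of each perturbed
    pathway's genes.  ``baseline_mean`` is on a log2-expression-like
    scale; ``noise_sd`` sets the per-gene measurement spread.
    """

    n_genes: int = 10000
    n_pathways: int = 175
    pathway_size_range: tuple = (16, 60)
    n_tumor_per_subtype: int = 50
    n_normal: int = 50
    subtypes: tuple = SUBTYPES
    n_shared_perturbed: int = 28
    n_specific_perturbed: Mapping[str, int] | int = field(
        default_factory=lambda: {"LuminalA": 4, "LuminalB": 2, "TripleNegative": 4, "HER2pos": 7}
    )
    core_fraction: float = 0.6
    effect_size: float = 2.0
    responsive_fraction: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    missing_rate: float = 0.0
    seed: int = 0

    def specific_counts(self) -> dict:
        if isinstance(self.n_specific_perturbed, int):
            return {s: self.n_specific_perturbed for s in self.subtypes}
        counts = dict(self.n_specific_perturbed)
        missing = [s for s in self.subtypes if s not in counts]
        if missing:
            raise ValueError(f"n_specific_perturbed lacks subtypes: {missing}")
        return {s: counts[s] for s in self.subtypes}

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("pathway_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("pathway_size_range max exceeds n_genes")
        if not self.subtypes:
            raise ValueError("at least one subtype required")
        total = self.n_shared_perturbed + sum(self.specific_counts().values())
        if total > self.n_pathways:
            raise ValueError(
                f"{total} perturbed pathways requested but only {self.n_pathways} exist"
            )
        if not (0 < self.responsive_fraction <= 1):
            raise ValueError("responsive_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.core_fraction <= 1):
            raise ValueError("core_fraction must be in [0, 1]")
        max_core_total = self.n_pathways * math.ceil(self.core_fraction * hi)
        if max_core_total > self.n_genes:
            raise ValueError(
                f"core allocation may need up to {max_core_total} genes "
                f"but only {self.n_genes} exist; lower core_fraction or pathway sizes"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth: which pathways and genes were perturbed.

    ``shifted_genes`` maps (subtype, gene) -> signed shift in log-units;
    every shifted gene belongs to at least one perturbed pathway for
    that subtype, and the specific sets are pairwise disjoint and
    disjoint from the shared set.
    """

    shared_perturbed: set
    specific_perturbed: dict
    shifted_genes: dict

    def perturbed_for(self, subtype: str) -> set:
        return set(self.shared_perturbed) | set(self.specific_perturbed.get(subtype, set()))


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_pathways(config: SimulationConfig, rng: np.random.Generator | None = None) -> PathwayCollection:
    """Draw ``n_pathways`` gene sets over the simulated universe.

    Sizes are uniform over ``pathway_size_range``.  Each pathway is a
    pathway-exclusive core (a ``core_fraction`` share of its genes,
    disjoint across pathways) plus a periphery sampled without
    replacement from the genes outside every core, so pathways overlap
    through their peripheries the way real pathways share crosstalk
    genes while keeping dedicated members.  With ``core_fraction=0``
    this degenerates to fully random, freely overlapping sets.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = np.array(_gene_names(config.n_genes))
    lo, hi = config.pathway_size_range
    width = max(4, len(str(config.n_pathways)))

    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_pathways)]
    core_sizes = [math.ceil(config.core_fraction * s) for s in sizes]
    shuffled = rng.permutation(genes)
    offset = 0
    cores = []
    for c in core_sizes:
        cores.append(shuffled[offset : offset + c])
        offset += c
    shared_pool = shuffled[offset:]

    pathways = []
    for i, (size, core) in enumerate(zip(sizes, cores), start=1):
        n_periph = size - len(core)
        periph = rng.choice(shared_pool, size=n_periph, replace=False) if n_periph else []
        pid = f"PW{i:0{width}d}"
        members = frozenset(core.tolist()) | frozenset(list(periph))
        pathways.append(Pathway(id=pid, name=f"Simulated pathway {i}", genes=members))
    return PathwayCollection(pathways)


def _pick_responsive(pathway: Pathway, n_pick: int, private_pool: set, rng: np.random.Generator) -> list:
    """Choose responsive genes, preferring genes exclusive to this pathway.

    Preferring genes that belong to no other pathway keeps the planted
    labels crisp: a shifted gene shared with another pathway genuinely
    perturbs that pathway too — in another subtype's contrast if it is
    planted elsewhere, in every contrast if it is unplanted — and
    "false positive" stops being well defined for recovery scoring.
    """
    members = sorted(pathway.genes)
    private = [g for g in members if g in private_pool]
    rest = [g for g in members if g not in private_pool]
    rng.shuffle(private)
    rng.shuffle(rest)
    chosen = (private + rest)[:n_pick]
    return chosen


def simulate_cohort(
    config: SimulationConfig,
    collection: PathwayCollection,
    rng: np.random.Generator | None = None,
):
    """Simulate per-subtype tumor cohorts against one shared normal cohort.

    Returns ``(datasets, truth, clinical)`` where ``datasets`` maps each
    subtype to an :class:`ExpressionDataset` holding that subtype's
    tumors plus the shared normals, ``truth`` is the planted
    :class:`SyntheticTruth`, and ``clinical`` is a list of
    :class:`ClinicalRecord` for the tumor samples (annotations
    consistent with subtype, fields blanked at ``missing_rate``).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = _gene_names(config.n_genes)
    if not set(collection.universe) <= set(genes):
        raise ValueError("collection universe contains genes outside the simulated universe")

    ids = collection.ids
    specific_counts = config.specific_counts()
    n_planted = config.n_shared_perturbed + sum(specific_counts.values())
    planted = rng.choice(np.array(ids), size=n_planted, replace=False).tolist()
    shared = set(planted[: config.n_shared_perturbed])
    specific: dict = {}
    offset = config.n_shared_perturbed
    for s in config.subtypes:
        k = specific_counts[s]
        specific[s] = set(planted[offset : offset + k])
        offset += k

    # Genes that appear in exactly one pathway: preferred shift targets.
    membership_count: dict = {}
    for p in collection:
        for g in p.genes:
            membership_count[g] = membership_count.get(g, 0) + 1
    private_pool = {g for g, c in membership_count.items() if c == 1}

    gene_index = {g: i for i, g in enumerate(genes)}
    shift_sign = {}  # gene -> +1/-1, shared across subtypes for consistency
    shifted_genes: dict = {}
    shift_vectors: dict = {}
    for s in config.subtypes:
        vec = np.zeros(config.n_genes)
        for pid in sorted(shared | specific[s]):
            p = collection[pid]
            n_pick = max(1, math.ceil(config.responsive_fraction * p.size))
            for g in _pick_responsive(p, n_pick, private_pool, rng):
                if g not in shift_sign:
                    shift_sign[g] = 1 if rng.random() < 0.5 else -1
                delta = shift_sign[g] * config.effect_size * config.noise_sd
                shifted_genes[(s, g)] = delta
                vec[gene_index[g]] = delta
        shift_vectors[s] = vec

    normal_ids = [f"N{i:03d}" for i in range(1, config.n_normal + 1)]
    normal = rng.normal(config.baseline_mean, config.noise_sd, size=(config.n_genes, config.n_normal))

    datasets: dict = {}
    clinical: list = []
    for s in config.subtypes:
        tumor_ids = [f"T_{s}_{i:03d}" for i in range(1, config.n_tumor_per_subtype + 1)]
        tumor = rng.normal(config.baseline_mean, config.noise_sd, size=(config.n_genes, config.n_tumor_per_subtype))
        tumor += shift_vectors[s][:, None]
        values = np.concatenate([tumor, normal], axis=1)
        samples = tumor_ids + normal_ids
        group = {sid: "tumor" for sid in tumor_ids}
        group.update({sid: "normal" for sid in normal_ids})
        datasets[s] = ExpressionDataset(genes=list(genes), samples=samples, values=values, group=group)

        template = _CLINICAL_TEMPLATE.get(s)
        if template is None:
            raise ValueError(f"no clinical template for subtype {s!r}")
        for sid in tumor_ids:
            fields = dict(template)
            for key in ("er_ihc", "pr_ihc", "her2_ihc", "her2_fish"):
                if config.missing_rate and rng.random() < config.missing_rate:
                    fields[key] = "missing"
            clinical.append(ClinicalRecord(sample_id=sid, **fields))

    truth = SyntheticTruth(shared_perturbed=shared, specific_perturbed=specific, shifted_genes=shifted_genes)
    return datasets, truth, clinical


def simulate_study(config: SimulationConfig):
    """One-call generator: pathways + cohorts + truth from a single RNG stream.

    Identical configs give byte-identical downstream outputs.
    """
    rng = np.random.default_rng(config.seed)
    collection = simulate_pathways(config, rng)
    datasets, truth, clinical = simulate_cohort(config, collection, rng)
    return collection, datasets, truth, clinical


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "shared_perturbed": sorted(truth.shared_perturbed),
        "specific_perturbed": {s: sorted(v) for s, v in sorted(truth.specific_perturbed.items())},
        "shifted_genes": [
            {"subtype": s, "gene": g, "shift": delta}
            for (s, g), delta in sorted(truth.shifted_genes.items())
        ],
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> SyntheticTruth:
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        shared_perturbed=set(payload["shared_perturbed"]),
        specific_perturbed={s: set(v) for s, v in payload["specific_perturbed"].items()},
        shifted_genes={(d["subtype"], d["gene"]): d["shift"] for d in payload["shifted_genes"]},
    )
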