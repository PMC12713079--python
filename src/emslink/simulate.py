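"""Synthetic EMS mutant-population generator.

Ethyl methanesulfonate (EMS) mutagenesis produces sparse, near-random point
mutations, dominated by G/A and C/T transitions, scattered over the gene
space of every mutant line.  In an *indexed* library each line's full
mutation catalogue is known from sequencing, so genotype-phenotype lookups
are possible, but per-site minor-allele frequencies are tiny (well below
1%), which is what motivates gene-level collapsing downstream.

This module simulates such a population with known ground truth:

* :func:`simulate_genotypes` -- per-line mutation catalogues over a gene
  catalogue, with a configurable transition bias and a functional-impact
  class mixture (HIGH / MODERATE / LOW / MODIFIER, as a SnpEff-style
  annotation would assign);
* :func:`simulate_phenotypes` -- additive gene effects plus pairwise
  epistatic effects plus Gaussian noise, with wild-type reference rows;
* :func:`simulate_spikelet_profiles` -- per-line ordered spikelet
  measurements drawn from template trajectories, for the spike-geometry
  pipeline.

All generators are bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: Purine/pyrimidine transition partners; the canonical EMS change is
#: G->A on one strand (seen as C->T on the other).
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_BASES = np.array(["A", "C", "G", "T"])
_TRANSVERSION_ALTS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

#: Column order of a mutation table (one row per line x variant).
MUTATION_COLUMNS = [
    "line_id", "chrom", "pos", "ref", "alt",
    "gene_id", "impact", "qual", "depth",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: id, number of mutable sites, and 1-based span."""

    gene_id: str
    n_sites: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"{self.gene_id}: n_sites must be >= 1")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.gene_id}: invalid span {self.start}-{self.end}")
        if self.end - self.start + 1 < self.n_sites:
            raise ValueError(
                f"{self.gene_id}: span too short for {self.n_sites} distinct sites"
            )


def uniform_gene_catalogue(
    n_genes: int,
    sites_per_gene: int = 10,
    chrom: str = "chr1",
    gene_span: int | None = None,
    spacing: int = 1000,
) -> list[GeneModel]:
    """Evenly spaced, non-overlapping genes on one chromosome.

    Convenience constructor for desk-scale experiments; real analyses load
    gene models from GFF3 instead.
    """
    span = gene_span if gene_span is not None else max(sites_per_gene * 3, 30)
    genes = []
    pos = 1
    for i in range(n_genes):
        genes.append(
            GeneModel(f"G{i:05d}", sites_per_gene, chrom, pos, pos + span - 1)
        )
        pos += span + spacing
    return genes


@dataclass
class SimulationConfig:
    """Study conditions for one simulated EMS population.

    Defaults mirror a wheat-scale indexed EMS library: a mean of 4072
    mutations per line, an 88.9% G/A-C/T transition fraction, and a
    59.7% MODERATE-impact share (the remaining mass split evenly over the
    other three classes).  Desk-scale runs override
    ``mean_mutations_per_line`` and the catalogue size.
    """

    n_lines: int
    genes: list[GeneModel]
    mean_mutations_per_line: float = 4072.0
    transition_fraction: float = 0.889
    impact_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "MODERATE": 0.597,
            "HIGH": (1 - 0.597) / 3,
            "LOW": (1 - 0.597) / 3,
            "MODIFIER": (1 - 0.597) / 3,
        }
    )
    causal_effects: dict[str, float] = field(default_factory=dict)
    epistatic_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 0.0
    n_wildtype: int = 15
    fixed_mutation_count: bool = False
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not self.genes:
            raise ValueError("gene catalogue is empty")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in catalogue")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValueError("transition_fraction must be in [0, 1]")
        if set(self.impact_mixture) != set(IMPACT_CLASSES):
            raise ValueError(f"impact_mixture must cover exactly {IMPACT_CLASSES}")
        total = sum(self.impact_mixture.values())
        if any(v < 0 or v > 1 for v in self.impact_mixture.values()):
            raise ValueError("impact_mixture proportions must be in [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"impact_mixture sums to {total}, expected 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        known = set(ids)
        for gid in self.causal_effects:
            if gid not in known:
                raise ValueError(f"causal gene {gid!r} not in catalogue")
        for gi, gj, _ in self.epistatic_pairs:
            if gi not in known or gj not in known:
                raise ValueError(f"epistatic pair ({gi}, {gj}) not in catalogue")
        total_sites = sum(g.n_sites for g in self.genes)
        if self.mean_mutations_per_line > total_sites:
            raise ValueError(
                f"mean_mutations_per_line ({self.mean_mutations_per_line}) exceeds "
                f"the {total_sites} available sites"
            )

    @property
    def total_sites(self) -> int:
        return sum(g.n_sites for g in self.genes)


def _build_site_catalogue(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place distinct sites in each gene and fix their ref/alt and impact.

    Site identity is (chrom, pos, alt); properties are assigned once at the
    catalogue level so that two lines hitting the same site always agree on
    the allele and annotation, as a VCF requires.  Cross-gene position
    collisions (overlapping spans) are resolved by re-draw.
    """
    chroms, positions, gene_ids = [], [], []
    used: set[tuple[str, int]] = set()
    for gene in config.genes:
        span = np.arange(gene.start, gene.end + 1)
        avail = np.array([p for p in span if (gene.chrom, int(p)) not in used])
        if len(avail) < gene.n_sites:
            raise ValueError(f"{gene.gene_id}: not enough free positions in span")
        chosen = np.sort(rng.choice(avail, size=gene.n_sites, replace=False))
        for p in chosen:
            used.add((gene.chrom, int(p)))
        chroms.extend([gene.chrom] * gene.n_sites)
        positions.extend(int(p) for p in chosen)
        gene_ids.extend([gene.gene_id] * gene.n_sites)

    n = len(positions)
    is_transition = rng.random(n) < config.transition_fraction
    ref = rng.choice(_BASES, size=n)
    alt = np.empty(n, dtype=object)
    pick = rng.integers(0, 2, size=n)  # which transversion partner
    for i in range(n):
        r = ref[i]
        if is_transition[i]:
            alt[i] = TRANSITION_PARTNER[r]
        else:
            alt[i] = _TRANSVERSION_ALTS[r][pick[i]]

    classes = list(IMPACT_CLASSES)
    probs = [config.impact_mixture[c] for c in classes]
    impact = rng.choice(classes, size=n, p=probs)

    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "gene_id": gene_ids,
            "impact": impact,
        }
    )


def simulate_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-line mutation catalogues.

    Per-line mutation counts are Poisson with the configured mean (or fixed
    at the mean when ``fixed_mutation_count`` is set); each line's mutations
    are placed uniformly without replacement over the site catalogue.

    Returns a mutation table (one row per line x variant) with columns
    :data:`MUTATION_COLUMNS`, sorted by (line_id, chrom, pos).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sites = _build_site_catalogue(config, rng)
    n_sites = len(sites)

    line_ids = [f"L{i:04d}" for i in range(config.n_lines)]
    if config.fixed_mutation_count:
        counts = np.full(config.n_lines, int(round(config.mean_mutations_per_line)))
    else:
        counts = rng.poisson(config.mean_mutations_per_line, size=config.n_lines)
    counts = np.minimum(counts, n_sites)

    frames = []
    for line_id, m in zip(line_ids, counts):
        if m == 0:
            continue
        idx = rng.choice(n_sites, size=int(m), replace=False)
        idx.sort()
        sub = sites.iloc[idx].copy()
        sub.insert(0, "line_id", line_id)
        sub["qual"] = np.round(rng.uniform(60.0, 2000.0, size=int(m)), 1)
        sub["depth"] = rng.poisson(20.0, size=int(m)) + 5
        frames.append(sub)

    if not frames:
        table = pd.DataFrame(columns=MUTATION_COLUMNS)
    else:
        table = pd.concat(frames, ignore_index=True)[MUTATION_COLUMNS]
    table = table.sort_values(["line_id", "chrom", "pos"], kind="mergesort")
    return table.reset_index(drop=True)


def gene_presence(mutations: pd.DataFrame, gene_ids: list[str],
                  line_ids: list[str]) -> pd.DataFrame:
    """0/1 gene x line presence matrix from a mutation table."""
    hit = mutations.dropna(subset=["gene_id"]).drop_duplicates(["gene_id", "line_id"])
    pres = (
        pd.crosstab(hit["gene_id"], hit["line_id"])
        .reindex(index=gene_ids, columns=line_ids, fill_value=0)
        .astype(np.int8)
    )
    pres.index.name = "gene_id"
    pres.columns.name = "line_id"
    return pres


def simulate_phenotypes(mutations: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Phenotypes from additive burden, pairwise epistasis, and noise.

    For line *l* with per-gene mutation counts ``c[g, l]``::

        y_l = baseline + sum_g effect_g * c[g, l]
                       + sum_(i,j) eps_ij * 1[c[i,l]>0] * 1[c[j,l]>0]
                       + N(0, noise_sd^2)

    Wild-type reference rows carry zero mutations by construction and are
    appended with ``is_wt = True``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    line_ids = [f"L{i:04d}" for i in range(config.n_lines)]

    y = pd.Series(config.baseline, index=pd.Index(line_ids, name="line_id"),
                  dtype=float)

    needed = set(config.causal_effects)
    for gi, gj, _ in config.epistatic_pairs:
        needed.update((gi, gj))
    if needed and len(mutations):
        sub = mutations[mutations["gene_id"].isin(needed)]
        counts = (
            sub.groupby(["gene_id", "line_id"], observed=True).size()
            .unstack(fill_value=0)
            .reindex(index=sorted(needed), columns=line_ids, fill_value=0)
        )
    else:
        counts = pd.DataFrame(0, index=sorted(needed), columns=line_ids)

    for gid, eff in config.causal_effects.items():
        y += eff * counts.loc[gid]
    for gi, gj, eps in config.epistatic_pairs:
        y += eps * ((counts.loc[gi] > 0) & (counts.loc[gj] > 0)).astype(float)
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=len(y))

    wt_ids = [f"WT{i:03d}" for i in range(config.n_wildtype)]
    wt_y = np.full(config.n_wildtype, config.baseline)
    if config.noise_sd > 0 and config.n_wildtype:
        wt_y = wt_y + rng.normal(0.0, config.noise_sd, size=config.n_wildtype)

    out = pd.DataFrame(
        {
            "line_id": line_ids + wt_ids,
            config.trait_name: np.concatenate([y.to_numpy(), wt_y]),
            "is_wt": [False] * len(line_ids) + [True] * len(wt_ids),
        }
    )
    return out


def simulate_spikelet_profiles(
    n_lines: int,
    templates: list[np.ndarray],
    proportions: list[float],
    noise_sd: float,
    seed: int,
    n_spikelets_range: tuple[int, int] = (15, 24),
    trait_name: str = "angle",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-line ordered spikelet measurements from template trajectories.

    Each template is a trajectory sampled at the 21 standard nodes 0..20
    (bottom to top of the spike).  Every line draws a template according to
    ``proportions``, a spikelet count uniform in ``n_spikelets_range``, and
    measurement values by linear interpolation of its template at the
    line's normalized positions plus N(0, noise_sd^2) noise.

    Returns the long-form measurement table (line_id, spikelet_index,
    <trait>) and the ground-truth template label per line.
    """
    templates = [np.asarray(t, dtype=float) for t in templates]
    for t in templates:
        if t.shape != (21,):
            raise ValueError("each template must have exactly 21 node values")
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(templates):
        raise ValueError("one proportion per template required")
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("proportions must be non-negative and sum to 1")
    lo, hi = n_spikelets_range
    if lo < 5:
        raise ValueError("minimum spikelet count must be >= 5")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    nodes = np.arange(21, dtype=float)
    rows = []
    labels = {}
    for i in range(n_lines):
        line_id = f"L{i:04d}"
        label = int(rng.choice(len(templates), p=props))
        labels[line_id] = label
        n = int(rng.integers(lo, hi + 1))
        positions = 20.0 * np.arange(n) / (n - 1)
        values = np.interp(positions, nodes, templates[label])
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=n)
        for j, v in enumerate(values, start=1):
            rows.append((line_id, j, v))

    table = pd.DataFrame(rows, columns=["line_id", "spikelet_index", trait_name])
    return table, pd.Series(labels, name="template")
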