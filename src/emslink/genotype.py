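"""Annotated-VCF input, quality filtering, and population-frequency filtering.

In an indexed EMS library every line is sequenced against the common
reference background, so a mutation seen independently in many lines is far
more likely a systematic artifact (alignment error, residual heterogeneity
of the parent) than a recurrent EMS hit.  The filter stack here follows
that logic:

1. :func:`filter_by_quality` -- drop records failing QUAL/depth floors
   (defaults: QUAL >= 50, DP >= 5);
2. :func:`null_frequency_threshold` -- estimate, by shuffling each line's
   mutations over site positions, how often a site would be shared among
   lines by chance alone, and derive a population-frequency cutoff from the
   upper tail of that null;
3. :func:`filter_by_population_frequency` -- remove every site whose
   carrier frequency strictly exceeds the cutoff (all lines' records at the
   site are removed together).

Mutation tables are pandas DataFrames with the columns in
:data:`~emslink.simulate.MUTATION_COLUMNS`; site identity is
(chrom, pos, alt), coordinates 1-based per VCF convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .simulate import MUTATION_COLUMNS, TRANSITION_PARTNER

logger = logging.getLogger(__name__)

#: SnpEff-style impact severity, most severe first.
IMPACT_SEVERITY = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}

SITE_KEY = ["chrom", "pos", "alt"]


@dataclass
class FrequencyThreshold:
    """A permutation-derived population-frequency cutoff.

    ``null_samples`` holds one upper-tail summary per permutation: the
    ``per_perm_tail``-th largest per-site null frequency (i.e. the smallest
    frequency inside the retained extreme block).  The cutoff is the
    ``rank``-th largest of those summaries, so rank 5 of 1000 permutations
    corresponds to an empirical tail level of 5/1000.
    """

    threshold: float
    n_perm: int
    per_perm_tail: int
    rank: int
    null_samples: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# VCF I/O


def _severest(annotations: list[tuple[str | None, str]]) -> tuple[str | None, str]:
    """Pick (gene_id, impact) with the most severe impact; ties keep first."""
    return min(annotations, key=lambda a: IMPACT_SEVERITY.get(a[1], 99))


def read_annotated_vcf(path: str, site_gene_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a multi-sample annotated VCF into a mutation table.

    One record is emitted per (sample, variant) with a non-reference
    genotype.  Gene id and impact come from the SnpEff-style ``ANN`` INFO
    field (``Allele|Annotation|Impact|Gene``); when a variant carries
    several annotations the most severe impact is kept.  If the VCF has no
    ``ANN`` field a ``site_gene_map`` DataFrame with columns
    (chrom, pos, gene_id, impact) must be supplied.
    """
    if site_gene_map is not None:
        map_idx = site_gene_map.set_index(["chrom", "pos"])

    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            gene_id, impact = None, "MODIFIER"
            ann = rec.info.get("ANN") if "ANN" in rec.info else None
            if ann is not None:
                if isinstance(ann, str):
                    ann = (ann,)
                parsed = []
                for entry in ann:
                    parts = entry.split("|")
                    if len(parts) >= 4:
                        parsed.append((parts[3] or None, parts[2]))
                if parsed:
                    gene_id, impact = _severest(parsed)
            elif site_gene_map is not None:
                key = (rec.chrom, rec.pos)
                if key in map_idx.index:
                    hit = map_idx.loc[key]
                    gene_id = hit["gene_id"]
                    impact = hit.get("impact", "MODIFIER")
            else:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos} has no ANN annotation and no "
                    "site->gene map was supplied"
                )
            depth = rec.info.get("DP") if "DP" in rec.info else None
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or not any(a not in (0, None) for a in gt):
                    continue
                rows.append(
                    (sample, rec.chrom, rec.pos, rec.ref, alt, gene_id,
                     impact, rec.qual, depth)
                )

    table = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    table = table.sort_values(["line_id", "chrom", "pos"], kind="mergesort")
    return table.reset_index(drop=True)


def write_vcf(table: pd.DataFrame, path: str, line_ids: list[str] | None = None) -> None:
    """Write a mutation table as a multi-sample VCF 4.2.

    One sample column per line (GT 0/1 for carriers, 0/0 otherwise), with
    ``ANN`` carrying ``alt|simulated|impact|gene`` and ``DP`` the median
    depth over carriers of the site.
    """
    if line_ids is None:
        line_ids = sorted(table["line_id"].unique())

    header = pysam.VariantHeader()
    header.add_meta("source", "emslink")
    for chrom in sorted(table["chrom"].unique()):
        length = int(table.loc[table["chrom"] == chrom, "pos"].max()) + 1000
        header.contigs.add(chrom, length=length)
    header.add_meta(
        "INFO",
        items=[("ID", "ANN"), ("Number", "."), ("Type", "String"),
               ("Description", "Functional annotations: Allele|Annotation|Impact|Gene")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Combined depth")],
    )
    header.formats.add("GT", 1, "String", "Genotype")
    for line_id in line_ids:
        header.add_sample(line_id)

    grouped = table.groupby(["chrom", "pos", "alt"], sort=True)
    with pysam.VariantFile(path, "w", header=header) as out:
        for (chrom, pos, alt), grp in grouped:
            rec = out.new_record(
                contig=chrom, start=int(pos) - 1, alleles=(grp["ref"].iloc[0], alt)
            )
            rec.qual = float(grp["qual"].median())
            gene = grp["gene_id"].iloc[0]
            impact = grp["impact"].iloc[0]
            rec.info["ANN"] = f"{alt}|simulated|{impact}|{gene if pd.notna(gene) else ''}"
            if grp["depth"].notna().any():
                rec.info["DP"] = int(grp["depth"].median())
            carriers = set(grp["line_id"])
            for line_id in line_ids:
                rec.samples[line_id]["GT"] = (0, 1) if line_id in carriers else (0, 0)
            out.write(rec)


# ---------------------------------------------------------------------------
# Filters


def filter_by_quality(table: pd.DataFrame, min_qual: float = 50.0,
                      min_depth: int = 5) -> pd.DataFrame:
    """Keep records with qual >= min_qual and depth >= min_depth.

    Records with missing qual or depth fail the filter (counted in the log).
    """
    if table.empty:
        return table.copy()
    qual = pd.to_numeric(table["qual"], errors="coerce")
    depth = pd.to_numeric(table["depth"], errors="coerce")
    keep = (qual >= min_qual) & (depth >= min_depth)
    n_missing = int(qual.isna().sum() + depth.isna().sum())
    if n_missing:
        logger.info("quality filter: %d records with missing qual/depth removed", n_missing)
    logger.info("quality filter: %d of %d records retained", int(keep.sum()), len(table))
    return table.loc[keep.fillna(False)].reset_index(drop=True)


def site_mutation_frequency(table: pd.DataFrame, n_lines: int) -> pd.Series:
    """Per-site carrier frequency: distinct carrier lines / n_lines."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if table.empty:
        return pd.Series(dtype=float)
    carriers = (
        table.drop_duplicates(["line_id", *SITE_KEY])
        .groupby(SITE_KEY, sort=True)
        .size()
    )
    return carriers / n_lines


def filter_by_population_frequency(table: pd.DataFrame, threshold: float,
                                   n_lines: int | None = None) -> pd.DataFrame:
    """Remove all records at sites with carrier frequency > threshold.

    The comparison is strictly greater: a site exactly at the threshold is
    retained.  ``n_lines`` defaults to the number of distinct lines present
    in the table.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if table.empty:
        return table.copy()
    if n_lines is None:
        n_lines = table["line_id"].nunique()
    freq = site_mutation_frequency(table, n_lines)
    bad = freq[freq > threshold].index
    key = pd.MultiIndex.from_frame(table[SITE_KEY])
    keep = ~key.isin(bad)
    logger.info(
        "frequency filter (> %.4g): removed %d sites, %d of %d records retained",
        threshold, len(bad), int(keep.sum()), len(table),
    )
    return table.loc[keep].reset_index(drop=True)


def null_frequency_threshold(
    table: pd.DataFrame,
    n_lines: int,
    n_perm: int = 1000,
    per_perm_tail: int = 500,
    rank: int = 5,
    seed: int = 0,
    n_sites: int | None = None,
) -> FrequencyThreshold:
    """Permutation null for the site-sharing frequency cutoff.

    Each permutation reassigns every line's mutations uniformly at random
    over the site catalogue (preserving each line's mutation count),
    recomputes per-site carrier frequencies, and retains one upper-tail
    summary: the ``per_perm_tail``-th largest per-site frequency.  The
    returned cutoff is the ``rank``-th largest summary across the
    ``n_perm`` permutations.  ``n_sites`` sets the catalogue size and
    defaults to the number of distinct sites observed in the table.
    """
    if rank > n_perm:
        raise ValueError("rank cannot exceed n_perm")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if table.empty:
        return FrequencyThreshold(0.0, n_perm, per_perm_tail, rank,
                                  np.zeros(n_perm), seed)

    observed = len(table.drop_duplicates(SITE_KEY))
    if n_sites is None:
        n_sites = observed
    elif n_sites < observed:
        raise ValueError("n_sites smaller than the number of observed sites")
    line_counts = (
        table.drop_duplicates(["line_id", *SITE_KEY]).groupby("line_id").size()
    ).to_numpy()
    k = min(per_perm_tail, n_sites)

    summaries = np.empty(n_perm)
    for p in range(n_perm):
        counts = _permuted_site_counts(rng, line_counts, n_sites)
        freq = counts / n_lines
        # k-th largest frequency = smallest value in the retained tail block
        summaries[p] = np.partition(freq, n_sites - k)[n_sites - k]

    order = np.sort(summaries)[::-1]
    return FrequencyThreshold(float(order[rank - 1]), n_perm, per_perm_tail,
                              rank, summaries, seed)


def _permuted_site_counts(rng: np.random.Generator, line_counts: np.ndarray,
                          n_sites: int) -> np.ndarray:
    """Carrier count per site after shuffling each line's mutations.

    Each line keeps its mutation count and draws that many distinct sites
    uniformly; counts across lines accumulate.
    """
    counts = np.zeros(n_sites, dtype=np.int64)
    for m in line_counts:
        idx = rng.choice(n_sites, size=int(min(m, n_sites)), replace=False)
        counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# Descriptive statistics


def ems_transition_fraction(table: pd.DataFrame) -> float:
    """Fraction of distinct sites that are canonical EMS transitions.

    The transition set is G->A, A->G, C->T, T->C.  Sites with non-ACGT
    alleles are skipped with a warning.
    """
    sites = table.drop_duplicates(SITE_KEY)
    if sites.empty:
        return float("nan")
    valid = sites["ref"].isin(TRANSITION_PARTNER) & sites["alt"].isin(TRANSITION_PARTNER)
    n_skipped = int((~valid).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} sites with non-ACGT alleles skipped")
    sites = sites.loc[valid]
    if sites.empty:
        return float("nan")
    is_transition = sites["ref"].map(TRANSITION_PARTNER) == sites["alt"]
    return float(is_transition.mean())


# ---------------------------------------------------------------------------
# Site -> gene assignment


def load_site_gene_map(path: str) -> pd.DataFrame:
    """Read a site->gene TSV with columns chrom, pos, gene_id[, impact]."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"site->gene map must have columns {sorted(required)}")
    return df


def load_gene_catalogue_gff3(path: str) -> pd.DataFrame:
    """Gene models (gene_id, chrom, start, end) from GFF3 gene features."""
    import pyranges as pr

    gr = pr.read_gff3(path)
    df = gr.df
    genes = df[df["Feature"] == "gene"]
    id_col = "ID" if "ID" in genes.columns else "gene_id"
    out = pd.DataFrame(
        {
            "gene_id": genes[id_col].astype(str),
            "chrom": genes["Chromosome"].astype(str),
            # pyranges stores 0-based half-open intervals
            "start": genes["Start"].astype(int) + 1,
            "end": genes["End"].astype(int),
        }
    )
    return out.reset_index(drop=True)


def assign_genes(table: pd.DataFrame, catalogue: pd.DataFrame) -> pd.DataFrame:
    """Fill gene_id by interval lookup against a gene catalogue.

    ``catalogue`` has columns (gene_id, chrom, start, end), 1-based
    inclusive.  Sites outside every gene get gene_id None.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, row in catalogue.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, row["gene_id"]
        )

    def lookup(chrom: str, pos: int) -> str | None:
        tree = trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        if not hits:
            return None
        return sorted(iv.data for iv in hits)[0]

    out = table.copy()
    out["gene_id"] = [
        lookup(c, int(p)) for c, p in zip(out["chrom"], out["pos"])
    ]
    return out
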